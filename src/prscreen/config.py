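"""Configuration objects for simulation and pipeline runs.

Both configs are plain dataclasses that round-trip losslessly through
YAML/JSON (sorted keys, so write->read->write is byte-identical).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

SCENARIOS = ("null", "pleiotropy", "structure", "disorder_to_trait", "trait_to_disorder")


@dataclass
class ScenarioConfig:
    """Generative parameters for one synthetic cohort.

    The five scenarios correspond to the alternative causal structures that
    can produce a polygenic-score/trait association: no relationship at all
    (``null``), horizontal pleiotropy through a latent mediator
    (``pleiotropy``), population structure with an environmental gradient
    (``structure``), a downstream effect of the disorder on the trait
    (``disorder_to_trait``), and the trait lying on the causal path to the
    disorder (``trait_to_disorder``).

    Liability is standardised: the heritable part contributes
    ``h2_liability`` of the variance and the residual tops it up to 1.
    """

    scenario: str = "null"
    n_individuals: int = 2000
    n_snps: int = 600
    ld_block_size: int = 10
    ld_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 30
    h2_liability: float = 0.3
    prevalence: float = 0.01
    n_subpops: int = 1
    fst: float = 0.0
    env_gradient: tuple[float, ...] | None = None
    env_liability_gradient: tuple[float, ...] | None = None
    trait_effect: float = 0.5
    misclassification_rate: float = 0.0
    medication_prob_slope: float = 2.0
    medication_trait_shift: float = 0.0
    seed: int = 0

    # secondary generative knobs (defaults = no effect)
    missing_rate: float = 0.0
    mediator_h2: float = 0.5
    trait_h2: float = 0.3
    trait_overlap: float = 0.5
    n_discovery: int = 100_000
    discovery_case_frac: float = 0.25
    n_control_traits: int = 0

    # migration / geography
    map_km: float = 500.0
    cell_km: float = 25.0
    n_urban_peaks: int = 5
    base_move_sd_km: float = 30.0
    migration_coupling: float = 0.0
    deprivation_trait_effect: float = 0.0
    deprivation_migration_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_individuals <= 0 or self.n_snps <= 0 or self.ld_block_size <= 0:
            raise ValueError("n_individuals, n_snps and ld_block_size must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ValueError("h2_liability must be in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.env_gradient is not None and len(self.env_gradient) != self.n_subpops:
            raise ValueError("env_gradient length must equal n_subpops")
        if (self.env_liability_gradient is not None
                and len(self.env_liability_gradient) != self.n_subpops):
            raise ValueError("env_liability_gradient length must equal n_subpops")
        if isinstance(self.env_liability_gradient, list):
            self.env_liability_gradient = tuple(self.env_liability_gradient)
        if not 0.0 <= self.misclassification_rate < 1.0:
            raise ValueError("misclassification_rate must be in [0, 1)")
        if isinstance(self.maf_range, list):
            self.maf_range = tuple(self.maf_range)
        if isinstance(self.env_gradient, list):
            self.env_gradient = tuple(self.env_gradient)

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


def _listify(obj):
    """Recursively turn tuples into lists so YAML/JSON dumps are canonical."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class RunConfig:
    """End-to-end pipeline settings with the published analysis defaults.

    Thresholds default to the values of the original screening analysis:
    variant missingness 0.02, MAF 0.01, HWE P 1e-8, sample missingness 0.01,
    kinship cutoff 0.088, clump r^2 0.1 in +/-250 kb windows, score inclusion
    P < 0.05 (genome-wide significance 5e-8), 20 PRS quantiles with the 11th
    as reference, 15 PCs (sensitivity rerun at 40).
    """

    genotypes: str | None = None
    sumstats: str | None = None
    phenotypes: str | None = None
    density_map: str | None = None
    out_dir: str = "prscreen_run"
    seed: int = 0

    # QC
    snp_missing_max: float = 0.02
    maf_min: float = 0.01
    hwe_p_min: float = 1e-8
    sample_missing_max: float = 0.01
    kinship_threshold: float = 0.088
    conjunctive_variant_filter: bool = False
    n_pcs: int = 15
    n_pcs_sensitivity: int = 40
    ancestry_k: int = 4

    # PRS
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    p_threshold: float = 0.05
    gw_threshold: float = 5e-8

    # screening / quantiles
    alpha: float = 0.05
    stringent_p: float = 1e-7
    n_quantiles: int = 20
    reference_quantile: int = 11

    base_covariates: tuple[str, ...] = ("age", "sex")
    extended_covariates: tuple[str, ...] = ("age", "sex", "deprivation", "education")

    scenario: ScenarioConfig | None = None

    def __post_init__(self) -> None:
        if isinstance(self.scenario, dict):
            self.scenario = ScenarioConfig.from_dict(self.scenario)
        if isinstance(self.base_covariates, list):
            self.base_covariates = tuple(self.base_covariates)
        if isinstance(self.extended_covariates, list):
            self.extended_covariates = tuple(self.extended_covariates)

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True, default_flow_style=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
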