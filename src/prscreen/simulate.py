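"""Synthetic cohort generator for polygenic-score screening analyses.

Generates LD-blocked biallelic genotypes with optional subpopulation
structure, a liability-threshold disorder, behavioural traits under five
alternative causal structures, diagnosis/medication labels, discovery-GWAS
summary statistics, and planar residence coordinates with a population
density raster.  Ground-truth generative quantities (per-SNP liability
effects, true pre-misclassification status, liabilities) are retained on the
cohort so recovery tests can compare estimates against truth.

Genotype model
--------------
Allele frequencies follow Balding-Nichols drift around an ancestral
frequency drawn uniformly from ``maf_range``: each subpopulation's frequency
is Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst``.  Within an LD block the
two haplotypes of each individual are thresholded AR(1) latent Gaussians
(lag-one correlation ``ld_rho``), which yields Hardy-Weinberg marginals with
tunable, measurable r^2 between neighbouring variants.

Disorder model
--------------
Standardised liability = genetic score (variance ``h2_liability``) +
scenario-specific contributions + Gaussian residual topped up to variance 1.
Cases are liabilities above the 1-``prevalence`` quantile.  The recorded
diagnosis optionally misclassifies a fraction of true cases as unaffected;
medication is sampled among diagnosed individuals with probability
increasing in liability.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .config import ScenarioConfig
from .migration import DensityMap

# unambiguous allele pairs (strand-resolvable); ambiguous A/T and C/G can be
# requested explicitly for harmonisation tests
_UNAMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass
class Cohort:
    """A simulated cohort with full generative ground truth.

    ``genotypes`` is an ``n_individuals x n_snps`` float matrix of effect
    allele dosages in {0, 1, 2} with NaN for missing calls.  ``diagnosed``
    is the recorded label (after misclassification); ``true_status`` the
    pre-misclassification case status.
    """

    genotypes: np.ndarray
    variant_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    config: ScenarioConfig
    liability: np.ndarray | None = None
    true_status: np.ndarray | None = None
    diagnosed: np.ndarray | None = None
    medicated: np.ndarray | None = None
    traits: pd.DataFrame | None = None
    locations: pd.DataFrame | None = None
    density_map: "object | None" = None
    allele_freqs: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]


def _block_bounds(n_snps: int, block_size: int) -> list[tuple[int, int]]:
    starts = list(range(0, n_snps, block_size))
    return [(s, min(s + block_size, n_snps)) for s in starts]


def simulate_genotypes(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> Cohort:
    """Draw LD-blocked dosages with optional Balding-Nichols structure.

    Blocks span ~100 kb (variants evenly spaced within a block) and
    successive blocks start 1 Mb apart, so the default +/-250 kb clumping
    window never straddles blocks.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range

    anc = rng.uniform(lo, hi, size=m)
    if config.n_subpops > 1 and config.fst > 0:
        F = config.fst
        a = anc * (1 - F) / F
        b = (1 - anc) * (1 - F) / F
        freqs = rng.beta(a, b, size=(config.n_subpops, m))
        freqs = np.clip(freqs, 1e-3, 1 - 1e-3)
    else:
        freqs = np.tile(anc, (max(config.n_subpops, 1), 1))

    subpop = rng.integers(0, max(config.n_subpops, 1), size=n)
    thresh = stats.norm.ppf(freqs)  # allele present if latent < threshold

    blocks = _block_bounds(m, config.ld_block_size)
    geno = np.empty((n, m), dtype=np.float64)
    rho = config.ld_rho
    innov = np.sqrt(1.0 - rho**2)
    for start, stop in blocks:
        w = stop - start
        # two haplotypes per individual, AR(1) latent along the block
        z = np.empty((n, 2, w))
        z[:, :, 0] = rng.standard_normal((n, 2))
        for j in range(1, w):
            z[:, :, j] = rho * z[:, :, j - 1] + innov * rng.standard_normal((n, 2))
        t = thresh[subpop, start:stop][:, None, :]  # (n, 1, w)
        geno[:, start:stop] = (z < t).sum(axis=1)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        geno[mask] = np.nan

    bp_step = 100_000 // config.ld_block_size
    bp = np.concatenate(
        [1_000_000 * i + 1 + bp_step * np.arange(stop - start)
         for i, (start, stop) in enumerate(blocks)]
    )
    pair_idx = rng.integers(0, len(_UNAMBIGUOUS_PAIRS), size=m)
    a1 = np.array([_UNAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_UNAMBIGUOUS_PAIRS[i][1] for i in pair_idx])
    variant_meta = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chr": 1,
            "bp": bp,
            "allele1": a1,
            "allele2": a2,
            "true_effect": 0.0,
        }
    )
    sample_meta = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:06d}" for i in range(n)],
            "age": rng.integers(38, 72, size=n).astype(float),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "deprivation": rng.standard_normal(n),
            "education": np.clip(rng.normal(13, 3, size=n), 7, 21),
            "subpop": subpop,
        }
    )
    # education mildly tracks (low) deprivation, as in real survey data
    sample_meta["education"] -= 1.0 * sample_meta["deprivation"]
    return Cohort(
        genotypes=geno,
        variant_meta=variant_meta,
        sample_meta=sample_meta,
        config=config,
        allele_freqs=freqs,
    )


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _genetic_score(geno: np.ndarray, weights_std: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Weighted sum over standardised dosages; missing treated as the mean."""
    p = freqs
    denom = np.sqrt(np.clip(2 * p * (1 - p), 1e-12, None))
    g = np.nan_to_num(geno - 2 * p, nan=0.0) / denom
    return g @ weights_std


def simulate_disorder(
    cohort: Cohort,
    rng: np.random.Generator | None = None,
    trait: np.ndarray | None = None,
    mediator: np.ndarray | None = None,
) -> Cohort:
    """Assign liabilities, case status, diagnosis labels and medication.

    ``trait`` is supplied for the trait->disorder scenario (it contributes
    ``trait_effect`` x standardised trait to liability); ``mediator`` for the
    pleiotropy scenario.  Per-SNP *total* liability effects (direct plus any
    mediated path) are written into ``variant_meta['true_effect']`` on the
    per-allele scale, which is what a discovery GWAS of the disorder would
    estimate.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n, m = cohort.genotypes.shape
    if not 0.0 <= cfg.h2_liability <= 1.0:
        raise ValueError("h2_liability must be in [0, 1]")

    if cfg.scenario == "trait_to_disorder" and "trait_effect_std" in cohort.variant_meta:
        # the disorder's direct causal set overlaps the trait's causal set
        trait_set = np.flatnonzero(cohort.variant_meta["trait_effect_std"].to_numpy())
        n_overlap = min(int(round(cfg.trait_overlap * cfg.n_causal)), len(trait_set))
        shared = rng.choice(trait_set, size=n_overlap, replace=False)
        rest_pool = np.setdiff1d(np.arange(m), trait_set)
        rest = rng.choice(rest_pool, size=cfg.n_causal - n_overlap, replace=False)
        causal = np.concatenate([shared, rest])
    else:
        causal = rng.choice(m, size=cfg.n_causal, replace=False)
    raw = rng.standard_normal(cfg.n_causal)
    w = np.zeros(m)
    w[causal] = raw
    pooled = np.nanmean(cohort.genotypes, axis=0) / 2.0
    pooled = np.clip(pooled, 1e-3, 1 - 1e-3)

    systematic = np.zeros(n)
    if cfg.h2_liability > 0:
        gs = _genetic_score(cohort.genotypes, w, pooled)
        sd = max(gs.std(), 1e-12)
        systematic = systematic + (gs - gs.mean()) / sd * np.sqrt(cfg.h2_liability)
        w_std = w * np.sqrt(cfg.h2_liability) / sd
    else:
        w_std = np.zeros(m)

    extra_effects = np.zeros(m)
    if cfg.scenario == "trait_to_disorder":
        if trait is None:
            raise ValueError("trait_to_disorder requires the trait to be simulated first")
        systematic = systematic + cfg.trait_effect * _standardise(trait)
        extra_effects = cfg.trait_effect * cohort.variant_meta["trait_effect_std"].to_numpy()
    elif cfg.scenario == "pleiotropy":
        if mediator is None:
            raise ValueError("pleiotropy requires the mediator to be simulated first")
        systematic = systematic + cfg.trait_effect * _standardise(mediator)
        extra_effects = cfg.trait_effect * cohort.variant_meta["mediator_effect_std"].to_numpy()
    elif cfg.scenario == "structure" and cfg.env_liability_gradient is not None:
        # location-varying environment raises disorder risk and the trait alike
        offs = np.asarray(cfg.env_liability_gradient, dtype=float)
        systematic = systematic + offs[cohort.sample_meta["subpop"].to_numpy()]

    var_sys = systematic.var()
    resid_sd = np.sqrt(max(1.0 - var_sys, 0.0))
    liability = systematic + resid_sd * rng.standard_normal(n)

    threshold = stats.norm.ppf(1.0 - cfg.prevalence)
    true_status = liability > threshold
    diagnosed = true_status.copy()
    if cfg.misclassification_rate > 0:
        flip = rng.random(n) < cfg.misclassification_rate
        diagnosed = diagnosed & ~flip

    medicated = np.zeros(n, dtype=bool)
    if diagnosed.any():
        case_liab = liability[diagnosed]
        centre = np.median(case_liab)
        p_med = expit(cfg.medication_prob_slope * (liability - centre))
        medicated = diagnosed & (rng.random(n) < p_med)

    # total per-allele liability effect = direct + mediated contribution
    denom = np.sqrt(np.clip(2 * pooled * (1 - pooled), 1e-12, None))
    cohort.variant_meta["true_effect"] = (w_std + extra_effects) / denom
    cohort.liability = liability
    cohort.true_status = true_status
    cohort.diagnosed = diagnosed
    cohort.medicated = medicated
    return cohort


def simulate_trait(
    cohort: Cohort,
    rng: np.random.Generator | None = None,
    n_control: int | None = None,
) -> Cohort:
    """Generate the scenario's behavioural trait (plus optional pure-noise
    control traits) into ``cohort.traits['trait']``.

    Scenario semantics: ``null`` is independent noise; ``pleiotropy`` drives
    the trait from a latent heritable mediator (which also feeds liability);
    ``structure`` offsets the trait mean by subpopulation only;
    ``disorder_to_trait`` shifts the trait by ``trait_effect`` in true
    (pre-misclassification) cases; ``trait_to_disorder`` gives the trait its
    own SNP effects overlapping the disorder's causal set.  Medicated
    individuals are additionally shifted by ``medication_trait_shift``.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n, m = cohort.genotypes.shape
    scen = cfg.scenario
    if scen not in ("null", "pleiotropy", "structure", "disorder_to_trait", "trait_to_disorder"):
        raise ValueError(f"unknown scenario {scen!r}")

    noise = rng.standard_normal(n)
    pooled = np.nanmean(cohort.genotypes, axis=0) / 2.0
    pooled = np.clip(pooled, 1e-3, 1 - 1e-3)

    if scen == "null":
        trait = noise
    elif scen == "structure":
        grads = cfg.env_gradient
        if grads is None:
            offs = np.arange(cfg.n_subpops, dtype=float)
            grads = tuple(offs - offs.mean())
        trait = np.asarray(grads)[cohort.sample_meta["subpop"].to_numpy()] + noise
    elif scen == "disorder_to_trait":
        if cohort.true_status is None:
            raise ValueError("disorder_to_trait requires simulate_disorder first")
        trait = noise + cfg.trait_effect * cohort.true_status.astype(float)
    elif scen == "pleiotropy":
        med_causal = rng.choice(m, size=cfg.n_causal, replace=False)
        wmed = np.zeros(m)
        wmed[med_causal] = rng.standard_normal(cfg.n_causal)
        mg = _genetic_score(cohort.genotypes, wmed, pooled)
        sd = max(mg.std(), 1e-12)
        wmed_std = wmed * np.sqrt(cfg.mediator_h2) / sd
        mediator = _standardise(mg) * np.sqrt(cfg.mediator_h2) + np.sqrt(
            1 - cfg.mediator_h2
        ) * rng.standard_normal(n)
        cohort.variant_meta["mediator_effect_std"] = wmed_std
        cohort._mediator = mediator  # type: ignore[attr-defined]
        trait = cfg.trait_effect * _standardise(mediator) + noise
    else:  # trait_to_disorder
        # the trait's causal set is drawn first; simulate_disorder later
        # draws a trait_overlap fraction of the disorder's direct causal set
        # from these indices
        tr_causal = rng.choice(m, size=cfg.n_causal, replace=False)
        wtr = np.zeros(m)
        wtr[tr_causal] = rng.standard_normal(cfg.n_causal)
        tg = _genetic_score(cohort.genotypes, wtr, pooled)
        sd = max(tg.std(), 1e-12)
        wtr_std = wtr * np.sqrt(cfg.trait_h2) / sd
        cohort.variant_meta["trait_effect_std"] = wtr_std
        trait = _standardise(tg) * np.sqrt(cfg.trait_h2) + np.sqrt(
            1 - cfg.trait_h2
        ) * rng.standard_normal(n)

    if cfg.deprivation_trait_effect != 0.0:
        trait = trait + cfg.deprivation_trait_effect * cohort.sample_meta["deprivation"].to_numpy()
    if cohort.medicated is not None and cfg.medication_trait_shift != 0.0:
        trait = trait + cfg.medication_trait_shift * cohort.medicated.astype(float)

    traits = cohort.traits if cohort.traits is not None else pd.DataFrame(index=range(n))
    traits = traits.copy()
    traits["trait"] = trait
    k = cfg.n_control_traits if n_control is None else n_control
    for i in range(k):
        traits[f"control_{i + 1}"] = rng.standard_normal(n)
    cohort.traits = traits
    return cohort


def _apply_medication_shift(cohort: Cohort) -> None:
    cfg = cohort.config
    if cfg.medication_trait_shift != 0.0 and cohort.medicated is not None:
        cohort.traits["trait"] = (
            cohort.traits["trait"].to_numpy()
            + cfg.medication_trait_shift * cohort.medicated.astype(float)
        )


def liability_to_log_or(beta_liab: np.ndarray, prevalence: float) -> np.ndarray:
    """Per-allele liability effect -> approximate log odds ratio.

    Uses the standard first-order liability/observed-scale conversion
    factor phi(t) / (K (1-K)) at threshold t = Phi^{-1}(1-K).
    """
    t = stats.norm.ppf(1.0 - prevalence)
    c = stats.norm.pdf(t) / (prevalence * (1.0 - prevalence))
    return np.asarray(beta_liab) * c


def generate_sumstats(
    cohort: Cohort,
    mode: str = "oracle",
    rng: np.random.Generator | None = None,
    discovery_cohort: Cohort | None = None,
) -> pd.DataFrame:
    """Emit discovery-GWAS summary statistics for the cohort's variants.

    ``oracle`` mode perturbs the true per-allele log odds ratios with the
    sampling noise implied by a nominal discovery sample (``n_discovery``
    individuals, ``discovery_case_frac`` cases); ``cohort_gwas`` runs an
    actual per-SNP logistic regression of case status on dosage in an
    independent simulated discovery cohort.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    vm = cohort.variant_meta

    if mode == "oracle":
        if "true_effect" not in vm or cohort.liability is None:
            raise ValueError("oracle mode requires simulated true effects")
        p = np.clip(np.nanmean(cohort.genotypes, axis=0) / 2.0, 1e-3, 1 - 1e-3)
        beta_true = liability_to_log_or(vm["true_effect"].to_numpy(), cfg.prevalence)
        y = cfg.discovery_case_frac
        info = cfg.n_discovery * y * (1 - y) * 2 * p * (1 - p)
        with np.errstate(divide="ignore"):
            se = np.where(info > 0, 1.0 / np.sqrt(info), np.inf)
        noise_sd = np.where(np.isfinite(se), se, 0.0)
        beta_hat = beta_true + noise_sd * rng.standard_normal(len(se))
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = np.where(se > 0, (beta_hat / se) ** 2, np.where(beta_hat == 0, 0.0, np.inf))
        pval = stats.chi2.sf(z2, df=1)
        # keep P in (0, 1]: exact zeros (se -> 0 limit) become the smallest float
        pval = np.clip(np.nan_to_num(pval, nan=1.0), np.nextafter(0, 1), 1.0)
    elif mode == "cohort_gwas":
        disc = discovery_cohort if discovery_cohort is not None else cohort
        if disc.diagnosed is None:
            raise ValueError("cohort_gwas mode requires a diagnosed discovery cohort")
        beta_hat, se, pval = _per_snp_logistic(disc.genotypes, disc.diagnosed.astype(float))
    else:
        raise ValueError(f"unknown sumstats mode {mode!r}")

    return pd.DataFrame(
        {
            "snp_id": vm["snp_id"],
            "chr": vm["chr"],
            "bp": vm["bp"],
            "effect_allele": vm["allele1"],
            "other_allele": vm["allele2"],
            "beta": beta_hat,
            "se": se,
            "p_value": pval,
        }
    )


def _per_snp_logistic(
    geno: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Newton-Raphson for intercept+dosage logistic per SNP.

    Missing dosages are mean-imputed per SNP.  Returns (beta, se, p) for the
    dosage term; non-converged or separated fits get se=inf, p=1.
    """
    n, m = geno.shape
    p = np.nanmean(geno, axis=0)
    x = np.where(np.isnan(geno), p, geno)
    b0 = np.zeros(m)
    b1 = np.zeros(m)
    yv = y[:, None]
    for _ in range(max_iter):
        eta = b0 + x * b1
        mu = expit(eta)
        wgt = mu * (1 - mu)
        g0 = (yv - mu).sum(axis=0)
        g1 = ((yv - mu) * x).sum(axis=0)
        h00 = wgt.sum(axis=0)
        h01 = (wgt * x).sum(axis=0)
        h11 = (wgt * x * x).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.nan_to_num(d0)
        d1 = np.nan_to_num(d1)
        b0 += d0
        b1 += d1
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < tol:
            break
    eta = b0 + x * b1
    mu = expit(eta)
    wgt = mu * (1 - mu)
    h00 = wgt.sum(axis=0)
    h01 = (wgt * x).sum(axis=0)
    h11 = (wgt * x * x).sum(axis=0)
    det = h00 * h11 - h01 * h01
    with np.errstate(divide="ignore", invalid="ignore"):
        var1 = h00 / det
    se = np.sqrt(np.where(var1 > 0, var1, np.inf))
    with np.errstate(invalid="ignore"):
        z = b1 / se
    pval = stats.chi2.sf(np.nan_to_num(z) ** 2, df=1)
    pval = np.clip(np.where(np.isfinite(se), pval, 1.0), np.nextafter(0, 1), 1.0)
    return b1, se, pval


def make_density_map(cfg: ScenarioConfig, rng: np.random.Generator) -> DensityMap:
    """Base rural density plus Gaussian urban peaks on a square map."""
    ncell = int(np.ceil(cfg.map_km / cfg.cell_km))
    centres = (np.arange(ncell) + 0.5) * cfg.cell_km
    xx, yy = np.meshgrid(centres, centres)
    dens = np.full((ncell, ncell), 50.0)
    for _ in range(cfg.n_urban_peaks):
        cx, cy = rng.uniform(0, cfg.map_km, size=2)
        amp = rng.uniform(1500, 4000)
        sd = rng.uniform(10, 30)
        dens += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd**2))
    return DensityMap(0.0, 0.0, cfg.cell_km, dens)


def simulate_locations(
    cohort: Cohort, rng: np.random.Generator | None = None
) -> Cohort:
    """Draw birth/current coordinates and a density raster.

    Birth locations are sampled proportionally to cell density (people live
    where people live); the displacement magnitude scales with
    ``exp(migration_coupling x standardised trait)`` and, when configured,
    with deprivation, so migration can be coupled to a risk-taking-like
    trait directly or through a deprivation confounder.  Years at current
    residence decline with distance moved.
    """
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 4) if rng is None else rng
    if cfg.migration_coupling != 0.0 and cohort.traits is None:
        raise ValueError("migration-trait coupling requires a simulated trait")
    n = cohort.n_individuals
    dmap = make_density_map(cfg, rng)

    ny, nx = dmap.values.shape
    probs = (dmap.values / dmap.values.sum()).ravel()
    cells = rng.choice(ny * nx, size=n, p=probs)
    iy, ix = np.divmod(cells, nx)
    birth_e = (ix + rng.random(n)) * dmap.cell_km
    birth_n = (iy + rng.random(n)) * dmap.cell_km

    logscale = np.zeros(n)
    if cfg.migration_coupling != 0.0:
        tr = _standardise(cohort.traits["trait"].to_numpy())
        logscale += cfg.migration_coupling * tr
    if cfg.deprivation_migration_effect != 0.0:
        logscale += cfg.deprivation_migration_effect * _standardise(
            cohort.sample_meta["deprivation"].to_numpy()
        )
    mag = np.abs(rng.normal(0.0, cfg.base_move_sd_km, size=n)) * np.exp(logscale)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    eps = 1e-6
    cur_e = np.clip(birth_e + mag * np.cos(theta), 0.0, dmap.x_max - eps)
    cur_n = np.clip(birth_n + mag * np.sin(theta), 0.0, dmap.y_max - eps)
    dist = np.hypot(cur_e - birth_e, cur_n - birth_n)
    years = np.clip(rng.normal(30.0 - 0.08 * dist, 6.0), 0.0, 60.0)

    cohort.locations = pd.DataFrame(
        {
            "birth_easting": birth_e,
            "birth_northing": birth_n,
            "current_easting": cur_e,
            "current_northing": cur_n,
            "years_at_residence": years,
        }
    )
    cohort.density_map = dmap
    return cohort


def subset_cohort(cohort: Cohort, idx) -> Cohort:
    """View of a cohort restricted to the given sample indices/mask.

    Used e.g. to split one simulated population into an independent
    discovery cohort (for ``cohort_gwas`` summary statistics) and a target
    cohort sharing the same allele-frequency structure.
    """
    idx = np.asarray(idx)
    take = (lambda a: None if a is None else a[idx])
    return Cohort(
        genotypes=cohort.genotypes[idx],
        variant_meta=cohort.variant_meta,
        sample_meta=cohort.sample_meta.iloc[idx].reset_index(drop=True),
        config=cohort.config,
        liability=take(cohort.liability),
        true_status=take(cohort.true_status),
        diagnosed=take(cohort.diagnosed),
        medicated=take(cohort.medicated),
        traits=None if cohort.traits is None else cohort.traits.iloc[idx].reset_index(drop=True),
        locations=None if cohort.locations is None else cohort.locations.iloc[idx].reset_index(drop=True),
        density_map=cohort.density_map,
        allele_freqs=cohort.allele_freqs,
    )


def simulate_cohort(config: ScenarioConfig, with_locations: bool = True) -> Cohort:
    """Full deterministic cohort build in scenario-appropriate order.

    trait->disorder simulates the trait before liability; disorder->trait
    the reverse; pleiotropy builds the mediator+trait first so the mediator
    can feed liability.  Identical config (including seed) yields an
    identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    cohort = simulate_genotypes(config, rng)
    scen = config.scenario
    if scen == "trait_to_disorder":
        simulate_trait(cohort, rng)
        simulate_disorder(cohort, rng, trait=cohort.traits["trait"].to_numpy())
        _apply_medication_shift(cohort)
    elif scen == "pleiotropy":
        simulate_trait(cohort, rng)
        simulate_disorder(cohort, rng, mediator=cohort._mediator)
        _apply_medication_shift(cohort)
    else:
        simulate_disorder(cohort, rng)
        simulate_trait(cohort, rng)
    if with_locations:
        simulate_locations(cohort, rng)
    return cohort
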