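"""Polygenic score construction from GWAS summary statistics.

Pipeline: harmonise discovery-study effect alleles against the target's
variant metadata (sign-flipping where the effect allele is the target's
other allele, dropping strand-ambiguous A/T and C/G pairs), greedily clump
to minimise linkage disequilibrium (r^2 >= 0.1 within +/-250 kb of each
index variant by default), keep index variants below the inclusion P-value
threshold (P < 0.05 for the best-fit profile, P < 5e-8 for the
genome-wide-significant profile), and score each individual as the sum of
effect-allele dosages weighted by the discovery log odds ratios.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class PRSProfile:
    """Per-sample polygenic score for one SNP-inclusion rule."""

    score: np.ndarray
    snp_set: list[str]
    p_threshold: float
    label: str  # "best_fit" or "gw_significant"


def harmonise(
    sumstats: pd.DataFrame,
    variant_meta: pd.DataFrame,
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join summary statistics onto target variants by SNP id.

    Returns ``(harmonised, exclusions)``.  In the harmonised frame ``beta``
    is oriented to the target's counted allele (allele1): records whose
    effect allele is the target's allele2 have beta negated exactly once and
    ``flipped=True``.  Exclusion reasons: ``duplicate``, ``ambiguous``,
    ``allele_mismatch``, ``not_in_target``.
    """
    ss = sumstats.copy()
    vm = variant_meta[["snp_id", "chr", "bp", "allele1", "allele2"]].copy()

    excl_rows = []
    dup_ss = ss["snp_id"].duplicated(keep=False)
    for sid in ss.loc[dup_ss, "snp_id"].unique():
        excl_rows.append({"snp_id": sid, "reason": "duplicate"})
    ss = ss[~dup_ss]
    dup_vm = vm["snp_id"].duplicated(keep=False)
    for sid in vm.loc[dup_vm, "snp_id"].unique():
        excl_rows.append({"snp_id": sid, "reason": "duplicate"})
    vm = vm[~dup_vm]

    missing = ~ss["snp_id"].isin(set(vm["snp_id"]))
    for sid in ss.loc[missing, "snp_id"]:
        excl_rows.append({"snp_id": sid, "reason": "not_in_target"})

    merged = ss.merge(vm, on="snp_id", how="inner", suffixes=("", "_target"))
    if merged.empty:
        raise ValueError("no summary-statistic variants match the target data")

    ea = merged["effect_allele"].to_numpy()
    oa = merged["other_allele"].to_numpy()
    a1 = merged["allele1"].to_numpy()
    a2 = merged["allele2"].to_numpy()

    ambiguous = np.array([frozenset({e, o}) in AMBIGUOUS for e, o in zip(ea, oa)])
    direct = (ea == a1) & (oa == a2)
    flip = (ea == a2) & (oa == a1)
    keep = (direct | flip) & ~(drop_ambiguous & ambiguous)

    for sid in merged.loc[drop_ambiguous & ambiguous & (direct | flip), "snp_id"]:
        excl_rows.append({"snp_id": sid, "reason": "ambiguous"})
    for sid in merged.loc[~(direct | flip), "snp_id"]:
        excl_rows.append({"snp_id": sid, "reason": "allele_mismatch"})

    out = merged.loc[keep, ["snp_id", "chr", "bp", "allele1", "allele2", "se", "p_value"]].copy()
    out["beta"] = np.where(flip[keep], -merged.loc[keep, "beta"], merged.loc[keep, "beta"])
    out["flipped"] = flip[keep]
    if out.empty:
        raise ValueError("harmonisation removed every variant")
    exclusions = pd.DataFrame(excl_rows, columns=["snp_id", "reason"])
    return out.reset_index(drop=True), exclusions


def _pairwise_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of one dosage vector against columns of Y;
    missing values mean-imputed, zero-variance pairs treated as r^2 = 0."""
    x = np.where(np.isnan(x), np.nanmean(x), x)
    Y = np.where(np.isnan(Y), np.nanmean(Y, axis=0), Y)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=0))
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / denom
    r = np.nan_to_num(r, nan=0.0)
    return r**2


def clump(
    stats: pd.DataFrame,
    ld_genotypes: np.ndarray,
    ld_variant_ids: "pd.Series | list[str]",
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping; returns index variant ids in selection order.

    Most significant first (ties by P, then bp, then id); each index claims
    all unclaimed variants on its chromosome within +/-``window_kb`` whose
    r^2 with it (computed from ``ld_genotypes`` dosages) is >= the
    threshold.
    """
    if stats["bp"].isna().any():
        raise ValueError("clumping requires bp positions for every variant")
    col_of = {sid: j for j, sid in enumerate(ld_variant_ids)}
    missing = [sid for sid in stats["snp_id"] if sid not in col_of]
    if missing:
        raise ValueError(f"LD source lacks variants: {missing[:5]}")

    df = stats.sort_values(["p_value", "bp", "snp_id"], kind="stable").reset_index(drop=True)
    bp = df["bp"].to_numpy(dtype=float)
    chrom = df["chr"].to_numpy()
    sids = df["snp_id"].to_numpy()
    cols = np.array([col_of[s] for s in sids])
    window = window_kb * 1000.0

    unclaimed = np.ones(len(df), dtype=bool)
    index_ids: list[str] = []
    for i in range(len(df)):
        if not unclaimed[i]:
            continue
        unclaimed[i] = False
        index_ids.append(sids[i])
        near = unclaimed & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window)
        if near.any():
            r2 = _pairwise_r2(ld_genotypes[:, cols[i]], ld_genotypes[:, cols[near]])
            claimed_idx = np.flatnonzero(near)[r2 >= r2_threshold]
            unclaimed[claimed_idx] = False
    return index_ids


def threshold(stats: pd.DataFrame, p_t: float = 0.05) -> pd.DataFrame:
    """Retain variants with P strictly below the inclusion threshold."""
    return stats[stats["p_value"] < p_t].reset_index(drop=True)


def score(
    genotypes: np.ndarray,
    stats: pd.DataFrame,
    variant_ids: "pd.Series | list[str]",
    standardise: bool = True,
    label: str = "best_fit",
    p_threshold: float = 0.05,
) -> PRSProfile:
    """Weighted allele-dosage sum over the harmonised, clumped, thresholded
    SNP subset.

    The contribution of a flipped SNP is beta_effect x (2 - dosage), i.e.
    the discovery effect allele's dosage; missing dosages are imputed with
    twice the sample effect-allele frequency.  With ``standardise`` the
    scores are zero-mean/unit-SD over the scored samples (the form used in
    downstream regressions).
    """
    if len(stats) == 0:
        raise ValueError("empty SNP subset")
    col_of = {sid: j for j, sid in enumerate(variant_ids)}
    cols = np.array([col_of[s] for s in stats["snp_id"]])
    G = np.asarray(genotypes, dtype=float)[:, cols]
    freq = np.nanmean(G, axis=0) / 2.0
    G = np.where(np.isnan(G), 2.0 * freq, G)
    w = stats["beta"].to_numpy(dtype=float)  # oriented to target allele1
    flipped = stats["flipped"].to_numpy(dtype=bool) if "flipped" in stats else np.zeros(len(w), bool)
    raw = G @ w - 2.0 * w[flipped].sum()  # constant restores effect-allele dosage
    if standardise:
        sd = raw.std()
        raw = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    return PRSProfile(score=raw, snp_set=list(stats["snp_id"]), p_threshold=p_threshold,
                      label=label)


class PRSBuilder(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: genotypes in, polygenic scores out.

    ``fit`` harmonises the supplied summary statistics against the target's
    variant metadata, clumps using the fit genotypes as the LD source and
    applies the P-value threshold; ``transform`` scores any genotype matrix
    with the same variant columns.  ``label='gw_significant'`` switches the
    inclusion threshold to ``gw_threshold`` (or an explicit sentinel-id
    list given via ``sentinel_ids``).
    """

    def __init__(
        self,
        p_threshold: float = 0.05,
        gw_threshold: float = 5e-8,
        r2_threshold: float = 0.1,
        window_kb: float = 250.0,
        drop_ambiguous: bool = True,
        standardise: bool = True,
        label: str = "best_fit",
    ):
        self.p_threshold = p_threshold
        self.gw_threshold = gw_threshold
        self.r2_threshold = r2_threshold
        self.window_kb = window_kb
        self.drop_ambiguous = drop_ambiguous
        self.standardise = standardise
        self.label = label

    def _effective_threshold(self) -> float:
        return self.gw_threshold if self.label == "gw_significant" else self.p_threshold

    def fit(self, X, y=None, *, sumstats: pd.DataFrame, variant_meta: pd.DataFrame,
            sentinel_ids: "list[str] | None" = None) -> "PRSBuilder":
        X = np.asarray(X, dtype=float)
        harm, excl = harmonise(sumstats, variant_meta, self.drop_ambiguous)
        self.harmonised_ = harm
        self.exclusions_ = excl
        vm_ids = variant_meta["snp_id"]
        self.variant_ids_ = list(vm_ids)
        col_of = {sid: j for j, sid in enumerate(vm_ids)}
        idx_ids = clump(harm, X, vm_ids, self.r2_threshold, self.window_kb)
        self.index_snps_ = idx_ids
        index_stats = harm[harm["snp_id"].isin(set(idx_ids))]
        if sentinel_ids is not None and self.label == "gw_significant":
            selected = index_stats[index_stats["snp_id"].isin(set(sentinel_ids))]
        else:
            selected = threshold(index_stats, self._effective_threshold())
        self.selected_ = selected.reset_index(drop=True)
        self._col_of = col_of
        return self

    def transform(self, X) -> np.ndarray:
        return self.score_profile(X).score.reshape(-1, 1)

    def score_profile(self, X) -> PRSProfile:
        check_is_fitted(self, "selected_")
        return score(
            np.asarray(X, dtype=float),
            self.selected_,
            self.variant_ids_,
            standardise=self.standardise,
            label=self.label,
            p_threshold=self._effective_threshold(),
        )
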