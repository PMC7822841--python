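"""Quantile-contrast analysis: PRS-bin trait trends in the undiagnosed
population with diagnosed case groups appended as extra quantiles.

The screened (undiagnosed) samples are split into 20 equal-count bins by
polygenic score; each trait is regressed on the bin indicators (11th bin as
reference) plus covariates, giving per-bin coefficients with 95% Wald
intervals.  Diagnosed individuals enter the same regression as extra factor
levels beyond the top bin — a single 21st group, or separate non-medicated
and medicated groups — reflecting their expectedly higher genetic burden.
A trend/case concordance label records whether each case group's trait
value lies in the direction the within-population trend predicts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

NON_MEDICATED = "non_medicated"
MEDICATED = "medicated"
CASES = "cases"


@dataclass
class QuantileTrend:
    """Per-bin coefficients (vs the reference bin) and appended case groups."""

    bins: pd.DataFrame            # columns: bin, n, coefficient, ci_low, ci_high
    groups: pd.DataFrame          # columns: group, n, coefficient, ci_low, ci_high
    reference: int
    trait: str = "trait"
    family: str = "linear"
    k: int = 20

    def to_frame(self) -> pd.DataFrame:
        b = self.bins.copy()
        b["group"] = b["bin"].astype(str)
        g = self.groups.copy()
        if len(g):
            g["bin"] = np.nan
        return pd.concat([b, g], ignore_index=True)[
            ["group", "bin", "n", "coefficient", "ci_low", "ci_high"]
        ]


def bin_by_prs(prs: np.ndarray, k: int = 20) -> np.ndarray:
    """Rank-based equal-count bins 1..k in ascending PRS order.

    Ties broken by stable sample order; bin sizes are floor/ceil(n/k)
    (differing by at most one, the first n % k bins larger).
    """
    prs = np.asarray(prs, dtype=float)
    if not np.isfinite(prs).all():
        raise ValueError("scores must be finite")
    n = len(prs)
    if n < k:
        raise ValueError(f"cannot form {k} bins from {n} samples")
    order = np.argsort(prs, kind="stable")
    base, rem = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:rem] += 1
    labels = np.empty(n, dtype=int)
    labels[order] = np.repeat(np.arange(1, k + 1), sizes)
    return labels


def _bin_design(bins: np.ndarray, levels: list, reference) -> tuple[np.ndarray, list]:
    keep = [lv for lv in levels if lv != reference]
    cols = [(np.asarray(bins, dtype=object) == lv).astype(float) for lv in keep]
    return (np.column_stack(cols) if cols else np.empty((len(bins), 0))), keep


def _fit(y, X, family):
    if family == "linear":
        return sm.OLS(y, X).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, X).fit(disp=0, maxiter=200)


def fit_trend(
    trait: np.ndarray,
    bins: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    reference: int = 11,
    family: str = "linear",
    trait_name: str = "trait",
    case_labels: np.ndarray | None = None,
) -> QuantileTrend:
    """Regress the trait on one-hot bin indicators plus covariates.

    The reference bin's coefficient is identically 0 with a zero-width CI.
    ``case_labels`` (same length, e.g. ``'non_medicated'``/``'medicated'``
    strings where diagnosed, NaN elsewhere) appends case groups as extra
    levels of the same regression.
    """
    y = np.asarray(trait, dtype=float)
    lab = np.asarray(bins, dtype=object).copy()
    if case_labels is not None:
        cl = np.asarray(case_labels, dtype=object)
        is_case = np.array([isinstance(v, str) for v in cl])
        lab[is_case] = cl[is_case]
    numeric_bins = sorted({lv for lv in lab if not isinstance(lv, str)})
    group_levels = [lv for lv in (NON_MEDICATED, MEDICATED, CASES) if (lab == lv).any()]
    levels = numeric_bins + group_levels
    if reference not in numeric_bins:
        raise ValueError(f"reference bin {reference} absent from data")

    C = None if covariates is None else np.asarray(covariates, dtype=float)
    ok = np.isfinite(y)
    if C is not None:
        if C.ndim == 1:
            C = C[:, None]
        ok &= np.isfinite(C).all(axis=1)
    y, lab = y[ok], lab[ok]
    if C is not None:
        C = C[ok]
    for lv in levels:
        if lv != reference and not (lab == lv).any():
            raise ValueError(f"bin/group {lv!r} is empty after missing-data deletion")

    D, kept = _bin_design(lab, levels, reference)
    X = np.column_stack([np.ones(len(y)), D])
    if C is not None and C.shape[1]:
        X = np.column_stack([X, C])
    res = _fit(y, X, family)
    coefs = res.params[1 : 1 + len(kept)]
    ses = res.bse[1 : 1 + len(kept)]
    z = sps.norm.ppf(0.975)

    rows_b, rows_g = [], []
    for lv, c, s in zip(kept, coefs, ses):
        row = {"n": int((lab == lv).sum()), "coefficient": float(c),
               "ci_low": float(c - z * s), "ci_high": float(c + z * s)}
        if isinstance(lv, str):
            rows_g.append({"group": lv, **row})
        else:
            rows_b.append({"bin": int(lv), **row})
    rows_b.append({"bin": int(reference), "n": int((lab == reference).sum()),
                   "coefficient": 0.0, "ci_low": 0.0, "ci_high": 0.0})
    bins_df = pd.DataFrame(rows_b).sort_values("bin").reset_index(drop=True)
    groups_df = pd.DataFrame(rows_g, columns=["group", "n", "coefficient", "ci_low", "ci_high"])
    return QuantileTrend(bins=bins_df, groups=groups_df, reference=reference,
                         trait=trait_name, family=family, k=len(numeric_bins))


def append_case_groups(
    trait: np.ndarray,
    prs_undiagnosed: np.ndarray,
    undiagnosed_mask: np.ndarray,
    medicated: np.ndarray | None = None,
    covariates: pd.DataFrame | np.ndarray | None = None,
    k: int = 20,
    reference: int = 11,
    family: str = "linear",
    trait_name: str = "trait",
    split_medication: bool = True,
) -> QuantileTrend:
    """Fit the 20-bin trend with diagnosed case groups as extra levels.

    ``trait`` and ``covariates`` cover the full cohort; the PRS bins are
    formed within the undiagnosed subset only (diagnosed individuals never
    occupy bins 1..k).  With ``split_medication`` and any medicated cases,
    two groups (non-medicated, medicated) are appended; otherwise a single
    21st group.  With zero diagnosed individuals the groups are omitted
    with a warning.
    """
    undiag = np.asarray(undiagnosed_mask, dtype=bool)
    n = len(undiag)
    lab = np.full(n, np.nan, dtype=object)
    lab[undiag] = bin_by_prs(np.asarray(prs_undiagnosed, dtype=float), k)
    diagnosed = ~undiag
    case_labels = np.full(n, np.nan, dtype=object)
    if not diagnosed.any():
        warnings.warn("no diagnosed individuals; case groups omitted")
    elif split_medication and medicated is not None and np.asarray(medicated).any():
        med = np.asarray(medicated, dtype=bool)
        case_labels[diagnosed & ~med] = NON_MEDICATED
        case_labels[diagnosed & med] = MEDICATED
    else:
        case_labels[diagnosed] = CASES

    use = undiag | np.array([isinstance(v, str) for v in case_labels])
    return fit_trend(
        np.asarray(trait, dtype=float)[use],
        lab[use],
        None if covariates is None else np.asarray(covariates, dtype=float)[use],
        reference=reference,
        family=family,
        trait_name=trait_name,
        case_labels=case_labels[use],
    )


def case_vs_top_quantile(
    trait: np.ndarray,
    bins_undiagnosed: np.ndarray,
    undiagnosed_mask: np.ndarray,
    case_mask: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    k: int = 20,
    family: str = "linear",
) -> dict:
    """Wald test of case-group trait values against the top undiagnosed bin.

    Regression of the trait on a case indicator (plus covariates) restricted
    to top-bin undiagnosed samples and the case group.
    """
    undiag = np.asarray(undiagnosed_mask, dtype=bool)
    cases = np.asarray(case_mask, dtype=bool)
    if not cases.any():
        raise ValueError("no cases to contrast")
    top = np.zeros(len(undiag), dtype=bool)
    top[undiag] = np.asarray(bins_undiagnosed) == k
    use = top | cases
    y = np.asarray(trait, dtype=float)[use]
    x = cases[use].astype(float)
    X = np.column_stack([np.ones(len(y)), x])
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)[use]
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    res = _fit(y[ok], X[ok], family)
    return {"effect": float(res.params[1]), "se": float(res.bse[1]),
            "p_value": float(res.pvalues[1]), "n_top": int(top.sum()),
            "n_cases": int(cases.sum())}


def classify_concordance(trend: QuantileTrend, alpha: float = 0.05) -> dict:
    """Label each appended case group concordant / discordant / flat.

    The trend direction is the sign of the least-squares slope of bin
    coefficients on bin index over bins 1..k; a group is concordant when its
    coefficient shares that sign, discordant otherwise, and all groups are
    flat when the slope is not nominally significant.
    """
    b = trend.bins.sort_values("bin")
    slope_fit = sps.linregress(b["bin"].to_numpy(float), b["coefficient"].to_numpy(float))
    out = {"trend_slope": float(slope_fit.slope), "trend_p": float(slope_fit.pvalue)}
    labels = {}
    for _, row in trend.groups.iterrows():
        if slope_fit.pvalue >= alpha:
            labels[row["group"]] = "flat"
        elif np.sign(row["coefficient"]) == np.sign(slope_fit.slope):
            labels[row["group"]] = "concordant"
        else:
            labels[row["group"]] = "discordant"
    out["labels"] = labels
    return out
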