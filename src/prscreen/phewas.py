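"""PheWAS-style screening of many traits against a polygenic score.

Each trait is regressed on the PRS with covariate adjustment (linear for
quantitative traits, logistic for binary) and summarised by the PRS term's
Wald statistics plus the incremental variance explained: R^2 of the
full model minus the covariates-only model for linear fits, and the
Nagelkerke pseudo-R^2 difference for logistic fits.  Two significance
tiers are flagged: plain Bonferroni (0.05 / n_traits) and a stringent
fixed cutoff of P < 1e-7 guarding against subtle confounding at
biobank-scale sample sizes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator


@dataclass
class AssociationResult:
    """One PRS-trait regression outcome."""

    trait: str
    family: str
    beta: float
    se: float
    p_value: float
    r2_incremental: float
    n_used: int
    covariates: str = ""
    prs_label: str = ""
    converged: bool = True


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 of a model against the intercept-only fit."""
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / denom) if denom > 0 else 0.0


def _design(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(len(C)), C])


def associate(
    trait: np.ndarray | pd.Series,
    prs: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    family: str = "linear",
    trait_name: str = "trait",
    covariates_label: str = "",
    prs_label: str = "best_fit",
) -> AssociationResult:
    """Fit covariates-only and covariates+PRS models; report the PRS term.

    Rows with any missing trait/covariate/PRS value are dropped (listwise
    deletion).  Logistic non-convergence or separation yields a flagged
    (``converged=False``) result rather than an exception; a constant trait
    is an error.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(prs, dtype=float)
    n0 = len(y)
    C = _design(covariates, n0)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(C).all(axis=1)
    y, x, C = y[ok], x[ok], C[ok]
    n = len(y)
    if n == 0:
        raise ValueError("no complete-case rows")
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait_name!r} is constant")

    X_cov = C
    X_full = np.column_stack([C, x])
    j = X_full.shape[1] - 1  # PRS column

    if family == "linear":
        fit_cov = sm.OLS(y, X_cov).fit()
        fit_full = sm.OLS(y, X_full).fit()
        r2_inc = max(fit_full.rsquared - fit_cov.rsquared, 0.0)
        beta, se, p = fit_full.params[j], fit_full.bse[j], fit_full.pvalues[j]
        converged = True
    elif family == "logistic":
        uniq = np.unique(y)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ValueError("logistic family requires a 0/1 trait")
        converged = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
                fit_cov = sm.Logit(y, X_cov).fit(disp=0, maxiter=100)
                fit_full = sm.Logit(y, X_full).fit(disp=0, maxiter=100)
            converged = bool(fit_cov.mle_retvals["converged"]
                             and fit_full.mle_retvals["converged"])
            r2_cov = _nagelkerke(fit_cov.llf, fit_null.llf, n)
            r2_full = _nagelkerke(fit_full.llf, fit_null.llf, n)
            r2_inc = max(r2_full - r2_cov, 0.0)
            beta, se, p = fit_full.params[j], fit_full.bse[j], fit_full.pvalues[j]
            if not np.isfinite(se):
                converged = False
        except Exception:
            return AssociationResult(trait_name, family, np.nan, np.nan, 1.0, 0.0,
                                     n, covariates_label, prs_label, converged=False)
    else:
        raise ValueError("family must be 'linear' or 'logistic'")

    p = float(min(max(p, np.nextafter(0, 1)), 1.0))
    return AssociationResult(trait_name, family, float(beta), float(se), p,
                             float(min(r2_inc, 1.0)), n, covariates_label,
                             prs_label, converged)


def screen(
    traits: pd.DataFrame,
    prs: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    families: dict[str, str] | None = None,
    alpha: float = 0.05,
    stringent_p: float = 1e-7,
    prs_label: str = "best_fit",
) -> pd.DataFrame:
    """Screen every trait column; flag Bonferroni and stringent hits.

    ``families`` maps trait name -> 'linear'/'logistic'; unlisted traits are
    treated as logistic when they take exactly the values {0, 1}.  The
    Bonferroni cutoff is alpha / n_traits over the screened set.
    """
    if traits.shape[1] == 0:
        raise ValueError("need at least one trait")
    n_traits = traits.shape[1]
    cutoff = alpha / n_traits
    rows = []
    for name in traits.columns:
        col = traits[name].to_numpy(dtype=float)
        if families and name in families:
            fam = families[name]
        else:
            vals = np.unique(col[np.isfinite(col)])
            fam = "logistic" if len(vals) <= 2 and np.isin(vals, [0.0, 1.0]).all() else "linear"
        res = associate(col, prs, covariates, fam, trait_name=name, prs_label=prs_label)
        rows.append(asdict(res))
    out = pd.DataFrame(rows)
    out["bonferroni_cutoff"] = cutoff
    out["bonferroni"] = out["p_value"] < cutoff
    out["stringent"] = out["p_value"] < stringent_p
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def compare_profiles(results_best: pd.DataFrame, results_gw: pd.DataFrame,
                     nominal_alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-trait concordance between best-fit and GW-significant profiles.

    Returns the merged table plus a summary: how many stringent best-fit
    hits are nominally significant with the same effect sign under the
    GW-significant score.
    """
    if set(results_best["trait"]) != set(results_gw["trait"]):
        raise ValueError("profile result tables cover different trait sets")
    merged = results_best.merge(results_gw, on="trait", suffixes=("_best", "_gw"))
    merged["sign_agree"] = np.sign(merged["beta_best"]) == np.sign(merged["beta_gw"])
    merged["gw_nominal"] = merged["p_value_gw"] < nominal_alpha
    hits = merged[merged["stringent_best"]] if "stringent_best" in merged else merged
    summary = {
        "n_traits": len(merged),
        "n_stringent_best": int(merged.get("stringent_best", pd.Series(dtype=bool)).sum()),
        "n_stringent_confirmed": int((hits["gw_nominal"] & hits["sign_agree"]).sum())
        if len(hits) else 0,
        "sign_agreement_rate": float(merged["sign_agree"].mean()),
    }
    return merged, summary


def pc_sensitivity(
    trait: np.ndarray,
    prs: np.ndarray,
    pcs: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    k_list: tuple[int, ...] = (15, 40),
    family: str = "linear",
) -> pd.DataFrame:
    """Refit the association with increasing numbers of PCs adjusted for.

    Reports each fit plus the beta ratio against the smallest k; a ratio
    near 1 indicates the association is robust to finer structure
    adjustment.
    """
    pcs = np.asarray(pcs, dtype=float)
    if max(k_list) > pcs.shape[1]:
        raise ValueError(f"requested {max(k_list)} PCs but only {pcs.shape[1]} available")
    rows = []
    for k in k_list:
        C = pcs[:, :k]
        if covariates is not None:
            C = np.column_stack([np.asarray(covariates, dtype=float), C])
        res = associate(trait, prs, C, family, covariates_label=f"{k}_pcs")
        rows.append({"k_pcs": k, "beta": res.beta, "se": res.se, "p_value": res.p_value,
                     "r2_incremental": res.r2_incremental})
    out = pd.DataFrame(rows)
    out["beta_ratio_vs_smallest"] = out["beta"] / out["beta"].iloc[0]
    return out


class PheWASScreen(BaseEstimator):
    """Estimator wrapper around :func:`screen` (results in ``results_``)."""

    def __init__(self, alpha: float = 0.05, stringent_p: float = 1e-7,
                 prs_label: str = "best_fit"):
        self.alpha = alpha
        self.stringent_p = stringent_p
        self.prs_label = prs_label

    def fit(self, traits: pd.DataFrame, prs: np.ndarray,
            covariates=None, families=None) -> "PheWASScreen":
        self.results_ = screen(traits, prs, covariates, families,
                               self.alpha, self.stringent_p, self.prs_label)
        self.bonferroni_cutoff_ = self.alpha / traits.shape[1]
        return self
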