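"""Variant and sample quality control, kinship pruning, PCA and ancestry
clustering.

Filters replicate the standard pre-PRS target-data pipeline: variant
missingness > 0.02, MAF < 0.01 and Hardy-Weinberg P < 1e-8 remove variants;
sample missingness > 0.01 removes samples; one member of every pair with
estimated kinship >= 0.088 (the third-degree cutoff) is pruned; the analysis
subset is the largest of four k-means clusters on the first two genotype
principal components.  All boundary inequalities are strict as stated
(`>` removes, `=` retains; kinship `>=` removes).

Estimators follow the scikit-learn protocol (fit / transform, fitted
attributes with trailing underscores) and compose with sklearn pipelines;
the module-level functions are thin wrappers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted


@dataclass
class QCReport:
    """Per-filter removal counts, in application order, plus retained ids."""

    steps: list[dict] = field(default_factory=list)
    retained_variants: np.ndarray | None = None
    retained_samples: np.ndarray | None = None

    def add(self, name: str, axis: str, n_in: int, n_removed: int) -> None:
        self.steps.append(
            {"filter": name, "axis": axis, "n_in": int(n_in),
             "n_removed": int(n_removed), "n_out": int(n_in - n_removed)}
        )

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "retained_variants": None if self.retained_variants is None
            else [int(i) for i in self.retained_variants],
            "retained_samples": None if self.retained_samples is None
            else [int(i) for i in self.retained_samples],
        }


def hwe_chisq(geno_col: np.ndarray) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions on one variant.

    Observed dosage counts among non-missing calls vs expectations from the
    estimated allele frequency; no continuity correction.
    """
    g = geno_col[~np.isnan(geno_col)]
    n = len(g)
    if n == 0:
        return 0.0, 1.0
    n2 = int((g == 2).sum())
    n1 = int((g == 1).sum())
    n0 = n - n1 - n2
    p = (2 * n2 + n1) / (2 * n)
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    obs = np.array([n0, n1, n2], dtype=float)
    ok = exp > 0
    chi2 = float(((obs[ok] - exp[ok]) ** 2 / exp[ok]).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


class VariantQC(BaseEstimator, TransformerMixin):
    """Remove variants by missingness, MAF and Hardy-Weinberg filters.

    Parameters mirror the published thresholds.  ``conjunctive=True``
    selects the literal conjunctive reading of the missingness/MAF rule
    (remove only variants failing both); the default treats them as
    independent removal rules applied in order missingness -> MAF -> HWE.
    """

    def __init__(self, snp_missing_max: float = 0.02, maf_min: float = 0.01,
                 hwe_p_min: float = 1e-8, conjunctive: bool = False):
        self.snp_missing_max = snp_missing_max
        self.maf_min = maf_min
        self.hwe_p_min = hwe_p_min
        self.conjunctive = conjunctive

    def fit(self, X: np.ndarray, y=None) -> "VariantQC":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty genotype matrix")
        n, m = X.shape
        report = QCReport()
        miss = np.isnan(X).mean(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(X, axis=0) / 2.0
        freq = np.nan_to_num(freq, nan=0.0)
        maf = np.minimum(freq, 1 - freq)

        fail_miss = miss > self.snp_missing_max
        fail_maf = maf < self.maf_min
        if self.conjunctive:
            keep = ~(fail_miss & fail_maf)
            report.add("missingness_and_maf", "variant", m, int((~keep).sum()))
        else:
            keep = ~fail_miss
            report.add("missingness", "variant", m, int(fail_miss.sum()))
            n_maf = int((fail_maf & keep).sum())
            keep &= ~fail_maf
            report.add("maf", "variant", int(m - fail_miss.sum()), n_maf)

        idx = np.flatnonzero(keep)
        hwe_fail = np.zeros(len(idx), dtype=bool)
        for j, col in enumerate(idx):
            chi2, p = hwe_chisq(X[:, col])
            hwe_fail[j] = p < self.hwe_p_min
        report.add("hwe", "variant", len(idx), int(hwe_fail.sum()))
        retained = idx[~hwe_fail]
        report.retained_variants = retained

        self.retained_ = retained
        self.report_ = report
        self.n_features_in_ = m
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "retained_")
        return np.asarray(X, dtype=float)[:, self.retained_]


class SampleQC(BaseEstimator, TransformerMixin):
    """Remove samples whose missing-call fraction exceeds the threshold.

    Missingness is computed over the variants present in the matrix given to
    ``fit`` (i.e. run after variant QC); the boundary is strict (> removed,
    = retained).
    """

    def __init__(self, sample_missing_max: float = 0.01):
        self.sample_missing_max = sample_missing_max

    def fit(self, X: np.ndarray, y=None) -> "SampleQC":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty genotype matrix")
        miss = np.isnan(X).mean(axis=1)
        self.retained_ = np.flatnonzero(miss <= self.sample_missing_max)
        self.missing_fraction_ = miss
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "retained_")
        return np.asarray(X, dtype=float)[self.retained_]


def king_kinship(X: np.ndarray) -> np.ndarray:
    """Pairwise KING-robust kinship estimates.

    phi_ij = (N_het,het - 2 N_opposite-homozygote) / (N_het(i) + N_het(j)),
    counts restricted to variants non-missing in both members.  ~0.5 for
    duplicates/MZ twins, ~0.25 first degree, ~0 for unrelated pairs.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).all(axis=1).any():
        raise ValueError("sample with all-missing genotypes")
    M = (~np.isnan(X)).astype(float)
    G = np.nan_to_num(X, nan=-1.0)
    H = (G == 1).astype(float)
    A0 = (G == 0).astype(float)
    A2 = (G == 2).astype(float)
    n_hethet = H @ H.T
    n_opp = A0 @ A2.T + A2 @ A0.T
    hm = H @ M.T  # het in i counted over j's non-missing variants
    denom = hm + hm.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    np.fill_diagonal(phi, 0.5)
    return phi


def grm_kinship(X: np.ndarray) -> np.ndarray:
    """Fallback estimator: half the standardised genomic relationship."""
    X = np.asarray(X, dtype=float)
    p = np.clip(np.nanmean(X, axis=0) / 2.0, 1e-6, 1 - 1e-6)
    Z = np.nan_to_num((X - 2 * p) / np.sqrt(2 * p * (1 - p)), nan=0.0)
    grm = Z @ Z.T / Z.shape[1]
    return grm / 2.0


class KinshipPruner(BaseEstimator, TransformerMixin):
    """Prune one member of each related pair (kinship >= threshold).

    Greedy: repeatedly drop the sample involved in the most flagged pairs,
    ties broken by sample order, until no flagged pair remains.
    """

    def __init__(self, threshold: float = 0.088, method: str = "king"):
        self.threshold = threshold
        self.method = method

    def fit(self, X: np.ndarray, y=None) -> "KinshipPruner":
        est = {"king": king_kinship, "grm": grm_kinship}
        if self.method not in est:
            raise ValueError("method must be 'king' or 'grm'")
        phi = est[self.method](X)
        n = phi.shape[0]
        with np.errstate(invalid="ignore"):
            flagged = np.asarray(phi) >= self.threshold  # NaN compares False
        np.fill_diagonal(flagged, False)
        active = np.ones(n, dtype=bool)
        removed: list[int] = []
        while True:
            counts = (flagged & active[None, :] & active[:, None]).sum(axis=1)
            counts[~active] = 0
            if counts.max(initial=0) == 0:
                break
            worst = int(np.argmax(counts))  # argmax takes the first (lowest id) tie
            active[worst] = False
            removed.append(worst)
        self.kinship_ = phi
        self.retained_ = np.flatnonzero(active)
        self.removed_ = np.array(removed, dtype=int)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "retained_")
        return np.asarray(X, dtype=float)[self.retained_]


class GenotypePCA(BaseEstimator, TransformerMixin):
    """Principal components of the standardised dosage matrix.

    Columns are mean-centred at twice the allele frequency and scaled by
    sqrt(2 p (1-p)) (Patterson convention; ``scaling='sd'`` uses the sample
    standard deviation).  Missing dosages are mean-imputed; zero-variance
    columns are dropped.  Component signs are fixed so each component's
    largest-magnitude loading is positive.
    """

    def __init__(self, n_components: int = 15, scaling: str = "patterson"):
        self.n_components = n_components
        self.scaling = scaling

    def fit(self, X: np.ndarray, y=None) -> "GenotypePCA":
        self._fit(np.asarray(X, dtype=float))
        return self

    def _fit(self, X: np.ndarray) -> np.ndarray:
        n, m = X.shape
        k = self.n_components
        if k > min(n, m):
            raise ValueError(f"n_components={k} exceeds min(n_samples, n_snps)")
        p = np.nanmean(X, axis=0) / 2.0
        if self.scaling == "patterson":
            scale = np.sqrt(2 * p * (1 - p))
        elif self.scaling == "sd":
            scale = np.nanstd(X, axis=0)
        else:
            raise ValueError("scaling must be 'patterson' or 'sd'")
        keep = scale > 0
        Z = np.nan_to_num((X[:, keep] - 2 * p[keep]) / scale[keep], nan=0.0)
        Z = Z - Z.mean(axis=0)
        self.kept_columns_ = np.flatnonzero(keep)
        if k == 0:
            self.components_ = np.empty((0, keep.sum()))
            self.explained_variance_ = np.empty(0)
            return np.empty((n, 0))
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
        # deterministic orientation: largest-|loading| positive per component
        for i in range(k):
            j = int(np.argmax(np.abs(Vt[i])))
            if Vt[i, j] < 0:
                Vt[i] *= -1
                U[:, i] *= -1
        self.components_ = Vt
        self.singular_values_ = S
        self.explained_variance_ = S**2 / max(n - 1, 1)
        self._mean_freq = p
        self._scale = scale
        return U * S

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self._fit(np.asarray(X, dtype=float))

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        keep = self.kept_columns_
        Z = np.nan_to_num(
            (X[:, keep] - 2 * self._mean_freq[keep]) / self._scale[keep], nan=0.0
        )
        return Z @ self.components_.T


class AncestryCluster(BaseEstimator):
    """k-means (k=4 by default) on the first two PCs; the largest cluster is
    the ancestry-homogeneous analysis subset."""

    def __init__(self, k: int = 4, random_state: int = 0, n_init: int = 10):
        self.k = k
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, pcs: np.ndarray, y=None) -> "AncestryCluster":
        pcs = np.asarray(pcs, dtype=float)
        if pcs.shape[0] < self.k:
            raise ValueError("fewer samples than clusters")
        if pcs.shape[1] < 2:
            raise ValueError("need at least two PC columns")
        km = KMeans(n_clusters=self.k, n_init=self.n_init,
                    random_state=self.random_state)
        self.labels_ = km.fit_predict(pcs[:, :2])
        self.cluster_centers_ = km.cluster_centers_
        sizes = np.bincount(self.labels_, minlength=self.k)
        self.majority_cluster_ = int(np.argmax(sizes))
        self.majority_ids_ = np.flatnonzero(self.labels_ == self.majority_cluster_)
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers

def variant_qc(genotypes, snp_missing_max=0.02, maf_min=0.01, hwe_p_min=1e-8,
               conjunctive=False):
    """Returns (retained variant indices, QCReport)."""
    est = VariantQC(snp_missing_max, maf_min, hwe_p_min, conjunctive).fit(genotypes)
    return est.retained_, est.report_


def sample_qc(genotypes, sample_missing_max=0.01):
    """Returns retained sample indices."""
    return SampleQC(sample_missing_max).fit(genotypes).retained_


def kinship_prune(genotypes, threshold=0.088, method="king"):
    """Returns (retained sample indices, pairwise kinship matrix)."""
    est = KinshipPruner(threshold, method).fit(genotypes)
    return est.retained_, est.kinship_


def pca(genotypes, k, scaling="patterson"):
    """Returns per-sample PC coordinates (n_samples x k)."""
    return GenotypePCA(n_components=k, scaling=scaling).fit_transform(genotypes)


def ancestry_cluster(pc_coords, k=4, random_state=0):
    """Returns (cluster labels, majority-cluster sample indices)."""
    est = AncestryCluster(k=k, random_state=random_state).fit(pc_coords)
    return est.labels_, est.majority_ids_
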