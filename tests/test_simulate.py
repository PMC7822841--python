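"""Generative model checks: LD structure, drift, liability threshold,
medication, scenario semantics and summary-statistic calibration."""
import numpy as np
import pytest
from scipy import stats

from prscreen.config import ScenarioConfig
from prscreen.prs import PRSBuilder
from prscreen.phewas import associate
from prscreen.simulate import (
    generate_sumstats,
    simulate_cohort,
    simulate_genotypes,
    subset_cohort,
)


def test_identical_seed_gives_identical_cohort():
    cfg = ScenarioConfig(scenario="pleiotropy", n_individuals=300, n_snps=100, seed=9)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    np.testing.assert_array_equal(a.liability, b.liability)
    np.testing.assert_array_equal(a.traits["trait"], b.traits["trait"])
    np.testing.assert_array_equal(a.locations.to_numpy(), b.locations.to_numpy())


def test_config_validation_errors():
    with pytest.raises(ValueError):
        ScenarioConfig(n_individuals=0)
    with pytest.raises(ValueError):
        ScenarioConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        ScenarioConfig(maf_range=(0.1, 0.6))
    with pytest.raises(ValueError):
        ScenarioConfig(scenario="bogus")
    with pytest.raises(ValueError):
        ScenarioConfig(n_causal=50, n_snps=20)


def test_hardy_weinberg_without_structure_or_ld():
    """fst=0, ld_rho=0: per-SNP genotype class frequencies match HW
    proportions of the realised allele frequency within binomial error."""
    cfg = ScenarioConfig(n_individuals=4000, n_snps=150, ld_block_size=1,
                         ld_rho=0.0, fst=0.0, seed=1)
    c = simulate_genotypes(cfg)
    G = c.genotypes
    n = G.shape[0]
    p = G.mean(axis=0) / 2.0
    for dose, expected in ((0, (1 - p) ** 2), (1, 2 * p * (1 - p)), (2, p**2)):
        obs = (G == dose).mean(axis=0)
        tol = 4 * np.sqrt(expected * (1 - expected) / n)
        assert (np.abs(obs - expected) <= tol + 1e-9).mean() > 0.97


def test_ld_decay_within_vs_between_blocks():
    """High latent correlation yields adjacent-SNP r^2 well above
    cross-block r^2, averaged over 50 blocks at n=2000."""
    cfg = ScenarioConfig(n_individuals=2000, n_snps=510, ld_block_size=10,
                         ld_rho=0.9, seed=2)
    G = simulate_genotypes(cfg).genotypes
    adj, cross = [], []
    for b in range(50):
        i = b * 10
        adj.append(np.corrcoef(G[:, i], G[:, i + 1])[0, 1] ** 2)
        cross.append(np.corrcoef(G[:, i], G[:, i + 10])[0, 1] ** 2)
    assert np.mean(adj) > np.mean(cross)
    assert np.mean(adj) > 0.2


def test_fst_recovery():
    """Balding-Nichols drift at F=0.1 is recovered within +/-0.03 by a
    frequency-variance (Hudson) estimator over 1000 SNPs."""
    cfg = ScenarioConfig(n_individuals=2000, n_snps=1000, ld_block_size=1,
                         ld_rho=0.0, n_subpops=2, fst=0.1, seed=5)
    c = simulate_genotypes(cfg)
    sub = c.sample_meta["subpop"].to_numpy()
    n1, n2 = (sub == 0).sum(), (sub == 1).sum()
    p1 = c.genotypes[sub == 0].mean(0) / 2
    p2 = c.genotypes[sub == 1].mean(0) / 2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    fst_hat = num.sum() / den.sum()
    assert abs(fst_hat - 0.1) < 0.03


def test_liability_standardised_and_case_rate():
    cfg = ScenarioConfig(n_individuals=20000, n_snps=100, h2_liability=0.3, seed=7)
    c = simulate_cohort(cfg, with_locations=False)
    assert abs(c.liability.var() - 1.0) < 0.05
    band = 3 * np.sqrt(0.01 * 0.99 / 20000)
    assert abs(c.true_status.mean() - 0.01) <= band


def test_zero_heritability_gives_null_prs_case_association():
    """h2=0: diagnosis is independent of genotypes, so a PRS built from the
    oracle statistics shows uniform association P over replicates."""
    pvals = []
    for s in range(40):
        cfg = ScenarioConfig(n_individuals=1500, n_snps=60, ld_block_size=5,
                             h2_liability=0.0, prevalence=0.2, seed=600 + s)
        c = simulate_cohort(cfg, with_locations=False)
        # true effects are all zero; score with raw standardised dosages
        p = np.clip(c.genotypes.mean(0) / 2, 1e-3, 1 - 1e-3)
        prs = ((c.genotypes - 2 * p) / np.sqrt(2 * p * (1 - p))).sum(1)
        res = associate(c.diagnosed.astype(float), prs, family="logistic")
        pvals.append(res.p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_medicated_cases_have_higher_liability():
    """With positive medication slope, medicated cases out-rank
    non-medicated on mean liability in >=95% of 100 replicate cohorts."""
    wins = n_ok = 0
    for s in range(100):
        cfg = ScenarioConfig(n_individuals=5000, n_snps=60, ld_block_size=5,
                             prevalence=0.02, medication_prob_slope=2.0, seed=700 + s)
        c = simulate_cohort(cfg, with_locations=False)
        med, nonmed = c.medicated, c.diagnosed & ~c.medicated
        if med.any() and nonmed.any():
            n_ok += 1
            wins += c.liability[med].mean() > c.liability[nonmed].mean()
    assert n_ok >= 90
    assert wins / n_ok >= 0.95


def test_medicated_implies_diagnosed_and_misclassification():
    cfg = ScenarioConfig(n_individuals=20000, n_snps=60, prevalence=0.05,
                         misclassification_rate=0.3, seed=8)
    c = simulate_cohort(cfg, with_locations=False)
    assert not (c.medicated & ~c.diagnosed).any()
    assert (c.diagnosed <= c.true_status).all()  # flips only true->false
    frac_hidden = 1 - c.diagnosed.sum() / c.true_status.sum()
    assert abs(frac_hidden - 0.3) < 0.1


def test_disorder_to_trait_attenuates_in_undiagnosed_subset():
    """The effect flows only through diagnosis, so excluding diagnosed
    individuals attenuates the PRS-trait association."""
    cfg = ScenarioConfig(scenario="disorder_to_trait", n_individuals=20000,
                         n_snps=100, trait_effect=2.0, seed=12)
    c = simulate_cohort(cfg, with_locations=False)
    ss = generate_sumstats(c)
    b = PRSBuilder().fit(c.genotypes, sumstats=ss, variant_meta=c.variant_meta)
    prs = b.score_profile(c.genotypes).score
    tr = c.traits["trait"].to_numpy()
    full = associate(tr, prs)
    undiag = ~c.diagnosed
    sub = associate(tr[undiag], prs[undiag])
    assert abs(sub.beta) < abs(full.beta)


def structure_config(seed: int, n: int = 6000, m: int = 800) -> ScenarioConfig:
    """Location-confounding setup: allele frequencies drift between two
    subpopulations while a shared environment raises both disorder risk and
    the trait; the discovery GWAS is run on an independent half of the
    population so its stratification bias carries into the target PRS."""
    return ScenarioConfig(
        scenario="structure", n_individuals=n, n_snps=m, ld_block_size=1,
        ld_rho=0.0, n_subpops=2, fst=0.1, h2_liability=0.5, n_causal=50,
        env_gradient=(-0.5, 0.5), env_liability_gradient=(-0.2, 0.2),
        prevalence=0.1, seed=seed,
    )


def structure_prs_and_trait(cfg: ScenarioConfig):
    """Split-cohort discovery GWAS -> target PRS, trait and genotypes."""
    c = simulate_cohort(cfg, with_locations=False)
    half = c.n_individuals // 2
    disc = subset_cohort(c, np.arange(half))
    targ = subset_cohort(c, np.arange(half, c.n_individuals))
    ss = generate_sumstats(c, mode="cohort_gwas", discovery_cohort=disc)
    b = PRSBuilder().fit(targ.genotypes, sumstats=ss, variant_meta=c.variant_meta)
    prs = b.score_profile(targ.genotypes).score
    return targ, prs


def test_structure_scenario_shrinks_with_subpop_adjustment():
    """Adjusting for the true subpopulation indicator removes most of a
    structure-driven PRS-trait association (one large cohort)."""
    targ, prs = structure_prs_and_trait(structure_config(seed=11))
    tr = targ.traits["trait"].to_numpy()
    sub = targ.sample_meta["subpop"].to_numpy(dtype=float)[:, None]
    unadj = associate(tr, prs)
    adj = associate(tr, prs, sub)
    assert unadj.p_value < 1e-6
    assert abs(adj.beta) < 0.5 * abs(unadj.beta)


class TestSumstats:
    def test_oracle_zero_noise_limit(self):
        cfg = ScenarioConfig(n_individuals=500, n_snps=60, n_causal=10, seed=3)
        cfg.n_discovery = float("inf")
        c = simulate_cohort(cfg, with_locations=False)
        ss = generate_sumstats(c)
        true_lor = c.variant_meta["true_effect"].to_numpy()
        causal = true_lor != 0
        np.testing.assert_allclose(
            ss["beta"][causal],
            true_lor[causal] * stats.norm.pdf(stats.norm.ppf(0.99)) / (0.01 * 0.99),
        )
        assert (ss["p_value"][causal] < 1e-300).all()
        assert (ss["p_value"][~causal] == 1.0).all()

    def test_oracle_null_pvalues_uniform(self):
        cfg = ScenarioConfig(n_individuals=200, n_snps=5000, ld_block_size=10,
                             n_causal=0, h2_liability=0.0, seed=4)
        c = simulate_cohort(cfg, with_locations=False)
        ss = generate_sumstats(c)
        assert stats.kstest(ss["p_value"], "uniform").pvalue > 0.01

    def test_cohort_gwas_ranks_causal_snps(self):
        """Causal SNPs land in the top decile of -log10 p in >=80% of 50
        replicate discovery GWASs (n=4000, 60 SNPs, 5 causal)."""
        hits = 0
        for s in range(50):
            cfg = ScenarioConfig(n_individuals=4000, n_snps=60, ld_block_size=1,
                                 ld_rho=0.0, n_causal=5, h2_liability=0.5,
                                 prevalence=0.1, seed=900 + s)
            c = simulate_cohort(cfg, with_locations=False)
            ss = generate_sumstats(c, mode="cohort_gwas")
            causal = np.flatnonzero(c.variant_meta["true_effect"].to_numpy() != 0)
            rank = stats.rankdata(-(-np.log10(ss["p_value"])))  # 1 = most significant
            hits += (rank[causal] <= 6).mean() >= 0.8
        assert hits >= 40

    def test_oracle_requires_effects(self):
        cfg = ScenarioConfig(n_individuals=100, n_snps=20, n_causal=5, seed=5)
        c = simulate_genotypes(cfg)
        with pytest.raises(ValueError):
            generate_sumstats(c, mode="oracle")


class TestLocations:
    def test_no_coupling_no_correlation(self):
        cfg = ScenarioConfig(n_individuals=10000, n_snps=30, n_causal=10,
                             migration_coupling=0.0, seed=21)
        c = simulate_cohort(cfg)
        d = np.hypot(
            c.locations["current_easting"] - c.locations["birth_easting"],
            c.locations["current_northing"] - c.locations["birth_northing"],
        )
        r = np.corrcoef(d, c.traits["trait"])[0, 1]
        assert abs(r) < 2 / np.sqrt(len(d))

    def test_positive_coupling_detected(self):
        """Distance regresses positively on the trait (P<0.01) in >=90% of
        50 replicates under positive migration-trait coupling."""
        wins = 0
        for s in range(50):
            cfg = ScenarioConfig(n_individuals=20000, n_snps=20, ld_block_size=5,
                                 n_causal=5, migration_coupling=0.3, seed=1100 + s)
            c = simulate_cohort(cfg)
            d = np.hypot(
                c.locations["current_easting"] - c.locations["birth_easting"],
                c.locations["current_northing"] - c.locations["birth_northing"],
            ).to_numpy()
            res = associate(d, c.traits["trait"].to_numpy())
            wins += (res.beta > 0) and (res.p_value < 0.01)
        assert wins >= 45

    def test_zero_displacement(self):
        cfg = ScenarioConfig(n_individuals=500, n_snps=20, n_causal=5,
                             base_move_sd_km=0.0, seed=22)
        c = simulate_cohort(cfg)
        d = np.hypot(
            c.locations["current_easting"] - c.locations["birth_easting"],
            c.locations["current_northing"] - c.locations["birth_northing"],
        )
        assert (d == 0).all()


@pytest.mark.parametrize("scenario,kwargs,expect_power", [
    ("null", {}, False),
    ("pleiotropy", {"trait_effect": 0.5}, True),
    ("structure", {}, True),
    ("trait_to_disorder", {"trait_effect": 0.5}, True),
    ("disorder_to_trait", {"trait_effect": 2.0, "n_individuals": 20000,
                           "n_snps": 60}, True),
])
def test_scenario_separability(scenario, kwargs, expect_power):
    """Only the configured causal arrow produces a PRS-trait association:
    power > 0.8 for causal scenarios, type-I <= 0.07 for the null, over 100
    replicates."""
    rejections = 0
    n_rep = 100
    for s in range(n_rep):
        if scenario == "structure":
            targ, prs = structure_prs_and_trait(
                structure_config(seed=5000 + s, n=3000, m=600))
            res = associate(targ.traits["trait"].to_numpy(), prs)
            rejections += res.p_value < 0.05
            continue
        base = dict(n_individuals=2000, n_snps=100, ld_block_size=5, n_causal=20)
        base.update(kwargs)
        cfg = ScenarioConfig(scenario=scenario, seed=5000 + s, **base)
        c = simulate_cohort(cfg, with_locations=False)
        ss = generate_sumstats(c)
        try:
            b = PRSBuilder().fit(c.genotypes, sumstats=ss, variant_meta=c.variant_meta)
            prs = b.score_profile(c.genotypes).score
        except ValueError:  # no SNP below threshold -> cannot reject
            continue
        res = associate(c.traits["trait"].to_numpy(), prs)
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    if expect_power:
        assert rate > 0.8
    else:
        assert rate <= 0.07
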