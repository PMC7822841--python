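"""Run-directory pipeline stages with fixed filenames.

Each stage reads its inputs from (and writes its outputs to) a single run
directory, so downstream stages auto-discover upstream outputs without a
workflow engine: ``genotypes.*`` / ``sumstats.tsv`` / ``phenotypes.tsv`` /
``locations.tsv`` / ``density_map.tsv`` from the simulate stage, then
``qc_report.json`` + ``pcs.tsv`` (qc), ``scores.tsv`` + ``clumps.tsv``
(prs), ``associations.tsv`` (phewas), ``quantile_trend.tsv`` (quantiles)
and ``migration.tsv`` (migration).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import migration as pmig
from . import phewas as pphe
from . import prs as pprs
from . import qc as pqc
from . import quantiles as pq
from .config import RunConfig, ScenarioConfig
from .simulate import generate_sumstats, simulate_cohort

log = logging.getLogger("prscreen")


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if not any(isinstance(h, logging.FileHandler) for h in log.handlers):
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    log.setLevel(logging.INFO)


def run_simulate(scfg: ScenarioConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    _setup_logging(out)
    log.info("simulate: scenario=%s n=%d m=%d seed=%d",
             scfg.scenario, scfg.n_individuals, scfg.n_snps, scfg.seed)
    cohort = simulate_cohort(scfg)
    sid = cohort.sample_meta["sample_id"]
    pio.write_plink(out / "genotypes", cohort.genotypes, cohort.variant_meta, sid)
    sumstats = generate_sumstats(cohort)
    pio.write_sumstats(out / "sumstats.tsv", sumstats, seed=scfg.seed)
    pheno = pd.concat(
        [
            cohort.sample_meta[["age", "sex", "deprivation", "education", "subpop"]].reset_index(drop=True),
            pd.DataFrame(
                {
                    "diagnosed": cohort.diagnosed.astype(int),
                    "medicated": cohort.medicated.astype(int),
                    "true_status": cohort.true_status.astype(int),
                    "liability": cohort.liability,
                }
            ),
            cohort.traits.reset_index(drop=True),
        ],
        axis=1,
    )
    pio.write_phenotypes(out / "phenotypes.tsv", pheno, sid, seed=scfg.seed)
    pio.write_phenotypes(out / "locations.tsv", cohort.locations, sid, seed=scfg.seed)
    pio.write_density_map(out / "density_map.tsv", cohort.density_map)
    cfg = RunConfig(scenario=scfg, seed=scfg.seed, out_dir=str(out))
    cfg.save(out / "config.yaml")
    log.info("simulate: wrote cohort (%d cases, %d medicated)",
             int(cohort.diagnosed.sum()), int(cohort.medicated.sum()))


def run_qc(out_dir: str | Path, cfg: RunConfig | None = None) -> dict:
    out = Path(out_dir)
    _setup_logging(out)
    cfg = cfg or RunConfig()
    G, vm, sids = pio.read_genotypes(out / "genotypes")
    log.info("qc: input %d samples x %d variants", *G.shape)

    vqc = pqc.VariantQC(cfg.snp_missing_max, cfg.maf_min, cfg.hwe_p_min,
                        cfg.conjunctive_variant_filter).fit(G)
    G1 = vqc.transform(G)
    sqc = pqc.SampleQC(cfg.sample_missing_max).fit(G1)
    G2 = sqc.transform(G1)
    report = vqc.report_
    report.add("sample_missingness", "sample", G1.shape[0],
               G1.shape[0] - len(sqc.retained_))
    pruner = pqc.KinshipPruner(cfg.kinship_threshold).fit(G2)
    G3 = pruner.transform(G2)
    report.add("kinship", "sample", G2.shape[0], len(pruner.removed_))

    k = min(cfg.n_pcs_sensitivity, min(G3.shape) - 1)
    pcs = pqc.GenotypePCA(n_components=k).fit_transform(G3)
    anc = pqc.AncestryCluster(k=cfg.ancestry_k, random_state=cfg.seed).fit(pcs[:, :2])
    report.add("ancestry", "sample", G3.shape[0], G3.shape[0] - len(anc.majority_ids_))

    sample_idx = np.asarray(sqc.retained_)[pruner.retained_][anc.majority_ids_]
    report.retained_samples = sample_idx
    (out / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    kept_sids = [sids[i] for i in sample_idx]
    (out / "retained_samples.txt").write_text("\n".join(kept_sids) + "\n")
    (out / "retained_variants.txt").write_text(
        "\n".join(vm["snp_id"].iloc[report.retained_variants]) + "\n")
    pcs_kept = pcs[anc.majority_ids_]
    pcs_df = pd.DataFrame(pcs_kept, columns=[f"PC{i+1}" for i in range(pcs_kept.shape[1])])
    pio.write_phenotypes(out / "pcs.tsv", pcs_df, kept_sids, seed=cfg.seed)
    for step in report.steps:
        log.info("qc: %s removed %d of %d (%s)", step["filter"], step["n_removed"],
                 step["n_in"], step["axis"])
    return report.to_dict()


def _analysis_subset(out: Path):
    G, vm, sids = pio.read_genotypes(out / "genotypes")
    kept_s = (out / "retained_samples.txt").read_text().split()
    kept_v = (out / "retained_variants.txt").read_text().split()
    s_idx = [sids.index(s) for s in kept_s]
    v_pos = {v: i for i, v in enumerate(vm["snp_id"])}
    v_idx = [v_pos[v] for v in kept_v]
    return G[np.ix_(s_idx, v_idx)], vm.iloc[v_idx].reset_index(drop=True), kept_s


def run_prs(out_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    out = Path(out_dir)
    _setup_logging(out)
    cfg = cfg or RunConfig()
    G, vm, sids = _analysis_subset(out)
    sumstats = pio.read_sumstats(out / "sumstats.tsv")
    frames = []
    for label in ("best_fit", "gw_significant"):
        builder = pprs.PRSBuilder(
            p_threshold=cfg.p_threshold, gw_threshold=cfg.gw_threshold,
            r2_threshold=cfg.clump_r2, window_kb=cfg.clump_window_kb, label=label,
        ).fit(G, sumstats=sumstats, variant_meta=vm)
        prof = builder.score_profile(G)
        log.info("prs: %s profile uses %d SNPs (threshold %g)",
                 label, len(prof.snp_set), prof.p_threshold)
        frames.append(pd.DataFrame({
            "sample_id": sids, "score": prof.score, "label": label,
            "p_threshold": prof.p_threshold, "n_snps": len(prof.snp_set),
        }))
        if label == "best_fit":
            pd.DataFrame({"index_snp": builder.index_snps_}).to_csv(
                out / "clumps.tsv", sep="\t", index=False)
    scores = pd.concat(frames, ignore_index=True)
    with open(out / "scores.tsv", "w") as fh:
        fh.write("\n".join(pio.provenance_lines(cfg.seed)) + "\n")
        scores.to_csv(fh, sep="\t", index=False)
    return scores


def _load_scores(out: Path, label: str) -> pd.DataFrame:
    sc = pd.read_csv(out / "scores.tsv", sep="\t", comment="#", dtype={"sample_id": str})
    return sc[sc["label"] == label].set_index("sample_id")


def _screen_inputs(out: Path, cfg: RunConfig, label: str = "best_fit"):
    pheno = pio.read_phenotypes(out / "phenotypes.tsv").set_index("sample_id")
    sc = _load_scores(out, label)
    pcs = pio.read_phenotypes(out / "pcs.tsv").set_index("sample_id")
    ids = sc.index
    pheno = pheno.loc[ids]
    pcs = pcs.loc[ids]
    cov_cols = [c for c in ("age", "sex", "deprivation") if c in pheno]
    cov = pd.concat([pheno[cov_cols], pcs.iloc[:, : cfg.n_pcs]], axis=1)
    meta_cols = {"age", "sex", "deprivation", "education", "subpop", "diagnosed",
                 "medicated", "true_status", "liability"}
    traits = pheno[[c for c in pheno.columns if c not in meta_cols]]
    return pheno, traits, sc["score"].to_numpy(), cov


def run_phewas(out_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    out = Path(out_dir)
    _setup_logging(out)
    cfg = cfg or RunConfig()
    pheno, traits, score, cov = _screen_inputs(out, cfg)
    undiag = pheno["diagnosed"].to_numpy() == 0 if "diagnosed" in pheno else np.ones(len(pheno), bool)
    results = pphe.screen(traits[undiag], score[undiag], cov[undiag],
                          alpha=cfg.alpha, stringent_p=cfg.stringent_p)
    log.info("phewas: %d traits screened, %d Bonferroni hits, %d stringent",
             len(results), int(results["bonferroni"].sum()), int(results["stringent"].sum()))
    with open(out / "associations.tsv", "w") as fh:
        fh.write("\n".join(pio.provenance_lines(cfg.seed)) + "\n")
        results.to_csv(fh, sep="\t", index=False)
    return results


def run_quantiles(out_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    out = Path(out_dir)
    _setup_logging(out)
    cfg = cfg or RunConfig()
    pheno, traits, score, cov = _screen_inputs(out, cfg)
    undiag = pheno["diagnosed"].to_numpy() == 0
    medicated = pheno["medicated"].to_numpy().astype(bool)
    trend = pq.append_case_groups(
        traits["trait"].to_numpy(), score[undiag], undiag, medicated,
        cov.to_numpy(), k=cfg.n_quantiles, reference=cfg.reference_quantile,
    )
    conc = pq.classify_concordance(trend)
    tidy = trend.to_frame()
    tidy["trait"] = trend.trait
    tidy["concordance"] = tidy["group"].map(conc["labels"]).fillna("")
    with open(out / "quantile_trend.tsv", "w") as fh:
        fh.write("\n".join(pio.provenance_lines(cfg.seed)) + "\n")
        tidy.to_csv(fh, sep="\t", index=False)
    log.info("quantiles: trend slope %.4g (p=%.3g), labels=%s",
             conc["trend_slope"], conc["trend_p"], conc["labels"])
    return tidy


def run_migration(out_dir: str | Path, cfg: RunConfig | None = None) -> pd.DataFrame:
    out = Path(out_dir)
    _setup_logging(out)
    cfg = cfg or RunConfig()
    pheno, traits, score, cov = _screen_inputs(out, cfg)
    loc = pio.read_phenotypes(out / "locations.tsv").set_index("sample_id")
    loc = loc.loc[pheno.index]
    dmap = pio.read_density_map(out / "density_map.tsv")
    table = pmig.migration_table(loc.reset_index(drop=True), dmap)
    with open(out / "migration.tsv", "w") as fh:
        fh.write("\n".join(pio.provenance_lines(cfg.seed)) + "\n")
        table.to_csv(fh, sep="\t", index=False)
    exposures = pd.DataFrame({"trait": traits["trait"].to_numpy(), "prs": score})
    covs = pheno[["age", "sex", "deprivation", "education"]].reset_index(drop=True)
    assoc = pmig.follow_up_associations(
        table, exposures, covs, base=cfg.base_covariates, extended=cfg.extended_covariates)
    with open(out / "migration_associations.tsv", "w") as fh:
        fh.write("\n".join(pio.provenance_lines(cfg.seed)) + "\n")
        assoc.to_csv(fh, sep="\t", index=False)
    log.info("migration: mean distance %.1f km, mean density change %.1f",
             table["distance_km"].mean(), table["density_change"].mean())
    return assoc


def run_all(scfg: ScenarioConfig, out_dir: str | Path, cfg: RunConfig | None = None) -> None:
    cfg = cfg or RunConfig(seed=scfg.seed)
    run_simulate(scfg, out_dir)
    run_qc(out_dir, cfg)
    run_prs(out_dir, cfg)
    run_phewas(out_dir, cfg)
    run_quantiles(out_dir, cfg)
    run_migration(out_dir, cfg)
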