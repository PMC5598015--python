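"""Stage orchestration: run the full analysis chain on a (simulated or
loaded) cohort and write canonical TSV outputs."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import differential, enrichment, prep, qtl, riskscore
from . import io as study_io
from .synthetic import CohortConfig, PlantedEffects, StudyCohort, simulate_cohort, simulate_gwa_summary

log = logging.getLogger("cardioqtl")

STAGES = (
    "simulate",
    "prep",
    "de",
    "deu",
    "deu-sim",
    "eqtl",
    "eqtl-specific",
    "sqtl",
    "ase",
    "ase-diff",
    "enrich-gwa",
    "riskscore",
)

_KNOWN_KEYS = {
    "seed",
    "outdir",
    "n_cases",
    "n_controls",
    "n_genes",
    "n_snps",
    "n_exons_per_gene",
    "maf_range",
    "nb_mean",
    "nb_size",
    "library_size_sd",
    "n_ase_sites",
    "cis_window",
    "eqtl_p_threshold",
    "n_expression_pcs",
    "n_genotype_pcs",
    "deu_sim_replicates",
    "deu_sim_exons",
    "max_sqtl_tests",
    "effects",
    "log_level",
}


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    n_cases: int = 40
    n_controls: int = 40
    n_genes: int = 30
    n_snps: int = 60
    n_exons_per_gene: tuple = (3, 6)
    maf_range: tuple = (0.1, 0.5)
    nb_mean: float = 100.0
    nb_size: float = 4.0
    library_size_sd: float = 0.2
    n_ase_sites: int = 12
    cis_window: int = 1_000_000
    eqtl_p_threshold: float = 1e-5
    n_expression_pcs: int = 5
    n_genotype_pcs: int = 3
    deu_sim_replicates: int = 5
    deu_sim_exons: int = 1000
    max_sqtl_tests: int = 200
    effects: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg


def _cohort_config(cfg: PipelineConfig) -> CohortConfig:
    eff = PlantedEffects(**{k: [tuple(x) for x in v] for k, v in (cfg.effects or {}).items()})
    return CohortConfig(
        n_cases=cfg.n_cases,
        n_controls=cfg.n_controls,
        n_genes=cfg.n_genes,
        n_snps=cfg.n_snps,
        n_exons_per_gene=tuple(cfg.n_exons_per_gene),
        maf_range=tuple(cfg.maf_range),
        nb_mean=cfg.nb_mean,
        nb_size=cfg.nb_size,
        library_size_sd=cfg.library_size_sd,
        n_ase_sites=cfg.n_ase_sites,
        effects=eff,
        seed=cfg.seed,
    )


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Execute the requested stages in dependency order.

    Returns a dict of in-memory results keyed by stage; each stage also
    writes its canonical TSV under ``cfg.outdir`` with a provenance header.
    Identical config and seed give byte-identical outputs.
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    # run in canonical order; implicit dependencies are satisfied by always
    # simulating/prepping in memory even when those outputs were not requested
    ordered = [s for s in STAGES if s in requested]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = study_io.config_hash(asdict(cfg))
    header = study_io.provenance_header(chash, cfg.seed)
    results: dict = {}

    cohort = simulate_cohort(_cohort_config(cfg))
    results["cohort"] = cohort
    groups = cohort.groups
    g01 = (groups == "case").astype(float)

    if "simulate" in ordered:
        study_io.write_table(cohort.samples, outdir / "samples.tsv", header)
        study_io.write_table(cohort.snps, outdir / "snps.tsv", header)
        study_io.write_matrix(cohort.genotypes, outdir / "genotypes.tsv", header)
        study_io.write_vcf(cohort.genotypes, cohort.snps, outdir / "genotypes.vcf")
        study_io.write_table(cohort.gene_models, outdir / "gene_models.tsv", header)
        study_io.write_matrix(cohort.gene_counts, outdir / "gene_counts.tsv", header)
        study_io.write_table(cohort.exon_parts, outdir / "exon_parts.tsv", header)
        study_io.write_matrix(cohort.exon_inclusion, outdir / "exon_inclusion.tsv", header)
        study_io.write_matrix(cohort.exon_totals, outdir / "exon_totals.tsv", header)
        study_io.write_table(cohort.allele_counts, outdir / "allele_counts.tsv", header)
        log.info("simulate: %d samples, %d genes, %d SNPs", len(cohort.samples),
                 len(cohort.gene_models), len(cohort.snps))

    # shared preprocessing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        scaled = prep.scale_counts_quantile(cohort.gene_counts)
        logged = np.log2(scaled + 1.0)
        covariates = cohort.samples.set_index("sample_id")[["age", "sex", "rin", "fibro"]]
        design = prep.build_design(covariates)
        adjusted = prep.adjust_covariates(logged, design, keep_mean=True)
    results["adjusted"] = adjusted
    if "prep" in ordered:
        study_io.write_matrix(adjusted, outdir / "adjusted_expression.tsv", header)

    if "de" in ordered:
        de = differential.wmw_differential_expression(adjusted, groups)
        results["de"] = de
        study_io.write_table(de.reset_index(names="gene_id"), outdir / "de_results.tsv", header)
        log.info("de: %d/%d genes flagged", int(de["differential"].sum()), len(de))

    psi = differential.psi_from_counts(cohort.exon_inclusion, cohort.exon_totals)
    if "deu" in ordered:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            deu = differential.diff_exon_usage(psi, groups, covariates=design.drop(columns="intercept"))
        results["deu"] = deu
        study_io.write_table(deu.reset_index(names="part_id"), outdir / "deu_results.tsv", header)
        log.info("deu: %d parts tested, %d flagged", int(deu["tested"].sum()),
                 int(deu["differential"].sum()))

    if "deu-sim" in ordered:
        report = differential.simulate_exon_usage_study(
            n_cases=cfg.n_cases,
            n_controls=cfg.n_controls,
            n_exons=cfg.deu_sim_exons,
            replicates=cfg.deu_sim_replicates,
            seed=cfg.seed,
        )
        results["deu_sim"] = report
        study_io.write_table(report.replicates, outdir / "deu_sim_replicates.tsv", header)
        with open(outdir / "deu_sim_summary.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)

    # eQTL preprocessing path
    rpkm_mat = prep.rpkm(cohort.gene_counts, cohort.gene_models.set_index("gene_id")["length"],
                         cohort.library_sizes)
    expressed = prep.filter_expressed(rpkm_mat, 0.0, 0.5, strict_fraction=False)
    qn = prep.quantile_normalize_samples(rpkm_mat.loc[expressed])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rank_norm = prep.rank_inverse_normal(qn, seed=cfg.seed)
        epcs = prep.genotype_pcs(rank_norm, k=min(cfg.n_expression_pcs, len(groups) - 2))
        gpcs = prep.genotype_pcs(cohort.genotypes, k=cfg.n_genotype_pcs)
        epcs.columns = [f"e{c}" for c in epcs.columns]
        gpcs.columns = [f"g{c}" for c in gpcs.columns]
    eqtl_design = pd.concat([design.drop(columns="intercept"), epcs, gpcs], axis=1)
    pairs = qtl.cis_pairs(cohort.gene_models, cohort.snps, window=cfg.cis_window)
    pairs = pairs[pairs["gene_id"].isin(expressed)].reset_index(drop=True)
    folded = prep.fold_rare_homozygotes(np.round(cohort.genotypes))

    eqtl_res = None
    if {"eqtl", "enrich-gwa", "riskscore", "eqtl-specific"} & set(ordered):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            eqtl_res = qtl.cis_eqtl_scan(rank_norm, folded, eqtl_design, pairs,
                                         p_threshold=cfg.eqtl_p_threshold)
        results["eqtl"] = eqtl_res
        if "eqtl" in ordered:
            study_io.write_table(eqtl_res, outdir / "eqtl_results.tsv", header)
            log.info("eqtl: %d pairs, %d significant", len(eqtl_res),
                     int(eqtl_res["significant"].sum()))

    if "eqtl-specific" in ordered:
        adj_rank = prep.adjust_covariates(rank_norm, eqtl_design, keep_mean=False)
        spec = qtl.specific_eqtl_scan(adj_rank, folded, g01, pairs)
        results["eqtl_specific"] = spec
        study_io.write_table(spec, outdir / "specific_eqtl_results.tsv", header)

    if "sqtl" in ordered:
        exon_logged = np.log2(cohort.exon_totals + 1.0)
        exon_qn = prep.quantile_normalize_samples(exon_logged)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            exon_rn = prep.rank_inverse_normal(exon_qn.T, seed=cfg.seed).T  # within-sample
        by_gene = {
            g: exon_rn.loc[sub["part_id"]]
            for g, sub in cohort.exon_parts.groupby("gene_id", sort=False)
            if len(sub) >= 2
        }
        part_gene = cohort.exon_parts.set_index("part_id")["gene_id"]
        triples = []
        for row in pairs.itertuples(index=False):
            for part in cohort.exon_parts.loc[
                cohort.exon_parts["gene_id"] == row.gene_id, "part_id"
            ]:
                triples.append({"gene_id": row.gene_id, "part_id": part, "snp_id": row.snp_id})
        triple_df = pd.DataFrame(triples).head(cfg.max_sqtl_tests)
        triple_df = triple_df[triple_df["gene_id"].isin(by_gene)]
        sq = qtl.sqtl_scan(by_gene, folded, triple_df)
        results["sqtl"] = sq
        study_io.write_table(sq, outdir / "sqtl_results.tsv", header)
        log.info("sqtl: %d tests, %d significant", len(sq), int(sq["significant"].sum()))

    ase_res = None
    if {"ase", "ase-diff"} & set(ordered):
        ase_res = ase_mod.ase_analysis(cohort.allele_counts, seed=cfg.seed)
        results["ase"] = ase_res
        if "ase" in ordered:
            study_io.write_table(ase_res, outdir / "ase_results.tsv", header)

    if "ase-diff" in ordered and ase_res is not None and len(ase_res):
        grp_map = groups.to_dict()
        ase_res = ase_res.assign(group=ase_res["sample"].map(grp_map))
        rows = []
        for (chrom, pos), sub in ase_res.groupby(["chrom", "pos"], sort=True):
            case_recs = sub[sub["group"] == "case"]
            ctrl_recs = sub[sub["group"] == "control"]
            if len(case_recs) == 0 or len(ctrl_recs) == 0:
                continue
            rec = ase_mod.differential_imbalance(f"{chrom}:{pos}", case_recs, ctrl_recs)
            rows.append(vars(rec))
        diff_df = pd.DataFrame(rows)
        results["ase_diff"] = diff_df
        study_io.write_table(diff_df, outdir / "ase_diff_results.tsv", header)

    if "enrich-gwa" in ordered and eqtl_res is not None:
        ld_pairs = compute_ld_pairs(cohort.genotypes, cohort.snps, max_dist=cfg.cis_window)
        blocks = enrichment.build_ld_blocks(list(cohort.snps["snp_id"]), ld_pairs)
        qtl_snps = set(eqtl_res.loc[eqtl_res["significant"], "snp_id"])
        if not qtl_snps:  # fall back to the strongest decile so the stage runs
            qtl_snps = set(eqtl_res.nsmallest(max(len(eqtl_res) // 10, 1), "p")["snp_id"])
        qtl_blocks = {bid for bid, mem in blocks.blocks.items() if mem & qtl_snps}
        gwa = simulate_gwa_summary(blocks, qtl_blocks, effect=1.0, seed=cfg.seed)
        study_io.write_table(gwa, outdir / "gwa_summary.tsv", header)
        try:
            enr = enrichment.block_enrichment_test(
                blocks, qtl_snps, gwa.set_index("snp_id")["p"]
            )
        except ValueError as exc:
            enr = {"error": str(exc)}
        results["enrich_gwa"] = enr
        with open(outdir / "gwa_enrichment.json", "w") as fh:
            json.dump(enr, fh, indent=2, sort_keys=True)

    if "riskscore" in ordered and eqtl_res is not None and min(
        int(g01.sum()), int((1 - g01).sum())
    ) < 20:
        log.warning("riskscore: skipped (fewer than 20 samples per class)")
        study_io.write_table(
            pd.DataFrame([{"set": "skipped", "median_auc": np.nan,
                           "mean_auc": np.nan, "n_folds": 0}]),
            outdir / "riskscore_summary.tsv", header,
        )
    elif "riskscore" in ordered and eqtl_res is not None:
        top_snps = (
            eqtl_res.dropna(subset=["p"]).sort_values("p").drop_duplicates("snp_id")["snp_id"]
        )
        snp_cols = list(top_snps.head(10))
        feats = cohort.genotypes.loc[snp_cols].T.copy()
        feats["age"] = covariates["age"].to_numpy()
        feats["sex"] = covariates["sex"].to_numpy()
        feats = (feats - feats.mean()) / feats.std(ddof=0).replace(0, 1.0)
        labels = g01.to_numpy().astype(int)
        sets = {"covariates": ["age", "sex"], "eqtl+covariates": snp_cols + ["age", "sex"]}
        n_folds = min(10, int(min(labels.sum(), (1 - labels).sum())))
        models = riskscore.fit_risk_model(
            feats, labels, sets, outer_folds=max(n_folds, 2),
            inner_folds=3, seed=cfg.seed,
        )
        summary = pd.DataFrame(
            [
                {
                    "set": name,
                    "median_auc": m.median_auc,
                    "mean_auc": float(np.mean(m.fold_aucs)),
                    "n_folds": len(m.fold_aucs),
                }
                for name, m in models.items()
            ]
        )
        results["riskscore"] = models
        study_io.write_table(summary, outdir / "riskscore_summary.tsv", header)

    return results


def compute_ld_pairs(genotypes: pd.DataFrame, snps: pd.DataFrame, max_dist: int = 1_000_000,
                     min_r2: float = 0.0) -> pd.DataFrame:
    """Pairwise dosage r-squared for SNPs within ``max_dist`` of each other."""
    rows = []
    arr = genotypes.to_numpy(dtype=float)
    ids = list(genotypes.index)
    pos = snps.set_index("snp_id")["pos"].reindex(ids).to_numpy()
    sd = arr.std(axis=1)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(pos[i] - pos[j]) > max_dist:
                continue
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = np.corrcoef(arr[i], arr[j])[0, 1]
            r2 = float(r * r)
            if r2 >= min_r2:
                rows.append({"snp_a": ids[i], "snp_b": ids[j], "r2": r2,
                             "distance": int(abs(pos[i] - pos[j]))})
    return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "distance"])
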