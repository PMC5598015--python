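"""Synthetic case/control cohorts with the statistical structure the
downstream analyses assume: Hardy-Weinberg genotypes, negative-binomial
expression with log-normal library sizes, binomial exon inclusion given true
PSI, allele-specific read counts, and planted effects of every kind the
pipeline tests for."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedEffects",
    "CohortConfig",
    "StudyCohort",
    "simulate_cohort",
    "simulate_gwa_summary",
]


@dataclass
class PlantedEffects:
    """Ground-truth effects to embed in a simulated cohort.

    eqtl: (gene_id, snp_id, beta) — additive per dosage unit on log scale.
    group_eqtl: (gene_id, snp_id, beta, group) — slope present in one group.
    de: (gene_id, log_fold_change) — case-group expression shift.
    dpsi: (part_id, delta) — additive case-group PSI shift.
    sqtl: (gene_id, part_id, snp_id, shift) — per-dosage PSI shift of one part.
    ase: (site_id, ref_fraction[, group]) — allelic ratio away from balance;
         with a group, the shift applies in that group only.
    """

    eqtl: list = field(default_factory=list)
    group_eqtl: list = field(default_factory=list)
    de: list = field(default_factory=list)
    dpsi: list = field(default_factory=list)
    sqtl: list = field(default_factory=list)
    ase: list = field(default_factory=list)


@dataclass
class CohortConfig:
    n_cases: int = 97
    n_controls: int = 108
    n_genes: int = 50
    n_exons_per_gene: tuple = (3, 8)
    n_snps: int = 100
    maf_range: tuple = (0.1, 0.5)
    fixed_maf: float | None = None
    nb_mean: float = 100.0
    nb_size: float = 4.0
    library_size_sd: float = 0.2
    exon_nb_mean: float = 100.0
    exon_nb_size: float = 4.0
    n_ase_sites: int = 20
    ase_coverage: float = 80.0
    center_confounding: float = 1.0
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    seed: int | None = None

    def __post_init__(self):
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 samples per group")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.nb_mean <= 0 or self.exon_nb_mean <= 0:
            raise ValueError("negative-binomial means must be positive")
        if not 0 <= self.center_confounding <= 1:
            raise ValueError("center_confounding must be in [0, 1]")


@dataclass
class StudyCohort:
    """All simulated components, aligned on the sample axis."""

    samples: pd.DataFrame          # sample_id, group, age, sex, rin, center, fibro
    snps: pd.DataFrame             # snp_id, chrom, pos, ref, alt, maf
    genotypes: pd.DataFrame        # snp x sample dosages in [0, 2]
    gene_models: pd.DataFrame      # gene_id, chrom, start, end, strand, length
    gene_counts: pd.DataFrame      # gene x sample counts
    library_sizes: pd.Series
    exon_parts: pd.DataFrame       # part_id, gene_id, chrom, start, end
    exon_inclusion: pd.DataFrame   # part x sample inclusion reads
    exon_totals: pd.DataFrame      # part x sample total reads
    allele_counts: pd.DataFrame    # sample, site_id, chrom, pos, ref, alt, counts, phred
    truth: dict                    # effect class -> ground-truth table

    @property
    def sample_ids(self) -> pd.Index:
        return self.samples["sample_id"]

    @property
    def groups(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group"]

    def validate(self) -> None:
        sids = list(self.samples["sample_id"])
        assert list(self.genotypes.columns) == sids
        assert list(self.gene_counts.columns) == sids
        assert list(self.exon_inclusion.columns) == sids
        assert list(self.exon_totals.columns) == sids
        g = self.genotypes.to_numpy()
        assert ((g >= 0) & (g <= 2)).all(), "dosages outside [0, 2]"
        assert (self.gene_counts.to_numpy() >= 0).all()
        assert (self.exon_inclusion.to_numpy() <= self.exon_totals.to_numpy()).all()


GENE_SPACING = 2_000_000  # bp between simulated gene starts; keeps cis windows tidy


def _check_effects(cfg: CohortConfig, gene_ids, snp_ids, part_ids, site_ids):
    eff = cfg.effects

    def _require(kind, name, pool):
        if name not in pool:
            raise ValueError(f"planted {kind} references unknown feature {name!r}")

    for gene, snp, _ in eff.eqtl:
        _require("eQTL gene", gene, gene_ids)
        _require("eQTL SNP", snp, snp_ids)
    for gene, snp, _, group in eff.group_eqtl:
        _require("group-eQTL gene", gene, gene_ids)
        _require("group-eQTL SNP", snp, snp_ids)
        if group not in ("case", "control"):
            raise ValueError(f"unknown group {group!r} in planted group-eQTL")
    for gene, _ in eff.de:
        _require("DE gene", gene, gene_ids)
    for part, _ in eff.dpsi:
        _require("dPSI exon part", part, part_ids)
    for gene, part, snp, _ in eff.sqtl:
        _require("sQTL gene", gene, gene_ids)
        _require("sQTL exon part", part, part_ids)
        _require("sQTL SNP", snp, snp_ids)
    for entry in eff.ase:
        _require("ASE site", entry[0], site_ids)


def simulate_cohort(config: CohortConfig) -> StudyCohort:
    """Draw a full study cohort from the configured generative model.

    Genotypes come from Hardy-Weinberg proportions at per-SNP MAFs; gene
    counts from a negative binomial whose log mean carries library size,
    planted fold changes (case group), and planted additive per-dosage eQTL
    shifts; exon inclusion from Binomial(total, PSI) with planted group and
    genotype-interaction PSI shifts; allele counts from binomials around the
    (possibly shifted) reference fraction.  The same seed reproduces the
    cohort exactly.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            ("covariates", "genotypes", "genes", "expression", "exons", "ase"),
            root.spawn(6),
        )
    }

    n = config.n_cases + config.n_controls
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    group = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)

    rc = rngs["covariates"]
    center = np.where(
        group == "case",
        "center_A",
        np.where(rc.uniform(size=n) < config.center_confounding, "center_B", "center_A"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group,
            "age": np.round(rc.normal(55, 10, size=n), 1),
            "sex": rc.integers(0, 2, size=n),
            "rin": np.round(rc.normal(8.0, 0.7, size=n), 2),
            "center": center,
            "fibro": rc.normal(0.0, 1.0, size=n),
        }
    )

    # gene models: one per GENE_SPACING slot along a single synthetic chromosome
    rg = rngs["genes"]
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    starts = np.arange(config.n_genes) * GENE_SPACING + 500_000
    lengths = rg.integers(1_000, 10_000, size=config.n_genes)
    gene_models = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr1",
            "start": starts,
            "end": starts + lengths,
            "strand": np.where(rg.uniform(size=config.n_genes) < 0.5, "+", "-"),
            "length": lengths,
        }
    )

    # SNPs round-robin within the cis window of each gene
    rs = rngs["genotypes"]
    snp_ids = [f"rs{i + 1:05d}" for i in range(config.n_snps)]
    host = np.arange(config.n_snps) % config.n_genes
    pos = starts[host] + rs.integers(-400_000, 400_000, size=config.n_snps)
    pos = np.maximum(pos, 1)
    if config.fixed_maf is not None:
        maf = np.full(config.n_snps, float(config.fixed_maf))
    else:
        maf = rs.uniform(*config.maf_range, size=config.n_snps)
    hwe = np.column_stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
    u = rs.uniform(size=(config.n_snps, n))
    cum = np.cumsum(hwe, axis=1)
    dosage = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(float)
    bases = np.array(list("ACGT"))
    ref = bases[rs.integers(0, 4, size=config.n_snps)]
    alt = np.array([bases[(list(bases).index(r) + 1 + rs.integers(0, 3)) % 4] for r in ref])
    snps = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": "chr1", "pos": pos, "ref": ref, "alt": alt, "maf": maf}
    )
    genotypes = pd.DataFrame(dosage, index=snp_ids, columns=sample_ids)

    # exon parts
    lo, hi = config.n_exons_per_gene
    n_parts_per_gene = rg.integers(lo, hi + 1, size=config.n_genes)
    part_rows = []
    for g_idx, gene in enumerate(gene_ids):
        width = lengths[g_idx] // (n_parts_per_gene[g_idx] + 1)
        for k in range(n_parts_per_gene[g_idx]):
            s = starts[g_idx] + k * (width + 10)
            part_rows.append(
                {
                    "part_id": f"{gene}:E{k + 1:03d}",
                    "gene_id": gene,
                    "chrom": "chr1",
                    "start": s,
                    "end": s + width,
                }
            )
    exon_parts = pd.DataFrame(part_rows)
    part_ids = list(exon_parts["part_id"])

    site_ids = [f"site_{i + 1:03d}" for i in range(config.n_ase_sites)]
    _check_effects(config, set(gene_ids), set(snp_ids), set(part_ids), set(site_ids))
    is_case = group == "case"

    # gene counts
    re_ = rngs["expression"]
    log_lib = re_.normal(0.0, config.library_size_sd, size=n)
    lib_factor = np.exp(log_lib)
    base_mu = re_.normal(np.log(config.nb_mean), 0.5, size=config.n_genes)
    log_mean = base_mu[:, None] + log_lib[None, :]
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    snp_pos = {s: i for i, s in enumerate(snp_ids)}
    for gene, lfc in config.effects.de:
        log_mean[gene_pos[gene], is_case] += lfc
    for gene, snp, beta in config.effects.eqtl:
        log_mean[gene_pos[gene]] += beta * dosage[snp_pos[snp]]
    for gene, snp, beta, grp in config.effects.group_eqtl:
        mask = is_case if grp == "case" else ~is_case
        log_mean[gene_pos[gene], mask] += beta * dosage[snp_pos[snp], mask]
    mean = np.exp(log_mean)
    p_nb = config.nb_size / (config.nb_size + mean)
    gene_counts = pd.DataFrame(
        re_.negative_binomial(config.nb_size, p_nb),
        index=gene_ids,
        columns=sample_ids,
    )
    library_sizes = pd.Series(
        np.round(1e6 * lib_factor).astype(int), index=sample_ids, name="library_size"
    )

    # exon usage
    rx = rngs["exons"]
    n_parts = len(part_ids)
    p_nb_x = config.exon_nb_size / (config.exon_nb_size + config.exon_nb_mean)
    totals = rx.negative_binomial(config.exon_nb_size, p_nb_x, size=(n_parts, n))
    true_psi = rx.uniform(0.05, 0.95, size=n_parts)
    psi = np.repeat(true_psi[:, None], n, axis=1)
    part_pos = {p: i for i, p in enumerate(part_ids)}
    for part, delta in config.effects.dpsi:
        psi[part_pos[part], is_case] += delta
    for gene, part, snp, shift in config.effects.sqtl:
        psi[part_pos[part]] += shift * dosage[snp_pos[snp]]
    psi = np.clip(psi, 0.0, 1.0)
    inclusion = rx.binomial(totals, psi)
    exon_totals = pd.DataFrame(totals, index=part_ids, columns=sample_ids)
    exon_inclusion = pd.DataFrame(inclusion, index=part_ids, columns=sample_ids)

    # allele-specific counts
    ra = rngs["ase"]
    ase_shift = {}
    for entry in config.effects.ase:
        site, frac = entry[0], entry[1]
        grp = entry[2] if len(entry) > 2 else None
        ase_shift[site] = (float(frac), grp)
    ase_rows = []
    site_pos = 1_000 + np.arange(config.n_ase_sites) * 50_000
    for si, site in enumerate(site_ids):
        het = ra.uniform(size=n) < 0.4
        for j in np.flatnonzero(het):
            total = 30 + ra.poisson(max(config.ase_coverage - 30, 1))
            frac, grp = ase_shift.get(site, (0.5, None))
            use_shift = grp is None or (grp == "case") == bool(is_case[j])
            p_ref = frac if use_shift else 0.5
            ref_reads = ra.binomial(total, p_ref)
            ase_rows.append(
                {
                    "sample": sample_ids[j],
                    "site_id": site,
                    "chrom": "chr1",
                    "pos": int(site_pos[si]),
                    "ref": "A",
                    "alt": "G",
                    "ref_reads": int(ref_reads),
                    "alt_reads": int(total - ref_reads),
                    "phred": 40,
                }
            )
    allele_counts = pd.DataFrame(ase_rows)

    truth = {
        "eqtl": pd.DataFrame(config.effects.eqtl, columns=["gene_id", "snp_id", "beta"]),
        "group_eqtl": pd.DataFrame(
            config.effects.group_eqtl, columns=["gene_id", "snp_id", "beta", "group"]
        ),
        "de": pd.DataFrame(config.effects.de, columns=["gene_id", "lfc"]),
        "dpsi": pd.DataFrame(config.effects.dpsi, columns=["part_id", "delta"]),
        "sqtl": pd.DataFrame(
            config.effects.sqtl, columns=["gene_id", "part_id", "snp_id", "shift"]
        ),
        "ase": pd.DataFrame(
            [(e[0], e[1], e[2] if len(e) > 2 else None) for e in config.effects.ase],
            columns=["site_id", "ref_fraction", "group"],
        ),
        "true_psi": pd.DataFrame({"part_id": part_ids, "psi": true_psi}),
    }

    cohort = StudyCohort(
        samples=samples,
        snps=snps,
        genotypes=genotypes,
        gene_models=gene_models,
        gene_counts=gene_counts,
        library_sizes=library_sizes,
        exon_parts=exon_parts,
        exon_inclusion=exon_inclusion,
        exon_totals=exon_totals,
        allele_counts=allele_counts,
        truth=truth,
    )
    cohort.validate()
    return cohort


def simulate_gwa_summary(blocks, enriched_block_ids, effect: float = 0.0, seed=None) -> pd.DataFrame:
    """Per-SNP GWA p-values with planted block-level enrichment.

    SNPs in non-enriched blocks get Uniform(0, 1) p-values; SNPs in enriched
    blocks get p = u * 10**(-effect), i.e. a shift of ``effect`` decades on
    the -log10 scale.
    """
    if len(blocks.blocks) == 0:
        raise ValueError("empty block set")
    enriched = set(enriched_block_ids)
    unknown = enriched - set(blocks.blocks)
    if unknown:
        raise KeyError(f"unknown block id(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for bid in sorted(blocks.blocks):
        boost = 10.0 ** (-effect) if bid in enriched else 1.0
        for snp in sorted(blocks.blocks[bid]):
            rows.append({"snp_id": snp, "p": float(rng.uniform()) * boost, "block_id": bid})
    return pd.DataFrame(rows)
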