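"""LD-block GWA enrichment, functional-annotation logistic regression,
gene-set Fisher tests, and GWA/eQTL intersection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LdBlockSet",
    "build_ld_blocks",
    "block_enrichment_test",
    "annotation_enrichment",
    "build_annotation_dataset",
    "distance_bins",
    "DISTANCE_BIN_LABELS",
    "match_hexamers",
    "geneset_fisher",
    "gwa_eqtl_overlap",
]


@dataclass
class LdBlockSet:
    """Partition of a SNP universe into LD blocks (connected components)."""

    blocks: dict  # block id -> frozenset of SNP ids
    snp_to_block: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.snp_to_block:
            self.snp_to_block = {
                snp: bid for bid, members in self.blocks.items() for snp in members
            }

    def __len__(self) -> int:
        return len(self.blocks)

    def members(self, block_id) -> frozenset:
        return self.blocks[block_id]


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_ld_blocks(snp_ids, ld_pairs: pd.DataFrame, rsq_threshold: float = 0.6) -> LdBlockSet:
    """Connected components of SNPs under the relation r-squared > threshold.

    SNPs without qualifying links become singleton blocks.  Block ids are
    ``block_<n>`` numbered by the lexicographically smallest member, which
    makes the result invariant to pair ordering and duplication.
    """
    r2 = ld_pairs["r2"].to_numpy(dtype=float) if len(ld_pairs) else np.array([])
    if len(r2) and ((r2 < 0).any() or (r2 > 1).any()):
        raise ValueError("r2 values must lie in [0, 1]")
    uf = _UnionFind()
    for snp in snp_ids:
        uf.find(snp)
    for row in ld_pairs.itertuples(index=False):
        if row.r2 > rsq_threshold:
            uf.union(row.snp_a, row.snp_b)
    groups: dict = {}
    for snp in uf.parent:
        groups.setdefault(uf.find(snp), set()).add(snp)
    ordered = sorted(groups.values(), key=lambda s: min(str(x) for x in s))
    blocks = {f"block_{i}": frozenset(members) for i, members in enumerate(ordered)}
    return LdBlockSet(blocks=blocks)


def block_enrichment_test(
    blocks: LdBlockSet,
    marked_snps,
    gwa_p: pd.Series,
    summary: str = "min",
) -> dict:
    """One-sided rank-sum test that GWA p-values of marked LD blocks are
    smaller than those of unmarked blocks.

    A block is marked when it contains at least one marked SNP (e.g. a QTL
    variant); its summary p is the smallest (or second-smallest, for the
    outlier-robust variant) GWA p among member SNPs that have one.
    """
    if summary not in ("min", "second_min"):
        raise ValueError("summary must be 'min' or 'second_min'")
    marked_snps = set(marked_snps)
    marked_vals, unmarked_vals = [], []
    for bid, members in blocks.blocks.items():
        ps = gwa_p.reindex([m for m in members if m in gwa_p.index]).dropna()
        if len(ps) == 0:
            raise ValueError(f"block {bid} has no SNP with a GWA p-value")
        vals = np.sort(ps.to_numpy())
        stat = vals[0] if summary == "min" or len(vals) == 1 else vals[1]
        if members & marked_snps:
            marked_vals.append(stat)
        else:
            unmarked_vals.append(stat)
    if not marked_vals or not unmarked_vals:
        raise ValueError("need both marked and unmarked blocks for a contrast")
    res = stats.mannwhitneyu(marked_vals, unmarked_vals, alternative="less")
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "n_marked": len(marked_vals),
        "n_unmarked": len(unmarked_vals),
    }


DISTANCE_BIN_LABELS = (
    "dist_1_10kb",
    "dist_10_20kb",
    "dist_20_30kb",
    "dist_30_40kb",
    "dist_40_50kb",
)


def distance_bins(distance: float) -> dict:
    """One-hot encode a SNP-target distance into five 10-kb bins.

    Distances beyond 50 kb fall into the implicit reference category (all
    zeros); distance 0 means the SNP lies inside the target and sets only the
    ``inside`` flag.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    out = {label: 0 for label in DISTANCE_BIN_LABELS}
    out["inside"] = 0
    if distance == 0:
        out["inside"] = 1
        return out
    bin_idx = int(np.ceil(distance / 10_000)) - 1
    if bin_idx < 5:
        out[DISTANCE_BIN_LABELS[bin_idx]] = 1
    return out


def build_annotation_dataset(
    qtl_results: pd.DataFrame,
    features: pd.DataFrame,
    target_col: str = "gene_id",
    snp_col: str = "snp_id",
    sig_col: str = "significant",
    p_col: str = "p",
) -> pd.DataFrame:
    """Causal-labeling dataset for :func:`annotation_enrichment`.

    One row per tested (SNP, target) pair; label 1 iff the SNP is the most
    significantly associated SNP for that target.  Pairs where the SNP is
    significant for the target but not its top hit are removed — they may be
    causal too and would dilute the contrast if labeled negative.
    """
    df = qtl_results[[target_col, snp_col, sig_col, p_col]].dropna(subset=[p_col]).copy()
    top_idx = df.groupby(target_col)[p_col].idxmin()
    df["label"] = 0
    df.loc[top_idx, "label"] = 1
    excluded = df[sig_col].astype(bool) & (df["label"] == 0)
    kept = df.loc[~excluded, [target_col, snp_col, "label"]]
    merged = kept.merge(features, on=[target_col, snp_col], how="inner")
    merged.attrs["n_excluded"] = int(excluded.sum())
    return merged


def annotation_enrichment(dataset: pd.DataFrame, feature_cols=None, label_col: str = "label") -> pd.DataFrame:
    """Multiple logistic regression of the causal label on binary annotations.

    Returns per-feature log-odds, odds ratio, Wald 95% CI, and
    likelihood-ratio p (full model vs model without that feature).
    Degenerate (constant) feature columns are dropped with a warning; perfect
    separation is flagged with unbounded CIs.
    """
    if feature_cols is None:
        feature_cols = [
            c for c in dataset.columns if c not in (label_col,) and dataset[c].dtype.kind in "ifb"
        ]
    y = dataset[label_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both positive and negative labels")
    X = dataset[list(feature_cols)].to_numpy(dtype=float)
    keep = [j for j in range(X.shape[1]) if len(np.unique(X[:, j])) > 1]
    dropped = [feature_cols[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropped degenerate feature columns: {dropped}", UserWarning, stacklevel=2)
    cols = [feature_cols[j] for j in keep]
    X = X[:, keep]
    Xc = sm.add_constant(X, has_constant="add")

    def _fit(mat):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, mat, family=sm.families.Binomial())
            return model.fit(maxiter=200)

    full = _fit(Xc)
    separated = bool(np.any(np.abs(full.params) > 20))
    rows = []
    for j, name in enumerate(cols):
        beta = full.params[j + 1]
        se = full.bse[j + 1]
        sub = np.delete(Xc, j + 1, axis=1)
        red = _fit(sub)
        lrt = 2.0 * (full.llf - red.llf)
        p = float(stats.chi2.sf(max(lrt, 0.0), 1))
        lo, hi = beta - 1.96 * se, beta + 1.96 * se
        rows.append(
            {
                "feature": name,
                "beta": float(beta),
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "p": p,
                "separated": separated and abs(beta) > 20,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["converged"] = bool(full.converged)
    out.attrs["separated"] = separated
    return out


def match_hexamers(sequence: str, hexamer_set) -> list:
    """All (possibly overlapping) start positions where any set member occurs.

    Windows containing non-ACGT characters are skipped with a warning (e.g.
    splice-enhancer hexamer scans over masked sequence).
    """
    seq = sequence
    hexamers = {h for h in hexamer_set}
    if not hexamers:
        return []
    k = len(next(iter(hexamers)))
    if any(len(h) != k for h in hexamers):
        raise ValueError("all hexamers must have equal length")
    positions = []
    skipped = 0
    valid = set("ACGT")
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if not set(window) <= valid:
            skipped += 1
            continue
        if window in hexamers:
            positions.append(i)
    if skipped:
        warnings.warn(f"skipped {skipped} window(s) with non-ACGT characters", UserWarning,
                      stacklevel=2)
    return positions


def _woolf_ci(table: np.ndarray, alpha: float = 0.05) -> tuple:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane correction
    orr = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = np.sqrt((1.0 / t).sum())
    z = stats.norm.ppf(1 - alpha / 2)
    return float(orr), float(orr * np.exp(-z * se)), float(orr * np.exp(z * se))


def geneset_fisher(hits, gene_set, universe) -> dict:
    """Fisher's exact test for overrepresentation of ``gene_set`` among
    ``hits`` within ``universe``, with a Woolf-type confidence interval for
    the odds ratio (Haldane 0.5 correction when a cell is empty)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits) & universe
    gene_set = set(gene_set) & universe
    a = len(hits & gene_set)
    b = len(hits - gene_set)
    c = len(gene_set - hits)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if (table == 0).any():
        warnings.warn("zero cell in contingency table; Haldane correction applied",
                      UserWarning, stacklevel=2)
    orr, lo, hi = _woolf_ci(table)
    return {"odds_ratio": orr, "ci_low": lo, "ci_high": hi, "p": p, "table": table}


def gwa_eqtl_overlap(
    gwa_table: pd.DataFrame,
    proxy_table: pd.DataFrame,
    qtl_results: pd.DataFrame,
    expressed_genes,
) -> dict:
    """Annotate GWA loci with eQTL evidence and test for enrichment.

    For each GWA SNP and candidate gene, the SNP itself is used when it was
    tested for that gene; otherwise its best proxy (highest r2, ties broken by
    smaller distance) among tested proxies contributes.  The universe for the
    Fisher test is every tested SNP restricted to ``expressed_genes``,
    classified eQTL/non-eQTL (significance flag) x GWA-linked/not.

    ``proxy_table`` columns: gwa_snp, proxy_snp, r2, distance.
    """
    expressed = set(expressed_genes)
    qtl = qtl_results[qtl_results["gene_id"].isin(expressed)]
    tested_pairs = set(zip(qtl["snp_id"], qtl["gene_id"]))
    qtl_lookup = {(r.snp_id, r.gene_id): r for r in qtl.itertuples(index=False)}

    annotations = []
    gwa_linked_snps: set = set()
    for row in gwa_table.itertuples(index=False):
        genes = [g for g in str(row.candidate_genes).split(";") if g] if hasattr(
            row, "candidate_genes"
        ) and pd.notna(row.candidate_genes) else sorted({g for _, g in tested_pairs})
        for gene in genes:
            if gene not in expressed:
                continue
            chosen = None
            if (row.snp_id, gene) in tested_pairs:
                chosen = (row.snp_id, 1.0, 0.0)
            else:
                proxies = proxy_table[proxy_table["gwa_snp"] == row.snp_id]
                proxies = proxies[
                    [(p, gene) in tested_pairs for p in proxies["proxy_snp"]]
                ]
                if len(proxies):
                    best = proxies.sort_values(
                        ["r2", "distance"], ascending=[False, True], kind="mergesort"
                    ).iloc[0]
                    chosen = (best["proxy_snp"], float(best["r2"]), float(best["distance"]))
            if chosen is None:
                annotations.append(
                    {"gwa_snp": row.snp_id, "gene_id": gene, "evaluable": False}
                )
                continue
            snp, r2, dist = chosen
            fit = qtl_lookup[(snp, gene)]
            gwa_linked_snps.add(snp)
            annotations.append(
                {
                    "gwa_snp": row.snp_id,
                    "gene_id": gene,
                    "tested_snp": snp,
                    "proxy_r2": r2,
                    "eqtl_p": fit.p,
                    "eqtl_significant": bool(fit.significant),
                    "evaluable": True,
                }
            )

    is_eqtl = qtl.groupby("snp_id")["significant"].any()
    is_gwa = pd.Series(
        {snp: snp in gwa_linked_snps for snp in is_eqtl.index}, dtype=bool
    )
    a = int((is_eqtl & is_gwa).sum())
    b = int((is_eqtl & ~is_gwa).sum())
    c = int((~is_eqtl & is_gwa).sum())
    d = int((~is_eqtl & ~is_gwa).sum())
    table = np.array([[a, c], [b, d]])
    fet_p = float(stats.fisher_exact(table)[1])
    orr, lo, hi = _woolf_ci(table)
    return {
        "annotations": pd.DataFrame(annotations),
        "table": table,
        "odds_ratio": orr,
        "ci_low": lo,
        "ci_high": hi,
        "p": fet_p,
    }
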