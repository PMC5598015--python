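"""Allele-specific expression: per-individual binomial imbalance testing with
coverage resampling, and case/control differential imbalance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .qtl import storey_qvalues

__all__ = [
    "filter_ase_sites",
    "individual_expected_ratio",
    "ase_site_test",
    "ase_analysis",
    "DifferentialAseRecord",
    "differential_imbalance",
    "ld_prune",
]

MIN_PHRED_DEFAULT = 30
MIN_READS_DEFAULT = 30


def _in_intervals(chrom, pos, intervals: pd.DataFrame | None) -> np.ndarray:
    """Membership of 1-based positions in a 0-based half-open interval table."""
    hit = np.zeros(len(pos), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    for c, sub in intervals.groupby("chrom", sort=False):
        mask = chrom == c
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p0 = pos[mask] - 1  # to 0-based
        inside = np.zeros(p0.size, dtype=bool)
        for s, e in zip(starts, ends):
            inside |= (p0 >= s) & (p0 < e)
        hit[mask] = inside
    return hit


def filter_ase_sites(
    site_table: pd.DataFrame,
    min_phred: float = MIN_PHRED_DEFAULT,
    min_reads: int = MIN_READS_DEFAULT,
    mappability_mask: pd.DataFrame | None = None,
    sim_bias_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Quality filter for allele-count records.

    Keeps sites with base quality strictly above ``min_phred``, total coverage
    of at least ``min_reads``, both alleles observed, and not overlapping
    either mapping-bias mask (BED-style interval tables).
    """
    df = site_table
    total = df["ref_reads"] + df["alt_reads"]
    keep = (
        (df["phred"] > min_phred)
        & (total >= min_reads)
        & (df["ref_reads"] > 0)
        & (df["alt_reads"] > 0)
    )
    keep &= ~_in_intervals(df["chrom"], df["pos"], mappability_mask)
    keep &= ~_in_intervals(df["chrom"], df["pos"], sim_bias_mask)
    return df.loc[keep].copy()


def individual_expected_ratio(records: pd.DataFrame) -> float:
    """Expected reference-allele ratio for one individual: the unweighted mean
    of per-site ref/(ref+alt) over that individual's passing het sites.

    Corrects residual genome-wide mapping/GC bias before site-level testing.
    """
    if len(records) == 0:
        raise ValueError("no passing heterozygous sites for this individual")
    ratios = records["ref_reads"] / (records["ref_reads"] + records["alt_reads"])
    return float(ratios.mean())


def ase_site_test(
    ref: int,
    alt: int,
    expected_ratio: float,
    mean_total: float,
    seed=None,
    resample: bool = True,
) -> dict:
    """Binomial imbalance test for one het site after coverage resampling.

    The site's counts are redrawn at ``n = round(mean_total)`` with the
    observed reference fraction so that coverage differences between sites do
    not drive significance; the two-sided exact binomial test then compares
    the resampled reference count against ``expected_ratio``.
    """
    if mean_total < 1:
        raise ValueError("mean_total must be >= 1")
    if not 0 < expected_ratio < 1:
        raise ValueError("expected_ratio must be in (0, 1)")
    total = ref + alt
    if total <= 0:
        raise ValueError("site has no reads")
    n = int(round(mean_total))
    if resample:
        rng = np.random.default_rng(seed)
        ref_rs = int(rng.binomial(n, ref / total))
    else:
        ref_rs = int(ref)
        n = int(total)
    p = stats.binomtest(ref_rs, n, expected_ratio, alternative="two-sided").pvalue
    return {"p": float(p), "ref_resampled": ref_rs, "alt_resampled": n - ref_rs, "n": n}


def ase_analysis(
    counts: pd.DataFrame,
    min_phred: float = MIN_PHRED_DEFAULT,
    min_reads: int = MIN_READS_DEFAULT,
    mappability_mask: pd.DataFrame | None = None,
    sim_bias_mask: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
    seed=None,
    resample: bool = True,
) -> pd.DataFrame:
    """Full per-individual ASE pass over an allele-count table.

    Input columns: sample, chrom, pos, ref, alt, ref_reads, alt_reads, phred.
    Per individual the expected reference ratio and mean total count are
    computed from that individual's passing sites (original counts); each site
    is then resampled and binomially tested, with q-values per individual.
    """
    passing = filter_ase_sites(counts, min_phred, min_reads, mappability_mask, sim_bias_mask)
    out_rows = []
    rng = np.random.default_rng(seed)
    for sample, recs in passing.groupby("sample", sort=False):
        expected = individual_expected_ratio(recs)
        mean_total = float((recs["ref_reads"] + recs["alt_reads"]).mean())
        for row in recs.itertuples(index=False):
            res = ase_site_test(
                row.ref_reads,
                row.alt_reads,
                expected,
                mean_total,
                seed=rng,
                resample=resample,
            )
            out_rows.append(
                {
                    "sample": sample,
                    "chrom": row.chrom,
                    "pos": row.pos,
                    "ref": row.ref,
                    "alt": row.alt,
                    "ref_reads": row.ref_reads,
                    "alt_reads": row.alt_reads,
                    "expected_ratio": expected,
                    "ref_resampled": res["ref_resampled"],
                    "alt_resampled": res["alt_resampled"],
                    "p": res["p"],
                }
            )
    out = pd.DataFrame(out_rows)
    if len(out) == 0:
        out["q"] = []
        out["imbalanced"] = []
        return out
    qs = np.full(len(out), np.nan)
    for sample, idx in out.groupby("sample", sort=False).groups.items():
        pvec = out.loc[idx, "p"].to_numpy()
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            qs[out.index.get_indexer(idx)] = storey_qvalues(pvec).q_values
    out["q"] = qs
    out["imbalanced"] = out["q"] < q_threshold
    return out


@dataclass
class DifferentialAseRecord:
    """Case/control comparison of imbalance at one site."""

    site_id: str
    het_case: int
    imb_case: int
    het_control: int
    imb_control: int
    fet_p: float
    prop_p: float
    alt_ratio_case: float
    alt_ratio_control: float
    delta_ratio: float
    differential: bool


def differential_imbalance(
    site_id: str,
    case_records: pd.DataFrame,
    control_records: pd.DataFrame,
    fet_alpha: float = 0.05,
    delta_threshold: float = 0.10,
) -> DifferentialAseRecord:
    """Compare imbalance between groups at a shared het site.

    Fisher's exact test contrasts the number of imbalanced heterozygotes;
    a two-proportion z-test contrasts pooled alternative-allele fractions.
    Flagged when FET p < ``fet_alpha`` and the absolute difference in mean
    alt-allele ratio exceeds ``delta_threshold``.

    Each record table needs columns imbalanced, ref_reads, alt_reads (one row
    per heterozygous individual).
    """
    for name, recs in (("case", case_records), ("control", control_records)):
        if len(recs) == 0:
            raise ValueError(f"no heterozygous individuals in {name} group")
    het_a, het_b = len(case_records), len(control_records)
    imb_a = int(case_records["imbalanced"].sum())
    imb_b = int(control_records["imbalanced"].sum())
    table = [[imb_a, het_a - imb_a], [imb_b, het_b - imb_b]]
    fet_p = float(stats.fisher_exact(table, alternative="two-sided")[1])

    alt_a = case_records["alt_reads"].sum()
    tot_a = alt_a + case_records["ref_reads"].sum()
    alt_b = control_records["alt_reads"].sum()
    tot_b = alt_b + control_records["ref_reads"].sum()
    if tot_a > 0 and tot_b > 0:
        _, prop_p = proportions_ztest([alt_a, alt_b], [tot_a, tot_b])
        prop_p = float(prop_p)
    else:  # pragma: no cover - filtered upstream
        prop_p = float("nan")
    ratio_a = (case_records["alt_reads"] / (case_records["alt_reads"] + case_records["ref_reads"])).mean()
    ratio_b = (control_records["alt_reads"] / (control_records["alt_reads"] + control_records["ref_reads"])).mean()
    delta = abs(float(ratio_a) - float(ratio_b))
    return DifferentialAseRecord(
        site_id=site_id,
        het_case=het_a,
        imb_case=imb_a,
        het_control=het_b,
        imb_control=imb_b,
        fet_p=fet_p,
        prop_p=prop_p,
        alt_ratio_case=float(ratio_a),
        alt_ratio_control=float(ratio_b),
        delta_ratio=delta,
        differential=(fet_p < fet_alpha) and (delta > delta_threshold),
    )


def ld_prune(sites: pd.DataFrame, ld_pairs: pd.DataFrame, r2_threshold: float = 0.8) -> pd.DataFrame:
    """Greedy LD pruning of a ranked site list.

    Sites are visited by ascending p (ties broken by position); a site is
    dropped when it is linked at r-squared above the threshold to any already
    kept site.  ``sites`` needs columns site_id, p, pos; ``ld_pairs`` needs
    snp_a, snp_b, r2 (treated as symmetric).
    """
    linked: dict[str, set] = {}
    for row in ld_pairs.itertuples(index=False):
        if row.r2 > r2_threshold:
            linked.setdefault(row.snp_a, set()).add(row.snp_b)
            linked.setdefault(row.snp_b, set()).add(row.snp_a)
    ordered = sites.sort_values(["p", "pos"], kind="mergesort")
    kept: list[str] = []
    kept_set: set = set()
    for row in ordered.itertuples(index=False):
        if any(other in kept_set for other in linked.get(row.site_id, ())):
            continue
        kept.append(row.site_id)
        kept_set.add(row.site_id)
    return sites[sites["site_id"].isin(kept_set)].copy()
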