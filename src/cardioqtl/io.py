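"""Readers and writers for the interchange formats: TSV matrices and tables
(with provenance headers), VCF genotypes, and BED intervals."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
    "load_genotypes",
    "write_vcf",
    "load_intervals",
    "overlap_intervals",
    "provenance_header",
]


def provenance_header(config_hash: str = "", seed=None) -> str:
    return f"# cardioqtl={__version__} config={config_hash} seed={seed}"


def config_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, header: str | None = None, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_matrix(df: pd.DataFrame, path, header: str | None = None) -> None:
    """Feature-by-sample matrix TSV: row ids in the first column, sample ids
    in the header row."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=True, index_label="feature_id", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_vcf(genotypes: pd.DataFrame, snps: pd.DataFrame, path, dosages: bool = True) -> None:
    """Write a minimal uncompressed VCF with GT and (optionally) DS fields."""
    path = Path(path)
    samples = list(genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosages:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        fmt = "GT:DS" if dosages else "GT"
        order = snps.sort_values(["chrom", "pos"], kind="mergesort")
        for row in order.itertuples(index=False):
            ds = genotypes.loc[row.snp_id].to_numpy(dtype=float)
            calls = []
            for d in ds:
                g = int(round(d))
                gt = ("0/0", "0/1", "1/1")[min(max(g, 0), 2)]
                calls.append(f"{gt}:{d:.4g}" if dosages else gt)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"{fmt}\t" + "\t".join(calls) + "\n"
            )


def _load_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    samples: list = []
    snp_rows = []
    dosage_rows = []
    n_multi = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise ValueError(f"malformed VCF header at line {lineno}: no samples")
                samples = cols[9:]
                continue
            if not samples:
                raise ValueError(f"malformed VCF: records before #CHROM header at line {lineno}")
            parts = line.split("\t")
            if len(parts) != 9 + len(samples):
                raise ValueError(f"malformed VCF record at line {lineno}")
            chrom, pos, vid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if "," in alt:
                n_multi += 1
                continue
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT") if "GT" in fmt else None
            ds_i = fmt.index("DS") if "DS" in fmt else None
            if gt_i is None and ds_i is None:
                raise ValueError(f"record at line {lineno} has neither GT nor DS")
            row = []
            for call in parts[9:]:
                fields = call.split(":")
                if ds_i is not None and ds_i < len(fields) and fields[ds_i] not in (".", ""):
                    row.append(float(fields[ds_i]))
                elif gt_i is not None:
                    gt = fields[gt_i].replace("|", "/")
                    if "." in gt:
                        row.append(np.nan)
                    else:
                        row.append(float(sum(int(a) for a in gt.split("/"))))
                else:
                    row.append(np.nan)
            snp_rows.append({"snp_id": vid, "chrom": chrom, "pos": int(pos),
                             "ref": ref, "alt": alt})
            dosage_rows.append(row)
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s)", UserWarning, stacklevel=3)
    snps = pd.DataFrame(snp_rows)
    geno = pd.DataFrame(dosage_rows, index=snps["snp_id"].to_numpy(), columns=samples)
    return geno, snps


def load_genotypes(path):
    """Load a genotype dosage matrix from a VCF (GT/DS; DS preferred) or a
    TSV with SNP row ids and sample columns.

    Returns ``(dosages, snp_table)``; for TSV input the SNP table holds ids
    only.  Dosages are clipped-checked to [0, 2] and the MAF column is
    computed from the dosage mean.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        geno, snps = _load_vcf(path)
    else:
        geno = read_matrix(path)
        snps = pd.DataFrame({"snp_id": geno.index})
    arr = geno.to_numpy(dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size and ((finite < 0).any() or (finite > 2).any()):
        raise ValueError("dosages outside [0, 2]")
    freq = np.nanmean(arr, axis=1) / 2.0
    snps = snps.copy()
    snps["maf"] = np.minimum(freq, 1 - freq)
    return geno, snps


def load_intervals(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into a sorted interval table;
    an optional 4th column is kept as ``label``."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"malformed BED line {lineno}: start >= end")
            row = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                row["label"] = parts[3]
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return df


def overlap_intervals(intervals: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Rows of a 0-based half-open interval table overlapping [start, end)."""
    sub = intervals[intervals["chrom"] == chrom]
    return sub[(sub["start"] < end) & (sub["end"] > start)]
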