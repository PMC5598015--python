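"""Normalization, transformation, covariate adjustment, and genotype utilities.

All matrix-valued functions operate on :class:`pandas.DataFrame` objects with
features in rows and samples in columns.  The :class:`ExpressionMatrix`
wrapper tracks the processing stage so that pipelines can assert they are
feeding the right representation into each analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "STAGES",
    "scale_counts_quantile",
    "rpkm",
    "filter_expressed",
    "quantile_normalize_samples",
    "rank_inverse_normal",
    "build_design",
    "adjust_covariates",
    "fibroblast_score",
    "fold_rare_homozygotes",
    "genotype_concordance",
    "genotype_pcs",
]

#: Allowed stage tags in processing order.  ``scaled`` and ``rpkm`` are
#: alternative second stages; everything downstream of ``log`` may hold
#: negative values.
STAGES = (
    "raw_counts",
    "scaled",
    "rpkm",
    "log",
    "quantile_norm",
    "rank_normal",
    "adjusted",
)

_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression matrix with a processing-stage tag."""

    values: pd.DataFrame
    stage: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if _STAGE_ORDER[self.stage] < _STAGE_ORDER["log"]:
            if (self.values.to_numpy() < 0).any():
                raise ValueError(f"negative values are not allowed at stage {self.stage!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def advance(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        """Return a new matrix at ``stage``, enforcing forward-only transitions."""
        if _STAGE_ORDER.get(stage) is None:
            raise ValueError(f"unknown stage {stage!r}")
        if _STAGE_ORDER[stage] < _STAGE_ORDER[self.stage]:
            raise ValueError(f"stage transition {self.stage!r} -> {stage!r} goes backwards")
        return ExpressionMatrix(values, stage)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return matrix


def scale_counts_quantile(counts, quantile: float = 0.75) -> pd.DataFrame:
    """Scale each sample so its upper quantile of nonzero counts matches the
    geometric mean of that quantile across samples.

    Parameters
    ----------
    counts
        Raw count matrix (features x samples).
    quantile
        Which quantile of the nonzero counts to equalize (default: upper
        quartile).

    Returns
    -------
    DataFrame of scaled counts.  Within-sample ordering is preserved because
    scaling is a single positive factor per sample.
    """
    df = _as_frame(counts)
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    qs = {}
    for sample in df.columns:
        col = df[sample].to_numpy(dtype=float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has all-zero counts")
        qs[sample] = np.quantile(nonzero, quantile)
    q = pd.Series(qs)
    target = stats.gmean(q.to_numpy())
    factors = q / target
    return df.div(factors, axis=1)


def rpkm(counts, gene_lengths: pd.Series, library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``value = count / ((length / 1e3) * (library / 1e6))``.
    """
    df = _as_frame(counts)
    lengths = pd.Series(gene_lengths).reindex(df.index)
    libs = pd.Series(library_sizes).reindex(df.columns)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return df.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def filter_expressed(
    rpkm_matrix,
    min_rpkm: float,
    min_fraction: float,
    strict_fraction: bool = True,
) -> pd.Index:
    """Feature ids whose value exceeds ``min_rpkm`` in more than
    ``min_fraction`` of samples.

    The value comparison is strict (``> min_rpkm``); the fraction comparison
    is strict by default and ``>=`` when ``strict_fraction`` is False.
    """
    df = _as_frame(rpkm_matrix)
    frac = (df > min_rpkm).mean(axis=1)
    keep = frac > min_fraction if strict_fraction else frac >= min_fraction
    return df.index[keep]


def quantile_normalize_samples(matrix) -> pd.DataFrame:
    """Force every sample (column) onto the identical empirical distribution.

    The reference distribution is the mean of order statistics across samples;
    ties within a sample receive the average of the corresponding reference
    values, which makes the transform idempotent.
    """
    df = _as_frame(matrix)
    arr = df.to_numpy(dtype=float)
    order = np.sort(arr, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        # average rank r maps to mean of reference[ceil(r)-1], reference[floor(r)-1]
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def rank_inverse_normal(matrix, seed=None) -> pd.DataFrame:
    """Map each feature (row) to a standard normal via rank transformation.

    Output is ``Phi^-1(r / (n + 1))`` for ranks ``r``; ties are resolved by a
    seeded random permutation, as required for count data where exact ties are
    common.  Constant rows are fully randomized and reported via a warning.
    """
    df = _as_frame(matrix)
    rng = np.random.default_rng(seed)
    arr = df.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 3:
        raise ValueError("rank-inverse-normal requires at least 3 samples")
    out = np.empty_like(arr)
    n_constant = 0
    for i in range(arr.shape[0]):
        row = arr[i]
        if np.all(row == row[0]):
            n_constant += 1
        jitter = rng.permutation(n)
        # stable lexsort: primary key value, secondary key random permutation
        order = np.lexsort((jitter, row))
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(1, n + 1)
        out[i] = stats.norm.ppf(ranks / (n + 1))
    if n_constant:
        warnings.warn(
            f"{n_constant} constant feature(s): ranks assigned at random",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def build_design(
    covariates: pd.DataFrame,
    columns=None,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Numeric design matrix from a covariate table.

    Categorical/object columns are dummy-encoded dropping the first level.
    Warns when two requested columns are perfectly confounded (e.g. recruiting
    center and case/control group when every case came from one center).
    """
    cols = list(columns) if columns is not None else list(covariates.columns)
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariates missing columns: {missing}")
    sub = covariates[cols]
    if sub.isna().any().any():
        bad = list(sub.columns[sub.isna().any()])
        raise ValueError(f"missing values in covariates: {bad}")
    parts = []
    codes = {}
    for c in cols:
        col = sub[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
            codes[c] = pd.factorize(col)[0]
        else:
            parts.append(col.astype(float).to_frame())
            codes[c] = col.to_numpy()
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            ca, cb = np.asarray(codes[a]), np.asarray(codes[b])
            if len(np.unique(ca)) > 1 and len(np.unique(cb)) > 1:
                tab = pd.crosstab(ca, cb).to_numpy()
                if np.all((tab > 0).sum(axis=1) == 1) and np.all((tab > 0).sum(axis=0) == 1):
                    warnings.warn(
                        f"covariates {a!r} and {b!r} are perfectly confounded",
                        UserWarning,
                        stacklevel=2,
                    )
    design = pd.concat(parts, axis=1)
    if add_intercept:
        design.insert(0, "intercept", 1.0)
    return design


def _drop_aliased(design: np.ndarray, names) -> tuple[np.ndarray, list]:
    """Greedily drop columns that do not increase matrix rank."""
    keep: list[int] = []
    rank = 0
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [names[j] for j in range(design.shape[1]) if j not in keep]
    return design[:, keep], dropped


def adjust_covariates(matrix, covariates: pd.DataFrame, keep_mean: bool = True) -> pd.DataFrame:
    """Per-feature OLS residuals against the covariate design.

    When ``keep_mean`` is set the feature mean is added back so the output
    retains absolute expression levels.  Aliased design columns are dropped
    with a warning.
    """
    df = _as_frame(matrix)
    design = covariates if _is_numeric_frame(covariates) else build_design(covariates)
    design = design.reindex(df.columns)
    if design.isna().any().any():
        raise ValueError("covariate table does not cover all samples")
    X = design.to_numpy(dtype=float)
    if "intercept" not in design.columns and not np.allclose(X.std(axis=0).min(), 0):
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + list(design.columns)
    else:
        names = list(design.columns)
    X, dropped = _drop_aliased(X, names)
    if dropped:
        warnings.warn(f"dropped aliased design columns: {dropped}", UserWarning, stacklevel=2)
    Y = df.to_numpy(dtype=float).T  # samples x features
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T
    if keep_mean:
        out = out + df.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _is_numeric_frame(df: pd.DataFrame) -> bool:
    return all(dt.kind in "fiub" for dt in df.dtypes)


def fibroblast_score(expression, marker_gene_ids, offset: float = 1.0) -> pd.Series:
    """Cell-type contamination score: per sample, sum of z-scaled
    log10(value + offset) over marker genes."""
    df = _as_frame(expression)
    markers = pd.Index(marker_gene_ids)
    missing = markers.difference(df.index)
    if len(missing):
        raise KeyError(f"marker genes absent from matrix: {sorted(missing)}")
    logged = np.log10(df.loc[markers].to_numpy(dtype=float) + offset)
    mu = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (logged - mu) / sd
    return pd.Series(z.sum(axis=0), index=df.columns, name="fibroblast_score")


def fold_rare_homozygotes(genotypes: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Recode minor-allele homozygotes to heterozygous when the class has
    fewer than ``min_count`` carriers at a SNP.

    Guards QTL scans against rare-genotype classes coinciding with expression
    outliers.  Input must be factor-encoded (values in {0, 1, 2}).
    """
    arr = genotypes.to_numpy(dtype=float).copy()
    vals = np.unique(arr[~np.isnan(arr)])
    if not np.all(np.isin(vals, [0.0, 1.0, 2.0])):
        raise ValueError("genotypes must be factor-encoded with values in {0, 1, 2}")
    for i in range(arr.shape[0]):
        row = arr[i]
        called = row[~np.isnan(row)]
        if called.size == 0:
            continue
        minor_hom = 2.0 if called.mean() / 2.0 <= 0.5 else 0.0
        n_hom = int((called == minor_hom).sum())
        if 0 < n_hom < min_count:
            row[row == minor_hom] = 1.0
    return pd.DataFrame(arr, index=genotypes.index, columns=genotypes.columns)


def genotype_concordance(calls_truth, calls_test, confidences=None) -> dict:
    """Concordance of two genotype call vectors.

    Returns ``accuracy`` (fraction equal among jointly called),
    ``nonref_accuracy`` (restricted to truth calls carrying at least one
    minor allele; NaN when no such calls), and ``efficacy`` (fraction of
    calls with confidence > 0.95, when confidences are given).
    """
    a = np.asarray(calls_truth, dtype=float)
    b = np.asarray(calls_test, dtype=float)
    if a.shape != b.shape:
        raise ValueError("call vectors differ in length")
    joint = ~np.isnan(a) & ~np.isnan(b)
    if not joint.any():
        raise ValueError("no overlapping calls")
    accuracy = float((a[joint] == b[joint]).mean())
    called_truth = a[~np.isnan(a)]
    minor_hom = 2.0 if called_truth.mean() / 2.0 <= 0.5 else 0.0
    carries_minor = joint & ((a == 1.0) | (a == minor_hom))
    if carries_minor.any():
        nonref = float((a[carries_minor] == b[carries_minor]).mean())
    else:
        nonref = float("nan")
    out = {"accuracy": accuracy, "nonref_accuracy": nonref}
    if confidences is not None:
        conf = np.asarray(confidences, dtype=float)
        out["efficacy"] = float((conf > 0.95).mean())
    return out


def genotype_pcs(genotypes: pd.DataFrame, k: int = 3, scale: bool = True) -> pd.DataFrame:
    """Sample scores on the first ``k`` principal components of the dosage
    matrix (SNPs x samples), computed by SVD of the centered (and optionally
    unit-variance scaled) sample-by-SNP matrix."""
    X = genotypes.to_numpy(dtype=float).T  # samples x SNPs
    if X.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        informative = sd > 0
        X = X[:, informative] / sd[informative]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"requested k={k} exceeds matrix rank {rank}")
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=genotypes.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
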