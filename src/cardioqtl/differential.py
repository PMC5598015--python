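"""Case/control differential expression and PSI-based differential exon usage,
plus the simulation engine that characterizes the exon-usage caller's
sensitivity and false discovery rate."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffResult",
    "UsageSimReport",
    "wmw_differential_expression",
    "diff_exon_usage",
    "fit_negative_binomial",
    "simulate_exon_usage_study",
    "psi_from_counts",
]

FC_THRESHOLD_DEFAULT = math.log(1.2)


def _group_indicator(groups, columns) -> np.ndarray:
    g = pd.Series(groups)
    g = g.reindex(columns) if set(columns).issubset(set(g.index)) else g
    if g.isna().any():
        raise ValueError("group labels do not cover all samples")
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(levels)}")
    # case/1/True coded as 1 when recognizable, otherwise second level
    order = sorted(levels, key=lambda x: str(x))
    one = "case" if "case" in [str(v) for v in levels] else order[-1]
    ind = (g.astype(str) == str(one)).to_numpy(dtype=float)
    return ind


def wmw_differential_expression(
    adjusted_expr: pd.DataFrame,
    groups,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon-Mann-Whitney differential expression between two groups.

    Parameters
    ----------
    adjusted_expr
        Covariate-adjusted log expression, genes x samples.
    groups
        Mapping sample -> group label (two levels; "case" treated as group 1).
    fc_threshold
        Minimum absolute log fold change required for the differential flag
        (default log 1.2, i.e. a 20% expression change).

    Returns
    -------
    DataFrame indexed by gene with columns ``W``, ``effect`` (difference of
    group means of adjusted values), ``p``, ``p_adj`` (Benjamini-Hochberg),
    and ``differential``.
    """
    ind = _group_indicator(groups, adjusted_expr.columns)
    if ind.sum() < 2 or (1 - ind).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    case = adjusted_expr.loc[:, ind == 1].to_numpy(dtype=float)
    ctrl = adjusted_expr.loc[:, ind == 0].to_numpy(dtype=float)
    res = stats.mannwhitneyu(case, ctrl, axis=1, alternative="two-sided", method="auto")
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "W": np.asarray(res.statistic, dtype=float),
            "effect": effect,
            "p": p,
            "p_adj": p_adj,
            "differential": (p_adj < alpha) & (np.abs(effect) > fc_threshold),
        },
        index=adjusted_expr.index,
    )
    return out


def _nested_f(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray):
    """Vectorized nested-model F test sharing one design across all rows of Y.

    Returns (F, p, df1, df2, beta_full) where beta_full has one row of
    coefficients per response row.
    """
    n = X_full.shape[0]
    rank_full = np.linalg.matrix_rank(X_full)
    rank_red = np.linalg.matrix_rank(X_red)
    df1 = rank_full - rank_red
    df2 = n - rank_full
    beta_f, *_ = np.linalg.lstsq(X_full, Y.T, rcond=None)
    beta_r, *_ = np.linalg.lstsq(X_red, Y.T, rcond=None)
    rss_f = ((Y.T - X_full @ beta_f) ** 2).sum(axis=0)
    rss_r = ((Y.T - X_red @ beta_r) ** 2).sum(axis=0)
    if df1 <= 0 or df2 <= 0:
        F = np.full(Y.shape[0], np.nan)
        p = np.full(Y.shape[0], np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_r - rss_f) / df1) / (rss_f / df2)
        F = np.where(rss_f <= 0, np.inf, F)
        p = stats.f.sf(F, df1, df2)
        p = np.where(np.isinf(F), 0.0, p)
    return F, p, df1, df2, beta_f.T


def diff_exon_usage(
    psi: pd.DataFrame,
    groups,
    covariates: pd.DataFrame | None = None,
    effect_threshold: float = 0.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential exon usage from PSI values via nested linear models.

    Fits ``PSI ~ group + covariates`` against ``PSI ~ covariates`` per exon
    part and evaluates the nested-model F statistic (the exact Gaussian form
    of the likelihood ratio test).  A part is flagged when its BH-adjusted p
    is below ``alpha`` and the absolute group coefficient exceeds
    ``effect_threshold`` (default 0.1, a 10-point PSI difference).

    Only parts with 0 < PSI < 1 in all samples are testable; others are
    returned with NaN statistics.
    """
    ind = _group_indicator(groups, psi.columns)
    arr = psi.to_numpy(dtype=float)
    testable = np.all((arr > 0) & (arr < 1), axis=1) & ~np.isnan(arr).any(axis=1)

    n = arr.shape[1]
    if covariates is not None:
        cov = covariates.reindex(psi.columns).to_numpy(dtype=float)
        X_red = np.column_stack([np.ones(n), cov])
    else:
        X_red = np.ones((n, 1))
    X_full = np.column_stack([X_red, ind])
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full == np.linalg.matrix_rank(X_red):
        warnings.warn(
            "group indicator is aliased with the covariates; test has no power",
            UserWarning,
            stacklevel=2,
        )

    out = pd.DataFrame(
        index=psi.index,
        data={
            "F": np.nan,
            "beta": np.nan,
            "p": np.nan,
            "p_adj": np.nan,
            "differential": False,
            "tested": testable,
        },
    )
    if testable.any():
        F, p, df1, df2, beta = _nested_f(arr[testable], X_full, X_red)
        out.loc[testable, "F"] = F
        out.loc[testable, "beta"] = beta[:, -1]
        out.loc[testable, "p"] = p
        if np.isfinite(p).any():
            p_adj = np.full(p.shape, np.nan)
            ok = np.isfinite(p)
            p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            out.loc[testable, "p_adj"] = p_adj
            out.loc[testable, "differential"] = (p_adj < alpha) & (
                np.abs(beta[:, -1]) > effect_threshold
            )
    return out


def fit_negative_binomial(counts, trim_quantile: float = 0.9) -> dict:
    """Method-of-moments negative binomial fit after trimming the upper tail.

    Counts above the ``trim_quantile`` quantile are excluded before computing
    mean and variance; ``size = mean^2 / (var - mean)``.  When the trimmed
    variance does not exceed the mean (Poisson-like data) the size is clamped
    to a large cap and a warning is emitted.
    """
    x = np.asarray(counts, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no counts provided")
    cutoff = np.quantile(x, trim_quantile)
    trimmed = x[x <= cutoff]
    if trimmed.size < 30:
        raise ValueError(f"only {trimmed.size} observations after trimming; need >= 30")
    mean = trimmed.mean()
    var = trimmed.var(ddof=1)
    cap = 1e8
    if var <= mean:
        warnings.warn(
            "trimmed variance <= mean; data look Poisson, size clamped",
            UserWarning,
            stacklevel=2,
        )
        size = cap
    else:
        size = min(cap, mean**2 / (var - mean))
    return {"mean": float(mean), "size": float(size)}


@dataclass
class UsageSimReport:
    """Operating characteristics of the exon-usage caller over replicates."""

    replicates: pd.DataFrame  # columns TP, FP, FN, TN, sensitivity, fdr
    params: dict = field(default_factory=dict)

    @property
    def mean_fdr(self) -> float:
        return float(np.nanmean(self.replicates["fdr"]))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean(self.replicates["sensitivity"]))

    def summary(self) -> dict:
        r = self.replicates
        return {
            "mean_fdr": self.mean_fdr,
            "sd_fdr": float(np.nanstd(r["fdr"], ddof=1)) if len(r) > 1 else float("nan"),
            "mean_sensitivity": self.mean_sensitivity,
            "sd_sensitivity": (
                float(np.nanstd(r["sensitivity"], ddof=1)) if len(r) > 1 else float("nan")
            ),
            "n_replicates": int(len(r)),
        }


def simulate_exon_usage_study(
    n_cases: int = 97,
    n_controls: int = 108,
    nb_mean: float = 100.0,
    nb_size: float = 1.0,
    frac_differential: float = 0.1,
    delta_psi: float = 0.1,
    n_exons: int = 5000,
    replicates: int = 100,
    seed=None,
    multiplicative_shift: bool = False,
    effect_threshold: float = 0.1,
    alpha: float = 0.05,
) -> UsageSimReport:
    """Simulation study of the PSI differential-usage caller.

    Per replicate: exon total reads ~ NegBin(nb_mean, nb_size) per sample;
    true PSI ~ Uniform(0, 1) per exon; ``frac_differential`` of exons get the
    case-group PSI shifted by ``+delta_psi`` (additive, clipped to [0, 1];
    multiplicative reading available behind ``multiplicative_shift``);
    inclusion reads ~ Binomial(total, PSI); exons failing the all-samples
    0 < PSI < 1 filter are removed from testing but kept in the sensitivity
    denominator.  The caller is the covariate-free nested F test with the
    double gate (BH FDR < ``alpha`` and |beta| > ``effect_threshold``).
    """
    if not 0 <= frac_differential < 1:
        raise ValueError("frac_differential must be in [0, 1)")
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    group = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    n_diff = int(round(frac_differential * n_exons))
    X_full = np.column_stack([np.ones(n), group])
    X_red = np.ones((n, 1))

    rows = []
    for _ in range(replicates):
        p_nb = nb_size / (nb_size + nb_mean)
        totals = rng.negative_binomial(nb_size, p_nb, size=(n_exons, n))
        true_psi = rng.uniform(0.0, 1.0, size=n_exons)
        psi_mat = np.repeat(true_psi[:, None], n, axis=1)
        diff_idx = rng.choice(n_exons, size=n_diff, replace=False)
        is_diff = np.zeros(n_exons, dtype=bool)
        is_diff[diff_idx] = True
        case_cols = group == 1
        if multiplicative_shift:
            shifted = psi_mat[diff_idx][:, case_cols] * (1.0 + delta_psi)
        else:
            shifted = psi_mat[diff_idx][:, case_cols] + delta_psi
        psi_mat[np.ix_(diff_idx, case_cols)] = np.clip(shifted, 0.0, 1.0)
        inclusion = rng.binomial(totals, psi_mat)

        with np.errstate(divide="ignore", invalid="ignore"):
            obs_psi = inclusion / totals
        testable = (
            np.all(totals > 0, axis=1)
            & np.all(inclusion > 0, axis=1)
            & np.all(inclusion < totals, axis=1)
        )

        flagged = np.zeros(n_exons, dtype=bool)
        if testable.any():
            F, p, df1, df2, beta = _nested_f(obs_psi[testable], X_full, X_red)
            p_adj = multipletests(p, method="fdr_bh")[1]
            flagged[testable] = (p_adj < alpha) & (np.abs(beta[:, -1]) > effect_threshold)

        tp = int((flagged & is_diff).sum())
        fp = int((flagged & ~is_diff).sum())
        fn = int(n_diff - tp)
        tn = int(n_exons - n_diff - fp)
        sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        # no discoveries -> no false discoveries (keeps FDR in [0, 1])
        fdr = fp / (fp + tp) if (fp + tp) > 0 else 0.0
        rows.append(
            {"TP": tp, "FP": fp, "FN": fn, "TN": tn, "sensitivity": sens, "fdr": fdr,
             "n_positive": tp + fp, "n_testable": int(testable.sum())}
        )

    report = UsageSimReport(
        replicates=pd.DataFrame(rows),
        params={
            "n_cases": n_cases,
            "n_controls": n_controls,
            "nb_mean": nb_mean,
            "nb_size": nb_size,
            "frac_differential": frac_differential,
            "delta_psi": delta_psi,
            "n_exons": n_exons,
            "replicates": replicates,
            "seed": seed,
            "multiplicative_shift": multiplicative_shift,
        },
    )
    return report


@dataclass
class DiffResult:
    """One feature's differential-test outcome (convenience record type)."""

    feature_id: str
    statistic: float
    effect: float
    p: float
    p_adj: float
    differential: bool


def psi_from_counts(inclusion: pd.DataFrame, totals: pd.DataFrame) -> pd.DataFrame:
    """PSI = inclusion / total; NaN where total is zero."""
    if not inclusion.index.equals(totals.index) or not inclusion.columns.equals(totals.columns):
        raise ValueError("inclusion and total tables must be aligned")
    inc = inclusion.to_numpy(dtype=float)
    tot = totals.to_numpy(dtype=float)
    if (inc > tot).any():
        raise ValueError("inclusion reads exceed total reads")
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(tot > 0, inc / tot, np.nan)
    return pd.DataFrame(psi, index=inclusion.index, columns=inclusion.columns)
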