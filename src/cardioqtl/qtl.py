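"""cis-eQTL scanning, condition-specific eQTL, exon-interaction sQTL,
Cochran-Armitage trend testing, and Storey q-values."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cis_pairs",
    "cis_eqtl_scan",
    "SpecificEqtlFit",
    "specific_eqtl_test",
    "specific_eqtl_scan",
    "armitage_trend_test",
    "SqtlFit",
    "sqtl_interaction_test",
    "sqtl_scan",
    "QvalueResult",
    "storey_qvalues",
    "rbm20_confounding_bound",
]

EQTL_P_THRESHOLD = 1e-5
CIS_WINDOW_DEFAULT = 1_000_000


def cis_pairs(
    gene_models: pd.DataFrame,
    snp_table: pd.DataFrame,
    window: int = CIS_WINDOW_DEFAULT,
) -> pd.DataFrame:
    """All (gene, SNP) pairs with the SNP within ``window`` bp of the gene body.

    Distance is signed from the nearest gene edge (negative upstream of the
    start, positive downstream of the end) and zero inside the gene.

    ``gene_models`` needs columns gene_id/chrom/start/end; ``snp_table`` needs
    snp_id/chrom/pos.  Positions are 1-based.
    """
    rows = []
    snps_by_chrom = dict(tuple(snp_table.groupby("chrom", sort=False)))
    for gene in gene_models.itertuples(index=False):
        snps = snps_by_chrom.get(gene.chrom)
        if snps is None:
            continue
        pos = snps["pos"].to_numpy()
        near = (pos >= gene.start - window) & (pos <= gene.end + window)
        if not near.any():
            continue
        sel = snps.loc[near]
        d = np.where(
            sel["pos"] < gene.start,
            sel["pos"] - gene.start,
            np.where(sel["pos"] > gene.end, sel["pos"] - gene.end, 0),
        )
        rows.append(
            pd.DataFrame(
                {"gene_id": gene.gene_id, "snp_id": sel["snp_id"].to_numpy(), "distance": d}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["gene_id", "snp_id", "distance"])
    return pd.concat(rows, ignore_index=True)


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each row of Y against the column space of X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def cis_eqtl_scan(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    pairs: pd.DataFrame,
    p_threshold: float = EQTL_P_THRESHOLD,
) -> pd.DataFrame:
    """Additive linear-model eQTL scan over precomputed cis pairs.

    Per pair, the slope, t statistic, and two-sided p of expression on
    genotype dosage with covariates are obtained by residualizing both
    expression and dosage against the covariate design once and correlating
    the residuals — numerically identical to the per-pair joint regression.

    Returns one row per evaluable pair with beta/se/t/p, BH-adjusted p, the
    nominal-significance flag at ``p_threshold``, and the cis distance.
    Monomorphic-genotype pairs are skipped.
    """
    samples = expression.columns
    if not genotypes.columns.equals(samples):
        genotypes = genotypes[samples]
    n = len(samples)
    if covariates is not None:
        X = covariates.reindex(samples).to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("covariates do not cover all samples")
        if not np.any(np.all(X == X[0], axis=0)):
            X = np.column_stack([np.ones(n), X])
    else:
        X = np.ones((n, 1))
    k = np.linalg.matrix_rank(X)
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")

    E = _residualize(expression.to_numpy(dtype=float), X)
    G = _residualize(genotypes.to_numpy(dtype=float), X)
    gene_idx = expression.index.get_indexer(pairs["gene_id"])
    snp_idx = genotypes.index.get_indexer(pairs["snp_id"])
    if (gene_idx < 0).any() or (snp_idx < 0).any():
        raise KeyError("pairs reference genes or SNPs absent from the matrices")

    e = E[gene_idx]
    g = G[snp_idx]
    raw_var = genotypes.to_numpy(dtype=float)[snp_idx].var(axis=1)
    gss = (g**2).sum(axis=1)
    ess = (e**2).sum(axis=1)
    cross = (e * g).sum(axis=1)
    ok = (raw_var > 0) & (gss > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = cross / gss
        r2 = cross**2 / (gss * ess)
        r2 = np.clip(r2, 0.0, 1.0)
        sigma2 = (ess - beta * cross) / df
        se = np.sqrt(sigma2 / gss)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pairs.copy()
    out["beta"] = np.where(ok, beta, np.nan)
    out["se"] = np.where(ok, se, np.nan)
    out["t"] = np.where(ok, t, np.nan)
    out["p"] = np.where(ok, p, np.nan)
    p_adj = np.full(len(out), np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out["p_adj"] = p_adj
    out["significant"] = ok & (p < p_threshold)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} monomorphic pair(s)", UserWarning, stacklevel=2)
    return out


@dataclass
class SpecificEqtlFit:
    """Group-specific eQTL fit: separate slope/intercept per group versus a
    shared-slope reduced model."""

    beta0: float  # group-1 (case) intercept
    beta1: float  # group-1 (case) slope
    beta2: float  # group-0 (control) intercept
    beta3: float  # group-0 (control) slope
    se1: float
    se3: float
    ci1: tuple
    ci3: tuple
    F: float
    p: float
    fdr: float = float("nan")
    call: str = "none"
    reason: str = ""


def _ols_fit(X: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss


def specific_eqtl_test(
    y,
    dosage,
    group,
    alpha: float = 0.05,
    significance_p: float | None = None,
) -> SpecificEqtlFit:
    """Test whether an eQTL slope differs between the two groups.

    Full model ``y = g(b0 + b1 x) + (1-g)(b2 + b3 x) + e`` versus the reduced
    model with a common slope ``y = g b0 + b1 x + (1-g) b2 + e``; p from the
    nested F test (df1=1).  The specificity call requires significance AND
    exactly one of the two slope 95% CIs containing zero:
    ``case_only`` when the control slope CI covers zero, ``control_only``
    when the case slope CI covers zero, ``shared`` when neither does.

    ``significance_p`` defaults to the nominal p; scans replace it with an
    FDR-adjusted value before calling :func:`_specificity_call`.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(dosage, dtype=float)
    g = np.asarray(group, dtype=float)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("group must be coded 0/1")
    n = len(y)
    for gv, name in ((1.0, "group 1"), (0.0, "group 0")):
        mask = g == gv
        if mask.sum() < 3:
            raise ValueError(f"{name} has fewer than 3 samples")
        if np.var(x[mask]) == 0:
            return SpecificEqtlFit(
                *(float("nan"),) * 4,
                se1=float("nan"),
                se3=float("nan"),
                ci1=(float("nan"), float("nan")),
                ci3=(float("nan"), float("nan")),
                F=float("nan"),
                p=float("nan"),
                call="none",
                reason=f"genotype monomorphic in {name}",
            )
    X_full = np.column_stack([g, g * x, 1 - g, (1 - g) * x])
    X_red = np.column_stack([g, x, 1 - g])
    beta_f, rss_f = _ols_fit(X_full, y)
    _, rss_r = _ols_fit(X_red, y)
    df2 = n - 4
    F = ((rss_r - rss_f) / 1.0) / (rss_f / df2)
    p = float(stats.f.sf(F, 1, df2))
    sigma2 = rss_f / df2
    xtx_inv = np.linalg.inv(X_full.T @ X_full)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tcrit = stats.t.ppf(1 - alpha / 2, df2)
    ci1 = (beta_f[1] - tcrit * se[1], beta_f[1] + tcrit * se[1])
    ci3 = (beta_f[3] - tcrit * se[3], beta_f[3] + tcrit * se[3])
    fit = SpecificEqtlFit(
        beta0=float(beta_f[0]),
        beta1=float(beta_f[1]),
        beta2=float(beta_f[2]),
        beta3=float(beta_f[3]),
        se1=float(se[1]),
        se3=float(se[3]),
        ci1=(float(ci1[0]), float(ci1[1])),
        ci3=(float(ci3[0]), float(ci3[1])),
        F=float(F),
        p=p,
    )
    sig_p = p if significance_p is None else significance_p
    fit.call = _specificity_call(fit, sig_p, alpha)
    return fit


def _specificity_call(fit: SpecificEqtlFit, sig_p: float, alpha: float) -> str:
    if not np.isfinite(sig_p) or sig_p >= alpha:
        return "none"
    zero_in_1 = fit.ci1[0] <= 0.0 <= fit.ci1[1]
    zero_in_3 = fit.ci3[0] <= 0.0 <= fit.ci3[1]
    if zero_in_1 and not zero_in_3:
        return "control_only"
    if zero_in_3 and not zero_in_1:
        return "case_only"
    if not zero_in_1 and not zero_in_3:
        return "shared"
    return "none"


def specific_eqtl_scan(
    expression: pd.DataFrame,
    genotypes: pd.DataFrame,
    group,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply :func:`specific_eqtl_test` over pairs with BH correction across
    the scan; specificity calls use the adjusted p."""
    g = pd.Series(group).reindex(expression.columns).to_numpy(dtype=float)
    fits = []
    for row in pairs.itertuples(index=False):
        y = expression.loc[row.gene_id].to_numpy(dtype=float)
        x = genotypes.loc[row.snp_id].to_numpy(dtype=float)
        try:
            fits.append(specific_eqtl_test(y, x, g, alpha=alpha))
        except ValueError as exc:
            fit = SpecificEqtlFit(
                *(float("nan"),) * 4,
                se1=float("nan"),
                se3=float("nan"),
                ci1=(float("nan"), float("nan")),
                ci3=(float("nan"), float("nan")),
                F=float("nan"),
                p=float("nan"),
                reason=str(exc),
            )
            fits.append(fit)
    ps = np.array([f.p for f in fits], dtype=float)
    ok = np.isfinite(ps)
    fdr = np.full(len(ps), np.nan)
    if ok.any():
        fdr[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for f, q in zip(fits, fdr):
        f.fdr = float(q)
        if f.reason == "":
            f.call = _specificity_call(f, q, alpha)
    out = pairs.copy()
    for col in ("beta0", "beta1", "beta2", "beta3", "F", "p", "fdr", "call", "reason"):
        out[col] = [getattr(f, col) for f in fits]
    return out


def armitage_trend_test(genotype_counts) -> dict:
    """Cochran-Armitage trend test for a 2 x 3 genotype-count table with
    scores (0, 1, 2).

    Rows are groups (e.g. cases, controls), columns genotype classes.
    Returns the chi-square statistic (df 1) and its p-value.
    """
    tab = np.asarray(genotype_counts, dtype=float)
    if tab.shape != (2, 3):
        raise ValueError("expected a 2x3 genotype count table")
    if (tab < 0).any():
        raise ValueError("counts must be non-negative")
    row_tot = tab.sum(axis=1)
    if (row_tot == 0).any():
        raise ValueError("each group must have a nonzero total")
    w = np.array([0.0, 1.0, 2.0])
    N = tab.sum()
    R = row_tot[0]  # group-1 total
    n_col = tab.sum(axis=0)
    T = (w * tab[0]).sum()
    num = N * T - R * (w * n_col).sum()
    den = R * (N - R) * (N * (w**2 * n_col).sum() - ((w * n_col).sum()) ** 2)
    if den == 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2 = N * num**2 / den
    return {"chi2": float(chi2), "p": float(stats.chi2.sf(chi2, 1))}


@dataclass
class SqtlFit:
    """Exon-by-genotype interaction fit for one (gene, target exon, SNP)."""

    gene_id: str
    target_part: str
    snp_id: str
    F: float
    df1: int
    df2: int
    p: float
    rss_full: float
    rss_reduced: float
    interaction_levels: tuple
    fdr: float = float("nan")


def _merge_rare_levels(factor: np.ndarray, min_count: int = 3) -> np.ndarray:
    """Merge genotype levels observed fewer than ``min_count`` times into the
    nearest (by dosage value) sufficiently populated level."""
    f = factor.astype(float).copy()
    levels, counts = np.unique(f, return_counts=True)
    good = levels[counts >= min_count]
    if good.size == 0:
        return f
    for lev, cnt in zip(levels, counts):
        if cnt < min_count:
            nearest = good[np.argmin(np.abs(good - lev))]
            f[f == lev] = nearest
    return f


def sqtl_interaction_test(
    exon_expr: pd.DataFrame,
    target_part: str,
    genotype_factor,
    gene_id: str = "",
    snp_id: str = "",
    min_level_count: int = 3,
) -> SqtlFit:
    """Splicing-QTL test: does genotype shift the target exon relative to its
    gene?

    Observations are the stacked (exon, sample) expression values of one gene,
    quantile-normalized across exons within each sample upstream.  The full
    model has per-sample terms, per-exon terms, and genotype-level terms
    restricted to the target exon; the reduced model drops the interaction.
    Genotype main effects are constant within sample and therefore absorbed by
    the per-sample terms — they contribute no degrees of freedom.  df1 is the
    number of observed genotype levels minus one; p comes from F(df1, df2).
    """
    parts = list(exon_expr.index)
    if target_part not in parts:
        raise KeyError(f"target part {target_part!r} not in exon table")
    if len(parts) < 2:
        raise ValueError("gene must have at least 2 exon parts")
    samples = exon_expr.columns
    geno = np.asarray(pd.Series(genotype_factor).reindex(samples), dtype=float)
    if np.isnan(geno).any():
        raise ValueError("genotype factor does not cover all samples")
    geno = _merge_rare_levels(np.round(geno), min_level_count)
    levels = np.unique(geno)
    if levels.size < 2:
        raise ValueError("genotype factor has fewer than 2 observed levels after merging")

    L, n = exon_expr.shape
    y = exon_expr.to_numpy(dtype=float).reshape(-1)  # part-major stacking
    N = L * n
    # sample dummies (drop first), exon dummies (drop first), intercept
    sample_idx = np.tile(np.arange(n), L)
    part_idx = np.repeat(np.arange(L), n)
    X_cols = [np.ones(N)]
    for j in range(1, n):
        X_cols.append((sample_idx == j).astype(float))
    for l in range(1, L):
        X_cols.append((part_idx == l).astype(float))
    X_red = np.column_stack(X_cols)
    tgt = parts.index(target_part)
    is_target = (part_idx == tgt).astype(float)
    geno_obs = geno[sample_idx]
    inter_cols = [is_target * (geno_obs == lev).astype(float) for lev in levels[1:]]
    X_full = np.column_stack([X_red] + inter_cols)

    beta_r, rss_r = _ols_fit(X_red, y)
    beta_f, rss_f = _ols_fit(X_full, y)
    df1 = int(levels.size - 1)
    df2 = int(N - np.linalg.matrix_rank(X_full))
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(F, df1, df2))
    return SqtlFit(
        gene_id=gene_id,
        target_part=target_part,
        snp_id=snp_id,
        F=float(F),
        df1=df1,
        df2=df2,
        p=p,
        rss_full=rss_f,
        rss_reduced=rss_r,
        interaction_levels=tuple(levels.tolist()),
    )


def sqtl_scan(
    exon_expr_by_gene: dict,
    genotypes: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the interaction test for each (gene, target part, SNP) triple.

    ``pairs`` needs columns gene_id, part_id, snp_id.  BH correction is
    applied across all evaluable triples.
    """
    rows = []
    for row in pairs.itertuples(index=False):
        table = exon_expr_by_gene.get(row.gene_id)
        if table is None:
            raise KeyError(f"no exon table for gene {row.gene_id!r}")
        geno = genotypes.loc[row.snp_id]
        try:
            fit = sqtl_interaction_test(
                table, row.part_id, geno, gene_id=row.gene_id, snp_id=row.snp_id
            )
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "part_id": row.part_id,
                    "snp_id": row.snp_id,
                    "F": fit.F,
                    "df1": fit.df1,
                    "df2": fit.df2,
                    "p": fit.p,
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "gene_id": row.gene_id,
                    "part_id": row.part_id,
                    "snp_id": row.snp_id,
                    "F": np.nan,
                    "df1": 0,
                    "df2": 0,
                    "p": np.nan,
                    "reason": str(exc),
                }
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna().to_numpy()
    fdr = np.full(len(out), np.nan)
    if ok.any():
        fdr[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["significant"] = ok & (fdr < alpha)
    return out


@dataclass
class QvalueResult:
    p_values: np.ndarray
    pi0: float
    q_values: np.ndarray

    @property
    def alt_fraction(self) -> float:
        """1 - pi0: upper bound on the fraction of non-null hypotheses."""
        return 1.0 - self.pi0


def storey_qvalues(p_values, lambda_grid=None) -> QvalueResult:
    """Storey q-values with the smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a cubic
    polynomial over the lambda grid and evaluated at the largest lambda.
    With fewer than 100 p-values pi0 is fixed at 1 (plain BH) with a warning;
    if smoothing fails, the single-lambda estimate at 0.5 is used.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.95, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    if m < 100:
        warnings.warn("fewer than 100 p-values: pi0 fixed to 1 (plain BH)", UserWarning,
                      stacklevel=2)
        pi0 = 1.0
    else:
        pi0_lam = np.array([(p > lam).mean() / (1 - lam) for lam in lambda_grid])
        try:
            coef = np.polyfit(lambda_grid, pi0_lam, deg=3)
            pi0 = float(np.polyval(coef, lambda_grid.max()))
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate grid
            warnings.warn("pi0 smoothing failed; using lambda=0.5", UserWarning, stacklevel=2)
            pi0 = float((p > 0.5).mean() / 0.5)
        pi0 = float(min(max(pi0, 1.0 / m), 1.0))

    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    ranked = p[order] * m / np.arange(1, m + 1) * pi0
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    return QvalueResult(p_values=p, pi0=pi0, q_values=q)


def rbm20_confounding_bound(trans_factor_expr, genotypes: pd.DataFrame,
                            covariates: pd.DataFrame | None = None) -> dict:
    """Bound on sQTL contamination by a trans-acting splicing factor.

    Regresses the factor's expression on each candidate sQTL SNP, collects the
    p-values, and reports 1 - pi0 as the upper limit of the fraction of SNPs
    whose splicing association could be confounded by the factor.
    """
    expr = pd.DataFrame([np.asarray(trans_factor_expr, dtype=float)],
                        index=["trans_factor"], columns=genotypes.columns)
    pairs = pd.DataFrame({
        "gene_id": "trans_factor",
        "snp_id": genotypes.index,
        "distance": 0,
    })
    res = cis_eqtl_scan(expr, genotypes, covariates, pairs)
    p = res["p"].dropna().to_numpy()
    qr = storey_qvalues(p)
    return {"pi0": qr.pi0, "confounded_fraction_bound": qr.alt_fraction, "n_snps": int(p.size)}
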