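"""Negative-binomial differential-testing engine.

A self-contained DESeq2-style workflow: median-of-ratios size factors,
per-feature method-of-moments dispersion with shrinkage toward a fitted
mean-dispersion trend, log-link NB GLM fitting by iteratively reweighted
least squares (size factors as offsets), Wald tests against a normal
reference, and Benjamini-Hochberg adjustment.  Supports the one-factor
(stage) model and the two-factor stage x assay model whose interaction
coefficient contrasts steady-state against nascent-transcription changes.

Counts may be fractional (e.g. after proportional multi-mapper
assignment): the quasi-likelihood IRLS updates and the deviance used for
convergence are continuous in the response.

The parameterization throughout is var = mu + alpha * mu^2.  Reported
fold changes are on the log2 scale; the GLM itself works on the natural
log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))
DISPERSION_FLOOR = 1e-8

FITRESULT_COLUMNS = ["baseMean", "log2FC", "lfcSE", "stat", "pvalue", "padj"]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over features (restricted to
    features positive in every sample) of count / geometric-mean-count.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in all samples; median-of-ratios is "
            "undefined — consider a pseudo-reference fallback"
        )
    logs = np.log(mat[positive])
    geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups: pd.Series,
    trend_weight: float | None = None,
) -> pd.Series:
    """Per-feature dispersion (alpha in var = mu + alpha mu^2).

    Gene-wise method-of-moments estimates from within-group residuals of
    normalized counts, floored at 1e-8, are blended on the log scale with
    a fitted a0 + a1/mu mean-dispersion trend.  By default the blend
    weight is chosen adaptively: the trend receives the fraction of the
    observed log-dispersion spread that is attributable to sampling noise
    of a variance estimate on the available residual degrees of freedom
    (so homogeneous data shrink almost fully to the trend, while genuinely
    heterogeneous dispersions retain their gene-wise signal).  Pass a
    number in [0, 1] to fix the trend weight instead.
    """
    groups = groups.reindex(counts.columns)
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError("dispersion estimation requires >= 2 replicates in some group")
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    q = counts.to_numpy(dtype=float) / sf  # normalized counts

    n_feat = q.shape[0]
    ss = np.zeros(n_feat)
    df = 0
    xi_terms = []
    for g in sizes.index[sizes >= 2]:
        cols = np.flatnonzero((groups == g).to_numpy())
        sub = q[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        ss += ((sub - m) ** 2).sum(axis=1)
        df += len(cols) - 1
        xi_terms.append((1.0 / sf[cols]).mean() * (len(cols) - 1))
    pooled_var = ss / df
    xi = sum(xi_terms) / df  # mean reciprocal size factor, df-weighted
    base_mean = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gw = (pooled_var - xi * base_mean) / base_mean**2
    alpha_gw = np.where(np.isfinite(alpha_gw), alpha_gw, DISPERSION_FLOOR)
    alpha_gw = np.maximum(alpha_gw, DISPERSION_FLOOR)

    alpha_trend = _fit_trend(base_mean, alpha_gw)
    if trend_weight is None:
        weight = _adaptive_trend_weight(alpha_gw, alpha_trend, base_mean, df, xi)
    else:
        weight = np.full_like(alpha_gw, float(trend_weight))
    log_final = (1.0 - weight) * np.log(alpha_gw) + weight * np.log(alpha_trend)
    return pd.Series(np.exp(log_final), index=counts.index, name="dispersion")


def _adaptive_trend_weight(
    alpha_gw: np.ndarray,
    alpha_trend: np.ndarray,
    base_mean: np.ndarray,
    df: int,
    xi: float,
) -> np.ndarray:
    """Per-gene empirical-Bayes weight of the trend in the log blend.

    The sampling variance of a log method-of-moments dispersion is
    approximately trigamma(df/2) inflated by (1 + xi/(alpha*mu))^2 — the
    Poisson-noise subtraction amplifies the variance-estimate noise when
    counts are low relative to 1/alpha.  The prior (true biological)
    spread around the trend is the observed mean squared log residual
    minus the mean sampling variance; the trend weight for each gene is
    s2_i / (s2_i + prior), so homogeneous data shrink almost fully while
    genuinely heterogeneous dispersions keep their gene-wise signal.
    Genes whose gene-wise estimate sits at the floor carry no dispersion
    information and take the trend outright.
    """
    informative = alpha_gw > 10 * DISPERSION_FLOOR
    mu = np.maximum(base_mean, 1e-12)
    inflation = (1.0 + xi / (np.maximum(alpha_trend, DISPERSION_FLOOR) * mu)) ** 2
    s2_samp = float(special.polygamma(1, df / 2.0)) * inflation
    if informative.sum() >= 10:
        resid2 = (np.log(alpha_gw[informative]) - np.log(alpha_trend[informative])) ** 2
        prior_var = max(float(resid2.mean() - s2_samp[informative].mean()), 0.0)
    else:
        prior_var = 0.0
    weight = s2_samp / (s2_samp + prior_var) if prior_var > 0 else np.ones_like(s2_samp)
    weight = np.where(informative, weight, 1.0)
    return np.clip(weight, 0.0, 1.0)


def _fit_trend(base_mean: np.ndarray, alpha_gw: np.ndarray) -> np.ndarray:
    """alpha_tr(mu) = a0 + a1/mu fitted to informative gene-wise estimates."""
    ok = (base_mean > 0) & (alpha_gw > 10 * DISPERSION_FLOOR)
    if ok.sum() < 10:
        med = float(np.median(alpha_gw[ok])) if ok.any() else DISPERSION_FLOOR
        return np.full_like(alpha_gw, max(med, DISPERSION_FLOOR))
    x = np.column_stack([np.ones(int(ok.sum())), 1.0 / base_mean[ok]])
    y = alpha_gw[ok]
    # two robustness passes: refit after dropping gross outliers from the trend
    coef = None
    keep = np.ones(len(y), dtype=bool)
    for _ in range(2):
        coef, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
        fitted = x @ coef
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(fitted > 0, y / fitted, np.inf)
        keep = (ratio > 1e-2) & (ratio < 1e2)
        if keep.all():
            break
    a0, a1 = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
    if a0 == 0.0 and a1 == 0.0:
        a0 = max(float(np.median(y)), DISPERSION_FLOOR)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.where(base_mean > 0, base_mean, np.inf)
    return np.maximum(trend, DISPERSION_FLOOR)


@dataclass
class GLMFit:
    coef: np.ndarray  # natural-log scale
    cov: np.ndarray
    mu: np.ndarray
    deviance: float
    converged: bool
    n_iter: int


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    mu = np.maximum(mu, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    if alpha < 1e-12:
        dev = 2.0 * np.sum(term1 - (y - mu))
    else:
        term2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
        dev = 2.0 * np.sum(term1 - term2)
    return float(dev)


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    dispersion: float,
    size_factors: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GLMFit:
    """Log-link NB GLM by IRLS with log(size factor) offsets.

    Returns natural-log-scale coefficients and their covariance
    (X' W X)^-1 with Fisher weights W = mu / (1 + alpha*mu).  Convergence
    is a relative deviance change below ``tol`` (default 1e-8), capped at
    ``max_iter`` (default 100) iterations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    offset = np.log(np.asarray(size_factors, dtype=float))
    alpha = max(float(dispersion), 0.0)

    # initialize from weighted LS on log pseudo-counts
    z0 = np.log((y + 0.5) / np.exp(offset))
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -500, 500))
    dev = _nb_deviance(y, mu, alpha)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        eta = X @ beta_new + offset
        mu = np.exp(np.clip(eta, -500, 500))
        dev_new = _nb_deviance(y, mu, alpha)
        delta = abs(dev_new - dev) / (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if delta < tol:
            converged = True
            break
    W = mu / (1.0 + alpha * mu)
    XtWX = (X.T * W) @ X
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        converged = False
    return GLMFit(coef=beta, cov=cov, mu=mu, deviance=dev, converged=converged, n_iter=it)


def wald_test(log2fc: float, se_log2: float) -> tuple[float, float]:
    """Wald statistic and two-sided normal p for one contrast (log2 scale)."""
    if not np.isfinite(se_log2) or se_log2 <= 0:
        return np.nan, np.nan
    stat = log2fc / se_log2
    return float(stat), float(2.0 * stats.norm.sf(abs(stat)))


def adjust_bh(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family size and returned as NaN.
    Output is monotone in the input ranks and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _design_one_factor(is_b: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(is_b.size), is_b.astype(float)])


def _design_two_factor(is_b: np.ndarray, is_rna: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(is_b.size),
            is_b.astype(float),
            is_rna.astype(float),
            (is_b & is_rna).astype(float),
        ]
    )


def _wald_table(
    counts: pd.DataFrame,
    design: np.ndarray,
    coef_index: int,
    size_factors: pd.Series,
    dispersions: pd.Series,
) -> pd.DataFrame:
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    base_mean = (mat / sf).mean(axis=1)

    n = mat.shape[0]
    log2fc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    n_failed = 0
    disp = dispersions.reindex(counts.index).to_numpy(dtype=float)
    for i in range(n):
        y = mat[i]
        if y.sum() == 0:
            continue
        fit = fit_nb_glm(y, design, disp[i], sf)
        if not fit.converged:
            n_failed += 1
            continue
        c = fit.coef[coef_index] / LN2
        s = np.sqrt(fit.cov[coef_index, coef_index]) / LN2
        log2fc[i], se[i] = c, s
        stat[i], pval[i] = wald_test(c, s)
    if n_failed:
        logger.warning("%d features failed GLM convergence; excluded from BH family", n_failed)
    res = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": adjust_bh(pval),
        },
        index=counts.index.copy(),
    )
    res.index.name = "feature"
    return res


def de_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """One-factor Wald test of stage B vs stage A.

    Returns the standard result table (baseMean, log2FC, lfcSE, stat,
    pvalue, padj) indexed by feature; log2FC > 0 means higher in stage B.
    """
    meta = metadata.set_index("sample")
    samples = [s for s in counts.columns if meta.loc[s, "stage"] in (stage_a, stage_b)]
    if not samples:
        raise ValueError(f"no samples for stages {stage_a!r}/{stage_b!r}")
    sub = counts[samples]
    is_b = np.array([meta.loc[s, "stage"] == stage_b for s in samples])
    for name, mask in ((stage_a, ~is_b), (stage_b, is_b)):
        if mask.sum() < 2:
            raise ValueError(f"stage {name!r} has fewer than 2 replicates")
    sf = size_factors.reindex(samples) if size_factors is not None else estimate_size_factors(sub)
    groups = pd.Series(np.where(is_b, stage_b, stage_a), index=samples)
    disp = estimate_dispersions(sub, sf, groups)
    return _wald_table(sub, _design_one_factor(is_b), 1, sf, disp)


def two_factor_interaction(
    chro: pd.DataFrame,
    rna: pd.DataFrame,
    metadata: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    joint_size_factors: bool = True,
) -> pd.DataFrame:
    """Stage x assay interaction test on the intersected gene universe.

    Fits counts ~ stage + assay + stage:assay per gene and reports the
    interaction coefficient, interpretable as
    log2[(RNA_B/RNA_A) / (ChRO_B/ChRO_A)]: positive values mean the
    steady-state change exceeded the transcriptional change.  Size factors
    are estimated jointly on the combined matrix by default (per-assay
    otherwise); BH runs across all tested genes.
    """
    common = chro.index.intersection(rna.index)
    if common.empty:
        raise ValueError("no shared genes between the two matrices")
    meta = metadata.set_index("sample")

    def pick(cols, assay):
        return [
            s for s in cols
            if meta.loc[s, "assay"] == assay and meta.loc[s, "stage"] in (stage_a, stage_b)
        ]

    chro_cols = pick(chro.columns, "chro")
    rna_cols = pick(rna.columns, "rna")
    combined = pd.concat([chro.loc[common, chro_cols], rna.loc[common, rna_cols]], axis=1)
    samples = list(combined.columns)
    is_b = np.array([meta.loc[s, "stage"] == stage_b for s in samples])
    is_rna = np.array([s in rna_cols for s in samples])
    for stage, assay, mask in (
        (stage_a, "chro", ~is_b & ~is_rna),
        (stage_b, "chro", is_b & ~is_rna),
        (stage_a, "rna", ~is_b & is_rna),
        (stage_b, "rna", is_b & is_rna),
    ):
        if mask.sum() < 2:
            raise ValueError(f"design cell (stage={stage}, assay={assay}) has < 2 samples")

    if joint_size_factors:
        sf = estimate_size_factors(combined)
    else:
        sf = pd.concat(
            [estimate_size_factors(combined[chro_cols]), estimate_size_factors(combined[rna_cols])]
        )
    cell = pd.Series(
        [f"{'B' if b else 'A'}:{'rna' if r else 'chro'}" for b, r in zip(is_b, is_rna)],
        index=samples,
    )
    disp = estimate_dispersions(combined, sf, cell)
    return _wald_table(combined, _design_two_factor(is_b, is_rna), 3, sf, disp)
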