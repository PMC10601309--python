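"""Spearman rank-correlation screens.

Used for miRNA-vs-gene expression screens across stages/timepoints and
for promoter-vs-enhancer TRE activity.  The statistic is Pearson on
average ranks (so ties are handled); the p-value is exact by full
permutation enumeration for n <= 10 and a t-approximation for larger n.
"""

from __future__ import annotations

from itertools import islice, permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant input: Spearman correlation is undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all n! pairings (chunked)."""
    n = rx.size
    n_perm = factorial(n)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    thresh = abs(rho_obs) * denom - 1e-12
    hits = 0
    perm_iter = permutations(ry)
    chunk = 100_000
    while True:
        block = np.array(list(islice(perm_iter, chunk)))
        if block.size == 0:
            break
        cov = (block - ry.mean()) @ rx_c
        hits += int((np.abs(cov) >= thresh).sum())
    return hits / n_perm


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p for paired series (length >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    n = x.size
    if n <= 10:
        p = _exact_perm_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, max(min(p, 1.0), np.finfo(float).tiny)


def correlate_entity_vs_matrix(
    series: pd.Series,
    matrix: pd.DataFrame,
    threshold: float = 0.8,
    on_r2: bool = False,
) -> pd.DataFrame:
    """Correlate one expression series against every row of a matrix.

    Returns per-gene rho, p and a ``passes`` flag (rho > threshold, or
    rho^2 > threshold with rho > 0 when ``on_r2``), sorted by descending
    rho.  Matrix columns must match the series index (sample order).
    """
    common = [c for c in matrix.columns if c in series.index]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    sv = series[common].to_numpy(dtype=float)
    rows = []
    for gene, values in matrix[common].iterrows():
        try:
            rho, p = spearman(sv, values.to_numpy(dtype=float))
        except ValueError:  # constant gene: undefined correlation
            rho, p = np.nan, np.nan
        rows.append((gene, rho, p))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p"]).set_index("gene")
    if on_r2:
        out["passes"] = (out["rho"] > 0) & (out["rho"] ** 2 > threshold)
    else:
        out["passes"] = out["rho"] > threshold
    out["passes"] = out["passes"].fillna(False)
    return out.sort_values("rho", ascending=False, kind="mergesort")


def tre_activity_correlation(
    promoter_activity: pd.DataFrame,
    enhancer_activity: pd.DataFrame,
) -> tuple[float, float]:
    """Spearman correlation of summed promoter vs enhancer TRE activity.

    Inputs are TRE x sample activity matrices for the two groups; each
    group is summed per sample before correlating.  Constant sums raise
    (the correlation is undefined).
    """
    common = [c for c in promoter_activity.columns if c in enhancer_activity.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    p_sum = promoter_activity[common].sum(axis=0).to_numpy(dtype=float)
    e_sum = enhancer_activity[common].sum(axis=0).to_numpy(dtype=float)
    return spearman(p_sum, e_sum)
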