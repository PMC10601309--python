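"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity by the most naive route
available (per-base scans, explicit step-up loops, rank-then-Pearson) so
they stay independent of the implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ptreg.quant import QuantParams, tss_exclusion_window
from ptreg.simulate import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=100, n_mirnas=12, seed=7)


def brute_force_gene_counts(
    reads: pd.DataFrame,
    genes: pd.DataFrame,
    tres: pd.DataFrame | None,
    params: QuantParams | None = None,
) -> pd.Series:
    """O(reads x genes) per-read scan applying every rule literally."""
    params = params or QuantParams()
    out: dict[str, float] = {}
    tre_list = (
        list(tres[["chrom", "start", "end"]].itertuples(index=False)) if tres is not None else []
    )
    for g in genes.itertuples(index=False):
        if g.end - g.start < params.min_gene_length_bp:
            continue
        excl = tss_exclusion_window(g.strand, g.tss, params.tss_exclusion_bp)
        total = 0.0
        for r in reads.itertuples(index=False):
            if r.chrom != g.chrom or r.strand != g.strand:
                continue
            if not (g.start <= r.position < g.end):
                continue
            if excl[0] <= r.position < excl[1]:
                continue
            in_tre = any(
                t.chrom == g.chrom
                and max(t.start, g.start) <= r.position < min(t.end, g.end)
                for t in tre_list
            )
            if in_tre:
                continue
            total += r.count
        out[g.gene_id] = total
    return pd.Series(out, dtype=float)


def brute_force_mirna_counts(
    reads: pd.DataFrame, mirna_coords: pd.DataFrame, params: QuantParams | None = None
) -> pd.Series:
    params = params or QuantParams()
    out: dict[str, float] = {}
    for m in mirna_coords.itertuples(index=False):
        lo = max(0, m.start - params.mirna_flank_bp)
        hi = m.end + params.mirna_flank_bp
        total = 0.0
        for r in reads.itertuples(index=False):
            if r.chrom == m.chrom and r.strand == m.strand and lo <= r.position < hi:
                total += r.count
        out[m.mirna_id] = total
    return pd.Series(out, dtype=float)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up: find largest k with p_(k) <= k*q/m by scanning q."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def brute_force_spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Average ranks by explicit tie groups, then plain Pearson."""

    def ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def random_genome_instance(rng: np.random.Generator):
    """A tiny random genome + reads for oracle comparison."""
    n_genes = int(rng.integers(2, 8))
    genes = []
    pos = int(rng.integers(0, 500))
    for i in range(n_genes):
        length = int(rng.integers(300, 4000))
        strand = str(rng.choice(["+", "-"]))
        start, end = pos, pos + length
        genes.append(
            {
                "gene_id": f"g{i}",
                "chrom": "chrT",
                "strand": strand,
                "start": start,
                "end": end,
                "tss": start if strand == "+" else end - 1,
            }
        )
        pos = end + int(rng.integers(50, 800))
    genes = pd.DataFrame(genes)
    span = int(genes["end"].max()) + 1000

    n_tres = int(rng.integers(0, 6))
    tres = pd.DataFrame(
        [
            {
                "tre_id": f"t{j}",
                "chrom": "chrT",
                "start": (s := int(rng.integers(0, span - 400))),
                "end": s + int(rng.integers(100, 400)),
            }
            for j in range(n_tres)
        ],
        columns=["tre_id", "chrom", "start", "end"],
    )
    n_reads = int(rng.integers(0, 300))
    reads = pd.DataFrame(
        {
            "chrom": "chrT",
            "strand": rng.choice(["+", "-"], size=n_reads),
            "position": rng.integers(0, span, size=n_reads),
            "count": rng.integers(1, 4, size=n_reads),
        }
    )
    return genes, tres, reads
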