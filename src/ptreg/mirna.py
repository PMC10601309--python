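"""miRNA quantification and differential expression.

Implements RPMMM (reads per million mapped to miRNAs) normalization,
proportional assignment of reads that align equally well to multiple
loci, and the published differential-expression filter: NB Wald test on
raw counts with the DE set restricted to miRNAs with adjusted P < 0.05,
|log2FC| > 0.5, and a stage-mean RPMMM above 1000 in at least one stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ptreg import nb
from ptreg.classify import PTThresholds


def assign_multimapped(
    records: list[tuple[str, list[str], float]],
    mode: str = "equal",
    unique_support: dict[str, float] | None = None,
) -> pd.Series:
    """Distribute multi-mapping read counts over their candidate loci.

    ``records`` holds (read_id, equally-best loci, count).  In ``equal``
    mode each read contributes count/|loci| to every listed locus; in
    ``weighted`` mode the split is proportional to each locus's
    unique-read support (falling back to equal when no listed locus has
    support).  Total read mass is conserved exactly.
    """
    totals: dict[str, float] = {}
    for read_id, loci, count in records:
        if not loci:
            raise ValueError(f"read {read_id!r} has an empty locus list")
        if mode == "equal" or unique_support is None:
            weights = np.ones(len(loci))
        elif mode == "weighted":
            weights = np.array([unique_support.get(l, 0.0) for l in loci], dtype=float)
            if weights.sum() == 0:
                weights = np.ones(len(loci))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        weights = weights / weights.sum()
        for locus, w in zip(loci, weights):
            totals[locus] = totals.get(locus, 0.0) + count * w
    return pd.Series(totals, name="count", dtype=float).sort_index()


def rpmmm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million mapped to miRNAs: columns rescaled to sum to 1e6."""
    colsum = counts.sum(axis=0)
    safe = colsum.replace(0, np.nan)
    return (counts / safe * 1e6).fillna(0.0)


def _looks_like_rpmmm(counts: pd.DataFrame) -> bool:
    colsum = counts.sum(axis=0)
    nonzero = colsum[colsum > 0]
    if nonzero.empty:
        return False
    return bool(np.allclose(nonzero, 1e6, rtol=1e-6))


@dataclass
class DEMirnaSet:
    """Up/down DE miRNA sets for one transition, plus the full table."""

    transition: str
    up: frozenset[str]
    down: frozenset[str]
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def diff_mirna(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    thresholds: PTThresholds | None = None,
) -> DEMirnaSet:
    """One-factor NB Wald test plus the expression floor.

    Testing runs on raw (possibly fractional) counts with size factors; an
    RPMMM matrix is rejected because its per-sample totals are fixed by
    construction.  The DE set keeps miRNAs with padj below the alpha,
    |log2FC| above the threshold, and max stage-mean RPMMM above the
    floor; signs of log2FC partition it into up (higher in stage B) and
    down.
    """
    th = thresholds or PTThresholds()
    if _looks_like_rpmmm(counts):
        raise ValueError(
            "input looks RPMMM-normalized (columns sum to 1e6); differential "
            "testing requires raw counts"
        )
    meta = metadata.set_index("sample")
    samples = [s for s in counts.columns if meta.loc[s, "stage"] in (stage_a, stage_b)]
    sub = counts[samples]

    rpmmm = rpmmm_normalize(sub)
    stages = meta.loc[samples, "stage"]
    stage_means = rpmmm.T.groupby(stages).mean().T
    rpmmm_max = stage_means.max(axis=1)

    table = nb.de_test(sub, metadata, stage_a, stage_b)
    table = table.assign(rpmmm_max_stage_mean=rpmmm_max.reindex(table.index))

    passing = (
        (table["padj"] < th.mirna_alpha)
        & (table["log2FC"].abs() > th.mirna_abs_log2fc)
        & (table["rpmmm_max_stage_mean"] > th.mirna_rpmmm_min)
    ).fillna(False)
    up = frozenset(table.index[passing & (table["log2FC"] > 0)])
    down = frozenset(table.index[passing & (table["log2FC"] < 0)])
    return DEMirnaSet(transition=f"{stage_a}->{stage_b}", up=up, down=down, table=table)
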