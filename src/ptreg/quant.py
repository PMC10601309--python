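"""Nascent-transcription quantification from single-base polymerase positions.

Counts sense-strand reads over gene bodies with two exclusion rules: the
first 150 bp downstream of the TSS (promoter-proximal pausing) and any
transcriptional regulatory element (TRE) interval intersected with the gene
body.  Genes with a body shorter than 1 kb are dropped.  Counts are
length-normalized to TPM; miRNA loci are quantified over +/-5 kb flanks
without exclusions.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class QuantParams:
    tss_exclusion_bp: int = 150
    min_gene_length_bp: int = 1000
    mirna_flank_bp: int = 5000
    track_norm_total: float = 1_000_000.0

    def __post_init__(self) -> None:
        if min(self.tss_exclusion_bp, self.min_gene_length_bp, self.mirna_flank_bp) < 0:
            raise ValueError("lengths must be >= 0")
        if self.track_norm_total <= 0:
            raise ValueError("track_norm_total must be > 0")


def _index_reads(reads: pd.DataFrame) -> dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]:
    """(chrom, strand) -> (sorted positions, cumulative counts)."""
    index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if len(reads) == 0:
        return index
    for (chrom, strand), grp in reads.groupby(["chrom", "strand"], sort=False):
        agg = grp.groupby("position")["count"].sum().sort_index()
        pos = agg.index.to_numpy(dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(agg.to_numpy(dtype=np.float64))])
        index[(str(chrom), str(strand))] = (pos, cum)
    return index


def _count_interval(idx, chrom: str, strand: str, start: int, end: int) -> float:
    entry = idx.get((chrom, strand))
    if entry is None or end <= start:
        return 0.0
    pos, cum = entry
    lo = np.searchsorted(pos, start, side="left")
    hi = np.searchsorted(pos, end, side="left")
    return float(cum[hi] - cum[lo])


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def tss_exclusion_window(strand: str, tss: int, width: int) -> tuple[int, int]:
    """150 bp downstream of the TSS in the direction of transcription."""
    if strand == "+":
        return tss, tss + width
    return tss - width + 1, tss + 1


def count_gene_body(
    reads: pd.DataFrame,
    genes: pd.DataFrame,
    tres: pd.DataFrame | None,
    params: QuantParams | None = None,
) -> pd.Series:
    """Per-gene sense-strand read counts with pause and TRE exclusions.

    Genes shorter than ``min_gene_length_bp`` are absent from the output.
    Reads on unknown chromosomes are ignored (the read index simply has no
    entry); a gene whose TSS lies outside its body is an error.
    """
    params = params or QuantParams()
    known_chroms = set(genes["chrom"].unique())
    if len(reads):
        stray = set(reads["chrom"].unique()) - known_chroms
        if stray:
            logger.warning("skipping reads on unknown chromosomes: %s", sorted(stray))
    idx = _index_reads(reads)
    tre_arr = (
        tres[["chrom", "start", "end"]].to_numpy(dtype=object)
        if tres is not None and len(tres)
        else None
    )

    out: dict[str, float] = {}
    for row in genes.itertuples(index=False):
        if not (row.start <= row.tss < row.end):
            raise ValueError(f"gene {row.gene_id}: TSS {row.tss} outside body [{row.start},{row.end})")
        if row.end - row.start < params.min_gene_length_bp:
            continue
        exclusions = [tss_exclusion_window(row.strand, row.tss, params.tss_exclusion_bp)]
        if tre_arr is not None:
            for chrom, s, e in tre_arr:
                if chrom == row.chrom and s < row.end and e > row.start:
                    exclusions.append((max(s, row.start), min(e, row.end)))
        # clip exclusions to the body, merge, and count the kept segments
        clipped = [(max(s, row.start), min(e, row.end)) for s, e in exclusions]
        total = _count_interval(idx, row.chrom, row.strand, row.start, row.end)
        for s, e in _merge_intervals(clipped):
            total -= _count_interval(idx, row.chrom, row.strand, s, e)
        out[row.gene_id] = total
    return pd.Series(out, name="count", dtype=float)


def count_gene_body_matrix(
    reads_by_sample: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    tres: pd.DataFrame | None,
    params: QuantParams | None = None,
) -> pd.DataFrame:
    cols = {s: count_gene_body(r, genes, tres, params) for s, r in reads_by_sample.items()}
    return pd.DataFrame(cols)


def tpm_normalize(counts: pd.Series | pd.DataFrame, genes: pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Length-normalize to transcripts per million.

    TPM_g = (count_g / length_kb_g) / sum_h(count_h / length_kb_h) * 1e6.
    The denominator uses only the genes present in ``counts`` (i.e. those
    that survived the length filter); the effective length is the full
    gene-body length.  An all-zero column maps to all-zero TPM.
    """
    lengths = (genes.set_index("gene_id")["end"] - genes.set_index("gene_id")["start"]) / 1000.0
    if isinstance(counts, pd.Series):
        rate = counts / lengths.reindex(counts.index)
        denom = rate.sum()
        return rate / denom * 1e6 if denom > 0 else rate * 0.0
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    denom = rate.sum(axis=0)
    safe = denom.replace(0.0, np.nan)
    return (rate / safe * 1e6).fillna(0.0)


def count_mirna_locus(
    reads: pd.DataFrame,
    mirna_coords: pd.DataFrame,
    params: QuantParams | None = None,
) -> pd.Series:
    """Sense-strand reads within +/-flank of each mature miRNA coordinate.

    Mature miRNAs sit inside longer primary transcripts, so transcription
    at the locus is measured over a flanked window with no TSS or TRE
    exclusion.  Windows are clipped at position 0.
    """
    params = params or QuantParams()
    idx = _index_reads(reads)
    out: dict[str, float] = {}
    for row in mirna_coords.itertuples(index=False):
        start = max(0, row.start - params.mirna_flank_bp)
        end = row.end + params.mirna_flank_bp
        out[row.mirna_id] = _count_interval(idx, row.chrom, row.strand, start, end)
    return pd.Series(out, name="count", dtype=float)


def normalize_track(reads: pd.DataFrame, params: QuantParams | None = None) -> pd.DataFrame:
    """Scale a position track so total |signal| equals ``track_norm_total``.

    Returns bedGraph-like rows (chrom, start, end, value) with minus-strand
    values emitted negative, so plus/minus signal plot above/below zero.
    """
    params = params or QuantParams()
    if len(reads) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    agg = (
        reads.groupby(["chrom", "strand", "position"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "position", "strand"], kind="mergesort")
    )
    total = float(agg["count"].sum())
    scale = params.track_norm_total / total
    value = agg["count"].to_numpy(dtype=float) * scale
    value[agg["strand"].to_numpy() == "-"] *= -1.0
    return pd.DataFrame(
        {
            "chrom": agg["chrom"].to_numpy(),
            "start": agg["position"].to_numpy(),
            "end": agg["position"].to_numpy() + 1,
            "value": value,
        }
    )
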