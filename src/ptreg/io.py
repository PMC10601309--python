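"""Plain-text readers/writers for the pipeline's on-disk formats.

Everything is tab-separated or BED-style text so that inputs and outputs
remain diffable and byte-stable across runs.  Coordinates are 0-based
half-open (BED convention) throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "tss"]
TRE_COLUMNS = ["tre_id", "chrom", "start", "end"]
READ_COLUMNS = ["chrom", "strand", "position", "count"]
SITE_COLUMNS = ["mirna", "gene", "site_type", "species"]

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix TSV: first column feature id, one column per sample."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="feature", float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample, assay, stage."""
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "stage"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def write_genes_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    """Gene models as BED12 (single-block genes; thick = full body)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            length = row.end - row.start
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\t"
                f"{row.start}\t{row.end}\t0\t1\t{length},\t0,\n"
            )


def read_genes_bed12(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            tss = start if strand == "+" else end - 1
            rows.append((name, chrom, strand, start, end, tss))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_tres_bed6(tres: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in tres.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.tre_id}\t0\t.\n")


def read_tres_bed6(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append((f[3], f[0], int(f[1]), int(f[2])))
    return pd.DataFrame(rows, columns=TRE_COLUMNS)


def write_reads_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    """Single-base polymerase positions as BED6; score column carries the count."""
    with open(path, "w") as fh:
        for row in reads.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.position}\t{row.position + 1}\tread\t{row.count}\t{row.strand}\n"
            )


def read_reads_bed6(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], f[5], int(f[1]), int(f[4])))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    out = sites.copy()
    out["species"] = out["species"].map(
        lambda s: ",".join(sorted(s)) if not isinstance(s, str) else s
    )
    out.to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    sites["species"] = sites["species"].map(lambda s: frozenset(s.split(",")))
    return sites


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def dump_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
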