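"""Synthetic data generators with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: a paired nascent-transcription (ChRO) / steady-state (RNA) count
design over a two-stage transition, negative-binomially distributed counts
with var = mu + alpha*mu^2, a promoter-proximal pause spike in polymerase
position tracks, intragenic regulatory-element (TRE) read contamination,
stage-structured miRNA profiles, and TargetScan-like target-site tables in
which designated causal miRNAs preferentially target designated gene sets.

Every generator is deterministic given the config seed: each one derives
its own independent `numpy` Generator from (seed, stream-id), so generators
can be called in any order or in isolation and still reproduce byte-identical
output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
CONS_SPECIES = ("chicken", "dog", "mouse", "rat")

# fixed stream ids so each generator owns an independent RNG
_STREAM_GENOME = 1
_STREAM_TRUTH = 2
_STREAM_READS = 3
_STREAM_COUNTS = 4
_STREAM_MIRNA = 5
_STREAM_SITES = 6


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the analyzed contrast at desk scale: a two-stage
    transition (definitive endoderm -> duodenal spheroid) with two assays
    and three replicates per (stage, assay) cell, NB dispersion 0.05,
    moderate library-size imbalance, and a planted minority of genes with
    purely transcriptional or purely post-transcriptional effects.
    """

    n_genes: int = 200
    n_mirnas: int = 24
    samples_per_group: int = 3
    stages: tuple[str, str] = ("DE", "Duo")
    nb_dispersion: float = 0.05
    mean_expression_log_range: tuple[float, float] = (1.0, 3.5)  # log10 of base mean
    frac_transcriptional: float = 0.3
    frac_pt: float = 0.1
    effect_log2fc: float = 1.5
    frac_short_genes: float = 0.05
    tre_per_gene_rate: float = 1.0
    pause_fraction: float = 0.4
    causal_mirnas: tuple[tuple[str, str], ...] = (("mir-001", "down"), ("mir-002", "up"))
    seed: int = 0
    # genome layout
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    # miRNA profile shape
    frac_de_mirnas: float = 0.25
    frac_low_mirnas: float = 0.2
    # target-site densities (per miRNA x gene pair)
    background_site_prob: float = 0.05
    causal_site_prob: float = 0.9
    causal_target_frac: float = 0.8
    cons_species_prob: float = 0.5
    # read-track simulation
    tre_read_rate: float = 30.0
    size_factor_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1 or self.samples_per_group < 1:
            raise ValueError("counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.frac_transcriptional <= 1 and 0 <= self.frac_pt <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_transcriptional + self.frac_pt > 1:
            raise ValueError("frac_transcriptional + frac_pt must be <= 1")
        if len(self.stages) != 2:
            raise ValueError("exactly two stages are supported")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["causal_mirnas"] = [list(c) for c in self.causal_mirnas]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "causal_mirnas" in d:
            d["causal_mirnas"] = tuple(tuple(c) for c in d["causal_mirnas"])
        for key in ("mean_expression_log_range", "size_factor_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted per-gene and per-miRNA effects.

    ``genes`` carries transcriptional_log2fc, pt_log2fc, pt_label and the
    NB base mean; ``mirnas`` carries de_log2fc and the causal/low flags;
    ``causal_target_map`` maps each causal miRNA to its target gene set.
    The pt_label is a deterministic function of the pt_log2fc sign.
    """

    genes: pd.DataFrame
    mirnas: pd.DataFrame
    causal_target_map: dict[str, frozenset[str]] = field(default_factory=dict)

    def gene_ids(self) -> list[str]:
        return list(self.genes.index)


def _pt_label(lfc: float) -> str:
    if lfc > 0:
        return "stable"
    if lfc < 0:
        return "unstable"
    return "none"


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Plant transcriptional and post-transcriptional effects.

    Effect groups are disjoint: a gene carries a transcriptional effect, a
    post-transcriptional effect, or neither.  Post-transcriptional effects
    act in stage B only, so the designed interaction log2FC equals
    pt_log2fc.  Causal 'down' miRNAs target planted stable genes (loss of
    suppression) and causal 'up' miRNAs target planted unstable genes.
    """
    rng = config.rng(_STREAM_TRUTH)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    lo, hi = config.mean_expression_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=config.n_genes)

    n_trans = int(round(config.frac_transcriptional * config.n_genes))
    n_pt = int(round(config.frac_pt * config.n_genes))
    order = rng.permutation(config.n_genes)
    trans_idx = order[:n_trans]
    pt_idx = order[n_trans : n_trans + n_pt]

    trans_lfc = np.zeros(config.n_genes)
    trans_lfc[trans_idx] = rng.choice([-1.0, 1.0], size=n_trans) * config.effect_log2fc
    pt_lfc = np.zeros(config.n_genes)
    pt_lfc[pt_idx] = rng.choice([-1.0, 1.0], size=n_pt) * config.effect_log2fc

    genes = pd.DataFrame(
        {
            "base_mean": base_mean,
            "transcriptional_log2fc": trans_lfc,
            "pt_log2fc": pt_lfc,
            "pt_label": [_pt_label(v) for v in pt_lfc],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    mirna_ids = [f"mir-{i + 1:03d}" for i in range(config.n_mirnas)]
    causal = dict(config.causal_mirnas)
    unknown = set(causal) - set(mirna_ids)
    if unknown:
        raise ValueError(f"causal miRNAs outside the miRNA universe: {sorted(unknown)}")

    de_lfc = np.zeros(config.n_mirnas)
    is_causal = np.array([m in causal for m in mirna_ids])
    n_extra = int(round(config.frac_de_mirnas * config.n_mirnas))
    free = np.flatnonzero(~is_causal)
    extra = rng.choice(free, size=min(n_extra, free.size), replace=False)
    de_lfc[extra] = rng.choice([-1.0, 1.0], size=extra.size) * config.effect_log2fc
    for i, m in enumerate(mirna_ids):
        if m in causal:
            de_lfc[i] = config.effect_log2fc * (1.0 if causal[m] == "up" else -1.0)

    low = np.zeros(config.n_mirnas, dtype=bool)
    n_low = int(round(config.frac_low_mirnas * config.n_mirnas))
    low_candidates = np.flatnonzero(~is_causal)
    low[rng.choice(low_candidates, size=min(n_low, low_candidates.size), replace=False)] = True

    mir_base = 10.0 ** rng.uniform(np.log10(2000), np.log10(20000), size=config.n_mirnas)
    mir_base[low] = 10.0 ** rng.uniform(0.3, 1.5, size=int(low.sum()))

    mirnas = pd.DataFrame(
        {
            "base_mean": mir_base,
            "de_log2fc": de_lfc,
            "causal": is_causal,
            "low_expressed": low,
        },
        index=pd.Index(mirna_ids, name="mirna_id"),
    )

    stable = [g for g, v in zip(gene_ids, pt_lfc) if v > 0]
    unstable = [g for g, v in zip(gene_ids, pt_lfc) if v < 0]
    target_map: dict[str, frozenset[str]] = {}
    for m, direction in config.causal_mirnas:
        pool = stable if direction == "down" else unstable
        k = max(1, int(round(config.causal_target_frac * len(pool)))) if pool else 0
        chosen = rng.choice(pool, size=k, replace=False) if k else []
        target_map[m] = frozenset(chosen)
    return GroundTruth(genes=genes, mirnas=mirnas, causal_target_map=target_map)


# ---------------------------------------------------------------------------
# genome + read-track simulation


def simulate_genome(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out non-overlapping gene bodies and TREs on one synthetic chromosome.

    A configured fraction of genes gets a body shorter than 1 kb (to
    exercise the length filter); TREs are placed both inside gene bodies
    and in intergenic space.  Raises if the requested genes cannot fit on
    the chromosome.
    """
    rng = config.rng(_STREAM_GENOME)
    n = config.n_genes
    n_short = int(round(config.frac_short_genes * n))
    lengths = np.concatenate(
        [
            rng.integers(200, 1000, size=n_short),
            rng.integers(1500, 15000, size=n - n_short),
        ]
    )
    rng.shuffle(lengths)
    slack = config.chrom_length - int(lengths.sum())
    min_gap = 500
    if slack < min_gap * (n + 1):
        raise ValueError(
            f"cannot place {n} genes (total body {int(lengths.sum())} bp) on a "
            f"{config.chrom_length} bp chromosome without overlap"
        )
    gap_weights = rng.dirichlet(np.ones(n + 1))
    gaps = min_gap + np.floor(gap_weights * (slack - min_gap * (n + 1))).astype(int)

    starts = np.empty(n, dtype=int)
    pos = 0
    for i in range(n):
        pos += gaps[i]
        starts[i] = pos
        pos += lengths[i]
    ends = starts + lengths
    strands = rng.choice(["+", "-"], size=n)
    tss = np.where(strands == "+", starts, ends - 1)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n)],
            "chrom": config.chrom,
            "strand": strands,
            "start": starts,
            "end": ends,
            "tss": tss,
        }
    )

    tre_rows = []
    k = 0
    for i in range(n):
        for _ in range(rng.poisson(config.tre_per_gene_rate)):
            width = int(rng.integers(150, 400))
            if rng.random() < 0.5 and lengths[i] > width + 2:
                s = int(rng.integers(starts[i], ends[i] - width))
            else:  # intergenic: in the gap upstream of this gene
                gap_lo = starts[i] - gaps[i]
                s = int(rng.integers(gap_lo, max(gap_lo + 1, starts[i] - width)))
            tre_rows.append((f"t{k:04d}", config.chrom, s, s + width))
            k += 1
    tres = pd.DataFrame(tre_rows, columns=["tre_id", "chrom", "start", "end"])
    return genes, tres


def simulate_chro_reads(
    genes: pd.DataFrame,
    tres: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Draw single-base polymerase positions per sample.

    Gene-associated reads are sense-strand and split between a
    promoter-pause spike confined to the first 150 bp downstream of the
    TSS (rate ``pause_fraction``) and uniform gene-body positions whose
    rate scales with 2^(transcriptional effect).  TRE-localized reads are
    added on both strands.  Per-sample depth varies log-uniformly to
    exercise normalization.
    """
    missing = set(genes["gene_id"]) - set(truth.genes.index)
    if missing:
        raise ValueError(f"ground truth does not cover genes: {sorted(missing)[:5]}")
    rng = config.rng(_STREAM_READS)
    lo, hi = config.size_factor_range
    out: dict[str, pd.DataFrame] = {}
    base = truth.genes["base_mean"].reindex(genes["gene_id"]).to_numpy()
    trans = truth.genes["transcriptional_log2fc"].reindex(genes["gene_id"]).to_numpy()
    for stage_i, stage in enumerate(config.stages):
        for rep in range(config.samples_per_group):
            depth = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            chroms, strands, positions = [], [], []
            lam = base * depth * (2.0**trans if stage_i == 1 else 1.0)
            n_reads = rng.poisson(lam)
            for gi, row in enumerate(genes.itertuples(index=False)):
                ng = int(n_reads[gi])
                if ng == 0:
                    continue
                n_pause = rng.binomial(ng, config.pause_fraction)
                if row.strand == "+":
                    pw_lo, pw_hi = row.tss, min(row.tss + 150, row.end)
                else:
                    pw_lo, pw_hi = max(row.tss - 149, row.start), row.tss + 1
                pos = np.concatenate(
                    [
                        rng.integers(pw_lo, pw_hi, size=n_pause),
                        rng.integers(row.start, row.end, size=ng - n_pause),
                    ]
                )
                positions.append(pos)
                strands.append(np.full(ng, row.strand))
                chroms.append(np.full(ng, row.chrom))
            for row in tres.itertuples(index=False):
                nt = rng.poisson(config.tre_read_rate * depth)
                if nt == 0:
                    continue
                positions.append(rng.integers(row.start, row.end, size=nt))
                strands.append(rng.choice(["+", "-"], size=nt))
                chroms.append(np.full(nt, row.chrom))
            if positions:
                reads = pd.DataFrame(
                    {
                        "chrom": np.concatenate(chroms),
                        "strand": np.concatenate(strands),
                        "position": np.concatenate(positions),
                        "count": 1,
                    }
                )
                reads = (
                    reads.groupby(["chrom", "strand", "position"], as_index=False)["count"]
                    .sum()
                    .sort_values(["chrom", "position", "strand"], kind="mergesort")
                    .reset_index(drop=True)
                )
            else:
                reads = pd.DataFrame(columns=["chrom", "strand", "position", "count"])
            out[f"chro_{stage}_r{rep + 1}"] = reads
    return out


# ---------------------------------------------------------------------------
# count-matrix simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with var = mu + alpha*mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


def simulate_count_matrices(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired ChRO/RNA NB count matrices plus sample metadata.

    ChRO mean for gene g in stage s is base_g * 2^(trans_gs); the RNA mean
    multiplies that by 2^(pt_gs), with the post-transcriptional effect
    acting in stage B only — so the designed interaction log2FC equals
    pt_log2fc.  A shared dispersion and per-sample size factors are applied.
    """
    rng = config.rng(_STREAM_COUNTS)
    genes = truth.genes
    base = genes["base_mean"].to_numpy()
    trans = genes["transcriptional_log2fc"].to_numpy()
    pt = genes["pt_log2fc"].to_numpy()
    lo, hi = config.size_factor_range

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for assay in ("chro", "rna"):
        for stage_i, stage in enumerate(config.stages):
            for rep in range(config.samples_per_group):
                sf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                mu = base * 2.0 ** (trans * stage_i)
                if assay == "rna":
                    mu = mu * 2.0 ** (pt * stage_i)
                name = f"{assay}_{stage}_r{rep + 1}"
                cols[name] = _nb_draw(rng, mu * sf, config.nb_dispersion)
                meta_rows.append((name, assay, stage))
    counts = pd.DataFrame(cols, index=genes.index.copy())
    meta = pd.DataFrame(meta_rows, columns=["sample", "assay", "stage"])
    chro_cols = meta.loc[meta["assay"] == "chro", "sample"]
    rna_cols = meta.loc[meta["assay"] == "rna", "sample"]
    return counts[list(chro_cols)], counts[list(rna_cols)], meta


def simulate_mirna_counts(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-structured miRNA NB counts plus metadata.

    Designated causal miRNAs shift with the configured direction and
    magnitude; a configured subset is kept at very low abundance so it
    falls below the RPMMM expression floor downstream.
    """
    rng = config.rng(_STREAM_MIRNA)
    mirnas = truth.mirnas
    base = mirnas["base_mean"].to_numpy()
    lfc = mirnas["de_log2fc"].to_numpy()
    lo, hi = config.size_factor_range
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for stage_i, stage in enumerate(config.stages):
        for rep in range(config.samples_per_group):
            sf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            mu = base * 2.0 ** (lfc * stage_i)
            name = f"mirna_{stage}_r{rep + 1}"
            cols[name] = _nb_draw(rng, mu * sf, config.nb_dispersion)
            meta_rows.append((name, "mirna", stage))
    counts = pd.DataFrame(cols, index=mirnas.index.copy())
    meta = pd.DataFrame(meta_rows, columns=["sample", "assay", "stage"])
    return counts, meta


def simulate_target_sites(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """TargetScan-like site table (mirna, gene, site_type, species).

    Causal miRNAs receive sites on their causal target genes at elevated
    density (and with stronger site types); every miRNA receives uniform
    background sites.  Every site is present in human; each additional
    species from {chicken, dog, mouse, rat} is included independently.
    """
    rng = config.rng(_STREAM_SITES)
    gene_ids = list(truth.genes.index)
    rows = []
    causal_type_p = (0.5, 0.3, 0.2)
    background_type_p = (0.2, 0.3, 0.5)
    for mirna in truth.mirnas.index:
        targets = truth.causal_target_map.get(mirna, frozenset())
        for gene in gene_ids:
            is_causal_pair = gene in targets
            p = config.causal_site_prob if is_causal_pair else config.background_site_prob
            if rng.random() >= p:
                continue
            site_type = rng.choice(
                SITE_TYPES, p=causal_type_p if is_causal_pair else background_type_p
            )
            species = {"human"}
            for sp in CONS_SPECIES:
                if rng.random() < config.cons_species_prob:
                    species.add(sp)
            rows.append((mirna, gene, site_type, frozenset(species)))
    return pd.DataFrame(rows, columns=["mirna", "gene", "site_type", "species"])


# ---------------------------------------------------------------------------
# bundle convenience


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    truth: GroundTruth
    genes: pd.DataFrame
    tres: pd.DataFrame
    reads: dict[str, pd.DataFrame]
    chro: pd.DataFrame
    rna: pd.DataFrame
    mirna: pd.DataFrame
    metadata: pd.DataFrame
    sites: pd.DataFrame


def simulate_bundle(config: SimulationConfig, with_reads: bool = False) -> SyntheticBundle:
    """Generate every input the pipeline consumes, with ground truth."""
    truth = make_ground_truth(config)
    genes, tres = simulate_genome(config)
    reads = simulate_chro_reads(genes, tres, truth, config) if with_reads else {}
    chro, rna, meta = simulate_count_matrices(truth, config)
    mirna, mirna_meta = simulate_mirna_counts(truth, config)
    sites = simulate_target_sites(truth, config)
    metadata = pd.concat([meta, mirna_meta], ignore_index=True)
    return SyntheticBundle(
        config=config,
        truth=truth,
        genes=genes,
        tres=tres,
        reads=reads,
        chro=chro,
        rna=rna,
        mirna=mirna,
        metadata=metadata,
        sites=sites,
    )
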