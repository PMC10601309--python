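"""End-to-end orchestration of the stage-transition analysis.

Composes the stages — (optional) read quantification, two-factor NB
interaction testing, post-transcriptional classification, differential
miRNA expression, Monte-Carlo target-site enrichment, and the correlation
screen — into one reproducible run that writes TSV tables, a JSON
summary, and a run log.  All outputs are byte-deterministic for a fixed
config and seed: no timestamps or absolute paths are embedded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ptreg import __version__, io, mirhub, mirna, nb, quant
from ptreg.classify import PTThresholds, classify_pt, summarize_transition
from ptreg.correlate import correlate_entity_vs_matrix
from ptreg.mirhub import ScoreParams
from ptreg.quant import QuantParams
from ptreg.simulate import SimulationConfig, simulate_bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    chro_counts: str | None = None
    rna_counts: str | None = None
    mirna_counts: str | None = None
    metadata: str | None = None
    genes: str | None = None
    tres: str | None = None
    sites: str | None = None
    reads_dir: str | None = None
    stage_a: str = "DE"
    stage_b: str = "Duo"
    seed: int = 0
    out_dir: str = "ptreg_run"
    thresholds: PTThresholds = field(default_factory=PTThresholds)
    quant_params: QuantParams = field(default_factory=QuantParams)
    score_params: ScoreParams = field(default_factory=ScoreParams)
    simulation: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = io.load_yaml(path) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = PTThresholds(**kwargs["thresholds"])
        if "quant_params" in kwargs:
            kwargs["quant_params"] = QuantParams(**kwargs["quant_params"])
        if "score_params" in kwargs:
            kwargs["score_params"] = ScoreParams(**kwargs["score_params"])
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        return cls(**kwargs)


def write_simulation(config: SimulationConfig, out_dir: str | Path, with_reads: bool = True) -> Path:
    """Materialize a full synthetic input bundle (plus ground truth) on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config, with_reads=with_reads)
    io.write_genes_bed12(bundle.genes, out / "genes.bed12")
    io.write_tres_bed6(bundle.tres, out / "tres.bed")
    io.write_counts(bundle.chro, out / "chro_counts.tsv")
    io.write_counts(bundle.rna, out / "rna_counts.tsv")
    io.write_counts(bundle.mirna, out / "mirna_counts.tsv")
    io.write_tsv(bundle.metadata, out / "metadata.tsv")
    io.write_sites(bundle.sites, out / "target_sites.tsv")
    truth_genes = bundle.truth.genes.reset_index()
    io.write_tsv(truth_genes, out / "truth_genes.tsv")
    truth_mirnas = bundle.truth.mirnas.reset_index()
    io.write_tsv(truth_mirnas, out / "truth_mirnas.tsv")
    target_rows = [
        {"mirna": m, "gene": g}
        for m, gs in sorted(bundle.truth.causal_target_map.items())
        for g in sorted(gs)
    ]
    io.write_tsv(pd.DataFrame(target_rows, columns=["mirna", "gene"]), out / "truth_targets.tsv")
    if with_reads:
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        for sample, reads in bundle.reads.items():
            io.write_reads_bed6(reads, reads_dir / f"{sample}.bed")
    io.dump_yaml({"simulation": config.to_dict()}, out / "config.yaml")
    return out


def _gene_lengths_tpm(chro_counts: pd.DataFrame, genes: pd.DataFrame | None) -> pd.DataFrame:
    if genes is not None:
        present = genes[genes["gene_id"].isin(chro_counts.index)]
        return quant.tpm_normalize(chro_counts.loc[present["gene_id"]], present)
    logger.warning("no gene models given: TPM computed with unit gene length")
    unit = pd.DataFrame(
        {"gene_id": chro_counts.index, "start": 0, "end": 1000}
    )
    return quant.tpm_normalize(chro_counts, unit)


def run_transition_analysis(config: PipelineConfig) -> dict:
    """Run the full workflow for one stage transition; returns the summary.

    Stages with missing inputs are skipped with an explicit log line,
    never silently.  Writes per-stage TSVs, a JSON summary, and run.log
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"ptreg {__version__}",
        f"seed {config.seed}",
        f"transition {config.stage_a} -> {config.stage_b}",
        f"thresholds {config.thresholds.to_dict()}",
    ]
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "transition": f"{config.stage_a}->{config.stage_b}",
        "thresholds": config.thresholds.to_dict(),
    }

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    metadata = io.read_metadata(config.metadata) if config.metadata else None
    genes = io.read_genes_bed12(config.genes) if config.genes else None
    tres = io.read_tres_bed6(config.tres) if config.tres else None

    # --- quantification (only when raw read tracks are supplied)
    chro_counts = None
    if config.reads_dir:
        if genes is None:
            log("SKIP quantification: reads given but no gene models")
        else:
            reads_by_sample = {
                p.stem: io.read_reads_bed6(p)
                for p in sorted(Path(config.reads_dir).glob("*.bed"))
            }
            chro_counts = quant.count_gene_body_matrix(
                reads_by_sample, genes, tres, config.quant_params
            )
            io.write_counts(chro_counts, out / "chro_counts_quantified.tsv")
            log(f"quantified {chro_counts.shape[0]} genes x {chro_counts.shape[1]} samples")
    if chro_counts is None and config.chro_counts:
        chro_counts = io.read_counts(config.chro_counts)

    rna_counts = io.read_counts(config.rna_counts) if config.rna_counts else None

    # --- two-factor interaction + classification
    classification = None
    if chro_counts is None or rna_counts is None or metadata is None:
        log("SKIP interaction/classification: need ChRO counts, RNA counts and metadata")
    else:
        interaction = nb.two_factor_interaction(
            chro_counts, rna_counts, metadata, config.stage_a, config.stage_b
        )
        chro_de = nb.de_test(chro_counts, metadata, config.stage_a, config.stage_b)
        rna_de = nb.de_test(rna_counts, metadata, config.stage_a, config.stage_b)
        tpm = _gene_lengths_tpm(chro_counts, genes)
        classification = classify_pt(
            interaction, chro_de, rna_de, tpm, metadata, config.thresholds
        )
        io.write_tsv(interaction.reset_index(), out / "interaction.tsv")
        io.write_tsv(chro_de.reset_index(), out / "chro_de.tsv")
        io.write_tsv(rna_de.reset_index(), out / "rna_de.tsv")
        io.write_tsv(classification.reset_index(), out / "classification.tsv")
        summary["pt_labels"] = summarize_transition(classification)
        log(f"pt label counts: {summary['pt_labels']}")

    # --- differential miRNA expression
    de_set = None
    if config.mirna_counts is None or metadata is None:
        log("SKIP miRNA DE: no miRNA counts or metadata")
    else:
        mirna_counts = io.read_counts(config.mirna_counts)
        de_set = mirna.diff_mirna(
            mirna_counts, metadata, config.stage_a, config.stage_b, config.thresholds
        )
        io.write_tsv(de_set.table.reset_index(), out / "mirna_de.tsv")
        (out / "up.txt").write_text("".join(f"{m}\n" for m in sorted(de_set.up)))
        (out / "down.txt").write_text("".join(f"{m}\n" for m in sorted(de_set.down)))
        summary["de_mirnas"] = {"up": sorted(de_set.up), "down": sorted(de_set.down)}
        log(f"DE miRNAs: {len(de_set.up)} up, {len(de_set.down)} down")

    # --- target-site enrichment + candidate regulators
    if config.sites is None or classification is None or de_set is None:
        log("SKIP miRhub: needs site table, classification and DE miRNAs")
    else:
        sites = mirhub.filter_cons1(io.read_sites(config.sites))
        all_mirnas = sorted(io.read_counts(config.mirna_counts).index)
        summary["candidate_regulators"] = {}
        for subset_col, fallback_col, direction, tag in (
            ("stringent_stable", "stable", "down", "stable"),
            ("stringent_unstable", "unstable", "up", "unstable"),
        ):
            gene_set = set(classification.index[classification[subset_col]])
            if not gene_set:
                gene_set = set(classification.index[classification[fallback_col]])
            if not gene_set:
                log(f"SKIP miRhub ({tag}): empty gene set")
                continue
            params = ScoreParams(
                site_type_weights=config.score_params.site_type_weights,
                n_iterations=config.score_params.n_iterations,
                null_mode=config.score_params.null_mode,
                seed=config.seed,
            )
            background = sorted(set(sites["gene"]) | set(classification.index))
            res = mirhub.monte_carlo_enrichment(
                gene_set, all_mirnas, sites, params, background=background
            )
            io.write_tsv(res.reset_index(), out / f"mirhub_{tag}.tsv")
            cands = mirhub.candidate_regulators(res, de_set, direction)
            summary["candidate_regulators"][tag] = cands
            log(f"candidate regulators ({tag}, {direction}-miRNAs): {cands}")

    # --- correlation screen (needs >= 3 stages of expression to rank)
    if metadata is not None and config.mirna_counts and rna_counts is not None:
        stages = sorted(metadata["stage"].unique())
        if len(stages) < 3:
            log("SKIP correlation screen: fewer than 3 stages")
        else:
            mirna_counts = io.read_counts(config.mirna_counts)
            rp = mirna.rpmmm_normalize(mirna_counts)
            meta = metadata.set_index("sample")
            mir_stage = rp.T.groupby(meta.loc[rp.columns, "stage"]).mean().T[stages]
            sf = nb.estimate_size_factors(rna_counts)
            rna_norm = rna_counts / sf
            rna_stage = rna_norm.T.groupby(meta.loc[rna_norm.columns, "stage"]).mean().T[stages]
            for tag in summary.get("candidate_regulators", {}):
                for m in summary["candidate_regulators"][tag]:
                    series = mir_stage.loc[m]
                    series.index.name = None
                    screen = correlate_entity_vs_matrix(series, rna_stage)
                    io.write_tsv(screen.reset_index(), out / f"correlation_{m}.tsv")
                    log(f"correlation screen for {m}: {int(screen['passes'].sum())} genes pass")
    else:
        log("SKIP correlation screen: missing miRNA or RNA inputs")

    io.dump_json(summary, out / "summary.json")
    (out / "run.log").write_text("".join(f"{line}\n" for line in log_lines))
    return summary
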