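"""Post-transcriptional stability classification for one stage transition.

A gene whose steady-state (RNA) change exceeds its nascent-transcription
(ChRO) change across a stage transition — a significantly positive
interaction log2FC — has lost post-transcriptional suppression ("stable");
a significantly negative interaction marks gained suppression
("unstable").  The stringent subsets additionally require essentially no
transcriptional change (ChRO padj > 0.1) but a significant steady-state
change, isolating genes regulated primarily post-transcriptionally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("stable", "unstable", "stringent_stable", "stringent_unstable", "concordant", "none")


@dataclass
class PTThresholds:
    """Decision thresholds for the stability and miRNA-DE calls."""

    interaction_abs_log2fc: float = 0.5
    interaction_alpha: float = 0.05
    chro_tpm_min: float = 20.0
    rna_basemean_min: float = 100.0
    stringent_chro_alpha_floor: float = 0.1
    stringent_rna_alpha: float = 0.05
    stringent_rna_abs_log2fc: float = 0.5
    mirna_rpmmm_min: float = 1000.0
    mirna_abs_log2fc: float = 0.5
    mirna_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("interaction_alpha", "stringent_rna_alpha", "mirna_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in (
            "interaction_abs_log2fc",
            "chro_tpm_min",
            "rna_basemean_min",
            "stringent_chro_alpha_floor",
            "stringent_rna_abs_log2fc",
            "mirna_rpmmm_min",
            "mirna_abs_log2fc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_pt(
    interaction: pd.DataFrame,
    chro_de: pd.DataFrame,
    rna_de: pd.DataFrame,
    chro_tpm: pd.DataFrame,
    metadata: pd.DataFrame,
    thresholds: PTThresholds | None = None,
) -> pd.DataFrame:
    """Label each gene for one stage transition.

    Expression gates: max stage-mean ChRO TPM above ``chro_tpm_min`` and
    RNA baseMean above ``rna_basemean_min``.  Gated genes with a
    significant interaction are stable (log2FC > threshold) or unstable
    (< -threshold); those additionally showing flat ChRO but significant,
    direction-matched RNA change are stringent.  Remaining genes are
    concordant (both single-assay tests significant, same direction) or
    none.  Genes missing from any input table are dropped with a logged
    count; genes whose interaction fit did not converge are never called
    stable/unstable.
    """
    th = thresholds or PTThresholds()
    universe = interaction.index
    common = universe.intersection(chro_de.index).intersection(rna_de.index).intersection(
        chro_tpm.index
    )
    dropped = len(universe) - len(common)
    if dropped:
        logger.warning("classify_pt: %d genes missing from some input table; excluded", dropped)

    meta = metadata.set_index("sample")
    tpm_cols = [c for c in chro_tpm.columns if c in meta.index and meta.loc[c, "assay"] == "chro"]
    tpm = chro_tpm[tpm_cols] if tpm_cols else chro_tpm
    stage_of = (
        meta.loc[[c for c in tpm.columns if c in meta.index], "stage"]
        if tpm_cols
        else None
    )
    if stage_of is not None and len(stage_of):
        stage_means = tpm.T.groupby(stage_of).mean().T
        tpm_max = stage_means.max(axis=1)
    else:  # no metadata for the TPM columns: fall back to per-sample max
        tpm_max = tpm.max(axis=1)
    tpm_max = tpm_max.reindex(common)

    inter = interaction.loc[common]
    chro = chro_de.loc[common]
    rna = rna_de.loc[common]

    gates = (tpm_max > th.chro_tpm_min) & (rna["baseMean"] > th.rna_basemean_min)
    inter_sig = (inter["padj"] < th.interaction_alpha).fillna(False)
    stable = gates & inter_sig & (inter["log2FC"] > th.interaction_abs_log2fc)
    unstable = gates & inter_sig & (inter["log2FC"] < -th.interaction_abs_log2fc)

    chro_flat = (chro["padj"] > th.stringent_chro_alpha_floor).fillna(False)
    rna_sig = (rna["padj"] < th.stringent_rna_alpha).fillna(False)
    stringent_stable = stable & chro_flat & rna_sig & (rna["log2FC"] > th.stringent_rna_abs_log2fc)
    stringent_unstable = (
        unstable & chro_flat & rna_sig & (rna["log2FC"] < -th.stringent_rna_abs_log2fc)
    )

    chro_sig = (chro["padj"] < th.interaction_alpha).fillna(False)
    same_dir = np.sign(chro["log2FC"].fillna(0)) == np.sign(rna["log2FC"].fillna(0))
    concordant = (~stable) & (~unstable) & chro_sig & rna_sig & same_dir & (rna["log2FC"] != 0)

    label = pd.Series("none", index=common, dtype=object)
    provenance = pd.Series("no_rule", index=common, dtype=object)
    label[concordant] = "concordant"
    provenance[concordant] = "both_assays_significant_same_direction"
    label[stable] = "stable"
    provenance[stable] = "interaction_positive"
    label[unstable] = "unstable"
    provenance[unstable] = "interaction_negative"
    label[stringent_stable] = "stringent_stable"
    provenance[stringent_stable] = "interaction_positive+chro_flat+rna_up"
    label[stringent_unstable] = "stringent_unstable"
    provenance[stringent_unstable] = "interaction_negative+chro_flat+rna_down"

    out = pd.DataFrame(
        {
            "label": label,
            "stable": stable | stringent_stable,
            "unstable": unstable | stringent_unstable,
            "stringent_stable": stringent_stable,
            "stringent_unstable": stringent_unstable,
            "provenance": provenance,
            "interaction_log2FC": inter["log2FC"],
            "interaction_padj": inter["padj"],
            "chro_log2FC": chro["log2FC"],
            "chro_padj": chro["padj"],
            "rna_log2FC": rna["log2FC"],
            "rna_padj": rna["padj"],
            "chro_tpm_max": tpm_max,
            "rna_basemean": rna["baseMean"],
        },
        index=common,
    )
    out.index.name = "gene"
    return out


def summarize_transition(classification: pd.DataFrame) -> dict[str, int]:
    """Tally labels; exclusive labels sum to the gene universe size.

    The stable/unstable totals include their stringent subsets (the
    stringent sets are subsets by construction).
    """
    counts = {lab: int((classification["label"] == lab).sum()) for lab in LABELS}
    counts["stable_total"] = int(classification["stable"].sum())
    counts["unstable_total"] = int(classification["unstable"].sum())
    counts["n_genes"] = int(len(classification))
    return counts
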