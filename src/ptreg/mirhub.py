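"""Monte-Carlo miRNA target-site enrichment (miRhub-style).

Given a gene set of interest (e.g. post-transcriptionally stable genes
for a stage transition) and a TargetScan-like table of predicted,
conservation-filtered target sites, each miRNA's targeting score on the
set is compared with scores on randomly drawn gene sets of the same size
to produce an empirical p-value with the (r+1)/(n+1) correction.
Candidate master regulators are enriched miRNAs whose own differential
expression moves opposite to the gene set (depleted miRNA <-> stabilized
targets, enriched miRNA <-> destabilized targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from ptreg.mirna import DEMirnaSet

CONS1_SPECIES = frozenset({"chicken", "dog", "mouse", "rat"})

DEFAULT_SITE_WEIGHTS = {"8mer": 3.0, "7mer-m8": 2.0, "7mer-A1": 1.0}

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class ScoreParams:
    """Scoring and null-model parameters.

    Site-type weights reflect canonical seed-match strength (8mer >
    7mer-m8 > 7mer-A1); the exact values are a configurable default, and
    enrichment conclusions should be read as rank statements, not
    absolute scores.
    """

    site_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_WEIGHTS)
    )
    n_iterations: int = 1000
    null_mode: str = "sampled"  # or "exhaustive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if any(w <= 0 for w in self.site_type_weights.values()):
            raise ValueError("site weights must be positive")
        if self.null_mode not in ("sampled", "exhaustive"):
            raise ValueError(f"unknown null_mode {self.null_mode!r}")


def filter_cons1(sites: pd.DataFrame) -> pd.DataFrame:
    """Keep sites conserved in human plus at least one of chicken/dog/mouse/rat."""
    keep = sites["species"].map(lambda sp: "human" in sp and bool(set(sp) & CONS1_SPECIES))
    return sites.loc[keep].reset_index(drop=True)


def _weight_matrix(
    sites: pd.DataFrame,
    genes: list[str],
    mirnas: list[str],
    weights: dict[str, float],
) -> np.ndarray:
    """genes x mirnas matrix of summed site weights."""
    W = np.zeros((len(genes), len(mirnas)))
    gi = {g: i for i, g in enumerate(genes)}
    mi = {m: i for i, m in enumerate(mirnas)}
    for row in sites.itertuples(index=False):
        i = gi.get(row.gene)
        j = mi.get(row.mirna)
        if i is None or j is None:
            continue
        W[i, j] += weights.get(row.site_type, 0.0)
    return W


def set_targeting_score(
    gene_set: set[str] | frozenset[str],
    mirna: str,
    sites: pd.DataFrame,
    params: ScoreParams | None = None,
) -> float:
    """Sum of site-type weights for one miRNA over a gene set.

    Genes without sites (or absent from the table) contribute zero; the
    score is additive over disjoint gene sets.
    """
    params = params or ScoreParams()
    sub = sites[(sites["mirna"] == mirna) & sites["gene"].isin(gene_set)]
    return float(sub["site_type"].map(params.site_type_weights).fillna(0.0).sum())


def monte_carlo_enrichment(
    gene_set: set[str] | frozenset[str],
    mirnas: list[str],
    sites: pd.DataFrame,
    params: ScoreParams | None = None,
    background: list[str] | None = None,
) -> pd.DataFrame:
    """Empirical target-site enrichment per miRNA.

    The null scores each of ``n_iterations`` random background subsets of
    size |gene_set| (drawn without replacement), or every subset in
    exhaustive mode (when C(|background|, |set|) <= 100,000).  The
    empirical p is (r+1)/(n+1) with r the number of null scores >= the
    observed score, so it can never be 0; exhaustive mode additionally
    reports the uncorrected tail probability r/n.
    """
    params = params or ScoreParams()
    if background is None:
        background = sorted(sites["gene"].unique())
    offenders = sorted(set(gene_set) - set(background))
    if offenders:
        raise ValueError(f"gene_set members missing from background: {offenders}")
    k = len(gene_set)
    if k == 0:
        raise ValueError("gene_set is empty")

    W = _weight_matrix(sites, list(background), list(mirnas), params.site_type_weights)
    gi = {g: i for i, g in enumerate(background)}
    obs_idx = np.array(sorted(gi[g] for g in gene_set))
    observed = W[obs_idx].sum(axis=0)

    if params.null_mode == "exhaustive":
        n_total = comb(len(background), k)
        if n_total > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive null has {n_total} subsets (> {EXHAUSTIVE_LIMIT}); use sampled mode"
            )
        null = np.empty((n_total, len(mirnas)))
        for t, idx in enumerate(combinations(range(len(background)), k)):
            null[t] = W[list(idx)].sum(axis=0)
    else:
        rng = np.random.default_rng(params.seed)
        n_total = params.n_iterations
        null = np.empty((n_total, len(mirnas)))
        for t in range(n_total):
            idx = rng.choice(len(background), size=k, replace=False)
            null[t] = W[idx].sum(axis=0)

    r = (null >= observed[None, :]).sum(axis=0)
    result = pd.DataFrame(
        {
            "observed_score": observed,
            "null_mean": null.mean(axis=0),
            "null_sd": null.std(axis=0, ddof=1) if n_total > 1 else 0.0,
            "empirical_p": (r + 1) / (n_total + 1),
        },
        index=pd.Index(mirnas, name="mirna"),
    )
    if params.null_mode == "exhaustive":
        result["tail_p"] = r / n_total
    return result


def candidate_regulators(
    mirhub_results: pd.DataFrame,
    de_set: DEMirnaSet,
    direction: str,
    alpha: float = 0.05,
) -> list[str]:
    """Intersect enrichment with the direction-matched DE miRNA set.

    ``direction`` selects which DE miRNAs can explain the gene set:
    "down" for stabilized genes (suppression lost as the miRNA is
    depleted) and "up" for destabilized genes.  Returns the qualifying
    miRNAs sorted by empirical p (ties by name).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    pool = de_set.down if direction == "down" else de_set.up
    hits = mirhub_results[
        (mirhub_results["empirical_p"] < alpha) & mirhub_results.index.isin(pool)
    ]
    return list(hits.sort_values(["empirical_p", "mirna"], kind="mergesort").index)


def screen_de_mirna_sites(
    tf_genes: list[str],
    de_up: set[str] | frozenset[str],
    sites: pd.DataFrame,
    require_all: bool = False,
) -> pd.DataFrame:
    """Which up-regulated miRNAs carry conserved sites on the listed genes.

    Rows are miRNAs from ``de_up`` with a conservation-filtered site on at
    least one listed gene (or on every gene when ``require_all``); columns
    are per-gene site-presence booleans.
    """
    cons = filter_cons1(sites)
    cons = cons[cons["mirna"].isin(de_up) & cons["gene"].isin(tf_genes)]
    if cons.empty:
        return pd.DataFrame(columns=tf_genes, index=pd.Index([], name="mirna"), dtype=bool)
    presence = (
        cons.assign(present=True)
        .pivot_table(index="mirna", columns="gene", values="present", aggfunc="any", fill_value=False)
        .reindex(columns=tf_genes, fill_value=False)
        .astype(bool)
    )
    keep = presence.all(axis=1) if require_all else presence.any(axis=1)
    out = presence.loc[keep].sort_index()
    out.index.name = "mirna"
    return out
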