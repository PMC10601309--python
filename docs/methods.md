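# Methods

## The model

The package separates transcriptional from post-transcriptional gene
regulation across a developmental stage transition by contrasting two
readouts of the same genes: nascent transcription (run-on style
polymerase-position counts over gene bodies, "ChRO") and steady-state
abundance (RNA-seq counts, "RNA"). For gene *g* with raw count *K_gj* in
sample *j*, we assume

    K_gj ~ NB(mu_gj, alpha_g),   var = mu + alpha * mu^2
    log mu_gj = log s_j + x_j' beta_g

with per-sample size factors *s_j* (median-of-ratios) entering as
offsets. The two-factor design is

    stage + assay + stage:assay

and the reported statistic is the interaction coefficient on the log2
scale, interpretable as

    log2[ (RNA_B / RNA_A) / (ChRO_B / ChRO_A) ].

A significantly positive interaction means the steady-state change
exceeded the transcriptional change — the gene lost post-transcriptional
suppression ("stable"); a negative interaction marks gained suppression
("unstable"). Stringent subsets additionally require a flat
transcriptional test (ChRO adjusted P > 0.1) together with a significant,
direction-matched steady-state change, isolating genes regulated
primarily post-transcriptionally. Significance is a Wald test
(coefficient / SE against a standard normal) with Benjamini–Hochberg
adjustment across tested genes.

Assumptions worth keeping in mind: shared NB dispersion across the four
design cells of a gene; size factors meaningful jointly across assays
(the default; per-assay estimation is a flag); independence of genes in
the BH family; and no fold-change shrinkage — thresholds are applied to
the raw Wald log2FC.

## Quantification rules

Gene-body counting from single-base polymerase positions applies three
rules before any statistics:

* genes with a body shorter than `min_gene_length_bp` (default 1000 bp)
  are excluded outright;
* reads in the first `tss_exclusion_bp` (default 150 bp) downstream of
  the TSS *in the direction of transcription* are excluded, removing the
  promoter-proximal pause spike;
* reads falling in any transcriptional regulatory element (TRE)
  intersected with the gene body are excluded, removing intragenic
  enhancer/promoter signal. TREs active in any stage of the comparison
  mask all samples (per-stage masking is available).

Only sense-strand reads are counted: the single base marks the polymerase
active site of the annotated transcription unit, and antisense signal
belongs to other units. Counts are normalized to TPM with the full
gene-body length in kb as the effective length (the masked TSS/TRE bases
are *not* subtracted; a flag provides the subtracted variant) and the
denominator restricted to genes passing the length filter. miRNA loci are
quantified over the mature coordinate ±`mirna_flank_bp` (default 5 kb,
clipped at the chromosome start) with no exclusions, because mature
miRNAs sit inside longer primary transcripts. Position tracks for
visualization are rescaled so total |signal| is 1e6, minus-strand values
negative.

All coordinates are 0-based half-open throughout.

## miRNA expression

Reads aligning equally well to several loci are split evenly across them
(a mode weighting by unique-read support is available); total mass is
conserved, so downstream counts may be fractional. Within-sample
normalization is RPMMM (reads per million mapped to miRNAs). Differential
testing runs on the raw (possibly fractional) counts — the IRLS updates
are continuous in the response, so fractional counts need no rounding —
and the DE set keeps miRNAs with adjusted P < 0.05, |log2FC| > 0.5, and
max stage-mean RPMMM > 1000. An RPMMM matrix is rejected as test input
(its column totals are fixed by construction).

## Dispersion estimation

Per-gene dispersions come from a method-of-moments estimate on
within-group residuals of normalized counts,

    alpha_gw = (s^2 - xi * mean) / mean^2,   xi = mean reciprocal size factor,

floored at 1e-8 and blended on the log scale with a fitted
`a0 + a1/mu` mean–dispersion trend. The blend weight is chosen per gene
by an empirical-Bayes argument: the sampling variance of the log
gene-wise estimate is approximately `trigamma(df/2) * (1 + xi/(alpha*mu))^2`
(the subtraction of Poisson noise inflates it at low counts), the prior
spread is the observed mean squared log residual around the trend minus
that sampling variance, and the trend receives weight
`s2_sampling / (s2_sampling + prior)`. Homogeneous data therefore shrink
nearly fully to the trend while genuinely heterogeneous dispersions keep
their gene-wise signal; a fixed weight in [0, 1] can be passed instead.
This choice was made because a fixed 0.5 blend let enough underestimated
dispersions through to push the null type-I fraction of the interaction
test above 6.5%; with adaptive weights the fraction sits at 4.7–5.8%
across seeds (2000 null genes, 3 samples per cell, dispersion 0.05).
Genes whose gene-wise estimate sits at the floor carry no dispersion
information and take the trend outright. This is a deliberate
simplification of full empirical-Bayes machinery (no Cox–Reid adjustment,
no outlier detection); calibration properties, not coefficient-identical
output of any particular tool, are the acceptance standard.

## GLM fitting

Log-link NB GLM by iteratively reweighted least squares, Fisher weights
`mu/(1 + alpha*mu)`, offsets `log s_j`, initialized from least squares on
log pseudo-counts. Convergence is a relative deviance change below 1e-8,
capped at 100 iterations; non-converged genes are reported NA and
excluded from the BH family with a logged count. The coefficient
covariance is `(X'WX)^{-1}`; Wald p-values use the normal reference.
All-zero genes are skipped.

## Target-site enrichment

A TargetScan-like site table (miRNA, gene, site type, conserving
species) is first filtered to sites present in human and at least one of
chicken, dog, mouse, rat ("cons1"). A miRNA's score on a gene set is the
sum of site-type weights over the set's sites; the default weights (8mer
3, 7mer-m8 2, 7mer-A1 1) encode the canonical seed-match strength
ordering but are configurable, and every conclusion the package draws
from scores is a rank/enrichment statement, never an absolute score. The
null distribution scores `n_iterations` (default 1000) random background
subsets of the same size drawn without replacement; when
C(|background|, |set|) ≤ 1e5 an exhaustive mode enumerates every subset.
The empirical p is (r+1)/(n+1) with r the number of null scores ≥
observed — it can never be 0, and ties count against enrichment.
Candidate master regulators are enriched miRNAs (empirical p < 0.05)
whose own differential expression is direction-matched to the gene set:
depleted miRNAs for stabilized genes, enriched miRNAs for destabilized
genes.

Because site counts are integers, the empirical p is discrete; it is
approximately uniform under the null only when the score support is wide
(many genes, appreciable site density). The null-calibration checks
therefore use a dense null table (site probability 0.3 per pair, 2000
genes, sets of 300) where the lattice tie mass is small; at sparse
densities the statistic is conservative (p mass near 1), which is the
correct behavior, not a defect.

## Correlation screens

Spearman rho is Pearson on average ranks (ties averaged). The p-value is
an exact two-sided permutation enumeration over all n! pairings for
n ≤ 10 (computed in chunks) and a t-approximation above. The
expression-screen threshold is applied to rho (> 0.8) by default; a flag
applies it to rho² instead, since both readings appear in practice.
Constant inputs are an error — the correlation is undefined, and
silently returning 0 would hide degenerate TRE activity sums.

## The synthetic-data generator

The generator is first-class, tested code that defines the study
conditions. Defaults mirror the analyzed contrast at desk scale: a
two-stage transition (definitive endoderm → duodenal spheroid), two
assays × 3 replicates per cell, NB dispersion 0.05, gene base means
log-uniform over 10^1–10^3.5, 30% of genes given a purely transcriptional
effect and 10% a purely post-transcriptional effect of ±1.5 log2 acting
in stage B only (so the designed interaction equals the planted pt
effect), per-sample size factors log-uniform in [0.5, 2], 24 miRNAs with
two planted causal regulators (one depleted targeting the planted stable
genes, one enriched targeting the unstable genes), 25% additional DE
miRNAs, and 20% kept below the RPMMM-1000 floor. Read tracks add a
promoter-pause spike confined to the 150 bp downstream of the TSS
(fraction 0.4 of gene reads), uniform gene-body reads scaling with
2^(transcriptional effect), and TRE-localized reads on both strands. The
genome is one synthetic 10 Mb chromosome with non-overlapping gene
bodies, a configured fraction of sub-1 kb bodies, and TREs placed both
inside and outside genes.

What it does not emulate: sequence (no FASTA, no seed-match discovery),
splicing and isoform structure, 3′UTR coordinates, GC or mappability
bias, correlated gene programs, batch effects, or count outliers.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real libraries.

Every generator derives an independent RNG stream from (seed, stream-id),
so any generator called twice with the same config is byte-identical and
generators can be invoked in isolation.

## Problem sizes

The shipped checks use desk-scale sizes chosen to make each property
measurable with comfortable margin: 200 random small genomes for the
exact counting oracle, 2000 genes for null calibration, 1000 genes for
stringent-recovery rates, 400 high-count genes for interaction-bias
measurement, 20 seeded replicates of the default study for end-to-end
regulator recovery, and 50 replicates for enrichment-null uniformity.

## Known limitations

* The NB engine is calibration-compatible with, but not bit-identical
  to, established DE tools: no independent filtering, no outlier
  replacement, no fold-change shrinkage.
* The Wald normal reference is mildly anti-conservative at 3 replicates
  per cell even with known dispersion (~5.5% at nominal 5%); this is a
  property of the method family, inherited deliberately.
* Enrichment p-values are conservative on sparse site tables (see
  above).
* The exact permutation p for Spearman is limited to n ≤ 10 by cost;
  beyond that the t-approximation is used.
* With only two stages, the cross-stage expression correlation screen is
  undefined (fewer than 3 points) and the pipeline skips it with an
  explicit log line.
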