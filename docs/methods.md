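# Methods

This note documents the models, conventions and design choices behind
`ctrdseq`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Biological setting

Plants exposed to a mild heat stress (priming, 37 °C) survive a later
acute stress (44 °C) better than naive plants. Two regimes are modelled:
SAT (short-term acquired thermotolerance, with priming; timepoints p1–p5)
and BT (basal thermotolerance, without priming; pA–pC), with biological
triplicates per timepoint and three assays per sample: total mRNA-seq,
polysomal mRNA-seq, and degradome 5′P-seq. 5′P-seq captures mRNAs with a
free 5′-monophosphate end — in a wild-type background these are dominated
by co-translational decay (CTRD) intermediates produced by the 5′→3′
exonuclease trailing the last translating ribosome.

## Coordinate and distance conventions

Transcript-local coordinates are 0-based half-open, 5′→3′; GFF3 I/O
converts at the boundary (1-based inclusive). The CDS includes the stop
codon. The distance from a 5′P end to the stop codon is
`index(first stop nt) − index(end)`, so the termination ribosome boundary
("16–17 nt upstream of the stop") is the two positions at distances 16
and 17. This single convention is shared by the simulator, the metagene
code and the TSI.

## TPM

TPM[g, s] = (count / length-in-kb) / (Σ_g count/length-in-kb / 10⁶); every
column sums to 10⁶ exactly. Gene length is the length of the gene's single
transcript model (the synthetic world is one transcript per gene); whether
a union-exon or transcript length is the better choice for multi-isoform
genomes is left to the caller, who can supply either. Zero-count genes get
TPM 0, not NA, so the downstream ≥ 1 TPM ubiquity filter treats absence as
absence of expression. The filter boundary is inclusive ("one or more
TPM"), evaluated on replicate-mean TPM per condition.

## Degradome profiling

**Metagene profiles** sum 5′P end counts over transcripts aligned at the
first nucleotide of the start or stop codon; transcripts that cannot host
the full window are excluded and counted, never padded (padding would
distort RPM). RPM normalisation divides by (total mapped ends across the
supplied track set)/10⁶. Default windows are −50..+100 around the start
and −100..+50 around the stop; these are display choices, configurable.

**Frame periodicity** is the fraction of CDS-internal ends in each frame
relative to `cds_start`, excluding the first and last 25 codons of the CDS
(standard metagene hygiene against initiation/termination artefacts;
configurable).

**TSI.** The numerator is the *sum* of the counts at the two boundary
positions; the denominator is the mean per-nucleotide count over the
flanking 100 nt, taken as 50 nt on each side of — and excluding — the
boundary pair. The flank geometry is symmetric so that the signal under
test never contaminates its own reference. Consequence of the sum
numerator: uniform coverage gives TSI = 2 exactly, so 2 (not 1) is the
neutral value; a boundary at 10 counts per position over a unit flank
gives 20. A zero flank makes the index undefined (flagged), never
infinite. TSI is invariant under uniform rescaling of a track.

## Translation efficiency

TE = (polysomal TPM + ε)/(degradome TPM + ε) on replicate-mean TPM with
ε = 0.1 TPM applied symmetrically. The pseudocount bounds log-ratios when
degradome signal vanishes; because conclusions could in principle depend
on it, ε is an explicit argument everywhere and sensitivity over
ε ∈ {0.01, 0.1, 1} is a one-line loop for the user. Log₂ ratios are taken
against the reference timepoint p1 (20 °C, which the study design treats
as equivalent to pA); the reference column is identically zero.
Distribution shifts against the reference use the two-sample
Kolmogorov–Smirnov test; primed-vs-unprimed comparisons between gene-set
distributions use the *unpaired* Wilcoxon rank-sum test (the gene sets
being compared are not meaningfully paired). Groups below n = 8 return a
flagged, p-less result rather than an underpowered test. Stars: * p<0.05,
** p<0.01, *** p<0.001.

## Differential expression engine

A from-scratch vectorised negative-binomial Wald test, authored here
because the selection cascade's logic — not any particular DE package —
is the scientific content; the published NB GLM engine (pydeseq2) serves
as an independent cross-check in the test suite on a planted fixture,
never as the implementation.

- **Normalisation**: median-of-ratios size factors against the
  geometric-mean reference (genes with any zero count excluded from the
  reference; total-count fallback when fewer than 10 remain), rescaled to
  geometric mean 1.
- **Dispersion**: per-gene method-of-moments estimates are extremely noisy
  at 3 replicates per group, so they are shrunk (weight 0.9) toward a
  mean–dispersion trend estimated by bin means over log-mean quantile
  bins. The moment estimator is mean-unbiased, so bin means converge on
  the true trend.
- **Inference**: Wald statistic on the log fold change of normalised group
  means, with Var(log mean) ≈ (1/μ + α)/n per group (delta method),
  referred to a t distribution with n₁+n₂−2 degrees of freedom. The t
  reference guards the small-sample tails; calibration on 2,000 null NB
  genes (μ = 200, α = 0.05, 3 vs 3) is verified in the acceptance suite
  (empirically conservative), with power ≈ 1 for 4-fold planted changes
  at the same size.
- **Decision rule**: significant ⇔ raw p < 0.05 AND replicate-mean TPM
  fold change > 2 in either direction (with the TE pseudocount guarding
  zeros). BH-adjusted p-values are reported alongside for users who want
  the stricter gate; the raw-p rule is the one the cascade applies.

## The CTRD cascade

ubiquitous (≥1 TPM everywhere) → remove genes DE in the total assay at any
stress timepoint (p2–p5, pB–pC) → remove genes DE in the polysomal assay →
keep genes DE in the degradome at ≥1 timepoint. The inclusion chain
ctrd ⊆ stable-polysomal ⊆ stable-total ⊆ ubiquitous and the subtraction
identities between reported sizes hold on every input by construction and
are asserted in the result object. The reference timepoint may not appear
as a contrast.

CTRD genes are clustered on their degradome log₂-ratio matrix (columns =
stress timepoints, reference excluded) by Ward linkage on Euclidean
distance, cut into k = 4 clusters by default — a small cluster count
matching how such heat maps are read; k is configurable. Cluster labels
are renumbered in dendrogram-leaf order so assignments are deterministic
for a given input order.

Venn set algebra is exact; a size-only variant (`venn_from_sizes`)
supports working from printed set sizes (e.g. 729/197 with 108 shared →
621/89, union 818).

## Nascent-peptide scoring

13-aa windows shifted one residue at a time across the first 80 aa; a
window is emitted only when complete (centers at residues 7..74).
Kyte–Doolittle windows are plain means. The HSP70/HSC70 window weights the
central 7 residues — the span an HSP70 substrate site occupies — at twice
the 3-residue flanks, normalised to sum 1, so a homopolymer window scores
exactly the residue's table value. The per-residue HSP70 table shipped in
`data/hsp70_binding_synthetic.tsv` is a *synthetic* default encoding the
qualitative DnaK/HSP70 substrate preferences (aliphatic/aromatic high,
acidic and proline low, basic mildly positive); any `residue<TAB>score`
TSV can replace it, and the table's provenance travels with the result.
Nonstandard residues (X, U, B, Z) score the table mean and are tallied;
sequences with internal stops are rejected.

Set profiles are position-wise means over the genes contributing a window
at that position, smoothed by an *interpolating* cubic spline (it
reproduces the knot values, used for display). Sets are compared with a
Welch t-test on gene-level mean scores — one number per gene — rather than
pooled windows, to avoid pseudo-replication from overlapping windows of
the same protein. Control sets are uniform draws without replacement,
seeded.

## Polysome quantification

Percent polysomes = 100 × polysome area / (40S + 60S + monosome +
polysome areas), each area the trapezoidal integral of (OD − baseline)
clipped at zero within the annotated region. The baseline is by default a
straight line between the trace values at the region's endpoints
(chart-recorder practice); a global constant can be supplied instead.
Region boundaries are inputs — gradient fractions are hand-assigned in
practice, so peak auto-detection is out of scope. Normalisation to a
control condition rescales all replicate percents by the control's
replicate mean, so the control reports exactly 100%, with SD and a
two-sample t-test against the control per sample.

## The synthetic-data generator

What it emulates: stop-terminated transcript models with realistic UTRs;
5′P tracks with 3-nt periodicity (default frame weights 0.55/0.25/0.20, a
clear but not extreme dominant frame), a multiplicative boundary boost
(default 8) at distances 16–17 nt, and Poisson total coverage (default
500 ends/transcript); NB counts (dispersion 0.05) over the full
SAT + BT triplicate design with log-normal expression baselines
(log-mean 5, log-sd 1 in count space) and mild log-normal library-size
variation (sd 0.1) to exercise TPM normalisation; Gaussian-peak gradient
traces with an exact pre-noise polysome area fraction.

The track position weights are 3-periodic over the *whole* transcript
(frame index extended mod 3 into the UTRs), which keeps the flanking
density around the stop boundary homogeneous — so the TSI of a boost-b
track concentrates near 2b — and still yields pure-frame tracks when one
frame weight is 1.

Planted perturbations: one shared set of DE genes (default 15%, |log₂FC|
= 2, random sign) perturbed coherently in all three assays at a random
non-empty subset of stress timepoints — a steady-state change propagates
through the polysome and the degradome — and a disjoint CTRD-only set
(default 5%, |log₂FC| = 2) perturbed in the degradome alone. Keeping the
transcriptional perturbation shared across assays (rather than three
independent per-assay draws) is what makes "degradome-only" a well-defined
planted category; every perturbation is recorded in the ground-truth
object, and reference timepoints (p1, pA) are never perturbed.

What it does **not** emulate: sequencing error, adapter/quality artefacts,
rRNA/organelle contamination, multi-isoform genes, positional coverage
bias, between-assay correlation of biological noise, or codon-level pause
structure beyond the stop boundary. Passing tests therefore demonstrate
the correctness and calibration of the *analysis* under the stated
generative model, not robustness to every artefact of real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen for statistical
resolution: 200 transcripts × 500 ends for periodicity/TSI recovery,
2,000 null and 500 planted genes for DE calibration and power, 1,000
genes (50 CTRD-only planted) for cascade recovery, 10 random fixtures for
the cascade identities. The full synthetic pipeline (200 transcripts, 24
samples × 3 assays) runs in seconds. Dispersion estimates are floored at
1e-8 and capped at 10; a half-count offset stabilises log fold changes of
sparse means; TSI and frame fractions raise or flag rather than emit
infinities on degenerate tracks; hierarchical clustering ties are resolved
by scipy's deterministic linkage given a fixed row order.

## Known limitations

- The NB Wald test is deliberately conservative at n = 3 (t reference,
  trended dispersion); users wanting maximum power at scale can substitute
  any engine that emits a `significant` column — the cascade is agnostic.
- The HSP70 table is a documented stand-in; quantitative HSP70-affinity
  claims require a published energy table supplied by the user.
- Gene-level TPM lengths ignore isoform structure.
- The polysome baseline model assumes the trace returns near baseline at
  region boundaries; heavily drifting gradients need the constant-baseline
  option or pre-detrending.
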