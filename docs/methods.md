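# Methods

This note records the models and procedures p73kit implements, the
parameters that matter, the design decisions taken where the convention was
genuinely open, and what the synthetic generators do and do not emulate.

## Junction-based isoform usage

### Model

A gene's alternative promoters and 3′ splice classes are each identified by
one diagnostic exon–exon junction. Usage is estimated as a ratio of
uniquely-mapped junction reads; no transcript-abundance model is fit. This
assumes the diagnostic junctions are captured with equal efficiency —
junction length, mappability and GC effects are not modeled, but a
per-junction efficiency multiplier is available in the generator to probe
sensitivity.

Coordinates: exons are 1-based inclusive; a junction is the 1-based
first/last intronic base in genomic orientation, matching the tab output of
spliced aligners so real junction files match without conversion. For a +
strand gene the junction of donor exon D and acceptor exon A is
(D.end + 1, A.start − 1); on the − strand the donor is the exon with larger
coordinates and the same genomic-left/right formula applies. Junction
matching is by chromosome and intron coordinates (the strand column in
junction files may be undefined, and coordinate collisions across strands
do not occur for a single gene).

### Decisions

* **α/β resolution.** The E10–E11 junction cannot separate α from β; its
  class share is split multiplicatively by the E12–E13 : E12–E14 read
  ratio. Proportional allocation is the minimal rule that keeps the five
  class percentages summing to 100. When E10–E11 has reads but neither
  resolver does, the share is reported as `alpha_beta_unresolved` with a
  flag rather than silently split.
* **Zero denominators.** A sample with no N-terminal (or C-terminal)
  junction coverage gets undefined percentages and a flag; it is excluded
  from the cross-sample mean of that statistic rather than counted as zero,
  and `n_defined` is always reported so either convention can be audited.
* **Aggregation.** Percentages are computed per sample and then averaged
  unweighted; counts are not pooled across samples, so deeply sequenced
  samples do not dominate.
* **γ and ε** are reported as one class (their diagnostic junction is
  shared); ζ and δ are separate.

## Single-cell QC and co-expression

A cell is excluded iff detected (non-spike-in) genes < 900, total counts
< 75,000, or spike-in percentage > 12. The wording of these rules is
strict, so cells sitting exactly on a boundary are retained. Two choices
the rules leave open, fixed here and exposed as parameters: the spike-in
percentage uses total counts (spike-ins included) as denominator, and
detected genes exclude spike-in features. Log-normalization is
ln(1 + s·count/total) with scale factor s = 10⁴ and per-cell totals over
non-spike-in genes; spike-ins are excluded from totals but still normalized
for inspection. Expression status is an inclusive threshold (≥ 0.5
log-normalized for count data; ≥ 1 for TPM data). Clustering, covariate
regression and embedding are out of scope: cluster labels are inputs.
Clusters emptied by filtering are omitted from the cross-tab with a
warning, not reported as 0/0.

## Reprogramming signature (PC1)

PCA of the sample × gene matrix after an optional log2(x+1) transform.
Genes are mean-centered; unit scaling is off by default (centering-only is
the common RNA-seq convention) and drops zero-variance genes with a warning
when enabled. "Top genes contributing to PC1" means largest absolute
loading. PCA sign being arbitrary, orientation is fixed by requiring the
largest-|loading| gene to be positive; tests assert this documented rule
rather than a particular global sign. The top-N set is partitioned by
loading sign into up/down sets; exact-zero loadings join neither and warn.
Variance fractions are eigenvalue shares and sum to 1 across all
components. At least 3 samples are required; `n_top` may not exceed the
gene count.

## Peak-to-TSS binding annotation

Coordinates are BED-standard 0-based half-open; 1-based TSS tables are
converted at read time behind an explicit flag. The binding rule: a gene is
bound iff some set of peaks from ≥ k distinct cell types (default k = 2 of
n = 3) has a non-empty common intersection, every peak in that set is
motif-positive (when the motif requirement is on), and the intersection
lies within the window (default 50 kb) of the TSS. Distance from a TSS at
position p to an intersection [a, b) is a − p upstream, p − b downstream,
0 inside; the gene qualifies when distance ≤ window. Any nonzero overlap
counts — no reciprocal-overlap fraction is required. Each qualifying peak
set is evaluated on its own, so a motif-negative peak overlapping an
otherwise qualifying pair does not veto the call; the coverage-based
`overlap_groups` view (maximal intervals covered by ≥ 2 cell types, with an
all-members-motif flag) is provided for reporting. The rule is monotone:
growing the window can only add bound genes, raising k can only remove
them. Motif evidence is an input flag per peak — motif discovery was an
external, partly manual step in the workflows this tool serves and is not
replicated; an IUPAC degenerate-consensus matcher is provided as optional
plumbing for users with peak sequences, and BED files without a motif
column default to motif-positive with a warning.

## Closed-form scores

H-score is linear and bounded in [0, 300]; inputs are validated to sum to
≤ 100%. Wound area treats caliper length/width as ellipse axes. Percent
closure is relative to the day-0 area and deliberately unclipped: an
expanding wound reports a negative closure with a warning. ΔΔCt averages
replicate Ct values first (triplicates typically); the fold change of
sample-vs-control and control-vs-sample multiply to exactly 1.

## Synthetic data: what it emulates, and what it does not

All generators draw from a single integer seed (`numpy.random.default_rng`)
and are byte-deterministic; every emitted file round-trips through the
corresponding reader.

* **Junction counts** emulate per-sample junction files: the N-terminal
  read pool is Poisson(depth) split multinomially between the TA and ΔN
  junctions, and independently the C-terminal pool over the six C-terminal
  junctions, with probabilities proportional to planted isoform proportions
  times per-junction efficiencies (default 1). The default proportions are
  a skin-like mix — 13.3/86.7 TA/ΔN and an α/β-dominant C-terminal split
  (75.2/20.2/3.0/1.0/0.8, normalized to sum to 1). Not emulated: overdispersion
  across samples, junction-length bias, multimapped reads.
* **Cell matrices** emulate plate-based scRNA-seq counts: negative-binomial
  baseline genes (default 2,000 genes, mean 100, dispersion θ = 0.5 — deep
  Smart-Seq2-like totals of ~200k per cell), ~20 ERCC-like spike-in
  features targeting 5% of reads, and two marker genes whose counts are
  driven by a per-cell joint status drawn from per-cluster probabilities.
  Positive markers get counts far above the 0.5 log-normalized threshold
  and negative markers get zero, so planted and thresholded status coincide
  and recovery error reflects only multinomial sampling of statuses. QC
  violators are constructed, not sampled: each breaks exactly one rule,
  and three boundary decoys sit exactly at 900 genes / 75,000 counts /
  12.0% spike-in and must survive filtering. Not emulated: gene–gene
  correlation, batch effects, ambient contamination, dropout structure
  beyond the NB.
* **Reprogramming matrices** are baseline + factor × loadings + Gaussian
  noise with the planted factor confined to a signature gene subset. The
  variance split is exact in-sample: factor scores are standardized to unit
  sample variance, the noise is centered, orthogonalized against the factor
  and rescaled to an exact total, and loadings are scaled so the factor
  owns exactly the requested share. With a handful of samples an
  expectation-level split wanders by several points per draw and the first
  eigenvalue absorbs ~(1−f)/(n−1) of the noise, which would confound
  generator variance with estimator error; the exact split makes recovery
  error attributable to the estimator alone. A uniform shift (not clipping)
  keeps values non-negative without touching the covariance. Not emulated:
  multiple factors, count noise, condition structure beyond the single axis.
* **Peaks/TSS** place genes far enough apart (2·window + 20·peak lengths)
  that no gene's peaks can reach another's window, plant motif-positive
  overlapping peaks in ≥ 2 cell types for bound genes, and probe each
  boundary rule with decoys: single-cell-type peaks, motif-negative
  overlaps, and overlaps whose distance from the TSS is exactly
  window + 1 bp. Remaining capacity (default 500 peaks per cell type) is
  filled with random background peaks in a region no TSS window reaches, so
  the planted bound set is exactly recoverable. Not emulated: realistic
  peak width/score distributions, chromosome structure.

Because marker thresholds, QC margins and peak placement are
deterministic-by-construction, passing recovery tests demonstrates that the
estimators implement their formulas and boundary conventions exactly; it
does not demonstrate robustness to the biological and technical noise of
real datasets, which enter only through the documented sampling layers.

## Problem sizes and numerics

The test suite and the acceptance script run each stage at its design size:
100 junction samples at depth 2,000; 1,000 cells (10% planted QC failures);
500 cells per cluster for co-expression recovery; twenty 9 × 2,000
one-factor matrices; 200 genes × 3 cell types × 500 peaks. Percentage
normalization identities are asserted to 1e−9; ratio formulas agree with
brute-force re-derivations to 1e−12; PCA uses the full (LAPACK) SVD solver
for determinism. Degenerate inputs (zero depth, empty clusters, zero
loadings, constant genes, zero initial wound area) return flagged/undefined
results or raise typed errors rather than NaNs.
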