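# Methods

`gcdecay` implements an analysis cascade for time-resolved, multimodal
profiling of mRNA regulation after depletion of a post-transcriptional
regulator: paired RNA-seq/Ribo-seq differential analysis with a
translation-efficiency (TE) interaction test, coding-sequence GC-content
(GCcds) feature engineering and importance modelling, SLAM-seq T>C
differential stability, and a 5'-end coverage-decay statistic.  A
first-class synthetic-data generator plants the regulatory structure the
downstream statistics are designed to detect, so every stage can be
validated quantitatively without sequencing data.

## Negative-binomial differential analysis

Counts for gene *g* in sample *j* are modelled NB2: `E[y] = mu`,
`Var[y] = mu + alpha * mu^2`, with a log link and median-of-ratios size
factors entering as offsets.  The TE test fits

    log mu = b0 + b1*condition + b2*assay + b3*condition:assay

and compares it by likelihood-ratio test (chi-square, 1 df) against the
reduced model without the interaction — i.e. against the hypothesis that
ribosome footprints and mRNA respond identically to the condition.  Genes
with Benjamini–Hochberg adjusted LRT p below the FDR cutoff (default
0.05) are classed `TE_down`/`TE_up` by the sign of `b3`.  Per-assay
condition tests (same machinery on each assay alone) drive the
coordinate-group taxonomy: `x` (RNA-dominant), `y` (Ribo-dominant), `xy`
(concordant), `-xy` (anti-correlated), with both-axes significance and
sign agreement as the membership rule; the exact rule is this package's
convention since only a graphical definition exists for the groups.

**Dispersion.** Per gene, a method-of-moments start is refined by
maximizing the Cox–Reid adjusted profile likelihood
(`llf - 0.5*log det(X'WX)`), which removes the downward bias of the
plain MLE when the mean model consumes a large share of the degrees of
freedom.  Gene-wise estimates are then moderated: a trend
`alpha(mu) = a0 + a1/mu` is fit by least squares, the prior width is the
residual spread around the trend after subtracting the sampling share
(`trigamma(df/2)`, floored at sd 0.25), and each gene is re-estimated at
the posterior mode under a log-normal prior centred on its trend value.
The MAP refit — rather than a linear blend of point estimates — is what
keeps genes with flat dispersion likelihoods (bound-hitting point
estimates) from being assigned near-zero dispersions and spuriously
small p-values.

**Fitting.** IRLS with a likelihood-based convergence criterion; a
coefficient may legitimately run to -inf under complete separation
(e.g. an all-zero covariate cell in SLAM designs) while the likelihood
is already stationary.  Non-converged fits fall back to Nelder–Mead.

**Small-sample behaviour.** At two replicates per cell (eight samples,
four parameters) the chi-square reference for the LRT is mildly liberal
— the familiar small-sample behaviour of count-GLM LRTs.  Calibration
studies in the test suite therefore run at four replicates per cell,
where the type-I rate sits at the nominal 0.05 and p-values pass a KS
uniformity test; recovery studies keep the default two-replicate design
and allow a Monte-Carlo margin on the observed false-discovery
proportion.

## Sequence features

One row per gene: log2 TPM, baseline TE (log2 Ribo/RNA control-count
ratio), a mature-RNA proxy (length-normalized exon:intron read ratio),
and per-region GC, log2 length and read densities for the 5'UTR, ±25 nt
windows around the start and stop codons, the CDS, non-coding internal
exons, introns and the 3'UTR; 61 sense-codon frequencies; GC at codon
positions 1/2/3; optionally an external codon-optimality score.  N bases
are excluded from GC denominators.  Absent regions get defined sentinels
(density 0, log-length 0) rather than NAs.  GC of the CDS region *is*
GCcds, so the table carries it once — duplicating it under a second name
would split importance credit arbitrarily.  All expression-derived
columns use control samples only, so predictors cannot contain the
response.  GC partitioning (`partition_by_gc`) cuts the GCcds *range*
into equal-width groups by default (quantile cutting available) and
reports pairwise Wilcoxon rank-sum tests.

## Importance modelling

Random Forest regression (500 trees by default, one third of features
per split) under 5-fold cross-validation.  Importance is the mean
decrease in accuracy realized as held-out permutation importance: the
drop in held-out R^2 when one column is shuffled, averaged over shuffles
and folds.  All permuted copies are stacked into a single predict call,
which is ~30x faster than per-column prediction on one CPU and computes
the identical quantity.  The Lasso runs on predictors standardized with
training-fold statistics only; the penalty follows the one-standard-error
rule (sparsest model within one inner-CV standard error of the optimum),
the usual convention when the Lasso is used for feature selection — the
CV-minimum penalty retains many numerically tiny coefficients.
Performance is always the held-out predicted-vs-observed correlation
(Pearson and Spearman).  Per-class models are fit independently.

Because codon frequencies form a linear basis for GC content and the
start/stop windows contain CDS sequence, those features legitimately
share a planted GCcds signal; "decoy" checks in the validation suite
therefore measure sparsity over the anatomy/expression features with no
constructed GC linkage.

## SLAM-seq stability

A read is "converted" when it carries >= 1 T>C mismatch on the
transcribed strand (genomic A>G for minus-strand genes); the threshold,
MAPQ >= 10 and base quality >= 20 defaults, and an optional SNP-position
blacklist are exposed.  Differential stability fits, per gene, an NB GLM
on converted-read counts with `labeling + degron` covariates and
`log(total reads)` as offset, restricted to the chase endpoint where the
2x2 labeling-by-degron design lives, and LRT-drops the degron term
(p cutoff 0.05).  A positive degron coefficient means more label
retained under depletion — stabilization.

## 5'-end coverage decay

Coverage vectors live in transcript coordinates (bedGraph I/O converts
from 0-based half-open; positions are reported 1-based).  Per
transcript, profiles are min/max normalized (an option divides by the
maximum only), which controls for expression-level changes; the coverage
start is the first position exceeding threshold 0.15.  A pooled start
(all samples summed) centres a 250 nt window (±125 nt; a 300 nt variant
is accepted where that convention is preferred) in which mean normalized
coverage is compared treated-vs-control as log2FC, with a pseudo-value
guard (the smallest positive normalized value on that transcript) when a
window mean is zero.  Time courses are summarized per transcript by OLS
slopes over the ordinal timepoint index — with intercept for the
start-position difference series, through the origin for the log2FC
series whose first value is 0; two-condition designs skip the regression
and report differences.  Classes (top-250 stabilized and degraded by
RNA-seq p-value with stable tie-breaking, 1,500 controls sampled at
p > 0.2 and TPM > 3, all scaled down proportionally on smaller gene
sets) are compared by one-sided Wilcoxon rank-sum tests; the identical
machinery applied to reversed profiles is the 3'-end negative control.

## Synthetic data

The generator emulates a five-timepoint (4, 8, 16, 24, 48 h),
two-condition degron design with two replicates, 4,000 genes by default
(scaled down in tests and the acceptance script; problem sizes are
recorded alongside each reported quantity).  Planted structure:

* **Classes.** 15% `TE_down`, 10% `TE_up`.  Response shapes are
  saturating exponentials: translation responds immediately
  (`1 - 2^(-t/4h)`), RNA responds only after a hard onset delay
  (`lag_hours`, default 12 h) — an explicit simplification standing in
  for buffering kinetics.
* **GC coupling.** The late RNA-stabilization amplitude of `TE_down`
  genes is `rna_base_amp + gc_effect_size * (GCcds - gc_min)`, anchored
  at the bottom of the GC range (0.35–0.75) so it stays positive and
  monotone.  The default `gc_effect_size` of 10 log2FC per unit GCcds
  (1 per 0.1) is a deliberately strong planted signal for recoverability
  studies, not an empirical estimate; no published effect magnitudes
  exist to calibrate against, and panel studies sweep it from 0.
* **Counts.** NB with shared dispersion 0.05 and per-sample depth
  factors in [0.7, 1.3].  Gene-level control reads are apportioned to
  regions by length (introns damped 10x) to supply density features.
* **Half-lives.** Log-normal around 8 h, negatively coupled to GCcds;
  treatment doubles half-lives of stabilized genes and halves degraded
  ones.
* **Coverage.** Plateau with a 50 nt 5' ramp; the onset recedes
  `decay_erosion_rate` (10 nt) per unit decay exposure, where treated
  exposure scales with the decay-rate ratio, so stabilized genes recede
  less; the 3' ramp is fixed across conditions.  Poisson noise per
  nucleotide.
* **SLAM.** Labeled conversion fractions decay as
  `bg + (init - bg) * 2^(-chase/half_life)` (init 0.5 after saturation
  labeling, background 0.01).  Conversion counts are beta-binomial with
  ICC 0.01 on labeled samples — emulating labeling/alkylation
  efficiency variability between libraries.  A purely binomial draw
  conditional on the total is *under*dispersed relative to any count
  model with a total-reads offset and would make the stability test's
  null unfixably conservative; unlabeled backgrounds stay binomial
  (platform-stable, effectively Poisson at 1%).

What the generator does **not** emulate: GC-dependent library
preparation bias, positional coverage biases beyond the single
ramp/plateau shape, isoform mixtures, multi-mapping, batch structure, or
kinetic (ODE-level) coupling between translation and decay.  Passing
tests therefore demonstrate that the statistics recover the structure
they target under their own model assumptions plus realistic noise —
not that real libraries are free of the confounders listed above.

## Numerical conventions

Dispersion bounds [1e-8, 20]; linear predictors clipped at ±30 on the
log scale; LRT statistics floored at zero; BH adjustment is NaN-tolerant
(missing p-values stay missing).  Isoform selection breaks ties by total
pooled coverage, then transcript length, then lexicographic id.  Gene
ranking for coverage classes sorts by (p-value, |log2FC| descending)
with a stable sort.  All randomness flows from explicit seeds; per-stage
generator streams are derived from the study seed so stages are
reproducible independently.

## Known limitations

The TE LRT is mildly liberal at two replicates (see above).  The
interaction model treats RNA and Ribo counts of the same gene as
independent observations, as the standard tools do.  The SLAM model uses
raw converted-read fractions, not mixture estimation of new/old RNA.
The coverage statistic assumes one dominant isoform per gene and a
monotone 5' boundary; transcripts with flat or degenerate profiles are
excluded and reported rather than imputed.
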