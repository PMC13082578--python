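# Methods

## The problem

Most multi-promoter genes can initiate transcription from more than one
promoter, and which promoter is used can change between tissues, conditions
or disease states even when total gene expression does not.  `promact`
quantifies promoter-level activity from standard bulk RNA-seq derivatives,
classifies promoters, tests differential activity and usage between two
conditions, and benchmarks any RNA-seq-derived quantification against
CAGE-style 5′-tag counts, which measure initiation directly.

## Promoter model

A promoter is a group of transcript first exons of one gene merged by
single-linkage overlap (≥ 1 shared base, same strand; a chain of pairwise
overlaps merges transitively).  The promoter's TSS is the 5′-most transcript
start of the group (minimum start on "+", maximum end on "−"), and promoters
of a gene are ranked 1..k from 5′ to 3′ in transcription direction.
Coordinates are 1-based inclusive throughout, matching GTF; conversion to
0-based half-open happens only at BED output and interval-tree boundaries.

Two classes of promoters are flagged and excluded from quantification while
staying in the map for audit:

* **internal** — the TSS lies inside a non-first exon of any transcript not
  belonging to the promoter.  Reads from elongation through that exon would
  be misread as initiation.  First exons of other transcripts never trigger
  the flag.
* **overlapping** — the first-exon footprint shares ≥ 1 base with a
  promoter of a *different* gene on the same strand; both partners are
  flagged.  This is a documented interpretation: overlap within a gene is by
  construction impossible after merging, and antisense overlap is kept
  because stranded counting can separate it.

The counting window for CAGE is `[tss − up, tss + down]` in transcription
orientation (so `window_up` is always genomically upstream on "+", downstream
coordinate-wise on "−"), clipped at position 1.  The default 500/500 bp is a
configurable convention, not a derived value.

## Quantification strategies

All three methods share the promoter universe of the map and differ only in
what they can see:

* **junction** — sum of uniquely mapped splice-junction reads whose intron
  coordinates exactly match one of the promoter's first introns (no fuzz
  window; exact matching keeps counts auditable).  Strand code 0 (undefined)
  matches either strand.  Intronless promoters are *not quantifiable* —
  reported as missing, never as zero.  A first intron shared by two
  promoters counts toward each and the pair is logged.  Library size = total
  unique junction reads.
* **transcript** — sum of per-transcript estimated read counts over member
  transcripts; ids missing from a quantification table count as zero with a
  warning.  The promoter length used for RPKM is the unweighted mean of
  member transcripts' exonic lengths.  Library size = total reads in the
  table.
* **first-exon** — member first exons are cut into disjoint bins at every
  member boundary; bins overlapping a bin of any other promoter (same
  strand) are removed from both sides as ambiguous.  A read counts once per
  promoter when any aligned segment overlaps any bin by ≥ 1 bp ("."-strand
  reads match either strand).  Library size = distinct read ids.
* **cage** — tag counts summed inside the promoter window, strand-matched by
  default (CAGE is stranded; unstranded counting would conflate
  bidirectional promoters); an `--unstranded` escape hatch exists.

Size factors are DESeq2-style median-of-ratios over promoters with
all-positive counts, rescaled to geometric mean 1.  Activity is
`log2(count / factor + 1)` (pseudocount configurable).  RPKM is
`count × 1e9 / (length × library_size)` and is refused for methods without a
length (junction, cage).

## Classification

Mean activity is taken on the log scale over the selected samples.  A
promoter with mean activity below 0.25 (the conventional threshold; the
sensitivity sweep 0.1–0.5 is exposed) is inactive; among a gene's active
promoters the highest mean is the major promoter, ties broken toward the
5′-most; the rest are minor/alternative.  Not-quantifiable promoters are
excluded from the gene maximum and totals and reported as their own
category, so "no signal" is never conflated with "cannot measure".

## Differential activity: NB Wald test

Raw counts (transcript-method fractions rounded to integers with a warning)
are modelled per promoter as negative binomial with a log link:

1. median-of-ratios size factors enter as offsets;
2. per-promoter dispersion α is estimated by a pooled method of moments on
   normalised counts, `α = (s² − μ) / μ²` with the within-group variances
   pooled across the two conditions;
3. **dispersion moderation.** With 2–3 replicates per group the raw estimate
   is so noisy that plugging it into a Wald test inflates type-I error to
   ~0.12 at nominal 0.05.  Log dispersions are therefore shrunk toward the
   central value (the mean of the raw estimates, which is nearly unbiased)
   with a normal–normal posterior weight.  The sampling spread of the
   estimator is measured by a one-round parametric bootstrap at the central
   dispersion and the observed per-promoter means (fixed internal seed, so
   results stay deterministic); the prior variance is the observed robust
   spread minus 1.15× the bootstrap spread, floored at 0.02.  When the
   observed spread is pure sampling noise the estimates collapse toward the
   common dispersion; genuine heterogeneity survives.  Simulation (in the
   test suite) shows type-I error 0.046–0.070 across seeds with uniform
   null p-values, while power for |log2FC| = 2 at 3 vs 3 stays ≈ 1;
4. the GLM (intercept + condition, plus batch dummies when present) is
   fitted by iteratively reweighted least squares, vectorised across all
   promoters (Fisher scoring with weights `μ/(1+αμ)`, ridge 1e-10, 50
   iterations max);
5. the Wald statistic is coefficient/SE for the condition coefficient with
   a two-sided standard-normal p-value; Benjamini–Hochberg correction runs
   over testable promoters only (all-zero and not-quantifiable promoters
   are excluded from the denominator).

Fold-change shrinkage is the normal-prior posterior mean
`lfc · τ²/(τ² + se²)`; when the prior sd is not supplied, τ² is the variance
of observed log2FCs minus the mean squared SE, floored at 1e-6.  P-values
are never altered by shrinkage.

Known limitations: no dispersion–mean trend fitting, no Cox–Reid
adjustment, no outlier refitting, and under strongly heterogeneous
dispersions at n = 3 the moderated test remains somewhat anticonservative —
the calibration guarantee is for the homogeneous-dispersion regime the
simulations cover.

## Usage and the alternative-promoter call

Promoter usage is the within-sample ratio of the promoter's raw count to the
summed raw counts of the gene's quantifiable promoters (within a sample the
ratio cancels depth, so normalisation is deliberately not applied); it is
missing when the gene total is zero.  The usage shift is the difference of
condition means (test − reference), and the effect-size filter keeps
|shift| > 0.1 by default.  An alternative-promoter event is called when all
three hold: activity change significant at FDR < 0.05, usage shift passes,
and the gene-level |log2FC| (computed on gene-summed counts with the same
test) stays within a cap (default 1.0) — large whole-gene changes would
otherwise masquerade as compositional shifts.  The cap's value is a package
choice exposed in the configuration.

## Benchmarking metrics

All comparisons fix the bias orientation as **method − reference**; negative
bias means the method underestimates.  The suite: Pearson and Spearman
(average ranks on ties) correlations, Lin's concordance correlation
coefficient with population (1/n) moments
`ccc = 2·cov / (var_x + var_y + (mean_x − mean_y)²)`, mean bias,
Bland–Altman bias (same as mean bias) and Bland–Altman trend, defined here
as the OLS slope of the paired differences on the pair means.  Values are
optionally log10(x + 1)-transformed first.  Exactly identical inputs
short-circuit to exact 1/0 values.  Degenerate inputs (n < 3 or zero
variance) give missing metrics with a warning rather than an exception.

Classification agreement for a category is precision = overlap/method-set
and recall = overlap/reference-set over identical promoter universes.

Bootstrap CIs resample promoter pairs with replacement (B = 1000 default,
seeded), report 2.5/97.5 percentiles per metric, skip and count
zero-variance resamples, and refuse data where more than half the resamples
degenerate.  Expression stratification keeps promoters with positive
reference signal, cuts them into six equal-frequency quantile bins (ties to
the lower bin) and recomputes the suite per bin.

## Synthetic data generator

The generator emulates every input modality with known truth: a GTF with
1–3 promoters per gene (disjoint first exons; multi-exon transcripts of a
gene splice into one shared downstream exon so each transcript contributes
a distinct first intron), a configurable intronless fraction (default 0.2,
matching the sizeable intronless share of real annotations), optional
injected internal/overlapping genes to exercise the flags, STAR-style
junction tables, Salmon-style quantification tables, read-interval BEDs and
CAGE tag tables for 3 + 3 samples.

Expected promoter counts are `depth × gene weight × usage` with lognormal
gene weights; the default depth of 2e6 assigned reads per sample is a
desk-scale stand-in for a ~20M-read library, keeping typical promoters in
the hundreds of counts.  Differential promoters scale by `2^log2FC`
(default 2) in the test condition; switch genes move Δ = 0.4 usage from the
major to a minor promoter with the gene total untouched.  The truth table
stores *realised* within-gene proportions, so they always sum to one.

Noise is hierarchical: the gene total is negative binomial (α = 0.05,
biological replicate variability acting on the gene) and promoter counts
split the total multinomially by true usage.  This matters: independent
per-promoter NB noise would put a depth-independent floor of roughly
`u(1−u)·√(2α)` on usage-shift errors, and usage recovery would never reach
the ±0.05 regime the recovery checks operate in.  Promoter counts remain
marginally overdispersed.  One count per promoter and sample feeds the
junction, transcript and read channels consistently; CAGE gets an
independent NB draw around the RNA mean times a promoter-level lognormal
platform factor (sd 0.3), which sets the true RNA–CAGE concordance the
benchmark measures.  Reads are single-segment and live only in the
first-exon channel; junction evidence lives only in the junction channel.

What the generator does **not** emulate: sequence content and mapping
error, positional/GC bias, multimapping ambiguity, split-read placement,
unannotated TSSs, and dispersion–mean trends.  Passing recovery tests
therefore demonstrates correctness of the counting and inference machinery
under the stated model, not performance on real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the calibration at 2,000
promoters (3 vs 3, μ = 100, α = 0.05), recovery at 1,000 promoters with 50
affected, usage recovery at 100–300 genes, and the end-to-end pipeline at
300–500 genes — sizes chosen so every property is measurable with
comfortable margins on a single CPU.  IRLS converges at tolerance 1e-8 with
η clipped to ±30; singular weighted designs are ridged at 1e-10.  All
generators are `numpy` `default_rng` seeded from a single configuration
seed; rerunning any stage with the same inputs and seed is byte-identical
(run manifests record a wall-clock timestamp and are excluded from that
guarantee).
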