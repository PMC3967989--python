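# Methods

## Scoring model

The pipeline consumes an already-summarized log2 probeset-by-sample matrix
(the output of RMA or any comparable summarization; background correction
and normalization across arrays are out of scope) plus a probeset → exon →
gene annotation with transcript order. Three transformations follow:

1. **Normal-cohort centering.** Each probeset value in each tumor has the
   arithmetic mean of the normal samples for that probeset subtracted.
   Both the centering and the normal mean operate on the log2 scale, so the
   result is a log2 fold change relative to the typical normal signal. The
   alternative — averaging on the linear scale before taking logs — is
   deliberately not used: the screening plots and the score are defined on
   the log2 scale throughout, and the subtraction form keeps a
   tumor-equals-normal probeset at exactly zero. The choice is isolated in
   `normalize_to_normal_mean`, so changing it is a one-line edit.
2. **Exon aggregation.** Exon values are unweighted arithmetic means of
   their probesets' centered values, regardless of probeset count.
3. **Max-min spread.** Per gene and tumor, the score is the difference
   between the largest and smallest exon value. It is non-negative, zero
   for single-exon genes, invariant to adding a constant to all exons of a
   gene in a tumor (whole-gene differential expression, array scaling
   effects), and scales linearly with the size of an exon-confined shift.

Genes are ranked by the plain mean of per-tumor scores over **all** tumors
(no trimming or QC subset). Ties are broken by ascending gene id so output
is byte-reproducible. Genes with fewer than 3 probesets (default,
configurable) are excluded before scoring — with one or two probesets there
is no within-gene contrast to measure. Genes whose exons all drop out of
the matrix are excluded with a logged reason rather than scored zero, so
they cannot silently dilute a rank list.

## Annotation contract

Coordinates are 0-based half-open (BED convention). Each probeset belongs
to exactly one exon and each exon to exactly one gene; an exon annotated to
two genes is rejected at load rather than resolved, because the array
design premise is non-overlapping probeset targets. The ≥3 filter counts
probesets over the whole gene, not per exon, so a single-exon gene with
three probesets survives (and will always score 0). Exon order inside a
gene model is transcriptional: ascending genomic start on the `+` strand,
descending on the `-` strand.

## Screening plots

For each candidate the cohort plot shows, per probeset in 5′→3′ order: the
difference of tumor and normal means (the tracing), a horizontal reference
at the grand mean of the raw log2 signal over the gene floored to an
integer (cosmetic only — it is computed but never enters the score), and a
signed histogram counting tumors strictly above the normal mean + 1 SD and
strictly below the normal mean − 1 SD. The SD is the normal cohort's
per-probeset sample standard deviation (n−1 denominator), so at least two
normal samples are required. Strict inequality at the thresholds is a
deliberate tie-break; values exactly at a threshold are not counted. Counts
are computed on raw signals against shifted thresholds, which is
arithmetically identical to counting centered values against ±1 SD. Under
pure Gaussian noise the expected per-probeset fraction of tumors beyond the
band is close to 2Φ(−1) ≈ 0.317 (slightly above, because the normal mean
and SD are themselves estimated from 25 samples); the test suite checks
this calibration. Per-tumor plots show one tumor's centered probeset values
with the same exon track. PNG and PDF rendering strips timestamp metadata
so re-rendering identical data is byte-identical.

## qPCR validation stage

Standard curves are ordinary least squares of Ct on log10(input copies)
over a serial ten-fold dilution series (≥3 points); amplification
efficiency is `10^(−1/slope) − 1`, so perfect doubling gives slope
−1/log10 2 ≈ −3.3219 and efficiency 1.0. A non-negative slope marks the
curve invalid rather than raising, so a failed assay can still be
inspected; inversion (Ct → copies) refuses invalid curves.

The splicing index is short/(short + long) on absolute copy numbers, a
proportion in [0, 1]; short and long indices of the same sample sum to 1.
When both channels are zero the index is undefined and the sample is
excluded with a logged count. The per-sample reference-gene (18S) factor
multiplies both channels and therefore cancels in the index; the pipeline
computes the index on raw copies and carries the reference column only for
reporting absolute levels. Cohorts are compared with the unequal-variance
two-sample t test using real-valued Welch–Satterthwaite degrees of freedom
and a two-sided p value; each group must retain at least two defined
indices. With only one isoform-specific short assay and one pooled "common"
long assay per gene, the data model carries exactly two copy-number
channels per gene, which covers pooled-isoform designs as well.

## Synthetic cohorts

The generator emulates the study design the scoring assumes: a discovery
cohort of 44 tumors and 25 normals (defaults) of log2 probeset intensities.
Each probeset draws a baseline affinity from N(6.0, 1.0²) log2 units;
every measurement adds independent Gaussian noise (default SD 0.25 log2
units, a typical post-summarization exon-array residual). Two disjoint gene
sets are spiked:

* **splice genes** (default 50 of 1000): a shift of `splice_delta`
  (default 1.5 log2 units) applied to all probesets of a contiguous exon
  block anchored at the 5′ or 3′ end of the transcript — the shape of an
  alternative first/last-exon switch — in a Bernoulli-sampled subset of
  tumors (default rate 0.5, at least one tumor);
* **differential-expression confounders** (default 50): the same magnitude
  applied to *every* probeset of the gene in *all* tumors. These genes are
  real expression changes but contain no splicing signal, and the score
  should ignore them.

Baseline affinities are snapped to a dyadic grid of 2⁻¹⁶ log2 units
(≈1.5 × 10⁻⁵, four orders of magnitude below the noise SD, statistically
invisible). The payoff is numerical: with `noise_sd = 0` every normal-mean,
centering and exon-averaging operation is exact in IEEE double arithmetic,
so a spiked gene scores *bit-exactly* its delta in affected tumors and all
unspiked genes score bit-exactly zero — the effect-propagation tests assert
equality, not tolerance.

The qPCR generator mirrors the validation design (47 tumors / 19 normals):
per sample, total gene copies are log-normal (median 10⁵), the short-isoform
fraction is the group proportion (defaults 0.8 tumor vs 0.3 normal,
matching a strong validated switch) jittered on the logit scale (SD 0.5),
and the 18S reference is an independent log-normal scalar. Each assay also
gets a six-point ten-fold dilution series from a configured true curve
(slope −3.3219, intercept 40 Ct) with 0.05 Ct jitter.

All streams derive from a single seed through `numpy.random.SeedSequence`
spawning (annotation = child 0, expression = child 1, qPCR = child 2), so
any stage regenerates independently and every output is byte-reproducible
under a fixed seed.

**What the generator does not emulate:** probe-sequence affinity structure,
cross-hybridization, background signal, non-linear dynamic range, correlated
noise between probesets of an exon, partial isoform mixtures (spikes are
clean additive blocks), or annotation error. Passing recovery tests
therefore demonstrate the score's algebraic selectivity — exon-confined
signal in, whole-gene signal out — under a favorable error model, not
performance on real arrays, where splicing signals are smaller and noise
heavier-tailed.

## Recovery metrics

`recovery_metrics` reports recall@k (fraction of spiked splice genes in the
top k ranks) and a rank-sum enrichment AUC — the probability that a spiked
gene outranks a non-spiked one, computed from the Mann-Whitney U statistic
on rank positions. The same AUC applied to the confounder set is the null
calibration: ≈0.5 means whole-gene expression changes do not leak into the
splicing ranking.

## Problem sizes and test design

The test suite runs the full discovery geometry (1,000 genes × 69 samples,
five seeds) for recovery, 20 random small instances (≤50 genes × ≤10
tumors) against an independent pure-Python triple-loop reference for
numerical equivalence (≤10⁻¹²), 20 seeds for the histogram null
calibration, and 1,000 replicates for the Welch p-value uniformity check
(Kolmogorov–Smirnov statistic < 0.1). The end-to-end CLI determinism check
uses a 40-gene cohort and three plots, which exercises every command while
keeping the suite fast. These sizes were chosen as the smallest that make
the statistical assertions stable across seeds.

## Known limitations

* The score has no significance calibration: it ranks, it does not test.
  Selection among top-ranked genes is a downstream (here: visual) judgment.
* A gene with one aberrant probeset in one exon can score as high as a
  clean isoform switch; the screening plots exist precisely to separate
  those cases, and that separation is manual.
* Probesets spanning two annotated exons are not representable; the
  annotation contract requires unique exon assignment.
* Real per-sample qPCR cohorts of published studies are not reproducible
  here; the validation stage is exercised on simulated cohorts with known
  proportions.
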