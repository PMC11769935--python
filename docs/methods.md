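# Methods

## Fragment counting and depth capping

Fragment length is `|TLEN|` of the first-in-pair record of each properly
paired alignment. The filter is samtools `-f 66 -q 30` semantics — all bits
of the required mask (paired + proper pair) must be set, combined with the
first-in-pair bit so each template is counted once — restricted to the
inclusive 1-bp grid [74, 439] (366 sizes). Records without a template length
are skipped and counted in the log.

Depth capping (default 2× mean coverage, canine genome size 2.4 Gb) is
implemented as per-size binomial thinning of the histogram with retention
`cap / observed`, not as BAM-level subsampling: for every per-sample
statistic computed downstream (densities, peaks, proportions) the two are
distributionally identical, and the histogram-level operation removes any
alignment-file dependency from tests. When the observed depth is not
supplied it is estimated as `pairs × read length × 2 / genome size`.

## Distributions and cohort summaries

Densities are counts divided by the per-sample total, so each sample's
aggregate density is exactly 1. All statistics are computed at native 1-bp
resolution; the 5-bp binning is a display/feature view only, because the
oscillation sub-peaks live at 1-bp positions and binning first would destroy
them. The binned view has 73 half-open bins starting at 74, 79, …, 434; the
final bin absorbs the grid's trailing size so mass is conserved exactly.
Cohort curves are per-size arithmetic means with (n−1)-denominator standard
deviations; a single-sample cohort gets sd 0 with a warning.

## Oscillation detection

The principal peak is the global argmax on the grid, ties broken toward the
smaller size. Sub-peaks are local maxima of a 3-bp centered moving average
(applied only for localization) in [74, main peak), with prominence
≥ 1e-4 density units; maxima closer than half the expected 10.4-bp period
are merged, keeping the higher. Each cycle's valley is the minimum of the
raw curve strictly between its peak and the next peak (the main peak for the
last cycle), and all reported densities come from the unsmoothed curve. The
prominence default sits below the smallest published peak-valley gap
(5e-4). The per-cycle statistic is `diff = peak − valley`; cross-group
comparisons (group means over inclusive 1-based cycle ranges, the per-cycle
|diff gap| ranking with ties toward the smaller index, and tolerance-based
position matching) operate on either detected profiles or plain density
vectors, so the published per-cycle table can be analysed directly.
Whether the statistics are computed on the cohort mean distribution or
averaged over per-sample profiles was an open choice; the cohort mean is the
default (per-sample profiles remain available through the same functions).

## Synthetic fragment-size cohorts

Each group's profile is a normalized mixture evaluated on the grid:

* a **sharp main-peak Gaussian** fixing the mode (normal 165 bp, sd 2.5;
  tumor 160 bp, sd 1.6) — the crest of the mono-nucleosome peak;
* a **broad mono-nucleosome envelope** (normal N(188, 42); tumor N(166, 27))
  carrying the bulk of the mass; its left flank sets the valley floor under
  the oscillation ladder, tuned so valley levels track the published
  per-cycle valley densities;
* **eight sub-peak Gaussians** (sd 2 bp) at 81–154 bp whose amplitudes are
  the published per-cycle diff statistics scaled by 1.8 and floored at
  1.2e-3 — the measured diff of a bump riding a sloped envelope is smaller
  than its amplitude, and the smallest printed diffs would otherwise fall
  below detectability;
* a **di-nucleosome shoulder** (normal N(332, 35), mass 0.057; tumor
  N(325, 30), mass 0.006), whose group asymmetry produces the normal-dog
  excess of long fragments around 336–395 bp (6.7–8.6× between pure
  profiles);
* an **exponential short-fragment floor** (heavier and faster-decaying in
  tumors) and a small **uniform noise floor** (normal 0.002, tumor 0.004
  mass) that dominates beyond ~400 bp, where the group contrast abates.

Tumor samples are multinomial draws from `(1−f)·normal + f·tumor` with
per-sample tumor fraction `f ~ Beta(5, 2)` (median ≈ 0.74, reflecting the
strong observed group separation); normals use f = 0. Per-sample biological
variability is a 5% multiplicative lognormal jitter on every component
weight. Defaults are the study scale: 36 normals, 21 tumors, 2×10⁶
fragments per sample (≈2× coverage at 150 bp paired-end reads).

What the generator emulates: the group modes and their 5-bp shift, the
eight-cycle ladder with uniformly larger per-cycle diffs and a ~2× tumor
peak-density ratio at cycles 5–8, the sub-174-bp tumor excess, and the
normal-dominated long-fragment band. What it does not emulate: breed or
pre-analytic variation, GC- or end-motif-dependent fragmentation, real
between-sample correlation structure, or the specific identity of the most
discriminative oscillation cycle. Passing tests therefore demonstrate the
pipeline's correctness and sensitivity under the stated generative
contrasts, not real-data performance; the published real-cohort AUCs and
chromosome lists require the original sequencing cohort and are out of
scope.

Note also that tumor-fraction mixing bounds cohort-level fold changes: with
mean fraction ≈ 0.71, a band where the pure tumor profile is 10× below
normal shows only a ~2.5–3.5× cohort-level ratio. The published 5–20× band
contrast is reproduced between pure profiles, not between mixed cohort
means.

## Feature selection

Features are per-sample densities: the full 366-position grid (default),
explicit position lists (e.g. detected peaks/valleys), or 73 5-bp bins.
Selection runs linear-SVM RFE (C = 1) on stratified 70% draws, standardizing
each column with train statistics first since margin-based ranking is
scale-sensitive. The elimination schedule drops 10% of remaining features
per step down to 20 survivors; survivor frequencies over 100 iterations are
thresholded at 0.5 and merged into maximal runs bridging gaps ≤ 2 bp. All
of k, step, cutoff, and gap tolerance are configurable.

A caveat discovered during validation: because successive 70% draws share
most samples, RFE on a *fixed* dataset is far more stable than a naive
permutation intuition suggests — even pure-noise features yield one or two
isolated positions above the 0.5 cutoff. The meaningful null signature is
the absence of *contiguous* stable regions; genuine signal produces
multi-position runs because neighboring densities are correlated.

## Classification bench

Seven algorithm families (AdaBoost, Bagging, Extra Trees, Gradient
Boosting, Random Forest, linear SVM with standardization, XGBoost) are
fitted per split with seeds derived from one master seed. Scores are
positive-class probabilities where available, otherwise the decision margin
through a logistic link (AUC needs a ranking; accuracy, sensitivity and
specificity need a cut, default 0.5). AUC is the rank statistic
P(score⁺ > score⁻) with ties worth one half. Repeated hold-out uses
stratified 70/30 splits (default 10 repeats, means ± sd over repeats);
k-fold CV uses stratified folds with out-of-fold scores pooled before
computing metrics, and k is reduced with a warning when it exceeds the
minority-class count (which also makes true leave-one-out unreachable under
stratification). No multiple-testing correction is applied across the
bench — means and sds only.

## Copy-number consensus

Counts are tallied per 500-kb half-open bin (trailing short bins kept). The
panel of normals stores the per-bin median of library-size-scaled counts and
the per-bin sd of the normals' log2 ratios, floored at its 5th percentile to
avoid infinite z-scores. Sample correction: scale to the panel total, log2
ratio against the panel median, subtract a LOESS fit of ratio on GC
(frac 0.3), z = ratio / panel dispersion. Bins with mappability < 0.9, zero
panel median, or zero counts are masked and can never be called.

The z-score caller (gain: z ≥ z_hi and ratio ≥ r_hi; loss: mirrored) is a
synthetic stand-in for the two external callers the consensus logic was
designed around — it is not a re-implementation of either. Its two presets
(z 5.5/ratio 0.25 and z 5.0/0.20) are deliberately strict so that a
spike-free cohort yields no calls while a clonal single-copy gain
(log2 ≈ 0.58 against ≈4% count noise) is detected essentially always.
Per-sample calls from the two presets are intersected per state (bedtools
semantics, 0-based half-open); recurrence is then tallied at bin resolution
— every call is bin-derived, so this is exact — keeping maximal runs present
in ≥ 7 samples (the "more than 6 of 21" rule, evaluated over the tumor
cohort and configurable). Gain and loss are counted independently, so a
chromosome may appear in both lists. Adapters read ichorCNA-style `.seg`
(1-based starts, call column mapped via gain/amp/hlamp vs hetd/homd) and
WisecondorX-style aberration BEDs, so the consensus + recurrence stage also
runs on genuine caller output.

The synthetic coverage cohort uses a 5-chromosome × 25-Mb toy genome
(50 bins per chromosome — desk-scale; real chromosome sizes can be loaded),
per-bin GC ~ Beta(42, 58), a unimodal GC bias peaking at GC 0.42, ~4% of
bins with low mappability, negative-binomial counts (mean 8000 per bin
≈ 2.4× coverage, dispersion 800), and spiked segments with a configurable
carrier count among the tumors (defaults: a 5-Mb gain in 8/21 and a 5-Mb
loss in 10/21).

## Pipeline and reproducibility

Every stage seed is derived from the master seed by hashing the stage name,
so enabling or disabling one stage never changes another's randomness, and
reports are byte-identical across reruns (JSON with sorted keys, rounded
floats). Stage outputs are plain TSV/BED with headers; filters log record
counts (fragments kept, bins masked) so the analysis is auditable.

## Numerical choices and degenerate inputs

Normalization requires a nonzero total and checks unit mass to 1e-9.
Argmax/argmin ties break toward the smaller index everywhere. Flat
distributions detect their mode at the grid start with a warning. Oscillation
detection returns an empty cycle list (valid) when no prominent maxima
exist. Profiles with all sub-peak weights zero are legal and yield zero
cycles. Mismatched cycle counts in cross-group comparison pair by index up
to the shorter profile with a warning. Fold-change screens flag zero
denominators as +inf rather than failing.

## Known limitations

The stand-in caller has no segmentation model (no HMM), no tumor-fraction
or ploidy estimation, and its thresholds are tuned for the synthetic noise
model, not for real shallow-WGS data — for real data, use the adapters to
feed genuine caller output into the consensus stage. Gene-level annotation
of recurrent intervals is out of scope. The classification numbers produced
on synthetic cohorts characterize the pipeline under the generator's
assumptions and should not be read as expected clinical performance.
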