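# Methods

This note documents the models and procedures implemented in `readgaze`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Screen geometry and angular units

Event kinematics are expressed in visual degrees. The default geometry is
a 22-inch 5:4 panel at 1280 × 1024 (pixel pitch ≈ 0.339 mm) viewed from
650 mm — a typical distance for remote desktop trackers; both are
configurable (`ScreenGeometry`). Conversion uses the full arctangent
expression θ = 2·atan(d/2D); it is linear to within 1% below ~5°, so the
choice of viewing distance rescales degree-valued features monotonically
without affecting any detection decision except through the dispersion
threshold.

Coordinates follow the screen convention: origin top-left, y grows
downward. "Upward on screen" (toward earlier text lines) is therefore
negative dy, and AOI rectangles are half-open on their max edges.

## Event detection

**Fixations** use the classical I-DT algorithm on the binocular mean
position: a maximal run of consecutive samples whose bounding-box
dispersion (x-range + y-range) stays within the threshold and whose time
span reaches the minimum duration becomes one fixation.

- *Minimum duration*: 80 ms.
- *Dispersion threshold*: 1.0° (converted to px through the geometry).
  The threshold value is a standard choice for dispersion-based detection
  at this tracker class and is exposed in the configuration.
- *Blink handling*: the tracker encodes blinks as samples at exactly
  (0, 0) px. Such samples never join a fixation and split any run they
  interrupt; sampling gaps longer than 2 nominal intervals do the same.

**Saccades** connect subsequent fixations; the interval spans from the
first fixation's offset to the second's onset. Displacement is measured
between fixation centroids; peak speed is the maximum sample-to-sample
angular speed within the interval (with a centroid-displacement fallback
for degenerate single-gap intervals). A saccade whose interval contains
any (0, 0) sample is flagged as a blink and excluded from all feature
pools.

**Regressions** are non-blink saccades satisfying dx ≤ −20 px OR
dy ≤ −20 px: at least 20 px against the reading direction on the same
line, or at least 20 px upward toward an earlier line. The 20 px floor
(about the width of the word "the" at this resolution) excludes corrective
microsaccades. The rule is deliberately literal: line-return sweeps (large
negative dx with downward dy) are **not** exempted, so the regression pool
contains both short re-reads (~2°) and full-width sweeps (~25°); this
mixture also explains why regression amplitude and peak-speed statistics
are much larger than their saccade counterparts.

## Feature extraction

Stage order: detect → pool-level outlier removal → AOI filter →
Coefficient K → session aggregation → baseline normalization.

- *Outlier rule*: per feature, over the whole event pool of the study, a
  value is removed when it lies more than 4 × IQR below the second
  quartile or above the third (quartiles by linear interpolation — the
  convention is recorded in the output manifest because the filter depends
  on it). The rule is deliberately lenient; a removal fraction above 20%
  is logged as a warning. An event is removed when any of its features is
  an outlier; fixation duration, fixation pupil size, saccade and
  regression amplitude/duration/peak speed, and K samples are filtered as
  separate pools.
- *AOI filter*: fixations must land in the title or content rectangle;
  saccades (hence regressions) require both bounding fixations retained.
- *Coefficient K*: for each fixation *i* followed by a retained non-blink
  saccade, K_i = (d_i − μ_d)/σ_d − (a_{i+1} − μ_a)/σ_a, where a_{i+1} is
  the amplitude of the saccade *following* fixation i and μ/σ are the
  participant's own statistics. The standardization pool is exactly the
  participant's set of (fixation, following-saccade) pairs after
  filtering; this makes the per-participant mean of K identically zero
  over its defining pool — the invariant the tests assert. A participant
  with zero-variance pools is excluded from K features with a warning.
- *Moments*: count, mean, sample variance (n−1), skewness g1 and excess
  kurtosis g2 (third/fourth standardized moments, no small-sample bias
  correction; a normal distribution scores g2 = 0). Statistics below their
  minimum sample size (2/3/4) or on constant pools are emitted as missing,
  never silently dropped.
- *Reading time*: last fixation offset minus first fixation onset, in
  seconds (onset-to-offset; a single fixation therefore spans its own
  duration).
- *Normalization*: every non-count feature is re-emitted minus the
  participant median (`_a`) and minus the participant × block median
  (`_b`) — the additive-baseline correction standard in psychophysiology.
  Coefficient K is already participant-standardized, but its re-centered
  variants are emitted too for a uniform variable set. Absolute pupil size
  has no cross-person meaning, so the raw pupil mean is excluded while its
  variance/skewness/kurtosis are kept in all variants. The emitted set is
  113 columns; the sidecar manifest (feature → family, statistic,
  normalization, units) is the authoritative enumeration.

## Screening

Rows with any missing feature value are removed. Near-zero-variance
columns are flagged with the caret-style convention (frequency ratio
≥ 95/5 and unique fraction < 10%) but retained by default. Column pairs
with |r| > .95 are de-duplicated greedily: from the currently worst pair,
the member with the larger mean absolute correlation against all retained
columns is dropped (name-sorted tie-break, sorted canonical column order),
until no pair exceeds the threshold. The greedy rule equals the exhaustive
optimum on cluster-structured redundancy (near-duplicate variants), which
is the case that actually occurs here; it is a heuristic in general.

## Statistical models

- *Scales*: three 7-point items per construct; reverse-coded differentials
  flipped (x → 8 − x) so higher = more comprehensible / more interesting;
  score = mean of the aligned items; reliability by Cronbach's α
  (k/(k−1) · (1 − Σ item variances / variance of sum)). For equicorrelated
  items α has the closed form kρ/(1 + (k−1)ρ), which the tests use as an
  independent anchor.
- *Stepwise regression*: bidirectional search minimizing
  AIC = n·log(RSS/n) + 2(p + 2), started from the full main-effects model
  (the conventional default of the classic stepwise routine in the R
  ecosystem). The search runs on standardized predictors through their
  Gram matrix; the reported model is refit by OLS on the original scale
  (R² in percent, F with degrees of freedom, per-predictor t-values).
  Identifiers, questionnaire items, the response and the other appraisal
  are never candidates (leakage guard).
- *LOOCV*: the selected predictor set is fixed; each session is predicted
  with coefficients retrained on the other N − 1. For OLS this equals the
  exact hat-matrix identity pred_i = y_i − e_i/(1 − h_ii), which is what
  is computed (equality with literal refitting is asserted in the tests);
  near-singular folds (h_ii ≈ 1) are flagged and excluded from summaries.
  nRMSE divides the RMSE by the **actual** response range; predictions are
  not clipped to [1, 7].
- *Correlation table*: Pearson r with two-sided t-test p-values, starred
  at .001/.01/.05, no multiple-testing correction (the number of tests is
  the table size); constant features yield missing entries.
- *Report*: predicted-vs-actual points, a lowess trend (span 0.75 by
  default), 95% prediction intervals from the linear fit of actual on
  predicted, kernel-density margins, and the chance baselines
  (100/7 = 14.29% for a 7-point scale, 50% binary).

## The synthetic-data generator

The generator emulates the *study conditions*, not reading itself: 30
participants × 18 articles in three counterbalanced blocks (block order
rotates across participants, article order shuffles within blocks); one
participant's gaze lost to a tracker failure (540 appraisal records, 522
gaze sessions); five sessions truncated after ~3 s by tracking loss, which
leaves them without defined regression moments and reproduces the five
missing-value rows removed at screening (517 modeled sessions).

**Scanpath.** A word-by-word model over a single-page layout (title line
plus ~180 body words in ~12 text lines on a 1280 × 1024 canvas):
lognormal fixation durations (median 385 ms, σ_log 0.4), Bernoulli word
skips (base 0.18), Bernoulli regressions (base 0.10; a one-fixation
revisit 1–7 words back), and line-return sweeps implied by the geometry.
Fixations are rendered as sample runs with sub-dispersion jitter, saccades
as 1–3 transition samples with stochastic crossing fractions (a crude
main-sequence analogue at the 60 Hz grid), and timestamps carry ±0.4 ms
clock jitter, without which event durations collapse onto the sampling
lattice and degenerate the IQR filter. Blinks arrive as a Poisson process
(8/min) with uniform 100–400 ms closures written as (0, 0) samples. Pupil
traces are per-eye baselines (which differ strongly across people but
carry no analytic weight, since absolute pupil size is excluded) plus slow
sinusoidal drift and white noise. Defaults center reading time near 75 s;
with ~170 fixations per session the implied mean fixation duration
(~400 ms) is on the long side of typical reading, a compromise forced by
anchoring reading time (the three descriptive anchors — fixation count,
mean duration and reading time — are not mutually consistent in the
reference descriptives).

**Appraisal structure.** Latent comprehensibility and interest are
standardized bivariate normal per session at r = .466 (21.7% shared
variance). They enter only through session-level multipliers
exp(gain_f · sign_f · (β_C·C + β_I·I)) with default signs −1 for reading
time, fixation duration, regression probability, saccade amplitude (via
the skip rate) and pupil variance. β_C = 0.08 is twice β_I = 0.04, which
yields the intended ordering of predictive performance (comprehensibility
above interest). Per-family gains compensate for the very different
session-level sampling noise of each feature family; a partial
compensation of skip-induced time savings (longer dwell when more words
are skipped, as in parafoveal-preview accounts) keeps the amplitude
channel from leaking into reading time. Questionnaire items come from a
common-factor model with the session latent as factor; because 7-point
discretization attenuates correlations, the latent loading is calibrated
analytically (Hermite expansion of the staircase transform, inverted by
Brent's method) so the *recorded* items carry the target inter-item
correlations (0.7356 / 0.7953 → α ≈ .893 / .921 at N = 540). One interest
differential (boring–exciting) is coded in the opposite direction from the
others; the reverse-coding map is recorded with the study.

**Variance split.** Participant traits (tempo, skip and regression
tendencies, pupil drift scale) and block-level drift are present but
small (log-sd 0.05 / 0.03), and all articles share one page template.
This is a deliberate design choice: repeated-measures structure lets a
high-dimensional model reconstruct participant or article chance-mean
ratings in leave-one-out cross-validation (measured at cv r ≈ +0.2 under
a pure null when traits or per-article layouts are strong), which would
confound the null calibration of the analysis. The cost is realism:
between-person differences in real reading are far larger, raw and
median-normalized feature variants are nearly collinear here (so the
|r| > .95 screen removes ~35 variant columns), and the generator makes no
attempt at word-level effects (frequency, predictability, spill-over) —
it is a session-level emulation.

## Known limitations

- **Selection bias in the two-step protocol.** The stepwise predictor set
  is chosen on the full data and only the coefficients are retrained in
  LOOCV. With ~90 candidate features at n ≈ 517 this optimism survives
  cross-validation: on pure noise the chained procedure measures
  cv r ≈ +0.2, while at moderate dimensionality (15 candidates, n = 500)
  it averages to zero. The package therefore calibrates the CV machinery
  under the null with a fixed, data-independent predictor set, and reports
  the chained behavior here: cross-validated r from this protocol should
  be read as an upper bound at high dimensionality.
- Detection is dispersion-based only (no velocity-threshold or HMM
  alternative), binocular-average only, and assumes the blink encoding
  (0, 0); smooth pursuit is out of scope.
- The generator's effect sizes are set for detectability (reading-time
  correlations ≈ −0.3 to −0.4), stronger than the weak effects typical of
  discourse-level reading data; passing tests demonstrate the pipeline's
  correctness and calibration, not expected effect sizes in real studies.
- Whether reading time should span onset-to-onset or onset-to-offset of
  the terminal fixation is a convention; onset-to-offset is implemented.
- Both behaviors around normalizing Coefficient K (already standardized,
  yet re-centered variants exist in the field's variable sets) are
  emitted; the modeling default uses the full set.
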