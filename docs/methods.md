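# Methods

This note documents the models, conventions and numerical choices behind
`facedecode`: a simulation-plus-analysis pipeline for time-resolved decoding
of sensor-level MEG/EEG evoked responses to facial-expression categories.

## The synthetic evoked-response generator

Every trial of subject *s* in category *c* is

    x(trial) = T_c(s) + ε,        ε ~ spatially mixed Gaussian AR(1)

with `T_c` a channels × samples template over the −200…500 ms epoch
(600 Hz default, 421 samples, the first 120 samples forming the [−200, 0) ms
baseline).

**Templates.** All categories share a common waveform: a Gaussian-windowed
half-sine deflection peaking at `peak_latency_ms` (default 105 ms, width
20 ms), a secondary ~170 ms deflection at 60 % amplitude, and — for the
emotional categories AD/HD/AH/HH — a sustained 200–350 ms component at 50 %
amplitude, mimicking the latency range of the early posterior negativity /
late posterior positivity. The spatial profile is a Gaussian bump over the
channel axis centred on the occipital/parieto-occipital groups with a 0.2
floor. On top of this, each category receives a unique unit-Frobenius-norm
random spatiotemporal pattern of amplitude `category_amplitude` (default 5),
and each configured category pair (a, b) an extra unit-norm pattern added to
b's template with amplitude

    effect(a,b; s) = base_effect(a,b) · max(0, 1 + β · z_s)

where `z_s` is the subject's trait score standardized by the instrument
range (IRI subscales are 7 items × 0–4, hence range 0–28; a uniform
distribution over that range has mean 14 and SD 28/√12). All temporal
components are tapered to exactly zero before stimulus onset, and templates
are de-meaned over the baseline window, so the template baseline mean is
exactly zero and the configured pair separation equals the L2 norm of the
template difference to ~1e−6 relative accuracy. Pattern draws use a
dedicated `pattern_seed` stream, so templates do not depend on the noise
seed and β = 0 reproduces identical templates regardless of traits.

**Noise.** Per trial and channel, a stationary Gaussian AR(1) process along
time (marginal SD `noise_sd`, default 1; lag-1 coefficient `ar1_coef`,
default 0.3), then mixed across neighbouring channels of the same modality
with a Gaussian kernel (width 3 channels) renormalized to unit L2 norm at
every position — mixing therefore preserves the per-channel marginal SD
exactly, which the calibration tests exploit (empirical baseline SD within
5 % of `noise_sd`; pooled lag-1 autocorrelation within 0.02 of `ar1_coef`
at ≥ 500 trials).

**Design.** Default: 8 categories × 88 trials × 2 sets (color/grayscale)
= 176 trials per category, 15 subjects. The color/grayscale distinction is
a tag only — both sets are generated from the same template, because every
downstream classification pools the sets. Traits default to independent
uniforms over 0–28 per subscale; no distributional claim is made for real
cohorts and the sampler is pluggable.

**What the generator does *not* emulate:** realistic forward-model field
patterns, 1/f and line noise, artifacts (blinks, cardiac), inter-subject
latency/topography variability, or within-category stimulus heterogeneity.
Passing tests therefore demonstrate the correctness and calibration of the
analysis machinery under a controlled noise model, not performance on real
recordings.

## Preprocessing conventions

- Baseline window **[−200, 0)**: inclusive of the first sample, exclusive of
  the stimulus-onset sample, so onset is never shared between baseline and
  response. Baseline correction subtracts the per-trace baseline mean and is
  idempotent.
- Low-pass: 4th-order Butterworth at 40 Hz applied forward–backward
  (`filtfilt`), i.e. zero phase — peak latencies, which the analysis
  interprets, are not shifted. Whether a causal or zero-phase filter was
  used in comparable published analyses is typically unstated; zero phase is
  this package's choice.
- Planar-gradiometer pairs are combined as pointwise √(a² + b²) (vector
  sum) on **evoked** (trial-averaged) responses before regional averaging;
  areal averages are plain means of the pair vector sums within each of the
  12 region groups.
- Baseline z-scoring divides each channel by its own baseline SD
  (ddof = 1); a zero baseline SD raises an error naming the channel.

## Decoding

- **Window grid.** Windows include both endpoint samples (an 80 ms window at
  600 Hz = 49 time points), so consecutive windows share boundary samples.
  A nominal 50 % overlap of 80 ms windows over 0–500 ms cannot tile the span
  with a 40 ms step and still end at 500 ms; `WindowSpec.overlapping` keeps
  the implied number of windows (11) and stretches the step minimally to
  42 ms (starts 0, 42, …, 420). An explicitly supplied non-tiling step is an
  error.
- **Sensor selection.** For MEG, the `k_channels` (default 50) gradiometers
  with the highest inter-trial synchrony — the mean pairwise Pearson
  correlation of single-trial time courses over 0–500 ms, pooled across all
  trials and categories — are selected once per subject and reused for every
  pair and window. Zero-variance traces contribute correlation 0 and are
  logged. EEG uses all electrodes. The synchrony statistic is computed via
  the identity Σ_{i<j} zᵢ·zⱼ = (‖Σz‖² − Σ‖z‖²)/2 on unit-normalized
  traces, verified against the brute-force pairwise loop in the tests.
- **Classifier.** Linear-kernel SVM, C = 1, features standardized
  per-feature with training-fold statistics only; stratified 5-fold CV on a
  seed-shuffled trial order; reported accuracy is the mean over folds. The
  hot loop calls libsvm's training routine directly (identical solver to
  `sklearn.svm.SVC`; prediction equivalence is asserted in the tests) with
  convergence tolerance 1e−2 — CV accuracies are insensitive to the tighter
  1e−3 default, and permutation nulls retrain the classifier ~10⁵ times.
- **Pseudo-trials.** Static (whole-window) decoding first averages disjoint
  random triplets within each category (176 → 58 pseudo-trials; remainder
  discarded). Averaging precedes the fold split with disjoint triplets, so
  no raw trial influences both training and testing.

## Permutation maximum statistics

One label shuffle per permutation, reused across all windows and pairs of
that permutation (preserving the dependence structure of the family); the
full grid is recomputed and its maximum accuracy recorded. The threshold is
the (1 − α) empirical quantile of the permutation maxima under the
ceiling-index convention — the ⌈(1 − α)·n⌉-th order statistic, e.g. the
190th of 200 at α = 0.05 — and an observed accuracy is significant iff it
**strictly** exceeds the threshold. Permutations are run and the threshold
applied per subject, matching per-subject inference; channel selection is
label-independent and is computed once, outside the permutation loop.

## Trait association

Spearman's rho (average ranks for ties) between per-subject accuracy and a
trait or response-time predictor, with a BCa bootstrap interval over case
(subject) resampling: bias correction z₀ from the bootstrap distribution's
position relative to the point estimate (ties counted half), acceleration
from jackknife skewness, bootstrap quantiles by linear interpolation. If the
bootstrap distribution is entirely one-sided or the jackknife variance is
zero, the plain percentile interval is returned with a warning. For pairs
involving dog-face categories, the animal-directed subscales (ani-EC,
ani-PT) are evaluated alongside EC/PT. Whole-window accuracies are graded
≥ 0.90 excellent, [0.70, 0.90) good, [0.60, 0.70) fair, else below.

## Problem sizes used in the calibration checks

Full-size simulation (1408 trials × 236 channels × 421 samples per subject,
~1.1 GB in float64) is supported but unnecessary for validating the
machinery; the shipped checks use reduced, documented sizes chosen so each
property is measured with adequate Monte-Carlo precision:

- *Chance calibration*: 2 identical-template categories, 200 trials each,
  16-channel posterior layout (8 selected), 50 replicate datasets; per
  window, the mean accuracy is compared to 0.5 with a z-interval from the
  empirical across-replicate SE at family-wise 99 % (Bonferroni over the 11
  windows). A naive binomial band with n = trials × replicates understates
  the variance of a cross-validated accuracy (predictions within a dataset
  share training folds), which is why the empirical SE is used.
- *Family-wise type-I control*: 4 categories × 40 trials, 5 non-overlapping
  100 ms windows at 150 Hz, 4 of 8 gradiometers selected, 50 permutations,
  100 replicate null runs; the observed rate of any supra-threshold
  accuracy is required to stay within 3 Monte-Carlo SEs of α = 0.05.
- *Effect-size monotonicity*: pair separations (0, 8, 20) against unit-SD
  noise, 48 trials/category, paired seeds. With ~16 pseudo-trials per class
  and ~1800 features, accuracy is limited by high-dimensional estimation
  noise rather than the Bayes error, which motivates these separations:
  they span chance → ~0.75 → ~1.0.
- *Trait recovery*: 15-subject cohorts, EC coupled to the AD–HD separation
  (base 8, β = 0.6); the EC × accuracy Spearman rho is positive in ≥ 90 %
  of 50 replicate cohorts while β = 0 cohorts centre on zero.

## Reproducibility

Every stochastic component draws from `numpy.random.default_rng` seeded via
`derive_seed(master, stage, index)` (CRC-32 of the stage tag mixed into a
`SeedSequence`; all derived seeds < 2³¹). Identical configuration and master
seed give bitwise-identical epochs, decoding results and CSV outputs; the
pipeline echoes its full configuration into `run_metadata.json`.

## Known limitations

- The inter-trial synchrony definition (mean pairwise trial correlation) is
  one reasonable reading of "synchrony"; alternatives (e.g. evoked-power
  ratios) can be substituted by passing precomputed channel lists.
- The permutation null is per subject; pooling permutations across subjects
  is not implemented.
- No multiclass decoding, nonlinear kernels, source-space analysis or
  cross-subject alignment.
- BCa intervals on n = 15 subjects are themselves noisy; the package
  reports the interval and leaves significance interpretation to the user.
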