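# Methods

## Problem setting

Waist-worn tri-axial accelerometry (100 Hz, ±8 g) of ambulatory subjects
with incomplete spinal cord injury, performing six instructed activities:
lying, standing, sitting, wheeling, walking, stair climbing.  Recordings
are labelled with activity intervals, cut into non-overlapping 10-s clips
(the classification unit), summarised by a 178-value feature bank, and
classified.  Three validation protocols quantify how much a classifier's
accuracy depends on the recording context: pooled ("within-subject")
10-fold CV on in-lab clips, training on lab / testing on home clips, and
pooled 10-fold CV on at-home clips.

## Segmentation

Within each label interval, half-open windows `[s, s+10 s)` are emitted
from the interval start; the trailing partial window is dropped and
windows never straddle two intervals, so transition samples are
discarded.  Windows do not overlap: overlapping windows would leak
near-duplicate clips across CV folds.  Recordings must already be at the
configured rate — a mismatch is an error, never a silent interpolation.
Rows outside the ±8 g dynamic range are physically impossible and are
rejected at ingestion (with a count reported).

## Feature bank

Group sizes: 6 (per-axis mean, |mean|), 9 (per-axis SD/skew/kurtosis),
12 (SD/skew/kurtosis of |a(t)| and of the cross-product signals xy, xz,
yz), 3 (per-axis RMS), 6 (RMS of the 5- and 10-point boxcar-smoothed
signal, reflective edge padding), 12 (per-axis min/max/|min|/|max|), 27
(per-axis z-score histograms), 96 (DFT magnitudes), 1 (mean acceleration
magnitude), 3 + 3 (cross-product means and their absolute values).

Numerical conventions, chosen once and fixed:

* **Moments** use population (1/N) normalisation; kurtosis is excess
  kurtosis; a zero-variance signal has skew and kurtosis defined as 0.
  Hence the identity SD² + mean² = RMS² holds exactly per axis.
* **Histograms** use 9 unit-width bins centred on integer z-scores
  −4…+4, z-scored with the axis's own clip mean/SD; values beyond ±4.5
  are clipped into the end bins so per-axis counts always sum to the
  sample count.  A zero-variance axis puts all mass in the centre bin.
* **Spectral block**: magnitudes of the first 32 DFT coefficients (DC
  included) of each raw axis signal over the full clip.  At 100 Hz and
  1000 samples this covers 0–3.1 Hz in 0.1 Hz steps — the band where
  gait and postural energy lies.  Truncating the spectrum (rather than
  resampling the signal to 32 samples) preserves that low-frequency
  content.
* The 12-value "derived signal" moment group uses only signals the bank
  itself already names: the magnitude signal and the three instantaneous
  cross-products.

Under positive scaling of a clip by c, all amplitude-type features scale
by c, cross-product means by c², and histograms/skew/kurtosis are
invariant; the test suite asserts this affine response on random clips.

## Classifiers

Five kinds with the replicated study's hyperparameters as defaults: RBF
SVM (C = 10, γ = 1), Gaussian naive Bayes, L1 logistic regression
(λ = 0.01, mapped to scikit-learn's inverse strength C = 1/λ), k-NN
(k = 5), decision tree (min 10 samples to split).  Features are
z-normalised with training-row statistics for the SVM (as the study
states) and for logistic regression (regularisation is scale-sensitive);
the other kinds see raw features.  Zero-variance features scale by 1.
Multiclass handling for SVM and logistic regression is one-vs-rest.
Grid search scans powers of ten 10⁻⁵…10⁵ (C, γ, λ) or the integers 1–30
(k, split threshold), maximising mean stratified k-fold CV accuracy with
a fixed fold assignment; ties break toward the smaller parameter value.
A tree split threshold of 1 is mapped to scikit-learn's minimum of 2
(the two are behaviourally identical).

## Validation and statistics

Folds are stratified by activity with a seeded shuffle-and-deal
assignment, deterministic given the seed.  Normalisation statistics are
computed inside each training fold only.  Confusion matrices use the
fixed class order (lie, stand, sit, wheel, walk, stairs), rows = truth.
Derived statistics: accuracy = trace/total (with an optional stated
denominator for recomputing published tables whose transcribed counts
are not fully self-consistent), per-class recall and precision (NaN for
zero-support classes, excluded from macro averages), class merging (sums
rows/columns within a partition; accuracy can only rise), and binomial
95% CIs — exact Clopper–Pearson via beta quantiles by default, the Wald
normal approximation as an alternative, because the study does not name
its method.  Printed percentages use one decimal with half-up rounding.
Leave-subject-out validation is deliberately not offered as a default
protocol: the replicated analysis pools clips across subjects.

## Synthetic cohort generator

No public recordings exist for this population, so the generator is a
first-class module that produces cohorts with the statistical structure
the analysis needs.  Each clip is a sum of:

* a **gravity projection** along a per-activity device orientation
  (x mediolateral, y vertical, z anteroposterior; upright activities
  carry gravity mostly on y, lying on z, wheeling close to sitting);
* a **dominant movement sinusoid** along that orientation (walking
  1.8 Hz, stairs 1.3 Hz, wheeling 0.8 Hz; static postures 0 Hz);
* a **movement-texture band**: one tone per DFT-grid frequency up to
  3.1 Hz with a Gaussian spectral envelope (per-activity peak, width and
  amplitude), each tone along a deterministic direction on a cone about
  the gravity axis.  This represents postural sway, step harmonics and
  movement irregularity, and gives every spectral and distributional
  feature activity-determined content.  A plain sinusoid-plus-white-noise
  model leaves ~85 of the 96 spectral features carrying nothing but the
  white-noise floor; after per-feature z-normalisation those dimensions
  dominate RBF distances and no kernel classifier at the study's γ can
  separate the classes, so the broadband texture is essential, not
  decorative;
* **impact transients** for gait classes: 12-ms Gaussian pulses locked
  to the movement cycle (heel strikes), which give walking and stair
  climbing their heavy-tailed, high-kurtosis sample distributions and
  populate the extreme z-score histogram bins deterministically;
* an **amplitude-modulated 7–13 Hz tremor band** along a stable random
  direction, emulating spasticity in this population; and
* **white sensor noise** (per-activity SD 0.002–0.012 g, the order of a
  real MEMS accelerometer's noise floor), with saturation at ±8 g.

The phases of all periodic components form a **movement signature drawn
once per (subject, activity)** and shared between contexts: a person's
movement waveform is a reproducible trait, and tones on the DFT grid
repeat with identical phase in every consecutive 10-s window of one
continuous recording.  Per clip, only small texture amplitude jitter
(1.5%), tone phase drift (0.012 rad), tremor phase drift and fresh noise
are drawn — this is what makes within-context CV strong, as it is on
real segmented recordings where consecutive clips of one bout are highly
similar.  Per-subject lognormal amplitude scaling (SD 0.15) provides
between-subject variance.

The **context shift** maps lab statistics to home statistics:

| parameter | default | meaning |
|---|---|---|
| `amp_scale` | 1.3 | home movements are larger/more vigorous; scales oscillation, texture and impacts |
| `freq_jitter_sd` | 0.008 Hz | per-clip cadence wobble (moves tones off the DFT grid) |
| `extra_noise_sd_g` | 0.003 g | added in quadrature per clip |
| `orientation_jitter_deg` | 0.7° | per-clip random device re-orientation |
| `placement_bias_deg` | 8° | per-subject systematic re-orientation: the self-placed waist strap at home sits differently than the clinician-placed one in the lab |

The identity shift (all zeros, scale 1) makes home statistically
identical to lab, and the test suite verifies that per-activity home
feature means then agree with lab means within sampling error and that a
lab-trained classifier loses nothing on identity-shifted home data.
Increasing the noise and jitter magnitudes never increases cross-context
accuracy (checked over paired seeds).

Default magnitudes were calibrated once so that the default SVM pipeline
reproduces the replicated study's qualitative pattern — in-lab CV >
at-home CV > lab-trained/home-tested accuracy, with a catastrophic
cross-context drop — across seeds; the exact published percentages are
out of reach without the original recordings and are not a calibration
target.  Cohort counts default to the study's 13 subjects with 1170 lab
and 1089 home clips; since 1089 is not divisible by 78 (subject,
activity) pairs, a stated total is spread as evenly as possible over
pairs in fixed order.

### What passing tests do and do not show

The generator emulates the *feature-space geometry* the analysis relies
on: six separable activity clusters, within-subject clip similarity,
between-subject variation, and a parametric distribution shift between
contexts.  It does not emulate biomechanically realistic gait, activity
transitions within a clip, labelling error, sensor drift, or the
heterogeneity of assistive-device use in the real cohort.  Passing the
pipeline tests on synthetic cohorts therefore demonstrates the
correctness and sensitivity of the *analysis machinery*, not clinical
performance on real iSCI recordings.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; a single experiment seed
fans out to per-stage seeds through a SHA-256 hash, so repeated runs
write byte-identical reports.  The test suite exercises the full
study-scale cohort (2259 clips, five seeds) for the headline ordering
check and small cohorts (tens to hundreds of clips) elsewhere; the
acceptance script evaluates one study-scale cohort, which takes roughly
half a minute on one CPU.

## Known limitations

* The published off-diagonal confusion counts are not fully
  self-consistent (the in-lab rows sum to 1172 against a stated 1170
  clips), so recomputed statistics use the stated denominators, and two
  published per-class recalls cannot be reproduced from the transcribed
  rows.
* The replicated study's binomial CI method is unnamed; both offered
  methods bracket its printed intervals but neither matches both ends
  exactly.
* Model files use joblib serialisation and are not portable across major
  scikit-learn versions; the feature-registry hash guards against
  applying a model to a mismatched feature layout.
* `GaussianNB`'s variance floor is relative (1e-9 × the largest feature
  variance) rather than absolute.
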