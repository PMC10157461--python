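# Methods

This note documents the models and procedures implemented in
`tremorglyc`, the defaults and numerical conventions chosen where the
design was genuinely open, and what the synthetic experiments do and do
not establish.

## Problem setting

Hypoglycemia (blood glucose < 70 mg/dL) in type 1 diabetes is accompanied
by a fine hand tremor concentrated in the 4–14 Hz band. The package
classifies 3-second windows of wrist acceleration as hypoglycemic or
nonhypoglycemic, using CGM readings as ground truth for supervision, and
evaluates with subject-aware cross-validation so that no person
contributes to both training and test data of a fold.

## Preprocessing

* **Filter.** Second-order Butterworth low-pass, 30 Hz cutoff, applied to
  each axis independently. At the nominal 64 Hz sampling rate the cutoff
  sits at 93.75 % of Nyquist — legal but nearly transparent; the
  implementation rejects only cutoffs at or above Nyquist. Filtering is
  causal (single forward pass) by default, matching a real-time
  deployment; `FilterSpec(zero_phase=True)` switches to forward–backward
  filtering. The filter state is seeded at each segment's first sample so
  short segments and DC inputs are not distorted. Filtering runs per
  contiguous segment, never across wear gaps.
* **Magnitude** is computed after filtering, as the per-sample Euclidean
  norm of the three filtered axes.
* **Windowing.** 3-second windows, 50 % overlap (1.5 s hop). A gap is any
  inter-sample interval exceeding twice the nominal period; gaps start a
  new contiguous segment, and leftover samples at a segment end that
  cannot fill a whole window are dropped. For a contiguous segment of
  T seconds the window count is ⌊(T − 3)/1.5⌋ + 1, so 15/30/60-second
  stretches hold 9/19/39 windows, and at scale n windows account for
  n × 1.5 s of stream.

## Labeling

The window center is matched to the nearest CGM timestamp; a match
farther than 150 s leaves the window unlabeled. With the standard
5-minute CGM cadence the ±150 s half-width tiles time exactly. Ties
between two equidistant readings resolve to the earlier one. Glucose
< 70 mg/dL labels the window hypoglycemic and 90–140 mg/dL (both ends
inclusive, the conventional reading of "between") nonhypoglycemic;
readings in [70, 90) or above 140 exclude the window — a deliberate
buffer zone between the classes. Runs of consecutive same-label windows
are cut into non-overlapping 9-window sequence blocks; shorter runs are
discarded, and no window is shared between blocks (sharing would leak
information between sequence examples). Training partitions may be
rebalanced by duplicating hypoglycemic windows uniformly at random
(seeded) until the nonhypo:hypo ratio reaches 3:1; sets already at or
below the ratio are untouched, and validation/test partitions are never
resampled.

## Features

86 features per window; counts are structural (9 stats × 4 channels + 6
correlations = 42 time; 7 stats × 4 channels + 4 HTFR stats × 4 channels
= 44 frequency). Conventions the literature leaves open, fixed here:

* Variance and SD use the population (n) estimator; kurtosis is excess
  kurtosis; both are switch-free and documented rather than configurable.
* A *peak* is a strict local maximum (greater than both neighbours,
  endpoints excluded) whose height exceeds the window mean; the same rule
  counts peaks on the PSD using the PSD mean.
* Welch PSD: 1-second Hann segments (64 samples), 50 % segment overlap,
  per-segment mean detrend — three averaged segments on a 192-sample
  window, giving a 1 Hz grid to 32 Hz. This balances spectral resolution
  against estimator variance at this window length.
* ABP is the trapezoidal band integral of the PSD divided by the
  bandwidth; NABP is the band-integrated power as a fraction of the total
  integrated power. The general-band ABP/NABP use the non-DC band
  [1 Hz, Nyquist]: the per-segment detrend empties the DC bin, so
  including it would only dilute the statistic. HTFR features use
  4–14 Hz.
* Degenerate inputs produce finite values: a constant channel emits 0 for
  SD, variance, range, NOP, skewness, kurtosis and its correlations; zero
  total power emits NABP = 0. Both are logged.
* The default selection drops the whole skewness, minimum, range,
  maximum, kurtosis and correlation families (26 features), the families
  that rank lowest under impurity-based importance, leaving 60. The drop
  list is a plain tuple of names and fully overridable.

## Classifiers and aggregation

Random forest (100 trees, depth 5, Gini), KNN (K = 27, Euclidean) and
RBF SVM (C = 1), all thresholded at probability 0.5 with the boundary
counting as hypoglycemic. KNN and SVM standardise features with
training-fold statistics (the features mix units — g, g², g²/Hz, Hz,
counts — so distance- and kernel-based members are meaningless without
scaling; the forest is scale-invariant and runs unscaled). The SVM's
probabilities come from Platt calibration so one threshold applies to all
members. The ensemble takes the majority of the three hard votes and
therefore has no score-based ROC. Sequence decisions over 9 (or 19, 39)
consecutive windows are hypoglycemic when at least ⌈0.5 × len⌉ windows
are — "at least 50 %", so an exact tie at even length counts as
hypoglycemic. Sequence predictions default to ensemble votes.

## Evaluation

Folds partition subjects: LOSO holds out one subject per fold; grouped
10-fold shuffles subjects (seeded) into 10 groups. A runtime guard
asserts train/test subject disjointness in every fold. Within a fold:
oversample the training partition only → fit (scaling fitted on training
data inside each member's pipeline) → predict held-out windows.
Confusion counts are pooled (micro-averaged) across folds; per-fold
reports are also kept. Metrics with zero denominators are reported as
missing, never as 0. ROC curves use pooled window scores and AUROC is
the trapezoid area (cross-checked in tests against an independent
rank-statistic implementation). MDI importance is the normalised mean
decrease in Gini impurity of the random-forest member with inter-tree
SD, averaged over folds. Window-level and sequence-level metrics are
reported separately.

## Synthetic cohort generator

The generator emulates the data regime of wrist-tremor hypoglycemia
studies; its defaults are the study conditions, not tuning knobs.

* **Glucose.** Between events, an Ornstein–Uhlenbeck process around
  110 mg/dL (stationary SD 10 mg/dL, 30-minute mean-reversion time),
  clipped to [75, 400] mg/dL so that every sub-70 sample is attributable
  to an event. Events arrive as a Poisson process at 1.06/day with
  log-normal durations (mean 27.31 min; the duration SD is exposed as a
  parameter, default 15 min). During an event glucose follows a half-sine
  dip to a nadir of 70 − `hypo_depth` (default nadir ≈ 55 mg/dL) and is
  clipped strictly below 70, so the event log is exact ground truth.
  Event onset/offset in the CGM trace is abrupt; sensor lag and error are
  deliberately not modelled.
* **Acceleration**, per worn block: a unit gravity vector with a random
  per-block tilt (≤ ~30°); voluntary motion as < 4 Hz filtered noise at
  0.05 g RMS with a very slow (< 0.02 Hz) log-normal activity envelope
  (log-SD 0.5) — wrists alternate between rest and activity, and activity
  leaks power into the tremor band, which is the realistic source of
  false positives; tremor as 6–10 Hz band-limited noise with a slow
  (< 0.05 Hz) log-normal amplitude envelope (log-SD 0.35), at RMS
  amplitude `tremor_amp_hypo` inside true events and
  `tremor_amp_normal = 0.005 g` outside; white sensor noise at 0.01 g.
  Amplitudes denote the RMS of the full tremor vector, split equally
  across axes.
* **Wear.** 2–4 contiguous worn blocks per day covering 40 % of the day
  (Dirichlet-split placements), emitted as gaps in the timestamp stream —
  contiguous blocks, not random dropout, so windowing's gap handling is
  exercised realistically.
* **Reproducibility.** One root seed; each subject draws from its own
  spawned substream, so cohorts are byte-identical under a repeated seed
  and adding subjects never perturbs existing ones.

### Amplitude calibration

The separation between classes is governed by `tremor_amp_hypo`.
`estimate_band_power_error` measures the difficulty of a tremor
configuration: it generates balanced labeled windows from the signal
model, featurises them, and reports the held-out error of an
unconstrained random forest — an upper-bound estimate of the window-level
Bayes error. (A single band-power threshold is not a valid proxy here:
motion bursts leak power into 4–14 Hz but remain identifiable from their
low-frequency signature, so the full descriptor separates the classes
much better than band power alone.) Two calibrated operating points are
frozen as constants:

* `TREMOR_AMP_MODERATE = 0.018 g` — estimated Bayes error ≈ 0.15; this is
  also the generator default, the regime whose LOSO difficulty mirrors
  the ~0.8 accuracy/precision/recall reported by wrist-tremor detection
  studies.
* `TREMOR_AMP_HIGH = 0.05 g` — estimated Bayes error ≈ 0.02; the
  high-separability regime used for the end-to-end checks that the
  pipeline detects a strong signal (AUROC > 0.85 for every member) and
  that AUROC collapses to 0.5 under a label-permutation null.

## Problem sizes

The study-scale experiments use 12 subjects × 3 days at 64 Hz — about
66 million worn samples and 830,000 windows per cohort. Labeling and
sequence blocking run over all windows, but model fitting uses a
subject-stratified subsample of sequence blocks (≤ 30 blocks per class
per subject, all-hypo-first; subjects without observed hypoglycemia
contribute at least 15 nonhypoglycemic blocks): the calibrated SVM is
quadratic in training size, and a capped subsample leaves AUROC and
importance rankings unchanged while keeping a full study run in minutes.
The subsample is class-balanced by construction, which keeps accuracy,
precision and recall on a common, interpretable scale across tremor
amplitudes; the raw stream's class imbalance (~2–3 % hypoglycemic
windows) is preserved upstream of the subsample and the 3:1 oversampling
path remains in the fold harness.

## What the synthetic experiments show — and what they do not

Passing tests establish that the implementation is internally correct
(oracle-checked arithmetic, exhaustive rule enumeration, leakage guards)
and that the pipeline's power responds to signal strength as it must:
monotone AUROC in tremor amplitude, HTFR band power at the top of the
importance ranking when tremor is injected, chance-level AUROC under
permutation. They do not establish clinical performance: the generator
has no insulin–glucose kinetics, no CGM lag or error, no per-subject
tremor-frequency or amplitude variation, no motion artifacts beyond
band-limited noise, and sharp event boundaries. Real-data figures can
differ substantially.

## Known limitations

* Irregular accelerometer streams are segmented, never resampled; heavy
  jitter shortens usable segments.
* Personalised hypoglycemia thresholds, activity recognition and
  motion-artifact removal are out of scope.
* The buffer-zone exclusion ([70, 90) and > 140 mg/dL) means the
  classifiers are trained and judged only on the two clearly separated
  glycemic states.
* Whether sequence-level or window-level metrics are "the" headline
  number is a reporting choice; both are emitted.
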