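# Methods

## Signal model and preprocessing

A trial is a time-stamped series of left/right pupil diameters (mm) with
per-eye validity flags, on a uniform grid at the recorder's sampling rate
(300 Hz for the sound protocol, 50 Hz for the word protocol), with time
expressed in seconds relative to stimulus onset. Preprocessing assumes
blinks and tracking loss appear as invalid/missing samples, not as
plausible-looking outliers.

The cleaning chain, in order:

1. **Eye averaging.** Per sample, the combined diameter is the mean of the
   valid eyes; one valid eye is used alone; none leaves the sample missing.
2. **Trial rejection.** A trial is discarded when more than 50% of the
   samples inside the analysis window `[-1 s, T_end]` are missing
   (`missing_drop_threshold`, default 0.5; the comparison is strict, so
   exactly half missing is retained).
3. **Gap interpolation.** Every missing run in a retained trial is filled
   by linear interpolation between its nearest valid neighbours; runs at
   the very ends are extended with the nearest valid value. All missing
   samples are filled, including short gaps: interpolating a small gap is
   strictly less invasive than leaving it, and it makes the rule monotone
   in gap length. Valid samples are never altered.
4. **Smoothing.** Centred moving average with span 7 samples. At the
   edges the window shrinks symmetrically (1, 3, 5, … points), so output
   length equals input length, constants are reproduced exactly and the
   interior of a linear ramp is unchanged.
5. **Baseline referencing**, two modes:
   - `reference` — the mean diameter over `[-3, 0)` s is stored next to
     the absolute-mm trace (used for the sound profile, whose reported
     group peaks are absolute millimetres);
   - `subtract_200ms` — the mean over `[-0.2, 0)` s is subtracted from
     every sample (word profile). The subtracted mean is stored with the
     signal so the absolute trace stays recoverable; see "Feature scale"
     below for why that matters.
6. **Valence averaging.** Trials are averaged pointwise per (subject,
   valence). Neutral-rated trials are excluded before averaging, so each
   subject contributes at most one positive and one negative signal.

Self-report labels come from seven basic-affect ratings on a 1–5 scale:
basic positive = mean(joviality, self-assurance, attentiveness), basic
negative = mean(fear, sadness, guilt, hostility); the larger aggregate
labels the trial, with exact ties (and explicitly flagged trials) labelled
neutral.

## Features

Windows: `T_before = (-1, 0)` s, `T_after = (0, T_end]` s, `T_critical =
(T_end − 1, T_end]` s, with `T_end` = 6 (sound) or 5 (words). Interval
membership is open on the stated open side; the sample at exactly `t = 0`
belongs to no window.

With `D(t)` the cleaned averaged signal, `V(t)` the backward difference
times the sampling rate (first point 0), and `∇D(t)` the central-difference
gradient (one-sided at the ends):

- f1 = max D over T_after (mm)
- f2 = max over T_after of the running integral of V — accumulated from the
  first sample of T_before, each step weighted by the sample spacing Δt —
  minus the maximum of the same running integral over T_before (mm). The
  Δt weighting makes f2 a displacement and hence sampling-rate invariant;
  anchoring both running maxima at the start of T_before makes the two
  terms comparable.
- f3 = max V over T_after − mean V over T_before (mm/s)
- f4 = max D over T_critical (mm)
- f5 = max pupil area π(D/2)² over T_after restricted to t > 0.2 s, minus
  the mean area over T_before (mm²). The 0.2 s offset skips the initial
  stimulus-presentation transient.
- f6 = max ∇D over T_after − mean ∇D over T_before (mm/s). The gradient is
  the 1-D temporal component; the max-minus-mean form parallels f3/f5.

No feature scaling or normalisation is applied; the classifier operates on
raw units. Feature rows are ordered by (subject, label), giving a 60 × 6
matrix for the full 30-subject design.

**Feature scale.** The area feature requires physically positive
diameters, so the pipeline always extracts features from the absolute-mm
signal: under `subtract_200ms` the stored baseline is added back first.
A global shift of all signals leaves Euclidean neighbour relations in
f1/f4 unchanged and only mildly affects f5, so this choice stabilises the
units without changing the classification problem.

## Classification protocol

- Stratified split: `round(0.7 · n_class)` rows of each class to training
  (21 + 21 of the 60), remainder to test (9 + 9), drawn with a seeded
  generator; "70% from each dataset" is implemented per class so both
  classes always appear in training.
- kNN with Euclidean distance and k = 2. A 1–1 vote tie is resolved by the
  single nearest neighbour (k = 2 thus behaves as a distance-weighted
  1-NN); exact distance ties fall back to the lower training-row index.
  These conventions are verified in tests against an exhaustive-search
  oracle and scikit-learn.
- A single 30% holdout has only 18 rows, so a percent-style confusion
  matrix cannot come from one split. `evaluate_repeated` (default 100
  repeats, each with an independent child seed) pools all test
  predictions and reports the confusion matrix as percent of true-class
  instances — each row sums to 100 — plus pooled accuracy, sensitivity
  `TP/(TP+FN)` and both specificities.
- Orientation convention: TP = true positives detected positive, FP = true
  positives detected negative, FN = true negatives detected positive,
  TN = true negatives detected negative. Two specificity variants are
  reported side by side: `TN/(TN+FN)`, which under this orientation is the
  detection rate of the negative class (and is the variant the summary
  metrics follow, because only it is consistent with the percent confusion
  matrices whose rows sum to 100), and the conventional false-alarm-based
  `TN/(TN+FP)`. Under a class swap, sensitivity and the *conventional*
  specificity interchange; the first variant does not have that symmetry.

## Repeated-measures F test

The positive-vs-negative contrast on last-second mean diameters (one pair
per subject) uses a one-way within-subject ANOVA with two levels:
`F = MS_condition / MS_error` with df = (1, n − 1), equal by identity to
the squared paired-t statistic; p from the F survival function. Two levels
need no sphericity correction. A zero error term with a zero condition
effect reports F = 0.

## Simulator

The generator emulates the group-level dynamics reported for emotional
pupillary responses; its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 30 | cohort size |
| trials_per_valence | 10 | trials per subject per valence |
| sampling_rate | 300 Hz | recorder rate (50 Hz for the word profile) |
| stimulus_duration | 6 s | analyzed post-onset span (5 s words) |
| pre_duration | 3 s | pre-stimulus recording (1 s words) |
| onset_latency | 0.25 s | dilation start after onset |
| peak_time | 2.2 s | time of peak dilation |
| peak_negative / peak_positive | 4.76 / 4.66 mm | valence peak diameters |
| sustain_fraction_negative | 0.85 | rise fraction retained at T_end |
| decay_rate_positive | 0.45 s⁻¹ | positive-tail decay |
| baseline_mean / baseline_sd | 4.3 / 0.3 mm | population baseline, between-subject SD |
| trial_drift_sd | 0.1 mm | trial-to-trial baseline drift SD |
| noise_sd / noise_tau | 0.08 mm / 0.3 s | slow-fluctuation SD and correlation time |
| eye_jitter_sd | 0.02 mm | white per-eye measurement noise |
| blink_rate / blink_duration | 0.15 s⁻¹ / 0.15 s | blink process |
| missing_fraction | 0.02 | extra random dropout |

Template shape: flat baseline to `onset_latency`, raised-cosine rise to
the valence peak at `peak_time` (the simplest smooth shape matching the
described onset/peak dynamics), then an exponential tail — the negative
tail relaxes so that `sustain_fraction_negative` of the rise remains at
`T_end`, the positive tail decays at `decay_rate_positive`. The template
maximum equals the configured peak exactly.

Design choices that deserve explanation:

- **Noise is band-limited, not white.** Real pupil traces fluctuate on a
  sub-second timescale ("spontaneous fluctuations"), not sample to
  sample; white noise at 300 Hz would also make the difference-based
  features (V, ∇D scale with the sampling rate) noise-dominated in a way
  no physiological trace is. Trial noise is therefore white noise
  convolved with a Hann kernel of width `noise_tau`, rescaled to a
  per-sample SD of `noise_sd`.
- **Trial-to-trial baseline drift.** Each trial draws its own baseline
  offset (SD `trial_drift_sd`) on top of the subject offset, modelling the
  slow wandering of resting diameter over a session. Without it a
  subject's positive and negative averaged rows would share one exact
  offset and become near-duplicates whenever the class dynamics are
  similar; a nearest-neighbour classifier then systematically picks the
  own-subject opposite-valence twin and scores *below* chance on a
  null cohort. With drift, the identical-dynamics control sits near 50%,
  which is what a chance-level control should do. A small below-chance
  pull (a few points) from the residual within-subject pairing remains;
  it is a genuine property of paired designs with nearest-neighbour
  classifiers, not a bug.
- Variability magnitudes (baseline_sd, trial_drift_sd, noise_sd,
  eye_jitter_sd) are stated modelling assumptions — group-level reports
  carry no trial-level noise figures — set once to values typical of
  laboratory pupillometry.

What the simulator does **not** model: luminance responses and the
light-reflex constriction (the initial dip seen with visual stimuli),
cognitive-load dilation, saccade/gaze artifacts, asymmetric eyes, and
non-stationary blink clustering. Passing tests on synthetic cohorts show
the pipeline recovers the class structure it was told exists under
realistic noise and missingness; they cannot certify performance on real
recordings.

## Numerical choices and degenerate inputs

- Windows at grid boundaries: membership uses strict/non-strict
  comparisons as written above; with a grid point at exactly `T_end` the
  last second contains a full second of samples.
- `smooth` rejects even spans; very short inputs (n < span) are handled
  with per-point largest centred windows.
- Baseline modes require their full pre-stimulus window (3 s / 0.2 s,
  with half-a-sample tolerance at the start); anything shorter raises a
  data error rather than silently using less data.
- On-disk tables are TSV/CSV with floats written as `%.17g` and read with
  round-trip float parsing, so write-then-read is the identity.
- Split sizes: `round(0.7 n)` is clamped so each class keeps at least one
  row on each side; classes with fewer than two members are rejected.
- All randomness (simulation, splits) flows from explicit seeds through
  numpy `SeedSequence` children; identical config + seed gives
  byte-identical reports.

## Problem sizes in the test suite

The acceptance-style end-to-end checks run the full 30-subject design
(600 trials) over seeds 1–10 with 50 split repeats per cohort, plus ten
identical-dynamics null cohorts; unit tests use scaled-down cohorts
(5–6 subjects, 50–60 Hz) chosen so the whole suite stays fast while the
full design is still exercised where the claim depends on it.

## Known limitations

- The primary specificity `TN/(TN+FN)` is the negative-class detection
  rate under this orientation, not the conventional false-alarm-based
  definition; both are always computed so nothing hides the discrepancy.
- k = 2 with the nearest-neighbour tie-break is equivalent to a
  distance-weighted 1-NN; it is kept because the protocol specifies k = 2.
- The word-profile pipeline reuses the sound-protocol simulator shape
  (no initial luminance dip); its first-second exclusion flag is recorded
  in the run log but the last-second statistics never touch that region.
- Percent confusion matrices from repeated splits depend (mildly) on the
  number of repeats; the default of 100 makes the pooled estimates stable
  to well under a percentage point of Monte-Carlo scatter.
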