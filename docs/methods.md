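# Methods

## Signal model and preprocessing

A smartphone accelerometer measures specific force: the sum of the gravity
reaction (a quasi-DC vector tracking device attitude) and body
acceleration from limb motion. The two are separated with low-pass
filtering. Preprocessing runs in two stages, both 4th-order Butterworth
filters applied forward–backward (`scipy.signal.sosfiltfilt`):

1. **Denoising** at 20 Hz (only meaningful when the sampling rate is well
   above 40 Hz; the 20 Hz preset is skipped for 20 Hz-sampled data).
2. **Gravity estimation** at 0.3 Hz; body acceleration is the residual,
   `body = input − gravity`, so the two components sum back to the input.

Zero-phase (two-pass) filtering removes group delay — windows need no lag
compensation — at the cost of squaring the magnitude response: the gain at
the corner frequency is 1/2, not 1/√2. Both corners and the order are
config keys (`denoise_cutoff_hz`, `gravity_cutoff_hz`, `filter_order`), so
a literal single-stage 20 Hz separation is also expressible. The
reconstruction identity holds to one ulp; bit-exact equality is not
representable in binary floating point because the real-valued complement
of a rounded subtraction need not be a float.

Windows are `slen` samples with 50 % overlap (step = round(slen/2)):
128 samples = 2.56 s at 50 Hz for two-device data, 200 samples = 10 s at
20 Hz for the single-accelerometer configuration. A window takes the
majority per-sample label; if no label covers more than half the samples
(possible only at activity transitions) the window is discarded.

## Feature extraction

Each 3-axis stream window maps to an ordered 37-value descriptor (see the
README table). Conventions that required a decision:

- **Variance** is population (1/N) throughout, so the identity
  power = mean² + STD² holds exactly per axis.
- **Jerk** is the scaled first difference Δx·f_s (length slen−1) — the
  simplest consistent derivative estimate; no smoothing-spline derivative.
- **AR coefficients (F13–24)**: order 4 per axis, estimated by a
  hand-written Burg lattice recursion (tests verify exact agreement with
  `statsmodels`' Burg solver and recovery of known AR(4) generators
  cross-checked by Yule–Walker). Sign convention: prediction form
  x[n] = Σ aₖ x[n−k] + e[n]. A constant axis yields zeros with a warning.
  The order is fixed at 4 by the 12-coefficient budget (3 axes × 4).
- **Entropy (F29, F32–34)**: Shannon entropy in nats of a 16-bin
  equal-width histogram spanning [min, max] of the series; a constant
  series has entropy 0; the bin count is a config key. "Entropy of JS"
  within the roll-angle block is read as the entropy of the roll-angle
  jerk (not a repetition of F32–34).
- **Roll angle (F27–30)**: arctan2(−BA_z, −BA_y) per sample, range
  (−π, π] with arctan2(0, 0) ≡ 0 (a +0.0 is added before negation because
  IEEE −0.0 would flip arctan2 to −π).
- **Tilt angle (F26)**: angle between the window-mean vector and +z. The
  reference axis is a convention (config-exposed); +z matches a phone
  lying flat.
- **x–gravity angle (F31)**: the representative body-acceleration x-vector
  is B_x = (mean of the x axis, 0, 0), with the sign of the mean retained
  so forward and backward tilt differ; G_m is the window mean of the same
  device's gravity stream. The cosine ratio is clamped to [−1, 1] so the
  arccos is always real. Gyroscope streams (no gravity of their own) use
  the device's accelerometer-derived G_m; the 37-feature recipe is applied
  uniformly to every stream.
- **SMA (F25)** is an unnormalized sum over the window, which grows
  linearly in slen — that is why the scaling stage divides it by slen²
  (a deliberate strong compression of the largest-magnitude feature).

Stream concatenation order is fixed: pocket before wrist; body accel,
gravity accel, gyroscope within a device (6 × 37 = 222); body and gravity
only for single-accelerometer data (2 × 37 = 74).

**Scaling** divides AR coefficients, tilt angle, AS mean/STD, JS mean,
roll mean, roll power and the x–gravity angle by slen, SMA by slen², and
leaves STD-of-jerk, roll STD, entropies and powers untouched. "Scaled by
slen" is read as division — the goal of the stage is to shrink
large-magnitude features. Unscaling multiplies the same divisors back:
bit-exact for power-of-two slen (the 128 default), one-ulp otherwise.

**Normalization** is per-feature min–max to [0, 1], fitted on training
records only and re-fitted inside every evaluation split, so no test-set
information leaks into the transform. Constant features map to 0; held-out
values outside the training range are not clipped.

## Classification and evaluation

The production classifier is `RandomForestClassifier(n_estimators=200,
max_depth=25, min_samples_split=2)`; RBF-SVM, a 75-neuron tanh MLP with an
L-BFGS (quasi-Newton) solver, and Gaussian naive Bayes are provided as
baselines. Protocols:

- **subject_dependent_x10** — per-class stratified 70/30 split (exact
  per-class rounding, hand-rolled for determinism), repeated 10 times with
  run seed = base seed + run index; both the split and the forest are
  re-seeded each run. Reported as mean ± STD over runs plus the pooled
  confusion matrix.
- **stratified_10fold** — `StratifiedKFold(shuffle=True)`; per-fold class
  counts are within one record of perfect stratification.
- **leave_one_subject_out** — one fold per subject; measures
  generalization to unseen people.

Accuracy is correct/total (trace of the confusion matrix over its sum).
Per-class precision = TP/(TP+FP) and recall = TP/(TP+FN) with 0/0 defined
as 0. The F-measure is reported twice: the standard harmonic mean
(default) and the arithmetic mean of precision and recall, macro-averaged
across classes. The sensitivity sweep evaluates every (forest size, depth)
cell of a grid — default 50/100/200/400 × 15/20/25/30/40 — under a chosen
protocol.

## Synthetic data generator

The simulator emits the simplest generative family in which every feature
group is informative: per activity block,

    accel = 9.81·o + Σ_{h=1..H} (A/h)·sin(2π h f t + φ_axis) + N(0, σ²)

with a unit orientation vector o, gait frequency f, harmonic stack of
depth H = 3 (amplitudes decaying 1/h), and white noise; the gyroscope
carries phase-shifted sinusoids with its own amplitude. AR coefficients
and entropies see the frequency content, tilt/roll/F31 see the
orientation, SMA and power see the intensity.

Defaults (the study conditions of the synthetic experiments):

- **Two-device preset**: 13 activities (7 full-body, 6 hand gestures),
  10 subjects, 50 Hz, pocket + wrist (the wrist is a 30° rotated copy of
  the pocket attitude with gesture-weighted amplitudes). Dynamic classes
  carry gait frequencies spaced 0.5 Hz apart (0.5–5.5 Hz); the two static
  postures differ in orientation. Block durations keep the collection
  protocol's 3 : 5-minute ratio scaled by 0.1 (18 s / 30 s per activity
  and subject, ≈ 2,360 windows in total) so the full study runs in
  minutes on one CPU.
- **Single-accelerometer preset**: 6 activities with class shares
  37.2/29.2/12.0/10.2/6.4/5.0 %, 29 subjects, 20 Hz, 300 s per subject.
- **Noise** SD 0.3 m/s² on acceleration (0.06 rad/s on the gyroscope) — a
  mid-grade MEMS level, well below the 0.1 g regime where gravity recovery
  degrades.
- **Inter-subject variability** (all gated on `subject_variability > 0`,
  default 0.10): per-activity log-normal jitter on amplitude and gait
  frequency (SD 0.10), and a per-subject, per-device random rotation of
  the device attitude (angle SD 0.15 rad ≈ 9°) emulating how differently
  people carry a phone. The rotation is what makes leave-one-subject-out
  genuinely harder than subject-dependent splitting: without it the
  generated population is subject-invariant and the two protocols
  coincide.

Everything is deterministic given (seed, subject index); the per-subject
RNG is `default_rng([seed, subject_index])`.

### What the simulator does and does not show

Synthetic activities are stationary harmonic stacks: no gait asymmetry, no
transients between activities (labels switch instantaneously), no sensor
bias/drift, no orientation changes within a block, and class-defining
parameters are well separated by construction. Passing tests therefore
demonstrate that the pipeline is *correct* (features measure what they
claim, protocols partition as specified, the classifier recovers planted
structure approaching its noise-free separability), not that the published
accuracy levels transfer to real human data. The relative ordering the
tests assert — subject-dependent ≥ 95 % and strictly above
leave-one-subject-out when subject variability is present — mirrors the
qualitative degradation pattern reported for real recordings.

## Numerical choices and degenerate inputs

- Filter preconditions: cutoff < Nyquist; stream longer than the
  `sosfiltfilt` padding (3·(2·sections+1) samples); violations raise.
- Analytic filter oracle in tests uses the prewarped bilinear form
  |H|² = 1/(1 + (tan(πf/f_s)/tan(πf_c/f_s))^(2n)), the exact closed form
  of the digital design.
- Degenerate windows: zero-norm means (tilt, F31) return 0 with a warning;
  constant axes give zero AR coefficients; arctan2(0,0) = 0; entropy of a
  constant series is 0. An all-zeros window yields an all-finite
  descriptor with zeros in every moment-based slot.
- Split edge rules: a class with fewer than 2 records cannot be split;
  k-fold requires every class ≥ k; 50/50 window label ties are discarded.
- Seeds: every stochastic step takes an explicit integer seed; protocol
  run seeds are base + index; the simulator folds (seed, subject) into a
  seed sequence.

## Known limitations

- The 37-feature recipe assumes tri-axial streams; single-axis sensors are
  not supported.
- No resampling: each dataset preset is processed at its native rate.
- Magnetometer and linear-accelerometer channels, frequency-domain (FFT)
  feature sets, and deployment transport (Bluetooth streaming) are out of
  scope.
- The raw two-device CSV dialect is this package's canonical definition
  (the content, not the file grammar, of the original collection is
  specified upstream); external files in other layouts need remapping to
  it.
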