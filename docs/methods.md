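# Methods

`wheelmotion` detects whether a wheelchair movement bout was self-propelled
(*active*) or pushed by an attendant (*passive*) using only
wheelchair-mounted inertial sensors: a 6-axis IMU in the right wheel hub
and, optionally, a second IMU on the frame crossbar, both sampled at 50 Hz.
This note describes the models and procedures the package implements, the
choices made where the design was open, and what the synthetic validation
does and does not demonstrate.

## Sensor model and reference frames

The wheel sensor's x axis lies along the axle pointing away from the chair;
its y and z axes spin with the wheel (z up at wheel angle zero).  The frame
sensor's z axis is vertical.  Chair-level axes are roll (about the axle —
wheel spin, proportional to forward speed), pitch (lateral horizontal) and
yaw (vertical; positive = counter-clockwise from above, i.e. a left turn).
A `sensor_side` flag flips the conventions for left-wheel mounting.

Gyro units are degrees/second at every interface; internal trigonometry
converts to radians as needed.

## Kinematic reconstruction

**Gyro bias.** MEMS gyros carry a slowly varying offset.  Following the
standard stationary-period approach, the per-axis bias is the mean gyro
value over *periods of no motion*, defined as samples whose gyro magnitude
stays below 5 °/s over a full 0.5 s window centered on the sample
(morphological erosion of the below-threshold mask).  The erosion matters:
at the onset and tail of every speed ramp the wheel gyro passes through low
rates while the chair is already moving, and including those samples biases
the estimate by enough (~0.1 °/s) to visibly corrupt dead-reckoned headings
over a 20-minute trial.  Because the wheel sensor witnesses any translation
as a large spin rate while the frame gyro stays small during gentle
turning, the wheel-derived stationarity mask is reused when correcting the
frame stream.

**Speeds.** Wheel-contact speed is v_wheel = ω_roll · r with r the wheel
radius.  Chair-center speed subtracts the turn differential,
v = v_wheel − s · Ω · w/2, where Ω is the yaw rate (rad/s), w the track
width and s = +1 when the sensed wheel runs on the outside of a positive
(left) turn, as a right-wheel sensor does.  Speed is signed; reverse
driving is legal (one simulated propulsion style drives backward by foot)
and segmentation uses |v|.

**Yaw.**  With the frame sensor (configuration S2, the "full" setup) the
yaw rate is simply the frame gyro's vertical component.  With the wheel
sensor alone (S1, the "wheel" setup) the spinning sensor's gyro must be
split into wheel spin and chair rotation.  The wheel angle θ is tracked by
a complementary attitude filter: gyro-x integration, corrected each sample
toward the gravity direction observed in the y–z accelerometer plane,
θ ← θ_g + k · wrap(atan2(a_y, a_z) − θ_g), with gain k = 0.02 per sample at
50 Hz (≈1 s time constant — drift-free θ with negligible lag at push
cadence).  Chair yaw and pitch then come from rotating the y/z gyro
components back through θ:

    yaw   =  g_y sin θ + g_z cos θ
    pitch = −g_y cos θ + g_z sin θ

Samples with near-free-fall acceleration (‖a‖ < 2 m/s²) hold the gyro-only
integration, since the gravity direction is unobservable there.  Camber is
assumed zero, so pitch ≈ 0 on flat ground and is retained only as a series.

**Derivatives.**  Linear and angular accelerations use a zero-phase
second-order Butterworth low-pass at 6 Hz (applied forward–backward) before
central differences.  Propulsion content sits below ~3 Hz; the filter
suppresses quantization and white noise while attenuating a 1 Hz component
by well under 2 %.  Series shorter than the filter warm-up (9 samples) fall
back to raw differences.

**Path.**  Heading integrates the yaw rate (trapezoid rule, ψ(0) = 0);
positions integrate v·cos ψ and v·sin ψ, also trapezoidal.  At 50 Hz and
wheelchair speeds the trapezoid rule closes a 20 s full circle to ~10⁻⁴ m,
comfortably inside the 10⁻² m contract; plain first-order Euler was
rejected because its O(h) drift is of the same order as that tolerance.

## Segmentation and labeling

A *segment* is a maximal run of samples with |v| > 0.1 m/s lasting at least
2 s (both comparisons strict; duration measured between the first and last
qualifying timestamps).  Shorter runs are discarded.  Labels come from the
supervisor's (or simulator's) timed annotation track by majority time
overlap; exact ties and uncovered segments become `unknown` and are
excluded from training.  Annotation gaps are legal and mean "unknown".

## Features

Each labeled segment maps to exactly 56 named predictors:

* **derived block** (8 series × 4 aggregates = 32): the one-sided FFT
  amplitude spectrum of chair speed (mean removed, amplitudes 2|c|/N, DC
  excluded — aggregating the spectrum keeps the predictor count independent
  of segment length), the linear acceleration, and the angular velocities
  and accelerations about roll/pitch/yaw;
* **raw block** (6 series × 4 aggregates = 24): the three raw gyro channels
  of the configuration's own sensor (wheel for S1, frame for S2, after
  offset correction) and their 6 Hz-filtered derivatives.

The aggregates are, in fixed order: median, standard deviation (population,
n denominator), moment skewness g₁ and excess kurtosis g₂; a constant
series aggregates to (value, 0, 0, 0).  The moment-based definitions are
fixed for reproducibility.  S1 and S2 share all 56 column names; only the
signal origin of the raw block (and the yaw source of the derived block)
differs.

**Pruning.**  Multicollinear predictors are removed once, on the full
feature matrix before any train/test split: zero-variance columns first,
then a greedy scan in canonical column order keeps a column iff its
absolute Pearson correlation with every already-kept column is ≤ 0.7
(strict exceedance drops).  Computing this before splitting mirrors the
upstream protocol but technically leaks a whisper of test-set information
into the column choice; the effect is negligible for a correlation screen
but is flagged here for honesty.

## Classification protocol

Stratified 80/20 split on (label × diagnosis) strata (each stratum
contributes round(n·0.2), at least 1, test rows — deterministic given the
seed).  On the training set, five classifier families at library defaults —
logistic regression and RBF-SVM (each behind a standard scaler), random
forest, Gaussian naive Bayes, and XGBoost gradient-boosted trees — are
scored by mean F1 over stratified 10-fold CV; the winner is refit on the
full training set and evaluated on the held-out 20 %.  The whole procedure
repeats over 25 independent random splits (reducible for quick runs) and
metrics are averaged arithmetically.

Metrics use active = 1 as the positive class (configurable; the choice is
not forced by the data since class balance is near-even): accuracy,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean.
Zero-denominator ratios are defined as 0.

Feature importance is the gain-based importance of an XGBoost model fit on
all the data with the pruned predictor set, normalized to sum to 1, each
predictor annotated with the sign of its Pearson correlation with the
target.

## The synthetic cohort

No public recordings of the target protocol exist, so validation rests on
a physics-based simulator whose rendering is the exact inverse of the
reconstruction: wheel spin from forward speed, yaw rotated through the
wheel angle into the spinning sensor's y/z gyro, gravity rotating in the
sensor's y–z accelerometer plane plus tangential and centripetal hub
accelerations, the frame sensor reading yaw directly — then white noise
(gyro 0.5 °/s, accel 0.05 m/s², typical MEMS figures) and a constant
per-trial gyro bias drawn uniformly within ±2 °/s per axis.

Each of 24 simulated participants (11 stroke / 13 amputation) performs the
semi-structured protocol — 9 m slow, 9 m normal, 9 m slalom, 9 m with two
near-standstills, each both self-propelled and attendant-pushed — followed
by free movement (≈16 active and ≈12 passive bouts of 4–16 s).  Active
propulsion oscillates speed at push cadence (~1 Hz, fraction ~0.25 of mean
speed with per-cycle jitter) with yaw jitter ~6 °/s; one-hand-one-foot
users add push-locked yaw wobble, one foot-propelling amputee drives
backward.  Attendant pushing is smoother (oscillation ~0.05 from gait
bounce, 0.3 Hz sway) and faster: self-propulsion means are ~0.56 m/s
(stroke) and ~0.68 m/s (amputation) while attendants push ~1.15 m/s with
wide between-attendant spread, so the class speed distributions overlap and
speed alone does not decide the label.  These defaults were fixed to the
study regime being emulated — ≈950 segments per cohort, ≈55 % active,
mostly under 20 s, cohort moving-time mean speed ≈0.75 m/s — and are not
tuning knobs.

A null switch (`distinguishable=False`) gives attendant bouts the
participant's own style parameters, removing all class signal; benchmark F1
then collapses into the chance band between the prevalence p and the
majority-vote value 2p/(1+p), confirming that performance is signal-driven
rather than leaked.

### What the synthetic validation does not show

The simulator is planar and slip-free, uses a single wheelchair geometry
and smooth surfaces, renders annotations with exact timing, and draws
styles from simple parametric families.  Real recordings add surface
texture, wheel slip, camber, hand-timed annotation error and richer
behavioral variability, all of which blur the classes.  Benchmark scores on
the synthetic cohort (mean F1 ≈ 0.99 for both configurations) are therefore
an upper bound demonstrating pipeline correctness, not a claim about field
accuracy — on real rehabilitation data this class of method reports F1 in
the 0.8–0.9 range, with the two-sensor setup slightly ahead of the
wheel-only one, an ordering the synthetic benchmark preserves.

## Numerical conventions and degenerate inputs

* Timestamps strictly increasing; synchronization linearly interpolates the
  frame stream onto the wheel clock over their overlap (≥ 2 s required) and
  is idempotent.  Sensors are assumed hardware-synchronized; no
  cross-correlation alignment is attempted.
* A stream with no qualifying stationary period is returned uncorrected
  with a warning rather than rejected.
* Segments entirely inside annotation gaps, and exact coverage ties, are
  `unknown` and never trained on.
* Greedy pruning ties are resolved by the canonical column order (derived
  block before raw block, aggregates innermost).
* Model-selection ties resolve toward the earlier family in the fixed
  family order, making reports bit-reproducible given (data, seed,
  n_splits); all estimators run single-threaded with seeded RNGs.
* All randomness descends from one root seed via named `SeedSequence`
  substreams (simulator / splits / CV / importance).

## Problem sizes

Default validation runs use the full 24-participant cohort (~470 s per
trial at 50 Hz, ≈960 segments).  The repeated-split benchmark uses 25
splits in the reproduction script and 5 splits in the test suite; both
sizes give split-to-split F1 standard errors well below the margins being
checked.
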