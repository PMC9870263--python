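# Methods

## The single-axis-rotation joint model

The model assumes the three sensors (sacrum, thigh, shank) are mounted
with their longitudinal (x) axes parallel to each other and to the limb
segments, so that sagittal-plane segment rotation appears as sensor
roll. Under that assumption the joint angles are pure differences:

    knee = roll_thigh − roll_shank        hip = roll_sacrum − roll_thigh

Flexion is positive. Because published descriptions of this model state
the hip difference in both operand orders, the implementation fixes
hip = sacrum − thigh and exposes `flip_hip_sign` / `flip_knee_sign`
flags rather than silently reconciling; flipping negates the series.

Roll is the third angle of an intrinsic Euler sequence ending in x
(default Z-Y-X, configurable to Y-Z-X). For Z-Y-X it is evaluated in
closed form, `roll = atan2(2(wx + yz), 1 − 2(x² + y²))`, which is
algebraically independent of the heading (yaw) — the property that
keeps magnetometer disturbances out of the joint angles. Quaternions
must be unit-norm within 1e-6. Angles are degrees throughout the public
interface; unwrapping uses period-360 phase unwrapping, so outputs
differ from inputs by exact multiples of 360° and successive steps stay
below 180°.

**Gimbal proximity.** At pitch = ±90° roll and yaw are degenerate. The
guard triggers when `1 − |sin(pitch)| < 1e-9` (pitch within ~2.6e-3° of
±90°): a warning is emitted and roll is returned from the stabilized
form `2·atan2(x, w)`, which attributes the whole degenerate rotation to
roll (yaw taken as zero). Gait never approaches this configuration; the
behaviour exists so the function is total.

## Calibration (zeroing)

Offsets are the arithmetic means of the hip and knee angles over a
10-second standing trial, subtracted from all subsequent series. An
optional `(start_s, end_s)` window restricts the average to exclude
postural sway at the trial edges; the default uses the full trial, since
the longer average already suppresses zero-mean sway. Sensor-derived
series are always zeroed before validation; the reference is compared
both raw and zeroed (the "raw" and "zeroed" variants in all outputs),
which separates constant frame offsets from genuine spread.
Zeroing an already-zeroed series raises rather than no-ops.

## Time alignment

Integer-sample lags only (both systems sample at the same 60 Hz; no
claim is made below one sample period). For each candidate lag in
±`max_lag_s` (default 5 s) the Pearson correlation of the overlapping
segments is computed after per-overlap mean removal; the reported peak
is therefore in [−1, 1] and constant offsets cannot bias the lag.
Ties resolve to the smallest |lag|, then to the negative lag, so exactly
periodic inputs behave deterministically. All-constant input is a
degenerate-input error. One lag per participant-trial is estimated on
the knee signal (the larger excursion) and applied to both joints;
`alignment_joint="per_joint"` switches to independent lags.

## Agreement statistics

`Sd` is the sample (n−1) standard deviation — standard Bland–Altman
practice. `RPC = 1.96·Sd`; `ULA/LLA = Mdif ± RPC`. The regression is
ordinary least squares of the reference on the sensor signal, so a knee
slope below one reads as the sensor overestimating flexion rates; the
orientation is switchable (`regression_predictor`). Metrics are
computed per participant / joint / timepoint / variant and then averaged
across participants for the cohort table; pooling all participants'
aligned samples into a single Bland–Altman/regression is a separate mode
(both are reported). Timepoint comparisons are two-tailed paired
t-tests on the per-participant values of each of the nine metrics, at
α = 0.05, with no multiple-testing correction. When the paired
differences have zero variance the t statistic is undefined; by
convention p = 1 if the mean difference is also zero, else p = 0, with a
warning — this keeps the noise-free end-to-end checks deterministic.

## The synthetic-data generator

The simulator emulates the study's session structure: per participant a
10-s standing calibration, then 20-s walking segments at T1 and T2,
60 Hz, 20 participants by default (1,200 samples per joint per segment;
24,000 pooled across the default cohort).

*Ground truth.* Hip and knee flexion are harmonic sums over the gait
cycle — hip `20·cos(phase) + 10°`, knee a two-harmonic shape with a
small stance wave and a swing peak near 60° — clamped to physiological
ranges (hip [−30°, 60°], knee [−5°, 90°]). Cycle duration is ~1.1 s
with a 3% coefficient-of-variation per-cycle jitter, matching typical
step-time variability; the jitter also makes the cross-correlation peak
unique despite the near-periodicity. Per-participant profiles draw
cycle duration, amplitudes and baselines from modest uniform ranges.
Segment rolls are solved exactly from the truth (sacrum = a small ±2°
pelvis roll; thigh = sacrum − hip; shank = thigh − knee), so with zero
noise the whole chain — rolls → quaternions → extraction → differences →
zeroing — reproduces the truth to floating-point precision.

*Sensor corruption* (all per-sensor, reproducible from one seed via
`default_rng([seed, participant, stream, timepoint])`):
constant mounting offsets (~N(0, 3°) per sensor; removed by zeroing),
white noise (0.2–0.5° sd), linear drift (0–0.2°/min), and a
soft-tissue artifact — the adjacent joint's mean-removed excursion,
low-pass filtered at 3 Hz, scaled by a 2–6% gain — applied to the
muscle-mounted thigh and shank sensors only, since the sacrum sensor
sits over bone. At T2 an attachment-degradation offset (~N(2.5°, 1°))
is added to the thigh sensor after calibration, emulating tape
loosening over the ~41-minute treadmill protocol (four 8-minute bouts
alternating with three 3-minute rests); this moves the knee bias and
intercept while leaving slope and r² stable.

*Reference.* The camera-like streams are truth plus 0.3° white noise
and optional per-joint constant frame offsets (~N(0, 1.5°)), which the
zeroed variant removes. The reference extends a 2-s pad before and
after the sensor window, so after recovering the injected integer lag
(drawn in ±0.5 s by default) the full 20-s window overlaps — the
cross-correlation lag equals `injected_lag − lead_samples`, and both
values are recorded in the manifest for recovery tests.

*What the simulator does not model*, and hence what passing tests do not
show about real data: marker-model kinematics and their own soft-tissue
errors, non-parallel sensor mounting (axis misalignment beyond a
constant roll offset), magnetometer disturbance, sub-sample clock skew,
nonstationary gait (fatigue, speed changes), and any frontal/transverse
coupling. Agreement numbers from the simulator characterize the
pipeline's correctness and sensitivity, not the field accuracy of a
physical sensor system.

## Numerical conventions and problem sizes

Tolerances: unit-quaternion check 1e-6; exact-invertibility assertions
1e-9°; statistical oracle comparisons 1e-9 relative. Report JSON
rounds floats to 6 decimals and sorts keys, making repeated runs
byte-identical. Test and example problem sizes follow the study
protocol (20 × 20 s × 60 Hz cohorts) — small enough that the full suite
runs in seconds while still exercising every stage at protocol scale.

## Known limitations

Only sagittal hip and knee angles are produced; no gait-event detection
or cycle normalization is provided (the statistics operate on raw
aligned samples, as the validation design intends). Alignment assumes
equal sampling rates. The regression's `r²` on near-noise-free
synthetic data saturates near 1, higher than typically observed with
real optical references.
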