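# Methods

This note records the models, parameter choices and numerical decisions
behind `wristacc`, and what the synthetic-data validation does and does not
establish about real recordings.

## Signal model of the synthetic generator

A free-living wrist recording is emulated as

    a(t) = clip( S ⊙ [ g(t) + σ_act(t)·w(t) + σ_n·ε(t) ] + b , ±range )

where `g(t)` is a unit gravity vector in a slowly rotating orientation,
`w(t)` is band-limited Gaussian activity noise with unit marginal SD,
`ε(t)` is white sensor noise, and `(S, b)` is a per-axis gain/offset
distortion emulating miscalibration. Components:

- **Orientation.** Azimuth advances at the drift rate (default 0.5°/min);
  elevation oscillates over ±60° with a 6-h period. Wear orientation is
  therefore continuous and visits much of the sphere over a day, which is
  what gives the autocalibration sphere coverage from real stillness (sleep).
  Non-wear episodes use one fixed random orientation each. The path is
  evaluated on a 10-s grid and linearly interpolated (rotation ≪ grid rate).
- **Activity amplitude from a target ENMO.** For isotropic Gaussian noise of
  per-axis SD σ added to unit gravity, the vector norm R has the exact 3-D
  Rician-type density
  f(r) = r/(σ√(2π)) [exp(−(r−1)²/2σ²) − exp(−(r+1)²/2σ²)],
  so E[(R−1)⁺] is a 1-D quadrature. Given a segment's target mean ENMO, the
  total σ is found by root bracketing and the sensor-noise contribution is
  subtracted in quadrature. Band-limiting (order-1 Butterworth band-pass,
  0.25–3 Hz, renormalised to unit marginal SD) leaves the Gaussian marginal —
  hence the expectation — unchanged while giving human-movement-like
  autocorrelation. Validated against Monte Carlo to < 1% and, in tests,
  against generated segments (5-min means within 10% of target on every
  seeded run).
- **Default daily schedule** (all targets configurable): sleep 23:00–07:00
  at 3 mg, daytime rest at 15 mg, light activity 07:00–08:00 and 21:00–23:00
  at 30 mg, one continuous MVPA block (default 17:00, 30 min, 200 mg).
  These place overall volume and MVPA in the range wrist studies report for
  adults. Sensor noise default 2 mg SD per axis.
- **Sleep micro-movements.** A 30-s burst of extra white noise (per-axis SD
  40 mg) every 20 min guarantees every 60-min window within sleep contains a
  burst, so sleep can never satisfy the non-wear range criterion — matching
  the protocol's intent that the long window keeps sleep out of non-wear.
- **Transport.** The first 2 h of day 0 and last 2 h of the final day are
  intermittent low-amplitude motion (60 s on / 120 s off at 30 mg),
  emulating the device in transit; these lie inside the 10 h/20 h boundary
  exclusion and are recorded in the ground truth.
- **Determinism.** All randomness flows from one `numpy` Generator seeded by
  the schedule; identical inputs give bit-identical recordings. Samples are
  float32 (device resolution is ~milli-g; single precision is generous);
  tests needing 1e-12 arithmetic build float64 recordings directly.

## Autocalibration

Stationary 10-s windows (per-axis SD < 13 mg on all three axes — the window
length is not dictated by the protocol; 13 mg mirrors the non-wear criterion
for internal consistency) provide mean vectors that should lie on the unit
sphere. The fit alternates projecting corrected means onto the sphere with
per-axis least squares of the projections on the raw means, to 1e-9
objective tolerance (max 1000 iterations; convergence is typically < 50).
Calibration error is the mean absolute deviation of stationary norms from
1 g. The correction is only applied when each axis attains values < −0.3 g
and > +0.3 g among stationary means (otherwise gains and offsets are
confounded with orientation) and when it does not increase the error on its
own evaluation set; the < 0.02 g file gate uses the post-fit error either
way. Calibration is per recording; no temperature term is modelled.

## Epochs, statuses and order of operations

Epochs (5 s) are aligned to the wall clock, not the recording start, so
identical clock slots on different days coincide — the property the
imputation rule needs. Trailing partial epochs, and epochs with < 50%
sample coverage, are `missing`. Status assignment is ordered: clipping
(any axis > 95% of range sustained ≥ 10 s — the protocol does not quantify
"sustained abnormally high", both numbers are configurable), then boundary
exclusion (measured from the first/last sample of the file, since the
excluded periods reflect handling logistics, not detected wear), then
non-wear, then imputation. Epoch durations by status always tile the
recording span.

## Non-wear semantics

The criterion is evaluated on the raw per-axis signal (SD < 13 mg and range
< 50 mg on ≥ 2 of 3 axes) over 60-min windows at every 15-min grid
position; a 15-min block is non-wear iff at least one qualifying window
covers it. This union-of-windows reading (rather than classifying each
block only by the single window centred on it) is what makes episode
recovery sharp: for an episode of at least 1 h, every fully-interior window
qualifies and the detected region matches the episode to within one
boundary block per edge, which is the resolution the windowing permits. A
centred-window-only rule blurs two blocks per edge and cannot reach the
≥ 0.95 block recall the tests demand on 2–8 h episodes. Windows truncated
by the file edges are evaluated when ≥ 30 min remains; blocks no evaluable
window covers are `unknown` and treated as worn but never imputed from.
Sub-block (7.5-min) moments are pooled exactly (parallel-variance formula),
so the implementation is linear-time and matches a brute-force oracle
bit-for-bit.

## Validity and imputation

File validity = calibration gate ∧ every one of the 96 15-min clock slots
holds ≥ 1 valid epoch on some day (coverage may be scattered over days).
"Valid day" is not defined by the protocol beyond requiring at least two;
here it is a calendar day with ≥ 16 h of valid wear (a conventional
threshold, configurable), used for participant inclusion, not for the file
gate — so a file can be valid while no single day is (complementary
half-days), which the tests pin. Imputation replaces each invalid epoch by
the mean of valid epochs at the same seconds-of-day on other days, falling
back to the enclosing 15-min slot mean (guaranteed non-empty by file
validity). Exact-slot first is the strictest reading of "similar
time-of-day data points". Imputation precedes all summaries, is idempotent,
and never touches valid epochs; originals are kept for audit.

## MVPA bouts

With L epochs per window (60 or 120), a window starting at i qualifies iff
epoch i ≥ 100 mg and ≥ ⌈0.8·(L−1)⌉ of the following L−1 epochs are ≥ 100 mg
(ceiling computed with a 1e-9 guard so exactly-representable products are
not pushed up). MVPA time counts each **above-threshold** epoch lying in at
least one qualifying window, once. Counting the below-threshold tolerance
epochs as MVPA would inflate a 30-min continuous block to ~31.9 min (every
trailing window that still satisfies 80% drags in sub-threshold epochs);
restricting to above-threshold epochs makes a continuous block of k
minutes score exactly k minutes, which is the behaviour the validation
pins. A greedy non-overlapping mode (`bout_mode="greedy"`) is available;
union is the default and the non-double-counting reading of "time spent".
Raising the threshold provably never increases MVPA time.

## Cohort statistics

Descriptive tables only: per-stratum n, mean and normal-approximation 95%
CI (z = Φ⁻¹(0.975)); guideline compliance with a binomial normal CI. The
stratified tables cover cohort × sex, SES quintile within cohort × sex,
weight status within cohort × sex, and both bout lengths per stratum. The
unstratified mean equals the n-weighted stratum mean exactly. Inferential
tests are deliberately out of scope.

Effect-recovery validation operates at the person-summary level:
`simulate_cohort` plants a +10 mg male effect and a linear SES gradient
(6 mg per quintile, person-level SD 12 mg, 100 persons per
cohort × sex × quintile stratum) and the tables must recover sign and
ordering in ≥ 95% of 50 replicates. These effect sizes are chosen so that
adjacent strata differ by ≳ 3.5 standard errors; the raw-signal path is
validated separately, so coupling the two would only re-test the generator.

## Problem sizes and limitations

Validation uses 5-day recordings at 85.7 Hz (≈ 37 M samples each): 20
recordings for non-wear recovery, 50 distortion draws (200 stationary means
each) for calibration, 1000 random epoch sequences (≤ 2880 epochs) for bout
equivalence, and 50 cohort replicates — sizes at which each property is
measured tightly while the whole suite stays comfortably runnable on one
CPU.

The generator emulates first- and second-moment structure, orientation
drift, and the protocol's artefacts (non-wear, transport, miscalibration),
not real human movement: no gait harmonics, no heteroscedastic bursts of
daily living, no temperature drift, no device-specific analog filtering.
Passing tests therefore demonstrate that the pipeline implements its
definitions exactly and recovers planted structure under realistic noise —
not that any particular cohort's numbers would be reproduced. Sleep is not
detected (only protected from non-wear misclassification), sedentary time
is not estimated, and no MET conversion is applied.
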