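# Methods

This note records the models, parameter choices and numerical decisions
behind `accelband`, in the package's own terms. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Count chains

**Legacy chain** (`ag_original`): 8th-order Butterworth anti-alias
low-pass at 5 Hz (the exact anti-alias stage of the original hardware is
not public; 5 Hz is half the internal Nyquist and is documented here as
this package's choice) → 4th-order Butterworth band-pass with half-power
edges 0.29/1.63 Hz → decimation from 30 Hz to the 10 Hz internal rate →
truncation at ±2.13 g → rectification → dead-band at 0.068 g (the value
used in the count-replication literature) → per-sample quantization
`floor(|x|·10³ / 16.640625)` → per-epoch summation. The mean-mg variant
runs the same chain without quantization and reports the epoch mean of
the rectified signal ×10³.

**Modified chains** (`bp4hz`, `bp10hz`, `hp_only`): 4th-order Butterworth
band-pass (high-pass only for `hp_only`) at the device rate, with no
anti-alias stage and no decimation; truncation at ±6 g only for
calibration data recorded at a wider dynamic range; identical
quantization; internal rate 30 Hz. "4th order" counts poles of the
band-pass (scipy `butter(2, [lo, hi], "bandpass")`); the tenth-order
sub-band filters are `butter(5, ...)` band-passes and a `butter(10, ...)`
high-pass.

Counts convert to mean acceleration by r/(b·f·e) with r = 4260 mg,
b = 256, f the internal rate and e the epoch length; because
quantization floors each sample, counts·r/(b·f·e) underestimates the
mean-mg output by at most one count quantum (16.64 mg) per sample —
a bound the tests check empirically.

Filtering is causal single-pass (`sosfilt`, zero initial conditions),
matching a real-time device chain; startup transients are not trimmed.
All designs are realized as second-order sections and verified stable;
realized half-power frequencies are measured from the magnitude response
on a 200 001-point grid and must sit within 2% of their nominal edges.

## Synthetic gait and free-living data

The generator reproduces the statistical structure the analysis assumes,
not biomechanics:

- **Harmonic stack.** Locomotion at speed v (km/h) is a sum of
  sinusoids at k·f_step with amplitudes a₁/k, a₁ = 0.045·v^1.5 g, capped
  at 10 Hz with the top harmonic amplitude tapered linearly so total
  power varies continuously with cadence. Step frequency is
  1.2 + 0.16·v Hz for adults, ×1.15 for children. Power splits across
  (vertical, AP, ML) axes as (0.6, 0.25, 0.15).
- **Stride component.** A component at f_step/2 (left–right asymmetry),
  amplitude 0.3·a₁, with a slow Brownian phase drift (~0.8 rad/√s):
  asymmetry is not steady in real gait. This component lies inside the
  legacy band even at running cadence and is the main reason real legacy
  counts keep growing with running speed.
- **Impact continuum.** Band-limited noise at 6–14 Hz, RMS 0.35·a₁,
  emulating heel-strike transients. The band is fixed in hertz so lab
  recordings (100 Hz) and free-living recordings (30 Hz) carry the same
  content. This is the content that separates the 10 Hz low-pass from
  the pure high-pass.
- **Cadence wander.** Instantaneous step frequency follows an
  Ornstein–Uhlenbeck process (3% CV, 2 s correlation time); all
  harmonics stay locked to the common phase track.
- **Sensor noise** white Gaussian, σ = 0.01 g per axis; samples are
  clipped to the configured dynamic range. An optional >10 Hz sinusoidal
  contaminant (e.g. vehicle vibration) exists and is off by default; its
  amplitude has no empirical anchor.
- **Energy expenditure.** METs(v) = 1 + k·(v/3)^1.9 with k = 1.0
  (adults) and 0.9 (children — higher RMR lowers their MET value at
  equal speed), giving compendium-like values (≈2 METs at 3 km/h,
  ≈3.6 at 5 km/h, >9 at 10 km/h for both groups). Breath-by-breath VO₂
  is RMR·METs with first-order onset kinetics (τ = 30 s) at 0.3 Hz
  breathing; the lab protocol is 20 min seated rest then 4-min stages at
  3/4/5/6/8/10 km/h.
- **Cohort structure.** Calibration uses ten subjects per age group (the
  lab-protocol group size) with log-normal between-subject variability:
  CV 0.10 on output amplitude, 0.05 on RMR and on the MET increment
  (gait economy). "Noise-free" settings switch off measurement noise
  while keeping the harmonic phases random — the rectified mean of a
  harmonic stack depends on the phase realization at the ±1–2% level,
  which is why group-level quantities pool subjects.
- **Free-living weeks.** Per day: non-wear until 06:30 and after 22:30
  (idle status flag, flat 1 g signal — non-wear is a status, not a
  signal property), rest bouts of 10–45 min interleaved with walking
  (2.5–6.5 km/h) and running (7–10.5 km/h) bouts; children run more
  often. Bouts carry log-normal amplitude variability (CV 0.20), cadence
  offsets (SD 0.4 Hz) and log-normal stride/impact content variability
  (CV 0.35): free-living movement is spectrally diverse across
  activities, and that diversity — not sensor noise — is what decouples
  the narrow and wide filters at high intensity. Ground-truth labels per
  bout come from the subject's MET curve and the 1.5/3/6/9 scheme.

What the generator does **not** model: soft-tissue artifact, posture
transitions, non-locomotor activity types, device orientation error, and
any literal biomechanics. Passing tests demonstrate that the processing
chain behaves correctly on signals with the assumed spectral structure;
they are not evidence about any particular real cohort.

## Calibration

RMR is the minimum of the 2-min centered moving average over the resting
segment, with half-window edges excluded so partial windows cannot fake
a minimum. Each stage contributes the half-open minute [2:45, 3:45):
METs = window-mean VO₂ / RMR (window-mean first, then divide — the
alternative breath-level division is indistinguishable in the source
description); acceleration is the mean mg over the same minute and the
window's counts rescaled to one minute.

The acceleration→METs curve is a cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) with a forced starting point
at (0 mg, 1 MET), realized as a pseudo-observation with 10⁶ times the
data weight (|curve(0) − 1| < 10⁻⁶ is asserted). The smoothing factor
p = 0.1 follows the convention p→0 least-squares line, p→1 interpolant,
with the unit-invariant penalty mapping

    lam = (1 − p)/p · (L/40)³ / 6,

where L is the fitted domain span: a de Boor-style balance at a fixed
reference resolution of 40 knots per domain. This keeps p meaningful
across units (mg vs counts·min⁻¹) and across replicate counts (7 clean
points vs 60 pooled subject-stages); the plain `lam = (1 − p)/p` mapping
(`lam_scale="raw"`) is near-interpolating at mg scale and makes
first-crossing cut-points ill-conditioned under within-stage scatter.

Cut-points are the *smallest* crossing of each MET threshold, located by
a 4001-point bracket scan plus Brent refinement — curvilinear fits can
wiggle at the extremes and the physiologically meaningful threshold is
the first attainment. Thresholds the curve never attains are reported
absent (the fitted curves plateau just above the highest stage METs, so
thresholds above ~10 METs are not meaningful). Counts-scale cut-points
derive from the mg cut-points through each variant's counts↔mg
conversion at a one-minute epoch. Age groups are fitted independently.

Known limitation: the legacy filter compresses running-speed output into
a narrow range, so inverting its curve at 6–9 METs is poorly conditioned
— exactly the saturation problem that motivates the wider filters. The
noise-free recovery check therefore compares the spline inverse against
the generator's known speed→output mapping (errors ≤0.5% at 3/6/9 METs
for every group × filter), while single-realization end-to-end recovery
carries the ±2–3% phase-realization floor described above.

## Free-living rules and summaries

An epoch is non-wear when more than 50% of its samples carry the idle
flag (threshold configurable). A calendar day is valid with ≥12 h wear,
counted over the full day; the 06:00–23:00 window is applied afterwards,
by epoch start time, half-open. Classification intervals are half-open
and lower-inclusive ([c₃, c₆) = MPA, etc.); counts cut-points calibrated
on one-minute aggregation scale linearly to shorter epochs (divide by
60/epoch) — no alternative rule is defined for sub-minute epochs.
Confusion charts are row-normalized over jointly included epochs with
the legacy filter as reference; empty rows are flagged, not silently
dropped. Intensity distributions are per-subject fractions of included
epochs, then averaged across subjects.

The sub-band histogram assigns each 3-s epoch to one of 41 bins of the
legacy-band output — forty 10 mg bins spanning 0–400 mg plus an
open-ended bin above 400 mg — and sums each band's output per bin.
Relative contributions (band/legacy) are emitted only for occupied bins;
at a 30 Hz device rate the >10 Hz band necessarily means 10 Hz–Nyquist.
In the lowest bin the legacy output is dominated by the dead-band floor,
so relative contributions there reflect the noise floor rather than
movement; comparisons across intensity should start above it.

## Problem sizes

Defaults were chosen as the package's own desk-scale study conditions:
calibration cohorts of 10 subjects per age group (the lab-protocol group
size); free-living simulation of 2 subjects per group × 7 days at 30 Hz
(the full cohort of several hundred subjects adds statistical precision
but no new mechanism); acceptance properties run on one simulated week
per group. One week at 30 Hz is ~18 M samples; the full four-variant,
four-band comparison runs in a few minutes on one core.
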