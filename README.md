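# accelband

Frequency-filter comparison for accelerometer-based physical-activity
measurement.

Waist-worn accelerometer studies overwhelmingly summarize raw acceleration
as **ActiGraph counts**: the signal is band-pass filtered between
half-power frequencies of 0.29 and 1.63 Hz, rectified, quantized and
summed over epochs. That narrow band discards most of the acceleration
produced by fast or high-cadence movement — human locomotion places energy
at frequencies up to ~10 Hz — so counts saturate at running intensities
and penalize high-cadence movers such as children. `accelband` implements
the full analysis chain needed to study this problem:

- **Count engine** — the legacy processing chain (anti-alias low-pass,
  0.29–1.63 Hz band-pass, decimation to a 10 Hz internal rate, ±2.13 g
  truncation, rectification, dead-band, 8-bit quantization, epoch
  summation) alongside modified fourth-order Butterworth band-pass
  variants with the low-pass edge widened to 4 Hz, 10 Hz, or removed
  (high-pass only). Output per axis and as vector magnitude, in integer
  counts or mean mg. Counts convert to mean acceleration via
  r/(b·f·e) = 4260 mg / (256 · 10 Hz · 60 s) = 0.0277 mg per count
  for the legacy chain (one count = 16.64 mg at one internal sample).
- **MET calibration** — breath-by-breath VO₂ → resting metabolic rate
  (minimum of a 2-min moving average over seated rest) → METs per
  treadmill stage (one minute starting 2:45 into each stage), paired with
  the same minute of acceleration output; an anchored cubic smoothing
  spline (smoothing factor 0.1, forced through 0 mg = 1 MET) maps
  acceleration to METs and is inverted at 1.5/3/6/9 METs to yield
  filter- and age-specific intensity cut-points (SED/LPA/MPA/VPA/VVPA).
- **Free-living comparison** — wear detection from the device idle flag,
  ≥12 h valid-day rule, 06:00–23:00 daily window, epoch classification at
  1/3/10/60 s, row-normalized confusion charts against the legacy filter,
  and time-in-intensity distributions.
- **Sub-band analysis** — decomposition into 0.29–1.63, 1.7–4, 4–10 and
  >10 Hz bands (tenth-order Butterworth for the three additional bands),
  aggregated over 41 reference-intensity bins (0–10 … 390–400, >400 mg)
  of the legacy-band 3-s output.
- **Synthetic data** — a gait-spectrum generator (step-frequency
  harmonics with 1/k roll-off, a stride-frequency asymmetry component,
  broadband heel-strike content, cadence wander), breath-by-breath VO₂
  with individual RMR, and free-living wear weeks with ground-truth
  intensity labels, so the whole chain is testable end to end.

The calibration spline and the epoch classifier follow scikit-learn
conventions (`fit`/`predict`, `get_params`), and the count chain is
exposed as a transform (`CountEngine(...).fit().transform(recording)`).

## Worked example

```python
from accelband import CountEngine, FilterSpec, design_filter
from accelband.synthetic import SubjectProfile, gen_locomotion_signal

resp = design_filter(FilterSpec.for_variant("bp10hz"), sample_rate_hz=30.0)
print("realized half-power edges (Hz):", [round(f, 3) for f in resp.realized_half_power_hz])

profile = SubjectProfile.default("adult")
model = profile.gait_model(speed_kmh=5.0, sample_rate_hz=30.0)
rec = gen_locomotion_signal(model, duration_s=120.0, sample_rate_hz=30.0,
                            seed=1, dynamic_range=6.0)
for variant in ("ag_original", "bp4hz", "bp10hz", "hp_only"):
    series = CountEngine(variant, epoch_length=60.0, unit="mg").fit().transform(rec)
    print(f"{variant:12s} mean filtered acceleration: {series.values[-1]:7.1f} mg")
```

```
realized half-power edges (Hz): [0.29, 10.0]
ag_original  mean filtered acceleration:   146.5 mg
bp4hz        mean filtered acceleration:   339.0 mg
bp10hz       mean filtered acceleration:   377.9 mg
hp_only      mean filtered acceleration:   388.4 mg
```

The same two minutes of 5 km/h walking register 146 mg under the legacy
band but 378 mg once the band extends to 10 Hz: the widened filters
recover the harmonic and impact content above 1.63 Hz that the legacy
chain discards. Calibrating each filter against energy expenditure on a
synthetic lab cohort (ten adults, treadmill stages at 3–6 km/h walking
and 8/10 km/h running) turns this into filter-specific cut-points in mg:

```python
from accelband.workflows import run_calibration_workflow
res = run_calibration_workflow({"seed": 0, "age_groups": ["adult"]})
print(res.table.pivot_table(index="filter", columns="met_level", values="mg").round(1))
```

```
met_level     1.5    3.0    6.0    9.0
filter
ag_original  18.6  116.6  200.1  253.9
bp10hz       69.6  290.6  575.3  839.3
bp4hz        61.3  262.1  502.7  720.9
hp_only      71.9  301.1  600.2  877.9
```

Cut-points grow with filter width at every MET level — a wider band
collects more acceleration at any given energy expenditure, so a higher
threshold marks the same intensity boundary.

## Command line

```bash
accelband simulate week.csv --kind freeliving --age-group child --seed 1
accelband counts week.csv epochs.csv --filter bp10 --epoch 3 --unit mg
accelband calibrate out/ --seed 0
accelband classify epochs.csv labels.csv --cutpoints out/cutpoints.csv --filter bp10
accelband subband week.csv hist.csv --epoch 3
accelband report out/ --seed 0        # full free-living comparison
```

All outputs are CSV with a provenance header (package version, config
hash, seed). Binary device formats are out of scope; `io.register_raw_reader`
accepts adapter callables for gt3x/CWA readers.

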