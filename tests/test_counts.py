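"""Count engine: rectified-mean chains, quantization, conversions, VM."""

import numpy as np
import pandas as pd
import pytest

from accelband.constants import MG_PER_COUNT, counts_to_mg_factor
from accelband.counts import (
    CountEngine,
    compute_counts,
    counts_to_mg,
    mean_filtered_mg,
    resample,
    vector_magnitude,
)
from accelband.filters import FilterSpec
from accelband.recording import EpochSeries, RawRecording

from conftest import tone_recording


def zero_recording(duration_s=60.0, rate=30.0):
    n = int(duration_s * rate)
    return RawRecording("2023-05-01", rate, np.zeros((n, 3)), dynamic_range=6.0)


@pytest.mark.parametrize("variant", ["ag_original", "bp4hz", "bp10hz", "hp_only"])
@pytest.mark.parametrize("unit", ["counts", "mg"])
def test_zero_input_gives_zero_output(variant, unit):
    series = CountEngine(variant, epoch_length=10.0, unit=unit).fit().transform(
        zero_recording()
    )
    assert np.all(series.values == 0)


@pytest.mark.parametrize("variant", ["ag_original", "bp10hz"])
def test_gravity_only_gives_zero_after_transient(variant):
    n = int(60 * 30)
    rec = RawRecording("2023-05-01", 30.0, np.tile([1.0, 0, 0], (n, 1)),
                       dynamic_range=6.0)
    series = CountEngine(variant, epoch_length=10.0, unit="counts").fit().transform(rec)
    # the high-pass kills DC; only the startup transient can register
    assert np.all(series.values[1:] == 0)


def test_in_band_tone_counts_larger_under_wide_filter():
    rec = tone_recording(2.0, 0.5, duration_s=120.0)
    wide = compute_counts(rec, FilterSpec.for_variant("bp10hz"), 60.0)[0]
    narrow = compute_counts(rec, FilterSpec.for_variant("ag_original"), 60.0)[0]
    assert wide.values[1] > narrow.values[1]


def test_full_wave_rectified_sine_mean():
    # a tone passed whole by the band has mean |x| = 2A/pi
    amp = 0.4
    rec = tone_recording(2.0, amp, duration_s=120.0)
    series = mean_filtered_mg(rec, FilterSpec.for_variant("bp10hz"), 60.0)[0]
    assert series.values[1] == pytest.approx(2 * amp / np.pi * 1e3, rel=0.05)


def test_counts_track_mg_within_quantization_bound(gait_recording):
    spec = FilterSpec.for_variant("bp10hz")
    counts = compute_counts(gait_recording, spec, 10.0)
    mgs = mean_filtered_mg(gait_recording, spec, 10.0)
    for c, m in zip(counts, mgs):
        approx = c.values * counts_to_mg_factor(c.internal_rate, c.epoch_length)
        # per-sample floor quantization loses at most one count quantum
        assert np.all(approx <= m.values + 1e-9)
        assert np.all(m.values - approx <= MG_PER_COUNT + 1e-9)


def test_amplitude_linearity():
    spec = FilterSpec.for_variant("bp10hz")
    a = mean_filtered_mg(tone_recording(2.0, 0.2, 120.0), spec, 60.0)[0].values[1]
    b = mean_filtered_mg(tone_recording(2.0, 0.4, 120.0), spec, 60.0)[0].values[1]
    assert b == pytest.approx(2 * a, rel=0.01)


def test_brute_force_rectified_mean_oracle_equivalence():
    # tone fully inside the pass band: counts agree with the closed-form
    # rectified-mean 2A/pi within the per-sample quantization bound
    amp = 0.5
    rec = tone_recording(1.5, amp, duration_s=120.0, gravity=False)
    counts = compute_counts(rec, FilterSpec.for_variant("bp10hz"), 60.0)[0]
    approx_mg = counts.values[1] * counts_to_mg_factor(30.0, 60.0)
    oracle_mg = 2 * amp / np.pi * 1e3
    assert approx_mg <= oracle_mg * 1.02
    assert oracle_mg - approx_mg <= MG_PER_COUNT + 0.02 * oracle_mg


def test_filter_width_monotonicity_on_gait_signal(adult_profile):
    # expected epoch output grows with the analysis band; averaged over
    # several phase realizations to suppress rectified-mean interference
    from accelband.synthetic import gen_locomotion_signal

    means = {}
    for variant in ["ag_original", "bp4hz", "bp10hz", "hp_only"]:
        vals = []
        for seed in range(6):
            model = adult_profile.gait_model(6.0, 30.0)
            rec = gen_locomotion_signal(model, 90.0, 30.0, seed, dynamic_range=6.0)
            s = CountEngine(variant, 60.0, "mg").fit().transform(rec)
            vals.append(s.values[-1])
        means[variant] = np.mean(vals)
    assert means["ag_original"] < means["bp4hz"] < means["bp10hz"] < means["hp_only"]


def test_counts_to_mg_conversion_values():
    assert counts_to_mg(1000, 10.0, 60.0) == pytest.approx(27.7, abs=0.05)
    assert counts_to_mg(0, 10.0, 60.0) == 0.0
    # 1800 counts at the 30 Hz internal rate over 60 s: 1800 * 4260/(256*30*60)
    assert counts_to_mg(1800, 30.0, 60.0) == pytest.approx(16.64, abs=0.01)
    with pytest.raises(ValueError):
        counts_to_mg(-1, 10.0, 60.0)
    with pytest.raises(ValueError):
        counts_to_mg(10, 0.0, 60.0)


def test_vector_magnitude():
    def es(vals):
        return EpochSeries("2023-05-01", 60.0, vals, "counts", "vertical",
                           "bp10hz", 30.0)

    x, y, z = es([3.0, 1.0]), es([4.0, 1.0]), es([0.0, 1.0])
    vm = vector_magnitude(x, y, z)
    assert vm.values[0] == pytest.approx(5.0)
    assert np.all(vm.values >= np.maximum.reduce([x.values, y.values, z.values]))
    one_axis = vector_magnitude(es([7.0, 2.0]), es([0.0, 0.0]), es([0.0, 0.0]))
    assert np.allclose(one_axis.values, [7.0, 2.0])
    with pytest.raises(ValueError, match="grids"):
        vector_magnitude(x, y, es([1.0, 2.0, 3.0]))


def test_resample_preserves_in_band_tone():
    rec = tone_recording(2.0, 0.5, duration_s=60.0, rate_hz=100.0, gravity=False)
    out = resample(rec, 30.0)
    assert out.sample_rate == 30.0
    # compare steady-state amplitude
    peak_in = np.abs(rec.samples[500:-500, 0]).max()
    peak_out = np.abs(out.samples[150:-150, 0]).max()
    assert peak_out == pytest.approx(peak_in, rel=0.01)
    assert abs(out.duration_s - rec.duration_s) <= 1.0 / 30.0


def test_resample_suppresses_aliasing():
    rec = tone_recording(40.0, 0.5, duration_s=60.0, rate_hz=100.0, gravity=False)
    out = resample(rec, 30.0)
    assert np.mean(out.samples[:, 0] ** 2) < 0.01 * np.mean(rec.samples[:, 0] ** 2)


def test_resample_identity_and_upsampling_error():
    rec = tone_recording(2.0, 0.5)
    assert resample(rec, 30.0) is rec
    with pytest.raises(ValueError, match="upsampling"):
        resample(rec, 60.0)


def test_trailing_partial_epoch_dropped():
    rec = tone_recording(2.0, 0.5, duration_s=65.0)
    series = CountEngine("bp10hz", 60.0, "counts").fit().transform(rec)
    assert len(series) == 1


def test_idle_samples_contribute_zero():
    rec = tone_recording(2.0, 0.5, duration_s=60.0)
    rec.status[:] = 1  # all idle
    series = CountEngine("bp10hz", 10.0, "counts").fit().transform(rec)
    assert np.all(series.values == 0)


def test_engine_sklearn_params_roundtrip():
    eng = CountEngine("bp4hz", epoch_length=10.0, unit="counts")
    params = eng.get_params()
    eng2 = CountEngine(**params)
    assert eng2.get_params() == params
    with pytest.raises(ValueError):
        CountEngine("bogus").fit()
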