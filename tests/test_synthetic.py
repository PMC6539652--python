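"""Synthetic-data generator: spectra, determinism, ground-truth plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from accelband.constants import DEFAULT_SCHEME
from accelband.freeliving import derive_wear_mask, filter_valid_days
from accelband.synthetic import (
    Bout,
    DaySchedule,
    GaitModel,
    SubjectProfile,
    build_week_schedule,
    gen_freeliving_recording,
    gen_locomotion_signal,
    gen_metabolic_trace,
    gen_rest_signal,
    truth_label_series,
)
from accelband.calibration import compute_rmr


def test_no_motion_model_gives_constant_gravity():
    model = GaitModel(step_frequency=1.0, harmonic_amplitudes=(0.0,), noise_sd=0.0)
    rec = gen_locomotion_signal(model, 10.0, 30.0, seed=0)
    assert np.allclose(rec.samples[:, 0], 1.0)
    assert np.allclose(rec.samples[:, 1:], 0.0)


def test_single_harmonic_psd_peaks_at_step_frequency():
    model = GaitModel(step_frequency=2.0, harmonic_amplitudes=(0.3,),
                      noise_sd=0.0, cadence_cv=0.0)
    rec = gen_locomotion_signal(model, 30.0, 30.0, seed=1)
    f, p = periodogram(rec.samples[:, 0] - 1.0, fs=30.0)
    assert f[np.argmax(p)] == pytest.approx(2.0, abs=f[1] - f[0])


def test_spectral_fidelity_with_cadence_wander():
    # >= 95% of non-DC power within +/-0.25 Hz of the harmonic
    model = GaitModel(step_frequency=2.0, harmonic_amplitudes=(0.3,), noise_sd=0.0)
    rec = gen_locomotion_signal(model, 60.0, 30.0, seed=2)
    f, p = periodogram(rec.samples[:, 0] - 1.0, fs=30.0)
    inband = (np.abs(f - 2.0) <= 0.25) & (f > 0)
    assert p[inband].sum() / p[f > 0].sum() >= 0.95


def test_determinism_equal_seeds():
    model = GaitModel(step_frequency=2.0, harmonic_amplitudes=(0.3, 0.15))
    a = gen_locomotion_signal(model, 10.0, 30.0, seed=5)
    b = gen_locomotion_signal(model, 10.0, 30.0, seed=5)
    assert np.array_equal(a.samples, b.samples)
    c = gen_locomotion_signal(model, 10.0, 30.0, seed=6)
    assert not np.array_equal(a.samples, c.samples)


def test_clipping_to_dynamic_range():
    model = GaitModel(step_frequency=2.0, harmonic_amplitudes=(20.0,), noise_sd=0.0)
    rec = gen_locomotion_signal(model, 5.0, 30.0, seed=0, dynamic_range=6.0)
    assert np.abs(rec.samples).max() <= 6.0


def test_nyquist_and_duration_validation():
    model = GaitModel(step_frequency=8.0, harmonic_amplitudes=(0.1, 0.05))
    with pytest.raises(ValueError, match="Nyquist"):
        gen_locomotion_signal(model, 5.0, 30.0, seed=0)
    with pytest.raises(ValueError, match="duration"):
        gen_locomotion_signal(GaitModel(1.0, (0.1,)), 0.0, 30.0, seed=0)


def test_gait_model_validation():
    with pytest.raises(ValueError):
        GaitModel(step_frequency=0.0, harmonic_amplitudes=(0.1,))
    with pytest.raises(ValueError):
        GaitModel(step_frequency=1.0, harmonic_amplitudes=(-0.1,))
    with pytest.raises(ValueError):
        GaitModel(1.0, (0.1,), axis_weights=(0.5, 0.5, 0.5))


def test_rest_signal_statistics():
    exact = gen_rest_signal(10.0, 30.0, noise_sd=0.0, seed=0)
    assert np.all(exact.samples[:, 0] == 1.0)
    noisy = gen_rest_signal(60.0, 30.0, noise_sd=0.005, seed=1)
    sd = noisy.samples[:, 0].std()
    assert 0.004 <= sd <= 0.006
    n = len(noisy)
    assert abs(noisy.samples[:, 0].mean() - 1.0) <= 3 * 0.005 / np.sqrt(n)


def test_metabolic_trace_rest_equals_rmr(adult_profile):
    trace = gen_metabolic_trace(adult_profile, noise_sd=0.0, seed=0)
    rest = trace.vo2[trace.times_s < 20 * 60]
    assert np.allclose(rest, adult_profile.rmr)


def test_metabolic_trace_steady_state_met(adult_profile):
    trace = gen_metabolic_trace(adult_profile, noise_sd=0.0, seed=0)
    # late in the 5 km/h stage (third stage) VO2/rmr reaches the curve value
    start = 20 * 60 + 2 * 240
    sel = (trace.times_s >= start + 200) & (trace.times_s < start + 240)
    met = trace.vo2[sel].mean() / adult_profile.rmr
    assert met == pytest.approx(float(adult_profile.met_at_speed(5.0)), rel=0.01)


def test_rmr_recovery_at_2pct_noise(adult_profile):
    trace = gen_metabolic_trace(
        adult_profile, noise_sd=0.02 * adult_profile.rmr, seed=3
    )
    rmr = compute_rmr(trace, rest_duration_s=20 * 60)
    assert rmr == pytest.approx(adult_profile.rmr, rel=0.02)


def test_empty_protocol_rejected(adult_profile):
    with pytest.raises(ValueError, match="protocol"):
        gen_metabolic_trace(adult_profile, protocol=())


def test_child_profile_encodes_age_differences(adult_profile, child_profile):
    v = np.linspace(2, 10, 9)
    assert np.all(child_profile.met_at_speed(v) < adult_profile.met_at_speed(v))
    for s in v:
        assert child_profile.step_freq_at_speed(s) > adult_profile.step_freq_at_speed(s)
    assert child_profile.rmr != adult_profile.rmr


def test_met_curve_monotone_and_invertible(adult_profile):
    v = np.linspace(0.1, 12, 50)
    m = adult_profile.met_at_speed(v)
    assert np.all(np.diff(m) > 0)
    for mets in (1.5, 3.0, 6.0, 9.0):
        assert adult_profile.met_at_speed(adult_profile.speed_at_met(mets)) == \
            pytest.approx(mets, rel=1e-9)


def _simple_day(wear_hours):
    d0 = pd.Timestamp("2023-05-01")
    bouts = [Bout(d0, 3600.0 * wear_hours, "rest")]
    rest = 24.0 - wear_hours
    bouts.append(Bout(d0 + pd.Timedelta(hours=wear_hours), 3600.0 * rest, "nonwear"))
    return DaySchedule(bouts)


@pytest.mark.parametrize("hours,valid", [(13, True), (11, False)])
def test_valid_day_rule_on_generated_day(hours, valid, adult_profile):
    rec, _ = gen_freeliving_recording(_simple_day(hours), adult_profile, seed=0)
    mask = derive_wear_mask(rec, 60.0)
    days = filter_valid_days(mask, min_wear_h=12.0)
    assert (len(days) == 1) is valid


def test_nonwear_fraction_matches_schedule(adult_profile):
    d0 = pd.Timestamp("2023-05-01")
    bouts = [
        Bout(d0, 2 * 3600.0, "rest"),
        Bout(d0 + pd.Timedelta(hours=2), 3600.0, "nonwear"),
        Bout(d0 + pd.Timedelta(hours=3), 3600.0, "rest"),
    ]
    rec, table = gen_freeliving_recording(DaySchedule(bouts), adult_profile, seed=0)
    mask = derive_wear_mask(rec, 60.0)
    n_nonwear = (~mask.wear).sum()
    scheduled = 3600 / 60
    assert abs(n_nonwear - scheduled) <= len(bouts)  # one epoch per boundary
    labels = truth_label_series(table, d0, 60.0, len(mask))
    assert (labels == "nonwear").sum() == n_nonwear


def test_overlapping_bouts_rejected():
    d0 = pd.Timestamp("2023-05-01")
    with pytest.raises(ValueError, match="overlap"):
        DaySchedule([Bout(d0, 3600.0, "rest"),
                     Bout(d0 + pd.Timedelta(minutes=30), 3600.0, "rest")])


def test_freeliving_truth_labels_follow_met_curve(adult_profile):
    d0 = pd.Timestamp("2023-05-01")
    speed = adult_profile.speed_at_met(5.0)  # squarely moderate
    bouts = [Bout(d0, 600.0, "rest"), Bout(d0 + pd.Timedelta(seconds=600), 600.0,
                                           "locomotion", speed)]
    _, table = gen_freeliving_recording(DaySchedule(bouts), adult_profile, seed=0)
    assert list(table.true_label) == ["SED", "MPA"]


def test_week_schedule_structure(adult_profile):
    sch = build_week_schedule(adult_profile, seed=0, n_days=2)
    df = sch.to_frame()
    assert df.start_time.is_monotonic_increasing
    # wear window is 16 h per day; overnight bouts are non-wear
    per_day = df.groupby(df.start_time.dt.date).apply(
        lambda d: d.loc[d.activity != "nonwear", "duration_s"].sum(), include_groups=False
    )
    assert np.all(per_day >= 12 * 3600)


def test_freeliving_determinism(adult_profile):
    sch = build_week_schedule(adult_profile, seed=3, n_days=1)
    a, _ = gen_freeliving_recording(sch, adult_profile, seed=11)
    b, _ = gen_freeliving_recording(sch, adult_profile, seed=11)
    assert np.array_equal(a.samples, b.samples)
    assert np.array_equal(a.status, b.status)
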