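"""Synthetic raw acceleration, breath-by-breath VO2 and free-living schedules.

The generator emulates the statistical structure the analysis chain
assumes rather than biomechanics: locomotion is a harmonic series at the
step frequency with a 1/k amplitude roll-off (so acceleration content
extends to ~10 Hz and widening the analysis band strictly increases
captured power), riding on a 1 g gravity baseline plus white sensor noise.
Step frequency rises with speed and is higher in children; the speed->MET
curve is monotone and curvilinear, with children reaching lower MET values
at equal speed because of their higher resting metabolic rate.

All randomness flows through a caller-supplied seed; equal seeds give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_SCHEME, IntensityScheme
from .recording import STATUS_ACTIVE, STATUS_IDLE, RawRecording

#: ceiling of physiologically relevant movement frequencies, Hz
GAIT_MAX_FREQ_HZ = 10.0


@dataclass(frozen=True)
class GaitModel:
    """Harmonic model of hip acceleration during steady locomotion.

    harmonic_amplitudes[k-1] is the peak acceleration (g) of the component
    at k times the step frequency. axis_weights give the fraction of signal
    power on (vertical, anteroposterior, mediolateral); amplitudes scale by
    the square root of the weight.
    """

    step_frequency: float
    harmonic_amplitudes: tuple[float, ...]
    stride_amplitude: float = 0.0  # component at f_step/2 (gait asymmetry)
    cadence_cv: float = 0.03  # within-bout step-frequency wander (OU, rel. sd)
    vertical_gravity_offset: float = 1.0
    noise_sd: float = 0.01
    axis_weights: tuple[float, float, float] = (0.6, 0.25, 0.15)
    impact_rms: float = 0.0  # broadband step-impact component (g RMS, >6 Hz)
    hf_contaminant_amplitude: float = 0.0  # >10 Hz component, off by default
    hf_contaminant_freq: float = 12.0

    def __post_init__(self) -> None:
        if self.step_frequency <= 0:
            raise ValueError("step_frequency must be positive")
        if any(a < 0 for a in self.harmonic_amplitudes):
            raise ValueError("harmonic amplitudes must be non-negative")
        if abs(sum(self.axis_weights) - 1.0) > 1e-9:
            raise ValueError("axis_weights must sum to 1")

    @property
    def highest_frequency(self) -> float:
        f = len(self.harmonic_amplitudes) * self.step_frequency
        if self.hf_contaminant_amplitude > 0:
            f = max(f, self.hf_contaminant_freq)
        return f


def harmonic_rolloff(a1: float, n_harmonics: int) -> tuple[float, ...]:
    """Default 1/k amplitude decay from the fundamental."""
    return tuple(a1 / k for k in range(1, n_harmonics + 1))


@dataclass(frozen=True)
class SubjectProfile:
    """Parametric subject: RMR, speed->MET curve and speed->step-frequency.

    met_at_speed(v) = 1 + met_coeff * (v / 3)**met_exponent for v > 0 and 1
    at rest -- monotone and curvilinear, calibrated to compendium-like
    values (3 km/h walk ~2 METs, 5 km/h ~3.6, 10 km/h run ~10.9 for
    adults) so the fastest stage exceeds 9 METs for both groups. Children
    get a 0.9x MET increment (higher RMR) and 1.15x step frequency at
    equal speed.
    """

    age_group: str = "adult"  # "child" | "adult"
    rmr: float = 0.30  # resting VO2, arbitrary consistent units
    met_coeff: float = 1.0
    met_exponent: float = 1.9
    step_freq_intercept: float = 1.2  # Hz at v -> 0
    step_freq_slope: float = 0.16  # Hz per km/h
    step_freq_factor: float = 1.0  # 1.15 for children
    amp_coeff: float = 0.045  # fundamental peak acceleration (g) at 1 km/h
    amp_exponent: float = 1.5  # superlinear growth of impact acceleration
    noise_sd: float = 0.01
    impact_fraction: float = 0.35  # step-impact RMS relative to the fundamental
    stride_fraction: float = 0.3  # stride-frequency (f_step/2) amplitude vs fundamental
    bout_amp_cv: float = 0.20  # free-living between-bout amplitude variability
    bout_stepfreq_sd: float = 0.4  # Hz: cadence differs widely across activities
    bout_spectral_cv: float = 0.35  # per-bout stride/impact content variability

    def __post_init__(self) -> None:
        if self.rmr <= 0:
            raise ValueError("rmr must be positive")
        if self.age_group not in ("child", "adult"):
            raise ValueError("age_group must be 'child' or 'adult'")

    @classmethod
    def default(cls, age_group: str) -> "SubjectProfile":
        if age_group == "adult":
            return cls()
        return cls(age_group="child", rmr=0.20, met_coeff=0.9, step_freq_factor=1.15)

    def met_at_speed(self, speed_kmh: float | np.ndarray) -> float | np.ndarray:
        v = np.asarray(speed_kmh, dtype=float)
        out = np.where(v > 0, 1.0 + self.met_coeff * (v / 3.0) ** self.met_exponent, 1.0)
        return float(out) if out.ndim == 0 else out

    def speed_at_met(self, mets: float) -> float:
        """Analytic inverse of met_at_speed for mets > 1."""
        if mets <= 1:
            return 0.0
        return 3.0 * ((mets - 1.0) / self.met_coeff) ** (1.0 / self.met_exponent)

    def step_freq_at_speed(self, speed_kmh: float) -> float:
        return self.step_freq_factor * (self.step_freq_intercept + self.step_freq_slope * speed_kmh)

    def gait_model(
        self,
        speed_kmh: float,
        sample_rate_hz: float,
        amp_factor: float = 1.0,
        stepfreq_offset: float = 0.0,
    ) -> GaitModel:
        """Gait model at a speed, harmonics capped at 10 Hz and Nyquist."""
        f_step = max(self.step_freq_at_speed(speed_kmh) + stepfreq_offset, 0.5)
        fmax = min(GAIT_MAX_FREQ_HZ, 0.95 * sample_rate_hz / 2)
        n_harm = max(1, int(np.ceil(fmax / f_step)))
        a1 = self.amp_coeff * speed_kmh**self.amp_exponent * amp_factor
        # taper the harmonic nearest the 10 Hz content ceiling so total
        # power varies continuously with cadence (no pop-in of harmonics)
        amps = list(harmonic_rolloff(a1, n_harm))
        for k in range(1, n_harm + 1):
            frac = np.clip((fmax - (k - 1) * f_step) / f_step, 0.0, 1.0)
            amps[k - 1] *= float(frac)
        return GaitModel(
            step_frequency=f_step,
            harmonic_amplitudes=tuple(amps),
            stride_amplitude=self.stride_fraction * a1,
            noise_sd=self.noise_sd,
            impact_rms=self.impact_fraction * a1,
        )


# ---------------------------------------------------------------------------
# Raw-signal generators

def gen_locomotion_signal(
    model: GaitModel,
    duration_s: float,
    sample_rate_hz: float,
    seed: int | np.random.Generator,
    start_time: pd.Timestamp | str = "2023-05-01 08:00:00",
    dynamic_range: float = 8.0,
) -> RawRecording:
    """Steady-gait triaxial acceleration from a harmonic model.

    Vertical axis carries the gravity offset; the harmonic series is split
    across axes by the power weights with independent uniform phases per
    axis and harmonic. Samples are clipped to the dynamic range.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if model.highest_frequency >= sample_rate_hz / 2:
        raise ValueError("harmonic frequency at or above Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    x = np.zeros((n, 3))
    x[:, 0] = model.vertical_gravity_offset
    w = np.sqrt(np.asarray(model.axis_weights))
    # instantaneous step frequency wanders (OU process) as in real cadence;
    # all components stay harmonically locked to the common phase track
    components = [(0.5, model.stride_amplitude)] + [
        (float(k), a) for k, a in enumerate(model.harmonic_amplitudes, start=1)
    ]
    any_periodic = any(a > 0 for _, a in components)
    if model.cadence_cv > 0 and any_periodic:
        from scipy.signal import lfilter

        dt = 1.0 / sample_rate_hz
        tau = 2.0  # s, correlation time of cadence fluctuations
        rho = np.exp(-dt / tau)
        eps = rng.normal(0.0, model.cadence_cv * np.sqrt(1 - rho**2), size=n)
        z0 = rng.normal(0.0, model.cadence_cv)
        delta, _ = lfilter([1.0], [1.0, -rho], eps, zi=[rho * z0])
        finst = model.step_frequency * (1.0 + delta)
    else:
        finst = np.full(n, model.step_frequency)
    phi = 2 * np.pi * np.cumsum(finst) / sample_rate_hz
    for k, a in components:
        phases = rng.uniform(0, 2 * np.pi, size=3)
        if a == 0:
            continue
        if k == 0.5:
            # left-right asymmetry is not steady: the stride component's
            # phase drifts slowly (Brownian, ~0.8 rad/sqrt(s)), decohering
            # it from the step harmonics over tens of seconds
            drift = np.cumsum(rng.normal(0.0, 0.8 / np.sqrt(sample_rate_hz), size=n))
        else:
            drift = 0.0
        for ax in range(3):
            x[:, ax] += a * w[ax] * np.sin(k * phi + phases[ax] + drift)
    if model.impact_rms > 0:
        # heel-strike continuum: band-limited noise in a fixed 6-14 Hz band
        # (rate-independent, so 100 Hz lab and 30 Hz free-living recordings
        # carry identical impact content), normalized to the requested RMS
        # and split by the axis weights
        from scipy import signal as _signal

        nyq = sample_rate_hz / 2
        band = (min(6.0, 0.4 * nyq), min(14.0, 0.95 * nyq))
        sos = _signal.butter(4, band, btype="bandpass", fs=sample_rate_hz, output="sos")
        u = _signal.sosfilt(sos, rng.normal(0.0, 1.0, size=(n, 3)), axis=0)
        u /= np.maximum(u.std(axis=0), 1e-12)
        x += model.impact_rms * u * w
    if model.hf_contaminant_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=3)
        for ax in range(3):
            x[:, ax] += model.hf_contaminant_amplitude * w[ax] * np.sin(
                2 * np.pi * model.hf_contaminant_freq * t + phases[ax]
            )
    if model.noise_sd > 0:
        x += rng.normal(0.0, model.noise_sd, size=x.shape)
    np.clip(x, -dynamic_range, dynamic_range, out=x)
    return RawRecording(
        start_time=pd.Timestamp(start_time),
        sample_rate=sample_rate_hz,
        samples=x,
        dynamic_range=dynamic_range,
    )


def gen_rest_signal(
    duration_s: float,
    sample_rate_hz: float,
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    start_time: pd.Timestamp | str = "2023-05-01 08:00:00",
    dynamic_range: float = 8.0,
) -> RawRecording:
    """Gravity-only sitting-still signal plus white sensor noise."""
    model = GaitModel(step_frequency=1.0, harmonic_amplitudes=(0.0,), noise_sd=noise_sd)
    return gen_locomotion_signal(
        model, duration_s, sample_rate_hz, seed, start_time, dynamic_range
    )


@dataclass
class MetabolicTrace:
    """Breath-by-breath VO2 series with subject metadata."""

    times_s: np.ndarray
    vo2: np.ndarray
    subject_id: str = "s0"
    age_group: str = "adult"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("breath timestamps must be strictly increasing")
        if np.any(self.vo2 <= 0):
            raise ValueError("VO2 must be positive")


#: treadmill protocol: walking 3-6 km/h, running 8 and 10 km/h, 4 min each
DEFAULT_PROTOCOL: tuple[tuple[float, float], ...] = (
    (3.0, 240.0), (4.0, 240.0), (5.0, 240.0), (6.0, 240.0), (8.0, 240.0), (10.0, 240.0),
)

REST_DURATION_S = 20 * 60.0


def gen_metabolic_trace(
    profile: SubjectProfile,
    protocol: tuple[tuple[float, float], ...] = DEFAULT_PROTOCOL,
    breath_rate_hz: float = 0.3,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    onset_tau_s: float = 30.0,
) -> MetabolicTrace:
    """Breath-by-breath VO2 over a 20 min seated rest plus the stage protocol.

    Steady-state VO2 at each stage is rmr * met_at_speed(speed); transitions
    follow first-order onset kinetics with time constant onset_tau_s, so the
    selection window late in each 4 min stage sees steady state.
    """
    if len(protocol) == 0:
        raise ValueError("empty protocol")
    if any(s < 0 for s, _ in protocol):
        raise ValueError("speeds must be non-negative")
    rng = np.random.default_rng(seed)
    segments = [(0.0, REST_DURATION_S)] + list(protocol)
    total = sum(d for _, d in segments)
    times = np.arange(0.5 / breath_rate_hz, total, 1.0 / breath_rate_hz)
    target = np.empty_like(times)
    t0 = 0.0
    level = profile.rmr
    for speed, dur in segments:
        steady = profile.rmr * float(profile.met_at_speed(speed))
        in_seg = (times >= t0) & (times < t0 + dur)
        dt = times[in_seg] - t0
        target[in_seg] = steady + (level - steady) * np.exp(-dt / onset_tau_s)
        level = steady + (level - steady) * np.exp(-dur / onset_tau_s)
        t0 += dur
    vo2 = target + rng.normal(0.0, noise_sd, size=target.shape)
    vo2 = np.maximum(vo2, 1e-6)
    return MetabolicTrace(times_s=times, vo2=vo2, age_group=profile.age_group)


# ---------------------------------------------------------------------------
# Free-living schedules

@dataclass(frozen=True)
class Bout:
    start_time: pd.Timestamp
    duration_s: float
    activity: str  # "nonwear" | "rest" | "locomotion"
    speed_kmh: float = 0.0

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)


@dataclass
class DaySchedule:
    """Chronologically ordered, non-overlapping bouts covering wear and gaps."""

    bouts: list[Bout]

    def __post_init__(self) -> None:
        if any(b.duration_s <= 0 for b in self.bouts):
            raise ValueError("bout durations must be positive")
        for a, b in zip(self.bouts, self.bouts[1:]):
            if b.start_time < a.end_time:
                raise ValueError("bouts overlap or are out of order")

    @property
    def start_time(self) -> pd.Timestamp:
        return self.bouts[0].start_time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_time": [b.start_time for b in self.bouts],
                "duration_s": [b.duration_s for b in self.bouts],
                "activity": [b.activity for b in self.bouts],
                "speed_kmh": [b.speed_kmh for b in self.bouts],
            }
        )


def gen_freeliving_recording(
    schedule: DaySchedule,
    profile: SubjectProfile,
    sample_rate_hz: float = 30.0,
    seed: int | np.random.Generator = 0,
    dynamic_range: float = 6.0,
    scheme: IntensityScheme = DEFAULT_SCHEME,
) -> tuple[RawRecording, pd.DataFrame]:
    """Synthesize a wear period from a schedule, with ground-truth labels.

    Non-wear bouts carry the idle status flag (flat 1 g signal, the device
    sleep-mode behaviour); locomotion bouts are generated from the profile's
    speed-dependent gait model with per-bout amplitude and step-frequency
    jitter emulating free-living variability. Returns the recording and the
    bout table extended with nominal METs and the true intensity label.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    status_chunks: list[np.ndarray] = []
    rows = []
    t_cursor = schedule.start_time
    for bout in schedule.bouts:
        if bout.start_time != t_cursor:
            raise ValueError("schedule has gaps; insert explicit rest/nonwear bouts")
        n = int(round(bout.duration_s * sample_rate_hz))
        if bout.activity == "nonwear":
            x = np.zeros((n, 3))
            x[:, 0] = 1.0
            st = np.full(n, STATUS_IDLE, dtype=np.uint8)
            mets = np.nan
        elif bout.activity == "rest":
            rec = gen_rest_signal(
                bout.duration_s, sample_rate_hz, profile.noise_sd, rng,
                start_time=bout.start_time, dynamic_range=dynamic_range,
            )
            x = rec.samples
            st = np.full(n, STATUS_ACTIVE, dtype=np.uint8)
            mets = 1.0
        elif bout.activity == "locomotion":
            # free-living movement is spectrally diverse: cadence, gait
            # asymmetry and impact content all vary between activities
            amp_factor = float(np.exp(rng.normal(0.0, profile.bout_amp_cv)))
            df_step = float(rng.normal(0.0, profile.bout_stepfreq_sd))
            model = profile.gait_model(bout.speed_kmh, sample_rate_hz, amp_factor, df_step)
            scv = profile.bout_spectral_cv
            if scv > 0:
                model = dataclasses.replace(
                    model,
                    stride_amplitude=model.stride_amplitude
                    * float(np.exp(rng.normal(0.0, scv))),
                    impact_rms=model.impact_rms * float(np.exp(rng.normal(0.0, scv))),
                )
            rec = gen_locomotion_signal(
                model, bout.duration_s, sample_rate_hz, rng,
                start_time=bout.start_time, dynamic_range=dynamic_range,
            )
            x = rec.samples
            st = np.full(n, STATUS_ACTIVE, dtype=np.uint8)
            mets = float(profile.met_at_speed(bout.speed_kmh))
        else:
            raise ValueError(f"unknown activity {bout.activity!r}")
        chunks.append(x[:n])
        status_chunks.append(st)
        rows.append(
            {
                "start_time": bout.start_time,
                "duration_s": bout.duration_s,
                "activity": bout.activity,
                "speed_kmh": bout.speed_kmh,
                "mets": mets,
                "true_label": "nonwear" if bout.activity == "nonwear"
                else scheme.label_for_mets(mets),
            }
        )
        t_cursor = bout.end_time
    recording = RawRecording(
        start_time=schedule.start_time,
        sample_rate=sample_rate_hz,
        samples=np.vstack(chunks),
        dynamic_range=dynamic_range,
        status=np.concatenate(status_chunks),
    )
    return recording, pd.DataFrame(rows)


def truth_label_series(
    bouts: pd.DataFrame,
    start_time: pd.Timestamp,
    epoch_length: float,
    n_epochs: int,
) -> np.ndarray:
    """Ground-truth label per epoch (by epoch start time) from a bout table."""
    labels = np.full(n_epochs, "nonwear", dtype=object)
    epoch_starts = pd.Timestamp(start_time) + pd.to_timedelta(
        np.arange(n_epochs) * epoch_length, unit="s"
    )
    ends = bouts["start_time"] + pd.to_timedelta(bouts["duration_s"], unit="s")
    for (_, row), end in zip(bouts.iterrows(), ends):
        in_bout = (epoch_starts >= row["start_time"]) & (epoch_starts < end)
        labels[in_bout] = row["true_label"]
    return labels


def build_week_schedule(
    profile: SubjectProfile,
    seed: int | np.random.Generator = 0,
    n_days: int = 7,
    start_date: str | pd.Timestamp = "2023-05-01",
) -> DaySchedule:
    """A realistic wear week: overnight non-wear, daytime rest with scattered
    walking and running bouts (more and faster running for children)."""
    rng = np.random.default_rng(seed)
    start_date = pd.Timestamp(start_date)
    bouts: list[Bout] = []
    run_prob = 0.35 if profile.age_group == "child" else 0.25
    for day in range(n_days):
        d0 = start_date + pd.Timedelta(days=day)
        bouts.append(Bout(d0, 6.5 * 3600, "nonwear"))
        t = d0 + pd.Timedelta(hours=6.5)
        day_end = d0 + pd.Timedelta(hours=22.5)
        while t < day_end - pd.Timedelta(minutes=15):
            rest_s = int(round(rng.uniform(10, 45) * 60))
            rest_s = min(rest_s, int((day_end - t).total_seconds()))
            bouts.append(Bout(t, rest_s, "rest"))
            t += pd.Timedelta(seconds=rest_s)
            if t >= day_end - pd.Timedelta(minutes=12):
                break
            if rng.uniform() < run_prob:
                speed = float(rng.uniform(7.0, 10.5))
                dur_s = int(round(rng.uniform(2, 8) * 60))
            else:
                speed = float(rng.uniform(2.5, 6.5))
                dur_s = int(round(rng.uniform(3, 12) * 60))
            bouts.append(Bout(t, dur_s, "locomotion", speed))
            t += pd.Timedelta(seconds=dur_s)
        if t < d0 + pd.Timedelta(hours=24):
            bouts.append(Bout(t, (d0 + pd.Timedelta(hours=24) - t).total_seconds(), "nonwear"))
    return DaySchedule(bouts)
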