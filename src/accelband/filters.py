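"""Digital filter designs for activity-count generation and sub-band analysis.

The legacy ActiGraph chain band-passes acceleration between half-power
frequencies of 0.29 and 1.63 Hz. The modified variants keep the 0.29 Hz
high-pass edge and widen (4 Hz, 10 Hz) or drop the low-pass edge; they are
fourth-order Butterworth designs. Sub-band analysis uses tenth-order
Butterworth filters at 1.7-4 Hz, 4-10 Hz and a 10 Hz high-pass.

"Order" follows the band-pass convention: a fourth-order band-pass has four
poles total (two per edge), i.e. scipy ``butter(order // 2, ..., "bandpass")``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

HIGH_PASS_CUTOFF_HZ = 0.29

#: variant -> low-pass half-power edge in Hz (None = high-pass only)
VARIANT_LOWPASS: dict[str, float | None] = {
    "ag_original": 1.63,
    "bp4hz": 4.0,
    "bp10hz": 10.0,
    "hp_only": None,
}

VARIANTS = tuple(VARIANT_LOWPASS)


@dataclass(frozen=True)
class FilterSpec:
    """Declarative band definition: variant name, order, half-power edges."""

    variant: str
    order: int = 4
    high_pass_cutoff: float = HIGH_PASS_CUTOFF_HZ
    low_pass_cutoff: float | None = None

    @classmethod
    def for_variant(cls, variant: str, order: int = 4) -> "FilterSpec":
        if variant not in VARIANT_LOWPASS:
            raise ValueError(f"unknown filter variant {variant!r}")
        return cls(variant=variant, order=order, low_pass_cutoff=VARIANT_LOWPASS[variant])


@dataclass
class FilterResponse:
    """A realized digital filter: second-order sections plus diagnostics."""

    spec: FilterSpec
    sample_rate: float
    sos: np.ndarray
    realized_half_power_hz: tuple[float, ...]

    def apply(self, x: np.ndarray, axis: int = 0) -> np.ndarray:
        """Causal single-pass filtering with zero initial conditions."""
        return signal.sosfilt(self.sos, x, axis=axis)

    def magnitude_squared(self, freqs_hz: np.ndarray) -> np.ndarray:
        w, h = signal.sosfreqz(self.sos, worN=2 * np.pi * np.asarray(freqs_hz) / self.sample_rate)
        return np.abs(h) ** 2

    def is_stable(self) -> bool:
        _, p, _ = signal.sos2zpk(self.sos)
        return bool(np.all(np.abs(p) < 1.0))


def _half_power_crossings(sos: np.ndarray, sample_rate: float) -> tuple[float, ...]:
    """Frequencies where |H(f)|^2 crosses 0.5, from a fine response grid."""
    nyq = sample_rate / 2
    freqs = np.linspace(1e-4, nyq * 0.9999, 200_001)
    w = 2 * np.pi * freqs / sample_rate
    _, h = signal.sosfreqz(sos, worN=w)
    mag2 = np.abs(h) ** 2
    above = mag2 >= 0.5
    crossings = []
    idx = np.nonzero(np.diff(above))[0]
    for i in idx:
        # linear interpolation of the 0.5 crossing between grid points
        f0, f1 = freqs[i], freqs[i + 1]
        m0, m1 = mag2[i], mag2[i + 1]
        crossings.append(f0 + (0.5 - m0) * (f1 - f0) / (m1 - m0))
    return tuple(crossings)


def design_filter(spec: FilterSpec, sample_rate_hz: float) -> FilterResponse:
    """Design the band as a digital Butterworth filter at the given rate.

    Returns a stable causal IIR realization (second-order sections) whose
    realized half-power frequencies match the spec edges within 2%.
    Raises ValueError for edges at or above Nyquist or an unstable design.
    """
    nyq = sample_rate_hz / 2
    hp = spec.high_pass_cutoff
    lp = spec.low_pass_cutoff
    if hp >= nyq or (lp is not None and lp >= nyq):
        raise ValueError(
            f"cutoff at or above Nyquist ({nyq} Hz) for sample rate {sample_rate_hz} Hz"
        )
    if lp is None:
        sos = signal.butter(spec.order, hp, btype="highpass", fs=sample_rate_hz, output="sos")
    else:
        if spec.order % 2:
            raise ValueError("band-pass order must be even (poles split between edges)")
        sos = signal.butter(
            spec.order // 2, [hp, lp], btype="bandpass", fs=sample_rate_hz, output="sos"
        )
    resp = FilterResponse(
        spec=spec,
        sample_rate=sample_rate_hz,
        sos=sos,
        realized_half_power_hz=_half_power_crossings(sos, sample_rate_hz),
    )
    if not resp.is_stable():
        raise ValueError("unstable filter realization")
    return resp


# ---------------------------------------------------------------------------
# Sub-band designs (tenth order)

SUBBAND_EDGES: dict[str, tuple[float, float | None]] = {
    "ag": (HIGH_PASS_CUTOFF_HZ, 1.63),
    "mid": (1.7, 4.0),
    "high": (4.0, 10.0),
    "vhigh": (10.0, None),
}

SUBBANDS = tuple(SUBBAND_EDGES)


@dataclass(frozen=True)
class SubbandSpec:
    """One of the four analysis sub-bands.

    The "ag" band reuses the legacy count chain's fourth-order band-pass so
    it stays consistent with the reference axis of the histogram analysis;
    the three additional bands are tenth-order Butterworth designs.
    """

    band: str
    order: int = 10

    def __post_init__(self) -> None:
        if self.band not in SUBBAND_EDGES:
            raise ValueError(f"unknown sub-band {self.band!r}")

    @property
    def edges(self) -> tuple[float, float | None]:
        return SUBBAND_EDGES[self.band]


def design_subband(spec: SubbandSpec, sample_rate_hz: float) -> FilterResponse:
    """Design a sub-band filter; the vhigh band is a high-pass at 10 Hz."""
    lo, hi = spec.edges
    if spec.band == "ag":
        return design_filter(FilterSpec.for_variant("ag_original", order=4), sample_rate_hz)
    fspec = FilterSpec(variant=f"subband_{spec.band}", order=spec.order,
                       high_pass_cutoff=lo, low_pass_cutoff=hi)
    return design_filter(fspec, sample_rate_hz)
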