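"""Device constants and the physical-activity intensity scheme.

The count quantum derives from the legacy ActiGraph analog front end: a
±2.13 g full scale digitized at 8-bit resolution, so one count corresponds
to 2 * 2.13 g * 1e3 / 2**8 = 16.640625 mg of rectified acceleration at one
internal sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Full-scale span of the legacy count front end, in mg (2 * 2.13 g * 1e3).
RANGE_MG: float = 4260.0

#: Quantization levels of the 8-bit converter.
QUANT_LEVELS: int = 256

#: Acceleration represented by one count at one internal sample, in mg.
MG_PER_COUNT: float = RANGE_MG / QUANT_LEVELS  # 16.640625, printed as 16.64

#: Truncation limit of the legacy chain, in g.
AG_TRUNCATION_G: float = 2.13

#: Dead-band threshold of the legacy chain, in g: rectified samples below
#: this are zeroed before quantization. Value from the count-replication
#: literature; the modified filter variants apply no dead-band.
AG_DEADBAND_G: float = 0.068

#: Internal aggregation rate of the legacy chain (decimated), in Hz.
AG_INTERNAL_RATE_HZ: float = 10.0


def counts_to_mg_factor(internal_rate_hz: float, epoch_length_s: float) -> float:
    """Conversion factor from aggregated counts to mean mg.

    ``r / (b * f * e)`` with r = 4260 mg, b = 256, f the internal sample
    rate the rectified samples were aggregated at, and e the epoch length.
    For the legacy chain (f = 10 Hz, e = 60 s) this is 0.0277 mg per count.
    """
    if internal_rate_hz <= 0 or epoch_length_s <= 0:
        raise ValueError("internal rate and epoch length must be positive")
    return RANGE_MG / (QUANT_LEVELS * internal_rate_hz * epoch_length_s)


INTENSITY_LABELS = ("SED", "LPA", "MPA", "VPA", "VVPA")


@dataclass(frozen=True)
class IntensityScheme:
    """Ordered MET thresholds separating the five intensity classes.

    Classification is lower-inclusive half-open: METs < 1.5 is sedentary,
    [1.5, 3) light, [3, 6) moderate, [6, 9) vigorous, >= 9 very vigorous.
    """

    thresholds: tuple[float, ...] = (1.5, 3.0, 6.0, 9.0)
    labels: tuple[str, ...] = INTENSITY_LABELS

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("MET thresholds must be increasing")
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need one more label than thresholds")

    def label_for_mets(self, mets: float) -> str:
        """Intensity class of a MET value under the half-open convention."""
        idx = 0
        for t in self.thresholds:
            if mets >= t:
                idx += 1
        return self.labels[idx]


DEFAULT_SCHEME = IntensityScheme()
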