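"""In-memory containers for raw acceleration and epoch-aggregated output."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: per-sample status codes
STATUS_ACTIVE = 0
STATUS_IDLE = 1

AXES = ("vertical", "ap", "ml")


@dataclass
class RawRecording:
    """Timestamped triaxial acceleration in g.

    samples is an (n, 3) float array with axes (vertical, anteroposterior,
    mediolateral). status is a per-sample uint8 flag: 0 = active wear,
    1 = idle (sleep-mode, treated as non-wear downstream).
    """

    start_time: pd.Timestamp
    sample_rate: float
    samples: np.ndarray
    dynamic_range: float = 6.0
    status: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        if self.status is None:
            self.status = np.zeros(len(self.samples), dtype=np.uint8)
        else:
            self.status = np.asarray(self.status, dtype=np.uint8)
            if self.status.shape != (len(self.samples),):
                raise ValueError("status must have one flag per sample")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self.samples)) / self.sample_rate, unit="s"
        )

    def clipped(self) -> "RawRecording":
        """Copy with samples clipped to the dynamic range."""
        r = self.dynamic_range
        return replace(self, samples=np.clip(self.samples, -r, r))


@dataclass
class EpochSeries:
    """Per-epoch scalar activity output (counts or mean mg).

    internal_rate is the rate at which rectified samples were aggregated
    (10 Hz for the legacy chain, the device rate for modified variants);
    it enters the counts <-> mg conversion.
    """

    start_time: pd.Timestamp
    epoch_length: float
    values: np.ndarray
    unit: str  # "counts" | "mg"
    axis: str  # "vertical" | "ap" | "ml" | "vector_magnitude"
    variant: str
    internal_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> pd.DatetimeIndex:
        """Start time of each epoch."""
        return self.start_time + pd.to_timedelta(
            np.arange(len(self.values)) * self.epoch_length, unit="s"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch_start": self.times,
                "value": self.values,
                "unit": self.unit,
                "axis": self.axis,
                "variant": self.variant,
                "epoch_length": self.epoch_length,
            }
        )

    def compatible_grid(self, other: "EpochSeries") -> bool:
        return (
            len(self) == len(other)
            and self.epoch_length == other.epoch_length
            and self.start_time == other.start_time
        )
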