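"""Free-living epoch processing: wear time, valid days, the daily window,
intensity classification and inter-filter agreement summaries.

Non-wear is taken from the device idle status (sleep mode), not from signal
content: an epoch is non-wear when more than half of its samples are idle.
A calendar day is valid with at least 12 h of wear; epochs starting outside
06:00-23:00 are excluded. Classification uses half-open, lower-inclusive
intervals between the calibrated cut-points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .calibration import CutPointSet
from .constants import INTENSITY_LABELS
from .recording import STATUS_IDLE, EpochSeries, RawRecording

NONWEAR = "nonwear"
EXCLUDED = "excluded"


@dataclass
class WearMask:
    """Per-epoch wear status on the same grid as an EpochSeries."""

    start_time: pd.Timestamp
    epoch_length: float
    wear: np.ndarray  # boolean, True = worn
    rule: str = "idle_status_majority"

    def __post_init__(self) -> None:
        self.wear = np.asarray(self.wear, dtype=bool)
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return len(self.wear)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self.wear)) * self.epoch_length, unit="s"
        )


def derive_wear_mask(
    recording: RawRecording,
    epoch_length_s: float,
    idle_fraction_threshold: float = 0.5,
) -> WearMask:
    """Epoch-level wear mask: non-wear iff more than the threshold fraction
    of the epoch's samples carry the idle status."""
    spe = int(round(recording.sample_rate * epoch_length_s))
    n_epochs = len(recording) // spe
    idle = (recording.status[: n_epochs * spe] == STATUS_IDLE).reshape(n_epochs, spe)
    wear = idle.mean(axis=1) <= idle_fraction_threshold
    return WearMask(recording.start_time, epoch_length_s, wear)


def filter_valid_days(mask: WearMask, min_wear_h: float = 12.0) -> set:
    """Calendar days (dates) with at least min_wear_h of wear time."""
    if len(mask) == 0:
        return set()
    days = pd.Series(mask.wear.astype(float) * mask.epoch_length, index=mask.times)
    wear_s = days.groupby(days.index.date).sum()
    return set(wear_s.index[wear_s >= min_wear_h * 3600.0])


def daily_window_mask(
    times: pd.DatetimeIndex, start: str = "06:00", end: str = "23:00"
) -> np.ndarray:
    """True for epochs whose start time falls in [start, end) local clock."""
    t0 = pd.Timestamp(f"2000-01-01 {start}").time()
    t1 = pd.Timestamp(f"2000-01-01 {end}").time()
    tod = np.array([t.time() for t in times])
    return (tod >= t0) & (tod < t1)


@dataclass
class LabelSeries:
    """Per-epoch intensity labels, with non-wear and excluded epochs marked."""

    start_time: pd.Timestamp
    epoch_length: float
    labels: np.ndarray  # object array over INTENSITY_LABELS + {nonwear, excluded}
    variant: str
    cutpoint_provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self.labels)) * self.epoch_length, unit="s"
        )

    @property
    def included(self) -> np.ndarray:
        return np.isin(self.labels, INTENSITY_LABELS)


class IntensityClassifier(BaseEstimator):
    """Predict-shaped classifier from a calibrated cut-point set.

    Labels epoch values by half-open lower-inclusive intervals:
    [0, c1.5) -> SED, [c1.5, c3) -> LPA, [c3, c6) -> MPA, [c6, c9) -> VPA,
    [c9, inf) -> VVPA. Counts cut-points (calibrated on one-minute
    aggregation) are scaled linearly to the epoch length.
    """

    def __init__(self, cutpoints: CutPointSet | None = None, unit: str = "mg"):
        self.cutpoints = cutpoints
        self.unit = unit

    def fit(self, X=None, y=None) -> "IntensityClassifier":
        if self.cutpoints is None:
            raise ValueError("cutpoints are required")
        if self.unit not in ("mg", "counts"):
            raise ValueError("unit must be 'mg' or 'counts'")
        self.classes_ = np.asarray(self.cutpoints.scheme.labels, dtype=object)
        return self

    def _edges(self, epoch_length_s: float) -> np.ndarray:
        if self.unit == "mg":
            return self.cutpoints.mg_array()
        return self.cutpoints.counts_array(epoch_length_s)

    def predict(self, X, epoch_length_s: float = 60.0) -> np.ndarray:
        if not hasattr(self, "classes_"):
            self.fit()
        values = np.asarray(X, dtype=float).reshape(-1)
        idx = np.searchsorted(self._edges(epoch_length_s), values, side="right")
        return self.classes_[idx]


def classify(
    series: EpochSeries,
    cutpoints: CutPointSet,
    wear_mask: WearMask | None = None,
    valid_days: set | None = None,
    window: tuple[str, str] | None = ("06:00", "23:00"),
) -> LabelSeries:
    """Label an epoch series, applying wear, valid-day and window rules.

    Unit is taken from the series; non-wear epochs get "nonwear", epochs on
    invalid days or outside the daily window get "excluded".
    """
    if series.unit not in ("mg", "counts"):
        raise ValueError(f"cannot classify unit {series.unit!r}")
    clf = IntensityClassifier(cutpoints, unit=series.unit).fit()
    labels = clf.predict(series.values, epoch_length_s=series.epoch_length).astype(object)
    times = series.times
    if wear_mask is not None:
        if len(wear_mask) != len(series) or wear_mask.epoch_length != series.epoch_length:
            raise ValueError("wear mask grid does not match the series")
        labels[~wear_mask.wear] = NONWEAR
    if valid_days is not None:
        on_valid = np.isin(np.asarray(times.date), sorted(valid_days))
        labels[~on_valid & (labels != NONWEAR)] = EXCLUDED
    if window is not None:
        in_win = daily_window_mask(times, *window)
        labels[~in_win & (labels != NONWEAR)] = EXCLUDED
    return LabelSeries(
        start_time=series.start_time,
        epoch_length=series.epoch_length,
        labels=labels,
        variant=series.variant,
        cutpoint_provenance=f"{cutpoints.age_group}/{cutpoints.filter_variant}",
    )


@dataclass
class ConfusionChart:
    """Row-normalized 5x5 agreement chart, reference labels on rows (%)."""

    matrix: pd.DataFrame  # rows: reference labels, cols: comparison, in %
    counts: pd.DataFrame  # raw epoch counts
    epoch_length: float
    ref_variant: str
    cmp_variant: str

    @property
    def empty_rows(self) -> list[str]:
        return list(self.matrix.index[self.counts.sum(axis=1) == 0])


def confusion_chart(ref: LabelSeries, cmp: LabelSeries) -> ConfusionChart:
    """Epoch-by-epoch agreement over jointly included epochs.

    Rows are reference (legacy-filter) labels, columns the comparison
    filter's labels; each occupied row is normalized to 100%.
    """
    if len(ref) != len(cmp) or ref.epoch_length != cmp.epoch_length:
        raise ValueError("label series grids do not match")
    both = ref.included & cmp.included
    labels = list(INTENSITY_LABELS)
    counts = pd.crosstab(
        pd.Categorical(ref.labels[both], categories=labels),
        pd.Categorical(cmp.labels[both], categories=labels),
        dropna=False,
    ).reindex(index=labels, columns=labels, fill_value=0)
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(row_sums, axis=0) * 100.0
    return ConfusionChart(
        matrix=pct,
        counts=counts,
        epoch_length=ref.epoch_length,
        ref_variant=ref.variant,
        cmp_variant=cmp.variant,
    )


def intensity_distribution(labels: LabelSeries | list[LabelSeries]) -> pd.Series:
    """Fraction of included epochs per intensity class, in percent.

    For a list (one LabelSeries per subject), per-subject fractions are
    computed first and then averaged, mirroring group-mean reporting.
    """
    if isinstance(labels, LabelSeries):
        labels = [labels]
    rows = []
    for ls in labels:
        inc = ls.labels[ls.included]
        if len(inc) == 0:
            continue
        counts = pd.Series(inc).value_counts()
        frac = counts.reindex(INTENSITY_LABELS, fill_value=0) / len(inc) * 100.0
        rows.append(frac)
    if not rows:
        raise ValueError("no included epochs")
    return pd.concat(rows, axis=1).mean(axis=1)
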