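"""MET calibration: RMR extraction, stage pairing, anchored smoothing
splines and intensity cut-points.

Breath-by-breath VO2 from 20 min of seated rest is smoothed with a 2 min
centered moving average and its minimum taken as the individual resting
metabolic rate (RMR). For each treadmill stage, one minute of data starting
at 2:45 into the stage is averaged; METs are the mean VO2 over that window
divided by RMR, paired with mean filtered acceleration (mg) and counts
aggregated to a one-minute epoch over the same window. Per age group and
filter, a cubic smoothing spline with smoothing factor 0.1 and a forced
starting point at (0 acceleration, 1 MET) maps acceleration to METs; the
spline is inverted at 1.5/3/6/9 METs to give intensity cut-points.

Smoothing-parameter convention: p in (0, 1] with p -> 0 the least-squares
line and p -> 1 the interpolant, realized through scipy's
`make_smoothing_spline`. The penalty weight uses the unit-invariant
mapping lam = (1 - p) / p * (L / 40)^3 / 6 with L the fitted domain span
(a de Boor-style balance at a fixed reference resolution of 40 knots per
domain). This makes p independent of both the abscissa units (mg vs
counts) and the number of pooled replicate points, so p = 0.1 follows the
curvilinear METs trend while smoothing through within-stage subject
scatter. `lam_scale="raw"` selects the plain MATLAB/csaps mapping
lam = (1 - p) / p, which at mg scale is near-interpolating. The anchor is
a pseudo-observation at (0, 1) with weight 1e6 times the data weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import DEFAULT_SCHEME, IntensityScheme, counts_to_mg_factor
from .recording import EpochSeries
from .synthetic import MetabolicTrace

#: selection window inside each stage: [2:45, 3:45) from stage start
STAGE_SEL_START_S = 165.0
STAGE_SEL_LEN_S = 60.0


def compute_rmr(
    trace: MetabolicTrace,
    window_s: float = 120.0,
    rest_duration_s: float | None = None,
) -> float:
    """Minimum of the 2 min centered moving-average VO2 over seated rest.

    rest_duration_s limits the search to the initial resting segment; None
    uses the whole trace (appropriate when the trace is rest only).
    """
    t, v = trace.times_s, trace.vo2
    if rest_duration_s is not None:
        keep = t < rest_duration_s
        t, v = t[keep], v[keep]
    if len(t) == 0 or t[-1] - t[0] < window_s:
        raise ValueError("resting segment shorter than the averaging window")
    s = pd.Series(v, index=pd.to_timedelta(t, unit="s"))
    smoothed = s.rolling(pd.Timedelta(seconds=window_s), center=True, min_periods=1).mean()
    # exclude half-window edges so partial windows cannot fake a minimum
    half = pd.Timedelta(seconds=window_s / 2)
    interior = (smoothed.index >= smoothed.index[0] + half) & (
        smoothed.index <= smoothed.index[-1] - half
    )
    return float(smoothed[interior].min())


@dataclass(frozen=True)
class CalibrationPoint:
    """One (stage, subject) pairing of METs with acceleration output."""

    subject_id: str
    age_group: str
    speed_kmh: float
    mets: float
    accel_mg: float
    counts_per_min: float
    variant: str = ""


def extract_stage(
    trace: MetabolicTrace,
    rmr: float,
    mg_epochs: EpochSeries,
    counts_epochs: EpochSeries,
    stage_start_s: float,
    speed_kmh: float,
    sel_start_s: float = STAGE_SEL_START_S,
    sel_len_s: float = STAGE_SEL_LEN_S,
    stage_duration_s: float = 240.0,
    subject_id: str = "s0",
) -> CalibrationPoint:
    """Pair window-mean METs with acceleration output for one stage.

    The selection window is half-open [stage_start + 2:45, +3:45). The
    acceleration epoch series must be aligned to the same clock as the
    metabolic trace (both starting at recording time zero) and use an epoch
    length that divides the window.
    """
    if stage_duration_s < sel_start_s + sel_len_s:
        raise ValueError("stage shorter than selection start + length")
    lo = stage_start_s + sel_start_s
    hi = lo + sel_len_s
    t = trace.times_s
    win = (t >= lo) & (t < hi)
    if not win.any():
        raise ValueError("no breaths in the selection window")
    mets = float(trace.vo2[win].mean()) / rmr

    def window_values(es: EpochSeries) -> np.ndarray:
        starts = np.arange(len(es)) * es.epoch_length
        sel = (starts >= lo) & (starts < hi)
        if not sel.any():
            raise ValueError("no epochs in the selection window")
        return es.values[sel]

    accel_mg = float(window_values(mg_epochs).mean())
    # counts aggregated to a one-minute epoch over the window
    cpm = float(window_values(counts_epochs).sum() * (60.0 / sel_len_s))
    return CalibrationPoint(
        subject_id=subject_id,
        age_group=trace.age_group,
        speed_kmh=speed_kmh,
        mets=mets,
        accel_mg=accel_mg,
        counts_per_min=cpm,
    )


class SplineCalibration(RegressorMixin, BaseEstimator):
    """Anchored cubic smoothing spline mapping acceleration (mg) to METs.

    Parameters
    ----------
    smoothing : float
        Smoothing factor p in (0, 1], MATLAB convention (see module docs).
    anchor : tuple or None
        Forced starting point, default (0 mg, 1 MET).
    anchor_weight : float
        Weight of the anchor pseudo-observation relative to a data point.
    min_points : int
        Minimum number of distinct acceleration values required.
    """

    def __init__(
        self,
        smoothing: float = 0.1,
        anchor: tuple[float, float] | None = (0.0, 1.0),
        anchor_weight: float = 1e6,
        min_points: int = 6,
        lam_scale: str = "domain",
    ):
        self.smoothing = smoothing
        self.anchor = anchor
        self.anchor_weight = anchor_weight
        self.min_points = min_points
        self.lam_scale = lam_scale

    def fit(self, X, y, sample_weight=None) -> "SplineCalibration":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        w = np.ones_like(x) if sample_weight is None else np.asarray(sample_weight, float)
        if not 0.0 < self.smoothing <= 1.0:
            raise ValueError("smoothing must be in (0, 1]")
        if self.anchor is not None:
            x = np.append(x, self.anchor[0])
            y = np.append(y, self.anchor[1])
            w = np.append(w, self.anchor_weight * w.max())
        order = np.argsort(x)
        x, y, w = x[order], y[order], w[order]
        # merge duplicate abscissae (weighted mean) -- spline needs x strictly increasing
        ux, inv = np.unique(np.round(x, 9), return_inverse=True)
        if len(ux) < self.min_points:
            raise ValueError(f"need at least {self.min_points} distinct acceleration values")
        wy = np.bincount(inv, weights=w * y)
        ws = np.bincount(inv, weights=w)
        ym = wy / ws
        # p -> lam mapping (see module docstring)
        lam = (1.0 - self.smoothing) / self.smoothing
        if self.lam_scale == "domain":
            lam *= ((ux[-1] - ux[0]) / 40.0) ** 3 / 6.0
        elif self.lam_scale != "raw":
            raise ValueError("lam_scale must be 'domain' or 'raw'")
        self.spline_ = make_smoothing_spline(ux, ym, w=ws, lam=lam)
        self.x_min_, self.x_max_ = float(ux[0]), float(ux[-1])
        self.n_points_ = len(ux)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.spline_(x)

    def first_crossing(self, mets: float, n_grid: int = 4001) -> float | None:
        """Smallest acceleration at which the curve attains a MET level.

        Returns None when the level is never reached on the fitted domain
        (the curves plateau at high intensity, so high thresholds can be
        unattainable).
        """
        grid = np.linspace(self.x_min_, self.x_max_, n_grid)
        vals = self.predict(grid) - mets
        if vals[0] >= 0:
            return float(grid[0])
        above = np.nonzero(vals >= 0)[0]
        if len(above) == 0:
            return None
        i = above[0]
        return float(brentq(lambda a: float(self.spline_(a)) - mets, grid[i - 1], grid[i]))


def fit_calibration(
    points: list[CalibrationPoint],
    smoothing: float = 0.1,
    anchor: tuple[float, float] = (0.0, 1.0),
    unit: str = "mg",
) -> SplineCalibration:
    """Fit the anchored spline to a set of calibration points (one group,
    one filter variant)."""
    attr = "accel_mg" if unit == "mg" else "counts_per_min"
    x = np.array([getattr(p, attr) for p in points])
    y = np.array([p.mets for p in points])
    return SplineCalibration(smoothing=smoothing, anchor=anchor).fit(x, y)


@dataclass
class CutPointSet:
    """Acceleration thresholds at the MET boundaries for one group/filter.

    thresholds_mg maps MET level -> mg cut-point (None if the curve never
    reaches the level); thresholds_counts_per_min is the same via the
    variant's counts conversion at a one-minute epoch.
    """

    age_group: str
    filter_variant: str
    internal_rate_hz: float
    thresholds_mg: dict[float, float | None]
    thresholds_counts_per_min: dict[float, float | None]
    scheme: IntensityScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def mg_array(self) -> np.ndarray:
        vals = [self.thresholds_mg[m] for m in self.scheme.thresholds]
        if any(v is None for v in vals):
            raise ValueError("cut-point set has unattainable thresholds")
        return np.asarray(vals, dtype=float)

    def counts_array(self, epoch_length_s: float = 60.0) -> np.ndarray:
        """Counts thresholds, linearly rescaled to the epoch length."""
        vals = [self.thresholds_counts_per_min[m] for m in self.scheme.thresholds]
        if any(v is None for v in vals):
            raise ValueError("cut-point set has unattainable thresholds")
        return np.asarray(vals, dtype=float) * (epoch_length_s / 60.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_group": self.age_group,
                "filter": self.filter_variant,
                "met_level": list(self.thresholds_mg),
                "mg": list(self.thresholds_mg.values()),
                "counts_per_min": list(self.thresholds_counts_per_min.values()),
            }
        )


def derive_cutpoints(
    curve: SplineCalibration,
    scheme: IntensityScheme = DEFAULT_SCHEME,
    internal_rate_hz: float = 30.0,
    age_group: str = "adult",
    filter_variant: str = "bp10hz",
) -> CutPointSet:
    """Invert a fitted mg-scale calibration curve at the MET thresholds.

    Each threshold is the smallest acceleration attaining the MET level
    (first crossing); unattainable levels are emitted as None. Counts
    thresholds follow from the variant's counts<->mg conversion at a
    one-minute epoch.
    """
    factor = counts_to_mg_factor(internal_rate_hz, 60.0)
    mg: dict[float, float | None] = {}
    cpm: dict[float, float | None] = {}
    for m in scheme.thresholds:
        a = curve.first_crossing(m)
        mg[m] = a
        cpm[m] = None if a is None else a / factor
    attained = [v for v in mg.values() if v is not None]
    if any(b <= a for a, b in zip(attained, attained[1:])):
        raise ValueError("derived cut-points are not strictly increasing")
    return CutPointSet(
        age_group=age_group,
        filter_variant=filter_variant,
        internal_rate_hz=internal_rate_hz,
        thresholds_mg=mg,
        thresholds_counts_per_min=cpm,
        scheme=scheme,
    )
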