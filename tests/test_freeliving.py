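"""Wear rules, daily window, classification and agreement summaries."""

import numpy as np
import pandas as pd
import pytest

from accelband.calibration import CutPointSet
from accelband.constants import DEFAULT_SCHEME, INTENSITY_LABELS
from accelband.freeliving import (
    IntensityClassifier,
    LabelSeries,
    WearMask,
    classify,
    confusion_chart,
    daily_window_mask,
    derive_wear_mask,
    filter_valid_days,
    intensity_distribution,
)
from accelband.recording import EpochSeries, RawRecording


def make_cutpoints(th=(20.0, 60.0, 150.0, 250.0), internal_rate=30.0):
    mg = dict(zip(DEFAULT_SCHEME.thresholds, th))
    factor = 4260.0 / (256 * internal_rate * 60)
    cpm = {m: v / factor for m, v in mg.items()}
    return CutPointSet("adult", "bp10hz", internal_rate, mg, cpm)


def make_series(values, epoch=60.0, unit="mg", start="2023-05-01 08:00:00"):
    return EpochSeries(start, epoch, np.asarray(values, float), unit,
                       "vector_magnitude", "bp10hz", 30.0)


class TestWearMask:
    def test_all_active_recording_is_all_wear(self):
        rec = RawRecording("2023-05-01", 30.0, np.zeros((30 * 600, 3)))
        mask = derive_wear_mask(rec, 60.0)
        assert mask.wear.all() and len(mask) == 10

    def test_idle_block_marks_nonwear_with_boundary_slack(self):
        n = 30 * 3600
        status = np.zeros(n, dtype=np.uint8)
        status[30 * 600: 30 * 1800] = 1  # 20 min idle
        rec = RawRecording("2023-05-01", 30.0, np.zeros((n, 3)), status=status)
        mask = derive_wear_mask(rec, 60.0)
        assert abs((~mask.wear).sum() - 20) <= 1

    def test_empty_recording_gives_empty_mask(self):
        rec = RawRecording("2023-05-01", 30.0, np.zeros((0, 3)))
        assert len(derive_wear_mask(rec, 60.0)) == 0


class TestValidDays:
    def _mask(self, wear_epochs, epoch=60.0):
        wear = np.zeros(1440, dtype=bool)
        wear[:wear_epochs] = True
        return WearMask(pd.Timestamp("2023-05-01"), epoch, wear)

    @pytest.mark.parametrize(
        "minutes,valid", [(13 * 60, True), (12 * 60, True), (12 * 60 - 1, False)]
    )
    def test_12h_boundary_inclusive(self, minutes, valid):
        days = filter_valid_days(self._mask(minutes))
        assert (len(days) == 1) is valid


class TestDailyWindow:
    @pytest.mark.parametrize(
        "start,kept",
        [("22:59:57", True), ("23:00:00", False), ("05:59:59", False),
         ("06:00:00", True)],
    )
    def test_epoch_start_convention(self, start, kept):
        times = pd.DatetimeIndex([pd.Timestamp(f"2023-05-01 {start}")])
        assert daily_window_mask(times)[0] == kept


class TestClassification:
    def test_boundary_is_lower_inclusive(self):
        clf = IntensityClassifier(make_cutpoints()).fit()
        labels = clf.predict([0.0, 19.9, 20.0, 60.0, 150.0, 250.0, 1e4])
        assert list(labels) == ["SED", "SED", "LPA", "MPA", "VPA", "VVPA", "VVPA"]

    def test_counts_cutpoints_scale_with_epoch_length(self):
        cps = make_cutpoints()
        clf = IntensityClassifier(cps, unit="counts").fit()
        cpm3 = cps.counts_array(3.0)
        labels = clf.predict([cpm3[1] - 1, cpm3[1]], epoch_length_s=3.0)
        assert list(labels) == ["LPA", "MPA"]

    def test_unit_mismatch_rejected(self):
        series = make_series([1.0], unit="nonsense")
        with pytest.raises(ValueError):
            classify(series, make_cutpoints())

    def test_classify_applies_wear_and_window(self):
        # epochs from 05:59 through 23:00; one non-wear epoch at 06:00
        start = "2023-05-01 05:59:00"
        vals = np.zeros(len(pd.date_range(start, "2023-05-01 23:00:00", freq="60s")))
        vals[:3] = [30.0, 30.0, 300.0]
        vals[-1] = 30.0
        series = make_series(vals, start=start)
        wear = WearMask(pd.Timestamp(start), 60.0, np.ones(len(vals), dtype=bool))
        wear.wear[1] = False
        ls = classify(series, make_cutpoints(), wear_mask=wear)
        assert ls.labels[0] == "excluded"  # before 06:00
        assert ls.labels[1] == "nonwear"
        assert ls.labels[2] == "VVPA"
        assert ls.labels[-1] == "excluded"  # 23:00:00 exactly

    def test_totals_partition_included_epochs(self):
        rng = np.random.default_rng(0)
        series = make_series(rng.uniform(0, 400, 500))
        ls = classify(series, make_cutpoints(), window=None)
        assert ls.included.sum() == 500
        counts = pd.Series(ls.labels).value_counts()
        assert counts.sum() == 500


class TestConfusion:
    def _labels(self, seq, epoch=60.0):
        return LabelSeries("2023-05-01", epoch, np.array(seq, dtype=object), "bp10hz")

    def test_self_comparison_is_identity(self):
        seq = ["SED"] * 5 + ["LPA", "MPA", "VPA", "VVPA"] * 3
        chart = confusion_chart(self._labels(seq), self._labels(seq))
        diag = np.diag(chart.matrix.to_numpy())
        assert np.allclose(diag, 100.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(1)
        a = rng.choice(INTENSITY_LABELS, 300)
        b = rng.choice(INTENSITY_LABELS, 300)
        chart = confusion_chart(self._labels(a), self._labels(b))
        assert np.allclose(chart.matrix.sum(axis=1), 100.0, atol=0.1)

    def test_empty_rows_flagged(self):
        a = self._labels(["SED", "LPA"] * 10)
        b = self._labels(["SED", "MPA"] * 10)
        chart = confusion_chart(a, b)
        assert "VVPA" in chart.empty_rows

    def test_excluded_epochs_ignored(self):
        a = self._labels(["SED", "nonwear", "MPA"])
        b = self._labels(["SED", "SED", "excluded"])
        chart = confusion_chart(a, b)
        assert chart.counts.to_numpy().sum() == 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_chart(self._labels(["SED"]), self._labels(["SED", "SED"]))


class TestDistribution:
    def _labels(self, seq):
        return LabelSeries("2023-05-01", 60.0, np.array(seq, dtype=object), "bp10hz")

    def test_all_sed(self):
        dist = intensity_distribution(self._labels(["SED"] * 20))
        assert dist["SED"] == pytest.approx(100.0)
        assert dist.drop("SED").sum() == 0.0

    def test_sums_to_100(self):
        rng = np.random.default_rng(2)
        ls = self._labels(list(rng.choice(INTENSITY_LABELS, 200)) + ["nonwear"] * 50)
        assert intensity_distribution(ls).sum() == pytest.approx(100.0, abs=0.1)

    def test_group_mean_over_subjects(self):
        a = self._labels(["SED"] * 10)
        b = self._labels(["MPA"] * 30)  # subject size must not weight the mean
        dist = intensity_distribution([a, b])
        assert dist["SED"] == pytest.approx(50.0)
        assert dist["MPA"] == pytest.approx(50.0)
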