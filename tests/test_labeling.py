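import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivestress.errors import SelectionError
from drivestress.io_formats import Segment, SegmentMap, SpeedRecording
from drivestress.labeling import (
    SELECTED_THRESHOLDS,
    ThresholdPair,
    assign_traffic_labels,
    default_grid,
    grid_search,
    label_road_type,
    label_traffic,
    speed_windows,
)


def make_speed(speeds, rate=1.0):
    t = np.arange(len(speeds)) / rate
    return SpeedRecording(t, np.asarray(speeds, dtype=float))


class TestSpeedWindows:
    def test_constant_speed(self):
        w = speed_windows(make_speed(np.full(720, 60.0)))
        assert len(w) == 2
        assert (w["ms"] == 60.0).all()
        assert (w["stds"] == 0.0).all()

    def test_two_level_mean(self):
        speeds = np.tile([20.0, 40.0], 180)  # one full window
        w = speed_windows(make_speed(speeds))
        assert w["ms"].iloc[0] == pytest.approx(30.0)

    def test_simulated_congestion_statistics(self, rng):
        speeds = rng.normal(25.0, 8.0, 360)
        w = speed_windows(make_speed(speeds))
        assert abs(w["ms"].iloc[0] - 25.0) < 3.0
        assert abs(w["stds"].iloc[0] - 8.0) < 4.0

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            speed_windows(make_speed(np.full(100, 30.0)))

    def test_trailing_partial_window_dropped(self):
        w = speed_windows(make_speed(np.full(500, 30.0)))
        assert len(w) == 1


class TestLabelTraffic:
    windows = pd.DataFrame(
        {
            "start": [0.0, 360.0, 720.0],
            "end": [360.0, 720.0, 1080.0],
            "ms": [30.0, 40.0, 35.0],
            "stds": [10.0, 10.0, 25.0],
            "valid": [True, True, True],
        }
    )

    def test_both_below_is_high_traffic(self):
        out = label_traffic(self.windows, ThresholdPair(40.0, 20.0))
        assert bool(out["high_traffic"].iloc[0]) is True

    def test_threshold_is_strict(self):
        out = label_traffic(self.windows, ThresholdPair(40.0, 20.0))
        assert bool(out["high_traffic"].iloc[1]) is False  # MS == 40 exactly

    def test_conjunction_required(self):
        out = label_traffic(self.windows, ThresholdPair(40.0, 20.0))
        assert bool(out["high_traffic"].iloc[2]) is False  # STDS too high

    def test_invalid_windows_stay_unlabeled(self):
        w = self.windows.copy()
        w.loc[0, "valid"] = False
        out = label_traffic(w, ThresholdPair(40.0, 20.0))
        assert pd.isna(out["high_traffic"].iloc[0])

    @settings(max_examples=40, deadline=None)
    @given(
        ms=st.lists(st.floats(0, 120), min_size=1, max_size=12),
        stds=st.floats(0, 40),
        thr_lo=st.sampled_from([(20.0, 10.0), (30.0, 15.0), (40.0, 20.0)]),
        bump=st.sampled_from([(10.0, 0.0), (0.0, 10.0), (10.0, 10.0)]),
    )
    def test_raising_thresholds_is_monotone(self, ms, stds, thr_lo, bump):
        n = len(ms)
        w = pd.DataFrame(
            {
                "start": np.arange(n) * 360.0,
                "end": (np.arange(n) + 1) * 360.0,
                "ms": ms,
                "stds": np.full(n, stds),
                "valid": np.full(n, True),
            }
        )
        lo = label_traffic(w, ThresholdPair(*thr_lo))["high_traffic"]
        hi_pair = ThresholdPair(thr_lo[0] + bump[0], thr_lo[1] + bump[1])
        hi = label_traffic(w, hi_pair)["high_traffic"]
        assert (hi | ~lo).all()  # high set never shrinks


class TestGridSearch:
    """Selection logic against a planted labeling, with a stub fit."""

    @staticmethod
    def _setup(truth_thr=ThresholdPair(40.0, 20.0), n=40, seed=0):
        rng = np.random.default_rng(seed)
        ms = np.where(rng.random(n) < 0.4, rng.uniform(15, 38, n), rng.uniform(55, 100, n))
        stds = np.where(ms < 40, rng.uniform(4, 18, n), rng.uniform(4, 28, n))
        windows = pd.DataFrame(
            {
                "start": np.arange(n) * 360.0,
                "end": (np.arange(n) + 1) * 360.0,
                "ms": ms,
                "stds": stds,
                "valid": np.full(n, True),
            }
        )
        features = pd.DataFrame(
            {
                "start": windows["start"],
                "end": windows["end"],
                "x": np.zeros(n),
            }
        )
        truth = label_traffic(windows, truth_thr)["high_traffic"].astype(bool)

        def stub_fit(feats, y):
            # a perfect classifier of the planted truth: its metrics
            # reflect pure label agreement with the generating criterion
            yt = truth.reindex(feats.index).to_numpy()
            tp = int(np.sum(yt & y)); tn = int(np.sum(~yt & ~y))
            fp = int(np.sum(~yt & y)); fn = int(np.sum(yt & ~y))
            def pct(a, b):
                return None if b == 0 else 100.0 * a / b
            return {
                "accuracy": pct(tp + tn, len(y)),
                "sensitivity": pct(tp, tp + fn),
                "specificity": pct(tn, tn + fp),
                "ppv": pct(tp, tp + fp),
            }

        return features, windows, stub_fit

    def test_grid_has_twenty_rows(self):
        features, windows, stub = self._setup()
        result = grid_search(features, windows, stub, min_class_cases=2)
        assert len(result.table) == 20
        assert len(default_grid()) == 20

    def test_planted_criterion_selected(self):
        features, windows, stub = self._setup()
        result = grid_search(features, windows, stub, min_class_cases=2)
        assert result.selected == SELECTED_THRESHOLDS

    def test_uniform_labels_raise_selection_error(self):
        features, windows, stub = self._setup()
        windows = windows.assign(ms=90.0, stds=25.0)  # no congestion anywhere
        with pytest.raises(SelectionError):
            grid_search(features, windows, stub, min_class_cases=2)

    def test_degenerate_rows_flagged(self):
        features, windows, stub = self._setup()
        result = grid_search(features, windows, stub, min_class_cases=2)
        low = result.table.iloc[0]  # (20, 10): almost nothing qualifies
        assert bool(low["degenerate"]) or low["mean_metric"] <= 100.0


class TestAssignTrafficLabels:
    def test_midpoint_containment(self):
        windows = pd.DataFrame(
            {
                "start": [0.0, 360.0],
                "end": [360.0, 720.0],
                "ms": [30.0, 80.0],
                "stds": [10.0, 10.0],
                "valid": [True, True],
            }
        )
        labeled = label_traffic(windows, ThresholdPair(40.0, 20.0))
        feats = pd.DataFrame(
            {"start": [0.0, 300.0, 700.0], "end": [360.0, 660.0, 1060.0]}
        )
        y = assign_traffic_labels(feats, labeled)
        assert bool(y.iloc[0]) is True     # midpoint 180 -> window 1 (high)
        assert bool(y.iloc[1]) is False    # midpoint 480 -> window 2 (low)
        assert pd.isna(y.iloc[2])          # midpoint 880 -> outside


class TestLabelRoadType:
    segments = SegmentMap(
        (
            Segment("City 1", "city", 0.0, 600.0),
            Segment("Highway 1", "highway", 600.0, 1320.0),
            Segment("Tollgate 1", "tollgate", 1320.0, 1380.0),
            Segment("Highway 2", "highway", 1380.0, 2100.0),
        )
    )

    @staticmethod
    def _windows(starts):
        return pd.DataFrame(
            {"start": starts, "end": [s + 360.0 for s in starts]}
        )

    def test_city_window_is_high_stress(self):
        labels = label_road_type(self._windows([0.0]), self.segments)
        assert labels.iloc[0] == "high"

    def test_highway_window_is_low_stress(self):
        labels = label_road_type(self._windows([1500.0]), self.segments)
        assert labels.iloc[0] == "low"

    def test_boundary_straddling_window_excluded(self):
        labels = label_road_type(self._windows([400.0]), self.segments)
        assert labels.iloc[0] == "excluded"

    def test_tollgate_touching_window_excluded(self):
        labels = label_road_type(self._windows([1000.0]), self.segments)
        assert labels.iloc[0] == "excluded"

    def test_window_outside_map_excluded(self):
        labels = label_road_type(self._windows([5000.0]), self.segments)
        assert labels.iloc[0] == "excluded"

    def test_every_window_gets_exactly_one_label(self):
        starts = np.arange(0.0, 1800.0, 60.0)
        labels = label_road_type(self._windows(list(starts)), self.segments)
        assert labels.isin(["high", "low", "excluded"]).all()
        assert len(labels) == len(starts)
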