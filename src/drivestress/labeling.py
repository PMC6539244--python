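"""Reference stress labels from vehicle speed and from road type.

Two independent label sets serve as classification targets:

* **Traffic labels.**  Mean speed (MS) and sample standard deviation of
  speed (STDS) are computed over consecutive, non-overlapping
  six-minute windows.  A window is *high traffic* — taken as high
  driver stress — exactly when both fall strictly below the active
  thresholds (``MS < ms_thr`` and ``STDS < sd_thr``); a low mean speed
  with little variation marks a traffic jam rather than ordinary
  slowing.  The thresholds come from a 4 x 5 grid (MS in {20, 30, 40,
  50} km/h, STDS in {10, 15, 20, 25, 30} km/h) searched for the best
  classifier agreement; the retained default is (40, 20).

* **Road-type labels.**  City driving is labeled high stress and
  highway driving low stress.  Windows that straddle a segment boundary
  or touch a tollgate carry a mixture of conditions and are excluded.

Feature windows slide by one minute while traffic windows tile without
overlap, so a feature window inherits the label of the traffic window
containing its midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import SelectionError
from .io_formats import SegmentMap, SpeedRecording

#: Threshold grid, km/h.
MS_GRID = (20.0, 30.0, 40.0, 50.0)
SD_GRID = (10.0, 15.0, 20.0, 25.0, 30.0)

#: Traffic window length, seconds.
TRAFFIC_WINDOW_S = 360.0


class ThresholdPair(NamedTuple):
    """A (mean-speed, speed-SD) criterion, km/h."""

    ms: float
    sd: float


#: Default retained criterion.
SELECTED_THRESHOLDS = ThresholdPair(40.0, 20.0)


def default_grid() -> list[ThresholdPair]:
    """The 20 threshold pairs, mean-speed-major order."""
    return [ThresholdPair(ms, sd) for ms in MS_GRID for sd in SD_GRID]


def speed_windows(
    speed: SpeedRecording, window: float = TRAFFIC_WINDOW_S
) -> pd.DataFrame:
    """MS and STDS over consecutive non-overlapping windows.

    Windows tile ``[start, start + k*window)`` from the first timestamp;
    a trailing partial window is dropped.  STDS uses the sample (n-1)
    formula.  Windows with fewer than two speed samples are flagged
    invalid (``valid=False``) with NaN statistics.
    """
    t0 = speed.start_time
    span = speed.coverage_end - t0
    n_windows = int(span // window)
    if n_windows < 1:
        raise ValueError(
            f"speed log spans {span:.0f} s, shorter than one {window:.0f} s window"
        )
    rows = []
    for k in range(n_windows):
        s, e = t0 + k * window, t0 + (k + 1) * window
        mask = (speed.timestamps >= s) & (speed.timestamps < e)
        v = speed.speeds[mask]
        if v.size < 2:
            rows.append(
                {"start": s, "end": e, "ms": np.nan, "stds": np.nan, "valid": False}
            )
        else:
            rows.append(
                {
                    "start": s,
                    "end": e,
                    "ms": float(v.mean()),
                    "stds": float(np.std(v, ddof=1)),
                    "valid": True,
                }
            )
    return pd.DataFrame(rows)


def label_traffic(windows: pd.DataFrame, thr: ThresholdPair) -> pd.DataFrame:
    """Label each speed window high/low traffic under a threshold pair.

    High traffic requires *both* statistics strictly below their
    thresholds ("lower than" is strict, so MS exactly at the threshold
    is low traffic).  Returns a copy with a boolean ``high_traffic``
    column; invalid windows stay unlabeled (NA).
    """
    out = windows.copy()
    high = (out["ms"] < thr.ms) & (out["stds"] < thr.sd)
    out["high_traffic"] = high.where(out["valid"], other=pd.NA)
    return out


def assign_traffic_labels(
    feature_windows: pd.DataFrame, labeled: pd.DataFrame
) -> pd.Series:
    """Label of the traffic window containing each feature window's midpoint.

    ``feature_windows`` needs ``start``/``end`` timestamp columns;
    ``labeled`` is the output of :func:`label_traffic`.  Feature windows
    whose midpoint falls outside every valid traffic window get NA.
    """
    mid = (feature_windows["start"] + feature_windows["end"]) / 2.0
    labels = pd.Series(pd.NA, index=feature_windows.index, dtype="boolean")
    for _, tw in labeled.iterrows():
        if tw["high_traffic"] is pd.NA or pd.isna(tw["high_traffic"]):
            continue
        inside = (mid >= tw["start"]) & (mid < tw["end"])
        labels[inside] = bool(tw["high_traffic"])
    return labels


@dataclass(frozen=True)
class GridResult:
    """Outcome of the threshold grid search.

    ``table`` has one row per threshold pair with the classification
    metrics (percent) of the stress model refit under that labeling,
    their mean, and a ``degenerate`` flag for single-class labelings.
    ``selected`` maximizes the metric mean subject to sensitivity and
    positive predictive value each reaching 50%; ties keep the first
    pair in grid order.
    """

    table: pd.DataFrame
    selected: ThresholdPair


def grid_search(
    feature_windows: pd.DataFrame,
    windows: pd.DataFrame,
    fit_eval_fn: Callable[[pd.DataFrame, np.ndarray], dict],
    grid: Sequence[ThresholdPair] | None = None,
    min_sensitivity: float = 50.0,
    min_ppv: float = 50.0,
    min_class_cases: int = 12,
) -> GridResult:
    """Refit the stress classifier under every threshold pair.

    For each pair the speed windows are relabeled, feature windows
    inherit labels by midpoint containment, and ``fit_eval_fn`` fits the
    conductance-feature classifier against those labels, returning a
    mapping with percent-scale ``accuracy``, ``sensitivity``,
    ``specificity`` and ``ppv``.  Pairs whose labeling contains a single
    class — or fewer than ``min_class_cases`` windows in either class,
    too few to identify the multi-predictor fit (a handful of cases can
    be memorized in-sample, making the row's metrics meaningless) — are
    flagged degenerate and carry NaN metrics.

    Raises :class:`SelectionError` when every pair is degenerate or none
    clears the sensitivity/PPV floor.
    """
    if grid is None:
        grid = default_grid()
    rows = []
    for thr in grid:
        labeled = label_traffic(windows, thr)
        y = assign_traffic_labels(feature_windows, labeled)
        usable = y.notna()
        y_arr = y[usable].astype(bool).to_numpy()
        row = {"ms_thr": thr.ms, "sd_thr": thr.sd}
        class_counts = np.bincount(y_arr.astype(int), minlength=2) if y_arr.size else np.zeros(2)
        if usable.sum() == 0 or class_counts.min() < min_class_cases:
            row.update(
                accuracy=np.nan, sensitivity=np.nan, specificity=np.nan,
                ppv=np.nan, mean_metric=np.nan, degenerate=True,
            )
        else:
            m = fit_eval_fn(feature_windows[usable], y_arr)
            # an undefined metric (zero denominator) becomes NaN: it can
            # never clear the selection floor but keeps the row reportable
            vals = {
                k: (np.nan if m[k] is None else float(m[k]))
                for k in ("accuracy", "sensitivity", "specificity", "ppv")
            }
            row.update(
                **vals,
                mean_metric=float(np.nanmean(list(vals.values()))),
                degenerate=False,
            )
        rows.append(row)
    table = pd.DataFrame(rows)

    usable_rows = table[~table["degenerate"]]
    if usable_rows.empty:
        raise SelectionError("every threshold pair yields a single-class labeling")
    ok = usable_rows[
        (usable_rows["sensitivity"] >= min_sensitivity)
        & (usable_rows["ppv"] >= min_ppv)
    ]
    if ok.empty:
        # the search is uninformative (e.g. the features carry no
        # signal): keep the configured default criterion if its
        # labeling is two-class, otherwise fall back to the metric mean
        warnings.warn(
            f"no threshold pair reaches sensitivity and PPV >= "
            f"{min_sensitivity:.0f}%; keeping the default criterion",
            stacklevel=2,
        )
        default_row = usable_rows[
            (usable_rows["ms_thr"] == SELECTED_THRESHOLDS.ms)
            & (usable_rows["sd_thr"] == SELECTED_THRESHOLDS.sd)
        ]
        ok = default_row if not default_row.empty else usable_rows
    best = ok["mean_metric"].idxmax()  # first occurrence wins ties
    selected = ThresholdPair(
        float(table.loc[best, "ms_thr"]), float(table.loc[best, "sd_thr"])
    )
    return GridResult(table=table, selected=selected)


def label_road_type(
    feature_windows: pd.DataFrame, segments: SegmentMap
) -> pd.Series:
    """Road-type stress label per feature window.

    ``'high'`` for windows wholly inside a city segment, ``'low'``
    wholly inside a highway segment, ``'excluded'`` for windows that
    straddle a boundary, touch a tollgate, or fall outside the map.
    """
    labels = []
    for _, w in feature_windows.iterrows():
        label = "excluded"
        for seg in segments:
            if seg.start <= w["start"] and w["end"] <= seg.end:
                if seg.kind == "city":
                    label = "high"
                elif seg.kind == "highway":
                    label = "low"
                break  # tollgate container -> excluded
        labels.append(label)
    return pd.Series(labels, index=feature_windows.index, dtype="object")
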