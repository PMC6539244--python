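"""Skin-conductance response detection and windowed feature statistics.

A phasic skin conductance response (SCR) is the valley-to-peak rise of
the conductance trace.  Each detected excursion carries two quantities:

* ``om`` — amplitude: conductance at the peak minus conductance at the
  preceding valley (µS);
* ``od`` — duration: peak index minus valley index, in samples at the
  analysis rate.

Features are the per-window min / max / mean / SD / sum / count of both
quantities over sliding analysis windows (six minutes long, sliding by
one minute at 15.5 Hz by default).  The amplitude and duration counts
are equal by construction, so models use a single count column ``n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocess import ANALYSIS_RATE_HZ, ProcessedEda

#: Default peak/valley prominence threshold — the sensor's resolution
#: floor (its working range starts at 0.01 µS).
MIN_PROMINENCE_US = 0.01

#: Feature column names as written to feature tables.
FEATURE_COLUMNS = [
    "min_od", "max_od", "mean_od", "sd_od", "sum_od", "n_od",
    "min_om", "max_om", "mean_om", "sd_om", "sum_om", "n_om",
]

#: Default predictor set for the logistic models: the event count plus
#: five amplitude statistics and four duration statistics.  The duration
#: count duplicates the amplitude count and the duration SD is withheld,
#: leaving ten predictors.
MODEL_FEATURES = [
    "n", "mean_om", "max_om", "min_om", "sum_om", "sd_om",
    "max_od", "min_od", "sum_od", "mean_od",
]


@dataclass(frozen=True)
class ScrEvent:
    """One valley-to-peak conductance excursion."""

    valley_index: int
    peak_index: int
    om: float  # amplitude, µS

    def __post_init__(self) -> None:
        if self.peak_index <= self.valley_index:
            raise ValueError("peak must follow its valley")
        if self.om <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def od(self) -> int:
        """Rise duration in samples at the analysis rate."""
        return self.peak_index - self.valley_index


@dataclass(frozen=True)
class WindowScheme:
    """Sliding analysis windows: length and slide in seconds at a rate.

    The defaults (360 s windows sliding by 60 s at 15.5 Hz) give
    5580-sample windows stepping by 930 samples.
    """

    window_length: float = 360.0
    step: float = 60.0
    rate: float = ANALYSIS_RATE_HZ

    def __post_init__(self) -> None:
        if not (self.window_length >= self.step > 0):
            raise ValueError("need window_length >= step > 0")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        for name, seconds in (("window", self.window_length), ("step", self.step)):
            samples = seconds * self.rate
            if abs(samples - round(samples)) > 1e-9:
                raise ValueError(
                    f"{name} of {seconds} s is not a whole number of samples at "
                    f"{self.rate} Hz"
                )

    @property
    def window_samples(self) -> int:
        return int(round(self.window_length * self.rate))

    @property
    def step_samples(self) -> int:
        return int(round(self.step * self.rate))

    def windows(self, signal_length: int) -> list[tuple[int, int]]:
        """Sample-index spans ``[start, end)`` of every full window."""
        out = []
        start = 0
        while start + self.window_samples <= signal_length:
            out.append((start, start + self.window_samples))
            start += self.step_samples
        return out


def _enforce_alternation(
    x: np.ndarray, peaks: np.ndarray, valleys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Drop extrema so peaks and valleys strictly alternate.

    Of several consecutive peaks with no valley between them the highest
    survives; of consecutive valleys the lowest.
    """
    marks = sorted(
        [(int(i), +1) for i in peaks] + [(int(i), -1) for i in valleys]
    )
    kept: list[tuple[int, int]] = []
    for idx, kind in marks:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            better = (
                x[idx] > x[prev_idx] if kind == +1 else x[idx] < x[prev_idx]
            )
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    new_peaks = np.array([i for i, k in kept if k == +1], dtype=int)
    new_valleys = np.array([i for i, k in kept if k == -1], dtype=int)
    return new_peaks, new_valleys


def find_extrema(
    x, min_prominence: float = MIN_PROMINENCE_US
) -> tuple[np.ndarray, np.ndarray]:
    """Locate alternating peaks and valleys of a conductance trace.

    Peaks are local maxima with topographic prominence of at least
    ``min_prominence``; valleys are prominent local minima (maxima of
    the negated trace).  After alternation enforcement there is exactly
    one valley between consecutive peaks and vice versa.  A flat or
    monotone trace yields two empty index arrays.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three samples to find extrema")
    peaks, _ = find_peaks(x, prominence=min_prominence)
    valleys, _ = find_peaks(-x, prominence=min_prominence)
    return _enforce_alternation(x, peaks, valleys)


def pair_events(peaks, valleys, x) -> list[ScrEvent]:
    """Pair every peak with its nearest preceding valley.

    Amplitude is the conductance rise from valley to peak; peaks with no
    preceding valley or a non-positive rise are dropped.
    """
    x = np.asarray(x, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    valleys = np.asarray(valleys, dtype=int)
    events: list[ScrEvent] = []
    if peaks.size == 0 or valleys.size == 0:
        return events
    for p in peaks:
        pos = int(np.searchsorted(valleys, p))
        if pos == 0:
            continue  # peak before any valley
        v = int(valleys[pos - 1])
        om = float(x[p] - x[v])
        if om <= 0:
            continue
        events.append(ScrEvent(valley_index=v, peak_index=int(p), om=om))
    return events


def _window_row(oms: np.ndarray, ods: np.ndarray) -> dict:
    n = len(oms)
    if n == 0:
        return {c: 0.0 for c in FEATURE_COLUMNS} | {"empty": True}
    sd_om = float(np.std(oms, ddof=1)) if n >= 2 else 0.0
    sd_od = float(np.std(ods, ddof=1)) if n >= 2 else 0.0
    return {
        "min_od": float(ods.min()), "max_od": float(ods.max()),
        "mean_od": float(ods.mean()), "sd_od": sd_od,
        "sum_od": float(ods.sum()), "n_od": float(n),
        "min_om": float(oms.min()), "max_om": float(oms.max()),
        "mean_om": float(oms.mean()), "sd_om": sd_om,
        "sum_om": float(oms.sum()), "n_om": float(n),
        "empty": False,
    }


def window_features(
    events: list[ScrEvent], scheme: WindowScheme, signal_length: int
) -> pd.DataFrame:
    """Twelve amplitude/duration statistics for every analysis window.

    An event belongs to the window(s) containing its peak sample, so its
    membership is unambiguous within any single tiling.  Standard
    deviations use the sample (n-1) formula and are zero for windows
    with fewer than two events.  Windows without events keep zero-valued
    statistics and set ``empty`` so the feature matrix stays
    rectangular.

    Returns one row per window with ``window_id``, sample span, the
    columns in :data:`FEATURE_COLUMNS`, an ``n`` alias of ``n_om``, and
    the ``empty`` flag.
    """
    spans = scheme.windows(signal_length)
    if not spans:
        warnings.warn(
            f"signal of {signal_length} samples is shorter than one "
            f"{scheme.window_samples}-sample window",
            stacklevel=2,
        )
    peak_idx = np.array([e.peak_index for e in events], dtype=int)
    oms = np.array([e.om for e in events], dtype=float)
    ods = np.array([e.od for e in events], dtype=float)
    order = np.argsort(peak_idx, kind="stable")
    peak_idx, oms, ods = peak_idx[order], oms[order], ods[order]

    rows = []
    for wid, (s, e) in enumerate(spans):
        lo = int(np.searchsorted(peak_idx, s, side="left"))
        hi = int(np.searchsorted(peak_idx, e, side="left"))
        row = {"window_id": wid, "start_sample": s, "end_sample": e}
        row.update(_window_row(oms[lo:hi], ods[lo:hi]))
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["window_id", "start_sample", "end_sample", *FEATURE_COLUMNS, "empty"],
    )
    df["n"] = df["n_om"]
    return df


def extract_features(
    processed: ProcessedEda,
    scheme: WindowScheme | None = None,
    min_prominence: float = MIN_PROMINENCE_US,
) -> pd.DataFrame:
    """Full chain: detect extrema, pair events, window the statistics.

    Adds absolute ``start`` / ``end`` timestamps (seconds) per window.
    """
    if scheme is None:
        scheme = WindowScheme(rate=processed.rate)
    elif abs(scheme.rate - processed.rate) > 1e-9:
        raise ValueError(
            f"scheme rate {scheme.rate} Hz does not match signal rate "
            f"{processed.rate} Hz"
        )
    peaks, valleys = find_extrema(processed.values, min_prominence)
    events = pair_events(peaks, valleys, processed.values)
    df = window_features(events, scheme, len(processed))
    df["start"] = processed.start_time + df["start_sample"] / processed.rate
    df["end"] = processed.start_time + df["end_sample"] / processed.rate
    return df
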