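"""Resampling, smoothing and time-slicing of the conductance signal.

The analysis chain brings the raw 4 Hz skin-conductance stream onto a
15.5 Hz grid by linear interpolation, then applies a trailing moving
average (60 samples by default).  At 15.5 Hz a six-minute analysis
window is exactly 5580 samples and a one-minute slide 930 samples, so
window bookkeeping stays in whole samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySliceError
from .io_formats import EdaRecording, Segment, SpeedRecording

#: Default analysis sampling rate, Hz.
ANALYSIS_RATE_HZ = 15.5
#: Default trailing moving-average window, samples at the analysis rate.
SMOOTH_WINDOW = 60


@dataclass(frozen=True)
class ProcessedEda:
    """Conductance series on the analysis clock.

    ``provenance`` records the source rate and smoothing window so a
    feature table can be traced back to its preprocessing settings.
    """

    start_time: float
    rate: float
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ValueError("analysis rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate


def resample_linear(
    rec: EdaRecording, target_rate: float = ANALYSIS_RATE_HZ
) -> ProcessedEda:
    """Resample a recording onto a uniform ``target_rate`` grid.

    Output sample ``k`` is the linear interpolation of the source at
    ``k / target_rate`` after the recording start.  The output covers the
    same duration as the input (``n_out = round(n_in * target / source)``),
    so one minute of 4 Hz signal becomes 930 samples at 15.5 Hz.  The few
    output instants past the last source sample hold its value.

    Raises ``ValueError`` for single-sample inputs, which cannot be
    interpolated.
    """
    if len(rec) < 2:
        raise ValueError("resampling needs at least two source samples")
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    n_out = max(1, int(round(len(rec) * target_rate / rec.rate)))
    t_out = np.arange(n_out) / target_rate
    t_in = np.arange(len(rec)) / rec.rate
    values = np.interp(t_out, t_in, rec.values)
    return ProcessedEda(
        start_time=rec.start_time,
        rate=target_rate,
        values=values,
        provenance={"source_rate": rec.rate, "smooth_window": None},
    )


def moving_average(x, w: int = SMOOTH_WINDOW) -> np.ndarray:
    """Trailing moving average with prefix shortening.

    Output ``i`` is the mean of ``x[max(0, i-w+1) .. i]``; the first
    ``w-1`` outputs average over the shorter available prefix, so the
    result has the same length as the input and no startup transient of
    missing values.  Causal (trailing) alignment suits streamed
    physiological signals.
    """
    if w < 1:
        raise ValueError(f"window must be >= 1, got {w}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("input must be non-empty")
    return (
        pd.Series(x).rolling(window=w, min_periods=1).mean().to_numpy()
    )


def smooth(p: ProcessedEda, w: int = SMOOTH_WINDOW) -> ProcessedEda:
    """Apply :func:`moving_average` to a processed series, keeping provenance."""
    prov = dict(p.provenance)
    prov["smooth_window"] = w
    return ProcessedEda(
        start_time=p.start_time,
        rate=p.rate,
        values=moving_average(p.values, w),
        provenance=prov,
    )


def preprocess_eda(
    rec: EdaRecording,
    target_rate: float = ANALYSIS_RATE_HZ,
    smooth_window: int = SMOOTH_WINDOW,
    smooth_enabled: bool = True,
) -> ProcessedEda:
    """Resample then (optionally) smooth — the standard preprocessing chain."""
    out = resample_linear(rec, target_rate)
    if smooth_enabled:
        out = smooth(out, smooth_window)
    return out


def slice_by_segment(series, seg: Segment):
    """Sub-series with timestamps inside ``[seg.start, seg.end)``.

    Accepts an :class:`~drivestress.io_formats.EdaRecording`,
    :class:`ProcessedEda` or
    :class:`~drivestress.io_formats.SpeedRecording`; returns the same
    type.  Raises :class:`EmptySliceError` when nothing intersects.
    """
    if isinstance(series, SpeedRecording):
        mask = (series.timestamps >= seg.start) & (series.timestamps < seg.end)
        if not mask.any():
            raise EmptySliceError(
                f"segment {seg.name!r} does not intersect the speed log"
            )
        return SpeedRecording(
            timestamps=series.timestamps[mask], speeds=series.speeds[mask]
        )

    times = series.times()
    mask = (times >= seg.start) & (times < seg.end)
    if not mask.any():
        raise EmptySliceError(f"segment {seg.name!r} does not intersect the recording")
    first = int(np.argmax(mask))
    if isinstance(series, ProcessedEda):
        return ProcessedEda(
            start_time=float(times[first]),
            rate=series.rate,
            values=series.values[mask],
            provenance=dict(series.provenance),
        )
    return EdaRecording(
        start_time=float(times[first]), rate=series.rate, values=series.values[mask]
    )
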