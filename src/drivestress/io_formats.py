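"""Readers, writers and alignment for the drive-data file dialects.

Three streams describe one drive:

* skin conductance from a wrist-worn EDA sensor, exported as a bare CSV
  whose first line is the Unix start time, second line the sampling rate
  in Hz, and every following line one conductance sample in microsiemens;
* vehicle speed decoded from an OBD-II logger, as a two-column CSV of
  Unix timestamp and speed in km/h;
* a route segment map (city / highway / tollgate intervals) as YAML or
  JSON.

Time intervals are half-open ``[start, end)`` throughout: a sample
belongs to the segment that contains its timestamp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import (
    AlignmentError,
    EmptyRecordingError,
    FormatError,
    OrderingError,
)

SEGMENT_KINDS = ("city", "highway", "tollgate")

#: Minimum overlap (seconds) two streams must share to be analysed
#: jointly — one analysis window.
MIN_OVERLAP_S = 360.0


@dataclass(frozen=True)
class EdaRecording:
    """Uniformly sampled skin-conductance series.

    Sample ``i`` is taken at ``start_time + i / rate``; the recording
    covers the half-open interval ``[start_time, start_time + n / rate)``.

    Parameters
    ----------
    start_time : float
        Unix time (seconds, UTC) of the first sample.
    rate : float
        Sampling rate in Hz, strictly positive.
    values : numpy.ndarray
        Conductance samples in microsiemens (µS).
    """

    start_time: float
    rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not np.isfinite(self.start_time):
            raise FormatError("start_time must be finite")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise FormatError(f"rate must be a positive number, got {self.rate!r}")
        if values.ndim != 1 or values.size < 1:
            raise EmptyRecordingError("a recording needs at least one sample")
        if not np.all(np.isfinite(values)):
            raise FormatError("conductance samples must all be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Covered duration in seconds (``n / rate``)."""
        return len(self.values) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Unix timestamp of every sample."""
        return self.start_time + np.arange(len(self.values)) / self.rate


@dataclass(frozen=True)
class SpeedRecording:
    """Timestamped vehicle speed log (km/h), strictly increasing in time."""

    timestamps: np.ndarray
    speeds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.speeds, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "speeds", v)
        if t.shape != v.shape or t.ndim != 1:
            raise FormatError("timestamps and speeds must be equal-length 1-D arrays")
        if t.size < 1:
            raise EmptyRecordingError("a speed log needs at least one row")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise FormatError("speed log entries must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise OrderingError("speed timestamps must be strictly increasing")
        if np.any(v < 0):
            raise FormatError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def start_time(self) -> float:
        return float(self.timestamps[0])

    @property
    def end_time(self) -> float:
        return float(self.timestamps[-1])

    @property
    def coverage_end(self) -> float:
        """End of the covered interval: one sampling step past the last
        timestamp, so a log sampled at 1 Hz from 0 covers [0, n)."""
        if len(self) < 2:
            return self.end_time
        return self.end_time + float(np.median(np.diff(self.timestamps)))


@dataclass(frozen=True)
class Segment:
    """One route interval: a named city/highway/tollgate stretch."""

    name: str
    kind: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise FormatError(
                f"segment kind must be one of {SEGMENT_KINDS}, got {self.kind!r}"
            )
        if not self.start < self.end:
            raise FormatError(
                f"segment {self.name!r}: start ({self.start}) must precede end ({self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class SegmentMap:
    """Ordered, non-overlapping route segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"segments {a.name!r} and {b.name!r} overlap or are out of order"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def start_time(self) -> float:
        return self.segments[0].start

    @property
    def end_time(self) -> float:
        return self.segments[-1].end

    def segment_at(self, t: float) -> Segment | None:
        """Segment containing time ``t``, or None between/outside segments."""
        for seg in self.segments:
            if seg.contains(t):
                return seg
        return None


# ---------------------------------------------------------------------------
# EDA CSV dialect (wrist-sensor export style)
# ---------------------------------------------------------------------------

def read_e4_csv(path: str | Path) -> EdaRecording:
    """Read a wrist-sensor style EDA CSV.

    Line 1 holds the Unix start time, line 2 the sampling rate in Hz,
    and each later line one conductance sample in µS.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise FormatError(f"{path}: missing start-time/rate header lines")
    try:
        start_time = float(lines[0])
        rate = float(lines[1])
    except ValueError as exc:
        raise FormatError(f"{path}: garbled header: {exc}") from exc
    if rate <= 0:
        raise FormatError(f"{path}: non-positive sampling rate {rate}")
    if len(lines) == 2:
        raise EmptyRecordingError(f"{path}: no samples after the header")
    try:
        values = np.array([float(v) for v in lines[2:]], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample line: {exc}") from exc
    return EdaRecording(start_time=start_time, rate=rate, values=values)


def write_e4_csv(rec: EdaRecording, path: str | Path) -> Path:
    """Write ``rec`` in the dialect read by :func:`read_e4_csv` (round-trips)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{float(rec.start_time)!r}\n{float(rec.rate)!r}\n")
        fh.writelines(f"{float(v)!r}\n" for v in rec.values)
    return path


# ---------------------------------------------------------------------------
# Speed log CSV
# ---------------------------------------------------------------------------

def read_speed_log(path: str | Path) -> SpeedRecording:
    """Read a ``timestamp,speed_kmh`` CSV into a validated SpeedRecording."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"timestamp", "speed_kmh"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return SpeedRecording(
        timestamps=df["timestamp"].to_numpy(dtype=float),
        speeds=df["speed_kmh"].to_numpy(dtype=float),
    )


def write_speed_log(rec: SpeedRecording, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"timestamp": rec.timestamps, "speed_kmh": rec.speeds}).to_csv(
        path, index=False
    )
    return path


# ---------------------------------------------------------------------------
# Segment map (YAML or JSON)
# ---------------------------------------------------------------------------

def read_segment_map(path: str | Path) -> SegmentMap:
    """Read a YAML/JSON list of ``{name, kind, start, end}`` entries."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)  # YAML is a superset of JSON
    if not isinstance(raw, list) or not raw:
        raise FormatError(f"{path}: expected a non-empty list of segment entries")
    segments = []
    for entry in raw:
        try:
            segments.append(
                Segment(
                    name=str(entry["name"]),
                    kind=str(entry["kind"]),
                    start=float(entry["start"]),
                    end=float(entry["end"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad segment entry {entry!r}: {exc}") from exc
    return SegmentMap(segments=tuple(segments))


def write_segment_map(segmap: SegmentMap, path: str | Path) -> Path:
    path = Path(path)
    payload = [dataclasses.asdict(seg) for seg in segmap]
    with path.open("w") as fh:
        if path.suffix.lower() == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Stream alignment
# ---------------------------------------------------------------------------

def align_streams(
    eda: EdaRecording,
    speed: SpeedRecording,
    segments: SegmentMap,
    min_overlap: float = MIN_OVERLAP_S,
) -> tuple[EdaRecording, SpeedRecording, SegmentMap]:
    """Clip all three streams to their common time interval.

    The common interval is the intersection of the EDA and speed spans;
    segments are clipped to it and empty ones dropped.  Raises
    :class:`AlignmentError` when the overlap is shorter than
    ``min_overlap`` seconds (one analysis window by default).
    """
    t0 = max(eda.start_time, speed.start_time)
    t1 = min(eda.end_time, speed.coverage_end)
    if t1 - t0 < min_overlap:
        raise AlignmentError(
            f"streams overlap for {max(t1 - t0, 0.0):.1f} s, "
            f"need at least {min_overlap:.0f} s"
        )

    # EDA: keep samples whose timestamps fall in [t0, t1).
    times = eda.times()
    keep = (times >= t0) & (times < t1)
    first = int(np.argmax(keep))
    eda_out = EdaRecording(
        start_time=float(times[first]),
        rate=eda.rate,
        values=eda.values[keep],
    )

    mask = (speed.timestamps >= t0) & (speed.timestamps <= t1)
    speed_out = SpeedRecording(
        timestamps=speed.timestamps[mask], speeds=speed.speeds[mask]
    )

    clipped = []
    for seg in segments:
        s, e = max(seg.start, t0), min(seg.end, t1)
        if s < e:
            clipped.append(Segment(name=seg.name, kind=seg.kind, start=s, end=e))
    segmap_out = SegmentMap(segments=tuple(clipped))
    return eda_out, speed_out, segmap_out
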