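"""Synthetic drives with known ground truth.

Generates the three streams of a commuting drive — vehicle speed, a
route segment map, and a skin-conductance signal — from an explicit
latent stress state, so every pipeline stage can be checked against
planted truth.

A drive is ~60 minutes over five main segments (two city stretches and
three highway stretches, separated by two tollgate points).  Speed is
drawn per second from the Gaussian regime of the active segment kind,
overridden inside planted congestion episodes (low mean, low spread,
e.g. 25 ± 8 km/h — strictly inside the default traffic-jam criterion of
mean < 40 and SD < 20 km/h).  City free flow (35 ± 15 km/h) also sits
inside that criterion, mimicking stop-and-go urban traffic; highway
free flow (90 ± 12 km/h) sits far outside it.

The latent stress state is *high* during city driving and during
congestion episodes, and *low* otherwise.  Conductance is a tonic
baseline with a slow sinusoidal drift plus phasic skin conductance
responses at Poisson event times: the event rate and the (log-normal)
amplitude distribution depend on the stress state, each response rising
linearly to its amplitude and decaying exponentially.  Gaussian sensor
noise is added on top.  All randomness flows from one seed through
named substreams, so fixtures are reproducible component-wise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyRecordingError
from .io_formats import (
    EdaRecording,
    Segment,
    SegmentMap,
    SpeedRecording,
    write_e4_csv,
    write_segment_map,
    write_speed_log,
)

#: Sensor sampling rates, Hz.
EDA_RATE_HZ = 4.0
SPEED_RATE_HZ = 1.0

#: Free-flow speed regimes (mean, SD) in km/h per segment kind.
FREE_FLOW = {
    "city": (35.0, 15.0),
    "highway": (90.0, 12.0),
    "tollgate": (30.0, 10.0),
}


@dataclass(frozen=True)
class CongestionEpisode:
    """A planted traffic jam: interval plus its speed regime."""

    start: float      # seconds from drive start
    duration: float   # seconds
    mu_speed: float   # km/h
    sd_speed: float   # km/h

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sd_speed < 0:
            raise ValueError("episode needs positive duration and SD >= 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class DrivePlan:
    """Route layout and speed regimes of one simulated drive."""

    segments: tuple[tuple[str, float], ...] = (
        ("city", 600.0),
        ("highway", 720.0),
        ("tollgate", 60.0),
        ("highway", 720.0),
        ("tollgate", 60.0),
        ("highway", 720.0),
        ("city", 720.0),
    )
    episodes: tuple[CongestionEpisode, ...] = (
        CongestionEpisode(start=1440.0, duration=360.0, mu_speed=25.0, sd_speed=8.0),
    )
    free_flow: dict = field(default_factory=lambda: dict(FREE_FLOW))

    def __post_init__(self) -> None:
        for kind, dur in self.segments:
            if kind not in FREE_FLOW or dur <= 0:
                raise ValueError(f"bad segment ({kind!r}, {dur})")
        for ep in self.episodes:
            if not (0 <= ep.start and ep.end <= self.duration):
                raise ValueError(f"episode {ep} outside the drive")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.segments))

    def segment_map(self, start_time: float = 0.0) -> SegmentMap:
        """Absolute-time SegmentMap with segments numbered per kind."""
        out, t, counters = [], start_time, {}
        for kind, dur in self.segments:
            counters[kind] = counters.get(kind, 0) + 1
            name = f"{kind.capitalize()} {counters[kind]}"
            out.append(Segment(name=name, kind=kind, start=t, end=t + dur))
            t += dur
        return SegmentMap(segments=tuple(out))

    def kind_per_second(self) -> np.ndarray:
        """Segment kind of every whole second of the drive."""
        n = int(round(self.duration))
        kinds = np.empty(n, dtype=object)
        t = 0
        for kind, dur in self.segments:
            kinds[t : t + int(round(dur))] = kind
            t += int(round(dur))
        return kinds

    def stress_per_second(self) -> np.ndarray:
        """Latent high-stress flag per second: city driving or congestion."""
        kinds = self.kind_per_second()
        high = kinds == "city"
        secs = np.arange(len(kinds), dtype=float)
        for ep in self.episodes:
            high |= (secs >= ep.start) & (secs < ep.end)
        return high


@dataclass(frozen=True)
class EdaModel:
    """Generative parameters of the synthetic conductance signal.

    Rates are SCR events per minute; amplitudes are log-normal with the
    given median (µS) and log-scale sigma; rise times are uniform in
    seconds; the decay is exponential with time constant ``decay_tau``
    seconds; ``noise_sd`` is the white sensor noise in µS.
    """

    tonic_level: float = 0.3
    drift_amplitude: float = 0.05
    drift_period: float = 1200.0
    rate_low: float = 4.0
    rate_high: float = 12.0
    amp_median_low: float = 0.05
    amp_median_high: float = 0.15
    amp_log_sigma: float = 0.4
    rise_min_s: float = 1.0
    rise_max_s: float = 3.0
    decay_tau: float = 4.0
    noise_sd: float = 0.003

    def __post_init__(self) -> None:
        if not (self.rate_high >= self.rate_low > 0):
            raise ValueError("need rate_high >= rate_low > 0")
        if min(self.amp_median_low, self.amp_median_high) <= 0:
            raise ValueError("amplitude medians must be positive")
        if not (0 < self.rise_min_s <= self.rise_max_s):
            raise ValueError("need 0 < rise_min_s <= rise_max_s")


def null_eda_model(base: EdaModel | None = None) -> EdaModel:
    """A no-signal variant: identical event statistics in both states."""
    base = base or EdaModel()
    return dataclasses.replace(
        base, rate_high=base.rate_low, amp_median_high=base.amp_median_low
    )


@dataclass(frozen=True)
class ScrTruth:
    """Ground truth for one planted conductance response."""

    time: float        # onset, seconds from drive start
    amplitude: float   # µS
    rise_s: float      # rise duration, seconds
    high_stress: bool


def simulate_speed(
    plan: DrivePlan,
    rate: float = SPEED_RATE_HZ,
    rng: np.random.Generator | None = None,
    start_time: float = 0.0,
) -> SpeedRecording:
    """Per-sample Gaussian speeds under the plan's regimes, floored at 0."""
    rng = rng or np.random.default_rng(0)
    n = int(round(plan.duration * rate))
    times = np.arange(n) / rate
    kinds = plan.kind_per_second()
    mu = np.array([plan.free_flow[k][0] for k in kinds], dtype=float)
    sd = np.array([plan.free_flow[k][1] for k in kinds], dtype=float)
    sec = np.minimum(times.astype(int), len(kinds) - 1)
    mu, sd = mu[sec], sd[sec]
    for ep in plan.episodes:
        inside = (times >= ep.start) & (times < ep.end)
        mu[inside], sd[inside] = ep.mu_speed, ep.sd_speed
    speeds = np.maximum(rng.normal(mu, sd), 0.0)
    return SpeedRecording(timestamps=start_time + times, speeds=speeds)


def render_scr_train(
    events: list[ScrTruth],
    n_samples: int,
    rate: float,
    decay_tau: float,
) -> np.ndarray:
    """Sum of phasic response kernels on a uniform sample grid.

    Each kernel rises linearly from 0 to its amplitude over ``rise_s``
    seconds, then decays exponentially with time constant ``decay_tau``.
    """
    signal = np.zeros(n_samples)
    t = np.arange(n_samples) / rate
    for ev in events:
        i0 = int(np.searchsorted(t, ev.time))
        i1 = min(n_samples, i0 + int((ev.rise_s + 8 * decay_tau) * rate) + 2)
        if i0 >= n_samples:
            continue
        dt = t[i0:i1] - ev.time
        kernel = np.where(
            dt < ev.rise_s,
            ev.amplitude * dt / ev.rise_s,
            ev.amplitude * np.exp(-(dt - ev.rise_s) / decay_tau),
        )
        signal[i0:i1] += kernel
    return signal


def simulate_eda(
    states: np.ndarray,
    model: EdaModel | None = None,
    rate: float = EDA_RATE_HZ,
    rng: np.random.Generator | None = None,
    start_time: float = 0.0,
    pad_s: float = 120.0,
) -> tuple[EdaRecording, list[ScrTruth]]:
    """Conductance signal driven by a per-second stress timeline.

    ``states`` is a boolean array, one entry per second (True = high
    stress).  The event process is simulated with ``pad_s`` seconds of
    burn-in and run-out (continuing the edge states), then trimmed to
    the drive, so the returned signal is stationary right from its
    first sample rather than ramping up from an event-free start.
    Returns the recording and the planted in-drive event list.
    """
    model = model or EdaModel()
    rng = rng or np.random.default_rng(0)
    states = np.asarray(states, dtype=bool)
    if states.size == 0:
        raise EmptyRecordingError("stress timeline is empty")
    pad = int(round(pad_s))
    padded = np.concatenate(
        [np.full(pad, states[0]), states, np.full(pad, states[-1])]
    )
    n = int(round(states.size * rate))
    n_padded = int(round(padded.size * rate))

    events: list[ScrTruth] = []
    for sec, high in enumerate(padded):
        lam = model.rate_high if high else model.rate_low
        if rng.random() < lam / 60.0:  # at most one onset per second
            median = model.amp_median_high if high else model.amp_median_low
            amp = float(
                np.exp(rng.normal(np.log(median), model.amp_log_sigma))
            )
            events.append(
                ScrTruth(
                    time=sec - pad + float(rng.random()),
                    amplitude=amp,
                    rise_s=float(rng.uniform(model.rise_min_s, model.rise_max_s)),
                    high_stress=bool(high),
                )
            )

    shifted = [dataclasses.replace(e, time=e.time + pad) for e in events]
    phasic = render_scr_train(shifted, n_padded, rate, model.decay_tau)
    lo = int(round(pad * rate))
    phasic = phasic[lo : lo + n]
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)  # drift is not synchronized to the route
    tonic = model.tonic_level + model.drift_amplitude * np.sin(
        2 * np.pi * t / model.drift_period + phase
    )
    noise = rng.normal(0.0, model.noise_sd, n) if model.noise_sd > 0 else 0.0
    values = np.maximum(tonic + phasic + noise, 0.0)
    in_drive = [e for e in events if 0.0 <= e.time < states.size]
    return EdaRecording(start_time=start_time, rate=rate, values=values), in_drive


@dataclass(frozen=True)
class Study:
    """One drive's bundled streams plus generator ground truth."""

    eda: EdaRecording
    speed: SpeedRecording
    segments: SegmentMap
    truth: dict


def is_valid_study(study: Study) -> bool:
    """Reject drives with unusable conductance (all-zero or constant)."""
    v = study.eda.values
    return bool(np.all(np.isfinite(v)) and np.ptp(v) > 0 and np.any(v > 0))


def make_study(
    plan: DrivePlan | None = None,
    eda_model: EdaModel | None = None,
    seed: int = 0,
    start_time: float = 1_515_600_000.0,
) -> Study:
    """Simulate one complete drive from a single seed."""
    plan = plan or DrivePlan()
    eda_model = eda_model or EdaModel()
    ss_speed, ss_eda = np.random.SeedSequence(seed).spawn(2)
    speed = simulate_speed(
        plan, rng=np.random.default_rng(ss_speed), start_time=start_time
    )
    states = plan.stress_per_second()
    eda, events = simulate_eda(
        states,
        eda_model,
        rng=np.random.default_rng(ss_eda),
        start_time=start_time,
    )
    truth = {
        "stress_seconds": states,
        "events": events,
        "plan": plan,
        "start_time": start_time,
    }
    return Study(eda=eda, speed=speed, segments=plan.segment_map(start_time), truth=truth)


def random_plan(rng: np.random.Generator) -> DrivePlan:
    """Default route with 1-2 congestion episodes at random positions.

    Episodes are aligned to six-minute window boundaries and placed
    wholly inside highway segments; their regimes (mean 20-30 km/h, SD
    5-12 km/h) sit strictly inside the default traffic-jam criterion.
    """
    candidates = [1440.0, 2160.0, 2520.0]  # window-aligned highway starts
    n_ep = int(rng.integers(1, 3))
    starts = rng.choice(candidates, size=n_ep, replace=False)
    episodes = tuple(
        CongestionEpisode(
            start=float(s),
            duration=360.0,
            mu_speed=float(rng.uniform(20.0, 30.0)),
            sd_speed=float(rng.uniform(5.0, 12.0)),
        )
        for s in sorted(starts)
    )
    return DrivePlan(episodes=episodes)


def make_batch(
    n_drives: int = 25,
    n_invalid: int = 4,
    seed: int = 0,
    eda_model: EdaModel | None = None,
    randomize_plans: bool = True,
) -> list[Study]:
    """A batch of day-indexed drives, some optionally spoiled.

    The first ``n_invalid`` drive indices (spread evenly over the batch)
    get an all-zero conductance channel, emulating sensor failures that
    a validity filter must remove.  Drives start one day apart.
    """
    if not 0 <= n_invalid <= n_drives:
        raise ValueError("need 0 <= n_invalid <= n_drives")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_drives)
    invalid_idx = set(
        np.linspace(0, n_drives - 1, n_invalid, dtype=int).tolist()
    ) if n_invalid else set()
    studies = []
    for i, child in enumerate(children):
        rng_plan = np.random.default_rng(child.spawn(1)[0])
        plan = random_plan(rng_plan) if randomize_plans else DrivePlan()
        study = make_study(
            plan=plan,
            eda_model=eda_model,
            seed=int(child.generate_state(1)[0] % (2**31)),
            start_time=1_515_600_000.0 + i * 86_400.0,
        )
        if i in invalid_idx:
            dead = EdaRecording(
                start_time=study.eda.start_time,
                rate=study.eda.rate,
                values=np.zeros_like(study.eda.values),
            )
            study = Study(
                eda=dead, speed=study.speed, segments=study.segments,
                truth={**study.truth, "invalid": True},
            )
        studies.append(study)
    return studies


def filter_valid(studies: list[Study]) -> list[Study]:
    """Drop drives whose conductance channel is unusable."""
    return [s for s in studies if is_valid_study(s)]


def write_study(study: Study, outdir: str | Path) -> dict[str, Path]:
    """Write one drive in the package's file dialects plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "eda": write_e4_csv(study.eda, outdir / "eda.csv"),
        "speed": write_speed_log(study.speed, outdir / "speed.csv"),
        "segments": write_segment_map(study.segments, outdir / "segments.yaml"),
    }
    truth = study.truth
    payload = {
        "start_time": truth.get("start_time"),
        "stress_seconds": np.asarray(truth["stress_seconds"], dtype=int).tolist(),
        "events": [dataclasses.asdict(e) for e in truth["events"]],
        "plan": {
            "segments": [list(s) for s in truth["plan"].segments],
            "episodes": [dataclasses.asdict(e) for e in truth["plan"].episodes],
        },
    }
    truth_path = outdir / "truth.json"
    with truth_path.open("w") as fh:
        json.dump(payload, fh)
    paths["truth"] = truth_path
    return paths
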