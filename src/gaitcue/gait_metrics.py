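"""Gait metrics: step time, %CV of step time, walking speed, freezing burden.

Step Time is the duration between consecutive heel strikes of contralateral
legs. Its variability is summarised as the coefficient of variation,

    %CV = (standard deviation / mean) * 100,

with the sample (n-1) standard deviation by default. The on-device statistic
is a *rolling* %CV over sliding windows of consecutive step times (window 2
by default, i.e. one %CV value per consecutive pair), which downstream
strategy logic consumes as an ordered array.

Walking speed is distance / duration over the marked straight segment
(10 m by default). Freezing burden is measured on the union of annotation
intervals, so overlapping or split annotations never double-count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidIntervalError, MissingMarkerError
from .signal_model import (
    EventSequence,
    EventKind,
    FogAnnotation,
    GaitEvent,
    Marker,
    MarkerKind,
    SensorLog,
)

DEFAULT_SEGMENT_LENGTH_M = 10.0


@dataclass(frozen=True)
class Step:
    """One step: a contralateral heel-strike pair and its duration."""

    duration: float
    from_event: GaitEvent
    to_event: GaitEvent


@dataclass
class StepTimeSeries:
    """Ordered step durations with provenance and anomaly flags."""

    steps: list[Step] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return np.array([s.duration for s in self.steps], dtype=float)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass
class CvArray:
    """Rolling %CV values, one per window of consecutive step times."""

    window: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.window < 2:
            raise DegenerateInputError("CvArray window must be >= 2")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def step_times(seq: EventSequence) -> StepTimeSeries:
    """Durations between each heel strike and the next contralateral one.

    Consecutive ipsilateral heel strikes (a missed contralateral event)
    produce no step and add a ``skipped ipsilateral pair`` flag.
    """
    strikes = [e for e in seq if e.kind == EventKind.HEEL_STRIKE]
    series = StepTimeSeries()
    for a, b in zip(strikes, strikes[1:]):
        if a.side == b.side:
            series.flags.append(
                f"skipped ipsilateral pair at t={a.time:.3f}->{b.time:.3f}"
            )
            continue
        series.steps.append(Step(duration=b.time - a.time, from_event=a, to_event=b))
    return series


def percent_cv(values: Sequence[float], ddof: int = 1) -> float:
    """Coefficient of variation in percent: (SD / mean) * 100.

    ``ddof=1`` gives the sample standard deviation (default); ``ddof=0``
    the population one. Requires at least two values and a positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("percent_cv needs at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise DegenerateInputError("percent_cv needs a positive mean")
    return float(arr.std(ddof=ddof) / mean * 100.0)


def rolling_cv(
    steps: StepTimeSeries | Sequence[float], window: int = 2, ddof: int = 1
) -> CvArray:
    """%CV over each sliding window of ``window`` consecutive step times.

    Fewer step times than the window yields an empty array.
    """
    if window < 2:
        raise DegenerateInputError("rolling window must be >= 2")
    durations = steps.durations if isinstance(steps, StepTimeSeries) else np.asarray(steps, dtype=float)
    n = len(durations)
    values = [
        percent_cv(durations[i : i + window], ddof=ddof) for i in range(n - window + 1)
    ]
    return CvArray(window=window, values=np.array(values, dtype=float))


def walking_speed(
    log_or_markers: SensorLog | Sequence[Marker],
    segment_distance_m: float = DEFAULT_SEGMENT_LENGTH_M,
) -> float:
    """Speed over the marked straight segment: distance / (t_end - t_start)."""
    if isinstance(log_or_markers, SensorLog):
        markers = log_or_markers.markers
    else:
        markers = list(log_or_markers)
    start = next((m.time for m in markers if m.kind == MarkerKind.SEGMENT_START), None)
    end = next((m.time for m in markers if m.kind == MarkerKind.SEGMENT_END), None)
    if start is None or end is None:
        raise MissingMarkerError("both segment_start and segment_end markers required")
    if not end > start:
        raise InvalidIntervalError("segment_end must be after segment_start")
    return segment_distance_m / (end - start)


def merge_intervals(
    intervals: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Union of intervals as maximal connected components (touching merges)."""
    if not intervals:
        return []
    ordered = sorted((float(s), float(e)) for s, e in intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def percent_time_frozen(
    ann: FogAnnotation, walk_start: float, walk_end: float
) -> float:
    """Percent of [walk_start, walk_end] covered by the union of FoG intervals."""
    if not walk_end > walk_start:
        raise InvalidIntervalError("walk interval must have walk_end > walk_start")
    covered = 0.0
    for s, e in merge_intervals(ann.intervals):
        lo = max(s, walk_start)
        hi = min(e, walk_end)
        if hi > lo:
            covered += hi - lo
    return 100.0 * covered / (walk_end - walk_start)


def count_fog_episodes(ann: FogAnnotation) -> int:
    """Number of maximal connected components of the annotation union."""
    return len(merge_intervals(ann.intervals))
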