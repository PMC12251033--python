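"""Data model and file I/O for insole sensor logs, gait events, cue timelines
and freezing-of-gait annotations.

The central object is :class:`SensorLog`: a uniformly sampled, per-foot record
of three force-sensitive-resistor (FSR) channels — two under the heel (lateral
and medial, to be robust to foot inversion/eversion) and one under the toe —
digitised to 10-bit ADC counts in [0, 1023], plus instantaneous pathway-marker
events that bracket the timed 10 m walkway segment.

All times are seconds on a common base with t = 0 at the first sample.
File formats are plain CSV dialects:

* sensor log — comment header ``# sample_rate_hz=<float>`` then columns
  ``time_s,L_heel_lat,L_heel_med,L_toe,R_heel_lat,R_heel_med,R_toe,marker``;
* annotations — ``start_s,end_s,source``;
* events — ``time_s,side,kind,label``;
* cue timeline — ``start_s,end_s,mode,reason``.

Reading validates every invariant and raises a named error on violation;
writing then reading any valid object is the identity.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AdcRangeError,
    ChannelLengthError,
    InvalidIntervalError,
    MalformedHeaderError,
    NonMonotonicTimeError,
    UnknownMarkerError,
)

ADC_MAX = 1023
#: tolerance on uniform sample spacing, seconds
TIME_TOL = 1e-9

SENSOR_COLUMNS = [
    "time_s",
    "L_heel_lat",
    "L_heel_med",
    "L_toe",
    "R_heel_lat",
    "R_heel_med",
    "R_toe",
    "marker",
]


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class EventKind(str, enum.Enum):
    HEEL_STRIKE = "heel_strike"
    TOE_OFF = "toe_off"


class MarkerKind(str, enum.Enum):
    SEGMENT_START = "segment_start"
    SEGMENT_END = "segment_end"


class CueMode(str, enum.Enum):
    NONE = "none"
    CONTINUOUS = "continuous"
    ON_DEMAND = "on_demand"


class CueReason(str, enum.Enum):
    CONTINUOUS = "continuous"
    TRIGGER_UPPER = "trigger_upper"
    TRIGGER_LOWER = "trigger_lower"


_LABELS = {
    (EventKind.HEEL_STRIKE, Side.LEFT): "L+",
    (EventKind.HEEL_STRIKE, Side.RIGHT): "R+",
    (EventKind.TOE_OFF, Side.LEFT): "L-",
    (EventKind.TOE_OFF, Side.RIGHT): "R-",
}
_LABEL_TO_KIND_SIDE = {v: k for k, v in _LABELS.items()}


@dataclass(frozen=True)
class Marker:
    time: float
    kind: MarkerKind


@dataclass(frozen=True)
class GaitEvent:
    """A sided, time-stamped heel-strike or toe-off event.

    The label follows the field convention: ``L+``/``R+`` for left/right
    heel strikes and ``L-``/``R-`` for toe-offs.
    """

    kind: EventKind
    side: Side
    time: float

    @property
    def label(self) -> str:
        return _LABELS[(self.kind, self.side)]

    @staticmethod
    def from_label(label: str, time: float) -> "GaitEvent":
        try:
            kind, side = _LABEL_TO_KIND_SIDE[label]
        except KeyError:
            raise ValueError(f"unknown event label {label!r}")
        return GaitEvent(kind=kind, side=side, time=time)


@dataclass
class FootChannels:
    """One foot's FSR channels, int arrays of equal length in [0, 1023]."""

    heel_lateral: np.ndarray
    heel_medial: np.ndarray
    toe: np.ndarray

    def __post_init__(self) -> None:
        self.heel_lateral = np.asarray(self.heel_lateral, dtype=np.int64)
        self.heel_medial = np.asarray(self.heel_medial, dtype=np.int64)
        self.toe = np.asarray(self.toe, dtype=np.int64)
        n = len(self.heel_lateral)
        if len(self.heel_medial) != n or len(self.toe) != n:
            raise ChannelLengthError(
                "heel_lateral, heel_medial and toe must have equal length"
            )
        for name in ("heel_lateral", "heel_medial", "toe"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() > ADC_MAX):
                raise AdcRangeError(
                    f"channel {name}: values outside [0, {ADC_MAX}]"
                )

    def __len__(self) -> int:
        return len(self.heel_lateral)


@dataclass
class SensorLog:
    """Uniformly sampled two-foot FSR recording with pathway markers."""

    sample_rate: float
    timestamps: np.ndarray
    left: FootChannels
    right: FootChannels
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise NonMonotonicTimeError("sample_rate must be positive")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = len(self.timestamps)
        if len(self.left) != n or len(self.right) != n:
            raise ChannelLengthError("channel length differs from timestamps")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if dt.min() <= 0:
                raise NonMonotonicTimeError("timestamps not strictly increasing")
            if np.abs(dt - 1.0 / self.sample_rate).max() > TIME_TOL:
                raise NonMonotonicTimeError(
                    "timestamps not uniform at 1/sample_rate "
                    f"(tolerance {TIME_TOL} s)"
                )
        kinds = [m.kind for m in self.markers]
        for k in (MarkerKind.SEGMENT_START, MarkerKind.SEGMENT_END):
            if kinds.count(k) > 1:
                raise UnknownMarkerError(f"more than one {k.value} marker")
        start = self.marker_time(MarkerKind.SEGMENT_START)
        end = self.marker_time(MarkerKind.SEGMENT_END)
        if start is not None and end is not None and not start < end:
            raise UnknownMarkerError("segment_start must precede segment_end")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) timestamp; (0, 0) for an empty log."""
        if self.n_samples == 0:
            return (0.0, 0.0)
        return (float(self.timestamps[0]), float(self.timestamps[-1]))

    def marker_time(self, kind: MarkerKind) -> float | None:
        for m in self.markers:
            if m.kind == kind:
                return m.time
        return None

    def foot(self, side: Side) -> FootChannels:
        return self.left if side == Side.LEFT else self.right


@dataclass
class FogAnnotation:
    """Freezing-of-gait intervals (clinician labels or simulator truth).

    Intervals may overlap on input; every derived measure works on their
    union, so splitting or permuting intervals never changes a result.
    """

    intervals: list[tuple[float, float]]
    source: str = "clinician"

    def __post_init__(self) -> None:
        if self.source not in ("clinician", "simulator"):
            raise InvalidIntervalError(
                f"annotation source must be clinician|simulator, got {self.source!r}"
            )
        clean = []
        for start, end in self.intervals:
            start, end = float(start), float(end)
            if not end > start:
                raise InvalidIntervalError(
                    f"annotation interval [{start}, {end}] has end <= start"
                )
            clean.append((start, end))
        self.intervals = clean


@dataclass(frozen=True)
class CueInterval:
    start: float
    end: float
    reason: CueReason


@dataclass
class CueTimeline:
    """Cue on/off intervals with trigger reasons, for one of three modes."""

    mode: CueMode
    intervals: list[CueInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode == CueMode.NONE and self.intervals:
            raise InvalidIntervalError("mode 'none' must have an empty timeline")
        if self.mode == CueMode.CONTINUOUS:
            if len(self.intervals) != 1 or self.intervals[0].reason != CueReason.CONTINUOUS:
                raise InvalidIntervalError(
                    "mode 'continuous' must have exactly one interval with "
                    "reason 'continuous'"
                )
        prev_end = -np.inf
        for iv in self.intervals:
            if not iv.end > iv.start:
                raise InvalidIntervalError(
                    f"cue interval [{iv.start}, {iv.end}] has end <= start"
                )
            if iv.start < prev_end:
                raise InvalidIntervalError("cue intervals overlap or are unordered")
            prev_end = iv.end

    def total_on_time(self) -> float:
        return float(sum(iv.end - iv.start for iv in self.intervals))

    def is_on(self, t: float) -> bool:
        return any(iv.start <= t < iv.end for iv in self.intervals)

    def __iter__(self) -> Iterator[CueInterval]:
        return iter(self.intervals)


@dataclass
class EventSequence:
    """A single time-ordered sequence of labeled gait events from both feet."""

    events: list[GaitEvent]

    def __iter__(self) -> Iterator[GaitEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def heel_strikes(self) -> list[GaitEvent]:
        return [e for e in self.events if e.kind == EventKind.HEEL_STRIKE]

    def toe_offs(self) -> list[GaitEvent]:
        return [e for e in self.events if e.kind == EventKind.TOE_OFF]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def write_sensor_log(log: SensorLog, path: str | Path) -> None:
    """Write a sensor log to CSV; numeric fields round-trip bit-identically.

    Markers are stored on the sample row whose timestamp equals the marker
    time; a marker whose time is not on the sampling grid (within 1e-9 s)
    raises :class:`UnknownMarkerError` rather than being silently moved.
    """
    marker_col = [""] * log.n_samples
    for m in log.markers:
        idx = int(np.argmin(np.abs(log.timestamps - m.time))) if log.n_samples else -1
        if idx < 0 or abs(log.timestamps[idx] - m.time) > TIME_TOL:
            raise UnknownMarkerError(
                f"marker at t={m.time} s is not on the sampling grid"
            )
        marker_col[idx] = m.kind.value
    buf = io.StringIO()
    buf.write(f"# sample_rate_hz={_fmt(log.sample_rate)}\n")
    buf.write(",".join(SENSOR_COLUMNS) + "\n")
    for i in range(log.n_samples):
        row = [
            _fmt(log.timestamps[i]),
            str(log.left.heel_lateral[i]),
            str(log.left.heel_medial[i]),
            str(log.left.toe[i]),
            str(log.right.heel_lateral[i]),
            str(log.right.heel_medial[i]),
            str(log.right.toe[i]),
            marker_col[i],
        ]
        buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_sensor_log(path: str | Path) -> SensorLog:
    """Read a sensor-log CSV, validating every invariant on the way in."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# sample_rate_hz="):
        raise MalformedHeaderError(
            f"{path}: expected '# sample_rate_hz=<float>' comment header"
        )
    try:
        sample_rate = float(first.split("=", 1)[1])
    except ValueError as exc:
        raise MalformedHeaderError(f"{path}: unparseable sample rate") from exc

    df = pd.read_csv(path, comment="#", dtype={"marker": "string"})
    if list(df.columns) != SENSOR_COLUMNS:
        raise MalformedHeaderError(
            f"{path}: columns {list(df.columns)} != expected {SENSOR_COLUMNS}"
        )
    for col in SENSOR_COLUMNS[1:-1]:
        vals = df[col]
        if not (vals == vals.astype(np.int64)).all():
            raise AdcRangeError(f"{path}: non-integer ADC value in {col}")
        if ((vals < 0) | (vals > ADC_MAX)).any():
            raise AdcRangeError(f"{path}: value outside [0, {ADC_MAX}] in {col}")
    markers = []
    marked = df[df["marker"].notna() & (df["marker"] != "")]
    for _, row in marked.iterrows():
        kind_str = row["marker"]
        try:
            kind = MarkerKind(kind_str)
        except ValueError:
            raise UnknownMarkerError(f"{path}: unknown marker kind {kind_str!r}")
        markers.append(Marker(time=float(row["time_s"]), kind=kind))
    return SensorLog(
        sample_rate=sample_rate,
        timestamps=df["time_s"].to_numpy(dtype=float),
        left=FootChannels(
            heel_lateral=df["L_heel_lat"].to_numpy(np.int64),
            heel_medial=df["L_heel_med"].to_numpy(np.int64),
            toe=df["L_toe"].to_numpy(np.int64),
        ),
        right=FootChannels(
            heel_lateral=df["R_heel_lat"].to_numpy(np.int64),
            heel_medial=df["R_heel_med"].to_numpy(np.int64),
            toe=df["R_toe"].to_numpy(np.int64),
        ),
        markers=markers,
    )


def write_annotations(ann: FogAnnotation, path: str | Path) -> None:
    lines = ["start_s,end_s,source"]
    for start, end in ann.intervals:
        lines.append(f"{_fmt(start)},{_fmt(end)},{ann.source}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path: str | Path) -> FogAnnotation:
    path = Path(path)
    df = pd.read_csv(path, dtype={"source": "string"})
    if list(df.columns) != ["start_s", "end_s", "source"]:
        raise MalformedHeaderError(f"{path}: bad annotation header {list(df.columns)}")
    source = "clinician" if df.empty else str(df["source"].iloc[0])
    intervals = [(float(r.start_s), float(r.end_s)) for r in df.itertuples()]
    return FogAnnotation(intervals=intervals, source=source)


def write_events(seq: EventSequence, path: str | Path) -> None:
    lines = ["time_s,side,kind,label"]
    for e in seq:
        lines.append(f"{_fmt(e.time)},{e.side.value},{e.kind.value},{e.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path: str | Path) -> EventSequence:
    path = Path(path)
    df = pd.read_csv(path, dtype={"side": "string", "kind": "string", "label": "string"})
    if list(df.columns) != ["time_s", "side", "kind", "label"]:
        raise MalformedHeaderError(f"{path}: bad event header {list(df.columns)}")
    events = []
    for r in df.itertuples():
        ev = GaitEvent(kind=EventKind(r.kind), side=Side(r.side), time=float(r.time_s))
        if ev.label != r.label:
            raise MalformedHeaderError(
                f"{path}: label {r.label!r} inconsistent with kind/side"
            )
        events.append(ev)
    return EventSequence(events=events)


def write_cue_timeline(timeline: CueTimeline, path: str | Path) -> None:
    lines = ["start_s,end_s,mode,reason"]
    for iv in timeline:
        lines.append(
            f"{_fmt(iv.start)},{_fmt(iv.end)},{timeline.mode.value},{iv.reason.value}"
        )
    if not timeline.intervals:
        # encode the mode of an empty timeline on a sentinel row with no interval
        lines.append(f",,{timeline.mode.value},")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cue_timeline(path: str | Path) -> CueTimeline:
    path = Path(path)
    df = pd.read_csv(path, dtype={"mode": "string", "reason": "string"})
    if list(df.columns) != ["start_s", "end_s", "mode", "reason"]:
        raise MalformedHeaderError(f"{path}: bad timeline header {list(df.columns)}")
    if df.empty:
        raise MalformedHeaderError(f"{path}: timeline file has no mode row")
    mode = CueMode(str(df["mode"].iloc[0]))
    intervals = []
    for r in df.itertuples():
        if pd.isna(r.start_s):
            continue
        intervals.append(
            CueInterval(start=float(r.start_s), end=float(r.end_s), reason=CueReason(str(r.reason)))
        )
    return CueTimeline(mode=mode, intervals=intervals)


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise MalformedHeaderError(f"{path}: config must be a mapping")
    return data
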