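"""Heel-strike / toe-off detection from FSR channels.

A heel strike is the *valid peak* of the merged heel signal: a contact
episode is a maximal run of samples at or above ``valid_peak_min`` (50 ADC
counts by default), and a new episode is only admitted after the signal has
returned to the valley level (0 counts by default) since the previous one.
The event time is the timestamp of the episode's maximum sample (earliest
sample on ties); anchoring at the episode onset is available via
``event_anchor="onset"``.

A toe-off is the first return of the toe channel to the valley level after
it has loaded following a heel strike; a heel strike whose toe-off is not
observed before the next ipsilateral heel strike (or the end of the log) is
flagged incomplete rather than given a fabricated event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ChannelLengthError, ConfigError
from .signal_model import (
    ADC_MAX,
    EventKind,
    EventSequence,
    GaitEvent,
    SensorLog,
    Side,
)


@dataclass(frozen=True)
class DetectorConfig:
    """Validity thresholds for peak/valley gait-event detection.

    valid_peak_min
        minimum ADC magnitude for a heel contact to count (counts).
    valley_level, valley_epsilon
        the signal must return to <= valley_level + valley_epsilon between
        contacts; epsilon > 0 tolerates baseline noise.
    event_anchor
        ``"peak"`` stamps the event at the episode's maximum sample,
        ``"onset"`` at its first supra-threshold sample.
    """

    valid_peak_min: int = 50
    valley_level: int = 0
    valley_epsilon: int = 0
    event_anchor: str = "peak"

    def __post_init__(self) -> None:
        if not (0 <= self.valley_level + self.valley_epsilon < self.valid_peak_min <= ADC_MAX):
            raise ConfigError(
                "require 0 <= valley_level + valley_epsilon < valid_peak_min <= 1023"
            )
        if self.event_anchor not in ("peak", "onset"):
            raise ConfigError("event_anchor must be 'peak' or 'onset'")

    @property
    def valley_threshold(self) -> int:
        return self.valley_level + self.valley_epsilon


class ToeOffDetection(NamedTuple):
    """Toe-off events plus the heel strikes left without one (incomplete)."""

    events: list[GaitEvent]
    incomplete: list[GaitEvent]


def merge_heel_channels(lateral: Sequence[int], medial: Sequence[int]) -> np.ndarray:
    """Element-wise maximum of the two heel FSRs.

    A valid contact on either the lateral or the medial sensor site then
    counts as heel contact, which is the point of instrumenting both sites.
    """
    lat = np.asarray(lateral)
    med = np.asarray(medial)
    if lat.shape != med.shape:
        raise ChannelLengthError(
            f"heel channel length mismatch: {lat.shape} vs {med.shape}"
        )
    return np.maximum(lat, med)


def detect_heel_strikes(
    heel: Sequence[int],
    timestamps: Sequence[float],
    cfg: DetectorConfig = DetectorConfig(),
    side: Side = Side.LEFT,
) -> list[GaitEvent]:
    """Detect heel strikes as valid peaks of one foot's merged heel signal.

    Implements a three-state machine over the sample stream: armed (valley
    seen), in-episode (samples >= valid_peak_min), and refractory (episode
    over but no valley yet). Runs of supra-threshold samples that are not
    preceded by a valley return are not admitted as episodes.
    """
    heel = np.asarray(heel)
    timestamps = np.asarray(timestamps, dtype=float)
    if heel.shape != timestamps.shape:
        raise ChannelLengthError("heel series and timestamps differ in length")

    events: list[GaitEvent] = []
    armed = True
    in_episode = False
    peak_idx = onset_idx = -1

    def emit() -> None:
        idx = peak_idx if cfg.event_anchor == "peak" else onset_idx
        events.append(
            GaitEvent(kind=EventKind.HEEL_STRIKE, side=side, time=float(timestamps[idx]))
        )

    for i, x in enumerate(heel):
        if in_episode:
            if x >= cfg.valid_peak_min:
                if x > heel[peak_idx]:  # earliest sample wins ties
                    peak_idx = i
            else:
                emit()
                in_episode = False
                armed = x <= cfg.valley_threshold
        else:
            if x <= cfg.valley_threshold:
                armed = True
            elif x >= cfg.valid_peak_min and armed:
                in_episode = True
                armed = False
                peak_idx = onset_idx = i
    if in_episode:  # contact truncated by end of log still has a peak
        emit()
    return events


def detect_toe_offs(
    toe: Sequence[int],
    timestamps: Sequence[float],
    heel_strikes: Sequence[GaitEvent],
    cfg: DetectorConfig = DetectorConfig(),
) -> ToeOffDetection:
    """Detect the toe-off following each ipsilateral heel strike.

    For each heel strike, scan forward for a supra-valley loading of the toe
    channel and then its first return to the valley level; that return sample
    is the toe-off. The search is bounded by the next ipsilateral heel strike
    (or end of log); a heel strike with no observed toe-off inside its bound
    is returned in ``incomplete``.
    """
    toe = np.asarray(toe)
    timestamps = np.asarray(timestamps, dtype=float)
    if toe.shape != timestamps.shape:
        raise ChannelLengthError("toe series and timestamps differ in length")

    events: list[GaitEvent] = []
    incomplete: list[GaitEvent] = []
    n = len(toe)
    for j, hs in enumerate(heel_strikes):
        bound_t = heel_strikes[j + 1].time if j + 1 < len(heel_strikes) else np.inf
        i = int(np.searchsorted(timestamps, hs.time, side="left"))
        # phase 1: toe loads
        while i < n and timestamps[i] < bound_t and toe[i] <= cfg.valley_threshold:
            i += 1
        if i >= n or timestamps[i] >= bound_t:
            incomplete.append(hs)
            continue
        # phase 2: first return to the valley
        while i < n and timestamps[i] < bound_t and toe[i] > cfg.valley_threshold:
            i += 1
        if i >= n or timestamps[i] >= bound_t:
            incomplete.append(hs)
            continue
        events.append(
            GaitEvent(kind=EventKind.TOE_OFF, side=hs.side, time=float(timestamps[i]))
        )
    return ToeOffDetection(events=events, incomplete=incomplete)


def build_event_sequence(
    left_events: Sequence[GaitEvent], right_events: Sequence[GaitEvent]
) -> EventSequence:
    """Stable time-ordered merge of per-foot events; left precedes right on ties."""
    merged: list[GaitEvent] = []
    li = ri = 0
    while li < len(left_events) and ri < len(right_events):
        if left_events[li].time <= right_events[ri].time:
            merged.append(left_events[li])
            li += 1
        else:
            merged.append(right_events[ri])
            ri += 1
    merged.extend(left_events[li:])
    merged.extend(right_events[ri:])
    return EventSequence(events=merged)


def detect_events(log: SensorLog, cfg: DetectorConfig = DetectorConfig()) -> EventSequence:
    """End-to-end detection on a sensor log: merge heels, find heel strikes
    and toe-offs per foot, and return the labeled two-foot sequence."""
    per_side: dict[Side, list[GaitEvent]] = {}
    for side in (Side.LEFT, Side.RIGHT):
        foot = log.foot(side)
        heel = merge_heel_channels(foot.heel_lateral, foot.heel_medial)
        strikes = detect_heel_strikes(heel, log.timestamps, cfg, side=side)
        toe = detect_toe_offs(foot.toe, log.timestamps, strikes, cfg)
        per_side[side] = sorted(strikes + toe.events, key=lambda e: e.time)
    return build_event_sequence(per_side[Side.LEFT], per_side[Side.RIGHT])
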