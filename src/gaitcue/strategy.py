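"""The cueing strategy generator.

The controller watches the rolling %CV array of step times and computes
``Ratio_StepTimeVariability``, the quotient of the two most recent %CV
values. The ratio is compared against an upper threshold Thresh_U (~2.5,
inclusive) that flags a sharp rise in variability — the pre-freeze
signature — and against a lower hesitation band Thresh_L
(0.5 < ratio < 1, both ends exclusive) meant to catch the drop-off seen
when a walk stalls. Either branch opens a visual cue in on-demand mode;
the lower band can be disabled.

Zero-CV conventions keep perfectly regular gait quiet: both %CV values
zero gives ratio 1 (no trigger); a zero denominator under a positive
numerator gives +inf (upper trigger).

Cue release is not part of the published decision flow and is configurable:
by default the cue closes after two consecutive non-triggering decisions,
or after a fixed duration if one is set. The controller is strictly
streaming — feeding step times one at a time or all at once yields the
same timeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ConfigError, DegenerateInputError
from .gait_metrics import CvArray, StepTimeSeries, percent_cv
from .signal_model import CueInterval, CueMode, CueReason, CueTimeline

CUE_LINE_LENGTH_M = 1.5
CUE_DISTANCE_HEIGHT_FRACTION = 0.4


@dataclass(frozen=True)
class StrategyConfig:
    """Thresholds and cue-release policy for the strategy generator.

    thresh_u
        upper ratio threshold, trigger at ratio >= thresh_u (default 2.5).
    lower_band
        hesitation band (low, high), trigger at low < ratio < high
        (default 0.5, 1.0), active only when ``lower_band_enabled``.
    cv_window
        step times per rolling %CV value (default 2: pairwise).
    min_cv_values
        %CV values required before the first decision (default 2).
    cue_release_steps_in_band
        close the cue after this many consecutive non-triggering decisions.
    cue_release_fixed_duration_s
        if set, close the cue this many seconds after the last trigger
        instead of counting decisions.
    """

    thresh_u: float = 2.5
    lower_band: tuple[float, float] = (0.5, 1.0)
    lower_band_enabled: bool = True
    cv_window: int = 2
    min_cv_values: int = 2
    cue_release_steps_in_band: int = 2
    cue_release_fixed_duration_s: float | None = None
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        low, high = self.lower_band
        if not (0 < low < high <= 1 < self.thresh_u):
            raise ConfigError("require 0 < lower_band.low < lower_band.high <= 1 < thresh_u")
        if self.cv_window < 2 or self.min_cv_values < 2:
            raise ConfigError("cv_window and min_cv_values must be >= 2")
        if self.cue_release_steps_in_band < 1:
            raise ConfigError("cue_release_steps_in_band must be >= 1")
        if self.cue_release_fixed_duration_s is not None and self.cue_release_fixed_duration_s <= 0:
            raise ConfigError("cue_release_fixed_duration_s must be positive")


@dataclass(frozen=True)
class CueDecision:
    """Outcome of one streaming threshold decision."""

    outcome: CueReason | None  # None = no trigger
    ratio: float
    at_step_index: int | None = None


def cv_ratio(cv: CvArray | Sequence[float], k: int) -> float:
    """Quotient of consecutive %CV array entries: cv[k] / cv[k-1].

    Conventions: both entries zero -> 1.0 (steady, perfectly regular gait);
    zero denominator with a positive numerator -> +inf (unambiguous rise).
    """
    values = cv.values if isinstance(cv, CvArray) else cv
    if k < 1 or k >= len(values):
        raise IndexError(f"cv_ratio needs entries at k-1 and k; got k={k}, len={len(values)}")
    num, den = float(values[k]), float(values[k - 1])
    if den == 0.0:
        return 1.0 if num == 0.0 else math.inf
    return num / den


def decide_cue(ratio: float, cfg: StrategyConfig = StrategyConfig()) -> CueDecision:
    """Threshold one ratio value: upper trigger, lower (hesitation) trigger, or none."""
    if ratio >= cfg.thresh_u:
        return CueDecision(outcome=CueReason.TRIGGER_UPPER, ratio=ratio)
    low, high = cfg.lower_band
    if cfg.lower_band_enabled and low < ratio < high:
        return CueDecision(outcome=CueReason.TRIGGER_LOWER, ratio=ratio)
    return CueDecision(outcome=None, ratio=ratio)


class CueController:
    """Streaming on-demand cue controller.

    Feed one completed step at a time with :meth:`push_step`; the controller
    maintains the rolling %CV array, evaluates the ratio of its two most
    recent entries once ``min_cv_values`` exist, and opens/closes cue
    intervals per the release policy. :meth:`finalize` closes any open cue
    at the end of the walk and returns the merged timeline.
    """

    def __init__(
        self,
        cfg: StrategyConfig = StrategyConfig(),
        walk_span: tuple[float, float] = (0.0, math.inf),
    ) -> None:
        self.cfg = cfg
        self.walk_span = (float(walk_span[0]), float(walk_span[1]))
        self._durations: list[float] = []
        self._cv: list[float] = []
        self._step_index = -1
        self._open_since: float | None = None
        self._open_reason: CueReason | None = None
        self._close_at: float | None = None  # fixed-duration release
        self._nontrigger_run = 0
        self._intervals: list[tuple[float, float, CueReason]] = []

    @property
    def cue_is_on(self) -> bool:
        return self._open_since is not None

    def cue_active_at(self, t: float) -> bool:
        """Whether the cue is visible at time t given decisions so far
        (accounts for a pending fixed-duration release)."""
        if not self.cue_is_on:
            return False
        return self._close_at is None or t < self._close_at

    def _close(self, t: float) -> None:
        assert self._open_since is not None and self._open_reason is not None
        if t > self._open_since:
            self._intervals.append((self._open_since, t, self._open_reason))
        self._open_since = None
        self._open_reason = None
        self._close_at = None
        self._nontrigger_run = 0

    def push_step(self, duration: float, heel_strike_time: float) -> CueDecision | None:
        """Register a completed step (its duration and the time of the heel
        strike that completed it); returns the decision taken, or None during
        warm-up."""
        cfg = self.cfg
        self._step_index += 1
        self._durations.append(float(duration))
        # fixed-duration release is time-based, checked before the new decision
        if self.cue_is_on and self._close_at is not None and heel_strike_time >= self._close_at:
            self._close(self._close_at)
        if len(self._durations) >= cfg.cv_window:
            self._cv.append(
                percent_cv(self._durations[-cfg.cv_window :], ddof=cfg.sd_ddof)
            )
        if len(self._cv) < cfg.min_cv_values:
            return None
        ratio = cv_ratio(self._cv, len(self._cv) - 1)
        decision = decide_cue(ratio, cfg)
        decision = CueDecision(
            outcome=decision.outcome, ratio=ratio, at_step_index=self._step_index
        )
        if decision.outcome is not None:
            if not self.cue_is_on:
                self._open_since = heel_strike_time
                self._open_reason = decision.outcome
            self._nontrigger_run = 0
            if cfg.cue_release_fixed_duration_s is not None:
                self._close_at = heel_strike_time + cfg.cue_release_fixed_duration_s
        elif self.cue_is_on and cfg.cue_release_fixed_duration_s is None:
            self._nontrigger_run += 1
            if self._nontrigger_run >= cfg.cue_release_steps_in_band:
                self._close(heel_strike_time)
        return decision

    def finalize(self) -> CueTimeline:
        """Close any open cue at the walk end and return the merged timeline."""
        if self.cue_is_on:
            end = self._close_at if self._close_at is not None else self.walk_span[1]
            self._close(min(end, self.walk_span[1]))
        lo, hi = self.walk_span
        clipped = [
            (max(s, lo), min(e, hi), r) for s, e, r in self._intervals if min(e, hi) > max(s, lo)
        ]
        merged: list[list] = []
        for s, e, r in clipped:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)  # keep first reason
            else:
                merged.append([s, e, r])
        return CueTimeline(
            mode=CueMode.ON_DEMAND,
            intervals=[CueInterval(start=s, end=e, reason=r) for s, e, r in merged],
        )


def run_cue_controller(
    steps: StepTimeSeries,
    mode: CueMode | str,
    cfg: StrategyConfig = StrategyConfig(),
    walk_span: tuple[float, float] = (0.0, math.inf),
) -> CueTimeline:
    """Produce the cue timeline for a whole walk in one of the three modes.

    ``none`` yields an empty timeline; ``continuous`` one interval spanning
    the walk; ``on_demand`` streams the step series through a
    :class:`CueController`.
    """
    mode = CueMode(mode)
    if mode == CueMode.NONE:
        return CueTimeline(mode=CueMode.NONE, intervals=[])
    if mode == CueMode.CONTINUOUS:
        if not math.isfinite(walk_span[1]) or not walk_span[1] > walk_span[0]:
            raise ConfigError("continuous mode needs a finite, positive walk span")
        return CueTimeline(
            mode=CueMode.CONTINUOUS,
            intervals=[
                CueInterval(start=walk_span[0], end=walk_span[1], reason=CueReason.CONTINUOUS)
            ],
        )
    controller = CueController(cfg=cfg, walk_span=walk_span)
    for step in steps.steps:
        controller.push_step(step.duration, step.to_event.time)
    return controller.finalize()


def cue_line_placement(height_m: float) -> tuple[float, float]:
    """Where to project the cue line: (distance ahead, line length), metres.

    The line is projected 40% of the wearer's height ahead of them and is
    1.5 m long.
    """
    if height_m <= 0:
        raise DegenerateInputError("height must be positive")
    return (CUE_DISTANCE_HEIGHT_FRACTION * height_m, CUE_LINE_LENGTH_M)
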