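"""Strategy generator: ratio conventions, thresholds, cue controller, geometry."""

import math

import numpy as np
import pytest

from conftest import brute_force_replay
from gaitcue.errors import ConfigError, DegenerateInputError
from gaitcue.gait_metrics import StepTimeSeries, step_times
from gaitcue.signal_model import CueMode, CueReason, EventKind, EventSequence, GaitEvent, Side
from gaitcue.simulator import BurstConfig, WalkConfig, simulate_step_times
from gaitcue.strategy import (
    CueController,
    StrategyConfig,
    cue_line_placement,
    cv_ratio,
    decide_cue,
    run_cue_controller,
)


def series_from_durations(durations, t0=0.0):
    """Build a StepTimeSeries with alternating-foot heel strikes."""
    times = [t0]
    for d in durations:
        times.append(times[-1] + d)
    sides = [Side.LEFT, Side.RIGHT] * (len(times) // 2 + 1)
    events = [
        GaitEvent(EventKind.HEEL_STRIKE, sides[i], t) for i, t in enumerate(times)
    ]
    return step_times(EventSequence(events))


class TestCvRatio:
    def test_direct_quotient(self):
        assert cv_ratio([4.0, 10.0], 1) == pytest.approx(2.5)

    def test_zero_denominator_positive_numerator(self):
        assert cv_ratio([0.0, 3.0], 1) == math.inf

    def test_both_zero_is_one(self):
        assert cv_ratio([0.0, 0.0], 1) == 1.0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            cv_ratio([1.0], 1)


class TestDecideCue:
    def test_upper_trigger_inclusive(self):
        assert decide_cue(2.6).outcome == CueReason.TRIGGER_UPPER
        assert decide_cue(2.5).outcome == CueReason.TRIGGER_UPPER
        assert decide_cue(math.inf).outcome == CueReason.TRIGGER_UPPER

    def test_lower_band_exclusive(self):
        assert decide_cue(0.7).outcome == CueReason.TRIGGER_LOWER
        assert decide_cue(0.5).outcome is None
        assert decide_cue(1.0).outcome is None

    def test_between_bands_no_trigger(self):
        assert decide_cue(1.5).outcome is None

    def test_lower_band_can_be_disabled(self):
        cfg = StrategyConfig(lower_band_enabled=False)
        assert decide_cue(0.7, cfg).outcome is None

    def test_config_invariant(self):
        with pytest.raises(ConfigError):
            StrategyConfig(thresh_u=0.9)
        with pytest.raises(ConfigError):
            StrategyConfig(lower_band=(0.8, 0.4))


class TestController:
    def test_mode_none_empty(self):
        tl = run_cue_controller(StepTimeSeries(), CueMode.NONE)
        assert tl.mode == CueMode.NONE and tl.intervals == []

    def test_mode_continuous_spans_walk(self):
        tl = run_cue_controller(StepTimeSeries(), CueMode.CONTINUOUS, walk_span=(0.0, 30.0))
        assert len(tl.intervals) == 1
        iv = tl.intervals[0]
        assert (iv.start, iv.end, iv.reason) == (0.0, 30.0, CueReason.CONTINUOUS)

    def test_constant_step_times_never_cue(self):
        """All %CV zero -> ratio convention 1 -> no trigger in on-demand mode."""
        series = series_from_durations([0.5] * 20)  # exactly representable
        tl = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=(0.0, 12.0))
        assert tl.intervals == []

    def test_warmup_no_decision_before_two_cv_values(self):
        ctrl = CueController()
        assert ctrl.push_step(0.5, 0.5) is None
        assert ctrl.push_step(0.9, 1.4) is None  # first %CV value exists, need two
        assert ctrl.push_step(0.5, 1.9) is not None

    def test_trigger_opens_at_strike_and_releases_after_band_steps(self):
        # constant -> burst: ratio inf at the first unequal pair
        durations = [0.5, 0.5, 0.5, 0.9, 0.5, 0.5, 0.5, 0.5]
        series = series_from_durations(durations)
        strikes = [s.to_event.time for s in series.steps]
        tl = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=(0.0, strikes[-1]))
        assert len(tl.intervals) == 1
        iv = tl.intervals[0]
        assert iv.reason == CueReason.TRIGGER_UPPER
        assert iv.start == pytest.approx(strikes[3])  # the triggering step's strike
        # 0.9 keeps %CV pairs unequal for two more decisions; the release
        # counts 2 consecutive non-triggering decisions after that
        assert iv.end > iv.start

    def test_fixed_duration_release(self):
        cfg = StrategyConfig(cue_release_fixed_duration_s=1.0)
        durations = [0.5, 0.5, 0.5, 0.9] + [0.5] * 10
        series = series_from_durations(durations)
        strikes = [s.to_event.time for s in series.steps]
        tl = run_cue_controller(series, CueMode.ON_DEMAND, cfg, walk_span=(0.0, strikes[-1]))
        spans = [(iv.start, iv.end) for iv in tl.intervals]
        assert all(e - s <= 1.0 + 1e-9 for s, e in spans)

    def test_streaming_equals_batch(self):
        truth = simulate_step_times(WalkConfig(seed=9, n_steps=80, baseline_cv=4.0))
        series = truth.step_series()
        span = truth.walk_span
        batch = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=span)
        ctrl = CueController(walk_span=span)
        for s in series.steps:
            ctrl.push_step(s.duration, s.to_event.time)
        assert ctrl.finalize().intervals == batch.intervals

    def test_determinism(self):
        truth = simulate_step_times(WalkConfig(seed=10, n_steps=60))
        series = truth.step_series()
        a = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=truth.walk_span)
        b = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=truth.walk_span)
        assert a.intervals == b.intervals

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize(
        "cfg",
        [
            StrategyConfig(),
            StrategyConfig(lower_band_enabled=False),
            StrategyConfig(cue_release_fixed_duration_s=1.5),
            StrategyConfig(cv_window=3, cue_release_steps_in_band=3),
        ],
        ids=["defaults", "upper-only", "fixed-release", "window3"],
    )
    def test_equals_brute_force_replay(self, seed, cfg):
        """The streaming controller timeline equals an independent batch
        replay of the decision flow (array build -> consecutive-pair ratio ->
        thresholds -> release) on simulated walks."""
        truth = simulate_step_times(
            WalkConfig(
                seed=seed,
                n_steps=70,
                baseline_cv=3.0,
                burst=BurstConfig(onset_step=30, length_steps=15, cv_multiplier=5.0),
            )
        )
        series = truth.step_series()
        span = truth.walk_span
        got = run_cue_controller(series, CueMode.ON_DEMAND, cfg, walk_span=span)
        want = brute_force_replay(
            [s.duration for s in series.steps],
            [s.to_event.time for s in series.steps],
            cfg,
            span,
        )
        assert [(iv.start, iv.end, iv.reason.value) for iv in got.intervals] == [
            (s, e, r) for s, e, r in want
        ]

    def test_timeline_within_span_and_bounded_by_continuous(self):
        truth = simulate_step_times(
            WalkConfig(seed=2, n_steps=80, burst=BurstConfig(40, 20, 5.0))
        )
        series = truth.step_series()
        span = truth.walk_span
        od = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=span)
        cont = run_cue_controller(series, CueMode.CONTINUOUS, walk_span=span)
        for iv in od.intervals:
            assert span[0] <= iv.start < iv.end <= span[1]
        assert od.total_on_time() <= cont.total_on_time() + 1e-12

    def test_burst_triggers_near_onset(self):
        """An SD step-change is usually flagged within a few steps of onset."""
        hits = 0
        n = 60
        for seed in range(n):
            truth = simulate_step_times(
                WalkConfig(seed=seed, n_steps=60, burst=BurstConfig(30, 20, 5.0))
            )
            series = truth.step_series()
            ctrl = CueController(cfg=StrategyConfig(lower_band_enabled=False))
            trig_step = None
            for i, s in enumerate(series.steps):
                d = ctrl.push_step(s.duration, s.to_event.time)
                if d is not None and d.outcome == CueReason.TRIGGER_UPPER and i >= 30:
                    trig_step = i
                    break
            if trig_step is not None and trig_step <= 32:
                hits += 1
        assert hits / n > 0.7  # the pairwise-ratio detector's typical range


class TestCueLinePlacement:
    @pytest.mark.parametrize("h,d", [(1.75, 0.70), (1.60, 0.64)])
    def test_forty_percent_of_height(self, h, d):
        dist, length = cue_line_placement(h)
        assert dist == pytest.approx(d)
        assert length == 1.5

    def test_non_positive_height(self):
        with pytest.raises(DegenerateInputError):
            cue_line_placement(0.0)
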