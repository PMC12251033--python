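"""Closed-loop gait simulator with ground truth.

Generates step-time sequences (log-normal, configurable baseline %CV) with
three pathological features layered on top:

* a **pre-freeze variability burst**: the step-time CV is multiplied by a
  factor over a contiguous block of steps, emulating the rise in step-time
  variability that precedes a freezing episode;
* **freezing intervals**: step-free time inserted with a per-step hazard
  that grows with the recent pairwise %CV (variability precedes freezing);
* **start hesitation**: an extra delay before the first step.

A cue-response model closes the loop: while a visual cue is visible the
step-time SD is multiplied by ``rho`` (< 1 = steadier gait), and under
*continuous* cueing the benefit decays exponentially with exposure
(habituation). In on-demand mode the strategy controller decides cue
visibility from the steps generated so far, exactly as the device would.

FSR waveforms are synthesised as piecewise-linear stance loading curves —
heel loads first, peaking at the true heel-strike time; the toe loads after
heel contact and first returns to zero exactly at the true toe-off time —
so the event detector can be validated against exact ground truth.

All randomness flows from a single integer seed; identical seeds give
identical walks, and with ``rho = 1`` and zero habituation the three cue
modes are draw-for-draw identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .errors import ConfigError, StepOverlapError
from .gait_events import build_event_sequence
from .gait_metrics import percent_cv, step_times as _step_times, StepTimeSeries
from .signal_model import (
    ADC_MAX,
    CueMode,
    CueTimeline,
    EventKind,
    EventSequence,
    FogAnnotation,
    FootChannels,
    GaitEvent,
    Marker,
    MarkerKind,
    SensorLog,
    Side,
)
from .strategy import CueController, StrategyConfig, run_cue_controller

# stance geometry (fractions of the heel-strike -> toe-off span, and absolute
# rise/fall times of the heel triangle); exact shape is irrelevant to the
# thresholds under test, only the peak/valley timing matters.
HEEL_RISE_S = 0.12
HEEL_FALL_S = 0.30
TOE_LOAD_FRACTION = 0.15
TOE_PEAK_FRACTION = 0.55
STANCE_STRIDE_FRACTION = 0.65
MAX_STANCE_STRIDES = 2.5  # cap stance when a freeze stretches the stride
MEDIAL_SCALE = 0.85  # medial heel FSR sees a slightly lighter load


@dataclass(frozen=True)
class BurstConfig:
    """CV multiplier over steps [onset_step, onset_step + length_steps)."""

    onset_step: int
    length_steps: int
    cv_multiplier: float

    def __post_init__(self) -> None:
        if self.onset_step < 0 or self.length_steps <= 0 or self.cv_multiplier < 1:
            raise ConfigError("burst needs onset >= 0, length > 0, multiplier >= 1")


@dataclass(frozen=True)
class FreezeConfig:
    """Per-step freeze hazard: hazard_base + hazard_cv_gain * recent %CV."""

    hazard_base: float = 0.01
    hazard_cv_gain: float = 0.01
    duration_mean_s: float = 3.0

    def __post_init__(self) -> None:
        if not (0 <= self.hazard_base <= 1) or self.hazard_cv_gain < 0 or self.duration_mean_s <= 0:
            raise ConfigError("invalid freeze hazard configuration")


@dataclass(frozen=True)
class HesitationConfig:
    """Start hesitation: exponential extra delay before the first step."""

    delay_mean_s: float = 1.0

    def __post_init__(self) -> None:
        if self.delay_mean_s <= 0:
            raise ConfigError("hesitation delay mean must be positive")


@dataclass(frozen=True)
class CueResponse:
    """While a cue is visible the step-time SD is multiplied by rho; under
    continuous exposure (1 - rho) decays at habituation_rate per second."""

    rho: float = 0.6
    habituation_rate: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1) or self.habituation_rate < 0:
            raise ConfigError("require 0 < rho <= 1 and habituation_rate >= 0")


@dataclass(frozen=True)
class AmplitudeConfig:
    heel_peak: int = 400
    toe_peak: int = 300

    def __post_init__(self) -> None:
        # peaks below the detector's 50-count validity threshold are legal:
        # synthesising an undetectable contact is a supported experiment
        if not (0 < self.heel_peak <= ADC_MAX) or not (0 < self.toe_peak <= ADC_MAX):
            raise ConfigError("peaks must lie in (0, 1023]")


@dataclass(frozen=True)
class WalkConfig:
    """Everything needed to generate one walk; see module docstring."""

    seed: int
    n_steps: int = 60
    mean_step_time: float = 0.55
    baseline_cv: float = 3.0
    burst: BurstConfig | None = None
    freeze: FreezeConfig | None = None
    hesitation: HesitationConfig | None = None
    cue_response: CueResponse = field(default_factory=CueResponse)
    amplitude: AmplitudeConfig = field(default_factory=AmplitudeConfig)
    noise_sd: float = 0.0
    sample_rate: float = 100.0
    start_time_s: float = 0.5
    place_markers: bool = True
    marker_start_step: int = 2
    segment_length_m: float = 10.0
    step_length_m: float = 0.625
    marker_times: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.mean_step_time <= 0 or self.baseline_cv < 0:
            raise ConfigError("need n_steps >= 1, positive mean step time, cv >= 0")
        if self.sample_rate <= 0 or self.noise_sd < 0:
            raise ConfigError("need positive sample_rate and noise_sd >= 0")
        if self.start_time_s < HEEL_RISE_S:
            raise ConfigError("start_time_s must leave room for the first heel rise")
        if self.place_markers and self.marker_times is None:
            if self.marker_start_step + self.n_segment_steps > self.n_steps:
                raise ConfigError(
                    "walk too short for the marked segment: need "
                    f"marker_start_step + {self.n_segment_steps} <= n_steps"
                )

    @property
    def n_segment_steps(self) -> int:
        return math.ceil(self.segment_length_m / self.step_length_m)


@dataclass
class WalkGroundTruth:
    """Simulator output: the true state the analysis chain should recover."""

    config: WalkConfig
    seed: int
    step_durations: np.ndarray  # drawn gait durations, one per step
    freeze_gaps: np.ndarray  # step-free seconds inserted before each step
    heel_strike_times: np.ndarray  # n_steps + 1 strikes, alternating feet
    sides: list[Side]
    toe_off_times: np.ndarray
    fog_intervals: list[tuple[float, float]]
    burst_onset_step: int | None
    hesitation_delay_s: float
    markers: list[Marker]
    cue_timeline: CueTimeline | None = None

    @property
    def walk_span(self) -> tuple[float, float]:
        end = max(self.heel_strike_times[-1], self.toe_off_times[-1])
        return (0.0, float(end + self.config.mean_step_time))

    def heel_strike_events(self) -> list[GaitEvent]:
        return [
            GaitEvent(kind=EventKind.HEEL_STRIKE, side=s, time=float(t))
            for s, t in zip(self.sides, self.heel_strike_times)
        ]

    def toe_off_events(self) -> list[GaitEvent]:
        return [
            GaitEvent(kind=EventKind.TOE_OFF, side=s, time=float(t))
            for s, t in zip(self.sides, self.toe_off_times)
        ]

    def event_sequence(self) -> EventSequence:
        left = sorted(
            (e for e in self.heel_strike_events() + self.toe_off_events() if e.side == Side.LEFT),
            key=lambda e: e.time,
        )
        right = sorted(
            (e for e in self.heel_strike_events() + self.toe_off_events() if e.side == Side.RIGHT),
            key=lambda e: e.time,
        )
        return build_event_sequence(left, right)

    def step_series(self) -> StepTimeSeries:
        """True step times as the analysis chain would see them (heel-strike
        intervals, i.e. freeze gaps included)."""
        return _step_times(self.event_sequence())

    def fog_annotation(self) -> FogAnnotation:
        return FogAnnotation(intervals=list(self.fog_intervals), source="simulator")


def _lognormal_step(rng_z: float, mean: float, cv_fraction: float) -> float:
    """One positive step time with exact mean and CV (degenerate at cv 0)."""
    if cv_fraction <= 0:
        return mean
    sigma2 = math.log1p(cv_fraction * cv_fraction)
    mu = math.log(mean) - 0.5 * sigma2
    return math.exp(mu + math.sqrt(sigma2) * rng_z)


def _generate(
    cfg: WalkConfig,
    mode: CueMode,
    strategy_cfg: StrategyConfig | None,
) -> WalkGroundTruth:
    """Sequential walk generation shared by the open- and closed-loop paths.

    The random stream is consumed in a mode-independent order (hesitation,
    then per step: hazard uniform, optional freeze length, step normal), so
    a null cue response (rho 1, no habituation) makes all modes identical
    draw for draw.
    """
    rng = np.random.default_rng(cfg.seed)
    resp = cfg.cue_response
    controller = (
        CueController(cfg=strategy_cfg or StrategyConfig(), walk_span=(0.0, math.inf))
        if mode == CueMode.ON_DEMAND
        else None
    )

    hesitation = (
        float(rng.exponential(cfg.hesitation.delay_mean_s)) if cfg.hesitation else 0.0
    )
    t = cfg.start_time_s + hesitation
    hs_times = [t]
    sides = [Side.LEFT]
    durations: list[float] = []
    gaps: list[float] = []
    fog: list[tuple[float, float]] = []

    for i in range(cfg.n_steps):
        # freeze hazard at this step boundary (not before the first step:
        # pre-walk delay is hesitation, not freezing)
        gap = 0.0
        if cfg.freeze is not None:
            u = float(rng.random())
            if i >= 1:
                recent_cv = (
                    percent_cv(durations[-2:]) if len(durations) >= 2 else 0.0
                )
                hazard = min(cfg.freeze.hazard_base + cfg.freeze.hazard_cv_gain * recent_cv, 0.95)
                if u < hazard:
                    gap = float(rng.exponential(cfg.freeze.duration_mean_s))
                    fog.append((t, t + gap))
                    t += gap
        gaps.append(gap)

        # effective SD multiplier from the cue model at the moment this step launches
        if mode == CueMode.CONTINUOUS:
            rho_eff = 1.0 - (1.0 - resp.rho) * math.exp(-resp.habituation_rate * t)
        elif mode == CueMode.ON_DEMAND and controller is not None and controller.cue_active_at(t):
            rho_eff = resp.rho
        else:
            rho_eff = 1.0

        cv = cfg.baseline_cv
        if cfg.burst is not None and cfg.burst.onset_step <= i < cfg.burst.onset_step + cfg.burst.length_steps:
            cv *= cfg.burst.cv_multiplier
        z = float(rng.standard_normal())
        d = _lognormal_step(z, cfg.mean_step_time, cv * rho_eff / 100.0)
        durations.append(d)
        t = t + d
        hs_times.append(t)
        sides.append(Side.RIGHT if sides[-1] == Side.LEFT else Side.LEFT)
        if controller is not None:
            # the controller sees the step the analysis chain would measure:
            # the heel-strike interval, freeze gap included
            controller.push_step(gap + d, t)

    hs = np.array(hs_times)
    # toe-off per heel strike: a fixed fraction of the (capped) ipsilateral stride
    toe_off = np.empty(len(hs))
    nominal_stride = 2.0 * cfg.mean_step_time
    for k in range(len(hs)):
        stride = hs[k + 2] - hs[k] if k + 2 < len(hs) else nominal_stride
        toe_off[k] = hs[k] + STANCE_STRIDE_FRACTION * min(stride, MAX_STANCE_STRIDES * cfg.mean_step_time)

    if cfg.marker_times is not None:
        markers = [
            Marker(time=cfg.marker_times[0], kind=MarkerKind.SEGMENT_START),
            Marker(time=cfg.marker_times[1], kind=MarkerKind.SEGMENT_END),
        ]
    elif cfg.place_markers:
        s_idx = cfg.marker_start_step
        e_idx = s_idx + cfg.n_segment_steps
        markers = [
            Marker(time=float(hs[s_idx]), kind=MarkerKind.SEGMENT_START),
            Marker(time=float(hs[e_idx]), kind=MarkerKind.SEGMENT_END),
        ]
    else:
        markers = []

    truth = WalkGroundTruth(
        config=cfg,
        seed=cfg.seed,
        step_durations=np.array(durations),
        freeze_gaps=np.array(gaps),
        heel_strike_times=hs,
        sides=sides,
        toe_off_times=toe_off,
        fog_intervals=fog,
        burst_onset_step=cfg.burst.onset_step if cfg.burst else None,
        hesitation_delay_s=hesitation,
        markers=markers,
    )
    if mode == CueMode.NONE:
        truth.cue_timeline = CueTimeline(mode=CueMode.NONE, intervals=[])
    elif mode == CueMode.CONTINUOUS:
        truth.cue_timeline = run_cue_controller(
            StepTimeSeries(), CueMode.CONTINUOUS, walk_span=truth.walk_span
        )
    else:
        assert controller is not None
        controller.walk_span = truth.walk_span
        truth.cue_timeline = controller.finalize()
    return truth


def pd_walk_config(seed: int, **overrides) -> WalkConfig:
    """Canonical parkinsonian walk used for closed-loop mode comparisons.

    A 100-step walk at baseline 3% CV with a late pre-freeze variability
    burst (SD x5 over 20 steps), variability-coupled freezing, start
    hesitation, and the timed 10 m segment placed over the burst so that
    freezing burden shows up in walking speed. Keyword overrides replace
    individual fields.
    """
    base = WalkConfig(
        seed=seed,
        n_steps=100,
        baseline_cv=3.0,
        burst=BurstConfig(onset_step=60, length_steps=20, cv_multiplier=5.0),
        freeze=FreezeConfig(hazard_base=0.01, hazard_cv_gain=0.01, duration_mean_s=3.0),
        hesitation=HesitationConfig(delay_mean_s=1.0),
        marker_start_step=55,
    )
    return replace(base, **overrides) if overrides else base


def simulate_step_times(cfg: WalkConfig) -> WalkGroundTruth:
    """Open-loop walk generation (no cue; equivalent to mode ``none``)."""
    return _generate(cfg, CueMode.NONE, None)


def synthesize_fsr(truth: WalkGroundTruth, cfg: WalkConfig | None = None) -> SensorLog:
    """Render a ground-truth walk into a sampled two-foot FSR sensor log.

    Heel channels carry a triangular loading pulse peaking exactly at each
    true heel-strike time; the toe channel loads after heel contact and
    falls back to zero exactly at the true toe-off time, so the detector's
    peak/valley rules can recover every event to within one sample period.
    """
    cfg = cfg or truth.config
    fs = cfg.sample_rate
    dt = 1.0 / fs
    t_end = truth.walk_span[1] + 0.5
    n = int(math.ceil(t_end * fs)) + 1
    times = np.arange(n) * dt

    chans = {
        side: {"heel": np.zeros(n), "toe": np.zeros(n)} for side in (Side.LEFT, Side.RIGHT)
    }

    hs = truth.heel_strike_times
    for k, (side, tc) in enumerate(zip(truth.sides, hs)):
        # overlap guard: the previous ipsilateral heel pulse must have decayed
        if k >= 2 and hs[k] - hs[k - 2] < HEEL_RISE_S + HEEL_FALL_S + dt:
            raise StepOverlapError(
                f"ipsilateral stride {hs[k] - hs[k-2]:.3f} s too short to synthesise"
            )
        lo = max(0, int(math.floor((tc - HEEL_RISE_S) * fs)))
        hi = min(n - 1, int(math.ceil((tc + HEEL_FALL_S) * fs)))
        tt = times[lo : hi + 1]
        rise = (tt - (tc - HEEL_RISE_S)) / HEEL_RISE_S
        fall = ((tc + HEEL_FALL_S) - tt) / HEEL_FALL_S
        pulse = cfg.amplitude.heel_peak * np.clip(np.minimum(rise, fall), 0.0, 1.0)
        heel = chans[side]["heel"]
        heel[lo : hi + 1] = np.maximum(heel[lo : hi + 1], pulse)

        to = truth.toe_off_times[k]
        span = to - tc
        load_start = tc + TOE_LOAD_FRACTION * span
        peak_t = tc + TOE_PEAK_FRACTION * span
        lo_t = max(0, int(math.floor(load_start * fs)))
        hi_t = min(n - 1, int(math.ceil(to * fs)))
        tt = times[lo_t : hi_t + 1]
        rise = (tt - load_start) / (peak_t - load_start)
        fall = (to - tt) / (to - peak_t)
        pulse = cfg.amplitude.toe_peak * np.clip(np.minimum(rise, fall), 0.0, 1.0)
        # exact zero at and after the true toe-off time
        pulse[tt >= to] = 0.0
        toe = chans[side]["toe"]
        toe[lo_t : hi_t + 1] = np.maximum(toe[lo_t : hi_t + 1], pulse)

    def digitise(x: np.ndarray, noise_rng: np.random.Generator | None) -> np.ndarray:
        if noise_rng is not None and cfg.noise_sd > 0:
            x = x + noise_rng.normal(0.0, cfg.noise_sd, size=x.shape)
        return np.clip(np.rint(x), 0, ADC_MAX).astype(np.int64)

    noise_rng = np.random.default_rng([truth.seed, 7]) if cfg.noise_sd > 0 else None
    feet = {}
    for side in (Side.LEFT, Side.RIGHT):
        heel = chans[side]["heel"]
        feet[side] = FootChannels(
            heel_lateral=digitise(heel, noise_rng),
            heel_medial=digitise(MEDIAL_SCALE * heel, noise_rng),
            toe=digitise(chans[side]["toe"], noise_rng),
        )

    markers = []
    for m in truth.markers:
        idx = int(np.clip(round(m.time * fs), 0, n - 1))
        markers.append(Marker(time=float(times[idx]), kind=m.kind))

    return SensorLog(
        sample_rate=fs,
        timestamps=times,
        left=feet[Side.LEFT],
        right=feet[Side.RIGHT],
        markers=markers,
    )


def closed_loop_session(
    cfg: WalkConfig,
    mode: CueMode | str,
    strategy_cfg: StrategyConfig | None = None,
) -> tuple[WalkGroundTruth, SensorLog, CueTimeline]:
    """Generate a full closed-loop session in one cue mode.

    Returns the ground truth, the synthesised sensor log and the cue
    timeline that was actually applied while generating the walk.
    """
    mode = CueMode(mode)
    truth = _generate(cfg, mode, strategy_cfg)
    log = synthesize_fsr(truth, cfg)
    assert truth.cue_timeline is not None
    return truth, log, truth.cue_timeline
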