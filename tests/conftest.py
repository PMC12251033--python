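import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def clean_walk_log():
    """A noise-free simulated walk (open loop, defaults) and its truth."""
    from gaitcue.simulator import WalkConfig, simulate_step_times, synthesize_fsr

    cfg = WalkConfig(seed=42, n_steps=40)
    truth = simulate_step_times(cfg)
    return truth, synthesize_fsr(truth)


def brute_force_percent_cv(values, ddof=1):
    """Independent %CV oracle: explicit sums, no numpy statistics."""
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = (ss / (n - ddof)) ** 0.5
    return sd / mean * 100.0


def brute_force_replay(durations, strike_times, cfg, walk_span):
    """Independent replay of the on-demand decision flow: build the whole
    %CV array, quotient consecutive entries, threshold each decision in
    order, and apply the release rule. Deliberately batch (non-streaming)
    and loop-based, as a cross-check for the streaming controller."""
    w = cfg.cv_window
    cvs = [
        brute_force_percent_cv(durations[i : i + w], ddof=cfg.sd_ddof)
        for i in range(len(durations) - w + 1)
    ]
    intervals = []
    open_since = None
    open_reason = None
    close_at = None
    run = 0
    for step_idx in range(len(durations)):
        t = strike_times[step_idx]
        if open_since is not None and close_at is not None and t >= close_at:
            intervals.append((open_since, close_at, open_reason))
            open_since = open_reason = close_at = None
            run = 0
        n_cv = step_idx + 2 - w  # cv entries available after this step
        if n_cv < cfg.min_cv_values:
            continue
        num, den = cvs[n_cv - 1], cvs[n_cv - 2]
        if den == 0.0:
            ratio = 1.0 if num == 0.0 else float("inf")
        else:
            ratio = num / den
        if ratio >= cfg.thresh_u:
            outcome = "trigger_upper"
        elif cfg.lower_band_enabled and cfg.lower_band[0] < ratio < cfg.lower_band[1]:
            outcome = "trigger_lower"
        else:
            outcome = None
        if outcome is not None:
            if open_since is None:
                open_since, open_reason = t, outcome
            run = 0
            if cfg.cue_release_fixed_duration_s is not None:
                close_at = t + cfg.cue_release_fixed_duration_s
        elif open_since is not None and cfg.cue_release_fixed_duration_s is None:
            run += 1
            if run >= cfg.cue_release_steps_in_band:
                intervals.append((open_since, t, open_reason))
                open_since = open_reason = None
                run = 0
    if open_since is not None:
        end = close_at if close_at is not None else walk_span[1]
        intervals.append((open_since, min(end, walk_span[1]), open_reason))
    lo, hi = walk_span
    clipped = [
        (max(s, lo), min(e, hi), r) for s, e, r in intervals if min(e, hi) > max(s, lo)
    ]
    merged = []
    for s, e, r in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e), merged[-1][2])
        else:
            merged.append((s, e, r))
    return merged
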