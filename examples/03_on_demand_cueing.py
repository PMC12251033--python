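"""On-demand cueing: trigger a visual cue when step-time variability spikes.

A walk with a pre-freeze variability burst (step-time SD x5 from step 30)
is streamed through the strategy controller, which quotients consecutive
rolling-%CV values and opens a cue when the ratio crosses the upper
threshold (2.5) or falls in the hesitation band (0.5-1).
"""

from gaitcue import (
    BurstConfig,
    CueMode,
    WalkConfig,
    cue_line_placement,
    run_cue_controller,
    simulate_step_times,
)

cfg = WalkConfig(
    seed=3,
    n_steps=60,
    baseline_cv=3.0,
    burst=BurstConfig(onset_step=30, length_steps=20, cv_multiplier=5.0),
    place_markers=False,
)
truth = simulate_step_times(cfg)
series = truth.step_series()

timeline = run_cue_controller(series, CueMode.ON_DEMAND, walk_span=truth.walk_span)
burst_t = truth.heel_strike_times[30]
print(f"variability burst begins at t = {burst_t:.2f} s (step 30)")
print(f"cue intervals ({len(timeline.intervals)}):")
for iv in timeline.intervals:
    print(f"  [{iv.start:6.2f}, {iv.end:6.2f}] s  opened by {iv.reason.value}")
on = timeline.total_on_time()
span = truth.walk_span[1]
print(f"cue on for {on:.1f} s of a {span:.1f} s walk ({100 * on / span:.0f}%)")

dist, length = cue_line_placement(height_m=1.75)
print(f"laser line for a 1.75 m wearer: {length} m line, {dist:.2f} m ahead")
# Expect a cue interval opening within a few steps of the burst onset; the
# earlier short intervals are hesitation-band (lower-threshold) triggers on
# ordinary baseline fluctuation.
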