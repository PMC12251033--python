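"""Compare the three cueing modes in closed loop on simulated walkers.

While a cue is visible the simulated walker's step-time SD shrinks by the
cue-response factor rho = 0.6; under continuous cueing the benefit decays
with exposure (habituation, 0.02/s). Freezing hazard tracks recent
variability, so steadier gait also freezes less and finishes the marked
10 m segment faster.
"""

import numpy as np

from gaitcue import CueMode, closed_loop_session, rolling_cv, walking_speed
from gaitcue.simulator import pd_walk_config

N = 30
out = {m: {"cv": [], "speed": [], "fog": []} for m in CueMode}
for seed in range(N):
    for mode in CueMode:
        truth, log, _ = closed_loop_session(pd_walk_config(seed), mode)
        out[mode]["cv"].append(rolling_cv(truth.step_series()).values.mean())
        out[mode]["speed"].append(walking_speed(log))
        out[mode]["fog"].append(len(truth.fog_intervals))

print(f"{N} simulated walkers x 3 modes (means):")
print(f"{'mode':<12}{'pairwise %CV':>14}{'speed m/s':>12}{'FoG count':>11}")
for mode in CueMode:
    v = out[mode]
    print(f"{mode.value:<12}{np.mean(v['cv']):>14.2f}{np.mean(v['speed']):>12.3f}"
          f"{np.mean(v['fog']):>11.2f}")
# Expected ordering: variability and freezing highest with no cue, lower
# with continuous cueing, lowest on demand; walking speed the reverse —
# on-demand cueing delivers the full (unhabituated) response exactly when
# variability rises.
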