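# Methods

This note records the models, conventions and free parameters behind the
package, the reasoning where the design was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Signal model and time base

A sensor log is a uniformly sampled (default 100 Hz, carried in the file
header) record of six FSR channels — per foot: heel-lateral, heel-medial,
toe — digitised to integer ADC counts in [0, 1023], with time in seconds and
t = 0 at the first sample. The pathway-segment detector is abstracted to two
instantaneous marker events (`segment_start`, `segment_end`) bracketing the
timed 10 m stretch. Logs with gaps or non-uniform spacing (tolerance 1 ns)
are rejected rather than resampled: every downstream guarantee ("within one
sample period") presumes a clean grid, and resampling would silently blur
event timing. All readers validate invariants and raise named errors;
nothing is coerced.

## Event detection

Heel-strike detection is a three-state machine over the merged heel signal
(element-wise maximum of the lateral and medial sensors, so a valid contact
on either site counts):

* a **contact episode** is a maximal run of samples ≥ `valid_peak_min`
  (50 counts);
* a new episode is admitted only after the signal has returned to
  ≤ `valley_level + valley_epsilon` (0 + 0 by default) since the previous
  one — supra-threshold runs without an intervening valley are discarded;
* the event time is the episode's maximum sample, earliest sample on ties.

Anchoring at the peak rather than contact onset follows the device
convention of time-stamping the *valid peak*; `event_anchor="onset"` is
available where onset timing is preferred. `valley_epsilon` exists for noisy
data: with additive baseline noise the signal never returns exactly to 0, so
ε should be set above the noise floor (the test suite uses ε = 12 counts for
noise of SD 4).

A toe-off is the first return of the toe channel to the valley level after a
supra-valley loading that follows the ipsilateral heel strike. The search is
bounded by the next ipsilateral heel strike or the end of the log; a heel
strike whose toe-off is not observed is flagged *incomplete*, never given a
fabricated event.

## Metrics

Step Time is the interval between consecutive heel strikes of opposite
feet; consecutive ipsilateral strikes (a missed event) produce no step and a
flag. Step times are deliberately *not* filtered by plausibility bounds: a
freeze shows up as one very long step, and the variability statistic must
see it.

`%CV = SD / mean × 100` uses the sample (n−1) standard deviation; `ddof=0`
is available. The rolling %CV window defaults to 2 — one %CV value per
consecutive step-time pair, matching how the on-device array is built — and
is configurable.

Walking speed is `segment_distance / (t_end − t_start)` over the marker
pair, 10 m by default. Freezing burden (episode count, % time frozen) is
computed on the union of annotation intervals, making it invariant to
overlapping, split or permuted annotations; the walk interval defaults to
the marked segment when markers exist, else the full log span.

## Strategy generator

The streaming controller maintains the rolling %CV array and, once two
values exist (i.e. from the fourth heel strike at window 2), quotients the
two most recent entries. Conventions: 0/0 → 1 (perfectly regular gait stays
quiet); x/0 → +∞ for x > 0 (an unambiguous rise; triggers). Decision rules:

* ratio ≥ 2.5 → upper trigger (inclusive, so a ratio of exactly the
  threshold fires);
* 0.5 < ratio < 1 (both ends exclusive) → hesitation trigger, intended to
  help re-initiate a stalling walk; disable with `lower_band_enabled=False`.

Cue release is not part of the published decision flow, so it is a policy
option: by default the cue closes after two consecutive non-triggering
decisions (long enough to be perceived, still "on demand"); a fixed-duration
release is available. Overlapping or adjacent cue intervals merge, keeping
the opening trigger's reason. The controller is strictly incremental;
streaming and batch processing provably (and test-verifiably) yield the same
timeline.

The cue line is projected 0.4 × wearer height ahead, 1.5 m long.

### Operating characteristics — a real limitation

The consecutive pairwise-%CV ratio is a noisy statistic. For i.i.d. step
times the pairwise %CV is approximately proportional to |d_k − d_{k+1}|, so
the ratio of consecutive (overlapping) pairs behaves like a quotient of
correlated half-normal variables — a heavy-tailed distribution with
P(ratio ≥ 2.5) ≈ 0.22 *per decision* at baseline CV 3%. A 100-step walk
therefore almost surely contains upper-threshold false triggers. Sensitivity
is likewise capped: when the step-time SD steps up by a factor of 4–5, only
the two or three decisions straddling the burst boundary carry an elevated
ratio (once both window members lie inside the burst the ratio returns
to ≈ 1), so the probability of an upper trigger within three steps of onset
plateaus near 85–90% (Monte Carlo, 500–2000 runs). Widening the %CV window
trades these against each other but cannot satisfy both a <5% per-walk false
rate and ≥95% within-3-steps sensitivity at threshold 2.5 (a scan over
windows 2–10 shows the false rate only drops below 5% where sensitivity has
fallen under 30%). The package implements the statistic faithfully and
reports its measured operating point rather than replacing it; a smoothed or
baseline-referenced variability index would be the natural evolution.

## Simulator

Step times are log-normal, parameterised to exact mean (0.55 s) and CV
(baseline 3%): positivity and mild right skew are physiologically
reasonable, and the thresholds under test only care about second-moment
structure. Features layered on the base process:

* **Burst** — CV multiplied by `cv_multiplier` over a step range; the
  pre-freeze signature.
* **Freezes** — per-step hazard `hazard_base + hazard_cv_gain × recent
  pairwise %CV` (defaults 0.01/step and 0.01 per %CV unit, mean duration
  3 s, exponential), inserting step-free time between two heel strikes.
  Coupling hazard to recent variability implements the premise that
  variability precedes freezing; the gain is a free parameter chosen to make
  a 100-step pathological walk freeze a handful of times.
* **Hesitation** — exponential extra delay (mean 1 s) before the first step.
* **Cue response** — while a cue is visible the drawn step-time SD is
  multiplied by ρ = 0.6; under *continuous* cueing the benefit decays as
  `ρ_eff(t) = 1 − (1 − ρ)·e^(−0.02 t)` with cumulative exposure
  (habituation). On-demand cues act at full ρ, since each exposure is brief.
  Direction and existence of both effects follow the cueing literature;
  the magnitudes are modeling choices, **not** estimates from human data.

Ground truth records drawn durations, inserted freeze gaps, exact event
times, freeze intervals, the applied cue timeline and the seed. Consistency
contract: heel-strike interval i = drawn duration i + freeze gap i, to
1 ns. The analysis-facing "step time" around a freeze is the full heel-strike
interval — the long step a real device would measure.

FSR synthesis renders each contact as piecewise-linear loading: the heel
triangle rises 0.12 s before and falls 0.30 s after its apex *at the true
heel-strike time*; the toe loads after heel contact and falls to zero
*exactly at the true toe-off time* (toe-off is placed at 65% of the
ipsilateral stride, capped during freezes). Steps too short to synthesise
raise rather than overlap. Amplitudes default to 400/300 counts (heel/toe);
sub-threshold amplitudes are allowed on purpose, so undetectable-contact
experiments can be constructed. Optional additive Gaussian noise is clipped
to the ADC range. Markers are snapped to the sampling grid at synthesis
time. The marked segment covers 16 steps of 0.625 m (10 m at ~1.1 m/s for
the default cadence), and the canonical pathological walk
(`pd_walk_config`) places the segment over the burst so that freezing
burden shows up in walking speed.

The single integer seed drives every draw through one generator consumed in
a mode-independent order, so ρ = 1 with zero habituation makes the three cue
modes draw-for-draw identical — the null-effect control used in the tests.

## Pipeline conventions

Percent change between modes is `100 × (a − b) / a` with the earlier mode
(in the order none, continuous, on-demand) as baseline `a`. Pearson r is
computed by direct summation (and cross-checked against both a hand-rolled
oracle and scipy in the tests); inferential tests are intentionally not
included — the report exposes per-stratum samples for external statistics
packages. Cohort reports are byte-deterministic for fixed inputs.

## What the synthetic experiments show — and what they do not

The simulator emulates the *timing structure* of pathological gait:
variability levels, bursts, freeze insertion, hesitation, cue response. It
does not emulate biomechanically realistic force profiles, turning,
dual-task cognition (beyond a CV multiplier), sensor drift, or the
heterogeneity of real patients. Passing tests therefore establish that the
decision logic is implemented exactly (oracle equivalences, ground-truth
recovery, mode orderings under the stated response model) — not that the
device's thresholds would achieve any particular clinical sensitivity or
specificity in people. Problem sizes in the validation runs (100 detection
walks, 500 controller replays, 200 closed-loop seeds per mode, 60–100 steps
per walk) were chosen to make Monte-Carlo orderings stable at desk scale.

## Known limitations

* The ratio statistic's operating point (above) is intrinsic to the
  published design, not to this implementation.
* Cue-response and habituation magnitudes are free parameters; closed-loop
  results are qualitative orderings only.
* Heel-strike timing is exact to one sample only for well-separated
  contacts; pathologies that blur the valley (shuffling with sustained heel
  load) would require a non-zero `valley_epsilon` and may merge contacts.
* The uniform-sampling assumption is load-bearing; jittered acquisition is
  rejected, not corrected.
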