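# Methods

## The task

Each *Collect Asteroids* subtask is a discrete corridor: the ship descends
one row per step for 470 steps and steers left/right (or not) across 9
playable columns between two walls. Asteroids (14 on easy, 30 on hard) are
placed uniformly over columns and over step indices outside two
asteroid-free spans — 40 steps at episode start and 40 steps centred on
step 235 — at most one per row. An asteroid is collected iff the ship
occupies its column at the step its row is reached; otherwise it is missed
at that step. Performance is the success rate SR = collected / total.
With input noise enabled, every left/right command receives an offset drawn
from N(0, σ² = 1.5), and the sum is rounded to the nearest integer column
displacement before wall clipping; straight-ahead commands are never
perturbed. The transition is deterministic without noise, stochastic with
it.

In the multitasking scenario two such subtasks run concurrently but only
one can be perceived and controlled at a time. A meta-agent chooses the
attended task on a fixed grid of 5 frames (94 decisions per episode); the
unattended environment executes the default no-steer action.

## Rewards

Sub-agents train on a dense shaping reward with two components, each scaled
to [0, 255] (the 8-bit image-intensity convention, since the occupancy
channel is conceptually a blurred image): (1) the value, at the ship's
cell, of the visible-asteroid impulse image convolved with a Gaussian of
σ = 1 cell (evaluated in closed form through the separable kernel, which
equals zero-padded `scipy.ndimage.gaussian_filter`; a unit impulse on the
ship's cell scores 255), and (2) a horizontal-distance term
255 · (1 − |Δx| / 8) toward the nearest visible asteroid. The two are mixed
with equal weight 0.5. Visibility is a 15-row lookahead window; an empty
window scores 0. The intensity scale matters beyond cosmetics: the
need-for-control normalisation divides rollout-return gaps by 100, which is
only meaningful when per-step rewards are of image-intensity magnitude —
with rewards normalised to [0, 1] the gap never exceeds ~7 and the
need-for-control cue degenerates to ≈0.

A sparse alternative pays +m per collection and −m per miss with
m = 100/N, so an episode total spans [−100, +100] and hits the bounds
exactly when all asteroids are collected or all are missed.

## The sense-of-control model

The situational sense of control of the attended task composes two
normalised cues:

- **Prediction error** — a noise-unaware forward model predicts the next
  state (all rows advance by one; the ship column follows the commanded
  action, clipped at walls). PE = tanh(0.5 · |x − x̂|) between realized and
  predicted ship columns, so a 4-column mismatch saturates near 1. Without
  input noise the model is exact and PE ≡ 0; with noise PE is purely
  aleatoric.
- **Need for control** — two forward-model rollouts of horizon N = 10 from
  the current state: one under a greedy oracle (steer toward the nearest
  visible asteroid, ties toward smaller |Δx| then toward the centre), one
  under the default no-steer policy. Each reward sequence
  (r_{t−1}, r̂_t, …, r̂_{t+N−2}) is summed with the first element
  undiscounted and the k-th predicted reward weighted γ^k, γ = 0.9;
  rollouts truncate at episode end. NfC = min(max(rs_opt − rs_def, 0)/100, 1).
  The lower clamp covers the case where a merely-trained "optimal" policy
  underperforms no-steer; the greedy oracle default makes NfC deterministic
  and testable without training, and a trained sub-policy can be plugged in.

SoC = 1 − (PE + NfC)/2 ∈ [0, 1]. The unattended task's SoC cannot be
measured; its estimate decays by φ = 0.1 per meta decision, floored at 0,
and resets to a fresh measurement at the first decision after the task is
re-attended. A fresh task (and both tasks at episode start) carries
SoC = 1. The decay cadence is a genuine design choice: applying φ per
environment frame (0.5 per decision slice) empties the estimate so fast
that a trained SoC-reward agent degenerates to switching at every decision;
per-decision decay preserves the intended dynamics (switch when the field
is clear, stay when control is needed) and is the default
(`SoCConfig.decay_per`, with `"frame"` available).

Rollout horizon N = 10 is chosen so a rollout spans the approach of the
nearest visible asteroid at the default geometry; it is configurable.

## Hierarchy and meta-agent variants

At each decision the meta-observation concatenates an attended-task
indicator with, per task slot, either positional vectors (ship column plus
(Δx, Δrow) of the 5 nearest visible asteroids, sentinel-padded — truth for
the attended task, a forward-model belief propagated under the default
action for the other) or the SoC pair (fresh for attended, decayed for
unattended). The meta reward is either the attended task's summed subtask
reward over the 5 frames, or the intrinsic ±1 signal that pays +1 for
attending the strictly-lower-SoC task, −1 for the opposite, 0 on ties. The
four observation × reward combinations are the no-SoC, SoC-as-observation,
SoC-as-reward and SoC agents. The attended task's NfC is measured once per
decision (at the slice's final state) and its PE from the slice's final
frame; this keeps an episode's cost at 94 rollout pairs rather than 470.

Before the first decision, task 0 counts as attended. The
switch-every-frame baseline therefore toggles starting with task 1, making
each of the 94 decisions a switch (its defining property), while a
never-switching policy on task 0 logs 0 switches.

## Training

All agents train with PPO (clipped surrogate, GAE, entropy bonus, Adam) on
a shared-body tanh MLP with 64 hidden units, implemented in numpy and
deterministic under a seed. Rewards are normalised online by a running
estimate of the discounted-return standard deviation, which makes training
insensitive to the 255× intensity scale. Defaults: learning rate 3e-3,
discount 0.9, GAE λ 0.95, entropy coefficient 0.005, rollout buffer 1024
steps (512 for meta-agents), 4 epochs of minibatch 256. A fixed-seed random
search over learning rate, discount, GAE λ and entropy coefficient is
provided; the shipped defaults came from a small manual search of that
space.

Two budget presets exist. The `paper` preset (10M env steps for
sub-agents; 1.3M meta decisions for active-reward meta-agents, 10k for
SoC-reward ones) carries the full-scale study budgets, is sized for GPU
clusters, and is not exercised by the test suite. The desk preset — the package's own choice of
problem sizes for a single CPU — uses 200k env steps for sub-agents and 6k
meta decisions for every meta-agent (matched across configurations so
comparisons are budget-fair). At these budgets the easy/no-noise sub-agent
reaches SR ≈ 0.75–0.91 (short of what full-scale budgets reach) and the SoC vs no-SoC ordering on
easy/easy without noise reproduces with a comfortable margin; absolute
desk-scale SRs undershoot full-scale values and only orderings should be
interpreted.

## Evaluation and statistics

Within a block, every agent is evaluated on the same list of per-episode
world-seed pairs, so cross-agent SR differences are paired. Metrics per
agent: mean/SD of overall SR (unweighted mean of the two per-task SRs),
per-task SRs, engagement ratio of task one, switch count (0–94), the
per-decision switching ratio across episodes (with asteroid-free decisions
flagged), and mean visible asteroids of the attended task at switch vs
non-switch decisions (the non-switch group is reported as absent for the
switch-every-frame baseline, which has none). Block-level inference: a
one-way ANOVA over per-agent SR samples, Bartlett's test for
homoscedasticity, and all pairwise two-tailed t-tests with a directly
implemented Holm step-down adjustment (cross-checked against statsmodels in
the tests), α = 0.05. Groups that are all constant are reported as
degenerate and the tests skipped.

## What the generator does and does not emulate

The world generator reproduces the study conditions: asteroid counts per
difficulty, uniform placement outside the two asteroid-free spans, the
470-step episode, and rounded-Gaussian input noise. It does not emulate
pixel rendering, frame timing, or human motor constraints; traces are
positional, and the human-comparison side of the original study (reaction
costs, fatigue, trial pacing) is out of scope. Corridor width (9), window
height (15), one-asteroid-per-row placement and the span lengths are not
derivable from the study description and are declared defaults, all
configurable. Consequently, passing tests show that the mechanism —
SoC-guided switching improving multitask SR — holds under these declared
geometry choices, not that any particular absolute SR level is recovered.

## Numerical choices and degenerate inputs

- Noise offsets round half-to-even via `np.rint` before wall clipping.
- The greedy oracle and the dense reward only react to asteroids inside
  the visibility window; deep inside asteroid-free spans (further than
  rollout horizon + window height from the span's end) optimal and default
  rollouts coincide exactly and NfC is exactly 0. Near a span's end the
  oracle legitimately pre-aligns with upcoming asteroids and NfC > 0.
- The blur term is capped at the single-impulse peak so overlapping
  asteroids cannot push the component above its nominal scale.
- `success_rate` is defined only at episode end; stepping a finished
  episode raises. A zero-asteroid world is valid for dynamics but cannot be
  produced by the generator.
- SoC composition validates its inputs to [0, 1]; the decay floor at 0 is
  absorbing. Ties in the SoC comparison pay 0 reward.

## Known limitations

The forward model is the exact noise-free transition, not a learned model,
so all prediction error is aleatoric by construction. The SoC reward
compares scalar SoCs only at decision boundaries; within a slice the
unattended estimate is linear by fiat rather than informed by the belief
state. Desk-scale PPO on a 64-unit MLP underfits the hard task; hard-block
orderings at desk scale are noisier than the easy blocks. No meta-level
sense of control is modelled.
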