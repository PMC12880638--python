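"""The situational sense-of-control (SoC) model.

SoC composes two normalised cues, each in [0, 1]:

* **prediction error** (PE): ``tanh(0.5 * |x - x_hat|)`` between the realized
  and forward-model-predicted ship column — the comparator-model cue.  Input
  noise is the only source of mismatch, so PE is purely aleatoric here.
* **need for control** (NfC): the gap between discounted reward sums of two
  forward-model rollouts from the current state — one under an optimal
  (greedy) policy, one under the default no-steer policy — scaled by 1/100
  and capped at 1.  A large gap means inaction is costly: the task needs
  attention.

``SoC = 1 - (PE + NfC) / 2``.  The unattended task's SoC cannot be measured
and is instead decayed by ``phi`` per step, floored at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from socrl.environment import EnvConfig, WorldState
from socrl.forward_model import predict_next

Policy = Callable[[WorldState, EnvConfig], int]


@dataclass(frozen=True)
class SoCConfig:
    """Parameters of the SoC model.

    rollout_horizon
        Trajectory length N of the NfC rollouts (one realized reward
        followed by N-1 predicted rewards).
    gamma
        Discount weighting the predicted rewards (0.9).
    decay_phi
        Decrement of the unattended task's SoC estimate per decay
        application (0.1).
    decay_per
        Cadence at which the decrement is applied while a task is
        unattended: ``"decision"`` (once per meta decision, the default) or
        ``"frame"`` (once per environment frame).
    nfc_scale
        Divisor normalising the rollout-return gap (100).
    pe_slope
        Slope inside the tanh of the prediction error (0.5): distances of 4
        or more columns map to a PE of ~1.
    initial_soc
        SoC assigned before any measurement (fresh task / episode start).
    """

    rollout_horizon: int = 10
    gamma: float = 0.9
    decay_phi: float = 0.1
    decay_per: str = "decision"
    nfc_scale: float = 100.0
    pe_slope: float = 0.5
    initial_soc: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")
        if self.decay_phi <= 0 or self.nfc_scale <= 0:
            raise ValueError("decay_phi and nfc_scale must be positive")
        if self.rollout_horizon < 2:
            raise ValueError("rollout_horizon must be >= 2")
        if self.decay_per not in ("decision", "frame"):
            raise ValueError("decay_per must be 'decision' or 'frame'")
        if not (0.0 <= self.initial_soc <= 1.0):
            raise ValueError("initial_soc must be in [0, 1]")


@dataclass
class SoCComponents:
    """Per-task SoC record at one timestep."""

    task_id: int
    timestep: int
    pe: float
    nfc: float
    soc: float
    is_estimate: bool  # True for the decayed, unattended-task value


def prediction_error(actual_x: float, predicted_x: float, cfg: SoCConfig) -> float:
    """tanh-normalised column distance between realized and predicted ship
    positions; 0 when they agree, ~1 from 4 columns of mismatch."""
    return math.tanh(cfg.pe_slope * abs(actual_x - predicted_x))


def rollout(
    start_state: WorldState,
    policy: Policy,
    horizon: int,
    config: EnvConfig,
    last_reward: float = 0.0,
) -> np.ndarray:
    """Reward sequence ``(r_{t-1}, r_hat_t, ..., r_hat_{t+N-2})``: the last
    realized reward followed by ``horizon - 1`` forward-model-predicted
    rewards under ``policy``, truncated at episode end."""
    if horizon < 2:
        raise ValueError("rollout horizon must be >= 2")
    rewards = [last_reward]
    state = start_state
    for _ in range(horizon - 1):
        if state.step_index >= config.episode_length:
            break
        pred = predict_next(state, policy(state, config), config)
        rewards.append(pred.predicted_reward)
        state = pred.predicted_state
    return np.asarray(rewards, dtype=float)


def discounted_sum(rewards: Sequence[float], gamma: float) -> float:
    """First (realized) reward undiscounted; k-th predicted reward weighted
    by gamma**k."""
    r = np.asarray(rewards, dtype=float)
    if r.size == 0:
        raise ValueError("empty reward sequence")
    return float(r[0] + np.sum(gamma ** np.arange(1, r.size) * r[1:]))


def need_for_control(
    state: WorldState,
    optimal_policy: Policy,
    default_policy: Policy,
    cfg: SoCConfig,
    config: EnvConfig,
    last_reward: float = 0.0,
) -> float:
    """``min(max(rs_opt - rs_def, 0) / nfc_scale, 1)``.

    The shared realized first reward cancels in the difference; the lower
    clamp guards the (theoretically impossible for a true optimum, but
    practically possible for a merely trained policy) case rs_opt < rs_def.
    """
    rs_o = discounted_sum(
        rollout(state, optimal_policy, cfg.rollout_horizon, config, last_reward), cfg.gamma
    )
    rs_d = discounted_sum(
        rollout(state, default_policy, cfg.rollout_horizon, config, last_reward), cfg.gamma
    )
    return min(max(rs_o - rs_d, 0.0) / cfg.nfc_scale, 1.0)


def compose_soc(pe: float, nfc: float) -> float:
    """``SoC = 1 - (PE + NfC) / 2``; both cues must lie in [0, 1]."""
    if not (0.0 <= pe <= 1.0 and 0.0 <= nfc <= 1.0):
        raise ValueError("pe and nfc must lie in [0, 1]")
    return 1.0 - (pe + nfc) / 2.0


def decay_inactive(prev_soc: float, cfg: SoCConfig) -> float:
    """Unattended-task estimate: ``max(0, SoC_{t-1} - phi)``."""
    if not (0.0 <= prev_soc <= 1.0):
        raise ValueError("prev_soc must lie in [0, 1]")
    return max(0.0, prev_soc - cfg.decay_phi)


def meta_soc_reward(soc_task0: float, soc_task1: float, chosen: int) -> int:
    """Meta-agent intrinsic reward: +1 for attending the task with the
    strictly lower SoC, -1 for the strictly higher one, 0 on ties."""
    if chosen not in (0, 1):
        raise ValueError("chosen must be 0 or 1")
    if soc_task0 == soc_task1:
        return 0
    lower = 0 if soc_task0 < soc_task1 else 1
    return 1 if chosen == lower else -1
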