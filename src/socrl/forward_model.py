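"""Deterministic one-step predictor of the next world state and reward.

The forward model mirrors the environment's noise-free dynamics: every
y-position drops by one row per step while the ship's x-position follows the
commanded action (left / none / right), clipped at the walls.  It is
deliberately unaware of input noise — with noise enabled the realized ship
position can deviate from the prediction, and that discrepancy is the
aleatoric prediction error feeding the sense-of-control model.  Collection
events along predicted trajectories are resolved with the same rule as the
environment so that multi-step rollouts stay consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from socrl.environment import (
    COLLECTED,
    MISSED,
    PENDING,
    ActionCommand,
    EnvConfig,
    WorldState,
    dense_reward,
)

_ACTION_DX = (-1, 0, 1)


@dataclass
class Prediction:
    """Predicted next state (positions and propagated statuses) and the
    dense reward the environment would assign in that state."""

    predicted_state: WorldState
    predicted_reward: float


def predict_next(state: WorldState, action: int, config: EnvConfig) -> Prediction:
    """Pure, noise-unaware transition: ship_row - 1, ship_x adjusted by the
    action and clipped at the walls, asteroid resolution as in the
    environment.  Consumes no randomness and never mutates ``state``."""
    action = ActionCommand(action)
    nxt = state.copy()
    nxt.ship_x = int(np.clip(state.ship_x + _ACTION_DX[action], 0, config.corridor_width - 1))
    nxt.ship_row -= 1
    nxt.step_index += 1
    reached = (nxt.asteroid_status == PENDING) & (nxt.asteroid_steps == nxt.step_index)
    hit = reached & (nxt.asteroid_cols == nxt.ship_x)
    nxt.asteroid_status[hit] = COLLECTED
    nxt.asteroid_status[reached & ~hit] = MISSED
    return Prediction(nxt, dense_reward(nxt, config))
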