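"""Scripted sub-task policies: the inactive default and a greedy oracle.

A policy here is any callable ``(WorldState, EnvConfig) -> action``.
"""

from __future__ import annotations

import numpy as np

from socrl.environment import ActionCommand, EnvConfig, WorldState, visible_mask


def default_policy(state: WorldState, config: EnvConfig) -> int:
    """The action executed in an unattended task: no steering."""
    return int(ActionCommand.NONE)


def greedy_policy(state: WorldState, config: EnvConfig) -> int:
    """Deterministic oracle: steer toward the nearest visible pending
    asteroid (nearest by rows ahead, ties by smaller |dx|, then by column
    closer to the corridor centre); hold straight when aligned or when
    nothing is visible."""
    vis = visible_mask(state, config)
    if not vis.any():
        return int(ActionCommand.NONE)
    dx = state.asteroid_cols[vis] - state.ship_x
    dy = state.asteroid_steps[vis] - state.step_index
    centre = (config.corridor_width - 1) / 2.0
    off_centre = np.abs(state.asteroid_cols[vis] - centre)
    target = np.lexsort((off_centre, np.abs(dx), dy))[0]
    d = int(dx[target])
    if d > 0:
        return int(ActionCommand.RIGHT)
    if d < 0:
        return int(ActionCommand.LEFT)
    return int(ActionCommand.NONE)
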