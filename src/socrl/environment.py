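"""The Collect Asteroids subtask simulator.

A spaceship flies down a walled vertical corridor populated with randomly
placed asteroids.  The ship advances one row per step; the player steers
left/right (or not at all) to align with asteroids and collect them as their
row is reached.  Difficulty sets the asteroid count (easy: 14, hard: 30).
Optional input noise perturbs every steering move by a rounded draw from
N(0, 1.5), making transitions stochastic.

Coordinates: columns are 0-based within the playable corridor (walls sit
just outside at -1 and ``corridor_width``).  The ship's row decreases by one
per step, so an asteroid is parameterised by the step index at which its row
is reached rather than by an absolute row.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import yaml

EASY_ASTEROIDS = 14
HARD_ASTEROIDS = 30
DEFAULT_EPISODE_LENGTH = 470

# asteroid status codes
PENDING = 0
COLLECTED = 1
MISSED = 2


class ActionCommand(enum.IntEnum):
    """Sub-task action space: steer left, no steering, steer right."""

    LEFT = 0
    NONE = 1
    RIGHT = 2


_ACTION_DX = {ActionCommand.LEFT: -1, ActionCommand.NONE: 0, ActionCommand.RIGHT: 1}


@dataclass(frozen=True)
class EnvConfig:
    """Static configuration of one Collect Asteroids subtask.

    Parameters
    ----------
    difficulty
        ``"easy"`` (14 asteroids) or ``"hard"`` (30 asteroids).
    input_noise
        If true, every left/right move receives a rounded Gaussian offset
        with mean ``noise_mean`` and variance ``noise_variance``.
    episode_length
        Number of steps per episode (470 by default).
    corridor_width
        Number of playable columns between the walls.
    window_height
        Rows of lookahead within which asteroids are *visible* (used by the
        dense reward, observations and the greedy oracle).
    asteroid_free_spans
        Half-open step-index intervals kept free of asteroids; defaults to a
        40-step span at episode start and a 40-step span centred on step 235.
    reward_mode
        ``"dense"`` (blurred occupancy + distance shaping) or ``"sparse"``
        (+-100/N per collection/miss).
    blur_sigma
        Gaussian blur width (cells) applied to the asteroid occupancy grid
        for the dense reward.
    distance_weight
        Mixing weight of the horizontal-distance term in the dense reward;
        both terms are normalised to [0, reward_scale] and mixed
        ``(1 - w) * blur + w * distance``.
    reward_scale
        Peak intensity of each dense-reward component (255, the 8-bit image
        convention: the blur term is the value of the blurred occupancy
        image at the ship's cell).  Rollout-return gaps on this scale make
        the need-for-control normalisation (gap / 100) meaningful.
    obs_slots
        Number of nearest-asteroid slots in the positional observation
        vector.
    """

    difficulty: str = "easy"
    input_noise: bool = False
    noise_mean: float = 0.0
    noise_variance: float = 1.5
    episode_length: int = DEFAULT_EPISODE_LENGTH
    corridor_width: int = 9
    window_height: int = 15
    asteroid_free_spans: tuple[tuple[int, int], tuple[int, int]] = ((0, 40), (215, 255))
    reward_mode: str = "dense"
    blur_sigma: float = 1.0
    distance_weight: float = 0.5
    reward_scale: float = 255.0
    obs_slots: int = 5
    max_per_row: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.difficulty not in ("easy", "hard"):
            raise ValueError(f"difficulty must be 'easy' or 'hard', got {self.difficulty!r}")
        if self.reward_mode not in ("dense", "sparse"):
            raise ValueError(f"reward_mode must be 'dense' or 'sparse', got {self.reward_mode!r}")
        if self.noise_variance <= 0:
            raise ValueError("noise_variance must be > 0")
        if self.episode_length <= 0 or self.corridor_width <= 0:
            raise ValueError("episode_length and corridor_width must be positive")
        for lo, hi in self.asteroid_free_spans:
            if not (0 <= lo <= hi <= self.episode_length):
                raise ValueError("asteroid_free_spans must lie within the episode")

    @property
    def asteroid_count(self) -> int:
        return EASY_ASTEROIDS if self.difficulty == "easy" else HARD_ASTEROIDS

    @classmethod
    def from_dict(cls, d: dict) -> "EnvConfig":
        spans = d.get("asteroid_free_spans")
        if spans is not None:
            d = dict(d)
            d["asteroid_free_spans"] = tuple(tuple(s) for s in spans)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "EnvConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class WorldState:
    """Full state of one subtask at one step.

    Asteroids are stored as parallel arrays: playable column, the step index
    at which their row is reached, and their status (pending / collected /
    missed).  ``ship_row`` follows the convention that the vertical index
    decreases by one per step.
    """

    ship_x: int
    ship_row: int
    step_index: int
    asteroid_cols: np.ndarray
    asteroid_steps: np.ndarray
    asteroid_status: np.ndarray

    def copy(self) -> "WorldState":
        return WorldState(
            ship_x=self.ship_x,
            ship_row=self.ship_row,
            step_index=self.step_index,
            asteroid_cols=self.asteroid_cols.copy(),
            asteroid_steps=self.asteroid_steps.copy(),
            asteroid_status=self.asteroid_status.copy(),
        )

    def counts(self) -> tuple[int, int, int]:
        """(pending, collected, missed) asteroid counts."""
        s = self.asteroid_status
        return int(np.sum(s == PENDING)), int(np.sum(s == COLLECTED)), int(np.sum(s == MISSED))


@dataclass
class StepOutcome:
    next_state: WorldState
    reward: float
    collected_now: int
    missed_now: int
    done: bool


def generate_world(config: EnvConfig, rng: np.random.Generator) -> WorldState:
    """Place ``asteroid_count`` asteroids uniformly over playable columns and
    over step indices outside the asteroid-free spans (at most
    ``max_per_row`` per row), with the ship starting centred."""
    n = config.asteroid_count
    allowed = np.ones(config.episode_length + 1, dtype=bool)
    allowed[0] = False  # nothing to resolve on the very first frame
    for lo, hi in config.asteroid_free_spans:
        allowed[lo:hi] = False
    allowed[config.episode_length] = allowed[config.episode_length] and True
    candidate_steps = np.flatnonzero(allowed)
    candidate_steps = candidate_steps[candidate_steps <= config.episode_length]
    capacity = candidate_steps.size * config.max_per_row
    if capacity < n:
        raise ValueError(
            f"corridor cannot host {n} asteroids: only {capacity} placement slots"
        )
    slots = np.repeat(candidate_steps, config.max_per_row)
    steps = np.sort(rng.choice(slots, size=n, replace=False))
    cols = rng.integers(0, config.corridor_width, size=n)
    return WorldState(
        ship_x=config.corridor_width // 2,
        ship_row=config.episode_length,
        step_index=0,
        asteroid_cols=cols.astype(np.int64),
        asteroid_steps=steps.astype(np.int64),
        asteroid_status=np.full(n, PENDING, dtype=np.int8),
    )


def apply_input_noise(intended_dx: int, config: EnvConfig, rng: np.random.Generator) -> int:
    """Perturb a unit steering move by a rounded Gaussian offset.

    The offset is drawn from N(noise_mean, noise_variance) and added to the
    intended +-1 displacement; the sum is rounded to the nearest integer
    column displacement (wall clipping happens later, in :func:`step`).
    """
    if intended_dx not in (-1, 1):
        raise ValueError("input noise applies only to unit left/right moves")
    eps = rng.normal(config.noise_mean, math.sqrt(config.noise_variance))
    return int(np.rint(intended_dx + eps))


def step(
    state: WorldState,
    action: int,
    config: EnvConfig,
    rng: Optional[np.random.Generator] = None,
) -> StepOutcome:
    """Advance one frame: steer (with optional noise), descend one row,
    resolve any asteroid whose row is reached, and compute the reward."""
    if state.step_index >= config.episode_length:
        raise RuntimeError("step() called on a finished episode")
    action = ActionCommand(action)
    intended_dx = _ACTION_DX[action]
    if config.input_noise and intended_dx != 0:
        if rng is None:
            raise ValueError("input_noise requires an rng")
        realized_dx = apply_input_noise(intended_dx, config, rng)
    else:
        realized_dx = intended_dx
    nxt = state.copy()
    nxt.ship_x = int(np.clip(state.ship_x + realized_dx, 0, config.corridor_width - 1))
    nxt.ship_row -= 1
    nxt.step_index += 1

    reached = (nxt.asteroid_status == PENDING) & (nxt.asteroid_steps == nxt.step_index)
    hit = reached & (nxt.asteroid_cols == nxt.ship_x)
    nxt.asteroid_status[hit] = COLLECTED
    nxt.asteroid_status[reached & ~hit] = MISSED
    collected_now = int(np.sum(hit))
    missed_now = int(np.sum(reached)) - collected_now

    if config.reward_mode == "sparse":
        reward = sparse_reward(collected_now, missed_now, config)
    else:
        reward = dense_reward(nxt, config)
    done = nxt.step_index == config.episode_length
    if done:
        # any still-pending asteroid past its row can only occur with a
        # mis-specified placement; resolve defensively as missed
        stale = nxt.asteroid_status == PENDING
        nxt.asteroid_status[stale] = MISSED
        missed_now += int(np.sum(stale))
    return StepOutcome(nxt, float(reward), collected_now, missed_now, done)


def visible_mask(state: WorldState, config: EnvConfig) -> np.ndarray:
    """Pending asteroids within the lookahead window (1..window_height rows
    ahead of the ship)."""
    ahead = state.asteroid_steps - state.step_index
    return (state.asteroid_status == PENDING) & (ahead >= 1) & (ahead <= config.window_height)


@lru_cache(maxsize=8)
def _blur_kernel(sigma: float) -> np.ndarray:
    """1-D discrete Gaussian kernel matching scipy's gaussian_filter1d with
    truncate=4 (normalised to sum 1)."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_reward(state: WorldState, config: EnvConfig) -> float:
    """Shaped subtask reward: blurred asteroid occupancy at the ship's cell
    plus a horizontal-distance term toward the nearest incoming asteroid.

    The occupancy term equals the value, at the ship's cell, of the visible
    asteroid impulse grid convolved with a Gaussian (sigma ``blur_sigma``,
    zero-padded borders); it is evaluated in closed form through the
    separable kernel and normalised so a single asteroid on the ship's cell
    scores ``reward_scale`` (255: an 8-bit image intensity).  The distance
    term is ``reward_scale * (1 - |dx| / (corridor_width - 1))`` for the
    nearest visible asteroid.  Both terms are mixed with weight
    ``distance_weight``; an empty field scores 0.
    """
    vis = visible_mask(state, config)
    if not vis.any():
        return 0.0
    dx = state.asteroid_cols[vis] - state.ship_x
    dy = state.asteroid_steps[vis] - state.step_index  # rows ahead of the ship
    k = _blur_kernel(config.blur_sigma)
    radius = (k.size - 1) // 2
    peak = k[radius] ** 2
    inside = (np.abs(dx) <= radius) & (dy <= radius)
    blur = float(np.sum(k[radius + dx[inside]] * k[radius + dy[inside]]) / peak)
    blur = min(blur, 1.0)
    order = np.lexsort((np.abs(dx), dy))
    nearest_dx = dx[order[0]]
    dist = 1.0 - abs(int(nearest_dx)) / (config.corridor_width - 1)
    w = config.distance_weight
    return config.reward_scale * ((1.0 - w) * blur + w * dist)


def sparse_reward(collected_now: int, missed_now: int, config: EnvConfig) -> float:
    """Event reward +-m per collection/miss this step, with m = 100 / N."""
    m = 100.0 / config.asteroid_count
    return m * (collected_now - missed_now)


def success_rate(state: WorldState, config: EnvConfig) -> float:
    """Fraction of asteroids collected; defined only at episode end."""
    if state.step_index < config.episode_length:
        raise RuntimeError("success_rate is defined only at episode end")
    pending, collected, _ = state.counts()
    assert pending == 0
    return collected / config.asteroid_count


# occupancy grid markers
GRID_EMPTY = 0
GRID_ASTEROID = 1
GRID_SHIP = 2
GRID_WALL = 3


def render_occupancy_grid(state: WorldState, config: EnvConfig) -> np.ndarray:
    """Simplified image of the visibility window.

    Rows 0..window_height are rows ahead of the ship (row 0 = ship's row);
    columns include the two walls.  Markers: 0 empty, 1 asteroid, 2 ship,
    3 wall.
    """
    h, w = config.window_height + 1, config.corridor_width + 2
    grid = np.full((h, w), GRID_EMPTY, dtype=np.int8)
    grid[:, 0] = GRID_WALL
    grid[:, -1] = GRID_WALL
    vis = visible_mask(state, config)
    dy = state.asteroid_steps[vis] - state.step_index
    grid[dy, state.asteroid_cols[vis] + 1] = GRID_ASTEROID
    grid[0, state.ship_x + 1] = GRID_SHIP
    return grid


def obs_vector(state: WorldState, config: EnvConfig) -> np.ndarray:
    """Fixed-length positional observation.

    ``[ship_x (scaled to [-1, 1]),
       (dx / (W-1), rows_ahead / window_height) for the obs_slots nearest
       visible asteroids]``, nearest first; empty slots carry the sentinel
    (0, 2) — a "row" beyond the window.
    """
    w = config.corridor_width
    out = np.zeros(1 + 2 * config.obs_slots, dtype=np.float32)
    out[0] = 2.0 * state.ship_x / (w - 1) - 1.0
    out[2::2] = 2.0  # sentinel rows
    vis = visible_mask(state, config)
    if vis.any():
        dx = state.asteroid_cols[vis] - state.ship_x
        dy = state.asteroid_steps[vis] - state.step_index
        order = np.lexsort((np.abs(dx), dy))[: config.obs_slots]
        for i, j in enumerate(order):
            out[1 + 2 * i] = dx[j] / (w - 1)
            out[2 + 2 * i] = dy[j] / config.window_height
    return out


class CollectAsteroidsEnv:
    """Gymnasium-style single-subtask environment.

    ``reset(seed)`` returns ``(obs, info)``; ``step(action)`` returns
    ``(obs, reward, terminated, truncated, info)``.  Observations are the
    positional vectors of :func:`obs_vector`.
    """

    n_actions = 3

    def __init__(self, config: EnvConfig):
        self.config = config
        self.state: Optional[WorldState] = None
        self.rng: Optional[np.random.Generator] = None
        self.obs_dim = 1 + 2 * config.obs_slots

    def reset(self, seed: Optional[int] = None) -> tuple[np.ndarray, dict]:
        if seed is not None:
            self.rng = np.random.default_rng(seed)
        elif self.rng is None:
            self.rng = np.random.default_rng(self.config.seed)
        self.state = generate_world(self.config, self.rng)
        return obs_vector(self.state, self.config), {"state": self.state}

    def step(self, action: int) -> tuple[np.ndarray, float, bool, bool, dict]:
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        out = step(self.state, action, self.config, self.rng)
        self.state = out.next_state
        info = {
            "collected_now": out.collected_now,
            "missed_now": out.missed_now,
            "state": self.state,
        }
        return obs_vector(self.state, self.config), out.reward, out.done, False, info

    @property
    def done(self) -> bool:
        return self.state is not None and self.state.step_index >= self.config.episode_length
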