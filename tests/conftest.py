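import numpy as np
import pytest

from socrl.environment import EnvConfig, WorldState


@pytest.fixture
def easy_cfg() -> EnvConfig:
    return EnvConfig(difficulty="easy")


@pytest.fixture
def hard_cfg() -> EnvConfig:
    return EnvConfig(difficulty="hard")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_world(cfg: EnvConfig, cols, steps, ship_x=None, step_index=0) -> WorldState:
    """Hand-built world with asteroids at given (column, reach-step) pairs."""
    cols = np.asarray(cols, dtype=np.int64)
    steps = np.asarray(steps, dtype=np.int64)
    return WorldState(
        ship_x=cfg.corridor_width // 2 if ship_x is None else ship_x,
        ship_row=cfg.episode_length - step_index,
        step_index=step_index,
        asteroid_cols=cols,
        asteroid_steps=steps,
        asteroid_status=np.zeros(len(cols), dtype=np.int8),
    )


@pytest.fixture
def empty_world(easy_cfg) -> WorldState:
    """A world with zero asteroids (degenerate but valid for dynamics)."""
    return make_world(easy_cfg, [], [])
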