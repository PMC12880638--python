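"""Unit and property tests for the Collect Asteroids simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.ndimage import gaussian_filter

from socrl.environment import (
    COLLECTED,
    MISSED,
    PENDING,
    CollectAsteroidsEnv,
    EnvConfig,
    apply_input_noise,
    dense_reward,
    generate_world,
    render_occupancy_grid,
    sparse_reward,
    step,
    success_rate,
    visible_mask,
)
from tests.conftest import make_world


class TestConfig:
    def test_difficulty_sets_asteroid_count(self):
        assert EnvConfig(difficulty="easy").asteroid_count == 14
        assert EnvConfig(difficulty="hard").asteroid_count == 30

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"difficulty": "medium"},
            {"reward_mode": "shaped"},
            {"noise_variance": 0.0},
            {"episode_length": 0},
            {"asteroid_free_spans": ((0, 40), (400, 500))},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnvConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "difficulty: hard\ninput_noise: true\nepisode_length: 470\n"
            "corridor_width: 9\nseed: 7\nreward_mode: sparse\n"
            "asteroid_free_spans: [[0, 40], [215, 255]]\n"
        )
        cfg = EnvConfig.from_yaml(str(p))
        assert cfg.asteroid_count == 30
        assert cfg.input_noise and cfg.reward_mode == "sparse" and cfg.seed == 7

    def test_unknown_yaml_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("difficulty: easy\nasteroids: 99\n")
        with pytest.raises(ValueError, match="unknown"):
            EnvConfig.from_yaml(str(p))


class TestWorldGeneration:
    @pytest.mark.parametrize("difficulty,count", [("easy", 14), ("hard", 30)])
    def test_counts_and_placement(self, difficulty, count, rng):
        cfg = EnvConfig(difficulty=difficulty)
        w = generate_world(cfg, rng)
        assert w.asteroid_cols.size == count
        assert (w.asteroid_status == PENDING).all()
        assert w.ship_x == cfg.corridor_width // 2
        assert w.step_index == 0
        assert ((w.asteroid_cols >= 0) & (w.asteroid_cols < cfg.corridor_width)).all()
        for lo, hi in cfg.asteroid_free_spans:
            assert not ((w.asteroid_steps >= lo) & (w.asteroid_steps < hi)).any()
        # at most one asteroid per row by default
        assert np.unique(w.asteroid_steps).size == count

    def test_same_seed_same_layout(self, easy_cfg):
        w1 = generate_world(easy_cfg, np.random.default_rng(9))
        w2 = generate_world(easy_cfg, np.random.default_rng(9))
        assert (w1.asteroid_cols == w2.asteroid_cols).all()
        assert (w1.asteroid_steps == w2.asteroid_steps).all()

    def test_overfull_corridor_rejected(self):
        cfg = EnvConfig(episode_length=10, asteroid_free_spans=((0, 5), (5, 10)))
        with pytest.raises(ValueError, match="cannot host"):
            generate_world(cfg, np.random.default_rng(0))


class _ZeroNoise:
    def normal(self, mean, sd):
        return 0.0


class TestInputNoise:
    def test_zero_offset_identity(self, easy_cfg):
        cfg = EnvConfig(input_noise=True)
        assert apply_input_noise(1, cfg, _ZeroNoise()) == 1
        assert apply_input_noise(-1, cfg, _ZeroNoise()) == -1

    def test_noise_disabled_moves_exactly(self, easy_cfg, empty_world):
        out = step(empty_world, 2, easy_cfg, None)
        assert out.next_state.ship_x == empty_world.ship_x + 1

    def test_rejects_non_unit_moves(self):
        with pytest.raises(ValueError):
            apply_input_noise(0, EnvConfig(input_noise=True), np.random.default_rng(0))

    def test_moments_match_rounded_gaussian(self):
        """Offsets follow round(N(0, 1.5)): compare against a brute-force
        oracle sampler on both moments and the full integer distribution."""
        cfg = EnvConfig(input_noise=True)
        n = 100_000
        rng = np.random.default_rng(77)
        draws = np.array([apply_input_noise(1, cfg, rng) - 1 for _ in range(n)])
        oracle = np.rint(np.random.default_rng(78).normal(0.0, np.sqrt(1.5), n)).astype(int)
        assert abs(draws.mean() - oracle.mean()) < 0.02
        assert abs(draws.var() - oracle.var()) < 0.05
        lo, hi = min(draws.min(), oracle.min()), max(draws.max(), oracle.max())
        bins = np.arange(lo, hi + 2) - 0.5
        obs = np.histogram(draws, bins)[0]
        exp = np.histogram(oracle, bins)[0]
        keep = (obs + exp) > 10
        chi2 = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert chi2.pvalue > 1e-4


class TestStep:
    @pytest.mark.parametrize("action,dx", [(0, -1), (1, 0), (2, 1)])
    def test_steering(self, easy_cfg, empty_world, action, dx):
        out = step(empty_world, action, easy_cfg)
        assert out.next_state.ship_x == empty_world.ship_x + dx
        assert out.next_state.ship_row == empty_world.ship_row - 1
        assert out.next_state.step_index == 1

    def test_wall_clipping(self, easy_cfg):
        w = make_world(easy_cfg, [], [], ship_x=0)
        assert step(w, 0, easy_cfg).next_state.ship_x == 0
        w = make_world(easy_cfg, [], [], ship_x=easy_cfg.corridor_width - 1)
        assert step(w, 2, easy_cfg).next_state.ship_x == easy_cfg.corridor_width - 1

    def test_collection_and_miss(self, easy_cfg):
        w = make_world(easy_cfg, cols=[4, 0], steps=[1, 2], ship_x=4)
        out = step(w, 1, easy_cfg)
        assert out.collected_now == 1 and out.missed_now == 0
        assert out.next_state.asteroid_status[0] == COLLECTED
        out2 = step(out.next_state, 1, easy_cfg)
        assert out2.collected_now == 0 and out2.missed_now == 1
        assert out2.next_state.asteroid_status[1] == MISSED

    def test_step_after_done_raises(self, easy_cfg):
        cfg = EnvConfig(episode_length=5, asteroid_free_spans=((0, 0), (0, 0)))
        w = make_world(cfg, [0], [3])
        for _ in range(5):
            w = step(w, 1, cfg).next_state
        with pytest.raises(RuntimeError):
            step(w, 1, cfg)

    def test_episode_runs_exactly_470_steps(self, easy_cfg, rng):
        w = generate_world(easy_cfg, rng)
        done = False
        n = 0
        while not done:
            out = step(w, 1, easy_cfg, rng)
            w, done = out.next_state, out.done
            n += 1
        assert n == 470

    @given(seed=st.integers(0, 10_000), data=st.data())
    @settings(max_examples=20, deadline=None)
    def test_asteroid_conservation(self, seed, data):
        """collected + missed + pending == N at every step; all resolved at
        the end; two noise-free runs of the same actions are identical."""
        cfg = EnvConfig(difficulty="easy", episode_length=100, asteroid_free_spans=((0, 10), (45, 55)))
        rng = np.random.default_rng(seed)
        w = generate_world(cfg, rng)
        actions = data.draw(st.lists(st.integers(0, 2), min_size=100, max_size=100))
        ws = [w]
        for a in actions:
            out = step(ws[-1], a, cfg, rng)
            p, c, m = out.next_state.counts()
            assert p + c + m == cfg.asteroid_count
            ws.append(out.next_state)
        assert ws[-1].counts()[0] == 0
        # determinism: replay with a fresh identically-seeded world
        w2 = generate_world(cfg, np.random.default_rng(seed))
        for a in actions:
            w2 = step(w2, a, cfg, None if not cfg.input_noise else rng).next_state
        assert w2.ship_x == ws[-1].ship_x
        assert (w2.asteroid_status == ws[-1].asteroid_status).all()


class TestRewards:
    def test_sparse_values(self, easy_cfg, hard_cfg):
        assert sparse_reward(1, 0, easy_cfg) == pytest.approx(100 / 14)
        assert sparse_reward(0, 1, hard_cfg) == pytest.approx(-100 / 30)
        assert sparse_reward(0, 0, easy_cfg) == 0.0

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=15, deadline=None)
    def test_sparse_episode_total_bounded(self, seed):
        cfg = EnvConfig(difficulty="easy", reward_mode="sparse", episode_length=100,
                        asteroid_free_spans=((0, 5), (45, 50)))
        rng = np.random.default_rng(seed)
        w = generate_world(cfg, rng)
        total = 0.0
        for _ in range(100):
            out = step(w, int(rng.integers(0, 3)), cfg, rng)
            total += out.reward
            w = out.next_state
        assert -100.0 - 1e-9 <= total <= 100.0 + 1e-9

    def test_dense_empty_field_is_zero(self, easy_cfg, empty_world):
        assert dense_reward(empty_world, easy_cfg) == 0.0

    def test_dense_alignment_monotone(self, easy_cfg):
        """With one incoming asteroid, reward is maximal for the aligned
        ship column and non-increasing in |dx| (checked over all columns)."""
        vals = []
        for x in range(easy_cfg.corridor_width):
            w = make_world(easy_cfg, cols=[4], steps=[3], ship_x=x)
            vals.append(dense_reward(w, easy_cfg))
        assert np.argmax(vals) == 4
        left, right = vals[: 4 + 1], vals[4:]
        assert all(np.diff(left) >= 0) and all(np.diff(right) <= 0)

    def test_dense_on_cell_beats_adjacent(self, easy_cfg):
        on = dense_reward(make_world(easy_cfg, [4], [1], ship_x=4), easy_cfg)
        off = dense_reward(make_world(easy_cfg, [5], [1], ship_x=4), easy_cfg)
        assert on > off

    def test_blur_term_matches_scipy_filter(self):
        """Dual route: the closed-form blur value equals applying scipy's
        gaussian_filter to the asteroid occupancy image of the window."""
        cfg = EnvConfig(distance_weight=0.0)  # isolate the blur term
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            cols = rng.integers(0, cfg.corridor_width, n)
            steps_ahead = rng.integers(1, cfg.window_height + 1, n)
            w = make_world(cfg, cols, steps_ahead, ship_x=int(rng.integers(0, cfg.corridor_width)))
            img = np.zeros((cfg.window_height + 1, cfg.corridor_width))
            for c, s in zip(cols, steps_ahead):
                img[s, c] += 1.0
            blurred = gaussian_filter(img, cfg.blur_sigma, mode="constant")
            impulse = np.zeros((17, 17))
            impulse[8, 8] = 1.0
            peak = gaussian_filter(impulse, cfg.blur_sigma, mode="constant").max()
            expected = cfg.reward_scale * min(blurred[0, w.ship_x] / peak, 1.0)
            assert dense_reward(w, cfg) == pytest.approx(expected, rel=1e-9)


class TestSuccessRate:
    def test_values_and_guard(self, hard_cfg):
        cfg = EnvConfig(difficulty="hard", episode_length=60, asteroid_free_spans=((0, 2), (28, 32)))
        w = make_world(cfg, cols=np.full(30, 4), steps=np.arange(2, 62, 2), step_index=0)
        with pytest.raises(RuntimeError):
            success_rate(w, cfg)
        # center-hold collects the 21 asteroids in column 4... place 21 on 4, rest off
        w.asteroid_cols[21:] = 0
        for _ in range(60):
            w = step(w, 1, cfg).next_state
        assert success_rate(w, cfg) == pytest.approx(21 / 30)  # == 0.7


class TestOccupancyGrid:
    def test_dimensions_and_markers(self, easy_cfg):
        w = make_world(easy_cfg, [2, 7], [3, 5], ship_x=4)
        g = render_occupancy_grid(w, easy_cfg)
        assert g.shape == (easy_cfg.window_height + 1, easy_cfg.corridor_width + 2)
        assert (g[:, 0] == 3).all() and (g[:, -1] == 3).all()
        assert g[0, 4 + 1] == 2
        assert g[3, 2 + 1] == 1 and g[5, 7 + 1] == 1

    def test_visible_asteroids_conserved(self, easy_cfg, rng):
        w = generate_world(easy_cfg, rng)
        g = render_occupancy_grid(w, easy_cfg)
        assert (g == 1).sum() == visible_mask(w, easy_cfg).sum()

    def test_empty_field_grid(self, easy_cfg, empty_world):
        g = render_occupancy_grid(empty_world, easy_cfg)
        assert (g == 1).sum() == 0 and (g == 2).sum() == 1


class TestGymInterface:
    def test_reset_step_contract(self, easy_cfg):
        env = CollectAsteroidsEnv(easy_cfg)
        obs, info = env.reset(seed=3)
        assert obs.shape == (1 + 2 * easy_cfg.obs_slots,)
        obs, r, term, trunc, info = env.step(1)
        assert isinstance(r, float) and not term and not trunc
        assert "collected_now" in info

    def test_seeded_reset_reproducible(self, easy_cfg):
        env = CollectAsteroidsEnv(easy_cfg)
        o1, _ = env.reset(seed=3)
        o2, _ = env.reset(seed=3)
        assert (o1 == o2).all()
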