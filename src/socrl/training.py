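"""PPO training harnesses for sub-agents and meta-agents.

Two budget presets: ``paper`` carries full-scale budgets sized for GPU
clusters (sub-agents 10M env steps; meta-agent 1.3M decisions with the
active reward, 10k with the SoC reward — the SoC reward converges that
quickly), while ``desk`` uses budgets sized for a single CPU with the
numpy PPO backend: 200k env steps for sub-agents and 6k meta decisions for
meta-agents, matched across meta configurations so comparisons are
budget-fair.  Absolute success rates at desk scale undershoot full-scale
training; orderings are the meaningful desk-scale quantity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from socrl.environment import CollectAsteroidsEnv, EnvConfig, WorldState, obs_vector
from socrl.hierarchy import MetaConfig, MetaObservation, MetaTaskEnv
from socrl.policies import greedy_policy
from socrl.ppo import PPO, ActorCriticNet, PPOConfig, TrainingCurve
from socrl.soc import SoCConfig

PRESETS = {
    "paper": {"sub": 10_000_000, "meta_active": 1_300_000, "meta_soc": 10_000},
    "desk": {"sub": 200_000, "meta_active": 6_000, "meta_soc": 6_000},
}

DEFAULT_SEARCH_SPACE = {
    "learning_rate": (1e-4, 1e-2),   # log-uniform
    "gamma_rl": (0.9, 0.999),
    "gae_lambda": (0.8, 1.0),
    "ent_coef": (0.0, 0.02),
}


@dataclass
class TrainConfig:
    """Training hyperparameters and budget for one agent.

    The four tuned dimensions (learning rate, discount, GAE lambda, entropy
    coefficient) are exposed directly and as ``search_space`` ranges for
    :func:`hyperparameter_search`.
    """

    target: str = "sub_agent"  # or "meta_agent"
    total_steps: Optional[int] = None  # None -> preset default for target
    learning_rate: float = 3e-3
    gamma_rl: float = 0.9
    gae_lambda: float = 0.95
    ent_coef: float = 0.005
    seed: int = 0
    preset: str = "desk"
    n_steps: int = 1024
    hidden: int = 64
    n_trials: int = 1
    search_space: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))

    def __post_init__(self) -> None:
        if self.target not in ("sub_agent", "meta_agent"):
            raise ValueError("target must be 'sub_agent' or 'meta_agent'")
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {sorted(PRESETS)}")

    def budget(self, meta_reward_mode: str = "active") -> int:
        if self.total_steps is not None:
            return self.total_steps
        key = "sub" if self.target == "sub_agent" else f"meta_{meta_reward_mode}"
        return PRESETS[self.preset][key]

    def ppo_config(self) -> PPOConfig:
        return PPOConfig(
            learning_rate=self.learning_rate,
            gamma=self.gamma_rl,
            gae_lambda=self.gae_lambda,
            ent_coef=self.ent_coef,
            n_steps=self.n_steps,
            hidden=self.hidden,
        )


class SubAgentPolicy:
    """Frozen trained sub-agent: deterministic argmax policy over the
    positional observation vector.  Callable as ``policy(state, config)``."""

    def __init__(self, net: ActorCriticNet):
        self.net = net

    def __call__(self, state: WorldState, config: EnvConfig) -> int:
        logits, _, _ = self.net.forward(obs_vector(state, config))
        return int(np.argmax(logits[0]))

    def save(self, path: str) -> None:
        np.savez(path, **self.net.params)

    @classmethod
    def load(cls, path: str, obs_dim: int, hidden: int = 64) -> "SubAgentPolicy":
        net = ActorCriticNet(obs_dim, 3, hidden)
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as d:
            net.load_state_dict({k: d[k] for k in d.files})
        return cls(net)


class MetaAgentPolicy:
    """Frozen trained meta-agent: deterministic argmax over the meta
    observation.  Callable as ``policy(decision_index, observation)``."""

    def __init__(self, net: ActorCriticNet):
        self.net = net

    def __call__(self, decision_index: int, observation: MetaObservation) -> int:
        logits, _, _ = self.net.forward(observation.vector)
        return int(np.argmax(logits[0]))


def train_sub_agent(
    env_config: EnvConfig, train_config: TrainConfig
) -> tuple[SubAgentPolicy, TrainingCurve, PPO]:
    """Train a sub-agent with PPO on one Collect Asteroids task.  Returns
    the frozen policy, the training curve, and the trainer (for
    checkpointing)."""
    env = CollectAsteroidsEnv(env_config)
    ppo = PPO(env, train_config.ppo_config(), seed=train_config.seed)
    budget = train_config.budget()
    curve = ppo.learn(budget) if budget > 0 else TrainingCurve()
    if curve.mean_return and curve.mean_return[-1] < 0.1 * max(curve.mean_return):
        import warnings

        warnings.warn("sub-agent training reward collapsed; checkpoint kept", RuntimeWarning)
    return SubAgentPolicy(ppo.net), curve, ppo


def train_meta_agent(
    meta_cfg: MetaConfig,
    sub_policies: Sequence,
    env_configs: Sequence[EnvConfig],
    train_config: TrainConfig,
    soc_cfg: SoCConfig = SoCConfig(),
    optimal_policy=greedy_policy,
) -> tuple[MetaAgentPolicy, TrainingCurve, PPO]:
    """Train a meta-agent with PPO at decision granularity over frozen
    sub-policies.  The budget counts meta decisions."""
    if len(sub_policies) != 2:
        raise ValueError("two frozen sub-policies are required")
    env = MetaTaskEnv(env_configs, meta_cfg, soc_cfg, sub_policies, seed=train_config.seed, optimal_policy=optimal_policy)
    cfg = train_config.ppo_config()
    cfg = dataclasses.replace(cfg, n_steps=min(cfg.n_steps, 512))
    ppo = PPO(env, cfg, seed=train_config.seed)
    budget = train_config.budget(meta_cfg.reward_mode)
    curve = ppo.learn(budget) if budget > 0 else TrainingCurve()
    return MetaAgentPolicy(ppo.net), curve, ppo


def hyperparameter_search(
    train_fn: Callable[[dict, int], tuple[object, TrainingCurve]],
    search_space: dict = DEFAULT_SEARCH_SPACE,
    n_trials: int = 1,
    seed: int = 0,
) -> dict:
    """Fixed-seed random search over the four tuned PPO dimensions.

    ``train_fn(params, trial_seed)`` must return ``(artifact, curve)``; the
    trial with the highest mean training reward is selected (ties go to the
    earlier trial).  Returns a dict with ``best_params``, ``best_artifact``,
    ``best_curve`` and the full ``trials`` log.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        params = {}
        for name, (lo, hi) in search_space.items():
            if name == "learning_rate":
                params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                params[name] = float(rng.uniform(lo, hi))
        artifact, curve = train_fn(params, int(rng.integers(0, 2**31 - 1)))
        trials.append({"params": params, "artifact": artifact, "curve": curve, "mean_reward": curve.overall_mean})
    best = int(np.argmax([tr["mean_reward"] for tr in trials]))
    return {
        "best_params": trials[best]["params"],
        "best_artifact": trials[best]["artifact"],
        "best_curve": trials[best]["curve"],
        "best_index": best,
        "trials": trials,
    }
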