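"""The multitask orchestrator.

Two Collect Asteroids environments run in parallel; a meta-policy picks the
attended task on a fixed grid of ``decision_interval`` (default 5) frames.
The chosen sub-policy emits 5 actions into its environment while the other
environment receives 5 default (no-steer) actions.  The attended task's SoC
is refreshed from fresh prediction-error and need-for-control measurements
at each decision; the unattended task's SoC estimate decays by ``phi``
(once per meta decision by default, or once per frame — see
``SoCConfig.decay_per``), and its positional belief is propagated through
the noise-unaware forward model under the default action.

Conventions: before the first decision, task 0 is the attended task.  The
switch-every-frame baseline therefore alternates starting with task 1, so
all 94 decisions of a 470-step episode are switches — matching its defining
property — while a never-switching policy holding task 0 logs 0 switches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from socrl.environment import CollectAsteroidsEnv, EnvConfig, WorldState, obs_vector, success_rate, visible_mask
from socrl.forward_model import predict_next
from socrl.policies import default_policy, greedy_policy
from socrl.soc import (
    SoCComponents,
    SoCConfig,
    compose_soc,
    decay_inactive,
    meta_soc_reward,
    need_for_control,
    prediction_error,
)

Policy = Callable[[WorldState, EnvConfig], int]
MetaPolicy = Callable[[int, "MetaObservation"], int]

_LABELS = {
    ("world_state", "active"): "no_soc",
    ("soc", "active"): "soc_as_observation",
    ("world_state", "soc"): "soc_as_reward",
    ("soc", "soc"): "soc",
}


@dataclass(frozen=True)
class MetaConfig:
    """Meta-agent configuration: what it observes and what rewards it.

    ``observation_mode``: ``"world_state"`` (positions: true for the active
    task, believed for the inactive) or ``"soc"`` (fresh SoC of the active
    task, decayed estimate for the inactive).  ``reward_mode``: ``"active"``
    (the attended sub-task's summed reward) or ``"soc"`` (+-1/0 for
    attending the lower-SoC task).  The four combinations map onto the agent
    labels no_soc / soc_as_observation / soc_as_reward / soc.
    """

    observation_mode: str = "soc"
    reward_mode: str = "soc"
    decision_interval: int = 5

    def __post_init__(self) -> None:
        if self.observation_mode not in ("world_state", "soc"):
            raise ValueError("observation_mode must be 'world_state' or 'soc'")
        if self.reward_mode not in ("active", "soc"):
            raise ValueError("reward_mode must be 'active' or 'soc'")
        if self.decision_interval <= 0:
            raise ValueError("decision_interval must be positive")

    @property
    def agent_label(self) -> str:
        return _LABELS[(self.observation_mode, self.reward_mode)]

    @classmethod
    def from_label(cls, label: str, decision_interval: int = 5) -> "MetaConfig":
        for (obs, rew), lab in _LABELS.items():
            if lab == label:
                return cls(observation_mode=obs, reward_mode=rew, decision_interval=decision_interval)
        raise ValueError(f"unknown agent label {label!r}")


@dataclass
class MetaObservation:
    """What the meta-agent sees at a decision point: the attended task's
    ground truth (positions or fresh SoC) concatenated with the unattended
    task's belief (propagated positions or decayed SoC), plus an explicit
    attended-task indicator."""

    active_task: int
    mode: str
    vector: np.ndarray
    soc_pair: tuple[float, float]


def build_meta_observation(
    active_task: int,
    task_states: Sequence[WorldState],
    beliefs: Sequence[WorldState],
    soc_pair: Sequence[float],
    meta_cfg: MetaConfig,
    env_configs: Sequence[EnvConfig],
) -> MetaObservation:
    """Assemble the POMDP observation.  Task slots keep a fixed order; the
    attended slot carries truth, the other carries the belief/estimate."""
    if meta_cfg.observation_mode == "soc":
        vec = np.array([float(active_task), soc_pair[0], soc_pair[1]], dtype=np.float32)
    else:
        parts = [np.array([float(active_task)], dtype=np.float32)]
        for task in (0, 1):
            src = task_states[task] if task == active_task else beliefs[task]
            parts.append(obs_vector(src, env_configs[task]))
        vec = np.concatenate(parts)
    return MetaObservation(active_task, meta_cfg.observation_mode, vec, (float(soc_pair[0]), float(soc_pair[1])))


def active_reward(sub_rewards_over_k: Sequence[float]) -> float:
    """Meta reward in 'active' mode: sum of the attended sub-task's rewards
    over the decision interval."""
    return float(np.sum(sub_rewards_over_k))


def belief_propagation(last_observed_state: WorldState, elapsed_steps: int, config: EnvConfig) -> WorldState:
    """Propagate a positional belief about an unattended task by iterating
    the forward model with the default action."""
    if elapsed_steps < 0:
        raise ValueError("elapsed_steps must be >= 0")
    state = last_observed_state
    for _ in range(elapsed_steps):
        if state.step_index >= config.episode_length:
            break
        state = predict_next(state, default_policy(state, config), config).predicted_state
    return state


def switch_every_frame_policy(decision_index: int, observation: Optional[MetaObservation] = None) -> int:
    """Baseline toggling the attended task at every decision point (task 1
    first, so each of the 94 decisions is a switch)."""
    return 1 - decision_index % 2


def never_switch_policy(task: int) -> MetaPolicy:
    """Meta-policy that always attends ``task``."""

    def policy(decision_index: int, observation: Optional[MetaObservation] = None) -> int:
        return task

    return policy


def random_switch_policy(rng: np.random.Generator) -> MetaPolicy:
    def policy(decision_index: int, observation: Optional[MetaObservation] = None) -> int:
        return int(rng.integers(0, 2))

    return policy


@dataclass
class EpisodeTrace:
    """Per-frame and per-decision log of one multitask episode.

    ``steps`` has one row per environment frame (0..469); ``decisions`` one
    row per meta decision (0..93).  ``metadata`` records seeds, configs and
    final per-task success rates.
    """

    steps: pd.DataFrame
    decisions: pd.DataFrame
    metadata: dict

    @property
    def success_rates(self) -> tuple[float, float]:
        return tuple(self.metadata["success_rates"])

    def to_csv(self, prefix: str) -> None:
        """Write ``<prefix>_steps.csv``, ``<prefix>_decisions.csv`` and a
        ``<prefix>_meta.json`` sidecar."""
        self.steps.to_csv(f"{prefix}_steps.csv", index=False)
        self.decisions.to_csv(f"{prefix}_decisions.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


class MultitaskSession:
    """Stepwise driver of one multitask episode at decision granularity.

    ``reset(seeds)`` returns the first :class:`MetaObservation`;
    ``decide(task)`` runs one decision interval and returns
    ``(observation, meta_reward, done, info)``.  Used both by
    :func:`run_multitask_episode` (with a meta-policy callable) and by the
    PPO meta-training adapter.
    """

    def __init__(
        self,
        env_configs: Sequence[EnvConfig],
        meta_cfg: MetaConfig,
        soc_cfg: SoCConfig,
        sub_policies: Sequence[Policy],
        optimal_policy: Policy = greedy_policy,
        log: bool = True,
    ):
        if env_configs[0].episode_length != env_configs[1].episode_length:
            raise ValueError("both tasks must share the episode length")
        if env_configs[0].episode_length % meta_cfg.decision_interval != 0:
            raise ValueError("episode_length must be a multiple of the decision interval")
        self.env_configs = tuple(env_configs)
        self.meta_cfg = meta_cfg
        self.soc_cfg = soc_cfg
        self.sub_policies = tuple(sub_policies)
        self.optimal_policy = optimal_policy
        self.log = log
        self.envs = (CollectAsteroidsEnv(env_configs[0]), CollectAsteroidsEnv(env_configs[1]))
        self.n_decisions = env_configs[0].episode_length // meta_cfg.decision_interval

    # -- episode lifecycle -------------------------------------------------
    def reset(self, seeds: Sequence[Optional[int]] = (None, None)) -> MetaObservation:
        for env, seed in zip(self.envs, seeds):
            env.reset(seed)
        self.seeds = tuple(seeds)
        ini = self.soc_cfg.initial_soc
        self.soc = [ini, ini]
        self.pe = [0.0, 0.0]
        self.nfc = [0.0, 0.0]
        self.is_estimate = [False, False]
        self.beliefs = [self.envs[0].state.copy(), self.envs[1].state.copy()]
        self.last_reward = [0.0, 0.0]
        self.prev_active = 0  # task 0 attended before the first decision
        self.decision_index = 0
        self.collected = [0, 0]
        self.missed = [0, 0]
        self._step_rows: list[dict] = []
        self._decision_rows: list[dict] = []
        return self._observation()

    def _observation(self) -> MetaObservation:
        states = (self.envs[0].state, self.envs[1].state)
        return build_meta_observation(
            self.prev_active, states, self.beliefs, self.soc, self.meta_cfg, self.env_configs
        )

    def decide(self, task: int) -> tuple[MetaObservation, float, bool, dict]:
        """Attend ``task`` for one decision interval."""
        if self.decision_index >= self.n_decisions:
            raise RuntimeError("episode already finished")
        if task not in (0, 1):
            raise ValueError("task must be 0 or 1")
        k = self.meta_cfg.decision_interval
        switch = task != self.prev_active
        # the situation in which the decision is taken: visible asteroids of
        # the task attended up to this frame
        n_visible = int(visible_mask(self.envs[self.prev_active].state, self.env_configs[self.prev_active]).sum())
        soc_at_choice = (self.soc[0], self.soc[1])
        if self.meta_cfg.reward_mode == "soc":
            meta_reward = float(meta_soc_reward(soc_at_choice[0], soc_at_choice[1], task))

        inactive = 1 - task
        # attending a task reveals its true state; drop the stale belief
        self.beliefs[task] = self.envs[task].state.copy()
        self.is_estimate[task] = False

        active_rewards = []
        pe_frame = 0.0
        for _ in range(k):
            act_env, inact_env = self.envs[task], self.envs[inactive]
            cfg_a, cfg_i = self.env_configs[task], self.env_configs[inactive]
            action = int(self.sub_policies[task](act_env.state, cfg_a))
            predicted = predict_next(act_env.state, action, cfg_a)
            x_before = act_env.state.ship_x
            _, r_a, _, _, info_a = act_env.step(action)
            pe_frame = prediction_error(act_env.state.ship_x, predicted.predicted_state.ship_x, self.soc_cfg)
            self.collected[task] += info_a["collected_now"]
            self.missed[task] += info_a["missed_now"]
            self.last_reward[task] = r_a
            active_rewards.append(r_a)

            x_before_i = inact_env.state.ship_x
            d_action = default_policy(inact_env.state, cfg_i)
            _, r_i, _, _, info_i = inact_env.step(d_action)
            self.collected[inactive] += info_i["collected_now"]
            self.missed[inactive] += info_i["missed_now"]
            self.beliefs[inactive] = belief_propagation(self.beliefs[inactive], 1, cfg_i)
            if self.soc_cfg.decay_per == "frame":
                self.soc[inactive] = decay_inactive(self.soc[inactive], self.soc_cfg)
            self.is_estimate[inactive] = True

            if self.log:
                step = self.envs[task].state.step_index - 1
                rewards = [0.0, 0.0]
                rewards[task], rewards[inactive] = r_a, r_i
                ship_x = [0, 0]
                ship_x[task] = act_env.state.ship_x
                ship_x[inactive] = inact_env.state.ship_x
                self._step_rows.append(
                    {
                        "step": step,
                        "active_task": task,
                        "action": action,
                        "realized_dx": act_env.state.ship_x - x_before,
                        "default_dx": inact_env.state.ship_x - x_before_i,
                        "ship_x_task0": ship_x[0],
                        "ship_x_task1": ship_x[1],
                        "reward_task0": rewards[0],
                        "reward_task1": rewards[1],
                        "pe_task0": self.pe[0],
                        "pe_task1": self.pe[1],
                        "nfc_task0": self.nfc[0],
                        "nfc_task1": self.nfc[1],
                        "soc_task0": self.soc[0],
                        "soc_task1": self.soc[1],
                        "is_estimate_task0": self.is_estimate[0],
                        "is_estimate_task1": self.is_estimate[1],
                        "collected_task0": self.collected[0],
                        "collected_task1": self.collected[1],
                        "missed_task0": self.missed[0],
                        "missed_task1": self.missed[1],
                    }
                )

        if self.soc_cfg.decay_per == "decision":
            self.soc[inactive] = decay_inactive(self.soc[inactive], self.soc_cfg)

        # fresh SoC for the attended task from the latest PE and an NfC
        # rollout at the current state
        self.pe[task] = pe_frame
        self.nfc[task] = need_for_control(
            self.envs[task].state,
            self.optimal_policy,
            default_policy,
            self.soc_cfg,
            self.env_configs[task],
            self.last_reward[task],
        )
        self.soc[task] = compose_soc(self.pe[task], self.nfc[task])
        self.is_estimate[task] = False

        if self.meta_cfg.reward_mode == "active":
            meta_reward = active_reward(active_rewards)

        if self.log:
            self._decision_rows.append(
                {
                    "decision": self.decision_index,
                    "step": self.envs[task].state.step_index - k,
                    "chosen_task": task,
                    "previous_task": self.prev_active,
                    "switch": switch,
                    "soc_task0_at_choice": soc_at_choice[0],
                    "soc_task1_at_choice": soc_at_choice[1],
                    "n_visible_active": n_visible,
                    "meta_reward": meta_reward,
                }
            )
        self.prev_active = task
        self.decision_index += 1
        done = self.decision_index >= self.n_decisions
        info = {"switch": switch, "active_rewards": active_rewards}
        return self._observation(), float(meta_reward), done, info

    # -- bookkeeping -------------------------------------------------------
    def soc_components(self, task: int) -> SoCComponents:
        """Snapshot of the current SoC record for one task."""
        step_index = self.envs[task].state.step_index
        return SoCComponents(
            task_id=task,
            timestep=step_index,
            pe=self.pe[task],
            nfc=self.nfc[task],
            soc=self.soc[task],
            is_estimate=self.is_estimate[task],
        )

    def trace(self, **metadata) -> EpisodeTrace:
        srs = [
            success_rate(self.envs[t].state, self.env_configs[t]) if self.envs[t].done else None
            for t in (0, 1)
        ]
        meta = {
            "seeds": list(self.seeds),
            "agent_label": self.meta_cfg.agent_label,
            "decision_interval": self.meta_cfg.decision_interval,
            "difficulties": [c.difficulty for c in self.env_configs],
            "input_noise": [c.input_noise for c in self.env_configs],
            "success_rates": srs,
            "collected": list(self.collected),
            "missed": list(self.missed),
        }
        meta.update(metadata)
        return EpisodeTrace(pd.DataFrame(self._step_rows), pd.DataFrame(self._decision_rows), meta)


def run_multitask_episode(
    meta_policy: MetaPolicy,
    sub_policies: Sequence[Policy],
    env_configs: Sequence[EnvConfig],
    meta_cfg: MetaConfig,
    soc_cfg: SoCConfig,
    seeds: Sequence[Optional[int]] = (None, None),
    optimal_policy: Policy = greedy_policy,
    **trace_metadata,
) -> EpisodeTrace:
    """Run one full multitask episode under ``meta_policy`` and return its
    trace.  ``meta_policy`` is called as ``meta_policy(decision_index,
    observation)`` and must return the task to attend (0 or 1)."""
    session = MultitaskSession(env_configs, meta_cfg, soc_cfg, sub_policies, optimal_policy)
    obs = session.reset(seeds)
    done = False
    while not done:
        task = int(meta_policy(session.decision_index, obs))
        obs, _, done, _ = session.decide(task)
    return session.trace(**trace_metadata)


class MetaTaskEnv:
    """Gymnasium-style adapter exposing the multitask session at decision
    granularity, for training meta-agents with PPO.  Each ``reset`` draws a
    fresh pair of world seeds from an internal seed sequence."""

    n_actions = 2

    def __init__(
        self,
        env_configs: Sequence[EnvConfig],
        meta_cfg: MetaConfig,
        soc_cfg: SoCConfig,
        sub_policies: Sequence[Policy],
        seed: int = 0,
        optimal_policy: Policy = greedy_policy,
    ):
        self.session = MultitaskSession(env_configs, meta_cfg, soc_cfg, sub_policies, optimal_policy, log=False)
        self._seed_rng = np.random.default_rng(seed)
        obs = self.session.reset(self._draw_seeds())
        self.obs_dim = obs.vector.size

    def _draw_seeds(self) -> tuple[int, int]:
        return tuple(int(s) for s in self._seed_rng.integers(0, 2**31 - 1, size=2))

    def reset(self, seed: Optional[int] = None) -> tuple[np.ndarray, dict]:
        if seed is not None:
            self._seed_rng = np.random.default_rng(seed)
        obs = self.session.reset(self._draw_seeds())
        return obs.vector, {}

    def step(self, action: int) -> tuple[np.ndarray, float, bool, bool, dict]:
        obs, reward, done, info = self.session.decide(int(action))
        return obs.vector, reward, done, False, info
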