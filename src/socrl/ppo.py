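"""A compact, dependency-free Proximal Policy Optimization (PPO) trainer.

Discrete-action PPO with a clipped surrogate objective, generalized
advantage estimation (GAE), an entropy bonus and Adam, on a small shared
tanh MLP with categorical-policy and value heads.  Everything is plain
numpy and fully deterministic under a seed, which keeps desk-scale training
reproducible on one CPU.

The environment contract is gymnasium-style: ``reset(seed) -> (obs, info)``
and ``step(a) -> (obs, reward, terminated, truncated, info)``, plus
``obs_dim`` / ``n_actions`` attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


def _logsumexp(x: np.ndarray, axis: int = -1, keepdims: bool = False) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(x - m), axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


class ActorCriticNet:
    """Shared-body MLP: obs -> tanh(hidden) -> (action logits, value)."""

    def __init__(self, obs_dim: int, n_actions: int, hidden: int = 64, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.obs_dim, self.n_actions, self.hidden = obs_dim, n_actions, hidden
        s1 = np.sqrt(2.0 / obs_dim)
        self.params = {
            "W1": rng.normal(0, s1, size=(hidden, obs_dim)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, 0.01, size=(n_actions, hidden)),
            "b2": np.zeros(n_actions),
            "W3": rng.normal(0, 1.0 / np.sqrt(hidden), size=(1, hidden)),
            "b3": np.zeros(1),
        }

    def forward(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (logits [B,A], values [B], hidden activations [B,H])."""
        obs = np.atleast_2d(obs)
        h = np.tanh(obs @ self.params["W1"].T + self.params["b1"])
        logits = h @ self.params["W2"].T + self.params["b2"]
        values = (h @ self.params["W3"].T + self.params["b3"])[:, 0]
        return logits, values, h

    def log_probs(self, logits: np.ndarray) -> np.ndarray:
        return logits - _logsumexp(logits, axis=-1, keepdims=True)

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, d: dict) -> None:
        for k in self.params:
            self.params[k] = np.asarray(d[k], dtype=float).copy()


@dataclass
class PPOConfig:
    learning_rate: float = 3e-4
    gamma: float = 0.99
    gae_lambda: float = 0.95
    ent_coef: float = 0.01
    vf_coef: float = 0.5
    clip_range: float = 0.2
    n_steps: int = 1024
    batch_size: int = 256
    n_epochs: int = 4
    hidden: int = 64
    max_grad_norm: float = 0.5
    # scale rewards by a running estimate of the discounted-return std so
    # training is insensitive to the environment's reward magnitude
    normalize_rewards: bool = True


@dataclass
class TrainingCurve:
    """Mean episodic return per rollout buffer, indexed by env steps."""

    steps: list = field(default_factory=list)
    mean_return: list = field(default_factory=list)

    def append(self, step: int, ret: float) -> None:
        self.steps.append(int(step))
        self.mean_return.append(float(ret))

    @property
    def overall_mean(self) -> float:
        return float(np.mean(self.mean_return)) if self.mean_return else float("nan")


class PPO:
    def __init__(self, env, config: PPOConfig = PPOConfig(), seed: int = 0):
        self.env = env
        self.cfg = config
        self.rng = np.random.default_rng(seed)
        self.net = ActorCriticNet(env.obs_dim, env.n_actions, config.hidden, self.rng)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.net.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.net.params.items()}
        self._adam_t = 0
        self._obs: Optional[np.ndarray] = None
        self.steps_trained = 0
        self._episode_return = 0.0
        self._seed = seed
        # running discounted-return statistics for reward normalization
        self._ret_acc = 0.0
        self._ret_count = 1e-4
        self._ret_mean = 0.0
        self._ret_m2 = 0.0

    # -- acting ------------------------------------------------------------
    def act(self, obs: np.ndarray, deterministic: bool = False) -> int:
        logits, _, _ = self.net.forward(obs)
        if deterministic:
            return int(np.argmax(logits[0]))
        p = np.exp(self.net.log_probs(logits)[0])
        return int(self.rng.choice(len(p), p=p))

    # -- learning ----------------------------------------------------------
    def learn(self, total_steps: int) -> TrainingCurve:
        curve = TrainingCurve()
        cfg = self.cfg
        if self._obs is None:
            self._obs, _ = self.env.reset(seed=int(self.rng.integers(0, 2**31 - 1)))
            self._episode_return = 0.0
        target = self.steps_trained + total_steps
        while self.steps_trained < target:
            batch = self._collect(cfg.n_steps)
            self._update(batch)
            curve.append(self.steps_trained, batch["mean_return"])
        return curve

    def _collect(self, n_steps: int) -> dict:
        cfg = self.cfg
        obs_buf = np.empty((n_steps, self.env.obs_dim))
        act_buf = np.empty(n_steps, dtype=np.int64)
        rew_buf = np.empty(n_steps)
        done_buf = np.empty(n_steps, dtype=bool)
        val_buf = np.empty(n_steps)
        logp_buf = np.empty(n_steps)
        ep_returns = []
        obs = self._obs
        for i in range(n_steps):
            logits, value, _ = self.net.forward(obs)
            logp = self.net.log_probs(logits)[0]
            a = int(self.rng.choice(self.env.n_actions, p=np.exp(logp)))
            nxt, r, terminated, truncated, _ = self.env.step(a)
            if cfg.normalize_rewards:
                self._ret_acc = cfg.gamma * self._ret_acc + r
                self._ret_count += 1
                d = self._ret_acc - self._ret_mean
                self._ret_mean += d / self._ret_count
                self._ret_m2 += d * (self._ret_acc - self._ret_mean)
                r_train = r / (np.sqrt(self._ret_m2 / self._ret_count) + 1e-8)
            else:
                r_train = r
            obs_buf[i], act_buf[i], rew_buf[i] = obs, a, r_train
            val_buf[i], logp_buf[i] = value[0], logp[a]
            done = terminated or truncated
            if done and cfg.normalize_rewards:
                self._ret_acc = 0.0
            done_buf[i] = done
            self._episode_return += r
            self.steps_trained += 1
            if done:
                ep_returns.append(self._episode_return)
                self._episode_return = 0.0
                nxt, _ = self.env.reset()
            obs = nxt
        self._obs = obs
        _, last_value, _ = self.net.forward(obs)
        adv = np.zeros(n_steps)
        gae = 0.0
        next_value = last_value[0]
        for i in reversed(range(n_steps)):
            nonterminal = 0.0 if done_buf[i] else 1.0
            delta = rew_buf[i] + cfg.gamma * next_value * nonterminal - val_buf[i]
            gae = delta + cfg.gamma * cfg.gae_lambda * nonterminal * gae
            adv[i] = gae
            next_value = val_buf[i]
        returns = adv + val_buf
        return {
            "obs": obs_buf,
            "actions": act_buf,
            "advantages": adv,
            "returns": returns,
            "logp_old": logp_buf,
            "mean_return": float(np.mean(ep_returns)) if ep_returns else float(np.sum(rew_buf)),
        }

    def _update(self, batch: dict) -> None:
        cfg = self.cfg
        n = batch["obs"].shape[0]
        adv = batch["advantages"]
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
        for _ in range(cfg.n_epochs):
            perm = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                grads = self._gradients(
                    batch["obs"][idx], batch["actions"][idx], adv[idx],
                    batch["returns"][idx], batch["logp_old"][idx],
                )
                self._adam_step(grads)

    def _gradients(self, obs, actions, adv, returns, logp_old) -> dict:
        cfg = self.cfg
        B = obs.shape[0]
        logits, values, h = self.net.forward(obs)
        logp_all = self.net.log_probs(logits)
        p = np.exp(logp_all)
        logp = logp_all[np.arange(B), actions]
        ratio = np.exp(logp - logp_old)
        clipped = np.clip(ratio, 1.0 - cfg.clip_range, 1.0 + cfg.clip_range)
        # gradient of the clipped surrogate flows only where the unclipped
        # term attains the min
        use = ratio * adv <= clipped * adv
        dlogp = np.where(use, ratio * adv, 0.0) * (-1.0 / B)
        dlogits = dlogp[:, None] * (np.eye(self.net.n_actions)[actions] - p)
        # entropy bonus: d(-ent_coef * H)/dlogits
        ent = -np.sum(p * logp_all, axis=1, keepdims=True)
        dlogits += cfg.ent_coef / B * p * (logp_all + ent)
        dvalues = cfg.vf_coef * 2.0 * (values - returns) / B

        g = {}
        g["W2"] = dlogits.T @ h
        g["b2"] = dlogits.sum(axis=0)
        g["W3"] = (dvalues[None, :] @ h)
        g["b3"] = np.array([dvalues.sum()])
        dh = dlogits @ self.net.params["W2"] + dvalues[:, None] * self.net.params["W3"]
        dpre = dh * (1.0 - h**2)
        g["W1"] = dpre.T @ obs
        g["b1"] = dpre.sum(axis=0)
        norm = np.sqrt(sum(float(np.sum(v**2)) for v in g.values()))
        if norm > cfg.max_grad_norm:
            scale = cfg.max_grad_norm / (norm + 1e-12)
            g = {k: v * scale for k, v in g.items()}
        return g

    def _adam_step(self, grads: dict, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        lr = self.cfg.learning_rate
        for k, gk in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = self._adam_m[k] / (1 - beta1**self._adam_t)
            vhat = self._adam_v[k] / (1 - beta2**self._adam_t)
            self.net.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str, **metadata) -> None:
        """npz weight archive plus a JSON metadata sidecar."""
        np.savez(path, **self.net.params)
        meta = {
            "obs_dim": self.net.obs_dim,
            "n_actions": self.net.n_actions,
            "hidden": self.net.hidden,
            "seed": self._seed,
            "steps_trained": self.steps_trained,
            "config": vars(self.cfg),
        }
        meta.update(metadata)
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)

    @classmethod
    def load_net(cls, path: str) -> ActorCriticNet:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        net = ActorCriticNet(meta["obs_dim"], meta["n_actions"], meta["hidden"])
        with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as d:
            net.load_state_dict({k: d[k] for k in d.files})
        return net
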