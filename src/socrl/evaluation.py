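"""Block enumeration, batch evaluation, behavioral metrics and statistics.

Ten experimental blocks combine the two tasks' difficulties (easy/easy,
easy/hard, hard/hard) with the placement of input noise (none, one task,
both; the easy/hard family distinguishes noise-in-easy from noise-in-hard).
Each agent is evaluated on the same seeded worlds within a block, so
cross-agent differences are not driven by world sampling.  Metrics follow
the behavioral analysis of voluntary task switching: success rates (overall
and per task), engagement ratio of task one, switch counts, the per-decision
switching ratio, and the number of visible asteroids at switch versus
non-switch decisions.  Block-level inference uses a one-way ANOVA,
Bartlett's homoscedasticity test, and Holm-adjusted pairwise two-tailed
t-tests at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from socrl.environment import EnvConfig
from socrl.hierarchy import EpisodeTrace, MetaConfig, MetaPolicy, run_multitask_episode, switch_every_frame_policy
from socrl.policies import greedy_policy
from socrl.soc import SoCConfig

ALPHA = 0.05


@dataclass(frozen=True)
class BlockConfig:
    """One multitasking configuration: per-task difficulty and input noise.

    ``block_id`` follows the canonical naming scheme, e.g.
    ``easy_hard_yes-in-easy-task``.  In same-difficulty blocks with noise in
    one task, task one carries the noise.
    """

    difficulty_one: str
    difficulty_two: str
    noise_one: bool
    noise_two: bool
    block_id: str

    @property
    def noise_assignment(self) -> str:
        if not (self.noise_one or self.noise_two):
            return "none"
        if self.noise_one and self.noise_two:
            return "both"
        if self.difficulty_one != self.difficulty_two:
            noisy = self.difficulty_one if self.noise_one else self.difficulty_two
            return f"{noisy}_task_only"
        return "task_one_only"

    def env_configs(self, **overrides) -> tuple[EnvConfig, EnvConfig]:
        return (
            EnvConfig(difficulty=self.difficulty_one, input_noise=self.noise_one, **overrides),
            EnvConfig(difficulty=self.difficulty_two, input_noise=self.noise_two, **overrides),
        )


def enumerate_blocks() -> list[BlockConfig]:
    """The canonical, deterministically ordered list of the 10 blocks."""
    blocks = [
        BlockConfig("easy", "easy", False, False, "easy_easy_no"),
        BlockConfig("easy", "easy", True, False, "easy_easy_yes-in-one-task"),
        BlockConfig("easy", "easy", True, True, "easy_easy_yes"),
        BlockConfig("easy", "hard", False, False, "easy_hard_no"),
        BlockConfig("easy", "hard", True, False, "easy_hard_yes-in-easy-task"),
        BlockConfig("easy", "hard", False, True, "easy_hard_yes-in-hard-task"),
        BlockConfig("easy", "hard", True, True, "easy_hard_yes"),
        BlockConfig("hard", "hard", False, False, "hard_hard_no"),
        BlockConfig("hard", "hard", True, False, "hard_hard_yes-in-one-task"),
        BlockConfig("hard", "hard", True, True, "hard_hard_yes"),
    ]
    return blocks


def get_block(block_id: str) -> BlockConfig:
    for b in enumerate_blocks():
        if b.block_id == block_id:
            return b
    raise KeyError(f"unknown block id {block_id!r}")


# -- per-trace metrics -----------------------------------------------------

def engagement_ratio(trace: EpisodeTrace, task: int = 1) -> float:
    """Fraction of environment steps controlled by ``task``."""
    steps = trace.steps
    return float(np.mean(steps["active_task"] == task))


def count_switches(trace: EpisodeTrace) -> int:
    """Decision points whose chosen task differs from the previously
    attended task (task 0 is attended before the first decision)."""
    return int(trace.decisions["switch"].sum())


def switching_ratio_per_timestep(traces: Sequence[EpisodeTrace]) -> pd.DataFrame:
    """Per decision index, the fraction of episodes in which a switch
    occurred, flagged where the decision lies inside an asteroid-free span
    (intersection of both tasks' spans, which coincide by default)."""
    if not traces:
        raise ValueError("at least one trace is required")
    mat = np.stack([t.decisions["switch"].to_numpy() for t in traces])
    steps = traces[0].decisions["step"].to_numpy()
    spans = ((0, 40), (215, 255))
    free = np.zeros(len(steps), dtype=bool)
    for lo, hi in spans:
        free |= (steps >= lo) & (steps < hi)
    return pd.DataFrame(
        {"decision": np.arange(mat.shape[1]), "step": steps, "switch_ratio": mat.mean(axis=0), "asteroid_free": free}
    )


def asteroids_at_switch(traces: Sequence[EpisodeTrace]) -> dict:
    """Mean (and SD) visible asteroids of the attended task at switch vs
    non-switch decisions, with contributing-decision counts.  When one group
    is empty (e.g. the switch-every-frame baseline has no non-switch
    decisions) its mean is reported as None."""
    dec = pd.concat([t.decisions for t in traces], ignore_index=True)
    out = {}
    for label, mask in (("switch", dec["switch"]), ("non_switch", ~dec["switch"])):
        vals = dec.loc[mask, "n_visible_active"]
        out[f"{label}_mean"] = float(vals.mean()) if len(vals) else None
        out[f"{label}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else None
        out[f"{label}_n"] = int(len(vals))
    return out


def overall_sr(trace: EpisodeTrace) -> float:
    """Unweighted mean of the two per-task success rates."""
    s0, s1 = trace.success_rates
    return (s0 + s1) / 2.0


# -- batch evaluation ------------------------------------------------------

def episode_seeds(base_seed: int, n_episodes: int) -> list[tuple[int, int]]:
    """The shared per-episode world-seed pairs used for every agent within a
    block (pairing across agents)."""
    rng = np.random.default_rng(base_seed)
    return [tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=2)) for _ in range(n_episodes)]


def evaluate(
    agents: dict[str, MetaPolicy],
    block: BlockConfig,
    sub_policies: Sequence,
    n_episodes: int = 100,
    base_seed: int = 0,
    soc_cfg: SoCConfig = SoCConfig(),
    meta_cfgs: Optional[dict[str, MetaConfig]] = None,
    optimal_policy=greedy_policy,
    env_overrides: Optional[dict] = None,
) -> tuple[pd.DataFrame, dict[str, list[EpisodeTrace]]]:
    """Evaluate named meta-policies on one block over shared-seed episodes.

    ``agents`` maps a label to a meta-policy callable; ``meta_cfgs`` may
    override the :class:`MetaConfig` per label (default: the label itself if
    it names a meta configuration, else the SoC configuration — baselines
    only need the trace bookkeeping).  Returns a per-(agent, metric) summary
    DataFrame and all traces.
    """
    env_configs = block.env_configs(**(env_overrides or {}))
    seeds = episode_seeds(base_seed, n_episodes)
    rows = []
    all_traces: dict[str, list[EpisodeTrace]] = {}
    for label, policy in agents.items():
        if meta_cfgs and label in meta_cfgs:
            mc = meta_cfgs[label]
        else:
            try:
                mc = MetaConfig.from_label(label)
            except ValueError:
                mc = MetaConfig()  # baselines: observation content is unused
        traces = [
            run_multitask_episode(
                policy, sub_policies, env_configs, mc, soc_cfg, seeds=s,
                optimal_policy=optimal_policy, block_id=block.block_id, agent=label,
            )
            for s in seeds
        ]
        all_traces[label] = traces
        srs = np.array([overall_sr(t) for t in traces])
        sr0 = np.array([t.success_rates[0] for t in traces])
        sr1 = np.array([t.success_rates[1] for t in traces])
        eng = np.array([engagement_ratio(t, task=1) for t in traces])
        sw = np.array([count_switches(t) for t in traces])
        ast = asteroids_at_switch(traces)
        rows.append(
            {
                "block": block.block_id,
                "agent": label,
                "n_episodes": n_episodes,
                "sr_mean": srs.mean(),
                "sr_sd": srs.std(ddof=1),
                "sr_task0_mean": sr0.mean(),
                "sr_task1_mean": sr1.mean(),
                "engagement_task1_mean": eng.mean(),
                "engagement_task1_sd": eng.std(ddof=1),
                "switches_mean": sw.mean(),
                "switches_sd": sw.std(ddof=1),
                "visible_at_switch_mean": ast["switch_mean"],
                "visible_at_non_switch_mean": ast["non_switch_mean"],
            }
        )
    return pd.DataFrame(rows), all_traces


# -- statistics ------------------------------------------------------------

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment: sort ascending, multiply the i-th smallest
    p by (m - i), enforce monotonicity, cap at 1; returned in input order."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def block_statistics(samples: dict[str, Sequence[float]], alpha: float = ALPHA) -> dict:
    """One-way ANOVA + Bartlett + Holm-adjusted pairwise t-tests over
    per-agent SR samples for one block."""
    if len(samples) < 2:
        raise ValueError("at least two groups are required")
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two samples")
    if all(np.allclose(v, v[0]) for v in groups.values()):
        return {"degenerate": True, "reason": "all groups have zero variance", "alpha": alpha}
    f_stat, f_p = stats.f_oneway(*groups.values())
    try:
        b_stat, b_p = stats.bartlett(*groups.values())
    except ValueError:  # a zero-variance group
        b_stat, b_p = float("nan"), float("nan")
    names = list(groups)
    pairs = list(combinations(names, 2))
    raw = []
    t_stats = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b])
        t_stats.append(float(t))
        raw.append(float(p))
    adj = holm_adjust(raw)
    return {
        "degenerate": False,
        "alpha": alpha,
        "anova": {"F": float(f_stat), "p": float(f_p), "significant": bool(f_p < alpha)},
        "bartlett": {"stat": float(b_stat), "p": float(b_p)},
        "pairwise": [
            {
                "pair": (a, b),
                "t": t_stats[i],
                "p_raw": raw[i],
                "p_holm": float(adj[i]),
                "significant": bool(adj[i] < alpha),
            }
            for i, (a, b) in enumerate(pairs)
        ],
    }


def sef_policy() -> MetaPolicy:
    """The switch-every-frame baseline as a meta-policy."""
    return switch_every_frame_policy


def plot_switching_ratio(ratio_frames: dict[str, pd.DataFrame], path: str) -> None:
    """Switching ratio over the 94 decision indices for several agents,
    with asteroid-free phases shaded.  ``ratio_frames`` maps an agent label
    to the output of :func:`switching_ratio_per_timestep`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.2))
    first = next(iter(ratio_frames.values()))
    free = first["asteroid_free"].to_numpy()
    edges = np.flatnonzero(np.diff(np.concatenate(([0], free.astype(int), [0]))))
    for lo, hi in zip(edges[::2], edges[1::2]):
        ax.axvspan(lo - 0.5, hi - 0.5, color="pink", alpha=0.4, lw=0)
    for label, df in ratio_frames.items():
        ax.plot(df["decision"], df["switch_ratio"], label=label, lw=1.2)
    ax.set_xlabel("decision index")
    ax.set_ylabel("switching ratio")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
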