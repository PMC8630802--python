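"""Evaluation protocol and controller-strategy analyses for frozen policies.

A policy is evaluated over a block of consecutive reaches (default 100) with
exploration off and carry-over start states.  Per reach we record success
(dwell completed within the 1 s timeout) and, for successes, the time to
target: 20 ms times the 0-based index of the first step of the completed
dwell streak, so the latest possible value is (50-5)*0.02 = 0.9 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .env import ReachEnv

__all__ = [
    "EpisodeRecord",
    "EvalSummary",
    "evaluate",
    "controller_trained",
    "activation_distribution",
    "coactivation_distribution",
    "save_strategy_histograms",
    "target_size_sweep",
    "rescore_episode",
]


@dataclass
class EpisodeRecord:
    """Per-step trajectory of one reach, for post-hoc analysis."""

    theta: np.ndarray        # (T, 2)
    actions: np.ndarray      # (T, 6)
    endpoints: np.ndarray    # (T, 2)
    goal_endpoint: np.ndarray
    radius: float
    success: bool
    time_to_target: float | None


@dataclass
class EvalSummary:
    """Aggregate metrics over one evaluation block."""

    n_reaches: int
    fraction_success: float
    times_to_target: list
    episodes: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_reaches": self.n_reaches,
                       "fraction_success": self.fraction_success,
                       "times_to_target": list(map(float, self.times_to_target))},
                      fh, indent=1)


def evaluate(policy, env: ReachEnv, n_reaches: int = 100,
             record_episodes: bool = True, carry: bool = False) -> EvalSummary:
    """Run an evaluation block of consecutive reaches with exploration off.

    ``policy`` maps an Observation to a 6-vector action deterministically
    (pass ``agent.act`` or equivalent; it is called with ``explore=False``
    semantics by construction).  The block starts from the rest posture and
    then carries the arm state over between its reaches; ``carry=True``
    instead keeps whatever state the environment is in.
    """
    if n_reaches <= 0:
        raise ValueError("n_reaches must be positive")
    successes = 0
    times = []
    episodes = []
    for i in range(n_reaches):
        obs, _ = env.reset(carry=(carry or i > 0))
        thetas, acts, eps = [], [], []
        done = False
        succ = False
        ttt = None
        while not done:
            action = policy(obs)
            obs, r, terminated, truncated, info = env.step(action)
            thetas.append(obs.theta)
            acts.append(info["action"])
            eps.append(info["endpoint"])
            done = terminated or truncated
            if terminated:
                succ = True
                ttt = info["time_to_target"]
        if succ:
            successes += 1
            times.append(ttt)
        if record_episodes:
            episodes.append(EpisodeRecord(
                theta=np.array(thetas), actions=np.array(acts),
                endpoints=np.array(eps),
                goal_endpoint=env.goal.endpoint_goal.copy(),
                radius=env.goal.radius, success=succ, time_to_target=ttt))
    return EvalSummary(n_reaches=n_reaches,
                       fraction_success=successes / n_reaches,
                       times_to_target=times, episodes=episodes)


def controller_trained(final_eval: EvalSummary) -> bool:
    """A controller counts as trained iff it acquired any target at the end."""
    return final_eval.fraction_success > 0.0


def activation_distribution(episodes, bins: int = 20):
    """Pooled histogram of commanded activations plus the extremeness fraction.

    ``fraction_extreme`` is P(a < 0.05 or a > 0.95) over all pooled per-step
    per-muscle commands — the "all or nothing" statistic.
    """
    episodes = list(episodes)
    if not episodes:
        raise ValueError("no episodes supplied")
    pooled = np.concatenate([ep.actions.ravel() for ep in episodes])
    hist, edges = np.histogram(pooled, bins=bins, range=(0.0, 1.0))
    frac_extreme = float(np.mean((pooled < 0.05) | (pooled > 0.95)))
    return {"hist": hist, "bin_edges": edges, "fraction_extreme": frac_extreme,
            "n_samples": pooled.size}


def coactivation_distribution(episodes, active_threshold: float = 0.10):
    """Distribution of the number of simultaneously active muscles (a > 10%).

    Returns a normalized 7-vector over counts 0..6 plus the modal count.
    """
    episodes = list(episodes)
    if not episodes:
        raise ValueError("no episodes supplied")
    counts = np.concatenate(
        [(ep.actions > active_threshold).sum(axis=1) for ep in episodes])
    dist = np.bincount(counts, minlength=7)[:7].astype(float)
    dist /= dist.sum()
    return {"distribution": dist, "mode": int(np.argmax(dist)),
            "n_steps": counts.size}


def save_strategy_histograms(episodes, out_dir) -> None:
    """Write the pooled activation histogram and coactivation distribution
    as CSV files (activation_hist.csv, coactivation_dist.csv)."""
    from pathlib import Path
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a = activation_distribution(episodes)
    pd.DataFrame({"bin_left": a["bin_edges"][:-1],
                  "bin_right": a["bin_edges"][1:],
                  "count": a["hist"]}).to_csv(
        out_dir / "activation_hist.csv", index=False)
    c = coactivation_distribution(episodes)
    pd.DataFrame({"n_active": np.arange(7),
                  "fraction": c["distribution"]}).to_csv(
        out_dir / "coactivation_dist.csv", index=False)


def rescore_episode(ep: EpisodeRecord, radius: float, dwell_steps: int = 5,
                    timeout_steps: int = 50) -> bool:
    """Re-judge a stored trajectory's success at a different target radius.

    Uses the recorded endpoint track against the recorded goal center; success
    requires an uninterrupted in-target dwell completed within the timeout.
    Exactly nested: success at radius r implies success at any larger radius.
    """
    dists = np.linalg.norm(ep.endpoints[:timeout_steps] - ep.goal_endpoint, axis=1)
    inside = dists <= radius
    streak = 0
    for flag in inside:
        streak = streak + 1 if flag else 0
        if streak >= dwell_steps:
            return True
    return False


def target_size_sweep(policy, env_factory, sizes=(0.075, 0.050, 0.025, 0.0125, 0.00625),
                      n_reaches: int = 100, mode: str = "resimulate",
                      episodes=None):
    """Evaluate a frozen policy across shrinking target radii without retraining.

    ``mode="resimulate"`` (default) runs a fresh evaluation block per radius
    using ``env_factory(radius) -> ReachEnv``.  ``mode="rescore"`` re-judges
    the supplied stored ``episodes`` at each radius, which preserves exact
    success-region nesting.  Returns ``{radius: EvalSummary}``.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    out = {}
    if mode == "resimulate":
        for radius in sizes:
            env = env_factory(radius)
            out[radius] = evaluate(policy, env, n_reaches=n_reaches,
                                   record_episodes=False)
    elif mode == "rescore":
        if not episodes:
            raise ValueError("rescore mode needs stored episodes")
        for radius in sizes:
            succ = [rescore_episode(ep, radius) for ep in episodes]
            out[radius] = EvalSummary(n_reaches=len(episodes),
                                      fraction_success=float(np.mean(succ)),
                                      times_to_target=[], episodes=[])
    else:
        raise ValueError("mode must be 'resimulate' or 'rescore'")
    return out
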