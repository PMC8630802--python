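"""Experiment orchestration: training grids, run logging, fixtures, reports.

A grid crosses algorithms (DDPG/TD3, with/without HER) with muscle-force
levels (100% / 50%), trains ``n_controllers`` independently seeded
controllers per cell, and summarizes the fraction of controllers that
trained successfully per cell — the headline comparison table — plus pooled
HER vs non-HER fractions.  Every run directory carries its config, seed and
learning-curve CSV so a run is reconstructible from the directory alone.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import ActorCriticAgent, AgentConfig, train
from .arm import ArmState, default_arm_params, default_muscles, set_force_scale, step as arm_step, forward_kinematics
from .config import save_config
from .env import ReachEnv, TaskConfig, sample_target
from .evaluation import EvalSummary, controller_trained, evaluate

__all__ = ["ExperimentGrid", "run_single", "run_grid", "make_fixtures"]

ALGORITHM_CELLS = ("DDPG", "DDPG-HER", "TD3", "TD3-HER")


@dataclass(frozen=True)
class ExperimentGrid:
    """One experiment campaign: which cells, how many controllers, how long."""

    algorithms: tuple = ALGORITHM_CELLS
    force_levels: tuple = (1.0, 0.5)
    n_controllers: int = 32
    total_steps: int = 100_000
    base_seed: int = 0
    eval_every: int = 15_000
    eval_reaches: int = 100

    def __post_init__(self):
        if self.n_controllers < 1:
            raise ValueError("n_controllers must be >= 1")
        for a in self.algorithms:
            if a not in ALGORITHM_CELLS:
                raise ValueError(f"unknown algorithm cell {a!r}")


def _cell_config(cell: str, seed: int) -> AgentConfig:
    algorithm = cell.replace("-HER", "")
    return AgentConfig(algorithm=algorithm, use_her=cell.endswith("-HER"), seed=seed)


def _eval_env(force_level: float, seed: int, radius: float = 0.075) -> ReachEnv:
    params = set_force_scale(default_arm_params(), force_level)
    return ReachEnv(arm_params=params, task=TaskConfig(radius=radius), seed=seed)


def run_single(cell: str, force_level: float, seed: int, total_steps: int,
               out_dir: Path | str, eval_every: int = 15_000,
               eval_reaches: int = 100):
    """Train one controller; write its learning-curve CSV and checkpoint.

    Returns ``(agent, final EvalSummary)``.  If the run directory already
    holds a completed summary, the run is skipped and reloaded (resume-by-
    skip for interrupted grids).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    done_file = out_dir / "final_eval.json"
    ckpt = out_dir / "checkpoint.npz"
    if done_file.exists() and ckpt.exists():
        agent = ActorCriticAgent.load(ckpt)
        meta = json.loads(done_file.read_text())
        final = EvalSummary(n_reaches=meta["n_reaches"],
                            fraction_success=meta["fraction_success"],
                            times_to_target=meta["times_to_target"])
        return agent, final

    cfg = _cell_config(cell, seed)
    params = set_force_scale(default_arm_params(), force_level)
    env = ReachEnv(arm_params=params, task=TaskConfig(), seed=seed)
    save_config(out_dir / "config.yaml", params, env.muscles, env.task, cfg)
    from . import __version__
    (out_dir / "run.json").write_text(json.dumps(
        {"cell": cell, "force_level": force_level, "seed": seed,
         "total_steps": total_steps, "fesreach_version": __version__}, indent=1))

    curve_path = out_dir / "learning_curve.csv"
    rows = []

    def hook(agent, step):
        ev = _eval_env(force_level, seed=seed + 100_000)
        s = evaluate(lambda o: agent.act(o, explore=False), ev,
                     n_reaches=eval_reaches, record_episodes=False)
        med = float(np.median(s.times_to_target)) if s.times_to_target else np.nan
        rows.append({"step": step, "sim_minutes": step * 0.02 / 60.0,
                     "fraction_success": s.fraction_success,
                     "median_time_to_target": med})
        return s

    agent, curve = train(env, cfg, total_steps=total_steps,
                         eval_hook=hook, eval_every=eval_every)
    pd.DataFrame(rows).to_csv(curve_path, index=False)
    agent.save(ckpt)
    final = curve[-1]
    final.to_json(done_file)
    return agent, final


def run_grid(grid: ExperimentGrid, out_dir: Path | str):
    """Train the full grid sequentially; returns the summary DataFrame.

    Writes per-run artifacts under ``<out>/<cell>/force<level>/run<i>/`` and a
    grid summary CSV with fraction-trained and median final success per cell,
    plus pooled HER vs non-HER fraction-trained.
    """
    out_dir = Path(out_dir)
    records = []
    for cell in grid.algorithms:
        for force in grid.force_levels:
            for i in range(grid.n_controllers):
                seed = grid.base_seed + i
                run_dir = out_dir / cell / f"force{int(force * 100)}" / f"run{i}"
                _, final = run_single(cell, force, seed, grid.total_steps,
                                      run_dir, grid.eval_every, grid.eval_reaches)
                records.append({"cell": cell, "force_level": force, "seed": seed,
                                "fraction_success": final.fraction_success,
                                "trained": controller_trained(final)})
    runs = pd.DataFrame(records)
    summary = (runs.groupby(["cell", "force_level"])
               .agg(fraction_trained=("trained", "mean"),
                    median_fraction_success=("fraction_success", "median"),
                    n=("trained", "size"))
               .reset_index())
    runs["her"] = runs["cell"].str.endswith("-HER")
    pooled = runs.groupby("her")["trained"].mean().rename("fraction_trained")
    out_dir.mkdir(parents=True, exist_ok=True)
    runs.to_csv(out_dir / "runs.csv", index=False)
    summary.to_csv(out_dir / "summary.csv", index=False)
    pooled.to_csv(out_dir / "pooled_her.csv")
    return summary


def make_fixtures(seed: int, out_dir: Path | str):
    """Write small deterministic artifacts used by the test suite and docs.

    1. a 50-step episode under a scripted open-loop excitation program,
    2. a 1,000-goal target sequence with its endpoint-distance statistics,
    3. a micro-training transcript (2,000 steps, TD3-HER).
    All plain CSV/JSON; regenerating with the same seed is bit-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = default_arm_params()
    muscles = default_muscles()

    # -- scripted open-loop episode
    state = ArmState(theta=np.deg2rad([55.0, 55.0]), omega=np.zeros(2),
                     act=np.zeros(6))
    rows = []
    rng = np.random.default_rng(seed)
    program = rng.uniform(0.0, 1.0, size=(50, 6))
    for t in range(50):
        state = arm_step(state, program[t], params, muscles)
        ep = forward_kinematics(state.theta, params)
        rows.append([round(t * params.dt, 3), *state.theta, *state.omega,
                     *state.act, *ep])
    cols = (["time", "theta1", "theta2", "omega1", "omega2"]
            + [f"a{i + 1}" for i in range(6)] + ["x", "y"])
    pd.DataFrame(rows, columns=cols).to_csv(out_dir / "openloop_episode.csv",
                                            index=False, float_format="%.10g")

    # -- target sequence and its distance statistics
    rng = np.random.default_rng(seed + 1)
    goals = np.array([sample_target(rng, params).theta_goal for _ in range(1000)])
    endpoints = forward_kinematics(goals, params)
    dists = np.linalg.norm(np.diff(endpoints, axis=0), axis=1)
    pd.DataFrame(np.c_[goals, endpoints],
                 columns=["theta1", "theta2", "x", "y"]).to_csv(
        out_dir / "target_sequence.csv", index=False, float_format="%.10g")
    (out_dir / "target_stats.json").write_text(json.dumps(
        {"mean_distance_m": float(dists.mean()),
         "std_distance_m": float(dists.std()), "n_pairs": len(dists)}, indent=1))

    # -- micro training transcript
    cfg = AgentConfig(algorithm="TD3", use_her=True, seed=seed + 2,
                      buffer_capacity=50_000)
    env = ReachEnv(seed=seed + 2)
    transcript = []

    def hook(agent, step):
        ev = ReachEnv(seed=seed + 3)
        s = evaluate(lambda o: agent.act(o, explore=False), ev, n_reaches=10,
                     record_episodes=False)
        transcript.append({"step": step, "fraction_success": s.fraction_success})
        return s

    train(env, cfg, total_steps=2000, eval_hook=hook, eval_every=1000)
    pd.DataFrame(transcript).to_csv(out_dir / "micro_run.csv", index=False,
                                    float_format="%.10g")
    return out_dir
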