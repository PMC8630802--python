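"""Goal-conditioned episodic reaching task on the muscle-driven planar arm.

Each episode ("reach") asks the controller to bring the hand endpoint into a
circular target region (default radius 7.5 cm) whose center is the endpoint
of a goal posture sampled uniformly in joint space over [20°, 90°] per joint.
The arm starts each reach in the end state of the previous reach, mimicking
continuous real-world use.  Reward per 20 ms step is

    r = -0.1 + 1·[endpoint in target] - 0.245·sqrt(sum_i a_i^2)

— a step cost, a sparse in-target bonus and an activation-effort penalty.
An episode terminates successfully once the endpoint has stayed inside the
target for an uninterrupted dwell (default 0.1 s = 5 steps) and is truncated
at the timeout (default 1 s = 50 steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm import (
    ArmParams,
    ArmState,
    default_arm_params,
    default_muscles,
    forward_kinematics,
    step as arm_step,
)

__all__ = ["ReachGoal", "Observation", "TaskConfig", "ReachEnv", "sample_target", "success", "reward"]

SPAWN_LO = np.deg2rad(20.0)
SPAWN_HI = np.deg2rad(90.0)


@dataclass(frozen=True)
class ReachGoal:
    """A goal posture with its Cartesian hand target."""

    theta_goal: np.ndarray      # (2,) rad
    endpoint_goal: np.ndarray   # (2,) m
    radius: float = 0.075


@dataclass(frozen=True)
class Observation:
    """What the controller sees: joint kinematics plus the goal posture.

    Muscle activations are deliberately absent — the internal actuator state
    is hidden from the controller.
    """

    theta: np.ndarray
    omega: np.ndarray
    theta_goal: np.ndarray

    def vector(self) -> np.ndarray:
        return np.concatenate([self.theta, self.omega, self.theta_goal])

    def as_dict(self) -> dict:
        """HER-style dict layout (observation / desired_goal)."""
        return {
            "observation": np.concatenate([self.theta, self.omega]),
            "desired_goal": self.theta_goal.copy(),
            "achieved_goal": self.theta.copy(),
        }


@dataclass(frozen=True)
class TaskConfig:
    """Episode and reward structure."""

    timeout_steps: int = 50
    dwell_steps: int = 5
    radius: float = 0.075
    spawn_box: tuple = ((SPAWN_LO, SPAWN_HI), (SPAWN_LO, SPAWN_HI))
    step_penalty: float = -0.1
    target_reward: float = 1.0
    activation_penalty_coef: float = 0.245
    in_target_reward_mode: str = "per_step"  # "per_step" | "once"

    def __post_init__(self):
        if not self.dwell_steps < self.timeout_steps:
            raise ValueError("dwell_steps must be < timeout_steps")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.in_target_reward_mode not in ("per_step", "once"):
            raise ValueError("in_target_reward_mode must be 'per_step' or 'once'")


def sample_target(rng: np.random.Generator, params: ArmParams,
                  radius: float = 0.075, spawn_box=None) -> ReachGoal:
    """Draw a goal posture uniformly (per joint) over the spawn box."""
    box = np.asarray(spawn_box if spawn_box is not None
                     else ((SPAWN_LO, SPAWN_HI), (SPAWN_LO, SPAWN_HI)))
    theta_goal = rng.uniform(box[:, 0], box[:, 1])
    return ReachGoal(theta_goal=theta_goal,
                     endpoint_goal=forward_kinematics(theta_goal, params),
                     radius=radius)


def success(endpoint: np.ndarray, goal: ReachGoal) -> bool:
    """Endpoint inside (or on) the circular target region."""
    return bool(np.linalg.norm(np.asarray(endpoint) - goal.endpoint_goal) <= goal.radius)


def reward(action: np.ndarray, in_target: bool, cfg: TaskConfig) -> float:
    """Per-step reward; raises if the action was not pre-clipped to [0,1]^6."""
    action = np.asarray(action, dtype=float)
    if np.any(action < 0.0) or np.any(action > 1.0):
        raise ValueError("action must be clipped to [0,1] before reward evaluation")
    r = cfg.step_penalty + (cfg.target_reward if in_target else 0.0)
    return float(r - cfg.activation_penalty_coef * np.sqrt(np.sum(action**2)))


class ReachEnv:
    """Episodic reaching environment with carry-over start states.

    Interface mirrors the common episodic-control API:
    ``reset() -> (Observation, info)`` and
    ``step(action) -> (Observation, reward, terminated, truncated, info)``.
    ``info`` carries ``achieved_goal`` (current joint angles), ``endpoint``,
    ``in_target`` and, on success, ``dwell_entry_step``.
    """

    def __init__(self, arm_params: ArmParams | None = None, muscles=None,
                 task: TaskConfig | None = None, seed: int | None = None):
        self.params = arm_params if arm_params is not None else default_arm_params()
        self.muscles = muscles if muscles is not None else default_muscles()
        self.task = task if task is not None else TaskConfig()
        self.rng = np.random.default_rng(seed)
        self.state: ArmState | None = None
        self.goal: ReachGoal | None = None
        self._done = True
        self._step_idx = 0
        self._dwell = 0
        self._dwell_entry: int | None = None
        self._rewarded_once = False

    # -- episode control ---------------------------------------------------

    def _initial_state(self) -> ArmState:
        box = np.asarray(self.task.spawn_box)
        mid = box.mean(axis=1)
        return ArmState(theta=mid, omega=np.zeros(2), act=np.zeros(len(self.muscles)))

    def sample_target(self) -> ReachGoal:
        return sample_target(self.rng, self.params, self.task.radius, self.task.spawn_box)

    def reset(self, goal: ReachGoal | None = None,
              carry_state: ArmState | None = None, carry: bool = True):
        """Start a new reach.

        The arm keeps its full state from the previous reach (carry-over); on
        the very first reach of a run it starts at rest at the spawn-box
        midpoint with zero activations.  ``carry=False`` forces the rest
        state; an explicit ``carry_state`` overrides both.
        """
        if carry_state is not None:
            self.state = carry_state.copy()
        elif self.state is None or not carry:
            self.state = self._initial_state()
        # else: keep current state (carry-over)
        self.goal = goal if goal is not None else self.sample_target()
        self._done = False
        self._step_idx = 0
        self._dwell = 0
        self._dwell_entry = None
        self._rewarded_once = False
        obs = self._observation()
        return obs, {"endpoint": forward_kinematics(self.state.theta, self.params),
                     "achieved_goal": self.state.theta.copy()}

    def _observation(self) -> Observation:
        return Observation(theta=self.state.theta.copy(),
                           omega=self.state.omega.copy(),
                           theta_goal=self.goal.theta_goal.copy())

    def step(self, action: np.ndarray):
        if self._done:
            raise RuntimeError("step() called on a finished episode; call reset()")
        action = np.clip(np.asarray(action, dtype=float), 0.0, 1.0)
        self.state = arm_step(self.state, action, self.params, self.muscles)
        endpoint = forward_kinematics(self.state.theta, self.params)
        in_target = success(endpoint, self.goal)

        if in_target:
            if self._dwell == 0:
                self._dwell_entry = self._step_idx  # 0-based entry step of streak
            self._dwell += 1
        else:
            self._dwell = 0
            self._dwell_entry = None
        self._step_idx += 1

        pay_target = in_target
        if in_target and self.task.in_target_reward_mode == "once":
            pay_target = not self._rewarded_once
            self._rewarded_once = True
        r = reward(action, pay_target, self.task)

        terminated = self._dwell >= self.task.dwell_steps
        truncated = (not terminated) and self._step_idx >= self.task.timeout_steps
        self._done = terminated or truncated
        info = {
            "endpoint": endpoint,
            "in_target": in_target,
            "achieved_goal": self.state.theta.copy(),
            "action": action,
        }
        if terminated:
            info["dwell_entry_step"] = self._dwell_entry
            info["time_to_target"] = self._dwell_entry * self.params.dt
        return self._observation(), r, bool(terminated), bool(truncated), info
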