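"""Forward dynamics of a horizontal-plane two-link arm driven by six Hill-type muscles.

The arm is a shoulder + elbow pin-joint chain moving on a frictionless
horizontal tabletop (no gravity component in the plane of motion).  Six
muscle-like actuators — four monoarticular, two biarticular — pull on the
joints through constant moment arms.  Each actuator is a minimal Hill model:
first-order activation dynamics feeding a force generator

    F_i = force_scale * Fmax_i * a_i * f_L(l_i / l_opt_i) * f_V(v_i / v_max_i)

with a Gaussian force-length curve peaking at the optimal fiber length and a
Hill hyperbola force-velocity curve (zero force at maximal shortening speed,
eccentric plateau at 1.4).  State integration is explicit forward Euler at a
20 ms control step.

Angle convention: theta1 is the shoulder angle measured from the +x axis
(anatomical right, origin at the shoulder); theta2 is elbow flexion relative
to the upper-arm axis.  Radians everywhere inside the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ArmParams",
    "MuscleParams",
    "ArmState",
    "default_arm_params",
    "default_muscles",
    "forward_kinematics",
    "muscle_kinematics",
    "muscle_forces",
    "joint_torques",
    "step",
    "set_force_scale",
]

# Winter-style anthropometric scaling for a 177 cm / 80 kg adult.
# Upper arm: shoulder->elbow. Forearm segment: elbow->hand center (the hand is
# the reaching endpoint, so the distal segment is Winter's forearm+hand).
_HEIGHT = 1.77
_MASS = 80.0
_L1 = 0.186 * _HEIGHT          # 0.329 m
_L2 = 0.200 * _HEIGHT          # 0.354 m  (elbow to hand center)
_M1 = 0.028 * _MASS            # 2.24 kg
_M2 = 0.022 * _MASS            # 1.76 kg (forearm + hand)
_C1 = 0.436 * _L1
_C2 = 0.682 * _L2
_I1 = _M1 * (0.542 * _L1) ** 2  # about the shoulder
_I2 = _M2 * (0.827 * _L2) ** 2  # about the elbow


@dataclass(frozen=True)
class ArmParams:
    """Rigid-body and simulation parameters of the two-link arm.

    Moments of inertia ``I1``/``I2`` are taken about each segment's proximal
    joint.  ``force_scale`` is a global multiplier on maximal muscle forces
    (1.0 = able-bodied, 0.5 = atrophied).  ``damping`` is a small passive
    viscous torque coefficient per joint (N·m·s/rad) standing in for passive
    tissue dissipation.
    """

    L1: float = _L1
    L2: float = _L2
    m1: float = _M1
    m2: float = _M2
    I1: float = _I1
    I2: float = _I2
    c1: float = _C1
    c2: float = _C2
    joint_limits: tuple = (
        (np.deg2rad(-10.0), np.deg2rad(170.0)),
        (np.deg2rad(0.0), np.deg2rad(160.0)),
    )
    force_scale: float = 1.0
    dt: float = 0.02
    damping: float = 0.1
    substeps: int = 1

    def __post_init__(self):
        for name in ("L1", "L2", "m1", "m2", "I1", "I2", "c1", "c2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.force_scale <= 1.0):
            raise ValueError("force_scale must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        for lo, hi in self.joint_limits:
            if not lo < hi:
                raise ValueError("joint_limits must satisfy min < max")


@dataclass(frozen=True)
class MuscleParams:
    """One Hill-type actuator.

    ``r_shoulder``/``r_elbow`` are signed constant moment arms (m); positive
    values flex the joint (increase its angle), zero means the muscle does not
    cross that joint.  ``l_ref`` is the muscle length at zero joint angles so
    that length = l_ref - r_shoulder*theta1 - r_elbow*theta2.  ``v_max`` is the
    maximal shortening velocity in optimal fiber lengths per second.
    """

    name: str
    Fmax: float
    l_opt: float
    r_shoulder: float
    r_elbow: float
    l_ref: float
    tau_act: float = 0.015
    tau_deact: float = 0.050
    v_max: float = 10.0

    def __post_init__(self):
        for name in ("Fmax", "l_opt", "l_ref", "tau_act", "tau_deact", "v_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ArmState:
    """Full physical state: joint angles, angular velocities, muscle activations."""

    theta: np.ndarray
    omega: np.ndarray
    act: np.ndarray

    def copy(self) -> "ArmState":
        return ArmState(self.theta.copy(), self.omega.copy(), self.act.copy())


def default_arm_params(**overrides) -> ArmParams:
    """Arm parameters for the default 177 cm / 80 kg subject."""
    return ArmParams(**overrides)


def _mk_muscle(name, Fmax, r_s, r_e, l_opt=0.10):
    # reference posture (55°, 55°) — spawn-box midpoint — is at optimal length
    mid = np.deg2rad(55.0)
    l_ref = l_opt + r_s * mid + r_e * mid
    return MuscleParams(name=name, Fmax=Fmax, l_opt=l_opt,
                        r_shoulder=r_s, r_elbow=r_e, l_ref=l_ref)


def default_muscles() -> list[MuscleParams]:
    """Six actuators mirroring the modeled muscle set.

    Four monoarticular (anterior/posterior deltoid at the shoulder,
    brachialis / short triceps head at the elbow) and two biarticular
    (biceps, long triceps head).  Maximal forces and moment arms are
    physiologically plausible values; the originals are not published.
    """
    return [
        _mk_muscle("anterior_deltoid", 800.0, +0.040, 0.0),
        _mk_muscle("posterior_deltoid", 800.0, -0.040, 0.0),
        _mk_muscle("brachialis", 1000.0, 0.0, +0.030),
        _mk_muscle("triceps_short", 1000.0, 0.0, -0.030),
        _mk_muscle("biceps", 700.0, +0.025, +0.035),
        _mk_muscle("triceps_long", 700.0, -0.025, -0.035),
    ]


def forward_kinematics(theta: np.ndarray, params: ArmParams) -> np.ndarray:
    """Hand endpoint position (m) in the shoulder-centered frame.

    Supports broadcasting: ``theta`` may be shape (2,) or (..., 2).
    """
    theta = np.asarray(theta, dtype=float)
    t1 = theta[..., 0]
    t12 = theta[..., 0] + theta[..., 1]
    x = params.L1 * np.cos(t1) + params.L2 * np.cos(t12)
    y = params.L1 * np.sin(t1) + params.L2 * np.sin(t12)
    return np.stack([x, y], axis=-1)


def muscle_kinematics(state: ArmState, muscles) -> tuple[np.ndarray, np.ndarray]:
    """Per-muscle (length, lengthening velocity) from joint state.

    Constant-moment-arm tendon excursion: l = l_ref - r1*theta1 - r2*theta2,
    so dl/dt = -r1*omega1 - r2*omega2 (negative = shortening).
    """
    r1 = np.array([m.r_shoulder for m in muscles])
    r2 = np.array([m.r_elbow for m in muscles])
    l_ref = np.array([m.l_ref for m in muscles])
    length = l_ref - r1 * state.theta[0] - r2 * state.theta[1]
    velocity = -r1 * state.omega[0] - r2 * state.omega[1]
    return length, velocity


def _force_length(x: np.ndarray) -> np.ndarray:
    """Gaussian active force-length curve, peak 1 at optimal length."""
    return np.exp(-(((x - 1.0) / 0.45) ** 2))


def _force_velocity(vn: np.ndarray) -> np.ndarray:
    """Hill force-velocity scaling; vn = (dl/dt)/(v_max*l_opt), negative shortening.

    Concentric branch: classic hyperbola, 1 at isometric, 0 at vn=-1.
    Eccentric branch: saturating rise to a 1.4 plateau.
    """
    vn = np.asarray(vn, dtype=float)
    shape = 0.25  # Hill a/F0 curvature parameter
    conc = (1.0 + vn) / (1.0 - vn / shape)
    ecc = 1.0 + 0.4 * vn / (vn + 0.25)
    out = np.where(vn < 0.0, conc, ecc)
    return np.clip(out, 0.0, 1.4)


def muscle_forces(state: ArmState, muscles, params: ArmParams) -> np.ndarray:
    """Six nonnegative tensile forces (N) given the current state."""
    length, velocity = muscle_kinematics(state, muscles)
    l_opt = np.array([m.l_opt for m in muscles])
    v_max = np.array([m.v_max for m in muscles])
    fmax = np.array([m.Fmax for m in muscles])
    fl = _force_length(length / l_opt)
    fv = _force_velocity(velocity / (v_max * l_opt))
    return np.maximum(params.force_scale * fmax * state.act * fl * fv, 0.0)


def joint_torques(forces: np.ndarray, muscles) -> np.ndarray:
    """Net (shoulder, elbow) torque from muscle forces via signed moment arms."""
    r1 = np.array([m.r_shoulder for m in muscles])
    r2 = np.array([m.r_elbow for m in muscles])
    return np.array([float(r1 @ forces), float(r2 @ forces)])


def _accelerations(state: ArmState, tau: np.ndarray, params: ArmParams) -> np.ndarray:
    """Solve the planar two-link equations of motion for angular acceleration.

    M(theta) * alpha + C(theta, omega) + b*omega = tau, with inertia about the
    proximal joints and Coriolis/centripetal coupling; no gravity in-plane.
    """
    c2 = np.cos(state.theta[1])
    m2L1c2 = params.m2 * params.L1 * params.c2
    M11 = params.I1 + params.I2 + params.m2 * params.L1**2 + 2.0 * m2L1c2 * c2
    M12 = params.I2 + m2L1c2 * c2
    M22 = params.I2
    h = m2L1c2 * np.sin(state.theta[1])
    w1, w2 = state.omega
    cor = np.array([-h * w2 * (2.0 * w1 + w2), h * w1**2])
    rhs = tau - cor - params.damping * state.omega
    M = np.array([[M11, M12], [M12, M22]])
    return np.linalg.solve(M, rhs)


def step(state: ArmState, excitation: np.ndarray, params: ArmParams, muscles) -> ArmState:
    """Advance the arm one control step (default 20 ms) by forward Euler.

    Sequence per sub-step: first-order activation dynamics (fast attack, slow
    decay), muscle force and joint torque evaluation, rigid-body integration,
    then a hard joint-limit clamp that zeroes the offending joint's velocity.
    Deterministic: identical inputs give identical outputs.
    """
    if not np.all(np.isfinite(state.theta)) or not np.all(np.isfinite(state.omega)):
        raise FloatingPointError("non-finite arm state: numerical blow-up")
    excitation = np.asarray(excitation, dtype=float)
    if excitation.shape != (len(muscles),):
        raise ValueError(f"excitation must have shape ({len(muscles)},)")
    if np.any(excitation < 0.0) or np.any(excitation > 1.0):
        warnings.warn("excitation outside [0,1]; clipping", stacklevel=2)
        excitation = np.clip(excitation, 0.0, 1.0)

    dt = params.dt / params.substeps
    theta, omega, act = state.theta.copy(), state.omega.copy(), state.act.copy()
    tau_a = np.array([m.tau_act for m in muscles])
    tau_d = np.array([m.tau_deact for m in muscles])
    limits = np.asarray(params.joint_limits)

    for _ in range(params.substeps):
        tau_act = np.where(excitation >= act, tau_a, tau_d)
        act = np.clip(act + dt * (excitation - act) / tau_act, 0.0, 1.0)
        cur = ArmState(theta, omega, act)
        forces = muscle_forces(cur, muscles, params)
        tau = joint_torques(forces, muscles)
        alpha = _accelerations(cur, tau, params)
        theta = theta + dt * omega
        omega = omega + dt * alpha
        # hard stop at the joint limits
        for j in range(2):
            if theta[j] < limits[j, 0]:
                theta[j], omega[j] = limits[j, 0], 0.0
            elif theta[j] > limits[j, 1]:
                theta[j], omega[j] = limits[j, 1], 0.0

    return ArmState(theta, omega, act)


def set_force_scale(params: ArmParams, fraction: float) -> ArmParams:
    """Return params with all maximal muscle forces scaled by ``fraction``.

    fraction=1.0 models the able-bodied arm; 0.5 models uniform atrophy.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("force fraction must lie in (0, 1]")
    return replace(params, force_scale=float(fraction))
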