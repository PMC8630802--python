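"""YAML configuration round-tripping for arm, muscles, task and agent.

Angles cross the config boundary in degrees; everything inside the package
is radians.  The shipped ``data/default_config.yaml`` holds the default
parameter tables in editable form.
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources

import numpy as np
import yaml

from .agents import AgentConfig
from .arm import ArmParams, MuscleParams
from .env import TaskConfig

__all__ = ["load_config", "save_config", "config_to_dict", "default_config_path"]


def default_config_path():
    return resources.files("fesreach.data") / "default_config.yaml"


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_dict(arm: ArmParams, muscles, task: TaskConfig, agent: AgentConfig) -> dict:
    arm_d = asdict(arm)
    arm_d["joint_limits_deg"] = [
        [float(np.rad2deg(lo)), float(np.rad2deg(hi))] for lo, hi in arm.joint_limits]
    del arm_d["joint_limits"]
    task_d = asdict(task)
    task_d["spawn_box_deg"] = [
        [float(np.rad2deg(lo)), float(np.rad2deg(hi))] for lo, hi in task.spawn_box]
    del task_d["spawn_box"]
    return _plain({
        "arm": arm_d,
        "muscles": [asdict(m) for m in muscles],
        "task": task_d,
        "agent": asdict(agent),
    })


def save_config(path, arm: ArmParams, muscles, task: TaskConfig, agent: AgentConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(arm, muscles, task, agent), fh, sort_keys=False)


def _deg_box(pairs):
    return tuple((float(np.deg2rad(lo)), float(np.deg2rad(hi))) for lo, hi in pairs)


def load_config(path=None):
    """Read a YAML config; returns (ArmParams, [MuscleParams], TaskConfig, AgentConfig)."""
    if path is None:
        text = default_config_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    arm_d = dict(raw["arm"])
    arm_d["joint_limits"] = _deg_box(arm_d.pop("joint_limits_deg"))
    arm = ArmParams(**arm_d)
    muscles = [MuscleParams(**m) for m in raw["muscles"]]
    task_d = dict(raw["task"])
    task_d["spawn_box"] = _deg_box(task_d.pop("spawn_box_deg"))
    task = TaskConfig(**task_d)
    agent = AgentConfig(**raw["agent"])
    return arm, muscles, task, agent
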