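# fesreach

Reinforcement-learning reaching controllers for a muscle-driven model of the
human arm.

Functional electrical stimulation (FES) can restore arm movement to people
with high-level spinal cord injury, but the controller that coordinates the
stimulation across muscles is hard to design by hand: the arm is nonlinear,
multi-input/multi-output, redundant (six muscles, two joints, including
biarticular muscles), and the controller can only observe joint kinematics —
never the internal state of the muscles. `fesreach` implements, end to end,
a simulation study of that problem:

- **Plant** — a horizontal-plane two-segment arm (shoulder + elbow pin
  joints) driven by six Hill-type muscle actuators (four monoarticular, two
  biarticular), integrated by forward Euler at 20 ms. No gravity in-plane,
  hard joint-limit stops, a global `force_scale` to model uniform muscle
  atrophy (1.0 able-bodied, 0.5 atrophied).
- **Task** — goal-conditioned reaching: targets are circles of radius 7.5 cm
  centered on the endpoint of postures drawn uniformly over [20°, 90°] per
  joint; each reach starts from the end state of the previous one. Per-step
  reward `r = −0.1 + 1·[in target] − 0.245·√(Σ aᵢ²)`; success requires a
  0.1 s uninterrupted dwell inside the target within a 1 s timeout.
- **Learners** — DDPG and TD3 (2×64 networks, ε-uniform exploration 0.3),
  optionally with hindsight experience replay (k = 4, "future" strategy):
  failed reaches are re-stored with goals the arm actually achieved later
  in the same reach, turning sparse failures into informative successes.
- **Evaluation** — 100-reach blocks with exploration off: fraction success,
  time to target (max 0.9 s by construction), fraction of controllers
  successfully trained, activation/coactivation strategy analyses, and
  target-size generalization sweeps ([7.5 → 0.625] cm without retraining).

The actor/critic networks are small enough that they are implemented
directly in numpy (manual reverse-mode gradients + Adam); runs are exactly
reproducible from a single integer seed.

## Worked example

Train a TD3+HER controller for 20,000 steps (≈ 6.7 simulated minutes) and
evaluate it on 100 reaches:

```python
import numpy as np
from fesreach import ReachEnv, AgentConfig, train, evaluate

env = ReachEnv(seed=3)
cfg = AgentConfig(algorithm="TD3", use_her=True, seed=3)
agent, _ = train(env, cfg, total_steps=20_000)

eval_env = ReachEnv(seed=12345)
summary = evaluate(lambda obs: agent.act(obs, explore=False),
                   eval_env, n_reaches=100)
print(f"fraction success: {summary.fraction_success:.2f}")
print(f"median time to target: {np.median(summary.times_to_target):.2f} s")
```

```
fraction success: 1.00
median time to target: 0.10 s
```

A fraction success of 1.00 means the controller brought the hand into the
7.5 cm target and held it there for 0.1 s on all 100 consecutive reaches;
the median successful reach entered the target 0.10 s after the reach
began — with carry-over starts, many targets spawn close to where the
previous reach ended, so well-trained controllers acquire them quickly.

The same study is available from the shell:

```
fesreach train --algorithm TD3 --her --steps 100000 --seed 0 --out runs/td3her
fesreach grid --reduced --out runs/grid         # algorithm x force-level grid
fesreach eval --checkpoint runs/td3her/checkpoint.npz \
              --target-sizes 0.075,0.05,0.025,0.0125,0.00625
fesreach report --grid-dir runs/grid
```

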