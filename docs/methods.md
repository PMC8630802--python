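# Methods

## The plant: a horizontal-plane, two-joint, six-muscle arm

The simulated system is a planar model of the human arm viewed from above:
two rigid segments (upper arm, forearm + hand) articulated by frictionless
pin joints at the shoulder and elbow, moving on a horizontal tabletop so
gravity has no in-plane component. Six muscle-like actuators pull on the
joints through constant signed moment arms: four monoarticular (anterior and
posterior deltoid at the shoulder; brachialis and the short triceps head at
the elbow) and two biarticular (biceps, long triceps head).

Rigid-body dynamics are the standard planar two-link equations

    M(θ) θ̈ + C(θ, θ̇) + b θ̇ = τ,

with segment inertias taken about the proximal joints, Coriolis/centripetal
coupling through the elbow angle, and a small passive viscous term
b = 0.1 N·m·s/rad per joint. The viscous term stands in for passive tissue
dissipation: a fully deactivated Hill muscle produces no force, so without it
the arm would coast indefinitely under explicit Euler integration. It is a
config field (`ArmParams.damping`) and can be set to zero.

Anthropometry follows Winter's proportional scaling for a 177 cm / 80 kg
adult. The distal segment runs from the elbow to the *hand center*
(L2 = 0.200·H = 0.354 m), because the hand is the reaching endpoint that
must land in the target; its mass, center of mass and radius of gyration use
the combined forearm+hand segment coefficients (0.022·W, 0.682·L2,
0.827·L2). The choice is validated by the task-geometry statistic below:
with the elbow-to-hand endpoint, the mean ± SD distance between successive
targets comes out at ≈ 28 ± 18 cm, matching the 27 ± 17 cm that the task was
designed to produce; an elbow-to-wrist endpoint (0.146·H) undershoots it
(23.5 ± 14.7 cm).

Each actuator is a minimal Hill model. First-order activation dynamics

    da/dt = (u − a)/τ,   τ = 15 ms on excitation rise, 50 ms on fall,

are Euler-stepped at the 20 ms control interval and clipped to [0, 1]
(dt > τ_act, so the explicit step overshoots and the clip pins the attack at
one step — an accepted artifact of integrating at the literal control rate).
Force is

    F = force_scale · Fmax · a · f_L(l/l_opt) · f_V(v/(v_max·l_opt)),

with a Gaussian force-length curve f_L(x) = exp(−((x−1)/0.45)²), and a Hill
force-velocity curve: the classic hyperbola (curvature a/F0 = 0.25) falling
to zero at the maximal shortening velocity v_max = 10 l_opt/s, and a
saturating eccentric branch plateauing at 1.4. Muscle length is the
constant-moment-arm excursion l = l_ref − r₁θ₁ − r₂θ₂, with l_ref chosen so
every muscle sits at optimal length at the spawn-box midpoint posture
(55°, 55°). Maximal forces (700–1000 N) and moment arms (2.5–4 cm) are
physiologically plausible reconstructions — the original model's tables are
not published — and live in one editable YAML file
(`fesreach/data/default_config.yaml`). `force_scale` scales all Fmax
uniformly: 1.0 is the able-bodied condition, 0.5 the atrophied condition.

Joint limits (shoulder [−10°, 170°], elbow [0°, 160°]) are hard stops:
a joint reaching its limit is clamped there with that joint's velocity
zeroed. The limits enclose the target spawn box with generous margin.

Integration is forward Euler with a single step per 20 ms control interval
(a `substeps` option exists, default 1). One simulated second is exactly 50
steps.

## The task

A reach asks the controller to bring the hand endpoint into a circle of
radius 7.5 cm (default) centered on the endpoint of a goal posture drawn
uniformly and independently per joint over [20°, 90°]². Success in a reach
requires the endpoint to stay inside the circle for an uninterrupted dwell
of 0.1 s (5 steps) within a 1 s (50-step) timeout. Each reach starts from
the full arm state (angles, velocities, activations) left by the previous
reach; the very first reach of a run starts at rest at the spawn-box
midpoint — the midpoint is our choice, as the original start state is
unspecified.

Per-step reward is

    r = −0.1 + 1·[endpoint in target] − 0.245·(Σᵢ aᵢ²)^½ ,

bounded in [−0.1 − 0.245√6, 0.9]. The in-target bonus is paid on every
in-target step (the convention compatible with hindsight relabeling); a
`once` mode that pays it only on first entry is available as a config
switch. Training episodes use the same dwell-termination and timeout as
evaluation.

The controller observes joint angles, joint velocities and the goal posture
— never the muscle activations; actuator internal state is hidden, as it
would be in a stimulated arm.

## The learners

DDPG and TD3 with feedforward 2×64 ReLU networks for actor and critic(s);
the actor's tanh output is rescaled from [−1, 1] to the [0, 1]⁶ excitation
box. Networks are plain numpy with hand-written reverse-mode gradients and
Adam — at this scale (≈5k parameters per net) that is fast, dependency-free
and exactly reproducible. Network inputs pass through a fixed affine
scaling (angles centered on the spawn midpoint with its half-width;
velocities divided by 10 rad/s); raw units are used everywhere outside the
networks. Without this scaling the ±10–20 rad/s velocity components dominate
the ~1 rad angle inputs and learning is badly degraded.

Exploration is ε-uniform: with probability 0.3 the action is drawn uniformly
from [0, 1]⁶, otherwise the deterministic policy acts. Evaluation always
uses ε = 0.

Stated hyperparameters: 2×64 networks, ε = 0.3, HER k = 4 with the "future"
strategy. Unstated ones are fixed to era-typical off-policy defaults:
γ = 0.98, Polyak τ = 0.005, actor/critic learning rate 10⁻³, batch 256,
buffer 10⁶ (FIFO), TD3 policy delay 2 with target-policy smoothing noise
0.2 clipped at 0.5, one gradient update per environment step. All are
fields of `AgentConfig`.

HER ("future"): when an episode ends, each transition t is stored once with
its original goal and k = 4 more times with goals drawn from the postures
achieved at uniformly sampled indices > t of the same episode (the final
transition relabels with its own achieved posture). The relabeled reward is
recomputed from the endpoint-space success predicate (forward kinematics of
achieved vs relabeled goal, same 7.5 cm radius) and the reward formula with
the original action. Relabeled transitions are stored non-terminal: a
hindsight goal did not actually end the episode, and the per-step in-target
bonus means the value of being at the goal is a discounted stream, not a
single step's reward — cutting the backup there conflicts with the
dwell-terminated original transitions and measurably destabilizes learning
(in an A/B across seeds and both algorithms, bootstrap-through relabeling
converged to ≈100% reach success by 20k steps on every run; the
terminal-cut variant ranged 0–100%). Goals are postures (joint angles);
success is always judged in endpoint space.

Training: 100,000 steps (2,000 simulated seconds) by default, carry-over
resets, updates start once the buffer holds one batch, evaluation hook every
15,000 steps (5 simulated minutes) and at the end. A single integer seed
drives every source of randomness (weight init, exploration, minibatch
sampling, target sampling, HER index draws); reruns are bitwise identical.

## Evaluation protocol

An evaluation block runs 100 consecutive reaches with exploration off,
starting at the rest posture and carrying state over within the block
(whether carry-over persists across the training/evaluation boundary is
unspecified; we restart each block from rest). Metrics:

- **fraction success** — reaches with a completed dwell within timeout;
- **time to target** — for successes only, 0.02 s × the 0-based index of
  the first step of the *completed* dwell streak, so the maximum is
  (50 − 5) × 0.02 = 0.9 s exactly;
- **controller trained** — a controller counts as successfully trained iff
  its end-of-training block acquired at least one target;
- **activation extremeness** — pooled over per-step per-muscle commands of
  controllers exceeding 90% success, the fraction below 5% or above 95%;
- **coactivation** — per-step count of muscles with activation strictly
  above 10%, as a normalized distribution over 0–6.

The generalization sweep re-evaluates a frozen policy at radii
[7.5, 5.0, 2.5, 1.25, 0.625] cm without retraining. Two modes: re-simulate
(fresh episodes per radius; the protocol's procedure) and re-score (re-judge
stored trajectories at each radius; success regions are nested, so the
success fraction is exactly non-increasing as the radius shrinks).

## Problem sizes used by the test suite

The shipped acceptance tests run the comparisons at reduced scale so the
whole suite completes on one CPU in minutes:

- HER-benefit ordering: one controller per cell (TD3±HER, DDPG±HER), 20,000
  steps, 100-reach final evaluation, comparing final fraction-success and
  fraction-trained. The full campaign (32 controllers per cell, 100,000
  steps, both force levels) is available via `fesreach grid --full`.
- Strategy statistics: TD3-HER controllers trained for 60,000 steps (the
  performance plateau), filtered at >90% final success, pooled.
- Determinism: two repetitions of a short run compared bitwise on their
  learning-curve CSVs.

At this scale per-cell fraction-trained is a 0/1 outcome, so the HER vs
no-HER comparison is strict on fraction-success and non-strict (≥) on
fraction-trained.

## What the synthetic setting does and does not show

All data are simulated; the generator *is* the experiment. Passing tests
show that the learning system solves the stated control problem on this
plant with these statistics — they do not show that the specific muscle
parameter table matches the original unpublished one (only its qualitative
structure: roles, signs, plausible magnitudes), nor anything about
electrode selectivity, fatigue, spasticity or 3-D kinematics, all of which
the plant deliberately omits. The activation-strategy statistics
(extremeness, modal coactivation) depend quantitatively on the
reconstructed muscle table and are therefore checked only loosely.

One property of this reconstruction worth knowing: the no-HER baselines are
not permanently stuck at a low success ceiling — given enough training
steps they too can converge on this plant. HER's advantage appears as much
faster and more seed-robust convergence, which is clearly visible at the
20,000-step scale the reduced checks use. Plausible contributors include
the reconstructed muscle table (possibly easier dynamics than the
unpublished original tables) and the fixed input scaling, which stabilizes
learning for all variants. The ordering HER > no-HER at that scale is what
the checks assert.

## Numerical choices and degenerate inputs

- Success is boundary-inclusive (‖e − g‖ ≤ r); measure-zero convention.
- Excitations outside [0, 1] are clipped with a warning at the plant
  boundary; the reward function instead *raises* on unclipped actions,
  since the environment must clip before scoring.
- Non-finite arm state raises immediately (signals numerical blow-up).
- `set_force_scale` rejects fractions outside (0, 1]; a zero-strength arm
  is degenerate.
- Checkpoint archives store all network parameters, the config and the
  generator state; loading reproduces `act()` bitwise.
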