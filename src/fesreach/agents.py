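"""Off-policy actor-critic learners (DDPG, TD3) with hindsight experience replay.

The controller observes joint angles, joint velocities and the goal posture
(6 numbers) and outputs 6 muscle excitations in [0, 1].  Actor and critics
are 2x64 ReLU MLPs; the actor's tanh output is rescaled to [0, 1].
Exploration is epsilon-uniform: with probability 0.3 the action is drawn
uniformly from the action box, otherwise the deterministic policy acts.

HER ("future" strategy) augments each stored episode: every transition is
additionally relabeled against k goals sampled from the postures actually
achieved later in the same episode, with reward and termination recomputed
from the success predicate in endpoint space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .arm import ArmParams, forward_kinematics
from .env import Observation, ReachEnv, TaskConfig, reward as reward_fn
from .nets import MLP, Adam, soft_update

__all__ = [
    "AgentConfig",
    "Transition",
    "ReplayBuffer",
    "ActorCriticAgent",
    "her_relabel",
    "train",
]

OBS_DIM = 6   # theta(2) + omega(2) + goal(2)
ACT_DIM = 6

# Fixed affine input scaling at the network boundary: joint angles and goal
# angles are centered on the spawn-box midpoint (55 deg) with its half-width,
# velocities scaled by a typical peak speed.  Raw units are kept everywhere
# outside the networks.
_MID = float(np.deg2rad(55.0))
_HALF = float(np.deg2rad(35.0))
_OBS_CENTER = np.array([_MID, _MID, 0.0, 0.0, _MID, _MID])
_OBS_SCALE = np.array([_HALF, _HALF, 10.0, 10.0, _HALF, _HALF])


def _norm_obs(vec: np.ndarray) -> np.ndarray:
    return (vec - _OBS_CENTER) / _OBS_SCALE


@dataclass(frozen=True)
class AgentConfig:
    """All learning hyperparameters.

    Network size (2x64), exploration rate (0.3) and the HER settings (k=4,
    "future") are the study's stated choices; the remaining values are
    era-typical off-policy defaults.
    """

    algorithm: str = "TD3"            # "DDPG" | "TD3"
    use_her: bool = True
    hidden_layers: int = 2
    units_per_layer: int = 64
    exploration_eps: float = 0.3
    her_k: int = 4
    her_strategy: str = "future"
    gamma: float = 0.98
    tau: float = 0.005
    actor_lr: float = 1e-3
    critic_lr: float = 1e-3
    batch_size: int = 256
    buffer_capacity: int = 1_000_000
    policy_delay: int = 2
    target_noise: float = 0.2
    noise_clip: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("DDPG", "TD3"):
            raise ValueError("algorithm must be 'DDPG' or 'TD3'")
        if self.her_strategy != "future":
            raise ValueError("only the 'future' HER strategy is implemented")
        if self.her_k < 0:
            raise ValueError("her_k must be >= 0")


@dataclass
class Transition:
    """One (s, a, r, s', done) record with its goal bookkeeping for HER."""

    obs: Observation
    action: np.ndarray
    reward: float
    next_obs: Observation
    terminated: bool
    desired_goal: np.ndarray   # (2,) rad
    achieved_goal: np.ndarray  # (2,) rad — posture after the step


class ReplayBuffer:
    """Flat FIFO transition store over preallocated arrays."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._state = np.empty((capacity, 4))
        self._goal = np.empty((capacity, 2))
        self._action = np.empty((capacity, ACT_DIM))
        self._reward = np.empty(capacity)
        self._next_state = np.empty((capacity, 4))
        self._terminated = np.empty(capacity)
        self._idx = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def add(self, tr: Transition) -> None:
        i = self._idx
        self._state[i] = np.concatenate([tr.obs.theta, tr.obs.omega])
        self._goal[i] = tr.desired_goal
        self._action[i] = tr.action
        self._reward[i] = tr.reward
        self._next_state[i] = np.concatenate([tr.next_obs.theta, tr.next_obs.omega])
        self._terminated[i] = float(tr.terminated)
        self._idx = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def add_many(self, transitions) -> None:
        for tr in transitions:
            self.add(tr)

    def sample(self, batch_size: int, rng: np.random.Generator):
        if self._size == 0:
            raise ValueError("cannot sample from an empty buffer")
        idx = rng.integers(0, self._size, size=batch_size)
        obs = np.concatenate([self._state[idx], self._goal[idx]], axis=1)
        next_obs = np.concatenate([self._next_state[idx], self._goal[idx]], axis=1)
        return obs, self._action[idx], self._reward[idx], next_obs, self._terminated[idx]


def her_relabel(episode, k: int, rng: np.random.Generator,
                arm_params: ArmParams, task: TaskConfig):
    """Hindsight relabeling with the "future" strategy.

    Returns the original transitions plus, for each transition at index t,
    ``k`` copies whose desired goal is the achieved posture of a uniformly
    sampled later transition (the final transition relabels with its own
    achieved posture).  The relabeled reward is recomputed from the
    endpoint-space success predicate and the reward formula with the original
    action.  Relabeled transitions never terminate (the critic bootstraps
    through them): a hindsight goal did not actually end the episode, and
    cutting the value backup there starves the in-target value of the
    per-step bonus that follows, which measurably destabilizes learning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    episode = list(episode)
    if not episode:
        raise ValueError("episode must be non-empty")
    out = list(episode)
    if k == 0:
        return out
    n = len(episode)
    achieved_endpoints = forward_kinematics(
        np.array([tr.achieved_goal for tr in episode]), arm_params)
    for t, tr in enumerate(episode):
        if t < n - 1:
            picks = rng.integers(t + 1, n, size=k)
        else:
            picks = np.full(k, n - 1)
        for j in picks:
            new_goal = episode[j].achieved_goal
            goal_ep = achieved_endpoints[j]
            in_target = bool(np.linalg.norm(achieved_endpoints[t] - goal_ep) <= task.radius)
            r = reward_fn(tr.action, in_target, task)
            new_obs = Observation(tr.obs.theta, tr.obs.omega, new_goal.copy())
            new_next = Observation(tr.next_obs.theta, tr.next_obs.omega, new_goal.copy())
            out.append(Transition(obs=new_obs, action=tr.action, reward=r,
                                  next_obs=new_next, terminated=False,
                                  desired_goal=new_goal.copy(),
                                  achieved_goal=tr.achieved_goal.copy()))
    return out


class ActorCriticAgent:
    """DDPG or TD3 learner over the 6-D observation / 6-D action spaces."""

    def __init__(self, cfg: AgentConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        h = [cfg.units_per_layer] * cfg.hidden_layers
        self.actor = MLP([OBS_DIM, *h, ACT_DIM], self.rng, out_activation="tanh")
        self.critic = MLP([OBS_DIM + ACT_DIM, *h, 1], self.rng)
        self.actor_target = self.actor.copy()
        self.critic_target = self.critic.copy()
        self.actor_opt = Adam(self.actor.params, lr=cfg.actor_lr)
        self.critic_opt = Adam(self.critic.params, lr=cfg.critic_lr)
        if cfg.algorithm == "TD3":
            self.critic2 = MLP([OBS_DIM + ACT_DIM, *h, 1], self.rng)
            self.critic2_target = self.critic2.copy()
            self.critic2_opt = Adam(self.critic2.params, lr=cfg.critic_lr)
        self.buffer = ReplayBuffer(cfg.buffer_capacity)
        self._update_count = 0

    # -- acting ------------------------------------------------------------

    def policy(self, obs_vec: np.ndarray) -> np.ndarray:
        """Deterministic policy: actor output squashed from [-1,1] to [0,1]."""
        y = self.actor(_norm_obs(np.asarray(obs_vec, dtype=float)))
        return (0.5 * (y + 1.0)).reshape(-1, ACT_DIM).squeeze(0)

    def act(self, obs: Observation | np.ndarray, explore: bool = False) -> np.ndarray:
        vec = obs.vector() if isinstance(obs, Observation) else np.asarray(obs)
        if explore and self.rng.random() < self.cfg.exploration_eps:
            return self.rng.uniform(0.0, 1.0, size=ACT_DIM)
        return self.policy(vec)

    # -- learning ----------------------------------------------------------

    def _critic_step(self, net, opt, obs_a, y):
        q, cache = net.forward(obs_a)
        diff = q - y
        loss = float(np.mean(diff**2))
        grads, _ = net.backward(cache, 2.0 * diff / len(y))
        opt.step(grads)
        return loss

    def _actor_step(self, obs):
        y_act, a_cache = self.actor.forward(obs)
        action = 0.5 * (y_act + 1.0)
        q, c_cache = self.critic.forward(np.concatenate([obs, action], axis=1))
        loss = float(-np.mean(q))
        _, dinput = self.critic.backward(c_cache, -np.ones_like(q) / len(q))
        da = dinput[:, OBS_DIM:] * 0.5  # through the [-1,1]->[0,1] rescale
        grads, _ = self.actor.backward(a_cache, da)
        self.actor_opt.step(grads)
        return loss

    def ddpg_update(self, batch):
        """One DDPG gradient step on a sampled batch."""
        obs, act, rew, next_obs, term = batch
        obs, next_obs = _norm_obs(obs), _norm_obs(next_obs)
        next_a = 0.5 * (self.actor_target(next_obs) + 1.0)
        q_next = self.critic_target(np.concatenate([next_obs, next_a], axis=1)).ravel()
        y = (rew + self.cfg.gamma * (1.0 - term) * q_next)[:, None]
        critic_loss = self._critic_step(self.critic, self.critic_opt,
                                        np.concatenate([obs, act], axis=1), y)
        actor_loss = self._actor_step(obs)
        soft_update(self.actor_target, self.actor, self.cfg.tau)
        soft_update(self.critic_target, self.critic, self.cfg.tau)
        return critic_loss, actor_loss

    def td3_update(self, batch, step_index: int | None = None):
        """One TD3 step: clipped double-Q target, delayed actor/target updates."""
        if step_index is None:
            step_index = self._update_count
        obs, act, rew, next_obs, term = batch
        obs, next_obs = _norm_obs(obs), _norm_obs(next_obs)
        next_a = 0.5 * (self.actor_target(next_obs) + 1.0)
        noise = np.clip(self.rng.normal(0.0, self.cfg.target_noise, size=next_a.shape),
                        -self.cfg.noise_clip, self.cfg.noise_clip)
        next_a = np.clip(next_a + noise, 0.0, 1.0)
        na = np.concatenate([next_obs, next_a], axis=1)
        q_next = np.minimum(self.critic_target(na), self.critic2_target(na)).ravel()
        y = (rew + self.cfg.gamma * (1.0 - term) * q_next)[:, None]
        obs_a = np.concatenate([obs, act], axis=1)
        c1 = self._critic_step(self.critic, self.critic_opt, obs_a, y)
        c2 = self._critic_step(self.critic2, self.critic2_opt, obs_a, y)
        actor_loss = None
        if step_index % self.cfg.policy_delay == 0:
            actor_loss = self._actor_step(obs)
            soft_update(self.actor_target, self.actor, self.cfg.tau)
            soft_update(self.critic_target, self.critic, self.cfg.tau)
            soft_update(self.critic2_target, self.critic2, self.cfg.tau)
        return c1, c2, actor_loss

    def update(self):
        """Sample a batch from the replay buffer and take one gradient step."""
        if len(self.buffer) == 0:
            raise ValueError("replay buffer is empty")
        batch = self.buffer.sample(self.cfg.batch_size, self.rng)
        if self.cfg.algorithm == "TD3":
            out = self.td3_update(batch, self._update_count)
        else:
            out = self.ddpg_update(batch)
        self._update_count += 1
        return out

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Serialize parameters, config and rng state to a single archive."""
        arrays = {}
        nets = {"actor": self.actor, "critic": self.critic,
                "actor_target": self.actor_target, "critic_target": self.critic_target}
        if self.cfg.algorithm == "TD3":
            nets["critic2"] = self.critic2
            nets["critic2_target"] = self.critic2_target
        for name, net in nets.items():
            for i, p in enumerate(net.params):
                arrays[f"{name}__{i}"] = p
        meta = {"config": asdict(self.cfg),
                "rng_state": self.rng.bit_generator.state,
                "version": 1}
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ActorCriticAgent":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode("utf-8"))
            cfg = AgentConfig(**meta["config"])
            agent = cls(cfg)
            agent.rng.bit_generator.state = meta["rng_state"]
            nets = {"actor": agent.actor, "critic": agent.critic,
                    "actor_target": agent.actor_target,
                    "critic_target": agent.critic_target}
            if cfg.algorithm == "TD3":
                nets["critic2"] = agent.critic2
                nets["critic2_target"] = agent.critic2_target
            for name, net in nets.items():
                for i in range(len(net.params)):
                    net.params[i][...] = data[f"{name}__{i}"]
        return agent


def train(env: ReachEnv, cfg: AgentConfig, total_steps: int,
          eval_hook=None, eval_every: int = 15_000,
          agent: ActorCriticAgent | None = None):
    """Run the training loop: carry-over reaches, HER storage, 1 update/step.

    ``eval_hook(agent, step)`` is invoked every ``eval_every`` environment
    steps (default 15,000 = 5 simulated minutes at 20 ms) and once at the
    end; its return values form the learning curve.  Returns
    ``(agent, curve)`` where ``curve`` is the list of hook results.
    """
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if agent is None:
        agent = ActorCriticAgent(cfg)
    curve = []
    obs, _ = env.reset()
    episode = []
    for step_i in range(1, total_steps + 1):
        action = agent.act(obs, explore=True)
        next_obs, r, terminated, truncated, info = env.step(action)
        episode.append(Transition(
            obs=obs, action=action, reward=r, next_obs=next_obs,
            terminated=terminated, desired_goal=obs.theta_goal.copy(),
            achieved_goal=info["achieved_goal"]))
        obs = next_obs
        if terminated or truncated:
            if cfg.use_her and cfg.her_k > 0:
                stored = her_relabel(episode, cfg.her_k, agent.rng,
                                     env.params, env.task)
            else:
                stored = episode
            agent.buffer.add_many(stored)
            episode = []
            obs, _ = env.reset()
        if len(agent.buffer) >= cfg.batch_size:
            agent.update()
        if eval_hook is not None and (step_i % eval_every == 0 or step_i == total_steps):
            curve.append(eval_hook(agent, step_i))
    return agent, curve
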