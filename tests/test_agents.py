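"""Tests for the DDPG/TD3 learners and hindsight relabeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fesreach.agents import (
    ActorCriticAgent,
    AgentConfig,
    ReplayBuffer,
    Transition,
    her_relabel,
    train,
)
from fesreach.arm import default_arm_params, forward_kinematics
from fesreach.env import Observation, ReachEnv, TaskConfig, reward as reward_fn


def _obs(theta, omega, goal):
    return Observation(np.asarray(theta, float), np.asarray(omega, float),
                       np.asarray(goal, float))


def random_episode(rng, length, arm_params):
    """Synthetic episode with postures in the spawn box and random actions."""
    lo, hi = np.deg2rad(20.0), np.deg2rad(90.0)
    task = TaskConfig()
    thetas = rng.uniform(lo, hi, size=(length + 1, 2))
    goal = rng.uniform(lo, hi, size=2)
    goal_ep = forward_kinematics(goal, arm_params)
    eps = []
    for t in range(length):
        action = rng.uniform(0, 1, 6)
        achieved = thetas[t + 1]
        in_target = bool(np.linalg.norm(
            forward_kinematics(achieved, arm_params) - goal_ep) <= task.radius)
        eps.append(Transition(
            obs=_obs(thetas[t], np.zeros(2), goal), action=action,
            reward=reward_fn(action, in_target, task),
            next_obs=_obs(thetas[t + 1], np.zeros(2), goal),
            terminated=in_target, desired_goal=goal.copy(),
            achieved_goal=achieved.copy()))
    return eps


class TestAct:
    def test_deterministic_without_exploration(self):
        agent = ActorCriticAgent(AgentConfig(seed=0, buffer_capacity=10))
        obs = _obs([1.0, 1.0], [0.0, 0.0], [0.8, 0.9])
        a1 = agent.act(obs, explore=False)
        a2 = agent.act(obs, explore=False)
        np.testing.assert_array_equal(a1, a2)

    def test_actions_always_in_unit_box(self):
        agent = ActorCriticAgent(AgentConfig(seed=1, buffer_capacity=10))
        rng = np.random.default_rng(0)
        for _ in range(200):
            obs = _obs(rng.uniform(0, 2, 2), rng.normal(0, 5, 2),
                       rng.uniform(0, 2, 2))
            for explore in (False, True):
                a = agent.act(obs, explore=explore)
                assert np.all(a >= 0.0) and np.all(a <= 1.0)

    def test_exploration_fraction_is_thirty_percent(self):
        """Over many draws ~30% of explore-mode actions are uniform-random."""
        agent = ActorCriticAgent(AgentConfig(seed=2, buffer_capacity=10))
        obs = _obs([1.0, 1.0], [0.0, 0.0], [0.8, 0.9])
        greedy = agent.act(obs, explore=False)
        n = 20_000
        random_count = sum(
            not np.array_equal(agent.act(obs, explore=True), greedy)
            for _ in range(n))
        assert random_count / n == pytest.approx(0.30, abs=0.01)


class TestReplayBuffer:
    def test_fifo_eviction_at_capacity(self, arm_params):
        buf = ReplayBuffer(capacity=5)
        eps = random_episode(np.random.default_rng(0), 8, arm_params)
        buf.add_many(eps)
        assert len(buf) == 5
        # oldest 3 evicted; slot 0 now holds transition 5
        np.testing.assert_array_equal(buf._action[0], eps[5].action)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ReplayBuffer(10).sample(4, np.random.default_rng(0))


class TestHerRelabel:
    def test_k_zero_is_identity(self, arm_params):
        eps = random_episode(np.random.default_rng(1), 10, arm_params)
        out = her_relabel(eps, 0, np.random.default_rng(0), arm_params, TaskConfig())
        assert out == eps

    def test_k_four_quintuples_storage(self, arm_params):
        eps = random_episode(np.random.default_rng(2), 12, arm_params)
        out = her_relabel(eps, 4, np.random.default_rng(0), arm_params, TaskConfig())
        assert len(out) == 5 * len(eps)

    def test_negative_k_raises(self, arm_params):
        eps = random_episode(np.random.default_rng(3), 5, arm_params)
        with pytest.raises(ValueError):
            her_relabel(eps, -1, np.random.default_rng(0), arm_params, TaskConfig())

    def test_empty_episode_raises(self, arm_params):
        with pytest.raises(ValueError):
            her_relabel([], 4, np.random.default_rng(0), arm_params, TaskConfig())

    def test_final_transition_self_relabel_succeeds(self, arm_params):
        """Relabeling the last step with its own achieved posture is a success."""
        eps = random_episode(np.random.default_rng(4), 6, arm_params)
        out = her_relabel(eps, 1, np.random.default_rng(0), arm_params, TaskConfig())
        last_relabel = out[-1]
        np.testing.assert_array_equal(last_relabel.desired_goal,
                                      eps[-1].achieved_goal)
        expected = reward_fn(eps[-1].action, True, TaskConfig())
        assert last_relabel.reward == pytest.approx(expected)

    def test_future_goals_only(self, arm_params):
        """Relabeled goals come from postures achieved later in the episode."""
        eps = random_episode(np.random.default_rng(5), 10, arm_params)
        out = her_relabel(eps, 3, np.random.default_rng(1), arm_params, TaskConfig())
        n = len(eps)
        achieved = [tr.achieved_goal for tr in eps]
        for idx, tr in enumerate(out[n:]):
            t = idx // 3
            future = achieved[t + 1:] if t < n - 1 else [achieved[-1]]
            assert any(np.array_equal(tr.desired_goal, g) for g in future)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 5), st.integers(0, 1000))
    def test_relabeled_rewards_match_formula(self, length, k, seed):
        """Every relabeled reward equals the formula recomputed from scratch."""
        params = default_arm_params()
        task = TaskConfig()
        rng = np.random.default_rng(seed)
        eps = random_episode(rng, length, params)
        out = her_relabel(eps, k, np.random.default_rng(seed + 1), params, task)
        for tr in out:
            d = np.linalg.norm(forward_kinematics(tr.achieved_goal, params)
                               - forward_kinematics(tr.desired_goal, params))
            in_target = d <= task.radius
            assert tr.reward == pytest.approx(reward_fn(tr.action, in_target, task))
        # relabeled copies bootstrap through: they never terminate
        assert all(not tr.terminated for tr in out[len(eps):])


class TestUpdates:
    def _filled_agent(self, algorithm, seed=0, batch=8):
        cfg = AgentConfig(algorithm=algorithm, seed=seed, batch_size=batch,
                          buffer_capacity=1000)
        agent = ActorCriticAgent(cfg)
        eps = random_episode(np.random.default_rng(seed), 40, default_arm_params())
        agent.buffer.add_many(eps)
        return agent

    def test_gamma_zero_td_target_is_reward(self):
        """With gamma=0 the critic regresses toward the immediate reward."""
        cfg = AgentConfig(algorithm="DDPG", gamma=0.0, seed=0, batch_size=16,
                          buffer_capacity=100, critic_lr=1e-2)
        agent = ActorCriticAgent(cfg)
        eps = random_episode(np.random.default_rng(0), 40, default_arm_params())
        agent.buffer.add_many(eps)
        for _ in range(800):
            agent.update()
        obs, act, rew, _, _ = agent.buffer.sample(16, np.random.default_rng(1))
        # critic should now predict ~r for seen state-actions
        from fesreach.agents import _norm_obs
        q = agent.critic(np.concatenate([_norm_obs(obs), act], axis=1)).ravel()
        assert float(np.mean(np.abs(q - rew))) < 0.05

    def test_tau_one_syncs_targets(self):
        cfg = AgentConfig(algorithm="DDPG", tau=1.0, seed=1, batch_size=8,
                          buffer_capacity=100)
        agent = ActorCriticAgent(cfg)
        agent.buffer.add_many(random_episode(np.random.default_rng(1), 20,
                                             default_arm_params()))
        agent.update()
        for pt, po in zip(agent.critic_target.params, agent.critic.params):
            np.testing.assert_array_equal(pt, po)

    def test_td3_identical_twins_match_ddpg_target(self):
        """min(Q,Q) = Q: with equal twins and no smoothing noise the TD3
        target equals the DDPG target from critic 1 alone."""
        cfg = AgentConfig(algorithm="TD3", seed=2, batch_size=8,
                          buffer_capacity=100, target_noise=0.0)
        agent = ActorCriticAgent(cfg)
        agent.critic2_target.set_params(agent.critic_target.get_params())
        batch = self._prep_batch(agent)
        obs, act, rew, next_obs, term = batch
        from fesreach.agents import _norm_obs
        nxt = _norm_obs(next_obs)
        na = 0.5 * (agent.actor_target(nxt) + 1.0)
        q1 = agent.critic_target(np.concatenate([nxt, na], axis=1)).ravel()
        q2 = agent.critic2_target(np.concatenate([nxt, na], axis=1)).ravel()
        np.testing.assert_array_equal(np.minimum(q1, q2), q1)

    def _prep_batch(self, agent):
        agent.buffer.add_many(random_episode(np.random.default_rng(3), 20,
                                             default_arm_params()))
        return agent.buffer.sample(8, np.random.default_rng(0))

    def test_td3_min_never_exceeds_either_twin(self):
        agent = self._filled_agent("TD3", seed=3)
        obs, act, rew, next_obs, term = agent.buffer.sample(
            32, np.random.default_rng(0))
        from fesreach.agents import _norm_obs
        nxt = _norm_obs(next_obs)
        na = 0.5 * (agent.actor_target(nxt) + 1.0)
        x = np.concatenate([nxt, na], axis=1)
        q1, q2 = agent.critic_target(x), agent.critic2_target(x)
        m = np.minimum(q1, q2)
        assert np.all(m <= q1) and np.all(m <= q2)

    def test_td3_policy_delay_gates_actor(self):
        """The actor updates only every policy_delay-th critic update."""
        agent = self._filled_agent("TD3", seed=4)
        losses = [agent.update() for _ in range(6)]
        actor_updates = [l[2] is not None for l in losses]
        assert actor_updates == [True, False, True, False, True, False]

    def test_empty_buffer_update_raises(self):
        agent = ActorCriticAgent(AgentConfig(seed=5, buffer_capacity=10))
        with pytest.raises(ValueError):
            agent.update()


class TestPersistence:
    def test_save_load_reproduces_policy_bitwise(self, tmp_path):
        agent = self._trained_agent()
        path = tmp_path / "ckpt.npz"
        agent.save(path)
        clone = ActorCriticAgent.load(path)
        obs = _obs([1.0, 0.9], [0.1, -0.2], [1.2, 0.7])
        np.testing.assert_array_equal(agent.act(obs, explore=False),
                                      clone.act(obs, explore=False))

    def _trained_agent(self):
        agent = ActorCriticAgent(AgentConfig(algorithm="TD3", seed=6,
                                             batch_size=8, buffer_capacity=500))
        agent.buffer.add_many(random_episode(np.random.default_rng(6), 60,
                                             default_arm_params()))
        for _ in range(10):
            agent.update()
        return agent


class TestTrainLoop:
    def test_nonpositive_steps_raises(self):
        env = ReachEnv(seed=0)
        with pytest.raises(ValueError):
            train(env, AgentConfig(seed=0, buffer_capacity=100), total_steps=0)

    def test_eval_hook_schedule(self):
        """Hooks fire every eval_every steps and at the final step."""
        env = ReachEnv(seed=0)
        cfg = AgentConfig(seed=0, batch_size=8, buffer_capacity=2000)
        calls = []
        train(env, cfg, total_steps=100, eval_every=30,
              eval_hook=lambda agent, step: calls.append(step))
        assert calls == [30, 60, 90, 100]

    def test_same_seed_same_learning_trace(self):
        """Full training reruns are deterministic under a fixed seed."""
        def run():
            env = ReachEnv(seed=9)
            cfg = AgentConfig(algorithm="DDPG", seed=9, batch_size=16,
                              buffer_capacity=5000)
            agent, _ = train(env, cfg, total_steps=300)
            obs = _obs([1.0, 1.0], [0.0, 0.0], [0.8, 0.9])
            return agent.act(obs, explore=False)

        np.testing.assert_array_equal(run(), run())

    def test_trivial_task_solved_immediately(self):
        """With a huge target the start state already succeeds every reach."""
        from fesreach.evaluation import evaluate
        env = ReachEnv(task=TaskConfig(radius=2.0), seed=0)
        cfg = AgentConfig(seed=0, batch_size=8, buffer_capacity=2000)
        agent, _ = train(env, cfg, total_steps=50)
        ev = ReachEnv(task=TaskConfig(radius=2.0), seed=1)
        s = evaluate(lambda o: agent.act(o, explore=False), ev, n_reaches=20,
                     record_episodes=False)
        assert s.fraction_success == 1.0
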