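"""Actor-critic wiring: WTA circuit, deterministic construction,
closed-loop stepping, and policy/value read-out."""

import dataclasses

import numpy as np
import pytest

from neuroloop.agent import (Agent, AgentConfig, build_agent,
                             build_wta_weights, extract_policy_value)
from neuroloop.coding import DiscreteEncoderSpec, Observation
from neuroloop.experiments import (frozenlake_agent_config,
                                   mountaincar_agent_config)
from neuroloop.plasticity import TDParams


class TestWTAWeights:
    @pytest.mark.parametrize("n,metric", [(3, "line"), (4, "ring"), (6, "ring")])
    def test_diagonal_is_excitatory(self, n, metric):
        w = build_wta_weights(n, 0.2, 0.5, metric).w
        np.testing.assert_allclose(np.diag(w), 0.2)

    def test_line_metric_max_distance_is_inhibitory(self):
        w = build_wta_weights(3, 0.2, 0.5, "line").w
        assert w[0, 2] == -0.5 and w[2, 0] == -0.5
        assert w[0, 1] == 0.2  # nearest neighbor excitation

    def test_ring_wraps_around(self):
        w = build_wta_weights(4, 0.2, 0.5, "ring").w
        assert w[0, 3] == 0.2      # ring neighbors
        assert w[0, 2] == -0.5     # opposite unit

    @pytest.mark.parametrize("n", range(2, 7))
    @pytest.mark.parametrize("metric", ["line", "ring"])
    def test_symmetric(self, n, metric):
        w = build_wta_weights(n, 0.17, 0.83, metric).w
        np.testing.assert_array_equal(w, w.T)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            build_wta_weights(1, 0.2, 0.5)


class TestBuildAgent:
    def test_plastic_projection_shapes(self):
        # 25 place cells, 3 actions: input->critic is 1x25,
        # input->actor is 3x25 (target x source)
        agent = build_agent(mountaincar_agent_config(), seed=0)
        assert agent.w_critic.w.shape == (1, 25)
        assert agent.w_actor.w.shape == (3, 25)

    def test_same_config_and_seed_give_identical_weights(self):
        a = build_agent(frozenlake_agent_config(), seed=5)
        b = build_agent(frozenlake_agent_config(), seed=5)
        np.testing.assert_array_equal(a.w_actor.w, b.w_actor.w)
        np.testing.assert_array_equal(a.w_critic.w, b.w_critic.w)

    def test_initial_plastic_weights_respect_floor(self):
        agent = build_agent(frozenlake_agent_config(), seed=1)
        assert np.all(agent.w_actor.w >= agent.w_actor.w_min)
        assert np.all(agent.w_critic.w >= agent.w_critic.w_min)

    def test_rpe_wiring_realizes_two_point_difference(self):
        agent = build_agent(frozenlake_agent_config(), seed=0)
        td = agent.cfg.td
        instant = [p for p in agent.net.projections
                   if p.src.name == "critic" and p.delay_steps == 0]
        delayed = [p for p in agent.net.projections
                   if p.src.name == "critic" and p.delay_steps > 0]
        assert instant[0].weights.w[0, 0] == pytest.approx(1 / td.d - 1 / td.tau_r)
        assert delayed[0].weights.w[0, 0] == pytest.approx(-1 / td.d)
        assert delayed[0].delay_steps == int(td.d / agent.cfg.dt)


class TestAgentStep:
    def test_frozen_learning_rate_leaves_weights_unchanged(self):
        cfg = frozenlake_agent_config()
        cfg.td = dataclasses.replace(cfg.td, eta=0.0)
        agent = build_agent(cfg, seed=2)
        wa, wc = agent.w_actor.w.copy(), agent.w_critic.w.copy()
        for k in range(200):
            agent.step(Observation(discrete_index=k % 16), reward=0.3)
        np.testing.assert_array_equal(agent.w_actor.w, wa)
        np.testing.assert_array_equal(agent.w_critic.w, wc)

    def test_zero_delta_episode_is_exact_noop_for_weights(self):
        # no reward and a zero-value critic: the RPE unit stays at
        # exactly zero, so a full episode changes no plastic weight
        cfg = frozenlake_agent_config()
        cfg.w_init_critic = 0.0
        cfg.w_min_critic = 0.0
        agent = build_agent(cfg, seed=3)
        wa = agent.w_actor.w.copy()
        for k in range(300):
            agent.step(Observation(discrete_index=k % 16), reward=0.0)
        assert agent.delta == 0.0
        np.testing.assert_array_equal(agent.w_actor.w, wa)

    def test_exploration_visits_every_action(self):
        # floor weights, no reward: action selection is driven by actor
        # noise and WTA dynamics; over 1000 steps every action occurs
        cfg = frozenlake_agent_config()
        cfg.td = dataclasses.replace(cfg.td, eta=0.0)
        cfg.w_init_actor = cfg.w_min_actor
        cfg.w_init_jitter = 0.0
        agent = build_agent(cfg, seed=4)
        seen = set()
        for k in range(1000):
            seen.add(agent.step(Observation(discrete_index=0), reward=0.0))
        assert seen == {0, 1, 2, 3}

    def test_dominant_feedforward_column_drives_action(self):
        cfg = frozenlake_agent_config()
        cfg.td = dataclasses.replace(cfg.td, eta=0.0)
        agent = build_agent(cfg, seed=5)
        agent.w_actor.w[:, 7] = agent.w_actor.w_min
        agent.w_actor.w[2, 7] = 2.0  # action 2 strongly wired to state 7
        actions = [agent.step(Observation(discrete_index=7), reward=0.0)
                   for _ in range(50)]
        assert all(a == 2 for a in actions[5:])  # after settling

    def test_learning_updates_move_weights(self):
        agent = build_agent(frozenlake_agent_config(), seed=6)
        wc = agent.w_critic.w.copy()
        for _ in range(50):
            agent.step(Observation(discrete_index=3), reward=1.0)
        assert not np.array_equal(agent.w_critic.w, wc)


class TestWTADynamics:
    def settle(self, cfg, drives, steps=300):
        cfg = dataclasses.replace(cfg)
        cfg.td = dataclasses.replace(cfg.td, eta=0.0)
        cfg.actor_noise = 0.0
        agent = build_agent(cfg, seed=0)
        agent.w_actor.w[:] = cfg.w_min_actor
        agent.w_actor.w[:, 0] = drives
        for _ in range(steps):
            agent.step(Observation(discrete_index=0), reward=0.0)
        return agent

    def test_exclusivity_four_units(self):
        # dominant feedforward drive, no noise: exactly one actor unit
        # settles above the plasticity gate
        cfg = frozenlake_agent_config()
        agent = self.settle(cfg, [0.05, 0.05, 0.5, 0.05])
        z = agent.net.z("actor")
        assert int((z > cfg.td.theta_post).sum()) == 1
        assert int(np.argmax(z)) == 2

    def test_exclusivity_three_units(self):
        # three actions on a line metric (as for the MountainCar agent);
        # a discrete probe input isolates the WTA dynamics
        mc = mountaincar_agent_config()
        cfg = frozenlake_agent_config()
        cfg.n_actions = 3
        cfg.wta = mc.wta
        cfg.actor_params = mc.actor_params
        agent = self.settle(cfg, [0.5, 0.05, 0.05])
        z = agent.net.z("actor")
        assert int((z > cfg.td.theta_post).sum()) == 1
        assert int(np.argmax(z)) == 0

    def test_winner_persists_under_constant_input(self):
        # the winning unit stays the winner for at least 100 consecutive
        # steps under constant drive (with the configured actor noise)
        cfg = frozenlake_agent_config()
        cfg = dataclasses.replace(cfg)
        cfg.td = dataclasses.replace(cfg.td, eta=0.0)
        agent = build_agent(cfg, seed=1)
        agent.w_actor.w[:] = cfg.w_min_actor
        agent.w_actor.w[1, 0] = 0.6
        winners = [agent.step(Observation(discrete_index=0), reward=0.0)
                   for _ in range(130)]
        assert all(w == 1 for w in winners[30:])


class TestPolicyValueMap:
    states = [Observation(discrete_index=i) for i in range(16)]

    def test_uniform_weights_give_uniform_values(self):
        agent = build_agent(frozenlake_agent_config(), seed=0)
        agent.w_critic.w[:] = 0.3
        agent.w_actor.w[:] = 0.1
        pv = extract_policy_value(agent, self.states)
        np.testing.assert_allclose(pv.values, 0.3)
        assert len(set(pv.actions.tolist())) == 1  # tie-ruled

    def test_hand_crafted_weights_set_the_policy(self):
        agent = build_agent(frozenlake_agent_config(), seed=0)
        agent.w_actor.w[:] = 0.05
        agent.w_actor.w[2, 0] = 1.0  # east preferred in state 0
        pv = extract_policy_value(agent, self.states)
        assert pv.actions[0] == 2

    def test_extraction_has_no_learning_side_effects(self):
        agent = build_agent(frozenlake_agent_config(), seed=0)
        wa = agent.w_actor.w.copy()
        extract_policy_value(agent, self.states)
        np.testing.assert_array_equal(agent.w_actor.w, wa)
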