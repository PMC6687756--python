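"""Rate-neuron dynamics: activation primitives, delayed input fields,
and the stochastic exponential-Euler integrator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroloop.network import (NetworkState, RateNetwork, RateNeuronParams,
                               WeightMatrix, activation, heaviside,
                               input_field, step_network)


def make_state(z, dt=1.0, depth=1):
    z = np.asarray(z, dtype=float)
    return NetworkState(z.size, dt, depth=depth, z0=z)


class TestHeaviside:
    @pytest.mark.parametrize("x, expected", [(1.0, 1.0), (-1.0, 0.0),
                                             (0.0, 0.0), (1e-300, 1.0)])
    def test_strict_step(self, x, expected):
        assert heaviside(x) == expected

    def test_rejects_non_finite(self):
        for bad in (np.nan, np.inf, -np.inf):
            with pytest.raises(ValueError):
                heaviside(bad)

    @given(st.floats(-1e6, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_matches_sign_definition(self, x):
        assert heaviside(x) == (1.0 if x > 0 else 0.0)


class TestActivation:
    @pytest.mark.parametrize("x, kind, expected", [
        (-2.0, "threshold_linear", 0.0),
        (3.0, "threshold_linear", 3.0),
        (-2.0, "linear", -2.0),
    ])
    def test_examples(self, x, kind, expected):
        assert activation(x, kind) == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            activation(1.0, "sigmoid")


class TestInputField:
    def test_zero_activity_gives_zero_field(self):
        w = WeightMatrix(np.random.default_rng(0).normal(size=(3, 3)))
        h = input_field(w, make_state(np.zeros(3)))
        assert np.all(h == 0)

    def test_identity_weights_return_activity(self):
        z = np.array([0.3, -1.2, 2.0])
        h = input_field(WeightMatrix(np.eye(3)), make_state(z))
        np.testing.assert_array_equal(h, z)

    def test_matches_double_loop_sum(self):
        rng = np.random.default_rng(42)
        w = rng.normal(size=(4, 4))
        z = rng.normal(size=4)
        h = input_field(WeightMatrix(w), make_state(z))
        expected = np.array([sum(w[i, j] * z[j] for j in range(4))
                             for i in range(4)])
        np.testing.assert_allclose(h, expected, rtol=1e-12)

    def test_delayed_field_reads_past_activity_exactly(self):
        state = NetworkState(2, dt=1.0, depth=6)
        history = []
        for k in range(6):
            z = np.array([float(k), float(-k)])
            state.push(z)
            history.append(z)
        w = WeightMatrix(np.eye(2), delay=3.0)
        h = input_field(w, state)
        np.testing.assert_array_equal(h, history[-4])

    def test_delay_exceeding_history_depth_raises(self):
        state = make_state([1.0], depth=2)
        with pytest.raises(ValueError):
            input_field(WeightMatrix(np.eye(1), delay=5.0), state)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            input_field(WeightMatrix(np.ones((2, 3))), make_state([1.0]))

    def test_non_divisible_delay_raises(self):
        with pytest.raises(ValueError):
            input_field(WeightMatrix(np.eye(1), delay=0.5),
                        make_state([1.0], dt=1.0, depth=3))


class TestStepNetwork:
    def test_free_decay_matches_closed_form_exactly(self):
        # sigma=0, no coupling, no drive: z(t) = exp(-t / tau)
        tau, dt = 7.0, 1.0
        p = RateNeuronParams(tau=tau)
        state = make_state([1.0], dt=dt)
        w = WeightMatrix(np.zeros((1, 1)))
        for k in range(1, 30):
            step_network(state, p, w, ext=np.zeros(1), dt=dt)
            np.testing.assert_allclose(state.z[0], np.exp(-k * dt / tau),
                                       rtol=1e-12)

    def test_constant_drive_converges_to_fixed_point(self):
        # dz/dt = (-z + c)/tau has fixed point c; compare against a
        # forward-Euler oracle on a 100x finer grid
        c, tau, dt = 1.7, 10.0, 1.0
        p = RateNeuronParams(tau=tau)
        state = make_state([0.0], dt=dt)
        w = WeightMatrix(np.zeros((1, 1)))
        n = 200
        for _ in range(n):
            step_network(state, p, w, ext=np.array([c]), dt=dt)
        z_fine = 0.0
        fine = dt / 100
        for _ in range(n * 100):
            z_fine += fine * (-z_fine + c) / tau
        assert abs(state.z[0] - c) < 1e-8
        assert abs(state.z[0] - z_fine) < 1e-3

    def test_ou_stationary_std_matches_closed_form(self):
        # free noisy neuron: stationary std is sigma_xi / sqrt(2)
        tau, dt, sigma = 10.0, 1.0, 0.8
        p = RateNeuronParams(tau=tau, sigma_xi=sigma)
        state = make_state([0.0], dt=dt)
        w = WeightMatrix(np.zeros((1, 1)))
        rng = np.random.default_rng(123)
        n = 120_000
        samples = np.empty(n)
        for k in range(n):
            step_network(state, p, w, ext=np.zeros(1), dt=dt, rng=rng)
            samples[k] = state.z[0]
        samples = samples[2000:]  # discard burn-in
        target = sigma / np.sqrt(2.0)
        # autocorrelation time ~ tau/dt -> effective sample count
        n_eff = samples.size / (2 * tau / dt)
        se = target / np.sqrt(2 * n_eff)
        assert abs(samples.std() - target) < 3 * se

    def test_noise_statistics_invariant_under_halving_dt(self):
        tau, sigma = 5.0, 1.0
        stds = []
        for dt in (1.0, 0.5):
            p = RateNeuronParams(tau=tau, sigma_xi=sigma)
            state = make_state([0.0], dt=dt)
            w = WeightMatrix(np.zeros((1, 1)))
            rng = np.random.default_rng(7)
            n = int(1.2e5)
            samples = np.empty(n)
            for k in range(n):
                step_network(state, p, w, ext=np.zeros(1), dt=dt, rng=rng)
                samples[k] = state.z[0]
            stds.append(samples[5000:].std())
        assert abs(stds[0] - stds[1]) / stds[0] < 0.05

    def test_exponential_euler_matches_fine_forward_euler_on_network(self):
        # 10-neuron random network, sigma=0: relative error < 1e-3
        rng = np.random.default_rng(5)
        n, tau, dt = 10, 10.0, 1.0
        w = 0.2 * rng.normal(size=(n, n))
        ext = rng.normal(size=n)
        p = RateNeuronParams(tau=tau, activation="threshold_linear", theta=0.1)
        state = make_state(rng.normal(size=n), dt=dt)
        z_fine = state.z.copy()
        wm = WeightMatrix(w)
        steps = 150  # long enough for the initial transient to settle
        for _ in range(steps):
            step_network(state, p, wm, ext=ext, dt=dt)
        fine = dt / 100
        for _ in range(steps * 100):
            drive = np.maximum(0.0, w @ z_fine + ext - p.theta)
            z_fine = z_fine + fine * (-z_fine + drive) / tau
        err = np.linalg.norm(state.z - z_fine) / np.linalg.norm(z_fine)
        assert err < 1e-3

    def test_linear_ode_analytic_agreement(self):
        # sigma=0, linear activation, constant input: relative error
        # below 1e-6 for dt <= tau/10 (exponential Euler is exact here)
        tau, dt, c = 10.0, 1.0, 0.5
        p = RateNeuronParams(tau=tau, mu=0.2)
        state = make_state([2.0], dt=dt)
        w = WeightMatrix(np.zeros((1, 1)))
        target = p.mu + c
        for k in range(1, 100):
            step_network(state, p, w, ext=np.array([c]), dt=dt)
            analytic = target + (2.0 - target) * np.exp(-k * dt / tau)
            assert abs(state.z[0] - analytic) <= 1e-6 * max(1.0, abs(analytic))

    def test_error_conditions(self):
        p = RateNeuronParams(tau=1.0, sigma_xi=1.0)
        state = make_state([0.0])
        w = WeightMatrix(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            step_network(state, p, w, ext=np.zeros(1), dt=-1.0)
        with pytest.raises(ValueError):
            step_network(state, p, w, ext=np.zeros(1), dt=1.0, rng=None)


class TestRateNetwork:
    def build(self, seed):
        net = RateNetwork(dt=1.0)
        net.add_population("a", 3, RateNeuronParams(tau=5.0, sigma_xi=0.5))
        net.add_population("b", 2, RateNeuronParams(tau=2.0))
        net.connect("a", "b", WeightMatrix(np.ones((2, 3)) * 0.1, delay=2.0))
        net.build(seed=seed)
        return net

    def test_seeded_runs_are_bit_identical(self):
        nets = [self.build(99), self.build(99)]
        for _ in range(50):
            for net in nets:
                net.step({"a": np.ones(3)})
        np.testing.assert_array_equal(nets[0].state.z, nets[1].state.z)

    def test_different_seeds_differ(self):
        n1, n2 = self.build(1), self.build(2)
        for _ in range(20):
            n1.step()
            n2.step()
        assert not np.array_equal(n1.z("a"), n2.z("a"))

    def test_lagged_lookup_respects_depth(self):
        net = self.build(0)
        net.step()
        with pytest.raises(ValueError):
            net.lagged("a", 50.0)
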