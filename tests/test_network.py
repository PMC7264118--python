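"""Finite-network sampler, integrator, order parameter, spike detection."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import cauchy, kstest

from thetanet import (ModelParams, NetworkRealization, order_parameter,
                      sample_population, simulate_network, spike_times)


@pytest.fixture()
def uncoupled_params():
    return ModelParams(0.0, 1.0, 0.0, 0.0, 2)


class TestSamplePopulation:
    def test_degenerate_width_collapses_to_center(self):
        real = sample_population(ModelParams(-0.7, 0.0, 3.0, 0.0, 2), 100,
                                 seed=0)
        assert np.all(real.eta == -0.7)
        assert np.all(real.k == 3.0)

    def test_quantile_median_hits_center(self, uncoupled_params):
        real = sample_population(uncoupled_params, 1001, scheme="quantile",
                                 seed=1)
        assert np.median(real.eta) == pytest.approx(0.0, abs=1e-12)

    def test_random_scheme_matches_cauchy_cdf(self, uncoupled_params):
        real = sample_population(uncoupled_params, 100_000, scheme="random",
                                 seed=2)
        stat = kstest(real.eta, cauchy(loc=0.0, scale=1.0).cdf).statistic
        assert stat < 0.01

    def test_quantile_marginals_match_cauchy_cdf(self):
        params = ModelParams(1.5, 0.3, -2.0, 0.7, 2)
        real = sample_population(params, 50_000, scheme="quantile", seed=3)
        assert kstest(real.eta, cauchy(loc=1.5, scale=0.3).cdf).statistic < 0.01
        assert kstest(real.k, cauchy(loc=-2.0, scale=0.7).cdf).statistic < 0.01

    def test_seed_determinism_bit_identical(self, uncoupled_params):
        for scheme in ("quantile", "random"):
            a = sample_population(uncoupled_params, 500, scheme=scheme, seed=11)
            b = sample_population(uncoupled_params, 500, scheme=scheme, seed=11)
            assert np.array_equal(a.eta, b.eta)
            assert np.array_equal(a.k, b.k)
            assert np.array_equal(a.theta, b.theta)

    def test_quantile_shuffles_break_comonotonicity(self):
        params = ModelParams(0.0, 1.0, 0.0, 1.0, 2)
        real = sample_population(params, 2000, scheme="quantile", seed=5)
        r = np.corrcoef(np.argsort(real.eta), np.argsort(real.k))[0, 1]
        assert abs(r) < 0.1

    def test_clip_flag_recorded_and_bounds_tails(self):
        params = ModelParams(0.0, 1.0, 0.0, 1.0, 2)
        real = sample_population(params, 10_000, scheme="random", seed=6,
                                 clip=True)
        assert real.clipped
        bound = abs(cauchy(0, 1).ppf(1e-4))
        assert np.max(np.abs(real.eta)) <= bound + 1e-9

    def test_invalid_size_rejected(self, uncoupled_params):
        with pytest.raises(ValueError, match="N"):
            sample_population(uncoupled_params, 0)


class TestOrderParameter:
    def test_full_synchrony(self):
        z = order_parameter(np.full(37, 1.3))
        assert z == pytest.approx(np.exp(1.3j), abs=1e-14)
        assert abs(z) == pytest.approx(1.0, abs=1e-14)

    def test_equispaced_phases_cancel(self):
        theta = 2 * np.pi * np.arange(64) / 64
        assert abs(order_parameter(theta)) < 1e-12

    def test_antipodal_pair_cancels(self):
        assert order_parameter(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))


def integrate_single_theta(eta, theta0, t_eval):
    """Reference single-neuron trajectory via a generic ODE solver."""
    sol = solve_ivp(lambda t, th: (1 - np.cos(th)) + eta * (1 + np.cos(th)),
                    (t_eval[0], t_eval[-1]), [theta0], t_eval=t_eval,
                    rtol=1e-10, atol=1e-12)
    return sol.y[0]


class TestSpikeTimes:
    def test_tonic_neuron_period(self):
        # closed form: a theta neuron with eta > 0 spikes every pi / sqrt(eta)
        t = np.linspace(0, 20, 20001)
        theta = integrate_single_theta(1.0, 0.0, t)
        count, times = spike_times(t, np.mod(theta, 2 * np.pi))
        assert count == int(20 / np.pi)
        assert np.diff(times) == pytest.approx(np.pi, rel=1e-3)

    def test_excitable_neuron_at_rest_never_spikes(self):
        eta = -0.3
        rest = -np.arccos((1 + eta) / (1 - eta))  # stable equilibrium phase
        t = np.linspace(0, 50, 5001)
        theta = integrate_single_theta(eta, rest, t)
        count, _ = spike_times(t, np.mod(theta, 2 * np.pi))
        assert count == 0

    def test_constant_trajectory_has_no_spikes(self):
        t = np.linspace(0, 1, 50)
        count, _ = spike_times(t, np.full(50, 2.0))
        assert count == 0

    def test_wrap_around_is_not_a_crossing(self):
        # phase passes 2 pi -> 0 without touching pi in between
        t = np.array([0.0, 1.0, 2.0])
        theta = np.array([6.1, 6.27, 0.05])
        count, _ = spike_times(t, theta)
        assert count == 0

    def test_interpolated_crossing_time(self):
        t = np.array([0.0, 1.0])
        theta = np.array([np.pi - 0.1, np.pi + 0.1])
        count, times = spike_times(t, theta)
        assert count == 1
        assert times[0] == pytest.approx(0.5, abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            spike_times(np.array([0.0]), np.array([1.0]))


class TestSimulateNetwork:
    def test_single_tonic_neuron_spike_count(self, pulse2):
        real = NetworkRealization(N=1, theta=np.zeros(1), eta=np.ones(1),
                                  k=np.zeros(1), seed=None, scheme="manual")
        res = simulate_network(real, pulse2, t_end=20.0, dt=1e-3,
                              record_stride=100, burn_in=0.0,
                              track_spikes=True)
        expected = 20.0 / np.pi
        assert abs(res.spike_counts[0] - expected) <= 1.0

    def test_permutation_symmetry_preserved(self, pulse2):
        # identical neurons with identical initial phases stay identical
        N = 16
        real = NetworkRealization(N=N, theta=np.full(N, 0.7),
                                  eta=np.full(N, 0.4), k=np.full(N, -2.0),
                                  seed=None, scheme="manual")
        res = simulate_network(real, pulse2, t_end=10.0, dt=1e-3,
                              record_stride=1000, burn_in=0.0)
        assert np.allclose(np.abs(res.z_series), 1.0, atol=1e-12)

    def test_order_parameter_bounded(self, pulse2):
        params = ModelParams(1.0, 0.4, -3.0, 0.5, 2)
        real = sample_population(params, 400, scheme="quantile", seed=4)
        res = simulate_network(real, pulse2, t_end=20.0, dt=2e-3,
                              record_stride=10, burn_in=10.0)
        assert np.all(np.abs(res.z_series) <= 1.0 + 1e-12)

    def test_time_step_convergence(self, pulse2):
        # halving dt from the default changes the measured mean |z| by < 1e-3
        params = ModelParams(0.0, 1.0, 0.0, 0.0, 2)
        means = []
        for dt in (2e-3, 1e-3):
            real = sample_population(params, 800, scheme="quantile", seed=9)
            res = simulate_network(real, pulse2, t_end=40.0, dt=dt,
                                  record_stride=25, burn_in=25.0)
            means.append(res.asymptotic_summary["mean_abs_z"])
        assert abs(means[0] - means[1]) < 1e-3

    def test_uncoupled_network_reaches_reduced_equilibrium(self, pulse2):
        # k = 0 decouples the neurons; the phase distribution settles on the
        # Cauchy-locked state whose centroid solves the reduced model
        params = ModelParams(0.0, 1.0, 0.0, 0.0, 2)
        real = sample_population(params, 4000, scheme="quantile", seed=10)
        res = simulate_network(real, pulse2, t_end=60.0, dt=2e-3,
                              record_stride=50, burn_in=40.0)
        assert res.asymptotic_summary["mean_abs_z"] == pytest.approx(
            np.sqrt(2) - 1, abs=0.02)

    def test_invalid_dt_rejected(self, pulse2):
        real = NetworkRealization(N=1, theta=np.zeros(1), eta=np.ones(1),
                                  k=np.zeros(1), seed=None, scheme="manual")
        with pytest.raises(ValueError):
            simulate_network(real, pulse2, dt=0.0)
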