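"""Pulse algebra, synaptic drive, reduced vector field, and Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import fsolve

from thetanet import (ModelParams, integrate_reduced, jacobian,
                      pulse_coefficients, reduced_vector_field,
                      synaptic_field, vector_field_xy)


class TestPulseCoefficients:
    def test_n1_exact(self):
        p = pulse_coefficients(1)
        assert p.a_n == pytest.approx(1.0, abs=1e-15)
        assert p.A == pytest.approx([1.0, -0.5], abs=1e-15)

    def test_n2_exact(self):
        p = pulse_coefficients(2)
        assert p.a_n == pytest.approx(2.0 / 3.0, abs=1e-15)
        assert p.A == pytest.approx([1.5, -1.0, 0.25], abs=1e-15)
        # normalization from the direct integral of (1 - cos)^2 over a period
        integral, _ = quad(lambda t: (1 - np.cos(t)) ** 2, 0, 2 * np.pi)
        assert p.a_n == pytest.approx(2 * np.pi / integral, rel=1e-12)

    @pytest.mark.parametrize("n", range(1, 10))
    def test_normalization_quadrature(self, n):
        # quadrature of a_n (1 - cos)^n over one period must give 2 pi
        p = pulse_coefficients(n)
        integral, _ = quad(p.evaluate, 0, 2 * np.pi, limit=200)
        assert integral == pytest.approx(2 * np.pi, abs=1e-9)

    @pytest.mark.parametrize("n", [1, 2, 5, 9, 15])
    def test_unit_mean_over_uniform_phases(self, n):
        p = pulse_coefficients(n)
        assert p.a_n * p.A[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", range(1, 10))
    def test_fourier_quadrature_oracle(self, n):
        # A_q are the cosine-series coefficients of the un-normalized pulse
        p = pulse_coefficients(n)
        for q in range(n + 1):
            weight = 1.0 if q == 0 else 2.0
            integral, _ = quad(
                lambda t: (1 - np.cos(t)) ** n * np.cos(q * t) / (weight * np.pi),
                0, 2 * np.pi, limit=200)
            assert integral / 2.0 * weight == pytest.approx(p.A[q], abs=1e-9)

    @pytest.mark.parametrize("bad", [0, -1, 1.5, "2", None])
    def test_invalid_n_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            pulse_coefficients(bad)


class TestSynapticField:
    def test_incoherence_gives_unit_drive(self, pulse2):
        assert synaptic_field(0.0, pulse2) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("n", [1, 2, 3, 9])
    def test_synchrony_at_rest_phase_silences_drive(self, n):
        assert synaptic_field(1.0, pulse_coefficients(n)) == pytest.approx(0.0, abs=1e-12)

    def test_synchrony_at_spike_phase(self, pulse2):
        # all mass at theta = pi: drive equals the pulse peak a_n 2^n
        assert synaptic_field(-1.0, pulse2) == pytest.approx(8.0 / 3.0, rel=1e-14)

    @pytest.mark.parametrize("n", [1, 2, 3, 9])
    def test_poisson_kernel_quadrature_oracle(self, n, rng):
        # H is the pulse averaged over the wrapped-Cauchy density with
        # centroid z; compare against direct quadrature at random z
        p = pulse_coefficients(n)
        for _ in range(25):
            z = complex(*(rng.uniform(-0.7, 0.7, 2)))
            r, psi = abs(z), np.angle(z)
            if r >= 0.98:
                continue

            def density(t):
                return (1 - r * r) / (2 * np.pi * (1 - 2 * r * np.cos(t - psi) + r * r))

            integral, _ = quad(lambda t: p.evaluate(t) * density(t),
                               0, 2 * np.pi, limit=400)
            assert integral == pytest.approx(synaptic_field(z, p), abs=1e-8)

    def test_domain_error_outside_disk(self, pulse2):
        with pytest.raises(ValueError, match="unit disk"):
            synaptic_field(1.1 + 0.2j, pulse2)

    @given(x=st.floats(-0.99, 0.99), y=st.floats(-0.99, 0.99),
           n=st.integers(1, 9))
    @settings(max_examples=60, deadline=None)
    def test_drive_nonnegative_and_bounded(self, x, y, n):
        # averaging a non-negative pulse bounded by its peak a_n 2^n
        z = complex(x, y)
        if abs(z) >= 1.0:
            return
        p = pulse_coefficients(n)
        H = synaptic_field(z, p)
        assert -1e-9 <= H <= p.a_n * 2.0 ** n + 1e-9


def luke_form(z, eta0, delta_eta, k0, pulse):
    """Independently coded reduced field for homogeneous coupling strength."""
    H = pulse.a_n * (pulse.A[0] + sum(2 * pulse.A[q] * (z ** q).real
                                      for q in range(1, pulse.n + 1)))
    return (-1j * (z - 1) ** 2 / 2
            + (z + 1) ** 2 / 2 * (-delta_eta + 1j * (eta0 + k0 * H)))


class TestReducedVectorField:
    def test_reduces_to_homogeneous_coupling_form(self, pulse2, rng):
        # with delta_k = 0 the synaptic-diversity term vanishes identically
        for _ in range(20):
            z = complex(*(rng.uniform(-0.7, 0.7, 2)))
            eta0, deta, k0 = rng.uniform(-5, 5), rng.uniform(0, 2), rng.uniform(-10, 10)
            params = ModelParams(eta0, deta, k0, 0.0, 2)
            assert reduced_vector_field(z, params, pulse2) == pytest.approx(
                luke_form(z, eta0, deta, k0, pulse2), abs=1e-12)

    def test_full_synchrony_boundary_value(self, pulse2):
        params = ModelParams(-0.3, 0.08, 5.0, 0.7, 2)
        assert reduced_vector_field(1.0, params, pulse2) == pytest.approx(
            2 * (-0.08 + 1j * -0.3), abs=1e-14)

    def test_uncoupled_equilibrium_closed_form(self, pulse2):
        # k0 = delta_k = 0, eta0 = 0, delta_eta = 1: the root of
        # ((z-1)/(z+1))^2 = i inside the disk has |z| = sqrt(2) - 1
        params = ModelParams(0.0, 1.0, 0.0, 0.0, 2)
        root = fsolve(lambda u: vector_field_xy(u, params, pulse2),
                      [0.1, -0.4], full_output=False)
        assert np.hypot(*root) == pytest.approx(np.sqrt(2) - 1, abs=1e-10)
        w = np.exp(1j * np.pi / 4)
        z_closed = (1 - w) / (1 + w)
        assert complex(root[0], root[1]) == pytest.approx(z_closed, abs=1e-9)

    def test_pulse_params_mismatch_rejected(self, pulse2):
        with pytest.raises(ValueError, match="does not match"):
            reduced_vector_field(0.0, ModelParams(0, 1, 0, 0, 3), pulse2)

    def test_forward_invariance_of_unit_disk(self, pulse2, rng):
        # trajectories started just inside |z| = 1 stay inside for t <= 100
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        for _ in range(5):
            params = ModelParams(rng.uniform(-5, 8), rng.uniform(0.05, 1.5),
                                 rng.uniform(-10, 10), rng.uniform(0, 1.5), 2)
            for a in angles:
                z0 = 0.999 * np.exp(1j * a)
                sol = integrate_reduced(z0, params, pulse2, (0.0, 100.0),
                                        rtol=1e-9, max_step=1.0)
                assert sol.success
                assert np.all(np.hypot(sol.y[0], sol.y[1]) <= 1.0 + 1e-6)


class TestJacobian:
    def test_matches_finite_differences(self, pulse2, rng):
        h = 1e-6
        for _ in range(20):
            z = complex(*(rng.uniform(-0.6, 0.6, 2)))
            params = ModelParams(rng.uniform(-5, 8), rng.uniform(0, 1.5),
                                 rng.uniform(-10, 10), rng.uniform(0, 2), 2)
            J = jacobian(z, params, pulse2).matrix
            fd = np.empty((2, 2))
            for j, dz in enumerate([h, 1j * h]):
                fp = reduced_vector_field(z + dz, params, pulse2)
                fm = reduced_vector_field(z - dz, params, pulse2)
                fd[0, j] = (fp - fm).real / (2 * h)
                fd[1, j] = (fp - fm).imag / (2 * h)
            assert J == pytest.approx(fd, abs=1e-6)

    def test_uncoupled_equilibrium_is_attracting(self, pulse2):
        params = ModelParams(0.0, 1.0, 0.0, 0.0, 2)
        w = np.exp(1j * np.pi / 4)
        z_e = (1 - w) / (1 + w)
        eig = jacobian(z_e, params, pulse2).eigenvalues
        assert np.all(eig.real < 0)

    def test_scalar_invariants_definitional(self, pulse2):
        J = jacobian(0.2 - 0.3j, ModelParams(1.0, 0.5, -3.0, 0.4, 2), pulse2)
        m = J.matrix
        assert J.trace == pytest.approx(m[0, 0] + m[1, 1], abs=1e-12)
        assert J.determinant == pytest.approx(np.linalg.det(m), rel=1e-12)
        assert J.discriminant == pytest.approx(J.trace ** 2 - 4 * J.determinant,
                                               abs=1e-12)


class TestModelParams:
    @pytest.mark.parametrize("kw", [dict(delta_eta=-0.1), dict(delta_k=-1.0),
                                    dict(n=0)])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(eta0=0.0, delta_eta=0.1, k0=0.0, delta_k=0.0, n=2)
        base.update(kw)
        with pytest.raises(ValueError):
            ModelParams(**base)
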