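"""Reduced macroscopic model of a heterogeneous theta-neuron network.

A globally coupled network of theta neurons with excitabilities ``eta_j`` and
synaptic coupling strengths ``k_j`` drawn from two independent Cauchy-Lorentz
distributions admits an exact mean-field closure: the Kuramoto order parameter
``z = <exp(i theta)>`` obeys a single complex ODE,

    dz/dt = -i (z - 1)^2 / 2
            + (z + 1)^2 / 2 * [-(delta_eta + delta_k * H(z, n))
                               + i (eta0 + k0 * H(z, n))],

where ``H(z, n)`` is the population-averaged synaptic pulse.  The pulse shape
is ``P_n(theta) = a_n (1 - cos theta)^n`` with ``a_n`` fixed so that the pulse
integrates to ``2 pi`` over one period; ``H`` is its finite Fourier expansion
evaluated against the wrapped-Cauchy phase density parameterized by ``z``.

This module holds the pulse algebra, the reduced vector field, and its exact
2x2 Jacobian with respect to ``(x, y) = (Re z, Im z)``.  Everything else in
the package (continuation, surfaces, network validation) builds on these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "DOMAIN_TOL",
    "ModelParams",
    "PulseShape",
    "JacobianInfo",
    "pulse_coefficients",
    "synaptic_field",
    "reduced_vector_field",
    "vector_field_xy",
    "jacobian",
]

#: Absolute tolerance on the unit-disk domain check |z| <= 1.  Continuation
#: steps may graze the boundary, so a strict check would be brittle.
DOMAIN_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Macroscopic parameters of the heterogeneous network.

    Parameters
    ----------
    eta0
        Center of the Cauchy-Lorentz distribution of excitabilities.
        Negative values describe predominantly excitable (resting) neurons,
        positive values predominantly spiking neurons.
    delta_eta
        Half-width at half-maximum (HWHM) of the excitability distribution;
        must be non-negative.
    k0
        Center of the coupling-strength distribution.  Negative values mean
        predominantly inhibitory synapses, positive predominantly excitatory.
    delta_k
        HWHM of the coupling-strength distribution (the "synaptic diversity");
        must be non-negative.
    n
        Sharpness exponent of the synaptic pulse; a positive integer.  Larger
        ``n`` gives a narrower pulse around the spike phase ``theta = pi``.
    """

    eta0: float
    delta_eta: float
    k0: float
    delta_k: float
    n: int = 2

    def __post_init__(self) -> None:
        if self.delta_eta < 0:
            raise ValueError(f"delta_eta must be >= 0, got {self.delta_eta}")
        if self.delta_k < 0:
            raise ValueError(f"delta_k must be >= 0, got {self.delta_k}")
        _validate_n(self.n)

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        d = dict(eta0=self.eta0, delta_eta=self.delta_eta, k0=self.k0,
                 delta_k=self.delta_k, n=self.n)
        d.update(kwargs)
        return ModelParams(**d)


def _validate_n(n) -> int:
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"pulse sharpness n must be an integer >= 1, got {n!r}")
    return int(n)


@dataclass(frozen=True)
class PulseShape:
    """Synaptic pulse ``P_n(theta) = a_n (1 - cos theta)^n`` in Fourier form.

    ``A`` holds the cosine-series coefficients ``A_0 .. A_n`` of the
    *un-normalized* pulse, so that

        (1 - cos theta)^n = A_0 + sum_{q=1..n} A_q (e^{i q theta} + e^{-i q theta}).

    The normalization ``a_n`` enforces a unit mean over uniform phases,
    ``a_n * A_0 = 1``, equivalently quadrature of ``P_n`` over one period
    equals ``2 pi``.
    """

    n: int
    a_n: float
    A: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        if self.A.shape != (self.n + 1,):
            raise ValueError("coefficient vector must have length n + 1")

    def evaluate(self, theta):
        """Evaluate ``P_n(theta)`` directly from its defining form."""
        return self.a_n * (1.0 - np.cos(theta)) ** self.n


@dataclass(frozen=True)
class JacobianInfo:
    """2x2 Jacobian of ``(dx/dt, dy/dt)`` w.r.t. ``(x, y)`` plus its scalars.

    ``discriminant = trace**2 - 4 * determinant``: negative means
    complex-conjugate eigenvalues (a focus), positive real eigenvalues
    (a node or saddle).
    """

    matrix: np.ndarray
    trace: float
    determinant: float
    discriminant: float

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.matrix)


@lru_cache(maxsize=64)
def _pulse_fractions(n: int) -> tuple:
    # Exact rational A_q = sum_{0<=m<=j<=n, j-2m=q} (-1)^q n! / (2^j m! (n-j)! (j-m)!)
    # Rational arithmetic keeps the coefficients bit-stable and overflow-free.
    fact = math.factorial
    A = [Fraction(0)] * (n + 1)
    for j in range(n + 1):
        for m in range(j + 1):
            q = j - 2 * m
            if 0 <= q <= n:
                Qjm = Fraction((-1) ** q * fact(n), 2**j * fact(m) * fact(n - j) * fact(j - m))
                A[q] += Qjm
    return tuple(A)


def pulse_coefficients(n: int) -> PulseShape:
    """Compute the normalization and Fourier coefficients of the pulse.

    The coefficients are evaluated in exact rational arithmetic and the
    normalization is obtained from them (``a_n = 1 / A_0``), which coincides
    with the closed form ``a_n = 2^n / binom(2n, n)``.

    Parameters
    ----------
    n
        Pulse sharpness; integer >= 1.

    Returns
    -------
    PulseShape
        With ``a_n`` and coefficients ``A_0 .. A_n``.
    """
    n = _validate_n(n)
    A = _pulse_fractions(n)
    a_n = 1 / A[0]
    return PulseShape(n=n, a_n=float(a_n), A=np.array([float(a) for a in A]))


def _check_domain(z: complex) -> complex:
    z = complex(z)
    if abs(z) > 1.0 + DOMAIN_TOL:
        raise ValueError(f"|z| = {abs(z):.6g} exceeds the unit disk (tolerance {DOMAIN_TOL})")
    return z


def synaptic_field(z: complex, pulse: PulseShape) -> float:
    """Rescaled synaptic drive ``H(z, n)`` felt by the population.

    ``H`` is the average of the pulse ``P_n`` over the wrapped-Cauchy
    (Poisson-kernel) phase density with centroid ``z``:

        H(z, n) = a_n * (A_0 + sum_{q=1..n} A_q (z^q + conj(z)^q)).

    It is real by construction.  ``H(0) = 1`` (unit mean over uniform phases)
    and ``H(1) = 0`` (full synchrony at the rest phase, where the pulse
    vanishes).
    """
    z = _check_domain(z)
    acc = pulse.A[0]
    zq = 1.0 + 0.0j
    for q in range(1, pulse.n + 1):
        zq *= z
        acc += 2.0 * pulse.A[q] * zq.real
    return pulse.a_n * acc


def _field_terms(z: complex, params: ModelParams, pulse: PulseShape):
    H = synaptic_field(z, pulse)
    B = 0.5 * (z + 1.0) ** 2
    G = -(params.delta_eta + params.delta_k * H) + 1j * (params.eta0 + params.k0 * H)
    return H, B, G


def reduced_vector_field(z: complex, params: ModelParams, pulse: PulseShape) -> complex:
    """Right-hand side ``dz/dt`` of the reduced order-parameter ODE."""
    if pulse.n != params.n:
        raise ValueError(f"pulse.n = {pulse.n} does not match params.n = {params.n}")
    z = _check_domain(z)
    _, B, G = _field_terms(z, params, pulse)
    return -0.5j * (z - 1.0) ** 2 + B * G


def vector_field_xy(xy, params: ModelParams, pulse: PulseShape) -> np.ndarray:
    """Real planar form ``(dx/dt, dy/dt)`` at ``z = x + i y``."""
    zdot = reduced_vector_field(complex(xy[0], xy[1]), params, pulse)
    return np.array([zdot.real, zdot.imag])


def _H_partials(z: complex, pulse: PulseShape):
    # d(Re z^q)/dx = q Re z^{q-1};  d(Re z^q)/dy = -q Im z^{q-1}
    Hx = 0.0
    Hy = 0.0
    zq = 1.0 + 0.0j  # z^{q-1}
    for q in range(1, pulse.n + 1):
        Hx += 2.0 * pulse.A[q] * q * zq.real
        Hy -= 2.0 * pulse.A[q] * q * zq.imag
        zq *= z
    return pulse.a_n * Hx, pulse.a_n * Hy


def jacobian(z: complex, params: ModelParams, pulse: PulseShape) -> JacobianInfo:
    """Exact Jacobian of the planar vector field at ``z``.

    Writing the complex field as ``F(z, H)`` with ``H = H(x, y)``, the chain
    rule gives ``dF/dx = F_z + F_H H_x`` and ``dF/dy = i F_z + F_H H_y``,
    where ``F_z`` is the holomorphic derivative at fixed ``H``.  All partials
    are closed-form; no differencing is involved.
    """
    z = _check_domain(z)
    _, B, G = _field_terms(z, params, pulse)
    Fz = -1j * (z - 1.0) + (z + 1.0) * G
    FH = B * (-params.delta_k + 1j * params.k0)
    Hx, Hy = _H_partials(z, pulse)
    dFdx = Fz + FH * Hx
    dFdy = 1j * Fz + FH * Hy
    m = np.array([[dFdx.real, dFdy.real], [dFdx.imag, dFdy.imag]])
    tr = m[0, 0] + m[1, 1]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return JacobianInfo(matrix=m, trace=tr, determinant=det, discriminant=tr * tr - 4.0 * det)
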