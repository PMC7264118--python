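"""First Lyapunov coefficient of Hopf bifurcations of the reduced flow.

The reduced vector field is polynomial in ``(x, y)`` of degree ``n + 2``, so
its partial derivatives up to third order are computed exactly (symbolically,
once per pulse sharpness ``n``, then compiled to numeric functions).  At a
Hopf point the field is transformed to the planar normal-form frame
``(u, v)`` in which the linearization is ``[[0, -omega], [omega, 0]]``, and
the cubic coefficient ``a`` of the radial normal form ``r' = a r^3 + ...`` is
evaluated with the standard planar formula

    16 a = F_uuu + F_uvv + G_uuv + G_vvv
           + (1/omega) [ F_uv (F_uu + F_vv) - G_uv (G_uu + G_vv)
                         - F_uu G_uu + F_vv G_vv ],

where ``F, G`` are the nonlinear parts in that frame.  ``a > 0`` means the
Hopf is subcritical (an unstable cycle exists alongside the stable focus);
``a < 0`` supercritical (a stable cycle is born).  ``a`` passing through zero
marks a Bautin (generalized Hopf) point.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Tuple

import numpy as np

from .model import ModelParams, PulseShape, jacobian, pulse_coefficients

__all__ = ["first_lyapunov_coefficient", "lyapunov_coefficient_at"]

#: |l1| below this at a Hopf point is flagged as a Bautin candidate.
BAUTIN_TOL = 1e-6
#: How exactly the Hopf test functions must hold at the input point.
HOPF_CHECK_TOL = 1e-6


@lru_cache(maxsize=16)
def _derivative_funcs(n: int):
    """Compiled exact partials of (f, g) up to third order, for pulse n."""
    import sympy as sp

    x, y, eta0, deta, k0, dk = sp.symbols("x y eta0 deta k0 dk", real=True)
    pulse = pulse_coefficients(n)
    z = x + sp.I * y
    H = sp.Rational(0)
    A = [sp.nsimplify(a, rational=True) for a in pulse.A]
    a_n = sp.nsimplify(pulse.a_n, rational=True)
    H = A[0]
    for q in range(1, n + 1):
        H += 2 * A[q] * sp.re(sp.expand(z**q))
    H = a_n * H
    zdot = (-sp.I * (z - 1) ** 2 / 2
            + (z + 1) ** 2 / 2 * (-(deta + dk * H) + sp.I * (eta0 + k0 * H)))
    f = sp.expand(sp.re(sp.expand(zdot)))
    g = sp.expand(sp.im(sp.expand(zdot)))
    vars2 = [(x, x), (x, y), (y, y)]
    vars3 = [(x, x, x), (x, x, y), (x, y, y), (y, y, y)]
    exprs = []
    for expr in (f, g):
        exprs.extend(sp.diff(expr, *v) for v in vars2)
        exprs.extend(sp.diff(expr, *v) for v in vars3)
    return sp.lambdify((x, y, eta0, deta, k0, dk), exprs, modules="numpy")


def _derivative_tensors(z: complex, params: ModelParams):
    """Symmetric 2nd/3rd derivative tensors of the planar field at ``z``."""
    vals = _derivative_funcs(params.n)(z.real, z.imag, params.eta0,
                                       params.delta_eta, params.k0, params.delta_k)
    D2 = np.empty((2, 2, 2))
    D3 = np.empty((2, 2, 2, 2))
    for i in range(2):
        fxx, fxy, fyy, fxxx, fxxy, fxyy, fyyy = vals[7 * i: 7 * (i + 1)]
        D2[i] = [[fxx, fxy], [fxy, fyy]]
        D3[i, 0, 0, 0] = fxxx
        D3[i, 0, 0, 1] = D3[i, 0, 1, 0] = D3[i, 1, 0, 0] = fxxy
        D3[i, 0, 1, 1] = D3[i, 1, 0, 1] = D3[i, 1, 1, 0] = fxyy
        D3[i, 1, 1, 1] = fyyy
    return D2, D3


def lyapunov_coefficient_at(z: complex, params: ModelParams,
                            pulse: PulseShape) -> float:
    """Cubic normal-form coefficient ``a`` at a Hopf equilibrium ``z``.

    Assumes ``z`` is an equilibrium with ``tr J = 0`` and ``det J > 0``;
    no checks are performed here (see :func:`first_lyapunov_coefficient`).
    """
    J = jacobian(z, params, pulse)
    omega = float(np.sqrt(J.determinant))
    # real eigenbasis: J q = i omega q; columns (Re q, -Im q) give the
    # canonical frame with linear part [[0, -omega], [omega, 0]]
    M = J.matrix
    # eigenvector for +i omega: (M - i omega I) q = 0
    q = np.array([-(M[0, 1]), M[0, 0] - 1j * omega])
    if np.allclose(q, 0):
        q = np.array([M[1, 1] - 1j * omega, -M[1, 0]])
    A = np.column_stack([q.real, -q.imag])
    S = np.linalg.inv(A)
    D2, D3 = _derivative_tensors(z, params)
    P2 = np.einsum("ip,pqr,qa,rb->iab", S, D2, A, A)
    P3 = np.einsum("ip,pqrs,qa,rb,sc->iabc", S, D3, A, A, A)
    Fuu, Fuv, Fvv = P2[0, 0, 0], P2[0, 0, 1], P2[0, 1, 1]
    Guu, Guv, Gvv = P2[1, 0, 0], P2[1, 0, 1], P2[1, 1, 1]
    Fuuu, Fuvv = P3[0, 0, 0, 0], P3[0, 0, 1, 1]
    Guuv, Gvvv = P3[1, 0, 0, 1], P3[1, 1, 1, 1]
    a = (Fuuu + Fuvv + Guuv + Gvvv) / 16.0 + (
        Fuv * (Fuu + Fvv) - Guv * (Guu + Gvv) - Fuu * Guu + Fvv * Gvv
    ) / (16.0 * omega)
    return float(a)


def first_lyapunov_coefficient(hopf, params: ModelParams,
                               pulse: PulseShape) -> Tuple[float, str]:
    """Classify a detected Hopf point as sub- or supercritical.

    Parameters
    ----------
    hopf
        A :class:`~thetanet.continuation.BifurcationPoint` of kind ``hopf``
        (or any object with ``z``, ``param_name`` and ``value`` attributes).
    params, pulse
        Model configuration; the sweep parameter is overridden with the
        point's value.

    Returns
    -------
    (l1, label)
        The signed coefficient and ``"subcritical"`` (l1 > 0),
        ``"supercritical"`` (l1 < 0), or ``"bautin-candidate"``
        (|l1| < ``BAUTIN_TOL``).
    """
    p = params.replace(**{hopf.param_name: hopf.value})
    J = jacobian(hopf.z, p, pulse)
    if abs(J.trace) > HOPF_CHECK_TOL or J.determinant <= 0:
        raise ValueError(
            f"not a Hopf point: tr J = {J.trace:.3g}, det J = {J.determinant:.3g}")
    l1 = lyapunov_coefficient_at(hopf.z, p, pulse)
    if abs(l1) < BAUTIN_TOL:
        label = "bautin-candidate"
    elif l1 > 0:
        label = "subcritical"
    else:
        label = "supercritical"
    return l1, label
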