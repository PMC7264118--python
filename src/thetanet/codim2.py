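"""Two-parameter tracking of Hopf points: Bautin point and Hopf disappearance.

A Hopf point of the reduced flow satisfies the three defining equations

    f(x, y; k0) = 0,   g(x, y; k0) = 0,   tr J(x, y; k0) = 0,

subject to ``det J > 0``.  At fixed pulse sharpness and excitability
distribution, these three equations in the four unknowns ``(x, y, k0,
delta_k)`` define a curve: the Hopf curve in the ``(k0, delta_k)`` plane.
This module continues that curve by pseudo-arclength from a Hopf point found
at ``delta_k = 0`` and detects two codimension-2 events along it:

* a **Bautin (generalized Hopf) point**, where the first Lyapunov
  coefficient changes sign — the boundary between sub- and supercritical
  Hopf bifurcations;
* a **fold of the Hopf curve** in ``delta_k`` (largest synaptic diversity at
  which any Hopf bifurcation survives on the sweep line), where the two Hopf
  points of the one-parameter diagrams coalesce and disappear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .continuation import BifurcationPoint, continue_equilibria
from .lyapunov import lyapunov_coefficient_at
from .model import ModelParams, PulseShape, jacobian, pulse_coefficients, \
    reduced_vector_field

__all__ = ["HopfCurve", "codim2_scan", "continue_hopf_curve", "hopf_points_at"]

#: Localization tolerance in delta_k for Bautin and hopf-fold events.
CODIM2_TOL = 1e-3


@dataclass
class HopfCurve:
    """Sampled Hopf curve in the (sweep parameter, delta_k) plane."""

    sweep_name: str
    points: List[np.ndarray]  # each (x, y, sweep_value, delta_k)
    l1: List[float]
    events: List[BifurcationPoint] = field(default_factory=list)
    termination: str = "range-exhausted"

    def to_frame(self):
        import pandas as pd

        rows = [dict(x=u[0], y=u[1], **{self.sweep_name: u[2]},
                     delta_k=u[3], l1=l) for u, l in zip(self.points, self.l1)]
        return pd.DataFrame(rows)


def _hopf_system(u: np.ndarray, params: ModelParams, pulse: PulseShape,
                 sweep_name: str) -> Optional[np.ndarray]:
    x, y, pv, dk = u
    if dk < 0 or np.hypot(x, y) > 1.0 + 1e-6:
        return None
    p = params.replace(delta_k=float(dk), **{sweep_name: float(pv)})
    z = complex(x, y)
    if abs(z) > 1.0:
        z /= abs(z)
    zdot = reduced_vector_field(z, p, pulse)
    tr = jacobian(z, p, pulse).trace
    return np.array([zdot.real, zdot.imag, tr])


def _hopf_jacobian(u: np.ndarray, params: ModelParams, pulse: PulseShape,
                   sweep_name: str, h: float = 1e-7) -> Optional[np.ndarray]:
    # central differences on the smooth polynomial defining system
    A = np.empty((3, 4))
    for j in range(4):
        up, um = u.copy(), u.copy()
        up[j] += h
        um[j] -= h
        if um[3] < 0:  # keep delta_k evaluations non-negative
            um[3] = 0.0
            up[3] = 2 * h
        fp = _hopf_system(up, params, pulse, sweep_name)
        fm = _hopf_system(um, params, pulse, sweep_name)
        if fp is None or fm is None:
            return None
        A[:, j] = (fp - fm) / (up[j] - um[j])
    return A


def _hopf_corrector(u_pred, tangent, params, pulse, sweep_name,
                    tol=1e-11, max_iter=15) -> Optional[np.ndarray]:
    u = u_pred.copy()
    for _ in range(max_iter):
        g3 = _hopf_system(u, params, pulse, sweep_name)
        if g3 is None:
            return None
        g = np.append(g3, tangent @ (u - u_pred))
        if np.max(np.abs(g3)) < tol and abs(g[3]) < 1e-10:
            return u
        A3 = _hopf_jacobian(u, params, pulse, sweep_name)
        if A3 is None:
            return None
        A = np.vstack([A3, tangent])
        try:
            step = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:
            return None
        u = u + step
        if not np.all(np.isfinite(u)) or np.linalg.norm(step) > 1.0:
            return None
    g3 = _hopf_system(u, params, pulse, sweep_name)
    if g3 is not None and np.max(np.abs(g3)) < 1e-9:
        return u
    return None


def _l1_at(u, params, pulse, sweep_name) -> float:
    p = params.replace(delta_k=float(max(u[3], 0.0)), **{sweep_name: float(u[2])})
    return lyapunov_coefficient_at(complex(u[0], u[1]), p, pulse)


def hopf_points_at(params: ModelParams, sweep_name: str,
                   sweep_range: Tuple[float, float],
                   pulse: Optional[PulseShape] = None) -> List[BifurcationPoint]:
    """Hopf points found by a fresh one-parameter sweep (used for seeding
    the curve and as an independent counting oracle)."""
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    out = []
    for direction in (+1.0,):
        for br in continue_equilibria(params, sweep_name, sweep_range,
                                      pulse=pulse, direction=direction):
            out.extend(br.events_of("hopf"))
    # dedupe
    uniq: List[BifurcationPoint] = []
    for e in out:
        if not any(abs(e.value - o.value) < 1e-5 and abs(e.z - o.z) < 1e-4
                   for o in uniq):
            uniq.append(e)
    uniq.sort(key=lambda e: e.value)
    return uniq


def continue_hopf_curve(
    params: ModelParams,
    sweep_name: str,
    sweep_range: Tuple[float, float],
    delta_k_range: Tuple[float, float] = (0.0, 2.0),
    pulse: Optional[PulseShape] = None,
    initial_step: float = 5e-3,
    max_step: float = 0.05,
    min_step: float = 1e-8,
    max_steps: int = 40000,
) -> HopfCurve:
    """Trace the Hopf curve from ``delta_k_range[0]`` and attach codim-2 events.

    The curve is seeded by a one-parameter sweep at the starting ``delta_k``.
    Continuation proceeds by pseudo-arclength, so the fold of the curve at
    the maximal ``delta_k`` is traversed smoothly; there the curve turns back
    toward smaller ``delta_k`` (the second Hopf point of the one-parameter
    diagrams).  Events:

    * ``bautin`` where the first Lyapunov coefficient crosses zero,
      localized in ``delta_k`` to :data:`CODIM2_TOL`;
    * ``hopf-fold`` at the fold, localized likewise; its ``value`` is the
      largest ``delta_k`` at which a Hopf point exists on the sweep line.
    """
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    dk_lo, dk_hi = delta_k_range
    p0 = params.replace(delta_k=dk_lo)
    seeds = hopf_points_at(p0, sweep_name, sweep_range, pulse)
    if not seeds:
        return HopfCurve(sweep_name=sweep_name, points=[], l1=[],
                         events=[], termination="no-hopf-at-start")
    seed = seeds[0]
    u0 = np.array([seed.z.real, seed.z.imag, seed.value, dk_lo])
    u0 = _hopf_corrector(u0, np.array([0.0, 0.0, 0.0, 1.0]), params, pulse,
                         sweep_name) if False else u0

    # initial tangent: null space of the 3x4 Jacobian, oriented toward +delta_k
    A = _hopf_jacobian(u0, params, pulse, sweep_name)
    _, _, Vt = np.linalg.svd(A)
    tangent = Vt[-1]
    if tangent[3] < 0:
        tangent = -tangent

    us = [u0]
    l1s = [_l1_at(u0, params, pulse, sweep_name)]
    h = initial_step
    termination = "range-exhausted"
    steps = fails = 0
    while steps < max_steps:
        steps += 1
        u_prev = us[-1]
        u_pred = u_prev + h * tangent
        u_new = _hopf_corrector(u_pred, tangent, params, pulse, sweep_name)
        if u_new is None:
            h *= 0.5
            fails += 1
            if h < min_step or fails > 80:
                termination = "corrector-divergence"
                break
            continue
        fails = 0
        # genuine Hopf requires det J > 0; stop at a Bogdanov-Takens end
        p = params.replace(delta_k=float(max(u_new[3], 0.0)),
                           **{sweep_name: float(u_new[2])})
        det = jacobian(complex(u_new[0], u_new[1]), p, pulse).determinant
        if det <= 0:
            termination = "bogdanov-takens"
            break
        us.append(u_new)
        l1s.append(_l1_at(u_new, params, pulse, sweep_name))
        nt = u_new - u_prev
        nn = np.linalg.norm(nt)
        if nn > 0:
            tangent = nt / nn
        h = min(h * 1.3, max_step)
        if u_new[3] > dk_hi or u_new[3] < dk_lo - 1e-12:
            termination = "range-exhausted"
            break
        if not (min(sweep_range) - 1e-9 <= u_new[2] <= max(sweep_range) + 1e-9):
            termination = "left-sweep-range"
            break

    curve = HopfCurve(sweep_name=sweep_name, points=us, l1=l1s,
                      termination=termination)
    _attach_codim2_events(curve, params, pulse, sweep_name)
    return curve


def _attach_codim2_events(curve: HopfCurve, params, pulse, sweep_name) -> None:
    us, l1s = curve.points, curve.l1
    events = curve.events
    # Bautin: l1 sign change along the curve, bisected on the chord
    for i in range(len(us) - 1):
        if l1s[i] == 0.0 or np.sign(l1s[i]) == np.sign(l1s[i + 1]):
            continue
        u_a, u_b = us[i], us[i + 1]
        chord = u_b - u_a
        tangent = chord / np.linalg.norm(chord)
        lo, hi = 0.0, 1.0
        sa = np.sign(l1s[i])
        u_star, l_star = u_a, l1s[i]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            u_mid = _hopf_corrector(u_a + mid * chord, tangent, params, pulse,
                                    sweep_name)
            if u_mid is None:
                break
            lm = _l1_at(u_mid, params, pulse, sweep_name)
            u_star, l_star = u_mid, lm
            if np.sign(lm) == sa:
                lo = mid
            else:
                hi = mid
            if (hi - lo) * abs(chord[3]) < 0.1 * CODIM2_TOL:
                break
        events.append(BifurcationPoint(
            kind="bautin", param_name="delta_k", value=float(u_star[3]),
            z=complex(u_star[0], u_star[1]),
            auxiliary={"l1": float(l_star), sweep_name: float(u_star[2])},
            bracket_width=float((hi - lo) * abs(chord[3]))))
    # fold of the curve in delta_k: sign change of the delta_k tangent component
    dks = np.array([u[3] for u in us])
    for i in range(1, len(us) - 1):
        if dks[i] >= dks[i - 1] and dks[i] >= dks[i + 1]:
            # local max: refine by arclength bisection on the tangent component
            u_star, width = _refine_fold(us[i - 1], us[i], us[i + 1], params,
                                         pulse, sweep_name)
            events.append(BifurcationPoint(
                kind="hopf-fold", param_name="delta_k", value=float(u_star[3]),
                z=complex(u_star[0], u_star[1]),
                auxiliary={sweep_name: float(u_star[2])},
                bracket_width=float(width)))
    events.sort(key=lambda e: e.value)


def _refine_fold(u_a, u_m, u_b, params, pulse, sweep_name):
    """Maximize delta_k along the curve near a discrete local maximum by
    golden-section search on the chord parameter."""
    gr = 0.5 * (np.sqrt(5.0) - 1.0)

    def dk_at(t):
        # piecewise-linear predictor through (u_a, u_m, u_b), corrected
        if t <= 0.5:
            pred = u_a + 2 * t * (u_m - u_a)
            tang = (u_m - u_a) / np.linalg.norm(u_m - u_a)
        else:
            pred = u_m + 2 * (t - 0.5) * (u_b - u_m)
            tang = (u_b - u_m) / np.linalg.norm(u_b - u_m)
        u = _hopf_corrector(pred, tang, params, pulse, sweep_name)
        return (u[3], u) if u is not None else (-np.inf, None)

    lo, hi = 0.0, 1.0
    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc, uc = dk_at(c)
    fd, ud = dk_at(d)
    best = max([(fc, uc), (fd, ud)], key=lambda t: t[0])
    for _ in range(60):
        if fc >= fd:
            hi, d, fd, ud = d, c, fc, uc
            c = hi - gr * (hi - lo)
            fc, uc = dk_at(c)
        else:
            lo, c, fc, uc = c, d, fd, ud
            d = lo + gr * (hi - lo)
            fd, ud = dk_at(d)
        cand = max([(fc, uc), (fd, ud)], key=lambda t: t[0])
        if cand[0] > best[0]:
            best = cand
        if abs(fc - fd) < 1e-12 and (hi - lo) < 1e-6:
            break
    width = abs(fc - fd) if np.isfinite(fc) and np.isfinite(fd) else np.nan
    return best[1], width


def codim2_scan(
    params: ModelParams,
    sweep_name: str,
    sweep_range: Tuple[float, float],
    delta_k_range: Tuple[float, float] = (0.0, 2.0),
    pulse: Optional[PulseShape] = None,
) -> List[BifurcationPoint]:
    """Codim-2 events (Bautin, Hopf fold) from continuing the Hopf curve.

    Returns an empty list when no Hopf point exists at the start of
    ``delta_k_range`` (nothing to continue).
    """
    curve = continue_hopf_curve(params, sweep_name, sweep_range,
                                delta_k_range, pulse=pulse)
    return curve.events
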