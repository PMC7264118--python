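"""Limit-cycle location and branch continuation for the reduced flow.

Cycles are located by single shooting on a Poincare section: a horizontal
line ``y = y_sec`` through the cycle's mean, with unknowns ``(x_start,
period)`` and residual ``Phi_T(x_start, y_sec) - (x_start, y_sec)``.  A seed
orbit is obtained by direct integration near a Hopf point — forward in time
for a stable (supercritical-side) cycle, backward for an unstable
(subcritical-side) one, since reversing time swaps the cycle's stability.

Branches are continued in one macroscopic parameter by pseudo-arclength on
``(x_start, period, parameter)``, so folds of the cycle branch — saddle-node
of periodic orbits (SNPO), where a stable and an unstable cycle coalesce —
are traversed and reported.  The nontrivial Floquet multiplier is computed
exactly for this planar flow as ``exp(integral of div f over one period)``;
it crosses 1 at an SNPO.

Near a homoclinic connection the period diverges only logarithmically in the
parameter, so the branch terminates with a ``homoclinic`` event when the
period exceeds a threshold or when continuation stalls while the orbit
passes within ``homoclinic_dist_tol`` of a saddle equilibrium with growing
period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .continuation import BifurcationPoint
from .equilibria import find_equilibria, newton_equilibrium
from .model import ModelParams, PulseShape, pulse_coefficients

__all__ = ["CycleRecord", "LimitCycleBranch", "find_cycle", "seed_cycle",
           "limit_cycle_branch", "integrate_reduced"]


@dataclass
class CycleRecord:
    """One converged periodic orbit."""

    param_value: float
    period: float
    x_section: float
    y_section: float
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    multiplier: float  # nontrivial Floquet multiplier
    min_saddle_dist: float

    @property
    def stable(self) -> bool:
        return abs(self.multiplier) < 1.0


@dataclass
class LimitCycleBranch:
    """Ordered cycle samples along a sweep, with attached events."""

    param_name: str
    cycles: List[CycleRecord]
    events: List[BifurcationPoint] = field(default_factory=list)
    termination: str = "range-exhausted"

    def __len__(self) -> int:
        return len(self.cycles)

    def events_of(self, kind: str) -> List[BifurcationPoint]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([c.__dict__ for c in self.cycles])


class _FastField:
    """Plain-float evaluator of the reduced field and its divergence.

    The shooting loops spend nearly all their time in RHS calls, so the
    coefficient lookups and domain checks of the public API are hoisted out
    once per parameter set here.  Matches ``reduced_vector_field`` /
    ``jacobian`` to machine precision (asserted in the tests).
    """

    def __init__(self, params: ModelParams, pulse: PulseShape):
        self.a = float(pulse.a_n)
        self.A = [float(a) for a in pulse.A]
        self.n = pulse.n
        self.c1 = complex(-params.delta_eta, params.eta0)
        self.c2 = complex(-params.delta_k, params.k0)

    def _H(self, z: complex) -> float:
        acc = self.A[0]
        zq = 1.0 + 0.0j
        for q in range(1, self.n + 1):
            zq *= z
            acc += 2.0 * self.A[q] * zq.real
        return self.a * acc

    def zdot(self, z: complex) -> complex:
        r = abs(z)
        if r > 1.0:
            z /= r
        B = 0.5 * (z + 1.0) ** 2
        return -0.5j * (z - 1.0) ** 2 + B * (self.c1 + self.c2 * self._H(z))

    def trace(self, z: complex) -> float:
        r = abs(z)
        if r > 1.0:
            z /= r
        G = self.c1 + self.c2 * self._H(z)
        Fz = -1j * (z - 1.0) + (z + 1.0) * G
        B = 0.5 * (z + 1.0) ** 2
        Hx = 0.0
        Hy = 0.0
        zq = 1.0 + 0.0j
        for q in range(1, self.n + 1):
            Hx += 2.0 * self.A[q] * q * zq.real
            Hy -= 2.0 * self.A[q] * q * zq.imag
            zq *= z
        FH = B * self.c2
        dFdx = Fz + FH * (self.a * Hx)
        dFdy = 1j * Fz + FH * (self.a * Hy)
        return dFdx.real + dFdy.imag


def _rhs(params: ModelParams, pulse: PulseShape, sign: float = 1.0):
    ff = _FastField(params, pulse)

    def f(t, u):
        zd = ff.zdot(complex(u[0], u[1]))
        return (sign * zd.real, sign * zd.imag)

    return f


def integrate_reduced(z0: complex, params: ModelParams,
                      pulse: Optional[PulseShape] = None,
                      t_span: Tuple[float, float] = (0.0, 100.0),
                      reverse: bool = False, rtol: float = 1e-10,
                      atol: float = 1e-12, **kw):
    """Integrate the reduced planar ODE from ``z0`` (scipy ``solve_ivp``)."""
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    return solve_ivp(_rhs(params, pulse, -1.0 if reverse else 1.0), t_span,
                     [z0.real, z0.imag], rtol=rtol, atol=atol, **kw)


def _flow(u0, T, params, pulse, rtol=1e-11):
    # high-order method: the shooting Newton differences these endpoints
    sol = solve_ivp(_rhs(params, pulse), (0.0, T), list(u0), rtol=rtol,
                    atol=1e-12, method="DOP853", dense_output=False)
    return sol.y[:, -1]


def _shoot_residual(x, T, y_sec, params, pulse):
    end = _flow((x, y_sec), T, params, pulse)
    return np.array([end[0] - x, end[1] - y_sec])


def _newton_cycle(x0, T0, y_sec, params, pulse, tol=1e-9, max_iter=12):
    """Newton on the 2-unknown shooting system at fixed parameters."""
    x, T = x0, T0
    for _ in range(max_iter):
        r = _shoot_residual(x, T, y_sec, params, pulse)
        if np.max(np.abs(r)) < tol:
            return x, T
        hx = 1e-6 * max(1.0, abs(x))
        hT = 1e-6 * max(1.0, T)
        Jx = (_shoot_residual(x + hx, T, y_sec, params, pulse)
              - _shoot_residual(x - hx, T, y_sec, params, pulse)) / (2 * hx)
        JT = (_shoot_residual(x, T + hT, y_sec, params, pulse)
              - _shoot_residual(x, T - hT, y_sec, params, pulse)) / (2 * hT)
        try:
            step = np.linalg.solve(np.column_stack([Jx, JT]), -r)
        except np.linalg.LinAlgError:
            return None
        x, T = x + step[0], T + step[1]
        if not (np.isfinite(x) and np.isfinite(T)) or T <= 0 or T > 1e4:
            return None
    return None


def _cycle_record(x, T, y_sec, pv, params, pulse, saddles=None) -> CycleRecord:
    sol = solve_ivp(_rhs(params, pulse), (0.0, T), [x, y_sec], rtol=1e-10,
                    atol=1e-12, method="DOP853", dense_output=True)
    ts = np.linspace(0.0, T, 400)
    u = sol.sol(ts)
    if saddles is None:
        saddles = [e.z_e for e in find_equilibria(params, pulse)
                   if e.label == "saddle"]
    if saddles:
        dmin = min(float(np.min(np.hypot(u[0] - s.real, u[1] - s.imag)))
                   for s in saddles)
    else:
        dmin = np.inf
    # planar Floquet multiplier: exp of the integrated divergence
    ff = _FastField(params, pulse)
    div = np.array([ff.trace(complex(a, b)) for a, b in zip(u[0], u[1])])
    mult = float(np.exp(np.trapezoid(div, ts)))
    return CycleRecord(param_value=pv, period=float(T), x_section=float(x),
                       y_section=float(y_sec),
                       x_min=float(u[0].min()), x_max=float(u[0].max()),
                       y_min=float(u[1].min()), y_max=float(u[1].max()),
                       multiplier=mult, min_saddle_dist=dmin)


def _extract_seed(sol_t, sol_y) -> Optional[Tuple[float, float, float]]:
    """Pull (x_start, period, y_sec) out of a settled trajectory tail."""
    x, y = sol_y
    if x.max() - x.min() < 1e-5 and y.max() - y.min() < 1e-5:
        return None  # converged to an equilibrium, no cycle here
    y_sec = 0.5 * (y.min() + y.max())
    cross = []
    for i in range(len(x) - 1):
        if y[i] < y_sec <= y[i + 1]:
            f = (y_sec - y[i]) / (y[i + 1] - y[i])
            cross.append((sol_t[i] + f * (sol_t[i + 1] - sol_t[i]),
                          x[i] + f * (x[i + 1] - x[i])))
    if len(cross) < 3:
        return None
    T = float(np.mean(np.diff([c[0] for c in cross[-4:]])))
    return cross[-1][1], T, y_sec


def seed_cycle(params: ModelParams, pulse: PulseShape, near: complex,
               reverse: bool, t_chunk: float = 300.0, t_max: float = 4000.0,
               perturbation: float = 5e-3) -> Optional[Tuple[float, float, float]]:
    """Converge onto a cycle by (possibly time-reversed) integration.

    Returns ``(x_start, period, y_section)`` or ``None``.  ``reverse=True``
    targets an unstable cycle (attracting in reverse time).  Near a Hopf
    point the transient decays slowly, so integration proceeds in chunks
    until the orbit's amplitude stops changing.
    """
    u = np.array([near.real + perturbation, near.imag])
    prev_amp = None
    t_done = 0.0
    while t_done < t_max:
        sol = integrate_reduced(complex(u[0], u[1]), params, pulse,
                                (0.0, t_chunk), reverse=reverse, rtol=1e-8,
                                max_step=0.5)
        if not sol.success:
            return None
        u = sol.y[:, -1]
        t_done += t_chunk
        tail = sol.t > 0.5 * t_chunk
        x, y = sol.y[:, tail]
        amp = x.max() - x.min()
        if amp < 1e-6 and t_done >= 2 * t_chunk:
            return None  # spiralled into an equilibrium
        if prev_amp is not None and amp > 1e-5 and \
                abs(amp - prev_amp) < 5e-3 * max(amp, prev_amp):
            return _extract_seed(sol.t[tail], sol.y[:, tail])
        prev_amp = amp
    if prev_amp and prev_amp > 1e-5:
        return _extract_seed(sol.t[tail], sol.y[:, tail])
    return None


def find_cycle(params: ModelParams, pulse: Optional[PulseShape] = None,
               near: Optional[complex] = None,
               reverse: bool = False) -> Optional[CycleRecord]:
    """Locate one periodic orbit: integrate to settle, then shoot to polish."""
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    if near is None:
        eqs = find_equilibria(params, pulse)
        foci = [e for e in eqs if "focus" in e.label]
        near = foci[0].z_e if foci else 0.1 + 0.0j
    seed = seed_cycle(params, pulse, near, reverse)
    if seed is None:
        return None
    x0, T0, y_sec = seed
    polished = _newton_cycle(x0, T0, y_sec, params, pulse)
    if polished is None:
        return None
    x, T = polished
    return _cycle_record(x, T, y_sec, np.nan, params, pulse)


# --- branch continuation ----------------------------------------------------

#: Scale applied to the period coordinate in the arclength metric, so that
#: period blow-up near a homoclinic drives the steps rather than stalling them.
PERIOD_SCALE = 25.0


def _branch_residual(v, y_sec, params, pulse, name):
    x, T, pv = v
    p = params.replace(**{name: float(pv)})
    return _shoot_residual(x, T, y_sec, p, pulse)


def _branch_corrector(v_pred, tangent, y_sec, params, pulse, name,
                      tol=1e-9, max_iter=6):
    v = v_pred.copy()
    scale = np.array([1.0, PERIOD_SCALE, 1.0])
    r0 = None
    for _ in range(max_iter):
        r = _branch_residual(v, y_sec, params, pulse, name)
        if r0 is None:
            r0 = np.max(np.abs(r))
        elif np.max(np.abs(r)) > 10.0 * max(r0, 1e-6):
            return None
        g = np.append(r, tangent @ ((v - v_pred) / scale))
        if np.max(np.abs(r)) < tol and abs(g[2]) < 1e-9:
            return v
        A = np.empty((3, 3))
        h = np.array([1e-7 * max(1.0, abs(v[0])), 1e-7 * max(1.0, v[1]), 1e-7])
        for j in range(3):
            vp = v.copy()
            vp[j] += h[j]
            A[:2, j] = (_branch_residual(vp, y_sec, params, pulse, name) - r) / h[j]
        A[2] = tangent / scale
        try:
            step = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:
            return None
        v = v + step
        if not np.all(np.isfinite(v)) or v[1] <= 0 or v[1] > 1e4:
            return None
    r = _branch_residual(v, y_sec, params, pulse, name)
    return v if np.max(np.abs(r)) < 1e-7 else None


def limit_cycle_branch(
    params: ModelParams,
    param_name: str,
    p_range: Tuple[float, float],
    init: Optional[BifurcationPoint] = None,
    init_state: Optional[Tuple[float, float, float, float]] = None,
    pulse: Optional[PulseShape] = None,
    hopf_offset: float = 0.1,
    initial_step: float = 2e-2,
    max_step: float = 0.25,
    min_step: float = 1e-7,
    max_steps: int = 3000,
    period_threshold: float = 500.0,
    homoclinic_dist_tol: float = 1e-3,
) -> LimitCycleBranch:
    """Continue a cycle branch seeded from a Hopf point or an explicit orbit.

    ``init`` is a Hopf :class:`BifurcationPoint` from ``continue_equilibria``
    on the same sweep; the cycle is seeded a distance ``hopf_offset`` past it
    on whichever side (and time direction) yields an orbit.  Alternatively
    ``init_state = (x_start, period, y_section, param_value)`` gives the
    starting cycle directly.

    Events attached: ``snpo`` at folds of the branch in the sweep parameter
    (multiplier crossing 1), ``homoclinic`` at termination with diverging
    period near a saddle.
    """
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    p_lo, p_hi = min(p_range), max(p_range)

    if init_state is not None:
        x0, T0, y_sec, pv0 = init_state
        polished = _newton_cycle(x0, T0, y_sec,
                                 params.replace(**{param_name: pv0}), pulse)
        if polished is None:
            return LimitCycleBranch(param_name, [], termination="seed-failed")
        seeds = [(polished[0], polished[1], y_sec, pv0)]
    elif init is not None:
        # the cycle may exist only in a narrow window next to the Hopf
        # (e.g. just before an SNPO), so shrink the offset on failure
        seeds = []
        for offset in (hopf_offset, hopf_offset / 2, hopf_offset / 5):
            for reverse in (False, True):
                for side in (-1.0, +1.0):
                    pv0 = init.value + side * offset
                    if not (p_lo <= pv0 <= p_hi):
                        continue
                    p = params.replace(**{param_name: pv0})
                    s = seed_cycle(p, pulse, init.z, reverse)
                    if s is None:
                        continue
                    polished = _newton_cycle(s[0], s[1], s[2], p, pulse)
                    if polished is not None:
                        seeds.append((polished[0], polished[1], s[2], pv0))
                        break
                if seeds:
                    break
            if seeds:
                break
        if not seeds:
            return LimitCycleBranch(param_name, [], termination="no-cycle-from-seed")
    else:
        raise ValueError("provide init (Hopf point) or init_state")

    x0, T0, y_sec, pv0 = seeds[0]
    p_seed = params.replace(**{param_name: pv0})
    # saddles are tracked by warm-started Newton along the sweep: a full
    # grid search at every continuation step would dominate the runtime
    saddle_zs = [e.z_e for e in find_equilibria(p_seed, pulse)
                 if e.label == "saddle"]

    def _update_saddles(p_new):
        kept = []
        for zs in saddle_zs:
            rec = newton_equilibrium(zs, p_new, pulse)
            if rec is not None and rec.jac.determinant < 0:
                kept.append(rec.z_e)
        return kept

    cycles = [_cycle_record(x0, T0, y_sec, pv0, p_seed, pulse,
                            saddles=saddle_zs)]
    v = np.array([x0, T0, pv0])
    v_seed = v.copy()
    amp0 = max(cycles[0].x_max - cycles[0].x_min,
               cycles[0].y_max - cycles[0].y_min)
    amp_stop = min(0.05, 0.6 * amp0)
    scale = np.array([1.0, PERIOD_SCALE, 1.0])
    # head away from the seeding Hopf point (or, lacking one, toward p_lo)
    away = np.sign(pv0 - init.value) if init is not None else -1.0
    tangent = np.array([0.0, 0.0, away if away != 0 else -1.0])
    h = initial_step
    termination = "range-exhausted"
    events: List[BifurcationPoint] = []
    steps = fails = 0
    while steps < max_steps:
        steps += 1
        v_pred = v + h * tangent * scale
        v_new = _branch_corrector(v_pred, tangent, y_sec, params, pulse, param_name)
        if v_new is None:
            h *= 0.5
            fails += 1
            if h < min_step or fails > 60:
                termination = "corrector-stall"
                break
            continue
        fails = 0
        p_new = params.replace(**{param_name: float(v_new[2])})
        saddle_zs = _update_saddles(p_new)
        rec = _cycle_record(v_new[0], v_new[1], y_sec, float(v_new[2]), p_new,
                            pulse, saddles=saddle_zs)
        prev = cycles[-1]
        # fold of the cycle branch in the sweep parameter: SNPO
        amp_new = max(rec.x_max - rec.x_min, rec.y_max - rec.y_min)
        if len(cycles) >= 2:
            d_prev = cycles[-1].param_value - cycles[-2].param_value
            d_new = rec.param_value - cycles[-1].param_value
            # a genuine SNPO is a fold where the nontrivial multiplier
            # crosses 1 (stable and unstable cycles coalescing); a branch
            # merely shrinking into a Hopf point, or a numerically reversed
            # step, has the multiplier on one side of 1 throughout
            crosses_1 = (prev.multiplier - 1.0) * (rec.multiplier - 1.0) < 0
            if d_prev * d_new < 0 and crosses_1 \
                    and abs(prev.multiplier - 1.0) < 0.25 \
                    and min(abs(d_prev), abs(d_new)) > 1e-6 and amp_new > 0.05:
                events.append(BifurcationPoint(
                    kind="snpo", param_name=param_name,
                    value=float(prev.param_value),
                    z=complex(prev.x_section, prev.y_section),
                    auxiliary={"period": prev.period,
                               "multiplier": prev.multiplier},
                    bracket_width=float(abs(d_prev) + abs(d_new))))
        cycles.append(rec)
        if len(cycles) >= 3:
            amp_prev = max(cycles[-2].x_max - cycles[-2].x_min,
                           cycles[-2].y_max - cycles[-2].y_min)
            if amp_new < amp_stop and amp_new < amp_prev and steps > 3:
                termination = "hopf-terminus"
                break
        # returning to the seed state means the branch has been covered
        # (a second pass would only retrace it)
        if steps > 10 and np.linalg.norm((v_new - v_seed) / scale) < \
                max(2.0 * h, 0.05):
            termination = "closed-branch"
            break
        # keep the section centred on the evolving cycle
        y_mid = 0.5 * (rec.y_min + rec.y_max)
        if abs(y_mid - y_sec) > 0.25 * (rec.y_max - rec.y_min):
            repol = _newton_cycle(0.5 * (rec.x_min + rec.x_max), rec.period,
                                  y_mid, p_new, pulse)
            if repol is not None:
                y_sec = y_mid
                v_new = np.array([repol[0], repol[1], rec.param_value])
        t_new = (v_new - v) / scale
        nt = np.linalg.norm(t_new)
        if nt > 0:
            tangent = t_new / nt
        v = v_new
        h = min(h * 1.25, max_step)
        if rec.period > period_threshold:
            termination = "period-threshold"
            break
        if rec.min_saddle_dist < homoclinic_dist_tol and \
                rec.period > cycles[-2].period:
            termination = "saddle-approach"
            break
        # sweep value has converged while the period keeps growing: the
        # branch is accumulating on a homoclinic connection
        if len(cycles) >= 3 and rec.period > cycles[-2].period and \
                abs(rec.param_value - cycles[-2].param_value) < 1e-6 and \
                rec.min_saddle_dist < 10.0 * homoclinic_dist_tol:
            termination = "saddle-approach"
            break
        if not (p_lo - 1e-9 <= v[2] <= p_hi + 1e-9):
            termination = "range-exhausted"
            break
    else:
        termination = "max-steps"

    last = cycles[-1]
    growing = len(cycles) >= 3 and cycles[-1].period > cycles[-3].period
    if termination in ("period-threshold", "saddle-approach") or (
            termination in ("corrector-stall", "max-steps")
            and last.min_saddle_dist < 10.0 * homoclinic_dist_tol and growing):
        events.append(BifurcationPoint(
            kind="homoclinic", param_name=param_name,
            value=float(last.param_value),
            z=complex(last.x_section, last.y_section),
            auxiliary={"period": last.period,
                       "min_saddle_dist": last.min_saddle_dist},
            bracket_width=np.nan))
        termination = "homoclinic"
    return LimitCycleBranch(param_name=param_name, cycles=cycles,
                            events=events, termination=termination)
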