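"""Pseudo-arclength continuation of equilibria with bifurcation detection.

A branch of equilibria of the planar reduced flow is traced in one
macroscopic parameter using a secant predictor and a Newton corrector on the
arclength-extended system, so folds (turning points in the parameter) are
followed rather than lost.  Along the branch three scalar test functions are
monitored:

* ``det J`` — zero at a saddle-node bifurcation;
* ``tr J`` (with ``det J > 0``) — zero at a Hopf bifurcation;
* ``tr J**2 - 4 det J`` — zero at a node-focus transition, where the
  eigenvalues change between real and complex-conjugate.  This is not a true
  bifurcation (existence and stability are unchanged) but it governs whether
  relaxation toward the equilibrium rings.

Each sign change is localized by bisection along the branch chord and emitted
as a :class:`BifurcationPoint`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .equilibria import EquilibriumRecord, classify_equilibrium, find_equilibria
from .model import (ModelParams, PulseShape, jacobian, pulse_coefficients,
                    reduced_vector_field, synaptic_field, vector_field_xy)

__all__ = [
    "BifurcationPoint",
    "Branch",
    "continue_equilibria",
    "param_derivative",
]

SWEEPABLE = ("eta0", "delta_eta", "k0", "delta_k")

#: Localization tolerance (in the sweep parameter) for emitted events.
BRACKET_TOL = 1e-6
#: Test-function magnitude required of a localized event.
EVENT_TOL = 1e-8


@dataclass
class BifurcationPoint:
    """A detected codimension-1 event (or codim-2, from the two-parameter scan)."""

    kind: str  # saddle-node | hopf | node-focus | homoclinic | snpo | bautin | hopf-fold
    param_name: str
    value: float
    z: complex
    auxiliary: Dict[str, float] = field(default_factory=dict)
    bracket_width: float = np.nan


@dataclass
class Branch:
    """An ordered equilibrium branch with its attached events."""

    param_name: str
    values: List[float]
    records: List[EquilibriumRecord]
    events: List[BifurcationPoint]
    termination: str = "range-exhausted"

    def __len__(self) -> int:
        return len(self.values)

    def events_of(self, kind: str) -> List[BifurcationPoint]:
        return [e for e in self.events if e.kind == kind]

    def to_frame(self):
        import pandas as pd

        rows = []
        for v, r in zip(self.values, self.records):
            rows.append(dict(sweep_value=v, x=r.x, y=r.y, trace=r.jac.trace,
                             det=r.jac.determinant, discriminant=r.jac.discriminant,
                             label=r.label))
        return pd.DataFrame(rows)


def param_derivative(z: complex, params: ModelParams, pulse: PulseShape,
                     name: str) -> complex:
    """Exact derivative of the complex vector field w.r.t. one parameter.

    The field is affine in all four distribution parameters at fixed ``z``:
    d(dz/dt)/d eta0 = iB, /d delta_eta = -B, /d k0 = iBH, /d delta_k = -BH,
    with ``B = (z+1)^2 / 2``.
    """
    B = 0.5 * (z + 1.0) ** 2
    if name == "eta0":
        return 1j * B
    if name == "delta_eta":
        return -B
    H = synaptic_field(z, pulse)
    if name == "k0":
        return 1j * B * H
    if name == "delta_k":
        return -B * H
    raise ValueError(f"unknown sweep parameter {name!r}")


def _extended_jacobian(u: np.ndarray, params: ModelParams, pulse: PulseShape,
                       name: str) -> np.ndarray:
    """2x3 Jacobian of the planar field w.r.t. (x, y, p)."""
    z = complex(u[0], u[1])
    if abs(z) > 1.0:  # corrector iterates may graze the boundary
        z /= abs(z)
    p = params.replace(**{name: u[2]})
    J = jacobian(z, p, pulse).matrix
    dp = param_derivative(z, p, pulse, name)
    return np.column_stack([J, [dp.real, dp.imag]])


def _field_u(u: np.ndarray, params: ModelParams, pulse: PulseShape, name: str):
    p = params.replace(**{name: u[2]})
    z = complex(u[0], u[1])
    if abs(z) > 1.0 + 1e-6:
        return None
    zc = z if abs(z) <= 1.0 else z / abs(z)
    zdot = reduced_vector_field(zc, p, pulse)
    return np.array([zdot.real, zdot.imag])


def _corrector(u_pred: np.ndarray, tangent: np.ndarray, params: ModelParams,
               pulse: PulseShape, name: str, tol: float = 1e-11,
               max_iter: int = 12) -> Optional[np.ndarray]:
    """Newton on [field = 0; tangent . (u - u_pred) = 0]."""
    u = u_pred.copy()
    for _ in range(max_iter):
        f = _field_u(u, params, pulse, name)
        if f is None:
            return None
        g = np.array([f[0], f[1], tangent @ (u - u_pred)])
        if np.max(np.abs(g[:2])) < tol and abs(g[2]) < 1e-10:
            return u
        A = np.vstack([_extended_jacobian(u, params, pulse, name), tangent])
        try:
            step = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        u = u + step
        if np.linalg.norm(step) > 1.0:
            return None
    f = _field_u(u, params, pulse, name)
    if f is not None and np.max(np.abs(f)) < 1e-9:
        return u
    return None


def _clip_disk(z: complex) -> complex:
    # branch points may graze |z| = 1 by a few ulp past the domain tolerance
    r = abs(z)
    return z / r if r > 1.0 else z


def _test_functions(u: np.ndarray, params: ModelParams, pulse: PulseShape,
                    name: str) -> Tuple[float, float, float]:
    p = params.replace(**{name: u[2]})
    j = jacobian(_clip_disk(complex(u[0], u[1])), p, pulse)
    return j.determinant, j.trace, j.discriminant


def _record_at(u: np.ndarray, params: ModelParams, pulse: PulseShape,
               name: str) -> EquilibriumRecord:
    p = params.replace(**{name: u[2]})
    z = _clip_disk(complex(u[0], u[1]))
    j = jacobian(z, p, pulse)
    f = vector_field_xy([z.real, z.imag], p, pulse)
    return EquilibriumRecord(params=p, z_e=z, jac=j, eigenvalues=j.eigenvalues,
                             label=classify_equilibrium(j), residual=float(np.hypot(*f)))


def _initial_tangent(u0: np.ndarray, params: ModelParams, pulse: PulseShape,
                     name: str, direction: float) -> Optional[np.ndarray]:
    """Tangent at the branch start, oriented toward increasing p * direction."""
    A = _extended_jacobian(u0, params, pulse, name)
    # tangent spans the null space of the 2x3 extended Jacobian
    _, _, Vt = np.linalg.svd(A)
    t = Vt[-1]
    if abs(t[2]) > 1e-14 and np.sign(t[2]) != np.sign(direction):
        t = -t
    return t


def _localize(u_a, u_b, idx, params, pulse, name, want_sign_of=None):
    """Bisect a test-function sign change along the chord between two branch
    points; returns the refined point or None."""
    ta = _test_functions(u_a, params, pulse, name)[idx]
    tb = _test_functions(u_b, params, pulse, name)[idx]
    if ta == 0.0:
        return u_a
    if np.sign(ta) == np.sign(tb):
        return None
    chord = u_b - u_a
    norm = np.linalg.norm(chord)
    if norm == 0:
        return None
    tangent = chord / norm
    lo, hi, u_lo = 0.0, 1.0, u_a
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        u_pred = u_a + mid * chord
        u_mid = _corrector(u_pred, tangent, params, pulse, name)
        if u_mid is None:
            return None
        tm = _test_functions(u_mid, params, pulse, name)[idx]
        if np.sign(tm) == np.sign(ta):
            lo, u_lo = mid, u_mid
        else:
            hi = mid
        # the emitted point must satisfy its test function, not merely sit
        # in a narrow parameter bracket
        if (hi - lo) * abs(chord[2]) < BRACKET_TOL and abs(tm) < 1e-9:
            break
        if (hi - lo) < 1e-15:
            break
    u_pred = u_a + 0.5 * (lo + hi) * chord
    u_star = _corrector(u_pred, tangent, params, pulse, name)
    if u_star is None:
        u_star = u_lo
    return u_star, (hi - lo) * abs(chord[2])


def continue_equilibria(
    params: ModelParams,
    param_name: str,
    p_range: Tuple[float, float],
    pulse: Optional[PulseShape] = None,
    initial_step: float = 1e-2,
    max_steps: int = 20000,
    start: Optional[EquilibriumRecord] = None,
    direction: float = +1.0,
    min_step: float = 1e-5,
    max_step: float = 0.1,
) -> List[Branch]:
    """Trace all equilibrium branches across ``p_range`` and attach events.

    Starts from every equilibrium found at the range endpoint (or from
    ``start``), follows each branch through folds by pseudo-arclength, and
    records saddle-node, Hopf, and node-focus events localized to a sweep-
    parameter bracket of ``BRACKET_TOL``.  Branches are truncated with a
    logged reason if the corrector diverges persistently or the branch
    leaves the unit disk.
    """
    if param_name not in SWEEPABLE:
        raise ValueError(f"sweep parameter must be one of {SWEEPABLE}")
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    p_lo, p_hi = (min(p_range), max(p_range))
    p_start = p_lo if direction > 0 else p_hi

    if start is not None:
        starts = [start]
    else:
        starts = find_equilibria(params.replace(**{param_name: p_start}), pulse)
    branches: List[Branch] = []
    for s in starts:
        u0 = np.array([s.z_e.real, s.z_e.imag, p_start])
        if any(_on_branch(u0, b) for b in branches):
            continue
        br = _trace_branch(u0, params, pulse, param_name, (p_lo, p_hi),
                           initial_step * direction, max_steps, min_step, max_step)
        if br is not None:
            branches.append(br)
    return branches


def _on_branch(u: np.ndarray, branch: Branch, tol: float = 1e-4) -> bool:
    for v, r in zip(branch.values, branch.records):
        if abs(v - u[2]) < tol and abs(r.z_e - complex(u[0], u[1])) < tol:
            return True
    return False


def _trace_branch(u0, params, pulse, name, bounds, h0, max_steps, min_step,
                  max_step) -> Optional[Branch]:
    p_lo, p_hi = bounds
    t0 = _initial_tangent(u0, params, pulse, name, np.sign(h0) or 1.0)
    if t0 is None:
        return None
    us = [u0]
    tangent = t0
    h = abs(h0)
    termination = "range-exhausted"
    steps = 0
    fails = 0
    while steps < max_steps:
        steps += 1
        u_prev = us[-1]
        u_pred = u_prev + h * tangent
        u_new = _corrector(u_pred, tangent, params, pulse, name)
        if u_new is None or np.linalg.norm(u_new - u_prev) > 4 * max(h, 1e-3):
            h *= 0.5
            fails += 1
            if h < min_step or fails > 60:
                termination = "corrector-divergence"
                break
            continue
        fails = 0
        if abs(complex(u_new[0], u_new[1])) > 1.0 + 1e-7:
            termination = "left-unit-disk"
            break
        us.append(u_new)
        new_tangent = (u_new - u_prev)
        nt = np.linalg.norm(new_tangent)
        if nt > 0:
            tangent = new_tangent / nt
        h = min(h * 1.3, max_step)
        if u_new[2] > p_hi + 1e-12 or u_new[2] < p_lo - 1e-12:
            termination = "range-exhausted"
            break
    events = _detect_events(us, params, pulse, name, (p_lo, p_hi))
    records = [_record_at(u, params, pulse, name) for u in us]
    return Branch(param_name=name, values=[float(u[2]) for u in us],
                  records=records, events=events, termination=termination)


def _emit_event(kind, u_a, u_b, idx, params, pulse, name, bounds, events):
    p_lo, p_hi = bounds
    loc = _localize(u_a, u_b, idx, params, pulse, name)
    if loc is None:
        return
    u_star, width = loc
    det, tr, disc = _test_functions(u_star, params, pulse, name)
    if kind == "hopf" and det <= 0:
        return  # neutral saddle, not a Hopf
    if kind == "node-focus" and abs(tr) < 1e-7:
        return  # coincides with the Hopf point itself
    value = float(u_star[2])
    if not (p_lo - 1e-6 <= value <= p_hi + 1e-6):
        return
    aux = {"det": det, "trace": tr, "discriminant": disc}
    if kind == "hopf":
        aux["omega"] = float(np.sqrt(max(det, 0.0)))
    events.append(BifurcationPoint(kind=kind, param_name=name, value=value,
                                   z=complex(u_star[0], u_star[1]),
                                   auxiliary=aux, bracket_width=float(width)))


def _refine_near_miss(u_a, u_m, u_b, idx, sign_out, params, pulse, name):
    """Golden-section minimize the test function (signed toward zero) along
    the two-segment chord through a deep local minimum; returns the branch
    point where it crosses zero, if it does."""
    gr = 0.5 * (np.sqrt(5.0) - 1.0)

    def value_at(t):
        if t <= 0.5:
            chord = u_m - u_a
            pred = u_a + 2 * t * chord
        else:
            chord = u_b - u_m
            pred = u_m + 2 * (t - 0.5) * chord
        nrm = np.linalg.norm(chord)
        if nrm == 0:
            return np.inf, None
        u = _corrector(pred, chord / nrm, params, pulse, name)
        if u is None:
            return np.inf, None
        return sign_out * _test_functions(u, params, pulse, name)[idx], u

    lo, hi = 0.0, 1.0
    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc, uc = value_at(c)
    fd, ud = value_at(d)
    best = min([(fc, uc), (fd, ud)], key=lambda t: t[0])
    for _ in range(50):
        if fc <= fd:
            hi, d, fd, ud = d, c, fc, uc
            c = hi - gr * (hi - lo)
            fc, uc = value_at(c)
        else:
            lo, c, fc, uc = c, d, fd, ud
            d = lo + gr * (hi - lo)
            fd, ud = value_at(d)
        cand = min([(fc, uc), (fd, ud)], key=lambda t: t[0])
        if cand[0] < best[0]:
            best = cand
        if best[0] < 0.0 or (hi - lo) < 1e-10:
            break
    if best[0] < 0.0 and best[1] is not None:
        return best[1]
    return None


def _detect_events(us, params, pulse, name, bounds) -> List[BifurcationPoint]:
    p_lo, p_hi = bounds
    events: List[BifurcationPoint] = []
    tf = [_test_functions(u, params, pulse, name) for u in us]
    kinds = (("saddle-node", 0), ("hopf", 1), ("node-focus", 2))
    for i in range(len(us) - 1):
        if not (p_lo - 1e-9 <= us[i][2] <= p_hi + 1e-9):
            continue
        for kind, idx in kinds:
            a, b = tf[i][idx], tf[i + 1][idx]
            if a == 0.0 or np.sign(a) == np.sign(b):
                continue
            _emit_event(kind, us[i], us[i + 1], idx, params, pulse, name,
                        bounds, events)
    # near-cusp pairs: the test function may dip through zero and back
    # between consecutive branch points (two events closer than the step);
    # refine deep local minima that show no sign change
    for kind, idx in kinds:
        vals = np.array([t[idx] for t in tf])
        for i in range(1, len(us) - 1):
            a, b, c = vals[i - 1], vals[i], vals[i + 1]
            if not (np.sign(a) == np.sign(b) == np.sign(c)) or b == 0.0:
                continue
            if not (abs(b) < abs(a) and abs(b) < abs(c)):
                continue
            if abs(b) > 1e-3 * max(1.0, abs(a), abs(c)):
                continue
            u_star = _refine_near_miss(us[i - 1], us[i], us[i + 1], idx,
                                       float(np.sign(b)), params, pulse, name)
            if u_star is None:
                continue
            _emit_event(kind, us[i - 1], u_star, idx, params, pulse, name,
                        bounds, events)
            _emit_event(kind, u_star, us[i + 1], idx, params, pulse, name,
                        bounds, events)
    events.sort(key=lambda e: e.value)
    return events
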