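"""Parametric bifurcation surfaces in (eta0, delta_eta, k0) parameter space.

At a prescribed equilibrium location ``z_e = x_e + i y_e`` (inside the open
unit disk, away from the degenerate points ``z_e = +-1``) the two equilibrium
conditions ``Re dz/dt = Im dz/dt = 0`` are *affine* in the three distribution
parameters ``(eta0, delta_eta, k0)`` at fixed ``delta_k``, because the
synaptic drive ``H`` depends only on ``z``.  Two affine constraints on three
unknowns leave a one-parameter family; closing the system with a bifurcation
condition picks out isolated parameter points:

* Hopf: ``tr J = 0`` is also affine, so solutions come from a single 3x3
  linear solve, then are filtered by ``det J > 0``;
* saddle-node: ``det J = 0`` is quadratic in the parameters; eliminating
  ``(eta0, delta_eta)`` through the affine equilibrium constraints leaves an
  exact scalar quadratic in ``k0`` with 0, 1 or 2 real roots;
* node-focus: ``tr J**2 - 4 det J = 0``, handled like the saddle-node case.

Scanning ``(x_e, y_e)`` over a polar grid sweeps out the bifurcation
surfaces.  Increasing the synaptic diversity ``delta_k`` migrates the
surfaces toward extreme and unphysical (``delta_eta < 0``) parameter
regions — the mechanism by which coupling-strength heterogeneity suppresses
the network's dynamical repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import ModelParams, PulseShape, jacobian, pulse_coefficients, \
    reduced_vector_field, synaptic_field

__all__ = [
    "DegeneratePointError",
    "SurfacePoint",
    "SurfaceMesh",
    "equilibrium_parameter_system",
    "surface_point",
    "build_surface_mesh",
    "surface_line_intersections",
    "cross_validate_point",
]

SURFACE_KINDS = ("saddle-node", "hopf", "node-focus")

#: Residual tolerances required of every emitted solution.
EQ_RESIDUAL_TOL = 1e-9
TEST_RESIDUAL_TOL = 1e-9

#: Exclusion radius around the degenerate equilibrium locations z_e = +-1.
DEGENERATE_RADIUS = 1e-3


class DegeneratePointError(ValueError):
    """The prescribed equilibrium location carries no parameter information."""


@dataclass
class SurfacePoint:
    """Solutions of one surface kind at one prescribed equilibrium location."""

    x_e: float
    y_e: float
    kind: str
    solutions: List[Tuple[float, float, float]]  # (eta0, delta_eta, k0)
    residuals: List[Tuple[float, float]]  # (equilibrium, test-function)
    physical: List[bool]  # delta_eta >= 0
    det_positive: List[bool]  # det J > 0 (Hopf admissibility)


@dataclass
class SurfaceMesh:
    """Surface solutions over a polar (x_e, y_e) grid, with skip accounting."""

    kind: str
    delta_k: float
    n: int
    points: List[SurfacePoint]
    clip: Optional[dict] = None
    n_dropped_unphysical: int = 0
    n_dropped_clip: int = 0
    n_degenerate: int = 0

    def solutions_array(self) -> np.ndarray:
        """All retained solutions as rows (x_e, y_e, eta0, delta_eta, k0)."""
        rows = [(p.x_e, p.y_e, *s) for p in self.points for s in p.solutions]
        return np.array(rows).reshape(-1, 5)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self.points:
            for s, r, ph, dp in zip(p.solutions, p.residuals, p.physical,
                                    p.det_positive):
                rows.append(dict(x_e=p.x_e, y_e=p.y_e, kind=p.kind,
                                 eta0=s[0], delta_eta=s[1], k0=s[2],
                                 residual_eq=r[0], residual_test=r[1],
                                 physical_flag=ph, det_positive_flag=dp))
        cols = ["x_e", "y_e", "kind", "eta0", "delta_eta", "k0",
                "residual_eq", "residual_test", "physical_flag",
                "det_positive_flag"]
        return pd.DataFrame(rows, columns=cols)


def _check_location(x_e: float, y_e: float) -> complex:
    z = complex(x_e, y_e)
    if abs(z) >= 1.0:
        raise ValueError(f"equilibrium location must satisfy |z| < 1, got |z| = {abs(z):.4g}")
    if abs(z - 1.0) < DEGENERATE_RADIUS or abs(z + 1.0) < DEGENERATE_RADIUS:
        raise DegeneratePointError(
            f"z_e = {z:.4g} is within {DEGENERATE_RADIUS} of a degenerate point +-1")
    return z


def equilibrium_parameter_system(x_e: float, y_e: float, delta_k: float,
                                 pulse: PulseShape):
    """Affine form of the equilibrium conditions in (eta0, delta_eta, k0).

    Returns ``(A, b)`` with ``A`` 2x3 and ``b`` length-2 such that the
    equilibrium conditions read ``A @ (eta0, delta_eta, k0) = b`` at the
    prescribed ``z_e`` and fixed ``delta_k``.

    Raises :class:`DegeneratePointError` at ``z_e = -1`` (where the
    parameter-coefficient matrix loses rank; all parameter dependence sits
    in the vanishing factor ``(z+1)^2``) and at ``z_e = +1`` (perfect
    synchrony at the rest phase, an equilibrium only on the measure-zero set
    ``eta0 = delta_eta = 0``).
    """
    z = _check_location(x_e, y_e)
    h = synaptic_field(z, pulse)
    B = 0.5 * (z + 1.0) ** 2
    C0 = -0.5j * (z - 1.0) ** 2
    iB = 1j * B
    A = np.array([[iB.real, -B.real, (iB * h).real],
                  [iB.imag, -B.imag, (iB * h).imag]])
    b = -np.array([(C0 - B * h * delta_k).real, (C0 - B * h * delta_k).imag])
    return A, b


def _affine_in_k0(A: np.ndarray, b: np.ndarray):
    """Solve the equilibrium pair for (eta0, delta_eta) as affine maps of k0:
    (eta0, delta_eta) = P + Q * k0."""
    A1 = A[:, :2]
    if abs(np.linalg.det(A1)) < 1e-14:
        raise DegeneratePointError("equilibrium system rank-deficient in (eta0, delta_eta)")
    P = np.linalg.solve(A1, b)
    Q = np.linalg.solve(A1, -A[:, 2])
    return P, Q


def _test_value(kind: str, z: complex, params: ModelParams,
                pulse: PulseShape) -> float:
    j = jacobian(z, params, pulse)
    if kind == "saddle-node":
        return j.determinant
    if kind == "hopf":
        return j.trace
    if kind == "node-focus":
        return j.discriminant
    raise ValueError(f"unknown surface kind {kind!r}")


def _params_at(k0: float, P, Q, delta_k: float, n: int) -> ModelParams:
    eta0 = float(P[0] + Q[0] * k0)
    deta = float(P[1] + Q[1] * k0)
    # delta_eta may legitimately be negative on the unphysical sheet; bypass
    # the constructor check and flag it downstream instead
    p = ModelParams.__new__(ModelParams)
    object.__setattr__(p, "eta0", eta0)
    object.__setattr__(p, "delta_eta", deta)
    object.__setattr__(p, "k0", float(k0))
    object.__setattr__(p, "delta_k", float(delta_k))
    object.__setattr__(p, "n", n)
    return p


def surface_point(kind: str, x_e: float, y_e: float, delta_k: float,
                  pulse: PulseShape) -> SurfacePoint:
    """All parameter triples at which ``z_e`` is an equilibrium undergoing
    the requested transition.

    The test function, restricted to the equilibrium family parameterized by
    ``k0``, is exactly affine (Hopf) or quadratic (saddle-node, node-focus)
    in ``k0``; its coefficients are recovered from three exact evaluations
    and its real roots enumerated.  Complex quadratic roots mean the surface
    does not pass over this ``(x_e, y_e)`` — an empty solution list.
    """
    if kind not in SURFACE_KINDS:
        raise ValueError(f"kind must be one of {SURFACE_KINDS}")
    z = _check_location(x_e, y_e)
    A, b = equilibrium_parameter_system(x_e, y_e, delta_k, pulse)
    P, Q = _affine_in_k0(A, b)
    n = pulse.n

    def phi(k0: float) -> float:
        return _test_value(kind, z, _params_at(k0, P, Q, delta_k, n), pulse)

    f0, fp, fm = phi(0.0), phi(1.0), phi(-1.0)
    c2 = 0.5 * (fp + fm) - f0  # quadratic coefficient (0 for Hopf)
    c1 = 0.5 * (fp - fm)
    c0 = f0
    scale = max(abs(c0), abs(c1), abs(c2), 1e-30)
    roots: List[float] = []
    if abs(c2) < 1e-12 * scale:
        if abs(c1) > 1e-12 * scale:
            roots = [-c0 / c1]
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc >= 0.0:
            sq = np.sqrt(disc)
            # numerically stable quadratic roots
            qq = -0.5 * (c1 + np.copysign(sq, c1))
            roots = sorted({qq / c2, c0 / qq if qq != 0 else -c1 / (2 * c2)})
    # Newton-polish each root on the exact test function: the fitted
    # quadratic is exact in exact arithmetic, but far roots of a nearly
    # linear quadratic are ill-conditioned in floating point
    polished = []
    for k0 in roots:
        for _ in range(4):
            fv = phi(k0)
            dv = c1 + 2.0 * c2 * k0
            if fv == 0.0 or abs(dv) < 1e-300:
                break
            step = fv / dv
            if not np.isfinite(step) or abs(step) > 1.0 + abs(k0):
                break
            k0 -= step
            if abs(step) < 1e-14 * max(1.0, abs(k0)):
                break
        if np.isfinite(k0) and abs(phi(k0)) < TEST_RESIDUAL_TOL:
            polished.append(k0)
    roots = sorted(set(polished))

    sols, resids, phys, detpos = [], [], [], []
    for k0 in roots:
        p = _params_at(k0, P, Q, delta_k, n)
        zdot = reduced_vector_field(z, p, pulse)
        j = jacobian(z, p, pulse)
        tval = _test_value(kind, z, p, pulse)
        ok_det = j.determinant > 0
        if kind == "hopf" and not ok_det:
            # fails the admissibility filter; recorded via flags only
            sols.append((p.eta0, p.delta_eta, p.k0))
            resids.append((abs(zdot), abs(tval)))
            phys.append(p.delta_eta >= 0)
            detpos.append(False)
            continue
        sols.append((p.eta0, p.delta_eta, p.k0))
        resids.append((abs(zdot), abs(tval)))
        phys.append(p.delta_eta >= 0)
        detpos.append(bool(ok_det))
    return SurfacePoint(x_e=x_e, y_e=y_e, kind=kind, solutions=sols,
                        residuals=resids, physical=phys, det_positive=detpos)


def default_surface_grid(n_r: int = 60, n_phi: int = 120) -> np.ndarray:
    """Polar (x_e, y_e) grid over the open unit disk avoiding z_e = +-1."""
    r = np.linspace(0.01, 0.995, n_r)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    R, PHI = np.meshgrid(r, phi)
    pts = np.column_stack([(R * np.cos(PHI)).ravel(), (R * np.sin(PHI)).ravel()])
    keep = (np.hypot(pts[:, 0] - 1.0, pts[:, 1]) > DEGENERATE_RADIUS) & \
           (np.hypot(pts[:, 0] + 1.0, pts[:, 1]) > DEGENERATE_RADIUS)
    return pts[keep]


def build_surface_mesh(
    kind: str,
    delta_k: float,
    pulse: Optional[PulseShape] = None,
    n: int = 2,
    grid: Optional[Sequence] = None,
    clip: Optional[dict] = None,
    physical_filter: bool = True,
) -> SurfaceMesh:
    """Map :func:`surface_point` over a grid; filter and count the drops.

    ``clip`` bounds are a dict with optional ``eta0``, ``delta_eta``, ``k0``
    entries, each a (lo, hi) pair.  With ``physical_filter`` on (default),
    solutions with ``delta_eta < 0`` are dropped and counted; turning it off
    retains the unphysical sheet (useful to follow surface migration).
    Hopf candidates failing ``det J > 0`` are always excluded from the
    retained solutions (kept only in the per-point flags).
    """
    if pulse is None:
        pulse = pulse_coefficients(n)
    pts = default_surface_grid() if grid is None else np.asarray(grid, float)
    mesh = SurfaceMesh(kind=kind, delta_k=delta_k, n=pulse.n, points=[],
                       clip=clip)
    for x_e, y_e in pts:
        try:
            sp = surface_point(kind, float(x_e), float(y_e), delta_k, pulse)
        except DegeneratePointError:
            mesh.n_degenerate += 1
            continue
        keep = SurfacePoint(x_e=sp.x_e, y_e=sp.y_e, kind=kind, solutions=[],
                            residuals=[], physical=[], det_positive=[])
        for s, r, ph, dp in zip(sp.solutions, sp.residuals, sp.physical,
                                sp.det_positive):
            if kind == "hopf" and not dp:
                continue
            if physical_filter and not ph:
                mesh.n_dropped_unphysical += 1
                continue
            if clip is not None and not _in_clip(s, clip):
                mesh.n_dropped_clip += 1
                continue
            keep.solutions.append(s)
            keep.residuals.append(r)
            keep.physical.append(ph)
            keep.det_positive.append(dp)
        if keep.solutions:
            mesh.points.append(keep)
    return mesh


def _in_clip(sol, clip) -> bool:
    names = ("eta0", "delta_eta", "k0")
    for v, name in zip(sol, names):
        if name in clip:
            lo, hi = clip[name]
            if not (lo <= v <= hi):
                return False
    return True


def export_mesh_obj(mesh: SurfaceMesh, path, grid_shape=None) -> int:
    """Write the surface as an ASCII Wavefront OBJ for external 3-D viewers.

    Vertices are ``(eta0, delta_eta, k0)`` triples (the first retained
    solution of each mesh point); faces connect grid-adjacent points when
    the polar grid shape ``(n_r, n_phi)`` is known and all four corners
    carry a solution.  Without a grid shape, a point cloud is written.
    Returns the number of vertices.
    """
    index = {}
    lines = ["# thetanet bifurcation surface",
             f"# kind={mesh.kind} delta_k={mesh.delta_k} n={mesh.n}"]
    for i, p in enumerate(mesh.points):
        s = p.solutions[0]
        index[(round(p.x_e, 12), round(p.y_e, 12))] = i + 1  # OBJ is 1-based
        lines.append(f"v {s[0]:.10g} {s[1]:.10g} {s[2]:.10g}")
    if grid_shape is not None:
        n_r, n_phi = grid_shape
        r = np.linspace(0.01, 0.995, n_r)
        phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)

        def vid(i_r, i_phi):
            x = r[i_r] * np.cos(phi[i_phi % n_phi])
            y = r[i_r] * np.sin(phi[i_phi % n_phi])
            return index.get((round(x, 12), round(y, 12)))

        for i_r in range(n_r - 1):
            for i_phi in range(n_phi):
                quad = [vid(i_r, i_phi), vid(i_r + 1, i_phi),
                        vid(i_r + 1, i_phi + 1), vid(i_r, i_phi + 1)]
                if all(q is not None for q in quad):
                    lines.append("f " + " ".join(str(q) for q in quad))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return len(index)


def surface_line_intersections(
    kind: str,
    fixed: dict,
    free: str,
    free_range: Tuple[float, float],
    delta_k: float,
    pulse: Optional[PulseShape] = None,
    n: int = 2,
    n_seeds: int = 400,
    seed: int = 7,
) -> List[Tuple[float, complex]]:
    """Where a parameter-space line pierces one bifurcation surface.

    ``fixed`` holds two of ``eta0, delta_eta, k0``; ``free`` names the third,
    which varies over ``free_range``.  Solves the three-equation system
    (equilibrium pair + test function) in the unknowns ``(x, y, free)`` by
    Newton from random seeds — independent of both the one-parameter
    continuation and the (x_e, y_e) mesh scan, so it serves as a
    cross-check for either.  Returns deduplicated ``(free_value, z_e)``
    pairs sorted by the free value.
    """
    if pulse is None:
        pulse = pulse_coefficients(n)
    if free in fixed or len(fixed) != 2:
        raise ValueError("fixed must hold exactly the two non-free parameters")
    base = ModelParams(delta_k=delta_k, n=pulse.n,
                       **{free: 0.0}, **fixed)

    def G(w):
        z = complex(w[0], w[1])
        if abs(z) > 1.0:
            z /= abs(z)
        try:
            p = base.replace(**{free: float(w[2])})
        except ValueError:
            return None  # e.g. a negative delta_eta iterate
        zdot = reduced_vector_field(z, p, pulse)
        return np.array([zdot.real, zdot.imag,
                         _test_value(kind, z, p, pulse)])

    rng = np.random.default_rng(seed)
    seeds = np.column_stack([
        rng.uniform(-0.95, 0.95, n_seeds),
        rng.uniform(-0.95, 0.95, n_seeds),
        rng.uniform(free_range[0], free_range[1], n_seeds),
    ])
    found: List[Tuple[float, complex]] = []
    for w0 in seeds:
        if np.hypot(w0[0], w0[1]) > 0.97:
            continue
        w = w0.copy()
        ok = False
        for _ in range(40):
            g = G(w)
            if g is None:
                break
            if np.max(np.abs(g)) < 1e-11:
                ok = True
                break
            Jn = np.empty((3, 3))
            bad = False
            for j in range(3):
                wp, wm = w.copy(), w.copy()
                wp[j] += 1e-7
                wm[j] -= 1e-7
                gp, gm = G(wp), G(wm)
                if gp is None or gm is None:
                    bad = True
                    break
                Jn[:, j] = (gp - gm) / 2e-7
            if bad:
                break
            try:
                step = np.linalg.solve(Jn, -g)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 10.0:
                break
            w = w + step
        if not ok:
            continue
        z = complex(w[0], w[1])
        if abs(z) > 1.0 - 1e-9 or not (free_range[0] <= w[2] <= free_range[1]):
            continue
        p = base.replace(**{free: float(w[2])})
        if p.delta_eta < 0:
            continue
        if kind == "hopf" and jacobian(z, p, pulse).determinant <= 0:
            continue
        if not any(abs(w[2] - f[0]) < 1e-5 and abs(z - f[1]) < 1e-4
                   for f in found):
            found.append((float(w[2]), z))
    found.sort(key=lambda t: t[0])
    return found


def cross_validate_point(solution: Tuple[float, float, float], kind: str,
                         z_e: complex, delta_k: float,
                         pulse: Optional[PulseShape] = None, n: int = 2,
                         window: float = 0.5, tol: float = 1e-4) -> dict:
    """Confirm a surface solution against one-parameter continuation.

    Runs ``continue_equilibria`` in ``k0`` through the solution and checks
    that an event of the matching kind occurs within ``tol`` of the
    solution's ``k0``.  Returns a report dict; a mismatch is reported, not
    raised.
    """
    from .continuation import continue_equilibria

    if pulse is None:
        pulse = pulse_coefficients(n)
    eta0, delta_eta, k0 = solution
    if delta_eta < 0:
        return {"ok": False, "reason": "unphysical-delta-eta", "events": []}
    # sweep through the event from both window ends: around a fold the
    # branch carrying z_e exists on one side of the event only
    events = []
    params = ModelParams(eta0, delta_eta, k0, delta_k, pulse.n)

    def _report():
        hits = [e for e in events if abs(e.value - k0) < tol]
        return {"ok": bool(hits), "expected_k0": k0,
                "events": [(e.kind, e.value) for e in events],
                "reason": None if hits else "no-matching-event"}

    # stage 1: sweeps from both window ends (covers branches reaching them)
    for direction in (+1.0, -1.0):
        branches = continue_equilibria(
            params, "k0", (k0 - window, k0 + window), pulse=pulse,
            direction=direction, initial_step=min(1e-2, window / 10))
        events.extend(e for b in branches for e in b.events_of(kind))
    rep = _report()
    if rep["ok"]:
        return rep
    # stage 2: fold "bubbles" whose arms never reach the window ends are
    # invisible from there; re-sweep starting right next to the prescribed
    # equilibrium, where all coexisting arms are picked up afresh
    for mag in (1e-4, 1e-3, 1e-2):
        for eps in (-mag, +mag):
            for rng_mid, direction in (((k0 + eps, k0 + window), +1.0),
                                       ((k0 - window, k0 + eps), -1.0)):
                branches = continue_equilibria(
                    params, "k0", rng_mid, pulse=pulse, direction=direction,
                    initial_step=min(1e-3, window / 100))
                events.extend(e for b in branches for e in b.events_of(kind))
        rep = _report()
        if rep["ok"]:
            return rep
    return rep
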