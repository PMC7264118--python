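"""Equilibrium location and linear-stability classification for the reduced ODE.

Equilibria of the planar order-parameter flow are roots of
``(dx/dt, dy/dt) = 0`` inside the closed unit disk.  The model restricts
attention to ``|z| <= 1``; roots outside the disk are discarded.  Up to three
equilibria coexist in the multistable regimes, so roots are hunted by damped
Newton iteration from a polar seed grid and deduplicated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .model import (DOMAIN_TOL, JacobianInfo, ModelParams, PulseShape,
                    jacobian, pulse_coefficients, vector_field_xy)

__all__ = [
    "EquilibriumRecord",
    "find_equilibria",
    "classify_equilibrium",
    "newton_equilibrium",
    "default_seed_grid",
]

#: Accepted equilibria must have |dz/dt| below this.
RESIDUAL_TOL = 1e-10
#: Roots closer than this in the (x, y) plane are considered identical.
DEDUP_TOL = 1e-7
#: |discriminant| below this is flagged as on the node-focus boundary.
NF_TIE_TOL = 1e-10


@dataclass
class EquilibriumRecord:
    """An equilibrium of the reduced flow with its local linearization."""

    params: ModelParams
    z_e: complex
    jac: JacobianInfo
    eigenvalues: np.ndarray
    label: str
    residual: float

    @property
    def x(self) -> float:
        return self.z_e.real

    @property
    def y(self) -> float:
        return self.z_e.imag

    @property
    def is_stable(self) -> bool:
        return self.label.startswith("stable")


def classify_equilibrium(jac: JacobianInfo) -> str:
    """Label an equilibrium from its Jacobian.

    ``saddle`` when ``det J < 0``; otherwise a node (real eigenvalues,
    ``disc > 0``) or focus (complex pair, ``disc < 0``), stable when
    ``tr J < 0``.  A discriminant within ``NF_TIE_TOL`` of zero sits on the
    node-focus boundary and is labelled as such.
    """
    if not (np.isfinite(jac.trace) and np.isfinite(jac.determinant)):
        raise ValueError("non-finite Jacobian")
    if jac.determinant < 0:
        return "saddle"
    stability = "stable" if jac.trace < 0 else "unstable"
    if abs(jac.discriminant) < NF_TIE_TOL:
        return f"{stability}-node-focus-boundary"
    shape = "focus" if jac.discriminant < 0 else "node"
    return f"{stability}-{shape}"


def _make_record(z: complex, params: ModelParams, pulse: PulseShape) -> EquilibriumRecord:
    jac = jacobian(z, params, pulse)
    f = vector_field_xy([z.real, z.imag], params, pulse)
    return EquilibriumRecord(
        params=params,
        z_e=z,
        jac=jac,
        eigenvalues=jac.eigenvalues,
        label=classify_equilibrium(jac),
        residual=float(np.hypot(*f)),
    )


def newton_equilibrium(
    z0: complex,
    params: ModelParams,
    pulse: PulseShape,
    max_iter: int = 60,
    tol: float = RESIDUAL_TOL,
) -> Optional[EquilibriumRecord]:
    """Damped Newton from a single seed; ``None`` on failure or exit from disk.

    Steps are damped by backtracking halving when the residual does not
    decrease, and iterates are pulled back to the disk boundary if they
    overshoot it, since the physical branch may touch ``|z| = 1``.
    """
    u = np.array([z0.real, z0.imag], dtype=float)
    f = _safe_field(u, params, pulse)
    if f is None:
        return None
    for _ in range(max_iter):
        r = np.hypot(*f)
        if r < tol:
            z = complex(u[0], u[1])
            if abs(z) > 1.0 + DOMAIN_TOL:
                return None
            return _make_record(z, params, pulse)
        J = jacobian(_clip_disk(u), params, pulse).matrix
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):
            u_new = u + lam * step
            f_new = _safe_field(u_new, params, pulse)
            if f_new is not None and np.hypot(*f_new) < r:
                break
            lam *= 0.5
        else:
            return None
        u, f = u_new, f_new
    return None


def _clip_disk(u: np.ndarray) -> complex:
    z = complex(u[0], u[1])
    r = abs(z)
    if r > 1.0:
        z = z / r
    return z


def _safe_field(u, params, pulse):
    # evaluate at the disk-clipped point; H extends smoothly but the model is
    # only meaningful inside, and Newton iterates may briefly overshoot
    z = complex(u[0], u[1])
    if abs(z) > 1.2:
        return None
    zc = _clip_disk(u)
    if zc != z:
        u = np.array([zc.real, zc.imag])
    return vector_field_xy(u, params, pulse)


def default_seed_grid(n_r: int = 21, n_phi: int = 21) -> np.ndarray:
    """Polar grid of seeds over the closed unit disk (plus the origin)."""
    r = np.linspace(0.02, 0.999, n_r)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    R, P = np.meshgrid(r, phi)
    pts = np.column_stack([(R * np.cos(P)).ravel(), (R * np.sin(P)).ravel()])
    return np.vstack([[0.0, 0.0], pts])


def find_equilibria(
    params: ModelParams,
    pulse: Optional[PulseShape] = None,
    seed_grid: Optional[Sequence] = None,
) -> List[EquilibriumRecord]:
    """All equilibria inside the unit disk, deduplicated, sorted by ``Im z``.

    An empty list is a valid outcome (no equilibrium in the disk).
    """
    if pulse is None:
        pulse = pulse_coefficients(params.n)
    seeds = default_seed_grid() if seed_grid is None else np.asarray(seed_grid, dtype=float)
    found: List[EquilibriumRecord] = []
    for s in seeds:
        rec = newton_equilibrium(complex(s[0], s[1]), params, pulse)
        if rec is None:
            continue
        if any(abs(rec.z_e - o.z_e) < DEDUP_TOL for o in found):
            continue
        found.append(rec)
    found.sort(key=lambda r: (r.z_e.imag, r.z_e.real))
    return found
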