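"""Homogeneous linear-FEM initializer for the nonlinear estimation.

Treating the material as homogeneous and linear, Young's modulus factors out
of the stiffness: K(E, v) = E * Kbar(v) with Kbar(v) = phi(v) K_G + psi(v) K_H
assembled at unit modulus.  For measured displacement fields u_i and force
vectors f~_i the initial parameters solve

    (E0, v0) = argmin_{E, v}  Sum_i || E * N_i(v) - f~_i ||^2,

where N_i(v) = Kbar(v) u_i is the force response at unit modulus.  The inner
minimization over E is a 1-D least squares with the closed form
E = Sum<N_i, f~_i> / Sum ||N_i||^2; the outer search over v is a coarse grid
followed by golden-section refinement.  The recovered (E0, v0) seed both the
regularization anchor and the solver start, as alpha0 = E0 * phi(v0).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize_scalar

from .elasticity import phi_psi
from .experiment import LoadCase
from .fem import FEMOperator

__all__ = ["InitialParams", "normalized_force", "optimal_E_given_v", "solve_initial_params",
           "per_load_case_fits"]

V_SEARCH_LO = 0.01
V_SEARCH_HI = 0.49


@dataclass(frozen=True)
class InitialParams:
    """Homogeneous initial estimate: E0 [Pa], v0, and alpha0 = E0*phi(v0) [Pa]."""

    E0: float
    v0: float
    alpha0: float
    objective: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def normalized_force(op: FEMOperator, v: float, u_free: np.ndarray) -> np.ndarray:
    """N(v) = Kbar(v) u: nodal forces of a homogeneous material at E = 1."""
    phi, psi = phi_psi(v)
    KG, KH = op.homogeneous_parts()
    return phi * (KG @ u_free) + psi * (KH @ u_free)


def _case_vectors(op: FEMOperator, cases: list[LoadCase]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    us, fs = [], []
    for lc in cases:
        if lc.U_full is None:
            raise ValueError("load case lacks a displacement field; complete the measurement first")
        us.append(op.free_vector_from_field(lc.U_full))
        fs.append(op.point_load(lc.load_node, lc.force_3vector()))
    return us, fs


def optimal_E_given_v(op: FEMOperator, v: float, cases: list[LoadCase]) -> float:
    """Closed-form inner minimizer E(v) = Sum<N_i, f~_i> / Sum ||N_i||^2."""
    us, fs = _case_vectors(op, cases)
    num = 0.0
    den = 0.0
    for u, f in zip(us, fs):
        N = normalized_force(op, v, u)
        num += float(N @ f)
        den += float(N @ N)
    if den == 0.0:
        raise ValueError("all normalized force responses vanish; degenerate displacement data")
    return num / den


def _objective(op: FEMOperator, v: float, us, fs) -> tuple[float, float]:
    """(objective, E(v)) at a fixed Poisson ratio."""
    Ns = [normalized_force(op, v, u) for u in us]
    den = sum(float(N @ N) for N in Ns)
    if den == 0.0:
        raise ValueError("degenerate displacement data")
    num = sum(float(N @ f) for N, f in zip(Ns, fs))
    E = num / den
    obj = sum(float(np.sum((E * N - f) ** 2)) for N, f in zip(Ns, fs))
    return obj, E


def solve_initial_params(
    op: FEMOperator,
    cases: list[LoadCase],
    n_grid: int = 49,
    v_tol: float = 1e-4,
) -> InitialParams:
    """Profile the objective over v on a coarse grid, refine by golden section.

    Deterministic; the grid guards against non-convexity of the 1-D profile,
    the bounded golden-section pass sharpens the best bracket to ``v_tol``.
    """
    if not cases:
        raise ValueError("no load cases supplied")
    us, fs = _case_vectors(op, cases)
    grid = np.linspace(V_SEARCH_LO, V_SEARCH_HI, n_grid)
    vals = np.array([_objective(op, v, us, fs)[0] for v in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda v: _objective(op, float(v), us, fs)[0],
        bounds=(lo, hi), method="bounded", options={"xatol": v_tol},
    )
    v0 = float(res.x)
    obj, E0 = _objective(op, v0, us, fs)
    # keep whichever of grid-best / refined is lower (refinement never worsens)
    if vals[i] < obj:
        v0 = float(grid[i])
        obj, E0 = _objective(op, v0, us, fs)
    if E0 <= 0:
        raise ValueError(f"linear fit produced non-positive modulus E0={E0:.3g}; data inconsistent")
    phi, _ = phi_psi(v0)
    return InitialParams(E0=E0, v0=v0, alpha0=E0 * phi, objective=obj)


def per_load_case_fits(op: FEMOperator, cases: list[LoadCase], **kw) -> list[InitialParams]:
    """One homogeneous linear fit per deformation set (the per-case protocol)."""
    return [solve_initial_params(op, [lc], **kw) for lc in cases]
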