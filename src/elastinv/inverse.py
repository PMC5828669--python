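"""Regularized nonlinear inverse problem for per-hexahedron (alpha, v).

The estimator minimizes, over all hexahedron parameters,

    Sum_i || K(alpha, v) u_i - f~_i ||^2
      + gamma * s^2 * Sum_j [ ((alpha_j - alpha0)/alpha0)^2 + ((v_j - v0)/0.5)^2 ],

where u_i are the (full) displacement fields of the n load cases, f~_i the
measured point-force vectors, and (alpha0, v0) the homogeneous linear-FEM
anchor.  The anchor terms are nondimensionalized — alpha deviations by the
anchor modulus, v deviations by the fixed width of the admissible Poisson
range (the fitted v0 can land near its search bound on mis-specified data,
so it is no safe yardstick) — and by the RMS force scale s, making gamma a
unitless relative weight.

The physical bounds alpha > 0 and 0 < v < 0.5 are enforced through a smooth
reparameterization (log for alpha, scaled logistic for v), so the LM solver
runs unconstrained.  The residual vector and its analytic Jacobian are
exposed as two callables; || residual ||^2 equals the objective above.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elasticity import phi_psi
from .experiment import LoadCase
from .fem import FEMOperator
from .linear_init import InitialParams

__all__ = ["ParameterField", "ObjectiveSpec", "pack", "unpack", "residual_vector",
           "jacobian", "complete_load_case"]

_T_CLIP = 30.0    # logistic argument clip; keeps v strictly inside (0, 0.5) in floats
_A_CLIP = 300.0   # log-alpha clip
_V_SCALE = 0.5    # natural scale of Poisson's ratio (width of its range)


@dataclass(frozen=True)
class ParameterField:
    """Per-hexahedron substitution parameters as flat arrays."""

    alpha: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if a.shape != v.shape or a.ndim != 1:
            raise ValueError("alpha and v must be 1-D arrays of equal length")
        if np.any(a <= 0):
            raise ValueError("all substitution moduli must be positive")
        if np.any((v <= 0) | (v >= 0.5)):
            raise ValueError("all Poisson ratios must lie strictly in (0, 0.5)")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "v", v)

    @property
    def k(self) -> int:
        return self.alpha.size

    def young_modulus(self) -> np.ndarray:
        return self.alpha * (1.0 + self.v) * (1.0 - 2.0 * self.v)


def pack(field: ParameterField) -> np.ndarray:
    """Map (alpha, v) to unconstrained coordinates x = [log alpha, logit 2v]."""
    a = np.log(field.alpha)
    t = np.log(2.0 * field.v) - np.log(1.0 - 2.0 * field.v)
    return np.concatenate([a, t])


def unpack(x: np.ndarray, k: int | None = None) -> ParameterField:
    """Inverse of :func:`pack`; any real x maps to a feasible field."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size % 2:
        raise ValueError(f"packed vector must have even length; got {x.shape}")
    k = x.size // 2 if k is None else k
    a = np.clip(x[:k], -_A_CLIP, _A_CLIP)
    t = np.clip(x[k:], -_T_CLIP, _T_CLIP)
    alpha = np.exp(a)
    v = 0.5 / (1.0 + np.exp(-t))
    return ParameterField(alpha=alpha, v=v)


def _transform_derivatives(field: ParameterField) -> tuple[np.ndarray, np.ndarray]:
    """(d alpha / d a, d v / d t) at the current field."""
    return field.alpha, field.v * (1.0 - 2.0 * field.v)


@dataclass
class ObjectiveSpec:
    """Data, regularization and bookkeeping for one inverse problem.

    gamma is the relative regularization weight (>= 0); the anchor is the
    pooled linear-init estimate.  ``force_scale`` nondimensionalizes the
    anchor rows; by default it is the RMS measured-force norm spread over
    the 2k parameters, so gamma ~ 1 balances data misfit and anchor pull.
    """

    op: FEMOperator
    cases: list[LoadCase]
    gamma: float
    anchor: InitialParams
    force_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative; got {self.gamma}")
        if not self.cases:
            raise ValueError("no load cases")
        self._u = []
        self._f = []
        for lc in self.cases:
            if lc.U_full is None:
                raise ValueError("load case lacks a displacement field; run complete_load_case first")
            self._u.append(self.op.free_vector_from_field(lc.U_full))
            self._f.append(self.op.point_load(lc.load_node, lc.force_3vector()))
        if self.force_scale == 0.0:
            k2 = 2 * self.op.n_hexes
            self.force_scale = float(np.sqrt(sum(f @ f for f in self._f) / k2))

    @property
    def k(self) -> int:
        return self.op.n_hexes

    @property
    def n_residuals(self) -> int:
        n = len(self.cases) * self.op.n_dof
        return n + (2 * self.k if self.gamma > 0 else 0)

    def objective_value(self, field: ParameterField) -> float:
        """Direct scalar evaluation of the regularized objective (oracle path)."""
        K = self.op.assemble(field.alpha, field.v)
        val = sum(float(np.sum((K @ u - f) ** 2)) for u, f in zip(self._u, self._f))
        if self.gamma > 0:
            w = self.gamma * self.force_scale**2
            val += w * float(np.sum(((field.alpha - self.anchor.alpha0) / self.anchor.alpha0) ** 2))
            val += w * float(np.sum(((field.v - self.anchor.v0) / _V_SCALE) ** 2))
        return val

    def residual_fn(self):
        return lambda x: residual_vector(x, self)

    def jacobian_fn(self):
        return lambda x: jacobian(x, self)

    def initial_point(self) -> np.ndarray:
        """Packed start: the homogeneous anchor replicated over all hexahedra."""
        k = self.k
        return pack(ParameterField(alpha=np.full(k, self.anchor.alpha0), v=np.full(k, self.anchor.v0)))


def residual_vector(x: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Stacked residual: per-case force residuals, then scaled anchor rows."""
    field = unpack(x, spec.k)
    K = spec.op.assemble(field.alpha, field.v)
    parts = [K @ u - f for u, f in zip(spec._u, spec._f)]
    if spec.gamma > 0:
        w = np.sqrt(spec.gamma) * spec.force_scale
        parts.append(w * (field.alpha - spec.anchor.alpha0) / spec.anchor.alpha0)
        parts.append(w * (field.v - spec.anchor.v0) / _V_SCALE)
    return np.concatenate(parts)


def jacobian(x: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Analytic Jacobian of :func:`residual_vector` in packed coordinates.

    The force block uses (dK/dalpha_j) u = Sum_{tets of j} (A_G + v_j A_H) u
    and (dK/dv_j) u = alpha_j Sum A_H u, chain-ruled through the bound
    transform; the anchor block is the scaled transform derivative.
    """
    field = unpack(x, spec.k)
    k = spec.k
    n_dof = spec.op.n_dof
    da, dt = _transform_derivatives(field)
    J = np.zeros((spec.n_residuals, 2 * k))
    for i, u in enumerate(spec._u):
        out_a, out_h = spec.op.stiffness_derivative_actions(field.v, u)
        rows = slice(i * n_dof, (i + 1) * n_dof)
        J[rows, :k] = out_a * da[None, :]
        J[rows, k:] = out_h * (field.alpha * dt)[None, :]
    if spec.gamma > 0:
        w = np.sqrt(spec.gamma) * spec.force_scale
        base = len(spec.cases) * n_dof
        J[base : base + k, :k] = np.diag(w * da / spec.anchor.alpha0)
        J[base + k :, k:] = np.diag(w * dt / _V_SCALE)
    return J


def complete_load_case(
    op: FEMOperator,
    v: float,
    case: LoadCase,
    measured_nodes: np.ndarray,
) -> LoadCase:
    """Fill unmeasured DOFs of a surface-only measurement by static condensation.

    The measured surface nodes are held at their recorded displacements
    (Dirichlet data) and every other free DOF is solved from interior
    equilibrium at a homogeneous material with Poisson ratio ``v`` — Young's
    modulus cancels because the unmeasured DOFs carry no external force.
    The loaded node must be among the measured nodes.
    """
    mesh = op.mesh
    if case.surface_disp is None:
        raise ValueError("load case has no measured surface displacements")
    measured_nodes = np.asarray(measured_nodes, dtype=int)
    if case.load_node not in set(measured_nodes.tolist()):
        raise ValueError("the loaded node must be part of the measured set")

    phi, psi = phi_psi(v)
    KG, KH = op.homogeneous_parts()
    K = (phi * KG + psi * KH).tocsr()

    surf_pos = {int(n): i for i, n in enumerate(mesh.surface_nodes)}
    m_dofs = []
    m_vals = []
    for n in measured_nodes:
        d = op.node_dof[n]
        if d < 0:
            continue
        m_dofs.extend(range(d, d + 3))
        m_vals.extend(case.surface_disp[surf_pos[int(n)]])
    m_dofs = np.asarray(m_dofs, dtype=int)
    m_vals = np.asarray(m_vals, dtype=float)

    all_dofs = np.arange(op.n_dof)
    unknown = np.setdiff1d(all_dofs, m_dofs)
    K_uu = K[unknown][:, unknown].tocsc()
    K_um = K[unknown][:, m_dofs]
    u_u = spla.splu(K_uu).solve(-K_um @ m_vals)

    u_free = np.zeros(op.n_dof)
    u_free[m_dofs] = m_vals
    u_free[unknown] = u_u
    return replace(case, U_full=op.field_from_free_vector(u_free))
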