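"""Stiffness assembly and static solves in substitution parameters.

Each tetrahedron contributes Ke(alpha, v) = alpha*A_G + alpha*v*A_H with the
parameter-independent operators

    A_G = Ve * Be^T G Be,      A_H = Ve * Be^T H Be,

precomputed once per element.  Reassembling the global stiffness for new
parameters is then a cheap weighted sum over a fixed sparsity pattern, and
the stiffness derivatives dK/dalpha_j and dK/dv_j needed by the inverse
problem are equally cheap.  Bottom-face constraints are applied by
eliminating fixed DOFs (row/column deletion), keeping the reduced matrix
symmetric positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elasticity import SubstitutionParams, basis_matrices, constitutive_matrix
from .mesh import Mesh, TetElement

__all__ = ["element_operators", "element_stiffness", "FEMOperator", "assemble_global", "solve_static", "compute_forces"]


def element_operators(elem: TetElement) -> tuple[np.ndarray, np.ndarray]:
    """Parameter-independent element operators (A_G, A_H), both 12x12 symmetric."""
    G, H = basis_matrices()
    A_G = elem.Ve * elem.Be.T @ G @ elem.Be
    A_H = elem.Ve * elem.Be.T @ H @ elem.Be
    return A_G, A_H


def element_stiffness(elem: TetElement, p: SubstitutionParams) -> np.ndarray:
    """Ke = alpha*A_G + alpha*v*A_H  (== Ve * Be^T D(alpha, v) Be)."""
    A_G, A_H = element_operators(elem)
    return p.alpha * A_G + (p.alpha * p.v) * A_H


class FEMOperator:
    """Precomputed assembly machinery for one mesh.

    Holds the stacked per-tetrahedron operators, the free-DOF numbering
    (fixed bottom-face DOFs eliminated) and the COO scatter pattern of the
    reduced global stiffness, so that K(alpha, v), the two partial
    stiffness-action derivatives, and the homogeneous split
    K = E*(phi*K_G + psi*K_H) are all vectorized operations.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        n_nodes = mesh.n_nodes
        self.n_hexes = mesh.hexahedra.shape[0]
        n_tet = len(mesh.tetrahedra)

        free_mask = np.ones(n_nodes, dtype=bool)
        free_mask[mesh.fixed_nodes] = False
        self.free_nodes = np.nonzero(free_mask)[0]
        self.n_free_nodes = self.free_nodes.size
        self.n_dof = 3 * self.n_free_nodes
        # node -> first free-DOF index, -1 if fixed
        self.node_dof = np.full(n_nodes, -1, dtype=int)
        self.node_dof[self.free_nodes] = 3 * np.arange(self.n_free_nodes)

        self.tet_nodes = np.array([t.node_ids for t in mesh.tetrahedra], dtype=int)
        self.tet_hex = mesh.tet_parent
        self.A_G = np.stack([element_operators(t)[0] for t in mesh.tetrahedra])
        self.A_H = np.stack([element_operators(t)[1] for t in mesh.tetrahedra])

        # per-tet 12 global free-DOF indices (-1 where the DOF is fixed)
        base = self.node_dof[self.tet_nodes]                     # (n_tet, 4)
        dofs = base[:, :, None] + np.arange(3)[None, None, :]    # (n_tet, 4, 3)
        dofs[base < 0] = -1
        self.tet_dofs = dofs.reshape(n_tet, 12)

        # COO pattern over free x free entries
        rows = np.repeat(self.tet_dofs, 12, axis=1)              # (n_tet, 144)
        cols = np.tile(self.tet_dofs, (1, 12))
        keep = (rows >= 0) & (cols >= 0)
        self._coo_rows = rows[keep]
        self._coo_cols = cols[keep]
        self._coo_keep = keep
        self._entry_tet = np.repeat(np.arange(n_tet), keep.sum(axis=1))

        # cache the CSR structure once; subsequent assemblies only fill data
        template = sp.coo_matrix(
            (np.ones_like(self._coo_rows, dtype=float), (self._coo_rows, self._coo_cols)),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()
        template.sort_indices()
        self._csr_indptr = template.indptr
        self._csr_indices = template.indices
        # map COO entries (duplicates sum) onto CSR data slots via a stable sort
        key = self._coo_rows.astype(np.int64) * self.n_dof + self._coo_cols
        self._entry_order = np.argsort(key, kind="stable")
        self._entry_key_sorted = key[self._entry_order]
        uniq, counts = np.unique(self._entry_key_sorted, return_counts=True)
        self._entry_slot = np.repeat(np.arange(uniq.size), counts)
        self._n_slots = uniq.size
        assert self._n_slots == self._csr_indices.size

        self._KG = None   # cached homogeneous pieces (assembled at weight 1)
        self._KH = None

    # -- assembly -----------------------------------------------------------

    def _fill_csr(self, entry_vals: np.ndarray) -> sp.csr_matrix:
        data = np.zeros(self._n_slots)
        np.add.at(data, self._entry_slot, entry_vals[self._entry_order])
        return sp.csr_matrix((data, self._csr_indices, self._csr_indptr), shape=(self.n_dof, self.n_dof))

    def _entry_values(self, tet_weights_G: np.ndarray, tet_weights_H: np.ndarray) -> np.ndarray:
        vals = (
            tet_weights_G[:, None, None] * self.A_G + tet_weights_H[:, None, None] * self.A_H
        ).reshape(len(self.tet_nodes), 144)
        return vals[self._coo_keep]

    def assemble(self, alpha: np.ndarray, v: np.ndarray) -> sp.csr_matrix:
        """Reduced global stiffness K(alpha, v) over free DOFs (CSR, SPD)."""
        alpha = np.asarray(alpha, dtype=float)
        v = np.asarray(v, dtype=float)
        if alpha.shape != (self.n_hexes,) or v.shape != (self.n_hexes,):
            raise ValueError(
                f"need one (alpha, v) pair per hexahedron ({self.n_hexes}); got {alpha.shape}, {v.shape}"
            )
        a_t = alpha[self.tet_hex]
        v_t = v[self.tet_hex]
        return self._fill_csr(self._entry_values(a_t, a_t * v_t))

    def homogeneous_parts(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """(K_G, K_H): assembled Sum A_G and Sum A_H, so that a homogeneous
        material gives K = E*(phi(v) K_G + psi(v) K_H)."""
        if self._KG is None:
            ones = np.ones(len(self.tet_nodes))
            zeros = np.zeros(len(self.tet_nodes))
            self._KG = self._fill_csr(self._entry_values(ones, zeros))
            self._KH = self._fill_csr(self._entry_values(zeros, ones))
        return self._KG, self._KH

    # -- derivative actions --------------------------------------------------

    def stiffness_derivative_actions(self, v: np.ndarray, u_free: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-hexahedron columns (dK/dalpha_j) u and (dK/dv_j) u / alpha_j.

        Returns two (n_dof, n_hexes) dense arrays:
        col j of the first  = Sum_{tets of j} (A_G + v_j A_H) u  scattered;
        col j of the second = Sum_{tets of j} A_H u               scattered
        (the caller multiplies by alpha_j for dK/dv_j).
        """
        u_t = self._gather(u_free)                                    # (n_tet, 12)
        gv = np.einsum("tij,tj->ti", self.A_G, u_t)
        hv = np.einsum("tij,tj->ti", self.A_H, u_t)
        da = gv + v[self.tet_hex][:, None] * hv
        out_a = np.zeros((self.n_dof, self.n_hexes))
        out_h = np.zeros((self.n_dof, self.n_hexes))
        dofs = self.tet_dofs
        ok = dofs >= 0
        hex_idx = np.repeat(self.tet_hex, 12).reshape(-1, 12)
        np.add.at(out_a, (dofs[ok], hex_idx[ok]), da[ok])
        np.add.at(out_h, (dofs[ok], hex_idx[ok]), hv[ok])
        return out_a, out_h

    def _gather(self, u_free: np.ndarray) -> np.ndarray:
        u_pad = np.append(u_free, 0.0)                                # -1 -> 0
        return u_pad[self.tet_dofs]

    # -- field bookkeeping ---------------------------------------------------

    def free_vector_from_field(self, U: np.ndarray) -> np.ndarray:
        """Flatten an (n_nodes, 3) displacement field to the free-DOF vector."""
        return np.asarray(U, dtype=float)[self.free_nodes].ravel()

    def field_from_free_vector(self, u_free: np.ndarray) -> np.ndarray:
        """Expand a free-DOF vector to an (n_nodes, 3) field (fixed nodes zero)."""
        U = np.zeros((self.mesh.n_nodes, 3))
        U[self.free_nodes] = np.asarray(u_free, dtype=float).reshape(-1, 3)
        return U

    def point_load(self, node: int, force: np.ndarray) -> np.ndarray:
        """Free-DOF force vector for a point load at ``node``."""
        d = self.node_dof[node]
        if d < 0:
            raise ValueError(f"node {node} is constrained; cannot load it")
        F = np.zeros(self.n_dof)
        F[d : d + 3] = force
        return F


@dataclass
class GlobalSystem:
    """Assembled reduced system: K over free DOFs plus the operator that
    knows the DOF bookkeeping."""

    K: sp.csr_matrix
    op: FEMOperator


def assemble_global(mesh: Mesh, params: list[SubstitutionParams] | tuple[np.ndarray, np.ndarray],
                    op: FEMOperator | None = None) -> GlobalSystem:
    """Assemble the constrained global stiffness for per-hexahedron parameters."""
    if op is None:
        op = FEMOperator(mesh)
    if isinstance(params, tuple):
        alpha, v = params
    else:
        alpha = np.array([p.alpha for p in params])
        v = np.array([p.v for p in params])
    return GlobalSystem(K=op.assemble(alpha, v), op=op)


def solve_static(system: GlobalSystem, F: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Solve K u = F on free DOFs with a sparse direct factorization.

    Raises if the relative residual exceeds ``rtol`` (singular or severely
    ill-conditioned K, e.g. missing constraints).
    """
    F = np.asarray(F, dtype=float)
    if F.shape[-1] != system.K.shape[0]:
        raise ValueError(f"force vector length {F.shape} does not match {system.K.shape[0]} free DOFs")
    if not np.any(F):
        return np.zeros_like(F)
    try:
        lu = spla.splu(system.K.tocsc())
        u = lu.solve(F)
    except RuntimeError as exc:                      # singular factorization
        raise np.linalg.LinAlgError(f"stiffness factorization failed: {exc}") from exc
    res = np.linalg.norm(system.K @ u - F) / np.linalg.norm(F)
    if not np.isfinite(res) or res > rtol:
        raise np.linalg.LinAlgError(
            f"static solve residual {res:.3e} exceeds tolerance {rtol:.1e}; "
            "check constraints and parameter ranges"
        )
    return u


def compute_forces(system: GlobalSystem, u: np.ndarray) -> np.ndarray:
    """Nodal force vector F = K u realized by a displacement state."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != system.K.shape[0]:
        raise ValueError(f"displacement vector length {u.shape} does not match {system.K.shape[0]} free DOFs")
    return system.K @ u
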