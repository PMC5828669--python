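"""Volumetric mesh construction from a surface sampling grid.

The measurement rig samples a regular rows x columns grid of markers on the
top surface of a rectangular block whose bottom face is fixed.  For the
finite-element model the surface grid is extruded through the block depth
into a lattice of hexahedral cells, and each hexahedron is split into five
tetrahedra.  The split parity alternates in a 3D checkerboard so that the
face diagonals of neighbouring hexahedra coincide (a conforming mesh).

Material parameters live per hexahedron; the five child tetrahedra of a
hexahedron share them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "TetElement",
    "Mesh",
    "build_grid_mesh",
    "split_hexahedron",
    "tet_geometry",
    "write_vtk",
]


@dataclass(frozen=True)
class GridSpec:
    """Lattice of nodes: ``n_cols x n_rows`` on the surface, ``n_layers`` deep.

    ``extent`` is the physical (L, W, H) of the block in meters; columns run
    along L (x), rows along W (y), layers through H (z, bottom at z = 0).
    """

    n_cols: int = 23
    n_rows: int = 13
    n_layers: int = 3
    extent: tuple[float, float, float] = (0.50, 0.30, 0.10)

    def __post_init__(self) -> None:
        for name in ("n_cols", "n_rows", "n_layers"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2; got {getattr(self, name)}")
        if any(e <= 0 for e in self.extent):
            raise ValueError(f"extents must be positive; got {self.extent}")

    @property
    def n_nodes(self) -> int:
        return self.n_cols * self.n_rows * self.n_layers

    @property
    def n_hexes(self) -> int:
        return (self.n_cols - 1) * (self.n_rows - 1) * (self.n_layers - 1)


@dataclass(frozen=True)
class TetElement:
    """Linear 4-node tetrahedron: volume Ve [m^3] and the constant 6x12
    strain-displacement matrix Be [1/m] (Voigt order xx,yy,zz,yz,xz,xy,
    engineering shear)."""

    node_ids: tuple[int, int, int, int]
    Ve: float
    Be: np.ndarray


@dataclass
class Mesh:
    """Conforming tetrahedral mesh over a hexahedral lattice.

    ``tetrahedra[t]`` belongs to hexahedron ``tet_parent[t]``; parameters are
    shared within a hexahedron.  ``surface_nodes`` lists the top-layer nodes
    in row-major (row, then column) order, matching the displacement CSVs.
    """

    nodes: np.ndarray                      # (n_nodes, 3) meters
    hexahedra: np.ndarray                  # (n_hex, 8) node indices
    tetrahedra: list[TetElement]
    tet_parent: np.ndarray                 # (n_tet,) hexahedron index
    fixed_nodes: np.ndarray                # bottom-face node indices
    surface_nodes: np.ndarray              # top-face node indices, row-major
    grid: GridSpec | None = None
    surface_grid_shape: tuple[int, int] = (0, 0)   # (n_rows, n_cols)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def surface_node_at(self, row: int, col: int, one_based: bool = False) -> int:
        """Node index of the surface marker at (row, col)."""
        if one_based:
            row, col = row - 1, col - 1
        n_rows, n_cols = self.surface_grid_shape
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise IndexError(f"surface position ({row}, {col}) outside grid {self.surface_grid_shape}")
        return int(self.surface_nodes[row * n_cols + col])


def tet_geometry(coords: np.ndarray, node_ids: tuple[int, int, int, int] = (0, 1, 2, 3)) -> TetElement:
    """Volume and strain-displacement matrix of a linear tetrahedron.

    ``coords`` is 4x3.  Shape-function gradients come from the inverse of
    the edge matrix; Be maps the 12 nodal displacement components (x,y,z per
    node, node-major) to the 6 Voigt strains and annihilates rigid
    translations by construction.
    """
    coords = np.asarray(coords, dtype=float)
    T = coords[1:] - coords[0]                       # rows: p2-p1, p3-p1, p4-p1
    det = np.linalg.det(T)
    if abs(det) < 1e-300 or abs(det) < 1e-12 * max(np.abs(T).max(), 1e-30) ** 3:
        raise ValueError("degenerate tetrahedron: coplanar nodes")
    Ve = abs(det) / 6.0
    # p = p1 + T^T (lam2, lam3, lam4), so grad lam_{i+1} are the rows of inv(T)^T
    grads = np.zeros((4, 3))
    grads[1:] = np.linalg.inv(T).T
    grads[0] = -grads[1:].sum(axis=0)
    Be = np.zeros((6, 12))
    for a in range(4):
        bx, by, bz = grads[a]
        c = 3 * a
        Be[0, c] = bx
        Be[1, c + 1] = by
        Be[2, c + 2] = bz
        Be[3, c + 1] = bz      # gamma_yz = dv/dz + dw/dy
        Be[3, c + 2] = by
        Be[4, c] = bz          # gamma_xz = du/dz + dw/dx
        Be[4, c + 2] = bx
        Be[5, c] = by          # gamma_xy = du/dy + dv/dx
        Be[5, c + 1] = bx
    return TetElement(node_ids=tuple(int(i) for i in node_ids), Ve=Ve, Be=Be)


# Corner selections of the standard 5-tet split.  Hexahedron corners are
# ordered VTK-style: bottom face 0-1-2-3 counter-clockwise, top 4-5-6-7.
# Even parity cuts off corners 0, 2, 5, 7; odd parity corners 1, 3, 4, 6.
# The alternation makes shared faces of neighbouring cells use the same
# diagonal.
_SPLIT_EVEN = ((0, 1, 3, 4), (1, 2, 3, 6), (4, 5, 6, 1), (4, 6, 7, 3), (1, 6, 3, 4))
_SPLIT_ODD = ((0, 1, 2, 5), (0, 2, 3, 7), (0, 4, 5, 7), (2, 5, 6, 7), (0, 5, 2, 7))


def split_hexahedron(corner_nodes, parity: int):
    """Split one hexahedron into 5 tetrahedra (4 corner tets + 1 central).

    ``corner_nodes`` are 8 node indices in VTK ordering; ``parity`` in {0, 1}
    selects which of the two mirror decompositions is used, to be alternated
    in a checkerboard across the lattice.
    """
    corner_nodes = list(corner_nodes)
    if len(corner_nodes) != 8:
        raise ValueError("a hexahedron has 8 corner nodes")
    pattern = _SPLIT_EVEN if parity % 2 == 0 else _SPLIT_ODD
    return [tuple(corner_nodes[i] for i in tet) for tet in pattern]


def _signed_vol(c: np.ndarray) -> float:
    return float(np.linalg.det(c[1:] - c[0])) / 6.0


def build_grid_mesh(spec: GridSpec) -> Mesh:
    """Extrude the surface sampling grid into a conforming 5-tet lattice mesh."""
    nc, nr, nl = spec.n_cols, spec.n_rows, spec.n_layers
    L, W, H = spec.extent
    xs = np.linspace(0.0, L, nc)
    ys = np.linspace(0.0, W, nr)
    zs = np.linspace(0.0, H, nl)

    def nid(c: int, r: int, l: int) -> int:
        return (l * nr + r) * nc + c

    nodes = np.empty((spec.n_nodes, 3))
    for l in range(nl):
        for r in range(nr):
            for c in range(nc):
                nodes[nid(c, r, l)] = (xs[c], ys[r], zs[l])

    hexes = []
    tets: list[TetElement] = []
    parents = []
    for l in range(nl - 1):
        for r in range(nr - 1):
            for c in range(nc - 1):
                # VTK ordering: bottom face CCW, then top face
                corners = (
                    nid(c, r, l), nid(c + 1, r, l), nid(c + 1, r + 1, l), nid(c, r + 1, l),
                    nid(c, r, l + 1), nid(c + 1, r, l + 1), nid(c + 1, r + 1, l + 1), nid(c, r + 1, l + 1),
                )
                hex_id = len(hexes)
                hexes.append(corners)
                for tet_nodes in split_hexahedron(corners, parity=(c + r + l) % 2):
                    coords = nodes[list(tet_nodes)]
                    if _signed_vol(coords) < 0:        # orient positively
                        tet_nodes = (tet_nodes[0], tet_nodes[1], tet_nodes[3], tet_nodes[2])
                        coords = nodes[list(tet_nodes)]
                    tets.append(tet_geometry(coords, tet_nodes))
                    parents.append(hex_id)

    fixed = np.array([nid(c, r, 0) for r in range(nr) for c in range(nc)], dtype=int)
    surface = np.array([nid(c, r, nl - 1) for r in range(nr) for c in range(nc)], dtype=int)
    return Mesh(
        nodes=nodes,
        hexahedra=np.array(hexes, dtype=int),
        tetrahedra=tets,
        tet_parent=np.array(parents, dtype=int),
        fixed_nodes=fixed,
        surface_nodes=surface,
        grid=spec,
        surface_grid_shape=(nr, nc),
    )


def write_vtk(mesh: Mesh, path, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the tetrahedral mesh as legacy-VTK ASCII for visual inspection.

    ``cell_data`` maps names to per-hexahedron scalars (e.g. estimated E or
    v maps); values are broadcast to the child tetrahedra.
    """
    lines = ["# vtk DataFile Version 3.0", "elastinv mesh", "ASCII", "DATASET UNSTRUCTURED_GRID"]
    lines.append(f"POINTS {mesh.n_nodes} double")
    lines.extend(" ".join(f"{x:.9g}" for x in p) for p in mesh.nodes)
    n_tet = len(mesh.tetrahedra)
    lines.append(f"CELLS {n_tet} {5 * n_tet}")
    lines.extend("4 " + " ".join(str(i) for i in t.node_ids) for t in mesh.tetrahedra)
    lines.append(f"CELL_TYPES {n_tet}")
    lines.extend(["10"] * n_tet)                      # VTK_TETRA
    if cell_data:
        lines.append(f"CELL_DATA {n_tet}")
        for name, vals in cell_data.items():
            vals = np.asarray(vals, dtype=float)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{vals[p]:.9g}" for p in mesh.tet_parent)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
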