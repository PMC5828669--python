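"""Containers for indentation load cases and synthetic experiments."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["LoadCase", "SyntheticExperiment"]


@dataclass
class LoadCase:
    """One indentation: a vertical point force and the deformation it caused.

    magnitude     -- measured external force, Newton (applied along -z)
    load_node     -- mesh node index where the force acts (top surface)
    U_full        -- (n_nodes, 3) displacement field in meters, when known
                     (synthetic truth, or a completed measurement); fixed
                     nodes carry zeros
    surface_disp  -- (n_surface, 3) measured surface displacements in meters,
                     ordered like ``mesh.surface_nodes`` (may carry noise)
    """

    magnitude: float
    load_node: int
    U_full: np.ndarray | None = None
    surface_disp: np.ndarray | None = None

    def force_3vector(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.magnitude])


@dataclass
class SyntheticExperiment:
    """Ground-truth experiment bundle produced by the synthetic generator."""

    mesh: Any
    true_alpha: np.ndarray          # per-hexahedron
    true_v: np.ndarray
    true_E: np.ndarray
    load_cases: list[LoadCase]
    noiseless_cases: list[LoadCase]
    provenance: dict = field(default_factory=dict)
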