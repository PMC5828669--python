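"""Isotropic linear-elastic constitutive model in substitution parameters.

The stress--strain law sigma = D eps for an isotropic material is usually
written in terms of Young's modulus E and Poisson's ratio v:

    D = E / ((1+v)(1-2v)) * (G + v*H)

with two constant 6x6 matrices G and H (Voigt ordering xx, yy, zz, yz, xz,
xy; engineering shear strains).  Introducing the substitution modulus

    alpha = E / ((1+v)(1-2v))

makes the law bilinear, D = alpha*G + alpha*v*H, which is what renders the
element stiffness nearly bilinear in (alpha, v) and keeps the inverse
problem tractable.  This module holds G, H, the parameter conversions and
the phi/psi helper factors used by the linear initializer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElasticParams",
    "SubstitutionParams",
    "basis_matrices",
    "substitution_from_engineering",
    "engineering_from_substitution",
    "constitutive_matrix",
    "phi_psi",
]

#: Voigt component order used everywhere in this package.
VOIGT_ORDER = ("xx", "yy", "zz", "yz", "xz", "xy")


def _check_poisson(v: float) -> None:
    # v = 0 (no lateral contraction) is admitted; v = 0.5 (incompressible)
    # is a genuine singularity of alpha and stays excluded.
    if not (0.0 <= v < 0.5):
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5); got {v}")


@dataclass(frozen=True)
class ElasticParams:
    """Engineering elastic parameters: Young's modulus E [Pa], Poisson's ratio v."""

    E: float
    v: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive; got {self.E}")
        _check_poisson(self.v)


@dataclass(frozen=True)
class SubstitutionParams:
    """Substitution parameters: alpha = E/((1+v)(1-2v)) [Pa], Poisson's ratio v."""

    alpha: float
    v: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"Substitution modulus must be positive; got {self.alpha}")
        _check_poisson(self.v)


# G + v*H reproduces the bracket of the classical isotropic elasticity
# matrix for every v: diagonal (1-v, 1-v, 1-v, (1-2v)/2 ...), off-diagonal
# v in the normal block.
_G = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
_H = np.zeros((6, 6))
_H[:3, :3] = 1.0
np.fill_diagonal(_H, -1.0)
_G.setflags(write=False)
_H.setflags(write=False)


def basis_matrices() -> tuple[np.ndarray, np.ndarray]:
    """Return the constant matrices (G, H) of the decomposition D = alpha(G + vH)."""
    return _G, _H


def substitution_from_engineering(p: ElasticParams) -> SubstitutionParams:
    """Convert (E, v) to (alpha, v) with alpha = E / ((1+v)(1-2v))."""
    return SubstitutionParams(alpha=p.E / ((1.0 + p.v) * (1.0 - 2.0 * p.v)), v=p.v)


def engineering_from_substitution(p: SubstitutionParams) -> ElasticParams:
    """Convert (alpha, v) back to (E, v): E = alpha (1+v)(1-2v)."""
    return ElasticParams(E=p.alpha * (1.0 + p.v) * (1.0 - 2.0 * p.v), v=p.v)


def constitutive_matrix(p: SubstitutionParams) -> np.ndarray:
    """6x6 stress-strain matrix D = alpha*G + alpha*v*H (symmetric, PD)."""
    return p.alpha * _G + (p.alpha * p.v) * _H


def phi_psi(v: float) -> tuple[float, float]:
    """Factors phi(v) = 1/((1+v)(1-2v)) and psi(v) = v*phi(v).

    With these, D = E*(phi(v) G + psi(v) H), i.e. Young's modulus factors
    out of the stiffness — the property the linear initializer exploits.
    """
    if not (0.0 <= v < 0.5):
        raise ValueError(f"Poisson's ratio must lie in [0, 0.5); got {v}")
    phi = 1.0 / ((1.0 + v) * (1.0 - 2.0 * v))
    return phi, v * phi
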