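import numpy as np
import pytest

from elastinv.fem import FEMOperator
from elastinv.mesh import GridSpec, build_grid_mesh
from elastinv.synthetic import ScenarioSpec, generate_experiment


def classical_isotropic_D(E: float, v: float) -> np.ndarray:
    """Independent oracle: the textbook isotropic elasticity matrix in Voigt
    notation (xx, yy, zz, yz, xz, xy; engineering shear strains)."""
    c = E / ((1.0 + v) * (1.0 - 2.0 * v))
    D = np.full((3, 3), c * v)
    np.fill_diagonal(D, c * (1.0 - v))
    out = np.zeros((6, 6))
    out[:3, :3] = D
    for i in range(3, 6):
        out[i, i] = c * (1.0 - 2.0 * v) / 2.0
    return out


@pytest.fixture(scope="session")
def small_mesh():
    """2-hexahedron bar, bottom fixed."""
    return build_grid_mesh(GridSpec(3, 2, 2, (0.2, 0.1, 0.1)))


@pytest.fixture(scope="session")
def small_op(small_mesh):
    return FEMOperator(small_mesh)


@pytest.fixture(scope="session")
def homogeneous_experiment():
    """Noiseless homogeneous indentation at (E*, v*) = (8000 Pa, 0.07)."""
    spec = ScenarioSpec(
        grid=GridSpec(6, 4, 3), field_style="homogeneous",
        E_range=(8000.0, 8000.0), v_range=(0.07, 0.07),
        load_rc=(2, 4), noise_sd=0.0, seed=11,
    )
    return generate_experiment(spec)


@pytest.fixture(scope="session")
def heterogeneous_experiment():
    """Noiseless smooth-heterogeneous indentation, 30 hexahedra."""
    spec = ScenarioSpec(
        grid=GridSpec(6, 4, 3), field_style="smooth-heterogeneous",
        load_rc=(2, 4), noise_sd=0.0, seed=7,
    )
    return generate_experiment(spec)
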