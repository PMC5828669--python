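"""Synthetic indentation experiments and sensor-calibration data.

The generator emulates the acquisition setup the estimators were designed
for: a 50 x 30 x 10 cm block of soft foam-like material, bottom face fixed,
surface sampled on a 23 x 13 marker grid, a vertical point force pressed
into the marker at row 7 / column 12 at six increasing magnitudes (about
18-30 N), surface positions tracked with ~1 mm precision, and a five-channel
voltage/force calibration table over 0-3000 g with a mild nonlinear drift.
Ground truth is always retained so every estimation stage can be scored.

Parameter fields are drawn in engineering (E, v) space — a low-frequency
cosine field keeps neighbouring hexahedra within ~20% of each other, the
spatial smoothness the estimators assume — and converted to substitution
parameters for the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .elasticity import phi_psi
from .experiment import LoadCase, SyntheticExperiment
from .fem import FEMOperator, GlobalSystem, solve_static
from .inverse import ParameterField
from .mesh import GridSpec, Mesh, build_grid_mesh

__all__ = ["ScenarioSpec", "full_scale_scenario", "default_scenario",
           "generate_parameter_field", "simulate_indentation", "add_noise",
           "generate_experiment", "CalibrationData", "generate_calibration_data"]

#: The six corrected external-force magnitudes (N) of the reference
#: deformation sets A-F; the generator's default load schedule.
DEFAULT_FORCES = (18.5814, 19.9533, 21.4443, 24.0542, 27.0678, 30.1766)


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one synthetic experiment."""

    grid: GridSpec = GridSpec(23, 13, 2)
    field_style: str = "smooth-heterogeneous"      # or "homogeneous"
    E_range: tuple[float, float] = (6e3, 9e3)      # Pa, soft-foam magnitudes
    v_range: tuple[float, float] = (0.05, 0.10)
    load_rc: tuple[int, int] = (7, 12)             # 1-based (row, column)
    force_magnitudes: tuple[float, ...] = DEFAULT_FORCES
    noise_sd: float = 1e-3                         # m; ~tracker precision
    seed: int = 0
    max_neighbor_jump: float = 0.2

    def __post_init__(self) -> None:
        if self.field_style not in ("homogeneous", "smooth-heterogeneous"):
            raise ValueError(f"unknown field style {self.field_style!r}")
        if not all(b > a > 0 or (a == b > 0) for a, b in (self.E_range,)):
            raise ValueError(f"bad E_range {self.E_range}")
        lo, hi = self.v_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError(f"bad v_range {self.v_range}")
        mags = np.asarray(self.force_magnitudes)
        if mags.size and np.any(np.diff(mags) <= 0):
            raise ValueError("force magnitudes must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def full_scale_scenario(**overrides) -> ScenarioSpec:
    """Full 23 x 13 surface grid on the 50 x 30 x 10 cm block."""
    return ScenarioSpec(**overrides)


def default_scenario(**overrides) -> ScenarioSpec:
    """Downsized grid (8 x 5 surface, 3 layers) for fast tests; the load
    moves to the analogous off-center interior marker."""
    kw = dict(grid=GridSpec(8, 5, 3), load_rc=(3, 5))
    kw.update(overrides)
    return ScenarioSpec(**kw)


def _cosine_field(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth random field on the hexahedron lattice, values roughly in [-1, 1]."""
    out = np.zeros(shape)
    coords = [np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    for axis in range(3):
        prof = np.zeros(shape[axis])
        for m in range(1, 4):                       # up to 3 low-frequency modes
            amp = rng.uniform(-1.0, 1.0) / m
            phase = rng.uniform(0.0, 2.0 * np.pi)
            prof += amp * np.cos(np.pi * m * coords[axis] + phase)
        sl = [None, None, None]
        sl[axis] = slice(None)
        out = out + prof[tuple(sl)]
    m = np.abs(out).max()
    return out / m if m > 0 else out


def _limit_neighbor_jump(vals: np.ndarray, max_jump: float) -> np.ndarray:
    """Shrink deviations from the mean until adjacent cells differ by < max_jump
    in relative terms (deterministic bisection-free contraction)."""
    center = vals.mean()
    for _ in range(60):
        worst = 0.0
        for axis in range(vals.ndim):
            a = np.moveaxis(vals, axis, 0)
            if a.shape[0] < 2:
                continue
            rel = np.abs(np.diff(a, axis=0)) / np.minimum(a[:-1], a[1:])
            if rel.size:
                worst = max(worst, float(rel.max()))
        if worst <= max_jump:
            return vals
        vals = center + 0.9 * (vals - center)
    return vals


def generate_parameter_field(spec: ScenarioSpec, mesh: Mesh | None = None) -> ParameterField:
    """Draw the ground-truth per-hexahedron (alpha, v) field for a scenario."""
    g = spec.grid
    lattice = (g.n_cols - 1, g.n_rows - 1, g.n_layers - 1)
    k = int(np.prod(lattice))
    rng = np.random.default_rng(spec.seed)
    if spec.field_style == "homogeneous":
        E = np.full(k, 0.5 * (spec.E_range[0] + spec.E_range[1]))
        v = np.full(k, 0.5 * (spec.v_range[0] + spec.v_range[1]))
    else:
        fE = _cosine_field(rng, lattice)
        fv = _cosine_field(rng, lattice)

        def to_range(f, lo, hi):
            f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
            return lo + f * (hi - lo)

        E3 = _limit_neighbor_jump(to_range(fE, *spec.E_range), spec.max_neighbor_jump)
        v3 = _limit_neighbor_jump(to_range(fv, *spec.v_range), spec.max_neighbor_jump)
        # hexahedron order in the mesh is (layer, row, col) C-order; the
        # lattice arrays here are (col, row, layer), so transpose
        E = E3.transpose(2, 1, 0).ravel()
        v = v3.transpose(2, 1, 0).ravel()
    alpha = E * np.array([phi_psi(x)[0] for x in v])
    return ParameterField(alpha=alpha, v=v)


def simulate_indentation(
    mesh: Mesh,
    field: ParameterField,
    load_node: int,
    magnitudes,
    op: FEMOperator | None = None,
) -> list[LoadCase]:
    """One static solve per force magnitude; vertical point load, full fields."""
    op = op or FEMOperator(mesh)
    if op.node_dof[load_node] < 0:
        raise ValueError(f"load node {load_node} is constrained")
    system = GlobalSystem(K=op.assemble(field.alpha, field.v), op=op)
    cases = []
    for mag in magnitudes:
        if mag < 0:
            raise ValueError("force magnitudes must be nonnegative")
        F = op.point_load(load_node, np.array([0.0, 0.0, -float(mag)]))
        u = solve_static(system, F)
        U = op.field_from_free_vector(u)
        cases.append(LoadCase(magnitude=float(mag), load_node=int(load_node),
                              U_full=U, surface_disp=U[mesh.surface_nodes].copy()))
    return cases


def add_noise(cases: list[LoadCase], sd: float, seed: int) -> list[LoadCase]:
    """Gaussian measurement noise on the surface displacement components only."""
    if sd < 0:
        raise ValueError("noise sd must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = []
    for lc in cases:
        surf = lc.surface_disp
        if sd > 0 and surf is not None:
            surf = surf + rng.normal(0.0, sd, size=surf.shape)
        noisy.append(replace(lc, surface_disp=surf))
    return noisy


def generate_experiment(spec: ScenarioSpec, op: FEMOperator | None = None) -> SyntheticExperiment:
    """Mesh + ground-truth field + noiseless and noisy load cases, all seeded."""
    mesh = build_grid_mesh(spec.grid)
    op = op or FEMOperator(mesh)
    field = generate_parameter_field(spec, mesh)
    load_node = mesh.surface_node_at(*spec.load_rc, one_based=True)
    clean = simulate_indentation(mesh, field, load_node, spec.force_magnitudes, op=op)
    noisy = add_noise(clean, spec.noise_sd, seed=spec.seed + 1)
    return SyntheticExperiment(
        mesh=mesh,
        true_alpha=field.alpha,
        true_v=field.v,
        true_E=field.young_modulus(),
        load_cases=noisy,
        noiseless_cases=clean,
        provenance={"scenario": spec.__dict__ | {"grid": spec.grid.__dict__}, "seed": spec.seed},
    )


@dataclass
class CalibrationData:
    """Voltage/force calibration table: 5 channels per sample, force in grams."""

    voltages: np.ndarray       # (n, 5) volts
    force_g: np.ndarray        # (n,) grams (reference, electronic-scale)
    truth: dict = field(default_factory=dict)

    @property
    def force_newton(self) -> np.ndarray:
        return self.force_g * 9.8e-3        # g = 9.8 m/s^2, grams -> N

    def __len__(self) -> int:
        return self.force_g.size


# per-channel affine sensor responses (V per gram, offset V); mild spread
_CH_GAIN = np.array([0.95, 1.00, 1.05, 0.90, 1.10]) * 1e-3
_CH_OFFSET = np.array([0.10, 0.05, 0.00, 0.15, 0.08])


def generate_calibration_data(
    n: int = 76,
    force_range: tuple[float, float] = (2.0, 3000.0),
    drift: float = 0.15,
    noise: float = 5e-3,
    seed: int = 0,
) -> CalibrationData:
    """Synthetic sensor calibration: affine response + cubic drift + noise.

    ``drift`` scales a cubic distortion (relative to full scale) emulating
    temperature/EMI nonlinearity; ``noise`` is the per-channel voltage noise
    sd in volts.  Forces are uniform over ``force_range`` (grams), sorted.
    """
    if n < 2:
        raise ValueError("need at least 2 calibration samples")
    lo, hi = force_range
    if not (0 <= lo < hi):
        raise ValueError(f"bad force range {force_range}")
    rng = np.random.default_rng(seed)
    force = np.sort(rng.uniform(lo, hi, size=n))
    x = force / 3000.0
    volts = force[:, None] * _CH_GAIN[None, :] + _CH_OFFSET[None, :]
    volts = volts + drift * (x**3)[:, None] * (_CH_GAIN * 3000.0)[None, :]
    if noise > 0:
        volts = volts + rng.normal(0.0, noise, size=volts.shape)
    return CalibrationData(voltages=volts, force_g=force,
                           truth={"drift": drift, "noise": noise, "seed": seed})
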