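"""Inverse problem: packing transform, residual/objective identity, Jacobian."""

import numpy as np
import pytest

from elastinv.fem import FEMOperator
from elastinv.inverse import (
    ObjectiveSpec,
    ParameterField,
    complete_load_case,
    jacobian,
    pack,
    residual_vector,
    unpack,
)
from elastinv.linear_init import solve_initial_params
from elastinv.mesh import GridSpec, build_grid_mesh
from elastinv.synthetic import ScenarioSpec, generate_experiment


@pytest.fixture(scope="module")
def two_hex_problem():
    """Tiny 2-hexahedron inverse problem with noiseless data."""
    spec = ScenarioSpec(grid=GridSpec(3, 2, 2, (0.2, 0.1, 0.1)),
                        field_style="smooth-heterogeneous",
                        load_rc=(1, 2), noise_sd=0.0, seed=13)
    exp = generate_experiment(spec)
    op = FEMOperator(exp.mesh)
    anchor = solve_initial_params(op, exp.noiseless_cases)
    return exp, op, anchor


class TestPacking:
    def test_round_trip(self):
        f = ParameterField(alpha=np.array([1e3, 5e4, 2.7]), v=np.array([0.01, 0.25, 0.499]))
        g = unpack(pack(f))
        assert np.allclose(g.alpha, f.alpha, rtol=1e-12)
        assert np.allclose(g.v, f.v, rtol=1e-12)

    def test_packed_length(self):
        f = ParameterField(alpha=np.ones(7) * 1e3, v=np.full(7, 0.2))
        assert pack(f).size == 14

    def test_any_real_vector_maps_to_feasible_field(self):
        rng = np.random.default_rng(3)
        x = rng.normal(scale=30.0, size=10)
        f = unpack(x)
        assert np.all(f.alpha > 0)
        assert np.all((f.v > 0) & (f.v < 0.5))

    def test_invalid_field_rejected(self):
        with pytest.raises(ValueError):
            ParameterField(alpha=np.array([-1.0]), v=np.array([0.2]))
        with pytest.raises(ValueError):
            ParameterField(alpha=np.array([1.0]), v=np.array([0.5]))


class TestResidual:
    def test_zero_at_truth_without_regularization(self, two_hex_problem):
        exp, op, anchor = two_hex_problem
        spec = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=0.0, anchor=anchor)
        x = pack(ParameterField(alpha=exp.true_alpha, v=exp.true_v))
        Y = residual_vector(x, spec)
        fnorm = np.sqrt(sum(f @ f for f in spec._f))
        assert np.linalg.norm(Y) < 1e-8 * fnorm

    def test_norm_squared_equals_scalar_objective(self, two_hex_problem):
        """||Y||^2 agrees with the direct scalar evaluation on random points."""
        exp, op, anchor = two_hex_problem
        spec = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=0.05, anchor=anchor)
        rng = np.random.default_rng(8)
        for _ in range(5):
            f = ParameterField(alpha=rng.uniform(3e3, 2e4, 2), v=rng.uniform(0.05, 0.4, 2))
            Y = residual_vector(pack(f), spec)
            assert float(Y @ Y) == pytest.approx(spec.objective_value(f), rel=1e-10)

    def test_large_gamma_pins_minimizer_to_anchor(self, two_hex_problem):
        from elastinv.lm import LMConfig, run

        exp, op, anchor = two_hex_problem
        spec = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=1e8, anchor=anchor)
        st = run(spec.residual_fn(), spec.jacobian_fn(),
                 spec.initial_point() + 0.05, LMConfig(epsilon=1e-10, max_iter=200))
        est = unpack(st.x, 2)
        assert np.allclose(est.alpha, anchor.alpha0, rtol=1e-3)
        assert np.allclose(est.v, anchor.v0, atol=1e-3)

    def test_gamma_zero_has_no_regularization_rows(self, two_hex_problem):
        exp, op, anchor = two_hex_problem
        s0 = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=0.0, anchor=anchor)
        s1 = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=0.1, anchor=anchor)
        x = s0.initial_point()
        assert residual_vector(x, s1).size - residual_vector(x, s0).size == 4


class TestJacobian:
    def test_matches_central_finite_differences(self, two_hex_problem):
        exp, op, anchor = two_hex_problem
        spec = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=0.02, anchor=anchor)
        rng = np.random.default_rng(9)
        x = spec.initial_point() + rng.normal(scale=0.1, size=4)
        J = jacobian(x, spec)
        for col in range(x.size):
            h = 1e-6 * max(abs(x[col]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[col] += h
            xm[col] -= h
            fd = (residual_vector(xp, spec) - residual_vector(xm, spec)) / (2 * h)
            denom = max(np.linalg.norm(fd), 1e-12)
            assert np.linalg.norm(J[:, col] - fd) / denom < 1e-5

    def test_gradient_vanishes_at_recovered_optimum(self, two_hex_problem):
        from elastinv.lm import LMConfig, run

        exp, op, anchor = two_hex_problem
        spec = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=1e-8, anchor=anchor)
        st = run(spec.residual_fn(), spec.jacobian_fn(), spec.initial_point(),
                 LMConfig(epsilon=1e-10, max_iter=300))
        Y = residual_vector(st.x, spec)
        J = jacobian(st.x, spec)
        assert np.linalg.norm(J.T @ Y) < 1e-8

    def test_insensitive_hexahedron_column_is_zero(self):
        """A hexahedron whose nodes carry no displacement cannot influence
        the residual: its Jacobian column vanishes."""
        spec_s = ScenarioSpec(grid=GridSpec(5, 2, 2, (0.4, 0.1, 0.1)),
                              field_style="homogeneous", load_rc=(1, 1), noise_sd=0.0, seed=2)
        exp = generate_experiment(spec_s)
        op = FEMOperator(exp.mesh)
        anchor = solve_initial_params(op, exp.noiseless_cases)
        import dataclasses

        # zero out displacements except near the loaded corner (col 0-1)
        cases = []
        for lc in exp.noiseless_cases:
            U = lc.U_full.copy()
            far = exp.mesh.nodes[:, 0] > 0.15
            U[far] = 0.0
            cases.append(dataclasses.replace(lc, U_full=U))
        spec = ObjectiveSpec(op=op, cases=cases, gamma=0.0, anchor=anchor)
        J = jacobian(spec.initial_point(), spec)
        # last hexahedron spans x in [0.3, 0.4]; all its nodes are zeroed
        assert np.abs(J[:, 3]).max() == 0.0
        assert np.abs(J[:, 7]).max() == 0.0


class TestCompletion:
    def test_completion_recovers_full_field_from_surface(self):
        """With homogeneous material and all surface nodes measured, static
        condensation reproduces the interior displacements."""
        spec = ScenarioSpec(grid=GridSpec(5, 4, 3), field_style="homogeneous",
                            E_range=(7e3, 7e3), v_range=(0.2, 0.2),
                            load_rc=(2, 3), noise_sd=0.0, seed=5)
        exp = generate_experiment(spec)
        op = FEMOperator(exp.mesh)
        lc = exp.noiseless_cases[0]
        import dataclasses

        stripped = dataclasses.replace(lc, U_full=None)
        completed = complete_load_case(op, 0.2, stripped, exp.mesh.surface_nodes)
        assert np.allclose(completed.U_full, lc.U_full, atol=1e-10 * np.abs(lc.U_full).max())

    def test_load_node_must_be_measured(self, two_hex_problem):
        exp, op, _ = two_hex_problem
        lc = exp.noiseless_cases[0]
        others = np.array([n for n in exp.mesh.surface_nodes if n != lc.load_node])
        with pytest.raises(ValueError):
            complete_load_case(op, 0.2, lc, others)
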