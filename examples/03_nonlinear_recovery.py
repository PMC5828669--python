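"""Recover a heterogeneous stiffness field with the self-adapting LM solver.

Generates noiseless indentation data from a 30-hexahedron block with a
smooth (E, v) field, starts the regularized per-element estimation from the
homogeneous linear fit, and compares the recovered substitution parameters
with the ground truth.
"""

import numpy as np

from elastinv.fem import FEMOperator
from elastinv.inverse import ObjectiveSpec, unpack
from elastinv.linear_init import solve_initial_params
from elastinv.lm import LMConfig, run
from elastinv.mesh import GridSpec
from elastinv.synthetic import ScenarioSpec, generate_experiment

spec = ScenarioSpec(grid=GridSpec(6, 4, 3), field_style="smooth-heterogeneous",
                    load_rc=(2, 4), noise_sd=0.0, seed=7)
exp = generate_experiment(spec)
op = FEMOperator(exp.mesh)

anchor = solve_initial_params(op, exp.noiseless_cases)
print(f"anchor (homogeneous fit): E0 = {anchor.E0:.0f} Pa, v0 = {anchor.v0:.3f}")

objective = ObjectiveSpec(op=op, cases=exp.noiseless_cases, gamma=1e-6, anchor=anchor)
state = run(objective.residual_fn(), objective.jacobian_fn(),
            objective.initial_point(), LMConfig(epsilon=1e-8, max_iter=500))
est = unpack(state.x, objective.k)

rel_alpha = (est.alpha - exp.true_alpha) / exp.true_alpha
print(f"LM: converged={state.converged} after {state.n_iter} iterations")
print(f"alpha RMS relative error: {100 * np.sqrt(np.mean(rel_alpha**2)):.3f} %")
print(f"max |v error| per element: {np.abs(est.v - exp.true_v).max():.4f}")
print(f"recovered E range: {est.young_modulus().min():.0f} - "
      f"{est.young_modulus().max():.0f} Pa  (truth {exp.true_E.min():.0f} - {exp.true_E.max():.0f})")
print()
print("Sub-percent alpha error and |v error| << 0.01 mean the per-element")
print("material map is recovered essentially exactly from noiseless data.")
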