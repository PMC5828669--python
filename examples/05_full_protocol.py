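"""Run the complete estimation protocol on a noisy full-scale experiment.

Simulates the 23 x 13 marker grid with 1 mm tracking noise, splits markers
into 249 sample / 50 held-out test nodes, fits per-deformation-set linear
models and the pooled per-element nonlinear model, then compares predicted
and measured displacements at the held-out nodes.
"""

import numpy as np

from elastinv.evaluation import ProtocolConfig, run_protocol
from elastinv.lm import LMConfig
from elastinv.synthetic import ScenarioSpec, generate_experiment

exp = generate_experiment(ScenarioSpec(seed=0))        # 1 mm noise default
report = run_protocol(exp, ProtocolConfig(n_test=50, seed=0, gamma=3.0,
                                          lm=LMConfig(epsilon=1e-6, max_iter=60)))

print(f"sample/test split: {len(report.sample_nodes)}/{len(report.test_nodes)} markers")
print(f"LM converged: {report.lm_converged} ({report.lm_iterations} iterations)")
print()
print("held-out displacement errors per deformation set (mm):")
print("set   linear dmax  dmean   nonlinear dmax  dmean")
for i in range(len(report.linear_dmax)):
    print(f"  {chr(65 + i)}   {report.linear_dmax[i]:10.2f} {report.linear_dmean[i]:6.2f}"
          f"   {report.nonlinear_dmax[i]:12.2f} {report.nonlinear_dmean[i]:6.2f}")
lin, nl = np.array(report.linear_dmax), np.array(report.nonlinear_dmax)
print()
print(f"nonlinear model predicts held-out nodes better in "
      f"{(nl < lin).sum()}/6 deformation sets")
print("The per-element estimate absorbs the material heterogeneity that a")
print("single homogeneous linear fit cannot, at the cost of regularized")
print("shrinkage toward the homogeneous anchor under measurement noise.")
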