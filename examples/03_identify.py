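"""Identify viscoelastic joint parameters from a synthetic trial.

Generates a noise-free trial with known ground truth, runs a deliberately
small evolutionary search (for a quick demonstration; the study-scale
budget is population 100 over 15 generations plus the refinement stage)
and reports the identified axial stiffnesses against the generating
values.
"""

import numpy as np

from neckdyn import (
    GAConfig,
    SynthConfig,
    compile_model,
    generate_bundle,
    identify_parameters,
)

bundle = generate_bundle(seed=1, config=SynthConfig(marker_noise_sd_m=0.0))
data = bundle.windowed(noisy=False)

ga = GAConfig(population_size=16, generations=5, seed=1, refine_evals=1000,
              refine_target_mm=1e-6)
result = identify_parameters(compile_model(bundle.model), data, ga)

print(f"tracking RMSE at optimum: {result.rmse_opt_mm:.4f} mm "
      f"({result.n_evaluations} simulations)")
print(f"best-fitness history (mm): {result.history_mm[0]:.3f} -> "
      f"{result.history_mm[-1]:.4f} over {len(result.history_mm)} updates")
print(f"{'joint':8s} {'true k_y (MN/m)':>16s} {'identified':>12s} {'error':>8s}")
joints = ("C2-C3", "C3-C4", "C4-C5", "C5-C6")
for j, joint in enumerate(joints):
    true_k = bundle.truth[j]
    est_k = result.parameters[j]
    print(f"{joint:8s} {true_k / 1e6:16.1f} {est_k / 1e6:12.1f} "
          f"{100 * (est_k / true_k - 1):+7.1f}%")
print("\nAt this demonstration budget the parameters are only loosely "
      "constrained even though the tracking error has dropped sixfold; "
      "the study-scale budget (see docs/methods.md) recovers all 16 "
      "parameters on noise-free data.")
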