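"""Cross-validation and Monte Carlo sensitivity around known parameters.

Uses a five-specimen synthetic cohort sharing a base parameter vector with
per-specimen jitter.  For speed, the per-specimen "identified" vectors are
the generating (ground-truth) ones; the example shows how transferred
median parameters degrade tracking and how simultaneous set perturbations
move the tracking error.
"""

import numpy as np

from neckdyn import (
    SynthConfig,
    compile_model,
    cross_validate_five_fold,
    evaluate_with_fixed_parameters,
    fit_pair_surface,
    generate_cohort,
    run_monte_carlo,
)
from neckdyn.identify import GAConfig, IdentificationResult
from neckdyn.sensitivity import SET_PAIRS

cfg = SynthConfig(marker_noise_sd_m=0.0)
cohort = generate_cohort(3, truth_jitter=0.2, config=cfg)

specimens, results = [], []
for bundle in cohort:
    data = bundle.windowed(noisy=False)
    compiled = compile_model(bundle.model)
    rmse = evaluate_with_fixed_parameters(compiled, data, bundle.truth)
    specimens.append((compiled, data))
    results.append(IdentificationResult(
        parameters=bundle.truth, rmse_opt_mm=rmse, history_mm=[rmse],
        seed=3, n_evaluations=0, config=GAConfig()))

cv = cross_validate_five_fold(specimens, results)
print("five-fold cross-validation (median of 4 transferred to the 5th):")
for fold in cv.folds:
    print(f"  held out {fold.held_out}: RMSE_val {fold.rmse_val_mm:.4f} mm "
          f"vs RMSE_opt {fold.rmse_opt_mm:.2e} mm")

samples = run_monte_carlo(specimens[0][0], specimens[0][1],
                          cohort[0].truth, n=60, seed=7)
deltas = np.array([s.delta_rmse_mm for s in samples])
print(f"\nMonte Carlo (60 samples, sets scaled 50-150%): "
      f"dRMSE {deltas.min():.4f}..{deltas.max():.4f} mm, all >= 0")
fit = fit_pair_surface(samples, SET_PAIRS[0])
print(f"cubic surface over {fit.pair}: value at origin "
      f"{fit(0.0, 0.0):+.2e} mm (residual norm {fit.residual_norm:.2e})")
print("\nTransferred medians track worse than each specimen's own "
      "parameters, and no perturbation of a noise-free optimum improves "
      "tracking - the optimum is genuinely optimal.")
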