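"""Head-impact scenario: constrained vs impact-specific vs quasi-static.

Drives a muscle-free head + C2-C6 chain with a 2 kN axial haversine pulse
(7.5 ms rise) and compares peak joint loads and displacements across the
three bushing-parameter variants.
"""

import numpy as np

from neckdyn import run_scenario_comparison
from neckdyn.scenario import FAILURE_DISPLACEMENT_MM, default_head_load

results = run_scenario_comparison(head_load=default_head_load(peak_N=2000.0,
                                                              rise_s=0.0075))

for kind, r in results.items():
    print(f"{kind}:")
    for i, joint in enumerate(r.joint_names):
        print(f"  {joint}: peak load {r.peak_compressive_load_N[i]:7.0f} N, "
              f"axial {r.peak_axial_displacement_mm[i]:.3f} mm, "
              f"shear {r.peak_shear_displacement_mm[i]:.3f} mm")

qs = results["quasi_static"]
im = results["impact_specific"]
ratio = qs.peak_compressive_load_N.mean() / im.peak_compressive_load_N.mean()
print(f"\nquasi-static loads are {100 * (ratio - 1):.0f}% above "
      f"impact-specific; quasi-static axial displacements "
      f"({qs.peak_axial_displacement_mm.max():.2f} mm) approach or exceed "
      f"the {FAILURE_DISPLACEMENT_MM} mm near-failure reference, while "
      f"impact-specific stays below 0.1 mm - soft quasi-static bushings "
      f"overstate joint excursion in impulsive events.")
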