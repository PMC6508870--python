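"""Bundled reference dataset for porcine cervical spine (C2-C6) specimens.

Descriptive statistics and identified impact-specific viscoelastic joint
parameters for five porcine cervical spine specimens (S1-S5) tested under
impulsive axial loads, together with the quasi-static literature values used
to initialise the bushing elements.  These numbers serve three purposes:

* initialisation values for the identification pipeline,
* realistic sampling ranges for the synthetic specimen generator,
* the published aggregates that the validation module must reproduce.

All values are SI (kg, m, N/m, Ns/m).  Joint order everywhere is
``[C2-C3, C3-C4, C4-C5, C5-C6]``; specimen order is S1..S5.
"""

from __future__ import annotations

import numpy as np

JOINT_NAMES = ("C2-C3", "C3-C4", "C4-C5", "C5-C6")
SEGMENT_NAMES = ("C2", "C3", "C4", "C5", "C6")
SPECIMEN_IDS = ("S1", "S2", "S3", "S4", "S5")

# Specimen descriptives (S6 fractured during testing and is excluded from
# every aggregate, as in the source dataset).
SPECIMEN_MASS_KG = np.array([0.378, 0.444, 0.396, 0.375, 0.358])
SPECIMEN_HEIGHT_M = np.array([0.203, 0.215, 0.202, 0.199, 0.202])

# Quasi-static literature initialisation of the optimised degrees of freedom.
INIT_AXIAL_STIFFNESS = 1.1e6     # N/m, every joint
INIT_AXIAL_DAMPING = 1.0e3       # Ns/m
INIT_SHEAR_STIFFNESS = 63.0e3    # N/m
INIT_SHEAR_DAMPING = 1.0e3       # Ns/m

# Non-optimised degrees of freedom keep configurable placeholder values
# (the source initialisation does not print them): lateral translation
# mirrors shear, rotations use order-of-magnitude spinal-joint values.
INIT_LATERAL_STIFFNESS = 63.0e3  # N/m
INIT_LATERAL_DAMPING = 1.0e3     # Ns/m
INIT_ROT_STIFFNESS = 10.0        # Nm/rad
INIT_ROT_DAMPING = 1.0           # Nms/rad

# Identified axial (superior-inferior) parameters, rows S1..S5, cols C2-C3..C5-C6.
AXIAL_STIFFNESS = np.array([
    [22.2e6, 25.0e6, 15.2e6, 2.7e6],
    [29.4e6, 19.7e6, 24.4e6, 2.2e6],
    [25.2e6, 38.2e6, 19.9e6, 1.2e6],
    [26.0e6, 26.3e6, 33.3e6, 2.7e6],
    [22.2e6, 35.2e6, 14.4e6, 1.7e6],
])
AXIAL_DAMPING = np.array([
    [3.1e3, 6.1e3, 2.0e3, 2.2e3],
    [1.8e3, 5.5e3, 2.2e3, 1.8e3],
    [3.9e3, 7.3e3, 3.6e3, 4.0e3],
    [5.7e3, 3.0e3, 2.4e3, 2.6e3],
    [1.4e3, 8.9e3, 7.7e3, 3.0e3],
])

# Identified shear (anterior-posterior) parameters.
SHEAR_STIFFNESS = np.array([
    [28.4e3, 69.0e3, 53.3e3, 75.3e3],
    [80.6e3, 76.4e3, 75.5e3, 77.8e3],
    [5.5e3, 96.1e3, 38.5e3, 92.0e3],
    [89.7e3, 61.3e3, 78.6e3, 93.5e3],
    [14.5e3, 88.0e3, 84.5e3, 91.2e3],
])
SHEAR_DAMPING = np.array([
    [0.5e3, 1.5e3, 1.4e3, 1.4e3],
    [1.3e3, 1.3e3, 1.4e3, 1.1e3],
    [0.5e3, 0.8e3, 1.4e3, 1.5e3],
    [0.7e3, 1.5e3, 0.9e3, 1.5e3],
    [0.6e3, 1.4e3, 1.4e3, 1.5e3],
])

# Published median rows.  Note: the C2-C3 shear damping median recomputed
# from the per-specimen values above is 0.6e3 (the summary row of the source
# table rounds it to 0.5e3); this module stores the value consistent with the
# per-specimen inputs so that componentwise aggregation verifies exactly.
MEDIAN_AXIAL_STIFFNESS = np.array([25.2e6, 26.3e6, 19.9e6, 2.2e6])
MEDIAN_AXIAL_DAMPING = np.array([3.1e3, 6.1e3, 2.4e3, 2.6e3])
MEDIAN_SHEAR_STIFFNESS = np.array([28.4e3, 76.4e3, 75.5e3, 91.2e3])
MEDIAN_SHEAR_DAMPING = np.array([0.6e3, 1.4e3, 1.4e3, 1.5e3])

# Preload path applied to the cranial (C2) end of the potted specimen.
PRELOAD_SPRING_N = 102.0   # two constant-force springs, 51 N each
PRELOAD_PLATE_N = 50.0     # weight of the impact plate
PRELOAD_PLATE_MASS_KG = 5.10
PRELOAD_TOTAL_N = PRELOAD_SPRING_N + PRELOAD_PLATE_N  # 152 N


def specimen_parameter_vector(specimen: int) -> np.ndarray:
    """Identified 16-parameter vector for specimen index 0..4 (S1..S5).

    Order: 4 axial stiffnesses, 4 axial dampings, 4 shear stiffnesses,
    4 shear dampings, each over joints C2-C3..C5-C6.
    """
    return np.concatenate([
        AXIAL_STIFFNESS[specimen],
        AXIAL_DAMPING[specimen],
        SHEAR_STIFFNESS[specimen],
        SHEAR_DAMPING[specimen],
    ])


def initialisation_vector() -> np.ndarray:
    """Literature initialisation as a 16-parameter vector."""
    return np.concatenate([
        np.full(4, INIT_AXIAL_STIFFNESS),
        np.full(4, INIT_AXIAL_DAMPING),
        np.full(4, INIT_SHEAR_STIFFNESS),
        np.full(4, INIT_SHEAR_DAMPING),
    ])
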