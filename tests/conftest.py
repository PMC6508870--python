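"""Shared fixtures: synthetic trials and minimal oracle models."""

from __future__ import annotations

import numpy as np
import pytest

from neckdyn import dynamics, synth
from neckdyn.model import (
    BushingParameters,
    ConstraintSpec,
    PreloadSpec,
    SegmentSpec,
    JointFrame,
    SpecimenModel,
)


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free synthetic trial with known ground truth (fixed seed)."""
    cfg = synth.SynthConfig(marker_noise_sd_m=0.0)
    return synth.generate_bundle(1, cfg)


@pytest.fixture(scope="session")
def clean_window(clean_bundle):
    """(force window, marker window) of the noise-free trial."""
    return clean_bundle.windowed(noisy=False)


@pytest.fixture(scope="session")
def clean_compiled(clean_bundle):
    return dynamics.compile_model(clean_bundle.model)


@pytest.fixture(scope="session")
def specimen_model():
    """A default specimen model at literature bushing values."""
    from neckdyn.model import build_specimen_model
    geometry, _, mass, _ = synth.generate_specimen(0)
    return build_specimen_model(geometry, mass)


def make_oscillator(
    mass: float = 1.0,
    k: float = 1.0e4,
    b: float = 0.0,
    gravity: bool = False,
    preload_N: float = 0.0,
) -> SpecimenModel:
    """Single mass on a single axial bushing above a fixed base.

    The mass translates axially only, so the chain reduces to the textbook
    damped harmonic oscillator x'' + (b/m) x' + (k/m) x = 0 about its
    equilibrium — the closed-form oracle used by the simulator tests.
    """
    inertia = np.eye(3) * 1e-4
    base = SegmentSpec(name="BASE", mass=1.0, inertia=inertia,
                       rest_position=np.zeros(3))
    mass_seg = SegmentSpec(
        name="MASS", mass=mass, inertia=inertia,
        rest_position=np.array([0.0, 0.1, 0.0]),
        marker_points={"M": np.array([0.01, 0.0, 0.0])})
    joint = JointFrame(
        caudal_segment="BASE", cranial_segment="MASS",
        origin_in_caudal=np.array([0.0, 0.05, 0.0]),
        orientation_in_caudal=np.eye(3),
        rest_offset=np.array([0.0, -0.05, 0.0]))
    bushing = BushingParameters(
        k_trans=np.array([0.0, k, 0.0]),
        b_trans=np.array([0.0, b, 0.0]),
        k_rot=np.zeros(3), b_rot=np.zeros(3))
    return SpecimenModel(
        segments=[mass_seg, base],
        joints=[joint],
        bushings=[bushing],
        constraints=ConstraintSpec(mobility={"MASS": "axial_translation_only",
                                             "BASE": "fixed"}),
        include_gravity=gravity,
        preload=PreloadSpec(spring_force_N=preload_N, plate_weight_N=0.0,
                            plate_mass_kg=0.0),
    )


@pytest.fixture()
def oscillator():
    return make_oscillator()
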