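"""Synthetic specimens, impact pulses and marker trials with known ground truth.

The generator emulates the drop-rig experiment end to end: a C2-C6 chain
preloaded at 152 N, an impulsive axial haversine pulse (experimental peaks
ranged 3.0-4.8 kN), 15 tracking markers (4 per cluster on C3/C4/C5 plus 3
cranial-pot markers) sampled at 4 kHz with sub-millimetre noise, and
ground-truth bushing parameters drawn within the identified ranges of the
bundled reference dataset.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reference
from .dynamics import CompiledModel, compile_model, simulate, static_equilibrium, _marker_frame
from .model import (
    SpecimenGeometry,
    SpecimenModel,
    build_specimen_model,
    unpack_parameters,
)
from .signals import (
    DEFAULT_FORCE_CUTOFF_HZ,
    DEFAULT_FORCE_FS,
    DEFAULT_MARKER_FS,
    DEFAULT_ONSET_THRESHOLD_N,
    DEFAULT_WINDOW_S,
    ForceTrace,
    MarkerTrajectories,
    align_and_window,
    detect_impact_onset,
    zero_lag_lowpass,
)

__all__ = [
    "SynthConfig",
    "GroundTruthBundle",
    "generate_specimen",
    "generate_load_pulse",
    "generate_trial",
    "generate_bundle",
    "generate_cohort",
]


@dataclass
class SynthConfig:
    """Study conditions of the emulated experiment.

    Specimen mass and height are drawn from the reference cohort's
    descriptive statistics; sagittal mid-plane tilts increase caudally
    (lordosis), so the caudal-most joint sees the axial load at the largest
    shear angle.  Ground-truth viscoelastic parameters are drawn log-uniform
    within the span of the identified reference values per degree of
    freedom.
    """

    mass_mean_kg: float = 0.390
    mass_sd_kg: float = 0.033
    height_mean_m: float = 0.204
    height_sd_m: float = 0.006
    disc_height_m: float = 0.005
    sagittal_tilts_deg: tuple[float, float, float, float] = (2.0, 4.0, 6.0, 10.0)
    cluster_offset_m: float = 0.025
    pulse_peak_N: float = 3.5e3        # within the measured 3.0-4.8 kN range
    pulse_rise_s: float = 2.5e-3
    pulse_delay_s: float = 0.010       # quiet pre-impact span for the baseline
    pulse_duration_s: float = 0.020
    force_fs: float = DEFAULT_FORCE_FS
    marker_fs: float = DEFAULT_MARKER_FS
    force_noise_sd_N: float = 0.0
    marker_noise_sd_m: float = 3.0e-4  # order of the mocap calibration error
    window_s: float = DEFAULT_WINDOW_S
    force_cutoff_hz: float = DEFAULT_FORCE_CUTOFF_HZ
    onset_threshold_N: float = DEFAULT_ONSET_THRESHOLD_N

    def truth_ranges(self) -> dict[str, tuple[float, float]]:
        """Log-uniform sampling span per parameter set, from the reference data."""
        return {
            "axial_k": (reference.AXIAL_STIFFNESS.min(), reference.AXIAL_STIFFNESS.max()),
            "axial_b": (reference.AXIAL_DAMPING.min(), reference.AXIAL_DAMPING.max()),
            "shear_k": (reference.SHEAR_STIFFNESS.min(), reference.SHEAR_STIFFNESS.max()),
            "shear_b": (reference.SHEAR_DAMPING.min(), reference.SHEAR_DAMPING.max()),
        }


@dataclass
class GroundTruthBundle:
    """One synthetic trial plus everything needed to score recovery.

    ``force`` is the "measured" cranial trace (preload baseline, pulse and
    noise); ``markers_noisy`` is what identification sees, ``markers_clean``
    the noise-free trajectories.  The ground-truth parameter vector lives in
    ``truth`` and is already installed in ``model``.
    """

    model: SpecimenModel
    truth: np.ndarray
    markers_clean: MarkerTrajectories
    markers_noisy: MarkerTrajectories
    force: ForceTrace
    seed: int
    marker_noise_sd_m: float
    force_noise_sd_N: float
    onset: int
    config: SynthConfig = field(default_factory=SynthConfig)

    def windowed(self, noisy: bool = True) -> tuple[ForceTrace, MarkerTrajectories]:
        """Filter the force trace, detect onset and cut the analysis window.

        This is the exact preprocessing identification applies, so the
        returned window is directly comparable to simulated kinematics.
        """
        filt = ForceTrace(
            zero_lag_lowpass(self.force.samples, self.force.fs,
                             self.config.force_cutoff_hz),
            fs=self.force.fs, t0=self.force.t0, label=self.force.label)
        onset = detect_impact_onset(filt, self.config.onset_threshold_N)
        markers = self.markers_noisy if noisy else self.markers_clean
        return align_and_window(filt, markers, onset, self.config.window_s)


def generate_specimen(
    seed: int, config: SynthConfig | None = None
) -> tuple[SpecimenGeometry, np.ndarray, float, float]:
    """Draw one specimen: geometry, ground-truth 16-vector, mass and height."""
    config = config or SynthConfig()
    rng = np.random.default_rng(seed)
    mass = 0.0
    while mass <= 0.05:
        mass = rng.normal(config.mass_mean_kg, config.mass_sd_kg)
    height = 0.0
    while height <= 0.05:
        height = rng.normal(config.height_mean_m, config.height_sd_m)

    disc = np.full(4, config.disc_height_m)
    vert = np.full(5, (height - disc.sum()) / 5.0)
    if np.any(vert <= 0):
        raise ValueError("invalid geometry ranges: non-positive vertebra height")
    geometry = SpecimenGeometry(
        vertebra_heights=vert,
        disc_heights=disc,
        sagittal_tilts=np.deg2rad(config.sagittal_tilts_deg),
        cluster_offset=config.cluster_offset_m,
    )

    ranges = config.truth_ranges()
    for lo, hi in ranges.values():
        if not (0 < lo < hi):
            raise ValueError("invalid truth parameter ranges")
    truth = np.concatenate([
        10.0 ** rng.uniform(np.log10(ranges[k][0]), np.log10(ranges[k][1]), 4)
        for k in ("axial_k", "axial_b", "shear_k", "shear_b")
    ])
    return geometry, truth, float(mass), float(height)


def generate_load_pulse(
    peak_N: float,
    rise_s: float,
    duration_s: float,
    fs: float = DEFAULT_FORCE_FS,
    noise_sd_N: float = 0.0,
    seed: int | None = None,
    baseline_N: float = reference.PRELOAD_TOTAL_N,
    delay_s: float = 0.010,
) -> ForceTrace:
    """Haversine axial pulse atop the preload baseline, plus white noise.

    The pulse rises from zero to ``peak_N`` over ``rise_s`` and falls
    symmetrically; it starts ``delay_s`` into the trace so the pre-impact
    baseline is observable.  ``duration_s`` at sampling rate ``fs`` yields
    ``round(fs * duration_s) + 1`` samples.
    """
    if peak_N <= 0:
        raise ValueError("peak force must be positive")
    if rise_s >= duration_s:
        raise ValueError("rise time must be shorter than the trace duration")
    if fs * rise_s < 20:
        raise ValueError("sampling rate too low to resolve the rise time")
    n = int(round(fs * duration_s)) + 1
    t = np.arange(n) / fs
    tau = t - delay_s
    pulse = np.where(
        (tau >= 0) & (tau <= 2 * rise_s),
        peak_N * np.sin(np.pi * tau / (2.0 * rise_s)) ** 2,
        0.0,
    )
    samples = baseline_N + pulse
    if noise_sd_N > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd_N, n)
    return ForceTrace(samples, fs=fs, t0=0.0, label="cranial")


def generate_trial(
    model: SpecimenModel,
    truth: np.ndarray,
    pulse: ForceTrace,
    marker_noise_sd_m: float = 3.0e-4,
    seed: int | None = None,
    config: SynthConfig | None = None,
) -> GroundTruthBundle:
    """Simulate a trial at the ground-truth parameters and add marker noise.

    The trial is generated with the same preprocessing identification will
    use (filter the force trace, detect onset, cut the window, simulate from
    the preloaded equilibrium), so on a noise-free bundle the tracking error
    at the generating parameters is at the integrator-determinism floor.
    Marker frames before onset hold the equilibrium pose; frames after the
    window hold the last simulated pose.
    """
    config = config or SynthConfig()
    model = model.with_bushings(unpack_parameters(truth, model.bushings))
    c = compile_model(model)

    filt = ForceTrace(
        zero_lag_lowpass(pulse.samples, pulse.fs, config.force_cutoff_hz),
        fs=pulse.fs, t0=pulse.t0, label=pulse.label)
    onset = detect_impact_onset(filt, config.onset_threshold_N)
    force_win, _ = _force_window_only(filt, onset, config.window_s)

    # marker frame grid over the whole recording
    n_frames = int(np.floor(pulse.duration * config.marker_fs + 1e-9)) + 1
    frame_times = np.arange(n_frames) / config.marker_fs
    t_on = float(filt.times[onset])
    in_win = (frame_times >= t_on - 1e-9) & (frame_times <= t_on + config.window_s + 1e-9)

    eq = static_equilibrium(c)
    res = simulate(c, force_win, window_s=config.window_s,
                   output_times=frame_times[in_win] - t_on, initial_state=eq)
    if res.markers.n_frames != int(np.sum(in_win)):
        raise RuntimeError("simulation did not cover the analysis window")

    eq_frame = _marker_frame(c, c.full_from_free(eq.q))
    positions = np.empty((n_frames, eq_frame.shape[0], 3))
    positions[frame_times < t_on - 1e-9] = eq_frame
    positions[in_win] = res.markers.positions
    after = frame_times > t_on + config.window_s + 1e-9
    positions[after] = res.markers.positions[-1]

    clean = MarkerTrajectories(list(c.marker_names), positions,
                               fs=config.marker_fs, t0=0.0)
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, marker_noise_sd_m, positions.shape)
             if marker_noise_sd_m > 0 else np.zeros_like(positions))
    noisy = MarkerTrajectories(list(c.marker_names), positions + noise,
                               fs=config.marker_fs, t0=0.0)
    return GroundTruthBundle(
        model=model, truth=np.asarray(truth, dtype=float).copy(),
        markers_clean=clean, markers_noisy=noisy, force=pulse,
        seed=-1 if seed is None else int(seed),
        marker_noise_sd_m=marker_noise_sd_m,
        force_noise_sd_N=0.0, onset=onset, config=config)


def _force_window_only(filt: ForceTrace, onset: int, window_s: float):
    """Window the filtered force alone (markers handled by the caller)."""
    from .signals import _baseline
    t_on = float(filt.times[onset])
    fwin = filt.slice_time(t_on, t_on + window_s)
    return ForceTrace(fwin.samples - _baseline(filt), fs=fwin.fs, t0=fwin.t0,
                      label=fwin.label), t_on


def generate_bundle(seed: int, config: SynthConfig | None = None) -> GroundTruthBundle:
    """One-call trial generation: specimen, pulse and noisy markers from a seed."""
    config = config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    s_spec, s_force, s_marker = (int(c.generate_state(1)[0] % (2**31))
                                 for c in ss.spawn(3))
    geometry, truth, mass, _ = generate_specimen(s_spec, config)
    model = build_specimen_model(geometry, mass)
    pulse = generate_load_pulse(
        config.pulse_peak_N, config.pulse_rise_s, config.pulse_duration_s,
        fs=config.force_fs, noise_sd_N=config.force_noise_sd_N,
        seed=s_force, delay_s=config.pulse_delay_s)
    bundle = generate_trial(model, truth, pulse,
                            marker_noise_sd_m=config.marker_noise_sd_m,
                            seed=s_marker, config=config)
    return replace(bundle, seed=seed,
                   force_noise_sd_N=config.force_noise_sd_N)


def generate_cohort(
    seed: int,
    n_specimens: int = 5,
    truth_jitter: float = 0.2,
    config: SynthConfig | None = None,
) -> list[GroundTruthBundle]:
    """A cohort sharing a base truth with per-specimen multiplicative jitter.

    Mirrors a homogeneous animal cohort: one base parameter vector drawn
    from the reference ranges, each specimen's truth scaled componentwise by
    uniform factors in ``[1 - truth_jitter, 1 + truth_jitter]``, with
    independently drawn masses/heights and noise realisations.
    """
    config = config or SynthConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_specimens + 1)
    base_seed = int(children[0].generate_state(1)[0] % (2**31))
    _, base_truth, _, _ = generate_specimen(base_seed, config)
    bundles = []
    for child in children[1:]:
        s_spec, s_force, s_marker, s_jit = (
            int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(4))
        geometry, _, mass, _ = generate_specimen(s_spec, config)
        model = build_specimen_model(geometry, mass)
        rng = np.random.default_rng(s_jit)
        truth = base_truth * rng.uniform(1 - truth_jitter, 1 + truth_jitter,
                                         base_truth.shape)
        pulse = generate_load_pulse(
            config.pulse_peak_N, config.pulse_rise_s, config.pulse_duration_s,
            fs=config.force_fs, noise_sd_N=config.force_noise_sd_N,
            seed=s_force, delay_s=config.pulse_delay_s)
        bundles.append(generate_trial(
            model, truth, pulse, marker_noise_sd_m=config.marker_noise_sd_m,
            seed=s_marker, config=config))
    return bundles
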