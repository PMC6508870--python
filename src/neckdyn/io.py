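"""File formats, run configuration and the end-to-end pipeline.

Formats: TRC for marker trajectories (tab-separated, positions in
millimetres per the format's convention — converted to metres at this
boundary), ``time_s,force_N`` CSV for force traces, JSON for models,
configurations and results.  All internal computation is SI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .identify import GAConfig, IdentificationResult, identify_parameters
from .model import (
    BushingParameters,
    ConstraintSpec,
    JointFrame,
    PreloadSpec,
    SegmentSpec,
    SpecimenModel,
)
from .signals import (
    DEFAULT_FORCE_CUTOFF_HZ,
    DEFAULT_MARKER_CUTOFF_HZ,
    DEFAULT_ONSET_THRESHOLD_N,
    DEFAULT_WINDOW_S,
    ForceTrace,
    MarkerTrajectories,
    align_and_window,
    detect_impact_onset,
    zero_lag_lowpass,
)

__all__ = [
    "read_marker_file", "write_marker_file",
    "read_force_file", "write_force_file",
    "model_to_dict", "model_from_dict", "save_model", "load_model",
    "save_identification_result", "save_simulation_result",
    "RunConfig", "PipelineError", "run_pipeline",
]

log = logging.getLogger("neckdyn")

_MM_PER_M = 1000.0


# ----------------------------------------------------------------------
# TRC marker files
# ----------------------------------------------------------------------

def write_marker_file(traj: MarkerTrajectories, path: str | Path) -> None:
    """Write trajectories as a TRC file (positions in mm)."""
    path = Path(path)
    n_fr, n_mk = traj.n_frames, traj.n_markers
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{traj.fs:.6f}\t{traj.fs:.6f}\t{n_fr}\t{n_mk}\tmm\t{traj.fs:.6f}\t1\t{n_fr}",
        "Frame#\tTime\t" + "\t\t\t".join(traj.names) + "\t\t",
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, n_mk + 1)),
        "",
    ]
    times = traj.times
    for f in range(n_fr):
        vals = "\t".join(f"{v:.9f}" for v in (traj.positions[f] * _MM_PER_M).ravel())
        lines.append(f"{f + 1}\t{times[f]:.9f}\t{vals}")
    path.write_text("\n".join(lines) + "\n")


def read_marker_file(path: str | Path) -> MarkerTrajectories:
    """Read a TRC file (or the CSV fallback written by this package)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_marker_csv(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise ValueError(f"{path}: malformed TRC header")
    meta = lines[2].split("\t")
    try:
        fs = float(meta[0])
        n_fr = int(meta[2])
        n_mk = int(meta[3])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed TRC header line 3") from exc
    names = [n for n in lines[3].split("\t")[2:] if n.strip()]
    if len(names) != n_mk:
        raise ValueError(
            f"{path}: header declares {n_mk} markers but names {len(names)}")
    rows = []
    times = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2 + 3 * n_mk:
            raise ValueError(
                f"{path}: data row has {len(parts) - 2} coordinate columns, "
                f"expected {3 * n_mk}")
        times.append(float(parts[1]))
        rows.append([float(v) for v in parts[2:]])
    if len(rows) != n_fr:
        raise ValueError(f"{path}: header declares {n_fr} frames, found {len(rows)}")
    pos = np.asarray(rows).reshape(n_fr, n_mk, 3) / _MM_PER_M
    if not np.all(np.isfinite(pos)):
        raise ValueError(f"{path}: NaN frames (gaps) are not supported")
    return MarkerTrajectories(names=names, positions=pos, fs=fs,
                              t0=float(times[0]) if times else 0.0)


def _read_marker_csv(path: Path) -> MarkerTrajectories:
    """CSV dialect: ``time_s,<m>_x,<m>_y,<m>_z,...`` in metres."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s")
    cols = list(df.columns[1:])
    if len(cols) % 3 != 0:
        raise ValueError(f"{path}: coordinate columns not a multiple of 3")
    names = [c[:-2] for c in cols[0::3]]
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.mean(np.diff(t)) if len(t) > 1 else 0.0
    pos = df[cols].to_numpy().reshape(len(df), len(names), 3)
    return MarkerTrajectories(names=names, positions=pos, fs=fs, t0=float(t[0]))


# ----------------------------------------------------------------------
# force CSV files
# ----------------------------------------------------------------------

def write_force_file(trace: ForceTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "force_N": trace.samples})
    df.to_csv(path, index=False, float_format="%.12g")


def read_force_file(path: str | Path) -> ForceTrace:
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "force_N"]:
        raise ValueError(f"{path}: header must be time_s,force_N")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time stamps must be strictly increasing")
    if np.max(np.abs(dt - dt.mean())) > 1e-6 * dt.mean():
        raise ValueError(f"{path}: non-uniform sampling (beyond 1 ppm)")
    return ForceTrace(df["force_N"].to_numpy(), fs=1.0 / dt.mean(), t0=float(t[0]))


# ----------------------------------------------------------------------
# model JSON
# ----------------------------------------------------------------------

def model_to_dict(model: SpecimenModel) -> dict:
    return {
        "units": {"length": "m", "mass": "kg", "force": "N", "time": "s",
                  "stiffness_trans": "N/m", "damping_trans": "Ns/m",
                  "stiffness_rot": "Nm/rad", "damping_rot": "Nms/rad"},
        "segments": [{
            "name": s.name, "mass": s.mass,
            "inertia": s.inertia.tolist(),
            "com_offset": s.com_offset.tolist(),
            "marker_points": {k: v.tolist() for k, v in s.marker_points.items()},
            "rest_position": s.rest_position.tolist(),
            "rest_orientation": s.rest_orientation.tolist(),
        } for s in model.segments],
        "joints": [{
            "caudal_segment": j.caudal_segment,
            "cranial_segment": j.cranial_segment,
            "origin_in_caudal": j.origin_in_caudal.tolist(),
            "orientation_in_caudal": j.orientation_in_caudal.tolist(),
            "rest_offset": j.rest_offset.tolist(),
        } for j in model.joints],
        "bushings": [{
            "k_trans": b.k_trans.tolist(), "b_trans": b.b_trans.tolist(),
            "k_rot": b.k_rot.tolist(), "b_rot": b.b_rot.tolist(),
        } for b in model.bushings],
        "constraints": dict(model.constraints.mobility),
        "gravity": model.gravity.tolist(),
        "include_gravity": model.include_gravity,
        "preload": {
            "spring_force_N": model.preload.spring_force_N,
            "plate_weight_N": model.preload.plate_weight_N,
            "plate_mass_kg": model.preload.plate_mass_kg,
        },
    }


def model_from_dict(d: dict) -> SpecimenModel:
    segments = [SegmentSpec(
        name=s["name"], mass=s["mass"], inertia=np.array(s["inertia"]),
        com_offset=np.array(s["com_offset"]),
        marker_points={k: np.array(v) for k, v in s["marker_points"].items()},
        rest_position=np.array(s["rest_position"]),
        rest_orientation=np.array(s["rest_orientation"]),
    ) for s in d["segments"]]
    joints = [JointFrame(
        caudal_segment=j["caudal_segment"], cranial_segment=j["cranial_segment"],
        origin_in_caudal=np.array(j["origin_in_caudal"]),
        orientation_in_caudal=np.array(j["orientation_in_caudal"]),
        rest_offset=np.array(j["rest_offset"]),
    ) for j in d["joints"]]
    bushings = [BushingParameters(
        k_trans=np.array(b["k_trans"]), b_trans=np.array(b["b_trans"]),
        k_rot=np.array(b["k_rot"]), b_rot=np.array(b["b_rot"]),
    ) for b in d["bushings"]]
    return SpecimenModel(
        segments=segments, joints=joints, bushings=bushings,
        constraints=ConstraintSpec(mobility=dict(d["constraints"])),
        gravity=np.array(d["gravity"]),
        include_gravity=bool(d.get("include_gravity", True)),
        preload=PreloadSpec(**d["preload"]),
    )


def _dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_model(model: SpecimenModel, path: str | Path) -> None:
    _dump_json(model_to_dict(model), path)


def load_model(path: str | Path) -> SpecimenModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def save_identification_result(res: IdentificationResult, path: str | Path,
                               config_hash: str | None = None) -> None:
    _dump_json({
        "units": {"stiffness": "N/m", "damping": "Ns/m", "rmse": "mm"},
        "parameters": res.parameters.tolist(),
        "parameter_order": ("axial stiffness C2-C3..C5-C6, axial damping, "
                            "shear stiffness, shear damping"),
        "rmse_opt_mm": res.rmse_opt_mm,
        "history_mm": list(res.history_mm),
        "seed": res.seed,
        "n_evaluations": res.n_evaluations,
        "config_hash": config_hash,
    }, path)


def save_simulation_result(res, out_dir: str | Path,
                           model: SpecimenModel | None = None,
                           seed: int | None = None) -> dict[str, str]:
    """Write a simulation as CSV time-series plus a JSON manifest.

    Produces ``markers.trc``, one CSV per channel group (joint forces and
    joint displacements, SI units) and ``manifest.json`` recording the
    model hash, integrator settings and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    write_marker_file(res.markers, out / "markers.trc")
    artifacts["markers"] = str(out / "markers.trc")
    for group, channels in (("joint_forces", ("axial_force", "shear_force")),
                            ("joint_displacements",
                             ("axial_displacement", "shear_displacement"))):
        cols = {"time_s": res.times}
        from .dynamics import extract_joint_series
        for joint in res.joint_names:
            for ch in channels:
                cols[f"{joint}_{ch}"] = extract_joint_series(res, joint, ch)
        path = out / f"{group}.csv"
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
        artifacts[group] = str(path)
    model_hash = None
    if model is not None:
        payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
        model_hash = hashlib.sha256(payload).hexdigest()[:16]
    _dump_json({
        "model_hash": model_hash,
        "integrator": {"scheme": "rk4_fixed_step", **res.meta},
        "seed": seed,
        "status": int(res.status),
        "artifacts": artifacts,
        "units": {"time": "s", "force": "N", "displacement": "m",
                  "markers": "mm (TRC convention)"},
    }, out / "manifest.json")
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one identification run needs, serialisable and hashable.

    A marker low-pass cutoff of ``None`` leaves the marker data unfiltered
    (synthetic trials are already band-limited by construction).
    """

    model_path: str = ""
    marker_path: str = ""
    force_path: str = ""
    out_dir: str = "neckdyn_run"
    force_cutoff_hz: float = DEFAULT_FORCE_CUTOFF_HZ
    marker_cutoff_hz: float | None = DEFAULT_MARKER_CUTOFF_HZ
    filter_order: int = 4
    onset_threshold_N: float = DEFAULT_ONSET_THRESHOLD_N
    window_s: float = DEFAULT_WINDOW_S
    ga: GAConfig = field(default_factory=GAConfig)
    units: str = "SI"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(config: RunConfig) -> dict:
    """Filter, detect onset, window, identify; write artifacts and manifest.

    Returns a dict of artifact paths.  Any stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stages_done: list[str] = []
    timings: dict[str, float] = {}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            timings[name] = time.perf_counter() - t0
            stages_done.append(name)
            log.info("stage %s done in %.2f s", name, timings[name])
            return result
        return wrap

    model = stage("load_model")(lambda: load_model(config.model_path))
    markers, force = stage("signal_processing")(lambda: _load_signals(config))
    force_f = stage("signal_processing.filter")(lambda: ForceTrace(
        zero_lag_lowpass(force.samples, force.fs, config.force_cutoff_hz,
                         order=config.filter_order),
        fs=force.fs, t0=force.t0, label=force.label))
    if config.marker_cutoff_hz:
        markers = stage("signal_processing.marker_filter")(
            lambda: markers.filtered(config.marker_cutoff_hz,
                                     order=config.filter_order))
    onset = stage("signal_processing.onset")(
        lambda: detect_impact_onset(force_f, config.onset_threshold_N))
    fwin, mwin = stage("signal_processing.window")(
        lambda: align_and_window(force_f, markers, onset, config.window_s))
    result = stage("identification")(
        lambda: identify_parameters(model, (fwin, mwin), config.ga))

    res_path = out / "result.json"
    save_identification_result(result, res_path,
                               config_hash=config.config_hash())
    artifacts["result"] = str(res_path)
    manifest = {
        "package": "neckdyn",
        "version": _pkg_version,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.ga.seed,
        "onset_sample": int(onset),
        "n_evaluations": result.n_evaluations,
        "stages": stages_done + ["identification.write"],
        "artifacts": artifacts,
    }
    man_path = out / "manifest.json"
    _dump_json(manifest, man_path)
    artifacts["manifest"] = str(man_path)
    return artifacts


def _load_signals(config: RunConfig):
    markers = read_marker_file(config.marker_path)
    force = read_force_file(config.force_path)
    return markers, force
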