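"""Rigid-body specimen model of a C2-C6 cervical spine with bushing joints.

The model is a chain of five vertebral segments coupled by four
six-degree-of-freedom viscoelastic bushing elements (Kelvin-Voigt: linear
spring and damper in parallel per component).  Joint frames sit at the
centres of the intervertebral mid-planes; the joint y-axis is normal to the
superior surface of the caudal vertebra (superior-inferior), x points
anteriorly and z completes a right-handed triad.  The experimental mounting
is reproduced by the constraint set: the caudal-most vertebra (C6) is fixed,
the cranial-most (C2) translates only axially, and the intermediate
vertebrae are free.

Coordinate convention: global frame right-handed with x anterior, y superior
(gravity is -y), z = x cross y.  All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import reference

__all__ = [
    "SegmentSpec",
    "JointFrame",
    "BushingParameters",
    "ConstraintSpec",
    "PreloadSpec",
    "SpecimenModel",
    "SpecimenGeometry",
    "State",
    "compute_joint_frame",
    "build_specimen_model",
    "default_bushing_init",
    "pack_parameters",
    "unpack_parameters",
    "marker_positions",
    "forward_kinematics_markers",
    "free_coordinates",
    "state_to_poses",
    "euler_xyz_to_matrix",
    "matrix_to_euler_xyz",
    "N_OPTIMISED_PARAMETERS",
]

#: Number of viscoelastic parameters identified by the pipeline: axial and
#: shear stiffness and damping at each of the four joints.
N_OPTIMISED_PARAMETERS = 16

_MOBILITY_KINDS = ("fixed", "axial_translation_only", "free")
#: per-body degree-of-freedom labels, order fixed throughout the package
DOF_LABELS = ("tx", "ty", "tz", "rx", "ry", "rz")


def euler_xyz_to_matrix(angles: np.ndarray) -> np.ndarray:
    """Rotation matrix for body-fixed (intrinsic) X-Y-Z Euler angles."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    return np.array([
        [cy * cz, -cy * sz, sy],
        [cx * sz + sx * sy * cz, cx * cz - sx * sy * sz, -sx * cy],
        [sx * sz - cx * sy * cz, sx * cz + cx * sy * sz, cx * cy],
    ])


def matrix_to_euler_xyz(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_xyz_to_matrix` (angles well inside gimbal range)."""
    sy = np.clip(R[0, 2], -1.0, 1.0)
    ay = np.arcsin(sy)
    ax = np.arctan2(-R[1, 2], R[2, 2])
    az = np.arctan2(-R[0, 1], R[0, 0])
    return np.array([ax, ay, az])


@dataclass
class SegmentSpec:
    """One rigid vertebral segment.

    ``marker_points`` are attachment points of motion-capture markers in the
    segment frame (origin at the centre of mass).  ``rest_position`` /
    ``rest_orientation`` give the segment's global pose in the undeflected
    reference configuration.
    """

    name: str
    mass: float
    inertia: np.ndarray                       # 3x3, about COM, segment frame
    com_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    marker_points: dict[str, np.ndarray] = field(default_factory=dict)
    rest_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rest_orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float)
        self.com_offset = np.asarray(self.com_offset, dtype=float)
        self.rest_position = np.asarray(self.rest_position, dtype=float)
        self.rest_orientation = np.asarray(self.rest_orientation, dtype=float)
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be positive")
        if not np.allclose(self.inertia, self.inertia.T):
            raise ValueError(f"segment {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ValueError(f"segment {self.name}: inertia must be positive definite")


@dataclass
class JointFrame:
    """Joint frame between a caudal and a cranial segment.

    ``origin_in_caudal`` and ``orientation_in_caudal`` locate the frame in
    the caudal segment frame.  ``rest_offset`` stores the joint origin in the
    cranial segment frame at zero deflection, which defines the point of the
    cranial body the bushing acts on.
    """

    caudal_segment: str
    cranial_segment: str
    origin_in_caudal: np.ndarray
    orientation_in_caudal: np.ndarray
    rest_offset: np.ndarray

    def __post_init__(self) -> None:
        self.origin_in_caudal = np.asarray(self.origin_in_caudal, dtype=float)
        self.orientation_in_caudal = np.asarray(self.orientation_in_caudal, dtype=float)
        self.rest_offset = np.asarray(self.rest_offset, dtype=float)
        R = self.orientation_in_caudal
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or np.linalg.det(R) < 0:
            raise ValueError("joint orientation must be a proper rotation")

    @property
    def name(self) -> str:
        return f"{self.cranial_segment}-{self.caudal_segment}"


@dataclass
class BushingParameters:
    """Kelvin-Voigt coefficients of one 6-DoF bushing.

    Translational order (x, y, z) = (anterior shear, axial, lateral) in the
    joint frame; rotational order about the same axes.
    """

    k_trans: np.ndarray   # N/m
    b_trans: np.ndarray   # Ns/m
    k_rot: np.ndarray     # Nm/rad
    b_rot: np.ndarray     # Nms/rad

    def __post_init__(self) -> None:
        for attr in ("k_trans", "b_trans", "k_rot", "b_rot"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{attr} must be a 3-vector")
            if np.any(v < 0):
                raise ValueError(f"{attr} components must be non-negative")
            setattr(self, attr, v)

    def copy(self) -> "BushingParameters":
        return BushingParameters(
            self.k_trans.copy(), self.b_trans.copy(),
            self.k_rot.copy(), self.b_rot.copy(),
        )

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(k, b) as 6-vectors ordered (tx, ty, tz, rx, ry, rz)."""
        return (np.concatenate([self.k_trans, self.k_rot]),
                np.concatenate([self.b_trans, self.b_rot]))


def default_bushing_init() -> BushingParameters:
    """Literature (quasi-static) initialisation of one bushing element."""
    return BushingParameters(
        k_trans=np.array([reference.INIT_SHEAR_STIFFNESS,
                          reference.INIT_AXIAL_STIFFNESS,
                          reference.INIT_LATERAL_STIFFNESS]),
        b_trans=np.array([reference.INIT_SHEAR_DAMPING,
                          reference.INIT_AXIAL_DAMPING,
                          reference.INIT_LATERAL_DAMPING]),
        k_rot=np.full(3, reference.INIT_ROT_STIFFNESS),
        b_rot=np.full(3, reference.INIT_ROT_DAMPING),
    )


@dataclass
class ConstraintSpec:
    """Per-segment mobility of the mounted specimen."""

    mobility: dict[str, str]

    def __post_init__(self) -> None:
        for name, kind in self.mobility.items():
            if kind not in _MOBILITY_KINDS:
                raise ValueError(f"unknown mobility {kind!r} for segment {name}")
        if sum(1 for k in self.mobility.values() if k == "fixed") != 1:
            raise ValueError("exactly one segment must be fixed")

    def free_mask(self, name: str) -> np.ndarray:
        """Boolean mask over (tx, ty, tz, rx, ry, rz)."""
        kind = self.mobility[name]
        if kind == "fixed":
            return np.zeros(6, dtype=bool)
        if kind == "axial_translation_only":
            return np.array([False, True, False, False, False, False])
        return np.ones(6, dtype=bool)


def specimen_constraints() -> ConstraintSpec:
    """Experimental mounting: C6 potted rigidly, C2 on an axial slider."""
    return ConstraintSpec(mobility={
        "C2": "axial_translation_only",
        "C3": "free", "C4": "free", "C5": "free",
        "C6": "fixed",
    })


@dataclass
class PreloadSpec:
    """Constant compressive preload applied at the cranial end.

    The two constant-force springs and the impact-plate weight sum to the
    preload carried by the specimen before impact (152 N at defaults); the
    plate mass additionally rides with the cranial segment's translation.
    """

    spring_force_N: float = reference.PRELOAD_SPRING_N
    plate_weight_N: float = reference.PRELOAD_PLATE_N
    plate_mass_kg: float = reference.PRELOAD_PLATE_MASS_KG

    @property
    def total_N(self) -> float:
        return self.spring_force_N + self.plate_weight_N


@dataclass
class SpecimenModel:
    """The assembled rigid-body chain.

    ``segments`` are ordered cranial to caudal (C2 first); ``joints`` and
    ``bushings`` are parallel lists ordered C2-C3 .. C5-C6.
    """

    segments: list[SegmentSpec]
    joints: list[JointFrame]
    bushings: list[BushingParameters]
    constraints: ConstraintSpec
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, -9.81, 0.0]))
    preload: PreloadSpec = field(default_factory=PreloadSpec)
    include_gravity: bool = True

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float)
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        markers = self.marker_names()
        if len(set(markers)) != len(markers):
            raise ValueError("marker names must be unique across segments")
        if len(self.bushings) != len(self.joints):
            raise ValueError("one BushingParameters per joint required")

    def segment(self, name: str) -> SegmentSpec:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    def segment_index(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise KeyError(name)

    def marker_names(self) -> list[str]:
        names: list[str] = []
        for s in self.segments:
            names.extend(s.marker_points.keys())
        return names

    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def with_bushings(self, bushings: Sequence[BushingParameters]) -> "SpecimenModel":
        return replace(self, bushings=list(bushings))

    def rest_poses(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {s.name: (s.rest_position.copy(), s.rest_orientation.copy())
                for s in self.segments}


# ----------------------------------------------------------------------
# geometry and model construction
# ----------------------------------------------------------------------

@dataclass
class SpecimenGeometry:
    """Parametric stacked-vertebra geometry of a C2-C6 specimen.

    Vertebral bodies are stacked along the global y-axis; intervertebral
    mid-planes are tilted about z by the per-joint sagittal angle
    (lordosis increases caudally, so the caudal-most joint sees the axial
    load at the largest shear angle).  Marker clusters sit on posterior
    lever arms from the C3/C4/C5 segments; three pot markers ride with C2.
    """

    vertebra_heights: np.ndarray        # 5, cranial (C2) to caudal (C6), m
    disc_heights: np.ndarray            # 4, C2-C3..C5-C6, m
    sagittal_tilts: np.ndarray          # 4, rad, about +z
    cluster_offset: float = 0.025       # posterior (-x) lever arm, m
    cluster_spread: float = 0.010       # half-size of the marker square, m
    pot_offset: float = 0.030           # cranial pot marker stand-off, m

    def __post_init__(self) -> None:
        self.vertebra_heights = np.asarray(self.vertebra_heights, dtype=float)
        self.disc_heights = np.asarray(self.disc_heights, dtype=float)
        self.sagittal_tilts = np.asarray(self.sagittal_tilts, dtype=float)
        if self.vertebra_heights.shape != (5,) or np.any(self.vertebra_heights <= 0):
            raise ValueError("need 5 positive vertebra heights")
        if self.disc_heights.shape != (4,) or np.any(self.disc_heights <= 0):
            raise ValueError("need 4 positive disc heights")
        if self.sagittal_tilts.shape != (4,):
            raise ValueError("need 4 sagittal tilt angles")

    @property
    def total_height(self) -> float:
        return float(self.vertebra_heights.sum() + self.disc_heights.sum())

    def segment_centres(self) -> np.ndarray:
        """Global rest COM positions, order C2..C6 (index 0 most cranial)."""
        centres = np.zeros((5, 3))
        y = 0.0  # build from the caudal base upwards
        for i in range(4, -1, -1):
            h = self.vertebra_heights[i]
            centres[i] = (0.0, y + h / 2.0, 0.0)
            y += h
            if i > 0:
                y += self.disc_heights[i - 1]
        return centres

    def mid_planes(self, joint: int) -> tuple[tuple[np.ndarray, np.ndarray],
                                              tuple[np.ndarray, np.ndarray]]:
        """(caudal superior plane, cranial inferior plane) for joint 0..3.

        Each plane is a (point, normal) pair in global coordinates; joint 0
        is C2-C3, joint 3 is C5-C6.
        """
        centres = self.segment_centres()
        caudal = joint + 1          # segment index of the caudal vertebra
        tilt = self.sagittal_tilts[joint]
        normal = np.array([-np.sin(tilt), np.cos(tilt), 0.0])
        top_of_caudal = centres[caudal] + np.array(
            [0.0, self.vertebra_heights[caudal] / 2.0, 0.0])
        bottom_of_cranial = centres[joint] - np.array(
            [0.0, self.vertebra_heights[joint] / 2.0, 0.0])
        return (top_of_caudal, normal), (bottom_of_cranial, normal)


def compute_joint_frame(
    caudal_superior_plane: tuple[np.ndarray, np.ndarray],
    cranial_inferior_plane: tuple[np.ndarray, np.ndarray],
    caudal_segment: str = "caudal",
    cranial_segment: str = "cranial",
    caudal_pose: tuple[np.ndarray, np.ndarray] | None = None,
    cranial_pose: tuple[np.ndarray, np.ndarray] | None = None,
    anterior: np.ndarray = (1.0, 0.0, 0.0),
) -> JointFrame:
    """Construct a joint frame from the two intervertebral mid-plane halves.

    The origin is the midpoint of the two plane centres; y is the unit
    normal of the caudal superior surface, x the anterior reference
    direction projected onto that surface, and z completes the right-handed
    triad.  ``caudal_pose``/``cranial_pose`` (global position, rotation) of
    the segments default to the identity pose at the origin.
    """
    p_ca, n_ca = (np.asarray(v, dtype=float) for v in caudal_superior_plane)
    p_cr, n_cr = (np.asarray(v, dtype=float) for v in cranial_inferior_plane)
    if np.linalg.norm(n_ca) == 0 or np.linalg.norm(n_cr) == 0:
        raise ValueError("degenerate mid-plane: zero normal")
    y = n_ca / np.linalg.norm(n_ca)
    a = np.asarray(anterior, dtype=float)
    x = a - (a @ y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("anterior reference is parallel to the plane normal")
    x = x / nx
    z = np.cross(x, y)
    R_global = np.column_stack([x, y, z])
    origin = 0.5 * (p_ca + p_cr)

    if caudal_pose is None:
        caudal_pose = (np.zeros(3), np.eye(3))
    if cranial_pose is None:
        cranial_pose = (np.zeros(3), np.eye(3))
    p0_ca, R0_ca = caudal_pose
    p0_cr, R0_cr = cranial_pose
    origin_in_caudal = R0_ca.T @ (origin - p0_ca)
    orientation_in_caudal = R0_ca.T @ R_global
    rest_offset = R0_cr.T @ (origin - p0_cr)
    return JointFrame(
        caudal_segment=caudal_segment,
        cranial_segment=cranial_segment,
        origin_in_caudal=origin_in_caudal,
        orientation_in_caudal=orientation_in_caudal,
        rest_offset=rest_offset,
    )


def _cylinder_inertia(mass: float, radius: float, height: float) -> np.ndarray:
    """Solid cylinder about its COM, axis along y."""
    i_axis = 0.5 * mass * radius**2
    i_trans = mass * (3.0 * radius**2 + height**2) / 12.0
    return np.diag([i_trans, i_axis, i_trans])


def _cluster_markers(prefix: str, offset: float, spread: float) -> dict[str, np.ndarray]:
    """Four markers on a square plate at the end of a posterior lever arm."""
    pts = {}
    for j, (dy, dz) in enumerate([(spread, spread), (spread, -spread),
                                  (-spread, spread), (-spread, -spread)], start=1):
        pts[f"{prefix}_{j}"] = np.array([-offset, dy, dz])
    return pts


def _pot_markers(prefix: str, half_height: float, offset: float) -> dict[str, np.ndarray]:
    """Three non-collinear markers on the cranial pot (rides with C2)."""
    return {
        f"{prefix}_1": np.array([offset, half_height, 0.0]),
        f"{prefix}_2": np.array([-0.5 * offset, half_height, 0.6 * offset]),
        f"{prefix}_3": np.array([-0.5 * offset, half_height, -0.6 * offset]),
    }


def build_specimen_model(
    geometry: SpecimenGeometry,
    mass_kg: float,
    mass_split: Sequence[float] | None = None,
    bushing_init: Sequence[BushingParameters] | None = None,
    segment_radius: float = 0.015,
    constraints: ConstraintSpec | None = None,
    preload: PreloadSpec | None = None,
) -> SpecimenModel:
    """Assemble a specimen model from parametric geometry.

    ``mass_split`` divides the total specimen mass over the five vertebrae
    (equal by default).  ``bushing_init`` supplies per-joint bushing
    parameters (literature initialisation by default).  Segment inertia is a
    solid-cylinder approximation using ``segment_radius`` and the per-vertebra
    height.
    """
    if mass_kg <= 0:
        raise ValueError("mass_kg must be positive")
    if mass_split is None:
        mass_split = np.full(5, 0.2)
    mass_split = np.asarray(mass_split, dtype=float)
    if mass_split.shape != (5,):
        raise ValueError("mass_split must have 5 weights (5 segments required)")
    if not np.isclose(mass_split.sum(), 1.0):
        raise ValueError("mass_split weights must sum to 1")
    if bushing_init is None:
        bushing_init = [default_bushing_init() for _ in range(4)]
    bushing_init = [b.copy() for b in bushing_init]
    if len(bushing_init) != 4:
        raise ValueError("need 4 per-joint bushing parameter sets")

    centres = geometry.segment_centres()
    segments: list[SegmentSpec] = []
    for i, name in enumerate(reference.SEGMENT_NAMES):
        m = float(mass_kg * mass_split[i])
        h = float(geometry.vertebra_heights[i])
        markers: dict[str, np.ndarray] = {}
        if name == "C2":
            markers = _pot_markers("POT", h / 2.0, geometry.pot_offset)
        elif name in ("C3", "C4", "C5"):
            markers = _cluster_markers(
                f"{name}CL", geometry.cluster_offset, geometry.cluster_spread)
        segments.append(SegmentSpec(
            name=name, mass=m,
            inertia=_cylinder_inertia(m, segment_radius, h),
            marker_points=markers,
            rest_position=centres[i],
            rest_orientation=np.eye(3),
        ))

    joints: list[JointFrame] = []
    for j in range(4):
        caudal_plane, cranial_plane = geometry.mid_planes(j)
        joints.append(compute_joint_frame(
            caudal_plane, cranial_plane,
            caudal_segment=reference.SEGMENT_NAMES[j + 1],
            cranial_segment=reference.SEGMENT_NAMES[j],
            caudal_pose=(centres[j + 1], np.eye(3)),
            cranial_pose=(centres[j], np.eye(3)),
        ))

    return SpecimenModel(
        segments=segments,
        joints=joints,
        bushings=bushing_init,
        constraints=constraints or specimen_constraints(),
        preload=preload or PreloadSpec(),
    )


# ----------------------------------------------------------------------
# parameter packing
# ----------------------------------------------------------------------

def pack_parameters(bushings: Sequence[BushingParameters]) -> np.ndarray:
    """Pack the optimised axial/shear entries of 4 bushings into a 16-vector.

    Order: [k_y per joint, b_y per joint, k_x per joint, b_x per joint],
    joints C2-C3..C5-C6.
    """
    if len(bushings) != 4:
        raise ValueError("exactly 4 joints required")
    return np.concatenate([
        [b.k_trans[1] for b in bushings],
        [b.b_trans[1] for b in bushings],
        [b.k_trans[0] for b in bushings],
        [b.b_trans[0] for b in bushings],
    ])


def unpack_parameters(
    p: np.ndarray, template: Sequence[BushingParameters]
) -> list[BushingParameters]:
    """Install a 16-vector into copies of the template bushings.

    Only the axial and shear translational entries are replaced; the lateral
    translation and all rotational coefficients keep their template values.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (N_OPTIMISED_PARAMETERS,):
        raise ValueError(f"parameter vector must have length {N_OPTIMISED_PARAMETERS}")
    if np.any(p < 0):
        raise ValueError("parameters must be non-negative")
    if len(template) != 4:
        raise ValueError("exactly 4 template bushings required")
    out = []
    for j, t in enumerate(template):
        b = t.copy()
        b.k_trans[1] = p[j]
        b.b_trans[1] = p[4 + j]
        b.k_trans[0] = p[8 + j]
        b.b_trans[0] = p[12 + j]
        out.append(b)
    return out


# ----------------------------------------------------------------------
# state and marker forward kinematics
# ----------------------------------------------------------------------

@dataclass
class State:
    """Generalised coordinates/velocities over the model's free DoF.

    Coordinates are deviations from the rest pose: translations in metres
    (global axes), rotations as body-fixed X-Y-Z Euler angles (radians)
    relative to the segment's rest orientation.  Layout follows
    :func:`free_coordinates`.
    """

    q: np.ndarray
    u: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.q.shape != self.u.shape:
            raise ValueError("q and u must have matching shapes")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.u))):
            raise ValueError("state entries must be finite")


def free_coordinates(model: SpecimenModel) -> list[tuple[str, str]]:
    """Ordered (segment, dof) labels of the model's free coordinates."""
    coords = []
    for s in model.segments:
        mask = model.constraints.free_mask(s.name)
        coords.extend((s.name, DOF_LABELS[k]) for k in range(6) if mask[k])
    return coords


def state_to_poses(
    model: SpecimenModel, state: State
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Global (position, rotation) of every segment for a given state."""
    coords = free_coordinates(model)
    if state.q.shape != (len(coords),):
        raise ValueError(
            f"state has {state.q.shape[0]} coordinates, model has {len(coords)}")
    poses = {}
    i = 0
    for s in model.segments:
        mask = model.constraints.free_mask(s.name)
        local = np.zeros(6)
        for k in range(6):
            if mask[k]:
                local[k] = state.q[i]
                i += 1
        p = s.rest_position + local[:3]
        R = s.rest_orientation @ euler_xyz_to_matrix(local[3:])
        poses[s.name] = (p, R)
    return poses


def marker_positions(
    model: SpecimenModel,
    poses: Mapping[str, tuple[np.ndarray, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Global marker positions for explicit segment poses."""
    out = {}
    for s in model.segments:
        p, R = poses[s.name]
        for name, local in s.marker_points.items():
            out[name] = p + R @ local
    return out


def forward_kinematics_markers(
    model: SpecimenModel, state: State
) -> dict[str, np.ndarray]:
    """Global position of every marker at the given state."""
    return marker_positions(model, state_to_poses(model, state))
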