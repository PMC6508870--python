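"""Forward dynamics of the bushing chain: equilibrium, integration, outputs.

The simulator integrates the free rigid-body coordinates under gravity, the
constant cranial preload, the Kelvin-Voigt bushing wrenches and an applied
compressive drive force, using a fixed-step classical RK4 scheme (default
1 microsecond, i.e. 5000 steps per 5 ms window).  Every simulation starts
from the static equilibrium under preload unless an explicit initial state
is given, matching the experimental protocol in which specimens were
preloaded before impact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import _engine
from .model import (
    BushingParameters,
    SpecimenModel,
    State,
    free_coordinates,
    euler_xyz_to_matrix,
    matrix_to_euler_xyz,
)
from .signals import ForceTrace, MarkerTrajectories, DEFAULT_MARKER_FS

__all__ = [
    "CompiledModel",
    "SimulationResult",
    "compile_model",
    "bushing_wrench",
    "state_derivative",
    "static_equilibrium",
    "simulate",
    "extract_joint_series",
    "mechanical_energy",
    "DEFAULT_TIMESTEP_S",
]

DEFAULT_TIMESTEP_S = 1.0e-6

JOINT_CHANNELS = ("axial_force", "shear_force", "axial_displacement",
                  "shear_displacement")


@dataclass
class CompiledModel:
    """Flat-array view of a :class:`SpecimenModel` for the integration kernel.

    All joint/marker attachment points are re-expressed relative to segment
    centres of mass; the full per-body state layout is (tx, ty, tz, rx, ry,
    rz) with constrained entries masked.
    """

    model: SpecimenModel
    p0: np.ndarray
    R0: np.ndarray
    mass: np.ndarray
    mextra: np.ndarray
    Iinv: np.ndarray
    free_mask: np.ndarray          # float (nb, 6)
    grav: np.ndarray
    const_F: np.ndarray
    ext_body: int
    jca: np.ndarray
    jcr: np.ndarray
    joc: np.ndarray
    jRjc: np.ndarray
    jacr: np.ndarray
    jRjcr: np.ndarray
    jk: np.ndarray
    jb: np.ndarray
    marker_body: np.ndarray
    marker_local: np.ndarray
    marker_names: list[str]
    free_idx: np.ndarray           # indices of free entries in the full vector

    @property
    def n_bodies(self) -> int:
        return self.mass.shape[0]

    @property
    def n_joints(self) -> int:
        return self.jca.shape[0]

    @property
    def n_free(self) -> int:
        return self.free_idx.shape[0]

    def kernel_args(self) -> tuple:
        return (self.p0, self.R0, self.mass, self.mextra, self.Iinv,
                self.free_mask, self.grav, self.const_F, self.ext_body,
                self.jca, self.jcr, self.joc, self.jRjc, self.jacr,
                self.jRjcr, self.jk, self.jb)

    def full_from_free(self, q_free: np.ndarray) -> np.ndarray:
        full = np.zeros(6 * self.n_bodies)
        full[self.free_idx] = q_free
        return full

    def free_from_full(self, q_full: np.ndarray) -> np.ndarray:
        return q_full[self.free_idx]


def compile_model(model: SpecimenModel, drive_body: str | None = None) -> CompiledModel:
    """Lower a specimen model to kernel arrays.

    ``drive_body`` names the segment receiving the external compressive
    drive force (the cranial-most segment by default, where the impact plate
    sits).
    """
    nb = len(model.segments)
    p0 = np.zeros((nb, 3))
    R0 = np.zeros((nb, 3, 3))
    mass = np.zeros(nb)
    mextra = np.zeros(nb)
    Iinv = np.zeros((nb, 3, 3))
    free_mask = np.zeros((nb, 6))
    const_F = np.zeros((nb, 3))
    for i, s in enumerate(model.segments):
        # segment frame origin may be offset from the COM
        p0[i] = s.rest_position + s.rest_orientation @ s.com_offset
        R0[i] = s.rest_orientation
        mass[i] = s.mass
        if np.any(np.linalg.eigvalsh(s.inertia) <= 0):
            raise ValueError(f"singular inertia for segment {s.name}")
        Iinv[i] = np.linalg.inv(s.inertia)
        free_mask[i] = model.constraints.free_mask(s.name).astype(float)

    drive = drive_body or model.segments[0].name
    ext_body = model.segment_index(drive)
    # the preload springs and plate weight act on the drive segment; the
    # plate mass rides with its translation
    const_F[ext_body, 1] -= model.preload.total_N
    mextra[ext_body] += model.preload.plate_mass_kg
    grav = model.gravity.copy() if model.include_gravity else np.zeros(3)

    nj = len(model.joints)
    jca = np.zeros(nj, dtype=np.int64)
    jcr = np.zeros(nj, dtype=np.int64)
    joc = np.zeros((nj, 3))
    jRjc = np.zeros((nj, 3, 3))
    jacr = np.zeros((nj, 3))
    jRjcr = np.zeros((nj, 3, 3))
    jk = np.zeros((nj, 6))
    jb = np.zeros((nj, 6))
    for j, (jf, bu) in enumerate(zip(model.joints, model.bushings)):
        ca = model.segment_index(jf.caudal_segment)
        cr = model.segment_index(jf.cranial_segment)
        jca[j] = ca
        jcr[j] = cr
        s_ca = model.segments[ca]
        s_cr = model.segments[cr]
        joc[j] = jf.origin_in_caudal - s_ca.com_offset
        jRjc[j] = jf.orientation_in_caudal
        jacr[j] = jf.rest_offset - s_cr.com_offset
        # rest orientation of the joint frame as carried by the cranial body
        RJ0 = s_ca.rest_orientation @ jf.orientation_in_caudal
        jRjcr[j] = s_cr.rest_orientation.T @ RJ0
        jk[j], jb[j] = bu.stacked()

    marker_body = []
    marker_local = []
    marker_names = []
    for i, s in enumerate(model.segments):
        for name, local in s.marker_points.items():
            marker_body.append(i)
            marker_local.append(np.asarray(local, dtype=float) - s.com_offset)
            marker_names.append(name)

    full_mask = free_mask.reshape(-1).astype(bool)
    return CompiledModel(
        model=model, p0=p0, R0=R0, mass=mass, mextra=mextra, Iinv=Iinv,
        free_mask=free_mask, grav=grav, const_F=const_F, ext_body=ext_body,
        jca=jca, jcr=jcr, joc=joc, jRjc=jRjc, jacr=jacr, jRjcr=jRjcr,
        jk=jk, jb=jb,
        marker_body=np.array(marker_body, dtype=np.int64),
        marker_local=(np.array(marker_local).reshape(-1, 3)
                      if marker_local else np.zeros((0, 3))),
        marker_names=marker_names,
        free_idx=np.flatnonzero(full_mask),
    )


def bushing_wrench(
    params: BushingParameters, d: np.ndarray, d_rate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kelvin-Voigt wrench for a 6-deflection and rate, in the joint frame.

    Returns ``(wrench_on_cranial, wrench_on_caudal)`` as 6-vectors
    (force, torque) acting at the joint origin; the caudal wrench is the
    equal-and-opposite reaction.  Component order (x, y, z, rx, ry, rz):
    each ``F_i = -k_i d_i - b_i d_rate_i``.
    """
    d = np.asarray(d, dtype=float)
    d_rate = np.asarray(d_rate, dtype=float)
    if d.shape != (6,) or d_rate.shape != (6,):
        raise ValueError("deflection and rate must be 6-vectors")
    k, b = params.stacked()
    w = -k * d - b * d_rate
    return w, -w


def _poses_from_full(c: CompiledModel, Q: np.ndarray):
    nb = c.n_bodies
    P = np.empty((nb, 3))
    R = np.empty((nb, 3, 3))
    for b in range(nb):
        o = 6 * b
        P[b] = c.p0[b] + Q[o:o + 3]
        R[b] = c.R0[b] @ euler_xyz_to_matrix(Q[o + 3:o + 6])
    return P, R


def joint_state(c: CompiledModel, Q: np.ndarray, U: np.ndarray):
    """Per-joint deflection, rate and cranial wrench for one full state.

    Reference (pure numpy) evaluation of the same bushing kinematics the
    compiled kernel uses; returns arrays of shape (n_joints, 6) in each
    joint's own frame.
    """
    P, R = _poses_from_full(c, Q)
    nb = c.n_bodies
    V = U.reshape(nb, 6)[:, :3]
    W = np.einsum("bij,bj->bi", c.R0, U.reshape(nb, 6)[:, 3:])
    nj = c.n_joints
    d = np.zeros((nj, 6))
    dd = np.zeros((nj, 6))
    w = np.zeros((nj, 6))
    for j in range(nj):
        ca, cr = c.jca[j], c.jcr[j]
        RJ = R[ca] @ c.jRjc[j]
        rca = R[ca] @ c.joc[j]
        rcr = R[cr] @ c.jacr[j]
        gap = (P[cr] + rcr) - (P[ca] + rca)
        d[j, :3] = RJ.T @ gap
        vrel = (V[cr] + np.cross(W[cr], rcr)) - (V[ca] + np.cross(W[ca], rca))
        dd[j, :3] = RJ.T @ vrel
        Rrel = RJ.T @ (R[cr] @ c.jRjcr[j])
        d[j, 3:] = matrix_to_euler_xyz(Rrel)
        dd[j, 3:] = RJ.T @ (W[cr] - W[ca])
        w[j] = -c.jk[j] * d[j] - c.jb[j] * dd[j]
    return d, dd, w


def _marker_frame(c: CompiledModel, Q: np.ndarray) -> np.ndarray:
    P, R = _poses_from_full(c, Q)
    return P[c.marker_body] + np.einsum(
        "mij,mj->mi", R[c.marker_body], c.marker_local)


def mechanical_energy(c: CompiledModel, Q: np.ndarray, U: np.ndarray) -> float:
    """Kinetic + elastic + gravitational energy of one full state (J)."""
    nb = c.n_bodies
    ke = 0.0
    pe = 0.0
    for b in range(nb):
        o = 6 * b
        v = U[o:o + 3]
        om = U[o + 3:o + 6]
        R = c.R0[b] @ euler_xyz_to_matrix(Q[o + 3:o + 6])
        I = np.linalg.inv(c.Iinv[b])
        mtot = c.mass[b] + c.mextra[b]
        ke += 0.5 * mtot * v @ v + 0.5 * om @ (I @ om)
        p = c.p0[b] + Q[o:o + 3]
        pe -= c.mass[b] * (c.grav @ p)
        # constant forces (preload springs, plate weight) as linear potentials
        pe -= c.const_F[b] @ p
    d, _, _ = joint_state(c, Q, np.zeros_like(U))
    elastic = 0.5 * float(np.sum(c.jk * d * d))
    return float(ke + pe + elastic)


def state_derivative(
    model_or_compiled: SpecimenModel | CompiledModel,
    state: State,
    external_force_N: float = 0.0,
) -> State:
    """Time derivative of a free-coordinate state under a compressive drive."""
    c = (model_or_compiled if isinstance(model_or_compiled, CompiledModel)
         else compile_model(model_or_compiled))
    Q = c.full_from_free(state.q)
    U = c.full_from_free(state.u)
    Qd = np.zeros_like(Q)
    Ud = np.zeros_like(U)
    _engine._rhs(Q, U, float(external_force_N), *c.kernel_args(), Qd, Ud)
    return State(q=c.free_from_full(Qd), u=c.free_from_full(Ud), time=state.time)


def static_equilibrium(
    model_or_compiled: SpecimenModel | CompiledModel,
    tol: float = 1e-4,
) -> State:
    """Static equilibrium of the preloaded chain (free coordinates).

    Solves for the free coordinates at which all generalised accelerations
    vanish with zero velocity and no external drive, via a Newton-type root
    solve starting from the rest pose.
    """
    c = (model_or_compiled if isinstance(model_or_compiled, CompiledModel)
         else compile_model(model_or_compiled))
    nfull = 6 * c.n_bodies
    Qd = np.zeros(nfull)
    Ud = np.zeros(nfull)
    U = np.zeros(nfull)
    args = c.kernel_args()

    def residual(q_free: np.ndarray) -> np.ndarray:
        Q = c.full_from_free(q_free)
        _engine._rhs(Q, U, 0.0, *args, Qd, Ud)
        return c.free_from_full(Ud)

    sol = optimize.root(residual, np.zeros(c.n_free), method="hybr",
                        options={"xtol": 1e-14})
    res = residual(sol.x)
    # residual is in acceleration units (m/s^2, rad/s^2); require it to be
    # negligible against gravitational acceleration
    if not np.all(np.isfinite(sol.x)) or np.max(np.abs(res)) > tol:
        raise RuntimeError("static equilibrium solve did not converge")
    return State(q=sol.x, u=np.zeros(c.n_free), time=0.0)


@dataclass
class SimulationResult:
    """Trajectories, joint series and marker kinematics of one simulation.

    ``times`` are seconds from the start of the window.  ``joint_wrenches``
    hold the 6-component wrench the bushing exerts on the cranial body in
    the joint frame (positive y force = compression resisted).  Joint
    displacement channels are referenced to ``d_equilibrium``.
    """

    times: np.ndarray
    body_q: np.ndarray                 # (frames, 6 * n_bodies)
    body_u: np.ndarray
    markers: MarkerTrajectories
    joint_names: list[str]
    joint_deflections: np.ndarray      # (frames, n_joints, 6)
    joint_rates: np.ndarray
    joint_wrenches: np.ndarray
    d_equilibrium: np.ndarray          # (n_joints, 6)
    status: int = _engine.OK
    meta: dict = field(default_factory=dict)

    @property
    def diverged(self) -> bool:
        return self.status != _engine.OK


def simulate(
    model_or_compiled: SpecimenModel | CompiledModel,
    load: ForceTrace,
    window_s: float = 0.005,
    dt: float = DEFAULT_TIMESTEP_S,
    output_times: np.ndarray | None = None,
    marker_fs: float = DEFAULT_MARKER_FS,
    initial_state: State | None = None,
    raise_on_divergence: bool = True,
) -> SimulationResult:
    """Integrate the chain over an analysis window driven by a force trace.

    The load trace is interpreted as the net compressive drive (baseline
    removed) applied along -y at the drive segment's COM; its first sample
    defines t = 0 of the simulation.  Output frames default to the marker
    rate grid over the window; ``output_times`` (seconds from window start)
    overrides it, e.g. to sample at measured marker timestamps.
    """
    c = (model_or_compiled if isinstance(model_or_compiled, CompiledModel)
         else compile_model(model_or_compiled))
    if load.duration < window_s - 2.0 / load.fs:
        raise ValueError("load trace shorter than the simulation window")
    n_steps = int(round(window_s / dt))
    grid = np.arange(2 * n_steps + 1) * (dt / 2.0)
    f_half = np.interp(grid, load.times - load.times[0], load.samples)

    if initial_state is None:
        initial_state = static_equilibrium(c)
    Q0 = c.full_from_free(initial_state.q)
    U0 = c.full_from_free(initial_state.u)
    d_eq, _, _ = joint_state(c, Q0, np.zeros_like(U0))

    status, reached, Qh, Uh = _engine.integrate(
        Q0, U0, n_steps, dt, f_half, *c.kernel_args())
    if status != _engine.OK:
        if raise_on_divergence:
            raise FloatingPointError(
                f"integrator diverged at step {reached} of {n_steps}")
        Qh = Qh[:reached + 1]
        Uh = Uh[:reached + 1]

    tgrid = np.arange(Qh.shape[0]) * dt
    if output_times is None:
        n_out = int(np.floor(window_s * marker_fs + 1e-9)) + 1
        output_times = np.arange(n_out) / marker_fs
    output_times = np.asarray(output_times, dtype=float)
    output_times = output_times[output_times <= tgrid[-1] + 1e-12]

    # interpolate full states onto the output grid
    nq = Qh.shape[1]
    Qo = np.empty((output_times.shape[0], nq))
    Uo = np.empty((output_times.shape[0], nq))
    for col in range(nq):
        Qo[:, col] = np.interp(output_times, tgrid, Qh[:, col])
        Uo[:, col] = np.interp(output_times, tgrid, Uh[:, col])

    nfr = output_times.shape[0]
    nj = c.n_joints
    defl = np.empty((nfr, nj, 6))
    rates = np.empty((nfr, nj, 6))
    wrench = np.empty((nfr, nj, 6))
    mk = np.empty((nfr, len(c.marker_names), 3))
    for f in range(nfr):
        defl[f], rates[f], wrench[f] = joint_state(c, Qo[f], Uo[f])
        mk[f] = _marker_frame(c, Qo[f])

    markers = MarkerTrajectories(
        names=list(c.marker_names), positions=mk,
        fs=marker_fs if output_times.shape[0] < 2 else
        1.0 / max(np.mean(np.diff(output_times)), 1e-12),
        t0=float(output_times[0]))
    return SimulationResult(
        times=output_times, body_q=Qo, body_u=Uo, markers=markers,
        joint_names=[j.name for j in c.model.joints],
        joint_deflections=defl, joint_rates=rates, joint_wrenches=wrench,
        d_equilibrium=d_eq, status=status,
        meta={"dt": dt, "n_steps": n_steps, "window_s": window_s},
    )


def extract_joint_series(
    result: SimulationResult, joint: str, channel: str
) -> np.ndarray:
    """Scalar per-sample series for one joint, in its joint frame (SI units).

    ``axial_force``/``shear_force`` are the bushing force components on the
    cranial body (axial positive in compression, shear positive anteriorly);
    displacement channels are metres relative to the preloaded equilibrium.
    """
    try:
        j = result.joint_names.index(joint)
    except ValueError:
        raise KeyError(f"unknown joint {joint!r}") from None
    if channel == "axial_force":
        return result.joint_wrenches[:, j, 1]
    if channel == "shear_force":
        return result.joint_wrenches[:, j, 0]
    if channel == "axial_displacement":
        return result.joint_deflections[:, j, 1] - result.d_equilibrium[j, 1]
    if channel == "shear_displacement":
        return result.joint_deflections[:, j, 0] - result.d_equilibrium[j, 0]
    raise KeyError(f"unknown channel {channel!r}; one of {JOINT_CHANNELS}")
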