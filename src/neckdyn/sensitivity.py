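"""Sensitivity of tracking error to parameter and joint-frame perturbations.

Three analyses around an identified optimum ``p``:

* individual-set sweeps: one functional set (axial stiffness, axial
  damping, shear stiffness or shear damping) scaled over 50-150 % of its
  optimum while the others stay put;
* Monte Carlo: all four sets perturbed simultaneously, ``p_i = p + r p``
  with one uniform coefficient ``r`` in [-0.5, 0.5] per set, and the
  tracking-error change ``dRMSE = RMSE_per - RMSE_opt`` recorded per
  sample; third-degree polynomial surfaces are fitted to the six set pairs;
* joint-frame position: all four joint origins shifted together by
  ``d_x`` in [-0.02, 0.02] m along their anteroposterior axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import CompiledModel, compile_model
from .identify import evaluate_objective
from .model import N_OPTIMISED_PARAMETERS, SpecimenModel
from .signals import ForceTrace, MarkerTrajectories
from .validate import SET_NAMES, SET_SLICES

__all__ = [
    "PerturbationSample",
    "SurfaceFit",
    "perturb_sets",
    "sweep_individual_set",
    "run_monte_carlo",
    "fit_pair_surface",
    "sweep_joint_frame_positions",
    "SET_PAIRS",
    "FRAME_SHIFT_BOUND_M",
]

#: the six unordered pairs of functional parameter sets
SET_PAIRS = tuple(
    (SET_NAMES[a], SET_NAMES[b])
    for a in range(4) for b in range(a + 1, 4)
)
FRAME_SHIFT_BOUND_M = 0.02
_R_BOUND = 0.5


@dataclass
class PerturbationSample:
    """One Monte Carlo draw: set coefficients, perturbed vector, errors."""

    r: np.ndarray                # 4 coefficients, order SET_NAMES
    p_i: np.ndarray              # perturbed 16-vector
    rmse_per_mm: float
    delta_rmse_mm: float


def perturb_sets(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Scale each functional set of ``p`` by ``(1 + r_set)``.

    ``r`` has one coefficient per set in [-0.5, 0.5] (order: axial
    stiffness, axial damping, shear stiffness, shear damping), so the
    perturbed parameters span 50-150 % of the optimum.
    """
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if p.shape != (N_OPTIMISED_PARAMETERS,):
        raise ValueError("expected a 16-parameter vector")
    if r.shape != (4,):
        raise ValueError("expected one perturbation coefficient per set")
    if np.any(np.abs(r) > _R_BOUND + 1e-12):
        raise ValueError("perturbation coefficients must lie in [-0.5, 0.5]")
    out = p.copy()
    for name, coeff in zip(SET_NAMES, r):
        out[SET_SLICES[name]] *= (1.0 + coeff)
    return out


def sweep_individual_set(
    model_or_compiled: SpecimenModel | CompiledModel,
    data: tuple[ForceTrace, MarkerTrajectories],
    p_opt: np.ndarray,
    set_id: str,
    grid: int = 11,
) -> pd.DataFrame:
    """RMSE while one set is scaled over [0.5, 1.5] of its optimum."""
    if set_id not in SET_NAMES:
        raise KeyError(f"unknown parameter set {set_id!r}")
    c = _compiled(model_or_compiled)
    scales = np.linspace(1.0 - _R_BOUND, 1.0 + _R_BOUND, grid)
    rows = []
    for s in scales:
        r = np.zeros(4)
        r[SET_NAMES.index(set_id)] = s - 1.0
        rmse = evaluate_objective(perturb_sets(p_opt, r), c, data[0], data[1])
        rows.append((s, rmse))
    return pd.DataFrame(rows, columns=["scale", "rmse_mm"])


def run_monte_carlo(
    model_or_compiled: SpecimenModel | CompiledModel,
    data: tuple[ForceTrace, MarkerTrajectories],
    p_opt: np.ndarray,
    n: int = 1000,
    seed: int = 0,
    per_parameter: bool = False,
) -> list[PerturbationSample]:
    """Simultaneous uniform perturbation of all four parameter sets.

    Each of the ``n`` samples draws one coefficient per set (or per
    parameter with ``per_parameter=True``) uniformly in [-0.5, 0.5],
    simulates, and records ``dRMSE`` relative to the optimum.  Reproducible
    for a given seed.
    """
    if n <= 0:
        raise ValueError("sample count must be positive")
    c = _compiled(model_or_compiled)
    p_opt = np.asarray(p_opt, dtype=float)
    rmse_opt = evaluate_objective(p_opt, c, data[0], data[1])
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        if per_parameter:
            r16 = rng.uniform(-_R_BOUND, _R_BOUND, N_OPTIMISED_PARAMETERS)
            p_i = p_opt * (1.0 + r16)
            # set-level coefficient reported as the per-set mean
            r = np.array([r16[SET_SLICES[s]].mean() for s in SET_NAMES])
        else:
            r = rng.uniform(-_R_BOUND, _R_BOUND, 4)
            p_i = perturb_sets(p_opt, r)
        rmse_per = evaluate_objective(p_i, c, data[0], data[1])
        samples.append(PerturbationSample(
            r=r, p_i=p_i, rmse_per_mm=rmse_per,
            delta_rmse_mm=rmse_per - rmse_opt))
    return samples


# full bivariate cubic basis: powers (i, j) with i + j <= 3, 10 terms
_CUBIC_POWERS = tuple((i, j) for d in range(4) for i in range(d + 1)
                      for j in [d - i])


@dataclass
class SurfaceFit:
    """Least-squares fit of dRMSE over one pair of set coefficients."""

    pair: tuple[str, str]
    coefficients: np.ndarray     # aligned with `powers`
    powers: tuple[tuple[int, int], ...]
    residual_norm: float

    def __call__(self, r_a: np.ndarray, r_b: np.ndarray) -> np.ndarray:
        r_a = np.asarray(r_a, dtype=float)
        r_b = np.asarray(r_b, dtype=float)
        out = np.zeros(np.broadcast(r_a, r_b).shape)
        for c, (i, j) in zip(self.coefficients, self.powers):
            out = out + c * r_a**i * r_b**j
        return out


def fit_pair_surface(
    samples: list[PerturbationSample], pair: tuple[str, str]
) -> SurfaceFit:
    """Fit a full third-degree polynomial surface dRMSE(r_a, r_b).

    The Monte Carlo samples are projected onto the two coordinates of the
    requested set pair and fitted by ordinary least squares on the
    ten-term bivariate cubic basis.
    """
    for s in pair:
        if s not in SET_NAMES:
            raise KeyError(f"unknown parameter set {s!r}")
    if len(samples) < len(_CUBIC_POWERS):
        raise ValueError("need at least 10 samples to fit a bivariate cubic")
    ia, ib = SET_NAMES.index(pair[0]), SET_NAMES.index(pair[1])
    ra = np.array([s.r[ia] for s in samples])
    rb = np.array([s.r[ib] for s in samples])
    y = np.array([s.delta_rmse_mm for s in samples])
    A = np.column_stack([ra**i * rb**j for (i, j) in _CUBIC_POWERS])
    if np.linalg.matrix_rank(A) < len(_CUBIC_POWERS):
        raise ValueError("rank-deficient design: too few distinct sample points")
    coeffs, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.linalg.norm(A @ coeffs - y))
    return SurfaceFit(pair=pair, coefficients=coeffs,
                      powers=_CUBIC_POWERS, residual_norm=resid)


def shift_joint_frames(model: SpecimenModel, d_x: float) -> SpecimenModel:
    """All four joint frames translated by ``d_x`` along their own x-axes."""
    joints = []
    for jf in model.joints:
        x_ca = jf.orientation_in_caudal[:, 0]
        caudal = model.segment(jf.caudal_segment)
        cranial = model.segment(jf.cranial_segment)
        # the same global shift expressed in the cranial segment frame
        shift_global = caudal.rest_orientation @ (x_ca * d_x)
        joints.append(replace(
            jf,
            origin_in_caudal=jf.origin_in_caudal + x_ca * d_x,
            rest_offset=jf.rest_offset + cranial.rest_orientation.T @ shift_global,
        ))
    return replace(model, joints=joints)


def sweep_joint_frame_positions(
    model: SpecimenModel,
    data: tuple[ForceTrace, MarkerTrajectories],
    p_opt: np.ndarray,
    grid: int = 9,
) -> pd.DataFrame:
    """RMSE as all four joint origins shift anteroposteriorly together."""
    shifts = np.linspace(-FRAME_SHIFT_BOUND_M, FRAME_SHIFT_BOUND_M, grid)
    rows = []
    for d_x in shifts:
        if abs(d_x) > FRAME_SHIFT_BOUND_M + 1e-12:
            raise ValueError("frame shift outside [-0.02, 0.02] m")
        shifted = compile_model(shift_joint_frames(model, float(d_x)))
        rmse = evaluate_objective(np.asarray(p_opt, dtype=float), shifted,
                                  data[0], data[1])
        rows.append((d_x, rmse))
    return pd.DataFrame(rows, columns=["d_x_m", "rmse_mm"])


def _compiled(m: SpecimenModel | CompiledModel) -> CompiledModel:
    return m if isinstance(m, CompiledModel) else compile_model(m)
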