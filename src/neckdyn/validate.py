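"""Parameter aggregation, five-fold cross-validation, fixed-parameter evaluation.

Identified 16-parameter vectors are grouped into four functional sets
(axial stiffness k_y, axial damping b_y, shear stiffness k_x, shear damping
b_x, each over the four joints).  Cross-validation transfers the
componentwise median of four specimens' identified parameters to the fifth
and re-runs forward dynamics only, comparing the resulting tracking error
(RMSE_val) against that specimen's own optimum (RMSE_opt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CompiledModel
from .identify import IdentificationResult, evaluate_objective
from .model import N_OPTIMISED_PARAMETERS, SpecimenModel
from .signals import ForceTrace, MarkerTrajectories

__all__ = [
    "ParameterSets",
    "FoldResult",
    "CrossValResult",
    "aggregate_median_parameters",
    "cross_validate_five_fold",
    "evaluate_with_fixed_parameters",
]

SET_NAMES = ("axial_stiffness", "axial_damping", "shear_stiffness", "shear_damping")
#: index slices of the four functional sets within a 16-vector
SET_SLICES = {
    "axial_stiffness": slice(0, 4),
    "axial_damping": slice(4, 8),
    "shear_stiffness": slice(8, 12),
    "shear_damping": slice(12, 16),
}


@dataclass
class ParameterSets:
    """A 16-parameter vector grouped by function (4-vector per set)."""

    k_y: np.ndarray
    b_y: np.ndarray
    k_x: np.ndarray
    b_x: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("k_y", "b_y", "k_x", "b_x"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (4,):
                raise ValueError(f"{attr} must be a 4-vector over joints")
            if np.any(v < 0):
                raise ValueError(f"{attr} must be non-negative")
            setattr(self, attr, v)

    @classmethod
    def from_vector(cls, p: np.ndarray) -> "ParameterSets":
        p = np.asarray(p, dtype=float)
        if p.shape != (N_OPTIMISED_PARAMETERS,):
            raise ValueError("expected a 16-parameter vector")
        return cls(k_y=p[0:4], b_y=p[4:8], k_x=p[8:12], b_x=p[12:16])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.k_y, self.b_y, self.k_x, self.b_x])


def aggregate_median_parameters(results: list[np.ndarray]) -> np.ndarray:
    """Componentwise median of identified parameter vectors.

    For an even number of inputs each component is the arithmetic midpoint
    of the two central values (the convention needed when each
    cross-validation fold aggregates exactly four specimens).
    """
    if len(results) == 0:
        raise ValueError("need at least one parameter vector")
    arr = np.asarray([np.asarray(r, dtype=float) for r in results])
    if arr.ndim != 2 or arr.shape[1] != N_OPTIMISED_PARAMETERS:
        raise ValueError("all parameter vectors must have length 16")
    return np.median(arr, axis=0)


def evaluate_with_fixed_parameters(
    model_or_compiled: SpecimenModel | CompiledModel,
    data: tuple[ForceTrace, MarkerTrajectories],
    p: np.ndarray,
) -> float:
    """Tracking RMSE (mm) with a fixed parameter vector, no optimisation.

    Degenerate vectors that make the simulation diverge return the finite
    penalty value rather than raising, flagging the evaluation as invalid.
    """
    force_window, measured = data
    return evaluate_objective(p, model_or_compiled, force_window, measured)


@dataclass
class FoldResult:
    held_out: str
    transferred: np.ndarray
    rmse_val_mm: float
    rmse_opt_mm: float

    @property
    def percent_increase(self) -> float:
        return 100.0 * (self.rmse_val_mm - self.rmse_opt_mm) / self.rmse_opt_mm


@dataclass
class CrossValResult:
    folds: list[FoldResult]

    def __post_init__(self) -> None:
        for f in self.folds:
            if not np.isfinite(f.rmse_val_mm) or f.rmse_val_mm < 0:
                raise ValueError(f"invalid RMSE_val in fold {f.held_out}")

    @property
    def mean_percent_increase(self) -> float:
        return float(np.mean([f.percent_increase for f in self.folds]))


def cross_validate_five_fold(
    specimens: list[tuple[SpecimenModel | CompiledModel,
                          tuple[ForceTrace, MarkerTrajectories]]],
    results: list[IdentificationResult],
    ids: list[str] | None = None,
) -> CrossValResult:
    """Leave-one-specimen-out transfer of median parameters, five folds.

    For each fold the median of the other four specimens' identified
    vectors (all 16 parameters jointly) is installed in the held-out
    specimen's model and evaluated by forward simulation alone.
    """
    if len(specimens) != 5 or len(results) != 5:
        raise ValueError("five-fold cross-validation requires exactly 5 specimens "
                         "with completed identifications")
    ids = ids or [f"S{i + 1}" for i in range(5)]
    folds = []
    for i in range(5):
        others = [results[j].parameters for j in range(5) if j != i]
        transferred = aggregate_median_parameters(others)
        rmse_val = evaluate_with_fixed_parameters(specimens[i][0],
                                                  specimens[i][1], transferred)
        folds.append(FoldResult(
            held_out=ids[i], transferred=transferred,
            rmse_val_mm=rmse_val, rmse_opt_mm=results[i].rmse_opt_mm))
    return CrossValResult(folds=folds)
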