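"""Viscoelastic parameter identification by genetic algorithm.

Sixteen parameters — axial and shear stiffness and damping at each of the
four joints — are estimated by minimising the root-mean-square tracking
error between measured and simulated 3D marker positions over the 5 ms
impact window.  Genes are encoded in log10 space (the parameters span
several decades); the search uses tournament selection, blend (BLX-alpha)
crossover, per-gene Gaussian mutation and single-individual elitism, and
the literature initialisation is injected into the starting population so
the identified optimum can never be worse than the initial model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .dynamics import CompiledModel, compile_model, simulate
from .model import N_OPTIMISED_PARAMETERS, SpecimenModel
from .signals import ForceTrace, MarkerTrajectories

__all__ = [
    "GAConfig",
    "IdentificationResult",
    "tracking_rmse",
    "evaluate_objective",
    "identify_parameters",
    "PENALTY_RMSE_MM",
]

#: finite fitness assigned to diverging simulations inside the GA loop
PENALTY_RMSE_MM = 1.0e6


def tracking_rmse(measured: MarkerTrajectories,
                  simulated: MarkerTrajectories) -> float:
    """RMS Euclidean marker distance pooled over frames and markers, in mm."""
    if set(measured.names) != set(simulated.names):
        raise ValueError("marker sets differ between measured and simulated data")
    if measured.n_frames != simulated.n_frames:
        raise ValueError(
            f"frame count mismatch: {measured.n_frames} vs {simulated.n_frames}")
    sim = simulated.reordered(measured.names)
    diff = measured.positions - sim.positions
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=2)))) * 1e3


def _set_parameters(c: CompiledModel, p: np.ndarray) -> None:
    """Install a 16-vector into the compiled bushing arrays in place."""
    p = np.asarray(p, dtype=float)
    c.jk[:, 1] = p[0:4]    # axial stiffness
    c.jb[:, 1] = p[4:8]    # axial damping
    c.jk[:, 0] = p[8:12]   # shear stiffness
    c.jb[:, 0] = p[12:16]  # shear damping


def evaluate_objective(
    p: np.ndarray,
    model_or_compiled: SpecimenModel | CompiledModel,
    force_window: ForceTrace,
    measured: MarkerTrajectories,
    window_s: float | None = None,
) -> float:
    """Tracking RMSE (mm) of the model simulated with parameter vector ``p``.

    ``p`` replaces the axial/shear translational coefficients; lateral and
    rotational coefficients keep the model's current values.  Simulations
    that diverge (unstable parameter corners) return the finite penalty
    :data:`PENALTY_RMSE_MM` so population-based search can continue.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (N_OPTIMISED_PARAMETERS,):
        raise ValueError(f"parameter vector must have length {N_OPTIMISED_PARAMETERS}")
    if isinstance(model_or_compiled, CompiledModel):
        base = model_or_compiled
    else:
        base = compile_model(model_or_compiled)
    c = _copy_compiled(base)
    _set_parameters(c, p)
    if window_s is None:
        # the half-open force window [onset, onset + window) has exactly
        # window * fs samples, so its nominal length recovers the window
        window_s = force_window.n / force_window.fs
    out_times = measured.times - force_window.t0
    try:
        res = simulate(c, force_window, window_s=window_s,
                       output_times=out_times)
    except (FloatingPointError, RuntimeError):
        return PENALTY_RMSE_MM
    if res.markers.n_frames != measured.n_frames:
        return PENALTY_RMSE_MM
    return tracking_rmse(measured, res.markers)


def _copy_compiled(c: CompiledModel) -> CompiledModel:
    from dataclasses import replace
    return replace(c, jk=c.jk.copy(), jb=c.jb.copy())


@dataclass
class GAConfig:
    """Evolutionary search settings (genes in log10 space).

    Default bounds bracket both the quasi-static initialisation values and
    the full range of identified impact-specific parameters: axial
    stiffness 1e5-1e8 N/m, shear stiffness 1e3-1e6 N/m, dampings
    10-1e5 Ns/m.

    ``refine_evals`` budgets the covariance-adapting evolution-strategy
    refinement that follows the genetic stage (0 disables it); the
    refinement stops early once the tracking error falls below
    ``refine_target_mm``.  The genetic stage explores globally; the
    refinement stage follows the narrow, curved stiffness/damping valleys
    that fixed-operator genetic search cannot descend.
    """

    population_size: int = 100
    generations: int = 15
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    mutation_sigma: float = 0.1      # log10 units
    blend_alpha: float = 0.5
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0
    include_initialisation: bool = True
    axial_k_bounds: tuple[float, float] = (1.0e5, 1.0e8)
    shear_k_bounds: tuple[float, float] = (1.0e3, 1.0e6)
    damping_bounds: tuple[float, float] = (1.0e1, 1.0e5)
    refine_evals: int = 13000
    refine_target_mm: float = 1.0e-5

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population size must be at least 4")
        for lo, hi in (self.axial_k_bounds, self.shear_k_bounds,
                       self.damping_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive with lower < upper")

    def log_bounds(self) -> np.ndarray:
        """(16, 2) array of log10 gene bounds in parameter-vector order."""
        rows = ([self.axial_k_bounds] * 4 + [self.damping_bounds] * 4
                + [self.shear_k_bounds] * 4 + [self.damping_bounds] * 4)
        return np.log10(np.array(rows, dtype=float))


@dataclass
class IdentificationResult:
    """Best parameter vector and convergence record of one GA run."""

    parameters: np.ndarray
    rmse_opt_mm: float
    history_mm: list[float]
    seed: int
    n_evaluations: int
    config: GAConfig = field(repr=False, default_factory=GAConfig)

    def __post_init__(self) -> None:
        self.parameters = np.asarray(self.parameters, dtype=float)
        if self.rmse_opt_mm < 0:
            raise ValueError("RMSE cannot be negative")


def identify_parameters(
    model_or_compiled: SpecimenModel | CompiledModel,
    data: tuple[ForceTrace, MarkerTrajectories],
    ga: GAConfig | None = None,
) -> IdentificationResult:
    """Estimate the 16 viscoelastic parameters from one windowed trial.

    ``data`` is the (force window, marker window) pair cut at impact onset.
    The run is deterministic for a given :class:`GAConfig` seed.
    """
    ga = ga or GAConfig()
    force_window, measured = data
    if measured.n_frames < 2:
        raise ValueError("empty or single-frame marker window")
    if isinstance(model_or_compiled, CompiledModel):
        base = model_or_compiled
    else:
        base = compile_model(model_or_compiled)

    bounds = ga.log_bounds()
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(ga.seed)
    npop, ngene = ga.population_size, N_OPTIMISED_PARAMETERS

    def fitness(genes: np.ndarray) -> float:
        return evaluate_objective(10.0 ** genes, base, force_window, measured)

    pop = rng.uniform(lo, hi, size=(npop, ngene))
    if ga.include_initialisation:
        pop[0] = np.clip(np.log10(reference.initialisation_vector()), lo, hi)
    fit = np.array([fitness(g) for g in pop])
    n_evals = npop
    best_idx = int(np.argmin(fit))
    best_genes = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]

    def tournament() -> np.ndarray:
        idx = rng.integers(0, npop, ga.tournament_size)
        return pop[idx[np.argmin(fit[idx])]]

    for _ in range(ga.generations):
        order = np.argsort(fit)
        elites = pop[order[:ga.elitism]].copy()
        elite_fit = fit[order[:ga.elitism]].copy()
        children = np.empty((npop - ga.elitism, ngene))
        for i in range(children.shape[0]):
            p1, p2 = tournament(), tournament()
            if rng.uniform() < ga.crossover_rate:
                gmin = np.minimum(p1, p2)
                gmax = np.maximum(p1, p2)
                d = gmax - gmin
                child = rng.uniform(gmin - ga.blend_alpha * d,
                                    gmax + ga.blend_alpha * d)
            else:
                child = p1.copy()
            mutate = rng.uniform(size=ngene) < ga.mutation_rate
            child = child + mutate * rng.normal(0.0, ga.mutation_sigma, ngene)
            children[i] = np.clip(child, lo, hi)
        child_fit = np.array([fitness(g) for g in children])
        n_evals += children.shape[0]
        pop = np.vstack([elites, children])
        fit = np.concatenate([elite_fit, child_fit])
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_genes = pop[gen_best].copy()
        history.append(best_fit)

    if best_fit >= PENALTY_RMSE_MM:
        raise RuntimeError(
            "every evaluated parameter vector diverged; check the model and data")

    # Evolution-strategy refinement, fully seeded: a broad full-space basin
    # search followed by a deep polish.  The objective has long, curved,
    # badly conditioned valleys (stiffness/damping trade-offs across
    # joints) on whose floors fixed-operator genetic search stalls;
    # covariance adaptation follows them to the optimum.
    if ga.refine_evals > 0:
        from ._cma import cma_es
        ss = np.random.SeedSequence(ga.seed)
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2)]
        stages = [
            (0.5, 32, int(0.4 * ga.refine_evals), seeds[0]),   # basin search
            (0.12, 16, ga.refine_evals - int(0.4 * ga.refine_evals),
             seeds[1]),                                        # polish
        ]
        genes = best_genes
        for sigma0, lam, budget, seed in stages:
            if budget <= 0 or best_fit <= ga.refine_target_mm:
                break
            genes, fit_s, used = cma_es(
                fitness, genes, sigma0, lo, hi, budget, seed=seed,
                popsize=lam, f_target=ga.refine_target_mm,
                callback=lambda bf: history.append(min(bf, history[-1])))
            n_evals += used
            if fit_s < best_fit:
                best_fit = float(fit_s)
                best_genes = genes.copy()

    return IdentificationResult(
        parameters=10.0 ** best_genes,
        rmse_opt_mm=best_fit,
        history_mm=history,
        seed=ga.seed,
        n_evaluations=n_evals,
        config=ga,
    )
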