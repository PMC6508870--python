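"""Covariance matrix adaptation evolution strategy (CMA-ES), bound-clipped.

Package-authored implementation of the standard (mu/mu_w, lambda) CMA-ES
with cumulative step-size adaptation and rank-one/rank-mu covariance
updates.  Used as the refinement stage of the parameter identification:
the tracking-error landscape has long, curved, badly conditioned valleys
(stiffness/damping trade-offs across joints) in which fixed-operator
genetic search stalls; covariance adaptation follows them to the optimum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cma_es"]


def cma_es(
    f,
    x0: np.ndarray,
    sigma0: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    max_evals: int,
    seed: int,
    popsize: int | None = None,
    f_target: float = -np.inf,
    callback=None,
):
    """Minimise ``f`` from ``x0`` with step size ``sigma0``.

    Candidates are clipped to the box ``[bounds_lo, bounds_hi]`` before
    evaluation.  Stops on the evaluation budget, on reaching ``f_target``
    or on step-size collapse.  Returns ``(best_x, best_f, n_evals)``;
    ``callback(best_f)`` runs once per generation (used to record
    convergence histories).
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w**2)
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    rng = np.random.default_rng(seed)
    xmean = x0.copy()
    sigma = float(sigma0)
    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    invsqrtC = np.eye(n)
    eigeneval = 0

    best_x = np.clip(x0, bounds_lo, bounds_hi)
    best_f = f(best_x)
    n_evals = 1

    while n_evals < max_evals and best_f > f_target and sigma > 1e-12:
        arz = rng.standard_normal((lam, n))
        arx = np.clip(xmean + sigma * arz @ (B * D).T, bounds_lo, bounds_hi)
        fits = np.array([f(x) for x in arx])
        n_evals += lam
        idx = np.argsort(fits)
        if fits[idx[0]] < best_f:
            best_f = float(fits[idx[0]])
            best_x = arx[idx[0]].copy()

        xold = xmean
        xmean = w @ arx[idx[:mu]]
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (
            invsqrtC @ (xmean - xold)) / sigma
        hsig = (np.linalg.norm(ps)
                / np.sqrt(1 - (1 - cs) ** (2 * n_evals / lam)) / chiN
                < 1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * (
            xmean - xold) / sigma
        artmp = (arx[idx[:mu]] - xold) / sigma
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
             + cmu * artmp.T @ (w[:, None] * artmp))
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chiN - 1))

        if n_evals - eigeneval > lam / (c1 + cmu) / n / 10:
            eigeneval = n_evals
            C = np.triu(C) + np.triu(C, 1).T
            eigvals, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(eigvals, 1e-30))
            invsqrtC = B @ np.diag(1.0 / D) @ B.T
        if callback is not None:
            callback(best_f)
    return best_x, best_f, n_evals
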