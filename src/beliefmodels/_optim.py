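"""Seeded stochastic optimization and finite-difference curvature.

Objective surfaces here (response log-likelihoods of sequential filters)
are smooth almost everywhere but can be multi-modal and contain regions
where the filter recursion is invalid (objective ``-inf``).  The maximizer
therefore uses a seeded multi-start simplex search: one start at the
supplied initial point plus randomized restarts, followed by a tight
polishing run from the incumbent.  ``-inf`` candidates are simply ranked
worst, steering the simplex back into the valid region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["OptimizerConfig", "OptimResult", "maximize", "hessian", "make_pd"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Budget and scale of the stochastic search.

    max_evals : total objective-evaluation budget across all starts.
    restarts : number of randomized restarts in addition to the first start.
    sigma0 : standard deviation of the Gaussian restart perturbations
        (transformed-parameter units).
    """

    max_evals: int = 5000
    restarts: int = 3
    sigma0: float = 1.0
    xatol: float = 1e-6
    fatol: float = 1e-9


@dataclass
class OptimResult:
    x: np.ndarray
    fun: float  # maximized objective value
    n_evals: int
    converged: bool
    seed: int


def _finite_start(f, x0, rng, sigma0):
    """A start point with finite objective (resampled around x0 if needed)."""
    x = np.asarray(x0, dtype=float)
    for _ in range(100):
        if np.isfinite(f(x)):
            return x
        x = np.asarray(x0, dtype=float) + sigma0 * rng.standard_normal(len(x0))
    raise RuntimeError("could not find a start point with finite objective")


def maximize(
    f,
    x0: np.ndarray,
    config: OptimizerConfig | None = None,
    seed: int = 0,
) -> OptimResult:
    """Maximize ``f`` by seeded multi-start Nelder-Mead with polishing."""
    config = config or OptimizerConfig()
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    n_starts = 1 + max(0, config.restarts)
    # reserve ~15% of the budget for the polishing run
    per_start = max(50, int(0.85 * config.max_evals / n_starts))

    evals = 0

    def neg(x):
        nonlocal evals
        evals += 1
        v = f(x)
        return -v if np.isfinite(v) else math.inf

    best_x, best_f = None, -math.inf
    converged = False
    for i in range(n_starts):
        start = x0 if i == 0 else x0 + config.sigma0 * rng.standard_normal(len(x0))
        try:
            start = _finite_start(f, start, rng, config.sigma0)
        except RuntimeError:
            continue
        res = optimize.minimize(
            neg,
            start,
            method="Nelder-Mead",
            options={
                "maxfev": per_start,
                "xatol": 10 * config.xatol,
                "fatol": 10 * config.fatol,
            },
        )
        if -res.fun > best_f:
            best_f, best_x = -res.fun, res.x
            converged = bool(res.success)

    if best_x is None:
        raise RuntimeError("optimization failed: no finite objective value found")

    polish_budget = max(100, config.max_evals - evals)
    res = optimize.minimize(
        neg,
        best_x,
        method="Nelder-Mead",
        options={"maxfev": polish_budget, "xatol": config.xatol, "fatol": config.fatol},
    )
    if -res.fun > best_f:
        best_f, best_x = -res.fun, res.x
        converged = bool(res.success)

    # gradient polish; -inf regions appear as a large finite penalty so the
    # line search can back off instead of failing
    def neg_capped(x):
        nonlocal evals
        evals += 1
        v = f(x)
        return -v if np.isfinite(v) else 1e15

    res = optimize.minimize(
        neg_capped, best_x, method="L-BFGS-B", options={"maxfun": 400}
    )
    if np.isfinite(res.fun) and -res.fun > best_f:
        best_f, best_x = -res.fun, res.x
        converged = True
    return OptimResult(x=np.asarray(best_x), fun=float(best_f), n_evals=evals,
                       converged=converged, seed=seed)


def _pair_term(f, x, i, j, hi, hj):
    """Central mixed second difference with step shrinking on -inf regions."""
    for _ in range(8):
        if i == j:
            e = np.zeros_like(x)
            e[i] = hi
            vals = (f(x + e), f(x), f(x - e))
            if all(np.isfinite(v) for v in vals):
                return (vals[0] - 2.0 * vals[1] + vals[2]) / hi**2
        else:
            ei = np.zeros_like(x)
            ej = np.zeros_like(x)
            ei[i] = hi
            ej[j] = hj
            vals = (f(x + ei + ej), f(x + ei - ej), f(x - ei + ej), f(x - ei - ej))
            if all(np.isfinite(v) for v in vals):
                return (vals[0] - vals[1] - vals[2] + vals[3]) / (4.0 * hi * hj)
        hi *= 0.5
        hj *= 0.5
    return math.nan


def hessian(f, x: np.ndarray, rel_step: float = 1e-3) -> np.ndarray:
    """Symmetric Hessian of ``f`` at ``x`` by central finite differences.

    Per-coordinate steps scale with the coordinate magnitude; steps shrink
    automatically where the objective is not finite.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        H[i, i] = _pair_term(f, x, i, i, h[i], h[i])
        for j in range(i + 1, n):
            H[i, j] = H[j, i] = _pair_term(f, x, i, j, h[i], h[j])
    return H


def stable_hessian(
    f, x: np.ndarray, steps: tuple[float, ...] = (1e-3, 0.05, 0.2, 0.5)
) -> tuple[np.ndarray, float, bool]:
    """Hessian of a log-density at its mode, robust to local roughness.

    Sequential-filter likelihoods can be locally chaotic (trajectories are
    extremely sensitive to parameters where the volatility update nears
    blow-up), making the fine-step Hessian at a maximum indefinite — pure
    noise.  Steps are coarsened until the negative Hessian is positive
    definite, measuring the curvature of the posterior bulk instead of the
    micro-structure.  Returns ``(H, step_used, is_pd)``; if no scale yields
    a definite matrix the finest-step Hessian is returned with
    ``is_pd=False`` (the caller is expected to ridge-repair it).
    """
    last = None
    for step in steps:
        H = hessian(f, x, rel_step=step)
        last = (H, step)
        ok = np.all(np.isfinite(H)) and np.linalg.eigvalsh(
            -0.5 * (H + H.T)
        ).min() > 0
        if ok:
            return H, step, True
    # chaotic at every scale: the coarsest step carries the least
    # finite-difference noise
    return last[0], last[1], False


def make_pd(A: np.ndarray, min_eig: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Symmetrize and eigenvalue-floor a matrix to be positive definite.

    Eigenvalues below the floor are raised to it (flooring, not a ridge
    shift, so well-determined directions are untouched).  The floor also
    scales with the largest curvature so the result stays invertible in
    floating point when curvatures span many decades.  Returns the repaired
    matrix and a flag saying whether anything changed.
    """
    A = np.asarray(A, dtype=float)
    repaired = False
    if not np.all(np.isfinite(A)):
        A = np.where(np.isfinite(A), A, 0.0)
        repaired = True
    A = 0.5 * (A + A.T)
    lam, V = np.linalg.eigh(A)
    floor = max(min_eig, 1e-10 * float(np.abs(lam).max()))
    if lam.min() < floor:
        lam = np.maximum(lam, floor)
        A = (V * lam) @ V.T
        A = 0.5 * (A + A.T)
        repaired = True
    return A, repaired


def pd_inverse(A: np.ndarray) -> np.ndarray:
    """Inverse of a (repaired) symmetric PD matrix via eigendecomposition.

    Guarantees a symmetric positive-definite result even when ``A`` is very
    ill-conditioned, unlike a plain matrix inverse.
    """
    lam, V = np.linalg.eigh(np.asarray(A, dtype=float))
    lam = np.maximum(lam, 1e-300)
    return (V / lam) @ V.T
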