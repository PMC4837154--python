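"""Analyses: model performance, group model selection, recovery diagnostics,
and trajectory-correlation comparisons.

``group_bms`` implements the standard random-effects Bayesian model
selection for group studies (variational Dirichlet scheme with a uniform
Dirichlet(1, ..., 1) prior); for two models the exceedance probability has
a closed form through the regularized incomplete beta function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .environments import StimulusBlock
from .filters import BeliefTrajectory, CPMParams, HGFParams, run_filter
from .inversion import FitResult
from .responses import BehavioralDataset
from .transforms import PARAM_ORDER, transform

__all__ = [
    "GroupComparisonResult",
    "ConfusionMatrix",
    "RecoveryDiagnostics",
    "performance_rmse",
    "group_bms",
    "confusion_experiment",
    "recovery_diagnostics",
    "trajectory_correlation",
    "exceedance_vs_median",
]

#: Trajectory variables compared between generating and inferred filters.
CORRELATION_VARIABLES = ("mu1", "alpha1", "eps1", "mu2", "eps2")


@dataclass
class GroupComparisonResult:
    """Random-effects model comparison for one group of agents."""

    alpha: np.ndarray  # Dirichlet posterior counts
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    winner: int

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance_probabilities": self.exceedance_probabilities.tolist(),
            "winner": int(self.winner),
        }


@dataclass
class ConfusionMatrix:
    """Rows: true generating model; columns: inferred (winning) model."""

    proportions: np.ndarray  # 2x2, rows sum to 1
    counts: np.ndarray
    labels: tuple[str, ...]
    condition: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions,
            index=[f"true_{l}" for l in self.labels],
            columns=[f"inferred_{l}" for l in self.labels],
        )


@dataclass
class RecoveryDiagnostics:
    """Per-parameter estimator quality across simulated agents."""

    param_names: tuple[str, ...]
    rmse: np.ndarray  # transformed space
    coverage: np.ndarray  # fraction of truths within +-2 std
    n_agents: int
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.param_names, "rmse": self.rmse, "coverage": self.coverage}
        )


def performance_rmse(trajectory: BeliefTrajectory, block: StimulusBlock) -> float:
    """Root-mean-square error of the posterior expectation vs the hidden state."""
    if trajectory.T != block.T:
        raise ValueError("trajectory and block must have equal length")
    return float(np.sqrt(np.mean((trajectory.mu1 - block.hidden1) ** 2)))


def group_bms(log_evidence_matrix: np.ndarray, max_iter: int = 500,
              tol: float = 1e-10) -> GroupComparisonResult:
    """Random-effects Bayesian model selection over a group of agents.

    ``log_evidence_matrix`` has one row per agent and one column per model.
    Returns the Dirichlet posterior over model frequencies, its mean, and
    the exceedance probabilities (closed form for two models).
    """
    L = np.asarray(log_evidence_matrix, dtype=float)
    if L.ndim != 2 or L.shape[0] < 1:
        raise ValueError("expected a k x m matrix of log evidences")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    k, m = L.shape

    alpha0 = np.ones(m)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        # per-agent posterior model assignment under the current Dirichlet
        log_u = L + special.digamma(alpha) - special.digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        beta = u.sum(axis=0)
        alpha_new = alpha0 + beta
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    if m == 2:
        # P(r_1 > r_2) = P(r_1 > 1/2), r_1 ~ Beta(alpha_1, alpha_2)
        p1 = float(stats.beta.sf(0.5, alpha[0], alpha[1]))
        exceedance = np.array([p1, 1.0 - p1])
    else:
        rng = np.random.default_rng(0)
        draws = rng.dirichlet(alpha, size=200_000)
        exceedance = np.bincount(np.argmax(draws, axis=1), minlength=m) / draws.shape[0]
    return GroupComparisonResult(
        alpha=alpha,
        expected_frequencies=expected,
        exceedance_probabilities=exceedance,
        winner=int(np.argmax(exceedance)),
    )


def confusion_experiment(
    pool: dict[str, np.ndarray],
    k: int = 20,
    n_groups: int = 1000,
    seed: int = 0,
    labels: tuple[str, ...] = ("hgf", "cpm"),
    condition: dict | None = None,
) -> ConfusionMatrix:
    """Resampled group-level model-recovery experiment.

    ``pool[true_model]`` is an ``n_agents x 2`` matrix of per-agent log
    evidences (columns ordered as ``labels``) for agents whose behavior was
    generated by ``true_model``.  Groups of ``k`` agents are resampled with
    replacement; each group is classified by :func:`group_bms` (winner =
    model with exceedance probability > 1/2).
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for row, true_model in enumerate(labels):
        evid = np.asarray(pool[true_model], dtype=float)
        if evid.shape[0] < k:
            raise ValueError(
                f"pool for {true_model!r} has {evid.shape[0]} agents, need >= {k}"
            )
        for _ in range(n_groups):
            idx = rng.integers(0, evid.shape[0], size=k)
            result = group_bms(evid[idx])
            counts[row, result.winner] += 1
    proportions = counts / counts.sum(axis=1, keepdims=True)
    return ConfusionMatrix(
        proportions=proportions, counts=counts, labels=labels,
        condition=condition or {},
    )


def recovery_diagnostics(
    fits: list[FitResult], truths: list[dict[str, float]]
) -> RecoveryDiagnostics:
    """Per-parameter RMSE and +-2 std coverage of fits against known truths.

    Truths are natural-scale parameter dicts; both RMSE and coverage are
    computed in the transformed space in which the fits live.  Fits without
    a usable covariance are excluded and counted.
    """
    if len(fits) != len(truths):
        raise ValueError("need one truth per fit")
    names = fits[0].param_names
    errors, hits = [], []
    n_excluded = 0
    for fit, truth in zip(fits, truths):
        rho_true = transform(truth, fit.model)
        if fit.covariance is None or not np.all(np.isfinite(fit.covariance)):
            n_excluded += 1
            continue
        err = fit.rho_star - rho_true
        errors.append(err)
        hits.append(np.abs(err) <= 2.0 * fit.std)
    errors = np.asarray(errors)
    hits = np.asarray(hits, dtype=float)
    return RecoveryDiagnostics(
        param_names=names,
        rmse=np.sqrt(np.mean(errors**2, axis=0)),
        coverage=hits.mean(axis=0),
        n_agents=len(errors),
        n_excluded=n_excluded,
    )


def _traj_vars(traj: BeliefTrajectory) -> dict[str, np.ndarray]:
    return {v: getattr(traj, v) for v in CORRELATION_VARIABLES}


def trajectory_correlation(
    dataset: BehavioralDataset,
    generating_trajectory: BeliefTrajectory,
    fitted_params: dict[str, float],
    inference_model: str,
) -> dict[str, float]:
    """Pearson correlations between generating and inferred belief trajectories.

    The inference model's filter is run at the fitted (natural-scale)
    perceptual parameters on the same stimuli; each internal variable is
    correlated with the generating trajectory's corresponding variable.
    The first trial is skipped (the level-2 prediction error is not defined
    before the first update for the CPM).  Zero-variance trajectories give
    NaN.
    """
    perceptual = {
        k: v for k, v in fitted_params.items()
        if k in PARAM_ORDER[inference_model] and k != "sigma_r"
    }
    params = (
        HGFParams(**perceptual) if inference_model == "hgf" else CPMParams(**perceptual)
    )
    inferred = run_filter(
        inference_model, params, dataset.stimuli.observations
    )
    out = {}
    gen = _traj_vars(generating_trajectory)
    inf_vars = _traj_vars(inferred)
    for v in CORRELATION_VARIABLES:
        a, b = gen[v][1:], inf_vars[v][1:]
        if np.std(a) == 0 or np.std(b) == 0:
            out[v] = math.nan
        else:
            out[v] = float(stats.pearsonr(a, b).statistic)
    return out


def exceedance_vs_median(corr_mle: np.ndarray, corr_bila: np.ndarray) -> float:
    """Fraction of MLE-based correlations above the BI-LA median correlation."""
    corr_mle = np.asarray(corr_mle, dtype=float)
    corr_bila = np.asarray(corr_bila, dtype=float)
    corr_mle = corr_mle[np.isfinite(corr_mle)]
    corr_bila = corr_bila[np.isfinite(corr_bila)]
    if corr_mle.size == 0 or corr_bila.size == 0:
        raise ValueError("correlation samples must be non-empty")
    return float(np.mean(corr_mle > np.median(corr_bila)))
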