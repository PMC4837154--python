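"""Behavioral-model inversion: Bayesian-Laplace and MLE-BIC fits.

Given one agent's stimuli and responses, both schemes search the
seven-dimensional transformed parameter space (see
:mod:`beliefmodels.transforms`):

* **BI-LA** maximizes the log-joint ``ln p(R | rho, O, m) + ln p(rho)``;
  the posterior is approximated by a Gaussian centered at the mode with
  covariance ``S = (-Hessian)^-1`` and the log model evidence by the
  Laplace value ``ln p(R, rho* | O, m) + 1/2 ln |2 pi S|``.

* **MLE** maximizes the log-likelihood alone and approximates the log
  evidence by the BIC value ``ln p(R | rho*, O, m) - (d/2) ln T``; the
  estimate's uncertainty is the inverse negative Hessian of the
  log-likelihood.

Parameter sets under which the filter recursion is invalid score ``-inf``
and are thereby rejected by the search.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import _optim
from .filters import CPMParams, HGFParams, run_filter
from .responses import BehavioralDataset, response_loglik
from .transforms import PARAM_ORDER, PriorSpec, default_prior, log_prior, untransform

__all__ = [
    "FitResult",
    "make_loglik",
    "fit_bi_la",
    "fit_mle",
    "BayesianLaplaceEstimator",
    "MLEEstimator",
]


@dataclass
class FitResult:
    """Outcome of one model fit to one agent's data.

    ``rho_star`` and ``covariance`` live in the transformed parameter space
    (order :data:`~beliefmodels.transforms.PARAM_ORDER`).  ``log_evidence``
    is the Laplace value for BI-LA and the BIC value for MLE.
    """

    method: str  # "bi-la" | "mle"
    model: str  # "hgf" | "cpm"
    rho_star: np.ndarray
    covariance: np.ndarray
    log_evidence: float
    loglik: float
    log_joint: float | None
    d: int
    T: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        """Fitted parameters on the natural scale."""
        return untransform(self.rho_star, self.model)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_ORDER[self.model]

    @property
    def std(self) -> np.ndarray:
        """Per-parameter standard deviations (transformed space)."""
        return np.sqrt(np.diag(self.covariance))

    def to_json(self, path: str) -> None:
        payload = {
            "method": self.method,
            "model": self.model,
            "rho_star": self.rho_star.tolist(),
            "covariance": self.covariance.tolist(),
            "log_evidence": self.log_evidence,
            "loglik": self.loglik,
            "log_joint": self.log_joint,
            "d": self.d,
            "T": self.T,
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "FitResult":
        with open(path) as fh:
            payload = json.load(fh)
        payload["rho_star"] = np.asarray(payload["rho_star"])
        payload["covariance"] = np.asarray(payload["covariance"])
        return cls(**payload)


def _perceptual_params(model: str, nat: dict[str, float]):
    if model == "hgf":
        return HGFParams(**{k: v for k, v in nat.items() if k != "sigma_r"})
    return CPMParams(**{k: v for k, v in nat.items() if k != "sigma_r"})


def make_loglik(model: str, stimuli: np.ndarray, responses: np.ndarray):
    """Response log-likelihood as a function of the transformed vector."""
    stimuli = np.asarray(stimuli, dtype=float)
    responses = np.asarray(responses, dtype=float)

    def loglik(rho: np.ndarray) -> float:
        nat = untransform(rho, model)
        try:
            params = _perceptual_params(model, nat)
            return response_loglik(
                responses, model, params, nat["sigma_r"], stimuli
            )
        except (ValueError, OverflowError):
            return -math.inf

    return loglik


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, BehavioralDataset):
        return dataset.stimuli.observations, dataset.responses
    stimuli, responses = dataset
    return np.asarray(stimuli, float), np.asarray(responses, float)


def fit_bi_la(
    dataset,
    model: str,
    prior: PriorSpec | None = None,
    optimizer_config: _optim.OptimizerConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Bayesian inversion with the Laplace approximation.

    ``dataset`` is a :class:`~beliefmodels.responses.BehavioralDataset` or a
    ``(stimuli, responses)`` pair.
    """
    model = model.lower()
    prior = prior or default_prior()
    stimuli, responses = _as_arrays(dataset)
    loglik = make_loglik(model, stimuli, responses)

    def log_joint(rho):
        ll = loglik(rho)
        return ll + log_prior(rho, model, prior) if np.isfinite(ll) else -math.inf

    names = PARAM_ORDER[model]
    x0 = prior.mean_vector(names)
    opt = _optim.maximize(log_joint, x0, optimizer_config, seed=seed)

    H, h_step, h_pd = _optim.stable_hessian(log_joint, opt.x)
    if h_pd:
        neg_h, repaired = _optim.make_pd(-H)
    else:
        # chaotic mode: measured curvature is noise at every scale, so bound
        # it below by the prior precision (the joint's curvature is the prior
        # precision plus the likelihood curvature at any smooth mode)
        min_prior_prec = 1.0 / float(np.max(prior.var_vector(PARAM_ORDER[model])))
        neg_h, repaired = _optim.make_pd(-H, min_eig=min_prior_prec)
    S = _optim.pd_inverse(neg_h)
    d = len(names)
    # ln|2 pi S| computed from -H directly: stays finite for extreme curvature
    _, logdet_negh = np.linalg.slogdet(neg_h)
    log_evidence = opt.fun + 0.5 * (d * math.log(2.0 * math.pi) - logdet_negh)
    return FitResult(
        method="bi-la",
        model=model,
        rho_star=opt.x,
        covariance=S,
        log_evidence=float(log_evidence),
        loglik=float(loglik(opt.x)),
        log_joint=float(opt.fun),
        d=d,
        T=len(responses),
        diagnostics={
            "n_evals": opt.n_evals,
            "converged": opt.converged,
            "pd_repaired": repaired,
            "hessian_step": h_step,
            "seed": seed,
        },
    )


def fit_mle(
    dataset,
    model: str,
    optimizer_config: _optim.OptimizerConfig | None = None,
    seed: int = 0,
    prior: PriorSpec | None = None,
) -> FitResult:
    """Maximum-likelihood fit with the BIC evidence approximation.

    The search runs in the same transformed space as the Bayesian fit (the
    likelihood is invariant to the reparametrization) and starts from the
    prior mean, but no prior enters the objective.
    """
    model = model.lower()
    prior = prior or default_prior()
    stimuli, responses = _as_arrays(dataset)
    loglik = make_loglik(model, stimuli, responses)

    names = PARAM_ORDER[model]
    x0 = prior.mean_vector(names)
    opt = _optim.maximize(loglik, x0, optimizer_config, seed=seed)

    H, h_step, h_pd = _optim.stable_hessian(loglik, opt.x)
    neg_h, repaired = _optim.make_pd(-H)
    S = _optim.pd_inverse(neg_h)
    d = len(names)
    T = len(responses)
    log_evidence = opt.fun - 0.5 * d * math.log(T)
    return FitResult(
        method="mle",
        model=model,
        rho_star=opt.x,
        covariance=S,
        log_evidence=float(log_evidence),
        loglik=float(opt.fun),
        log_joint=None,
        d=d,
        T=T,
        diagnostics={
            "n_evals": opt.n_evals,
            "converged": opt.converged,
            "pd_repaired": repaired,
            "hessian_step": h_step,
            "seed": seed,
        },
    )


class _InversionEstimator(BaseEstimator, RegressorMixin):
    """Shared fit/predict machinery of the two inversion estimators."""

    method: str = ""

    def __init__(self, model="hgf", max_evals=5000, restarts=3, sigma0=1.0, seed=0):
        self.model = model
        self.max_evals = max_evals
        self.restarts = restarts
        self.sigma0 = sigma0
        self.seed = seed

    def _config(self) -> _optim.OptimizerConfig:
        return _optim.OptimizerConfig(
            max_evals=self.max_evals, restarts=self.restarts, sigma0=self.sigma0
        )

    def fit(self, X, y):
        """Fit the behavioral model to stimuli ``X`` and responses ``y``."""
        X = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if self.method == "bi-la":
            result = fit_bi_la(
                (X, y), self.model, optimizer_config=self._config(), seed=self.seed
            )
        else:
            result = fit_mle(
                (X, y), self.model, optimizer_config=self._config(), seed=self.seed
            )
        self.result_ = result
        self.rho_ = result.rho_star
        self.params_ = result.params
        self.covariance_ = result.covariance
        self.log_evidence_ = result.log_evidence
        return self

    def predict(self, X):
        """Mean response (level-1 expectation trajectory) at the fitted mode."""
        nat = self.params_
        params = _perceptual_params(self.model, nat)
        return run_filter(self.model, params, np.asarray(X, float)).mu1


class BayesianLaplaceEstimator(_InversionEstimator):
    """Bayesian inversion (Laplace approximation) as an sklearn estimator."""

    method = "bi-la"


class MLEEstimator(_InversionEstimator):
    """Maximum-likelihood inversion with BIC evidence as an sklearn estimator."""

    method = "mle"
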