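"""Sequential perceptual filters: two-level HGF and variational change-point model.

Both filters map a stimulus stream ``o_1..o_T`` to per-trial posterior
beliefs about the hidden state via delta-rule updates with adaptive
learning rates:

* The **hierarchical Gaussian filter (HGF)** tracks the hidden state at
  level 1 and its log-volatility at level 2; the level-1 learning rate
  grows with the currently estimated volatility ``exp(mu2)``.  Its
  per-trial surprise is the negative variational free energy, a lower
  bound on the marginal log-likelihood of the observation.

* The **change-point model (CPM)** tracks the hidden state of a switching
  process: on every trial it computes the posterior change-point
  probability ``Omega_t`` from a two-component predictive mixture and uses
  it to discount the accumulated precision, transiently raising the
  learning rate after a likely change.  Its per-trial surprise is the
  exact negative marginal log-likelihood of the mixture.

All Gaussian widths are variances.  The numerically hot recursions are
numba-compiled; the single-step functions call the same kernels so the two
code paths cannot diverge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "HGFParams",
    "CPMParams",
    "BeliefState",
    "TrialInternals",
    "BeliefTrajectory",
    "InvalidUpdateError",
    "hgf_step",
    "cpm_step",
    "cpm_change_probability",
    "hgf_trial_free_energy",
    "cpm_trial_surprise",
    "run_filter",
    "HGFFilter",
    "CPMFilter",
]

_LOG2PI = math.log(2.0 * math.pi)
_OMEGA_CLAMP = 1e-12  # keeps the logit of the change probability finite
_LOGIT_MAX = math.log((1.0 - _OMEGA_CLAMP) / _OMEGA_CLAMP)


class InvalidUpdateError(RuntimeError):
    """The filter recursion produced an invalid (non-positive) precision."""

    def __init__(self, trial: int, message: str | None = None):
        self.trial = trial
        super().__init__(message or f"invalid filter update at trial {trial}")


@dataclass(frozen=True)
class HGFParams:
    """Perceptual parameters of the two-level HGF.

    mu0_1, sigma0_1 : prior expectation / uncertainty of the hidden state.
    s : believed observation-noise variance.
    mu0_2, sigma0_2 : prior expectation / uncertainty of the log-volatility.
    eta : believed diffusion variance of the log-volatility walk.
    """

    mu0_1: float = 0.0
    sigma0_1: float = 1.0
    s: float = 1.0
    mu0_2: float = 0.0
    sigma0_2: float = 1.0
    eta: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sigma0_1", "s", "sigma0_2", "eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not (np.isfinite(self.mu0_1) and np.isfinite(self.mu0_2)):
            raise ValueError("prior expectations must be finite")


@dataclass(frozen=True)
class CPMParams:
    """Perceptual parameters of the change-point model.

    mu0_1, sigma0_1 : prior expectation / uncertainty of the hidden state.
    s : believed observation-noise variance.
    w1 : believed diffusion variance of the stable random walk.
    w2 : believed variance of the post-change redraw distribution.
    h : believed per-trial change (hazard) probability.
    a : positive scaling constant of the logit reparametrization of the
        change probability (arbitrary; correlation analyses are invariant
        to it).
    """

    mu0_1: float = 0.0
    sigma0_1: float = 1.0
    s: float = 1.0
    w1: float = 0.01
    w2: float = 10.0
    h: float = 0.1
    a: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma0_1", "s", "w1", "w2", "a"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if not (0.0 <= self.h <= 1.0) or not np.isfinite(self.h):
            raise ValueError(f"h must lie in [0, 1], got {self.h!r}")
        if not np.isfinite(self.mu0_1):
            raise ValueError("mu0_1 must be finite")

    @property
    def mu0_2(self) -> float:
        """Initial logit-scale change probability: the logit of the hazard."""
        h = min(max(self.h, _OMEGA_CLAMP), 1.0 - _OMEGA_CLAMP)
        return math.log(h / (1.0 - h)) / self.a


@dataclass(frozen=True)
class BeliefState:
    """Posterior expectation/uncertainty at both levels (sigma2 NaN for CPM)."""

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float = math.nan


@dataclass(frozen=True)
class TrialInternals:
    """Per-trial internal variables of one filter update.

    HGF-only fields (delta2, w2t, r2t) and the CPM-only field (omega) are
    NaN for the other model.  ``surprise`` is the per-trial negative
    (approximate) marginal log-likelihood.
    """

    alpha1: float
    eps1: float
    eps2: float
    mu2: float
    surprise: float
    delta2: float = math.nan
    w2t: float = math.nan
    r2t: float = math.nan
    omega: float = math.nan


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _hgf_fe(o, mu1_prev, s1_prev, mu2_prev, s2_prev, mu1, s1, mu2, s2, s, eta):
    """Per-trial variational free energy of the HGF update."""
    d1 = s1_prev + math.exp(mu2)
    d2 = s2_prev + eta
    return (
        -0.5 * math.log(s)
        - 0.5 * (s1 + (o - mu1) ** 2) / s
        - 0.5 * math.log(d1)
        - 0.5 * (s1 + (mu1 - mu1_prev) ** 2) / d1
        - 0.5 * math.log(d2)
        - 0.5 * (s2 + (mu2 - mu2_prev) ** 2) / d2
        - 0.5 * _LOG2PI
        + 1.0
        + 0.5 * math.log(s1 * s2)
    )


@njit(cache=False)
def _hgf_kernel(obs, mu1_0, s1_0, mu2_0, s2_0, s, eta):
    """Run the HGF recursion.

    The level-2 Newton step can produce a non-positive posterior precision
    for extreme inputs; on such trials the level-2 belief falls back to its
    prior-predictive value (sigma2 += eta, mu2 unchanged).  Returns the
    trajectories, the number of fallback trials, and the 1-based index of
    the first fallback (0 if none).
    """
    T = obs.shape[0]
    mu1 = np.empty(T)
    sigma1 = np.empty(T)
    mu2 = np.empty(T)
    sigma2 = np.empty(T)
    alpha1 = np.empty(T)
    eps1 = np.empty(T)
    eps2 = np.empty(T)
    delta2 = np.empty(T)
    w2t = np.empty(T)
    r2t = np.empty(T)
    surprise = np.empty(T)

    m1, v1, m2, v2 = mu1_0, s1_0, mu2_0, s2_0
    n_fallback = 0
    first_fallback = 0
    for t in range(T):
        o = obs[t]
        ev = math.exp(m2)
        denom = v1 + ev
        v1_new = 1.0 / (1.0 / s + 1.0 / denom)
        a1 = v1_new / s
        e1 = a1 * (o - m1)
        m1_new = m1 + e1

        d2 = (v1_new + e1 * e1) / denom - 1.0
        w2 = ev / denom
        r2 = (ev - v1) / denom
        prec2 = 1.0 / (v2 + eta) + 0.5 * w2 * (w2 + r2 * d2)
        if prec2 > 0.0 and np.isfinite(prec2):
            v2_new = 1.0 / prec2
            a2 = 0.5 * v2_new * w2
            e2 = a2 * d2
            m2_new = m2 + e2
        else:
            v2_new = v2 + eta
            e2 = 0.0
            m2_new = m2
            n_fallback += 1
            if first_fallback == 0:
                first_fallback = t + 1

        surprise[t] = -_hgf_fe(
            o, m1, v1, m2, v2, m1_new, v1_new, m2_new, v2_new, s, eta
        )
        mu1[t] = m1_new
        sigma1[t] = v1_new
        mu2[t] = m2_new
        sigma2[t] = v2_new
        alpha1[t] = a1
        eps1[t] = e1
        eps2[t] = e2
        delta2[t] = d2
        w2t[t] = w2
        r2t[t] = r2
        m1, v1, m2, v2 = m1_new, v1_new, m2_new, v2_new

    return (mu1, sigma1, mu2, sigma2, alpha1, eps1, eps2, delta2, w2t, r2t,
            surprise, n_fallback, first_fallback)


@njit(cache=False)
def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + math.log(var) + (x - mean) ** 2 / var)


@njit(cache=False)
def _cpm_omega_logden(o, mu1_prev, s1_prev, s, w1, w2, h):
    """Change-point probability, log predictive density, and stable logit.

    The logit of the change probability equals the difference of the two
    weighted component log-densities, which stays accurate when the
    probability saturates; it is clamped to the logit of
    ``[_OMEGA_CLAMP, 1 - _OMEGA_CLAMP]``.
    """
    if h <= 0.0:
        return 0.0, _norm_logpdf(o, mu1_prev, s1_prev + w1 + s), -_LOGIT_MAX
    if h >= 1.0:
        return 1.0, _norm_logpdf(o, 0.0, s + w2), _LOGIT_MAX
    l1 = _norm_logpdf(o, mu1_prev, s1_prev + w1 + s) + math.log(1.0 - h)
    l2 = _norm_logpdf(o, 0.0, s + w2) + math.log(h)
    m = l1 if l1 > l2 else l2
    logden = m + math.log(math.exp(l1 - m) + math.exp(l2 - m))
    logit = min(max(l2 - l1, -_LOGIT_MAX), _LOGIT_MAX)
    return math.exp(l2 - logden), logden, logit


@njit(cache=False)
def _cpm_kernel(obs, mu1_0, s1_0, mu2_0, s, w1, w2, h, a):
    """Run the CPM recursion; always succeeds for valid parameters."""
    T = obs.shape[0]
    mu1 = np.empty(T)
    sigma1 = np.empty(T)
    mu2 = np.empty(T)
    alpha1 = np.empty(T)
    eps1 = np.empty(T)
    eps2 = np.empty(T)
    omega = np.empty(T)
    surprise = np.empty(T)

    m1, v1, m2 = mu1_0, s1_0, mu2_0
    for t in range(T):
        o = obs[t]
        om, logden, logit = _cpm_omega_logden(o, m1, v1, s, w1, w2, h)
        surprise[t] = -logden
        v1_new = 1.0 / ((1.0 - om) / (v1 + w1) + 1.0 / s)
        a1 = v1_new / s
        e1 = a1 * (o - m1)
        m1_new = m1 + e1
        m2_new = logit / a
        e2 = m2_new - m2

        mu1[t] = m1_new
        sigma1[t] = v1_new
        mu2[t] = m2_new
        alpha1[t] = a1
        eps1[t] = e1
        eps2[t] = e2
        omega[t] = om
        m1, v1, m2 = m1_new, v1_new, m2_new

    return mu1, sigma1, mu2, alpha1, eps1, eps2, omega, surprise


@njit(cache=False)
def _hgf_session_fe(obs2d, mu1_0, s1_0, mu2_0, s2_0, s, eta):
    """Total free energy over a session of blocks.

    Beliefs are reset to the priors at the start of every block.  Uses the
    same level-2 prior-predictive fallback as :func:`_hgf_kernel`.
    """
    total = 0.0
    for n in range(obs2d.shape[0]):
        m1, v1, m2, v2 = mu1_0, s1_0, mu2_0, s2_0
        for t in range(obs2d.shape[1]):
            o = obs2d[n, t]
            ev = math.exp(m2)
            denom = v1 + ev
            v1_new = 1.0 / (1.0 / s + 1.0 / denom)
            a1 = v1_new / s
            e1 = a1 * (o - m1)
            m1_new = m1 + e1
            d2 = (v1_new + e1 * e1) / denom - 1.0
            w2 = ev / denom
            r2 = (ev - v1) / denom
            prec2 = 1.0 / (v2 + eta) + 0.5 * w2 * (w2 + r2 * d2)
            if prec2 > 0.0 and np.isfinite(prec2):
                v2_new = 1.0 / prec2
                m2_new = m2 + 0.5 * v2_new * w2 * d2
            else:
                v2_new = v2 + eta
                m2_new = m2
            total += _hgf_fe(
                o, m1, v1, m2, v2, m1_new, v1_new, m2_new, v2_new, s, eta
            )
            m1, v1, m2, v2 = m1_new, v1_new, m2_new, v2_new
    return total


@njit(cache=False)
def _cpm_session_fe(obs2d, mu1_0, s1_0, mu2_0, s, w1, w2, h, a):
    """Total exact marginal log-likelihood over a session of blocks."""
    total = 0.0
    for n in range(obs2d.shape[0]):
        m1, v1 = mu1_0, s1_0
        for t in range(obs2d.shape[1]):
            o = obs2d[n, t]
            om, logden, _ = _cpm_omega_logden(o, m1, v1, s, w1, w2, h)
            total += logden
            v1_new = 1.0 / ((1.0 - om) / (v1 + w1) + 1.0 / s)
            m1 = m1 + (v1_new / s) * (o - m1)
            v1 = v1_new
    return total


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class BeliefTrajectory:
    """Per-trial belief trajectories of one filter run over a block."""

    model: str
    mu1: np.ndarray
    sigma1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray  # NaN for CPM
    alpha1: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    surprise: np.ndarray
    delta2: np.ndarray  # HGF only, else NaN
    w2t: np.ndarray
    r2t: np.ndarray
    omega: np.ndarray  # CPM only, else NaN
    params: dict
    n_fallbacks: int = 0  # HGF level-2 prior-predictive fallback trials

    @property
    def T(self) -> int:
        return len(self.mu1)

    @property
    def total_surprise(self) -> float:
        return float(np.sum(self.surprise))

    @property
    def total_free_energy(self) -> float:
        """Block-level (approximate) marginal log-likelihood: -total surprise."""
        return -self.total_surprise

    @property
    def states(self) -> list[BeliefState]:
        return [
            BeliefState(self.mu1[t], self.sigma1[t], self.mu2[t], self.sigma2[t])
            for t in range(self.T)
        ]

    @property
    def internals(self) -> list[TrialInternals]:
        return [
            TrialInternals(
                alpha1=self.alpha1[t],
                eps1=self.eps1[t],
                eps2=self.eps2[t],
                mu2=self.mu2[t],
                surprise=self.surprise[t],
                delta2=self.delta2[t],
                w2t=self.w2t[t],
                r2t=self.r2t[t],
                omega=self.omega[t],
            )
            for t in range(self.T)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-trial representation."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.T + 1),
                "model": self.model,
                "mu1": self.mu1,
                "sigma1": self.sigma1,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "alpha1": self.alpha1,
                "eps1": self.eps1,
                "eps2": self.eps2,
                "delta2": self.delta2,
                "w2t": self.w2t,
                "r2t": self.r2t,
                "omega": self.omega,
                "surprise": self.surprise,
            }
        )


def _initial_state(model: str, params: HGFParams | CPMParams) -> BeliefState:
    if model == "hgf":
        return BeliefState(params.mu0_1, params.sigma0_1, params.mu0_2, params.sigma0_2)
    return BeliefState(params.mu0_1, params.sigma0_1, params.mu0_2)


def hgf_step(
    state: BeliefState, o: float, params: HGFParams
) -> tuple[BeliefState, TrialInternals]:
    """One HGF update: level 1 first, then the volatility level."""
    if state.sigma1 <= 0 or state.sigma2 <= 0:
        raise ValueError("belief uncertainties must be positive")
    out = _hgf_kernel(
        np.array([float(o)]),
        state.mu1,
        state.sigma1,
        state.mu2,
        state.sigma2,
        params.s,
        params.eta,
    )
    if out[-2] != 0:
        raise InvalidUpdateError(trial=1)
    (mu1, sigma1, mu2, sigma2, alpha1, eps1, eps2, delta2, w2t, r2t,
     surprise, _, _) = out
    new = BeliefState(mu1[0], sigma1[0], mu2[0], sigma2[0])
    internals = TrialInternals(
        alpha1=alpha1[0],
        eps1=eps1[0],
        eps2=eps2[0],
        mu2=mu2[0],
        surprise=surprise[0],
        delta2=delta2[0],
        w2t=w2t[0],
        r2t=r2t[0],
    )
    return new, internals


def cpm_step(
    state: BeliefState, o: float, params: CPMParams
) -> tuple[BeliefState, TrialInternals]:
    """One CPM update: change probability, precision discount, delta rule."""
    if state.sigma1 <= 0:
        raise ValueError("belief uncertainty must be positive")
    mu1, sigma1, mu2, alpha1, eps1, eps2, omega, surprise = _cpm_kernel(
        np.array([float(o)]),
        state.mu1,
        state.sigma1,
        state.mu2,
        params.s,
        params.w1,
        params.w2,
        params.h,
        params.a,
    )
    new = BeliefState(mu1[0], sigma1[0], mu2[0])
    internals = TrialInternals(
        alpha1=alpha1[0],
        eps1=eps1[0],
        eps2=eps2[0],
        mu2=mu2[0],
        surprise=surprise[0],
        omega=omega[0],
    )
    return new, internals


def cpm_change_probability(state: BeliefState, o: float, params: CPMParams) -> float:
    """Posterior probability that the hidden state was just redrawn.

    Ratio of the hazard-weighted redraw predictive density to the full
    two-component predictive mixture.  Exact 0/1 limits for h in {0, 1}.
    """
    om, _, _ = _cpm_omega_logden(
        float(o), state.mu1, state.sigma1, params.s, params.w1, params.w2, params.h
    )
    return float(om)


def hgf_trial_free_energy(
    prev: BeliefState, new: BeliefState, o: float, params: HGFParams
) -> float:
    """Variational free energy of one HGF trial (surprise is its negative)."""
    for st in (prev, new):
        if st.sigma1 <= 0 or st.sigma2 <= 0:
            raise ValueError("belief uncertainties must be positive")
    return float(
        _hgf_fe(
            float(o),
            prev.mu1,
            prev.sigma1,
            prev.mu2,
            prev.sigma2,
            new.mu1,
            new.sigma1,
            new.mu2,
            new.sigma2,
            params.s,
            params.eta,
        )
    )


def cpm_trial_surprise(state: BeliefState, o: float, params: CPMParams) -> float:
    """Exact negative marginal log-likelihood of one CPM observation."""
    _, logden, _ = _cpm_omega_logden(
        float(o), state.mu1, state.sigma1, params.s, params.w1, params.w2, params.h
    )
    return float(-logden)


def _empty_trajectory(model: str, params) -> BeliefTrajectory:
    z = np.empty(0)
    return BeliefTrajectory(
        model=model, mu1=z, sigma1=z, mu2=z, sigma2=z, alpha1=z, eps1=z,
        eps2=z, surprise=z, delta2=z, w2t=z, r2t=z, omega=z, params=asdict(params),
    )


def run_filter(
    model: str,
    params: HGFParams | CPMParams,
    observations: np.ndarray,
    strict: bool = False,
) -> BeliefTrajectory:
    """Run a perceptual filter over a block of observations.

    Beliefs start at the prior ``(mu0, sigma0)``.  HGF trials whose level-2
    precision update turns non-positive fall back to the level-2
    prior-predictive belief; the trajectory records how many such trials
    occurred (``n_fallbacks``).  With ``strict=True`` the first such trial
    raises :class:`InvalidUpdateError` instead.
    """
    model = model.lower()
    if model not in ("hgf", "cpm"):
        raise ValueError(f"unknown model {model!r}")
    obs = np.asarray(observations, dtype=float).ravel()
    if obs.size and not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    if obs.size == 0:
        return _empty_trajectory(model, params)

    nan = np.full(obs.size, np.nan)
    n_fallbacks = 0
    if model == "hgf":
        (mu1, sigma1, mu2, sigma2, alpha1, eps1, eps2,
         delta2, w2t, r2t, surprise, n_fallbacks, first_fb) = _hgf_kernel(
            obs, params.mu0_1, params.sigma0_1, params.mu0_2, params.sigma0_2,
            params.s, params.eta,
        )
        if strict and n_fallbacks > 0:
            raise InvalidUpdateError(trial=int(first_fb))
        omega = nan
    else:
        mu1, sigma1, mu2, alpha1, eps1, eps2, omega, surprise = _cpm_kernel(
            obs, params.mu0_1, params.sigma0_1, params.mu0_2,
            params.s, params.w1, params.w2, params.h, params.a,
        )
        sigma2 = nan
        delta2 = w2t = r2t = nan
    return BeliefTrajectory(
        model=model, mu1=mu1, sigma1=sigma1, mu2=mu2, sigma2=sigma2,
        alpha1=alpha1, eps1=eps1, eps2=eps2, surprise=surprise,
        delta2=delta2, w2t=w2t, r2t=r2t, omega=omega, params=asdict(params),
        n_fallbacks=int(n_fallbacks),
    )


def write_trajectory(traj: BeliefTrajectory, csv_path: str) -> None:
    """Write a trajectory as tidy CSV with a JSON params sidecar."""
    import json
    import os

    traj.to_frame().to_csv(csv_path, index=False)
    with open(os.path.splitext(csv_path)[0] + ".json", "w") as fh:
        json.dump({"model": traj.model, "params": traj.params}, fh, indent=2)


# ---------------------------------------------------------------------------
# scikit-learn style estimators
# ---------------------------------------------------------------------------


class _PerceptualFilter(BaseEstimator, TransformerMixin):
    """Shared machinery of the two perceptual-filter estimators.

    ``transform`` maps a block of observations to the per-trial belief
    trajectory; ``fit`` emulates the training session by optimizing the
    perceptual parameters to minimize total surprise over many blocks.
    """

    _model: str = ""

    def _params_obj(self):
        raise NotImplementedError

    def transform(self, X) -> pd.DataFrame:
        """Belief trajectory (tidy frame) for observations ``X`` (1-D)."""
        return self.trajectory(X).to_frame()

    def trajectory(self, X) -> BeliefTrajectory:
        params = getattr(self, "params_", None) or self._params_obj()
        return run_filter(self._model, params, np.asarray(X, dtype=float))

    def fit(self, X, y=None, prior=None, optimizer_config=None, seed: int = 0):
        """Optimize perceptual parameters over training blocks.

        ``X`` is a 2-D array (blocks x trials) or a list of
        :class:`~beliefmodels.environments.StimulusBlock`.
        """
        from . import training  # local import avoids a module cycle

        result = training.train_perceptual(
            self._model, X, prior=prior, optimizer_config=optimizer_config, seed=seed
        )
        self.params_ = result.theta_star_obj
        self.training_result_ = result
        return self


class HGFFilter(_PerceptualFilter):
    """Two-level hierarchical Gaussian filter as a transformer."""

    _model = "hgf"

    def __init__(self, mu0_1=0.0, sigma0_1=1.0, s=1.0, mu0_2=0.0,
                 sigma0_2=1.0, eta=0.1):
        self.mu0_1 = mu0_1
        self.sigma0_1 = sigma0_1
        self.s = s
        self.mu0_2 = mu0_2
        self.sigma0_2 = sigma0_2
        self.eta = eta

    def _params_obj(self) -> HGFParams:
        return HGFParams(self.mu0_1, self.sigma0_1, self.s, self.mu0_2,
                         self.sigma0_2, self.eta)


class CPMFilter(_PerceptualFilter):
    """Variational change-point filter as a transformer."""

    _model = "cpm"

    def __init__(self, mu0_1=0.0, sigma0_1=1.0, s=1.0, w1=0.01, w2=10.0,
                 h=0.1, a=1.0):
        self.mu0_1 = mu0_1
        self.sigma0_1 = sigma0_1
        self.s = s
        self.w1 = w1
        self.w2 = w2
        self.h = h
        self.a = a

    def _params_obj(self) -> CPMParams:
        return CPMParams(self.mu0_1, self.sigma0_1, self.s, self.w1, self.w2,
                         self.h, self.a)
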