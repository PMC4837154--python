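"""Unconstrained reparametrization of the behavioral-model parameters.

Both behavioral models (perceptual filter + Gaussian response model) have
seven free parameters.  Optimization and the Laplace approximation operate
in a transformed space where every parameter is unconstrained:

* identity for location parameters (``mu0_1``, ``mu0_2``),
* ``ln`` for variance-like parameters (``s``, ``w1``, ``w2``, ``eta``,
  ``sigma0_1``, ``sigma0_2``, ``sigma_r``),
* logit for the hazard probability ``h``.

Priors are independent Gaussians in the transformed space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PARAM_ORDER",
    "PARAM_TRANSFORMS",
    "PriorSpec",
    "default_prior",
    "transform",
    "untransform",
    "transform_named",
    "untransform_named",
    "transform_dict",
    "untransform_dict",
    "log_prior",
    "log_prior_named",
]

#: Parameter names, in optimizer order, for each behavioral model.
PARAM_ORDER: dict[str, tuple[str, ...]] = {
    "hgf": ("mu0_1", "sigma0_1", "s", "mu0_2", "sigma0_2", "eta", "sigma_r"),
    "cpm": ("mu0_1", "sigma0_1", "s", "w1", "w2", "h", "sigma_r"),
}

#: Map tag per parameter name.
PARAM_TRANSFORMS: dict[str, str] = {
    "mu0_1": "identity",
    "mu0_2": "identity",
    "sigma0_1": "log",
    "sigma0_2": "log",
    "s": "log",
    "w1": "log",
    "w2": "log",
    "eta": "log",
    "sigma_r": "log",
    "h": "logit",
}

_PRIOR_MEANS = {
    "mu0_1": 0.0, "mu0_2": 0.0, "sigma0_1": 0.0, "sigma0_2": 0.0,
    "s": 0.0, "w1": 0.0, "w2": 7.0, "eta": -2.0, "h": -3.0, "sigma_r": 0.0,
}
_PRIOR_VARS = {name: 5.0 for name in _PRIOR_MEANS} | {"h": 2.0}


@dataclass(frozen=True)
class PriorSpec:
    """Independent Gaussian prior in transformed space (means/variances)."""

    means: dict[str, float] = field(default_factory=lambda: dict(_PRIOR_MEANS))
    variances: dict[str, float] = field(default_factory=lambda: dict(_PRIOR_VARS))

    def __post_init__(self) -> None:
        for name, v in self.variances.items():
            if v <= 0:
                raise ValueError(f"prior variance for {name!r} must be positive")

    def mean_vector(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.means[n] for n in names])

    def var_vector(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.variances[n] for n in names])


def default_prior() -> PriorSpec:
    """The package's standard weakly-informative prior (see module doc)."""
    return PriorSpec()


def _fwd(name: str, x: float) -> float:
    tag = PARAM_TRANSFORMS[name]
    if tag == "identity":
        return float(x)
    if tag == "log":
        if x <= 0:
            raise ValueError(f"{name} must be positive to transform, got {x!r}")
        return math.log(x)
    if not (0.0 < x < 1.0):
        raise ValueError(f"{name} must lie in (0, 1) to transform, got {x!r}")
    return math.log(x / (1.0 - x))


def _inv(name: str, rho: float) -> float:
    tag = PARAM_TRANSFORMS[name]
    if tag == "identity":
        return float(rho)
    if tag == "log":
        try:
            return math.exp(rho)
        except OverflowError:
            return math.inf
    if rho >= 0:
        return 1.0 / (1.0 + math.exp(-rho))
    e = math.exp(rho)
    return e / (1.0 + e)


def transform_named(params: dict[str, float], names: tuple[str, ...]) -> np.ndarray:
    """Natural-scale values -> transformed vector for an explicit name order."""
    return np.array([_fwd(n, params[n]) for n in names])


def untransform_named(rho: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(names),):
        raise ValueError(f"expected vector of length {len(names)}")
    return {n: _inv(n, r) for n, r in zip(names, rho)}


def log_prior_named(
    rho: np.ndarray, names: tuple[str, ...], prior: "PriorSpec | None" = None
) -> float:
    """Gaussian log prior of a transformed vector for an explicit name order."""
    prior = prior or default_prior()
    rho = np.asarray(rho, dtype=float)
    m = prior.mean_vector(names)
    v = prior.var_vector(names)
    return float(
        -0.5 * np.sum(np.log(2.0 * np.pi * v)) - 0.5 * np.sum((rho - m) ** 2 / v)
    )


def transform(params: dict[str, float], model: str) -> np.ndarray:
    """Natural-scale parameter dict -> transformed vector (optimizer order)."""
    names = PARAM_ORDER[model]
    return np.array([_fwd(n, params[n]) for n in names])


def untransform(rho: np.ndarray, model: str) -> dict[str, float]:
    """Transformed vector -> natural-scale parameter dict."""
    names = PARAM_ORDER[model]
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(names),):
        raise ValueError(f"expected vector of length {len(names)} for {model}")
    return {n: _inv(n, r) for n, r in zip(names, rho)}


def transform_dict(params: dict[str, float]) -> dict[str, float]:
    """Elementwise forward map keeping dict form (any parameter subset)."""
    return {n: _fwd(n, v) for n, v in params.items()}


def untransform_dict(rho: dict[str, float]) -> dict[str, float]:
    return {n: _inv(n, v) for n, v in rho.items()}


def log_prior(rho: np.ndarray, model: str, prior: PriorSpec | None = None) -> float:
    """Gaussian log prior density of a transformed parameter vector."""
    names = PARAM_ORDER[model]
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (len(names),):
        raise ValueError(f"expected vector of length {len(names)} for {model}")
    return log_prior_named(rho, names, prior)
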