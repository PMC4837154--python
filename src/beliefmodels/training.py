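"""Training session: optimize perceptual parameters to minimize surprise.

A simulated participant familiarizes with an environment over many
independent stimulus blocks.  Training maximizes, in the transformed
parameter space,

    ln p(theta) + sum_blocks sum_trials F_t(theta),

where ``F_t`` is the per-trial variational free energy for the HGF and the
exact per-trial marginal log-likelihood for the CPM.  Beliefs are reset to
the priors ``(mu0, sigma0)`` at the start of every block.  The same
Gaussian prior is used as in model inversion, so training and inversion
share one coherent parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _optim
from .environments import StimulusBlock
from .filters import CPMParams, HGFParams, _cpm_session_fe, _hgf_session_fe
from .transforms import (
    PriorSpec,
    default_prior,
    log_prior_named,
    transform_named,
    untransform_named,
)

__all__ = ["PERCEPTUAL_PARAM_ORDER", "TrainingResult", "train_perceptual"]

#: Perceptual (non-response) parameter names per model, in optimizer order.
PERCEPTUAL_PARAM_ORDER: dict[str, tuple[str, ...]] = {
    "hgf": ("mu0_1", "sigma0_1", "s", "mu0_2", "sigma0_2", "eta"),
    "cpm": ("mu0_1", "sigma0_1", "s", "w1", "w2", "h"),
}


@dataclass
class TrainingResult:
    """Optimized perceptual parameters for one model in one environment."""

    model: str
    theta_star: dict[str, float]  # natural scale
    objective_value: float  # penalized total free energy at the optimum
    n_blocks: int
    T: int
    trace: dict

    @property
    def theta_star_obj(self) -> HGFParams | CPMParams:
        if self.model == "hgf":
            return HGFParams(**self.theta_star)
        return CPMParams(**self.theta_star)


def _blocks_to_array(blocks) -> np.ndarray:
    if isinstance(blocks, np.ndarray):
        obs = np.atleast_2d(np.asarray(blocks, dtype=float))
    else:
        if isinstance(blocks, StimulusBlock):
            blocks = [blocks]
        obs = np.stack([np.asarray(b.observations, dtype=float) for b in blocks])
    if obs.size == 0:
        raise ValueError("training requires at least one non-empty block")
    return obs


def session_free_energy(model: str, theta: dict[str, float], obs2d: np.ndarray) -> float:
    """Total (approximate) marginal log-likelihood over a session of blocks."""
    obs2d = np.atleast_2d(np.asarray(obs2d, dtype=float))
    if model == "hgf":
        p = HGFParams(**theta)
        total = _hgf_session_fe(
            obs2d, p.mu0_1, p.sigma0_1, p.mu0_2, p.sigma0_2, p.s, p.eta
        )
    else:
        p = CPMParams(**theta)
        total = _cpm_session_fe(
            obs2d, p.mu0_1, p.sigma0_1, p.mu0_2, p.s, p.w1, p.w2, p.h, p.a
        )
    return float(total)


def train_perceptual(
    model: str,
    blocks,
    prior: PriorSpec | None = None,
    optimizer_config: _optim.OptimizerConfig | None = None,
    seed: int = 0,
) -> TrainingResult:
    """Find perceptual parameters minimizing total surprise over blocks.

    ``blocks`` may be a list of :class:`StimulusBlock` or a 2-D array of
    observations with one row per block.
    """
    model = model.lower()
    if model not in PERCEPTUAL_PARAM_ORDER:
        raise ValueError(f"unknown model {model!r}")
    prior = prior or default_prior()
    obs2d = _blocks_to_array(blocks)
    names = PERCEPTUAL_PARAM_ORDER[model]

    def objective(rho):
        theta = untransform_named(rho, names)
        try:
            fe = session_free_energy(model, theta, obs2d)
        except (ValueError, OverflowError):
            return -math.inf
        if not np.isfinite(fe):
            return -math.inf
        return fe + log_prior_named(rho, names, prior)

    x0 = prior.mean_vector(names)
    opt = _optim.maximize(objective, x0, optimizer_config, seed=seed)
    theta_star = untransform_named(opt.x, names)
    return TrainingResult(
        model=model,
        theta_star=theta_star,
        objective_value=float(opt.fun),
        n_blocks=obs2d.shape[0],
        T=obs2d.shape[1],
        trace={
            "n_evals": opt.n_evals,
            "converged": opt.converged,
            "seed": seed,
            "rho_star": opt.x.tolist(),
        },
    )
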