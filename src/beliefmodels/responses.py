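"""Gaussian response model: beliefs -> noisy behavioral responses.

The simulated participant reports, on each trial, the level-1 posterior
expectation corrupted by Gaussian response noise with variance ``sigma_r``:
``r_t = mu_t(1) + sqrt(sigma_r) * n_t``.  The response is conditioned on
the belief *after* observing the trial's stimulus (observe, then respond).
This is the optimal response under a quadratic loss, plus noise.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environments import StimulusBlock
from .filters import (
    BeliefTrajectory,
    CPMParams,
    HGFParams,
    InvalidUpdateError,
    run_filter,
)

__all__ = ["BehavioralDataset", "generate_responses", "response_loglik"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class BehavioralDataset:
    """Stimuli plus responses of one simulated agent.

    ``true_params`` stores the full generating parameter set (perceptual
    parameters plus ``sigma_r``) on the natural scale, for recovery scoring.
    """

    stimuli: StimulusBlock
    responses: np.ndarray
    generating_model: str
    true_params: dict
    seed: int

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.responses) != self.stimuli.T:
            raise ValueError("responses must have one entry per stimulus trial")

    @property
    def T(self) -> int:
        return self.stimuli.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.T + 1),
                "observation": self.stimuli.observations,
                "response": self.responses,
            }
        )

    def save(self, csv_path: str) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = {
            "generating_model": self.generating_model,
            "true_params": self.true_params,
            "seed": self.seed,
            "env_kind": self.stimuli.env_kind,
            "env_params": self.stimuli.params,
            "stimulus_seed": self.stimuli.seed,
        }
        with open(os.path.splitext(csv_path)[0] + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def generate_responses(
    trajectory: BeliefTrajectory | np.ndarray, sigma_r: float, seed: int
) -> np.ndarray:
    """Draw noisy responses around the level-1 expectation trajectory."""
    if sigma_r < 0:
        raise ValueError("sigma_r must be non-negative")
    mu1 = trajectory.mu1 if isinstance(trajectory, BeliefTrajectory) else np.asarray(trajectory, float)
    rng = np.random.default_rng(seed)
    return mu1 + math.sqrt(sigma_r) * rng.standard_normal(len(mu1))


def gaussian_loglik(residuals: np.ndarray, sigma_r: float) -> float:
    """Sum of Gaussian log densities with variance ``sigma_r``."""
    T = len(residuals)
    return float(
        -0.5 * T * (_LOG2PI + math.log(sigma_r))
        - 0.5 * np.sum(residuals**2) / sigma_r
    )


def response_loglik(
    responses: np.ndarray,
    model: str,
    params: HGFParams | CPMParams,
    sigma_r: float,
    stimuli: np.ndarray,
) -> float:
    """Log-likelihood of responses given stimuli and a behavioral model.

    Runs the stated perceptual filter on the stimuli and scores the
    responses as Gaussian around the resulting ``mu_t(1)`` trajectory.
    Parameter sets that make the filter recursion invalid score ``-inf``
    rather than raising, so optimizers treat them as rejected candidates.
    """
    responses = np.asarray(responses, dtype=float)
    stimuli = np.asarray(stimuli, dtype=float)
    if len(responses) != len(stimuli):
        raise ValueError("responses and stimuli must have equal length")
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    try:
        traj = run_filter(model, params, stimuli)
    except InvalidUpdateError:
        return -math.inf
    ll = gaussian_loglik(responses - traj.mu1, sigma_r)
    return ll if np.isfinite(ll) else -math.inf
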