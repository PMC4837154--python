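"""Synthetic experimental environments.

Two kinds of changing environment are simulated, both emitting a scalar
stimulus stream ``o_1..o_T`` around a hidden state ``x_t(1)``:

* **switching** — the hidden state usually follows a slow Gaussian random
  walk (diffusion variance ``w1``) but on each trial is, with hazard
  probability ``h``, redrawn from a zero-mean Gaussian with variance ``w2``.
* **diffusive** — the hidden state follows a Gaussian random walk whose
  log-variance (the volatility ``x_t(2)``) itself performs a random walk
  with diffusion variance ``eta``.

All Gaussian widths in this package are **variances**, never standard
deviations.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SwitchingEnvParams",
    "DiffusiveEnvParams",
    "StimulusBlock",
    "SWITCHING_DEFAULT",
    "DIFFUSIVE_DEFAULT",
    "simulate_switching",
    "simulate_diffusive",
    "simulate_session",
    "write_blocks",
    "read_blocks",
]


def _check_variance(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative variance, got {value!r}")


@dataclass(frozen=True)
class SwitchingEnvParams:
    """Parameters of the switching (change-point) environment.

    h : per-trial probability that the hidden state is redrawn.
    w1 : diffusion variance of the stable random walk.
    w2 : variance of the zero-mean redraw distribution.
    s : observation-noise variance.
    x0 : mean of the hidden state before the first trial.
    x0_var : variance of the initial hidden state (0 = deterministic start).
    """

    h: float = 0.1
    w1: float = 0.01
    w2: float = 10.0
    s: float = 1.0
    x0: float = 0.0
    x0_var: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h <= 1.0) or not np.isfinite(self.h):
            raise ValueError(f"h must lie in [0, 1], got {self.h!r}")
        for name in ("w1", "w2", "s", "x0_var"):
            _check_variance(name, getattr(self, name))
        if not np.isfinite(self.x0):
            raise ValueError("x0 must be finite")
        if self.w2 <= self.s:
            warnings.warn(
                "w2 <= s: the change-point filter's conditional-uncertainty "
                "approximation assumes w2 >> s",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DiffusiveEnvParams:
    """Parameters of the diffusive (volatility) environment.

    eta : diffusion variance of the log-volatility random walk.
    s : observation-noise variance.
    x0_1 : mean of the initial hidden state (level 1).
    x0_2 : initial log-volatility (level 2).
    x0_var : variance of the initial hidden state (0 = deterministic start).
    """

    eta: float = 0.1
    s: float = 1.0
    x0_1: float = 0.0
    x0_2: float = 0.0
    x0_var: float = 0.0

    def __post_init__(self) -> None:
        _check_variance("eta", self.eta)
        _check_variance("s", self.s)
        _check_variance("x0_var", self.x0_var)
        if not (np.isfinite(self.x0_1) and np.isfinite(self.x0_2)):
            raise ValueError("initial states must be finite")


#: Standard switching environment: rare redraws (h=0.1) from a wide (w2=10)
#: distribution, slow drift (w1=0.01), unit observation noise.  Each block
#: starts from the stationary redraw distribution, x0 ~ N(0, w2), i.e., as
#: if a change had just occurred.
SWITCHING_DEFAULT = SwitchingEnvParams(x0_var=10.0)

#: Standard diffusive environment: volatility diffusion eta=0.1, unit
#: observation noise.  The initial state is drawn with the same variance as
#: the switching environment's stationary start so the two environments
#: present comparable state ranges.
DIFFUSIVE_DEFAULT = DiffusiveEnvParams(x0_var=10.0)


@dataclass
class StimulusBlock:
    """One experimental block of ``T`` trials.

    ``hidden2`` holds the level-2 trajectory for the diffusive environment
    and the 0/1 change indicators for the switching environment.
    """

    observations: np.ndarray
    hidden1: np.ndarray
    hidden2: np.ndarray
    env_kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        self.hidden1 = np.asarray(self.hidden1, dtype=float)
        self.hidden2 = np.asarray(self.hidden2, dtype=float)
        if not (len(self.observations) == len(self.hidden1) == len(self.hidden2)):
            raise ValueError("all trajectories in a block must have equal length")
        if self.env_kind not in ("switching", "diffusive"):
            raise ValueError(f"unknown env_kind {self.env_kind!r}")

    @property
    def T(self) -> int:
        return len(self.observations)


def simulate_switching(
    params: SwitchingEnvParams, T: int, seed: int
) -> StimulusBlock:
    """Simulate ``T`` trials of the switching environment.

    On each trial the hidden state is redrawn ``x ~ N(0, w2)`` with
    probability ``h`` and otherwise continues the random walk
    ``x_t = x_{t-1} + N(0, w1)``; the stimulus is ``o_t = x_t + N(0, s)``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    x_init = params.x0 + math.sqrt(params.x0_var) * rng.standard_normal()
    changes = rng.random(T) < params.h
    walk_noise = rng.standard_normal(T) * math.sqrt(params.w1)
    redraws = rng.standard_normal(T) * math.sqrt(params.w2)
    obs_noise = rng.standard_normal(T) * math.sqrt(params.s)

    x = np.empty(T)
    prev = x_init
    for t in range(T):
        prev = redraws[t] if changes[t] else prev + walk_noise[t]
        x[t] = prev
    return StimulusBlock(
        observations=x + obs_noise,
        hidden1=x,
        hidden2=changes.astype(float),
        env_kind="switching",
        seed=int(seed),
        params=asdict(params),
    )


def simulate_diffusive(
    params: DiffusiveEnvParams, T: int, seed: int
) -> StimulusBlock:
    """Simulate ``T`` trials of the diffusive environment.

    ``x_t(2) = x_{t-1}(2) + N(0, eta)``;
    ``x_t(1) = x_{t-1}(1) + N(0, exp(x_t(2)))``; ``o_t = x_t(1) + N(0, s)``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    x_init = params.x0_1 + math.sqrt(params.x0_var) * rng.standard_normal()
    x2 = params.x0_2 + np.cumsum(rng.standard_normal(T) * math.sqrt(params.eta))
    x1 = x_init + np.cumsum(rng.standard_normal(T) * np.exp(0.5 * x2))
    obs = x1 + rng.standard_normal(T) * math.sqrt(params.s)
    return StimulusBlock(
        observations=obs,
        hidden1=x1,
        hidden2=x2,
        env_kind="diffusive",
        seed=int(seed),
        params=asdict(params),
    )


def block_seeds(master_seed: int, N: int) -> np.ndarray:
    """Per-block seeds derived deterministically from a master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=N)


def simulate_session(
    env: SwitchingEnvParams | DiffusiveEnvParams,
    N: int,
    T: int,
    seed: int,
) -> list[StimulusBlock]:
    """Simulate ``N`` independent blocks of ``T`` trials each.

    The hidden state is re-initialized at every block; block seeds are
    derived from the master seed and recorded in each block.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    seeds = block_seeds(seed, N)
    if isinstance(env, SwitchingEnvParams):
        return [simulate_switching(env, T, int(s)) for s in seeds]
    if isinstance(env, DiffusiveEnvParams):
        return [simulate_diffusive(env, T, int(s)) for s in seeds]
    raise TypeError(f"unsupported environment parameter type {type(env)!r}")


def write_blocks(blocks: list[StimulusBlock], out_dir: str) -> str:
    """Write blocks as a tidy CSV plus a JSON sidecar with params/seeds."""
    os.makedirs(out_dir, exist_ok=True)
    frames = []
    for i, b in enumerate(blocks):
        frames.append(
            pd.DataFrame(
                {
                    "block": i,
                    "trial": np.arange(1, b.T + 1),
                    "observation": b.observations,
                    "hidden1": b.hidden1,
                    "hidden2": b.hidden2,
                }
            )
        )
    csv_path = os.path.join(out_dir, "blocks.csv")
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    sidecar = {
        "env_kind": blocks[0].env_kind,
        "params": blocks[0].params,
        "seeds": [b.seed for b in blocks],
        "T": blocks[0].T,
        "N": len(blocks),
    }
    with open(os.path.join(out_dir, "blocks.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return csv_path


def read_blocks(out_dir: str) -> list[StimulusBlock]:
    """Read blocks written by :func:`write_blocks`."""
    df = pd.read_csv(os.path.join(out_dir, "blocks.csv"))
    with open(os.path.join(out_dir, "blocks.json")) as fh:
        sidecar = json.load(fh)
    blocks = []
    for i, g in df.groupby("block", sort=True):
        blocks.append(
            StimulusBlock(
                observations=g["observation"].to_numpy(),
                hidden1=g["hidden1"].to_numpy(),
                hidden2=g["hidden2"].to_numpy(),
                env_kind=sidecar["env_kind"],
                seed=int(sidecar["seeds"][int(i)]),
                params=sidecar["params"],
            )
        )
    return blocks
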