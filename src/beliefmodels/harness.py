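"""End-to-end experiment orchestration with full seed bookkeeping.

The factorial experiment crosses two environments (switching, diffusive)
with two simulated agents (CPM, HGF), optionally over several experiment
durations and response-noise levels:

1. **train** each perceptual model in each environment (minimize surprise
   over a long session of blocks);
2. **simulate** agents: fresh stimuli, beliefs from the trained filter,
   noisy responses;
3. **fit** every agent with both behavioral models by both inversion
   methods (BI-LA, MLE-BIC);
4. **evaluate**: group-level confusion matrices, parameter-recovery
   diagnostics, trajectory correlations.

Every artifact records the seeds that produced it, so a run is fully
reproducible from its manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import evaluation, training
from ._optim import OptimizerConfig
from .environments import (
    DIFFUSIVE_DEFAULT,
    SWITCHING_DEFAULT,
    SwitchingEnvParams,
    simulate_diffusive,
    simulate_session,
    simulate_switching,
)
from .filters import BeliefTrajectory, CPMParams, HGFParams, run_filter
from .inversion import FitResult, fit_bi_la, fit_mle
from .responses import BehavioralDataset, generate_responses

__all__ = [
    "ENVIRONMENTS",
    "ExperimentConfig",
    "AgentRecord",
    "simulate_agent",
    "simulate_agents",
    "fit_agents",
    "train_in_environment",
    "coverage_study",
    "run_experiment",
    "make_fixture",
    "FIXTURE_KINDS",
]

ENVIRONMENTS = {"switching": SWITCHING_DEFAULT, "diffusive": DIFFUSIVE_DEFAULT}

#: Environment in which each model's generative assumptions are matched.
MATCHED_ENV = {"cpm": "switching", "hgf": "diffusive"}


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def _simulate_block(env_params, T, seed):
    if isinstance(env_params, SwitchingEnvParams):
        return simulate_switching(env_params, T, seed)
    return simulate_diffusive(env_params, T, seed)


@dataclass
class AgentRecord:
    """One simulated agent: data, generating trajectory, and fits."""

    dataset: BehavioralDataset
    generating_trajectory: BeliefTrajectory
    env_kind: str
    fits: dict = field(default_factory=dict)  # (model, method) -> FitResult


def simulate_agent(
    env_params,
    model: str,
    theta: HGFParams | CPMParams,
    sigma_r: float,
    T: int,
    seed: int,
) -> AgentRecord:
    """Simulate one agent: stimuli, beliefs, and noisy responses."""
    stim_seed, resp_seed = (int(s) for s in _derive_seeds(seed, 2))
    block = _simulate_block(env_params, T, stim_seed)
    traj = run_filter(model, theta, block.observations)
    responses = generate_responses(traj, sigma_r, resp_seed)
    true_params = dict(theta.__dict__) | {"sigma_r": sigma_r}
    true_params.pop("a", None)  # fixed scaling constant, not a free parameter
    dataset = BehavioralDataset(
        stimuli=block,
        responses=responses,
        generating_model=model,
        true_params=true_params,
        seed=int(seed),
    )
    return AgentRecord(dataset=dataset, generating_trajectory=traj,
                       env_kind=block.env_kind)


def simulate_agents(
    env_params, model, theta, sigma_r, n_agents: int, T: int, seed: int
) -> list[AgentRecord]:
    seeds = _derive_seeds(seed, n_agents)
    return [
        simulate_agent(env_params, model, theta, sigma_r, T, int(s)) for s in seeds
    ]


def fit_agents(
    agents: list[AgentRecord],
    models: tuple[str, ...] = ("hgf", "cpm"),
    methods: tuple[str, ...] = ("bi-la", "mle"),
    optimizer_config: OptimizerConfig | None = None,
    seed: int = 0,
) -> None:
    """Fit every agent in place with each candidate model and method."""
    seeds = _derive_seeds(seed, len(agents))
    for agent, s in zip(agents, seeds):
        for model in models:
            for method in methods:
                if method == "bi-la":
                    fit = fit_bi_la(agent.dataset, model,
                                    optimizer_config=optimizer_config, seed=int(s))
                else:
                    fit = fit_mle(agent.dataset, model,
                                  optimizer_config=optimizer_config, seed=int(s))
                agent.fits[(model, method)] = fit


def train_in_environment(
    model: str,
    env_params,
    n_blocks: int = 1000,
    T: int = 100,
    seed: int = 0,
    optimizer_config: OptimizerConfig | None = None,
) -> training.TrainingResult:
    """Emulate the training session for one model in one environment."""
    blocks = simulate_session(env_params, n_blocks, T, seed)
    return training.train_perceptual(
        model, blocks, optimizer_config=optimizer_config, seed=seed
    )


def coverage_study(
    seed: int = 0,
    n_agents: int = 50,
    T: int = 100,
    sigma_r: float = 1.0,
    n_train_blocks: int = 500,
    train_config: OptimizerConfig | None = None,
    fit_config: OptimizerConfig | None = None,
) -> dict:
    """Matched-model coverage of the Bayesian-Laplace posterior intervals.

    For each model in its matched environment (CPM/switching,
    HGF/diffusive): train the perceptual parameters, simulate ``n_agents``
    agents at the trained values, fit each agent's own generating model
    with BI-LA, and measure the per-parameter fraction of truths within
    two posterior standard deviations of the mode.
    """
    rng_seeds = _derive_seeds(seed, 6)
    results = {}
    per_param = {}
    for i, model in enumerate(("cpm", "hgf")):
        env = ENVIRONMENTS[MATCHED_ENV[model]]
        trained = train_in_environment(
            model, env, n_blocks=n_train_blocks, T=T,
            seed=int(rng_seeds[i]), optimizer_config=train_config,
        )
        agents = simulate_agents(
            env, model, trained.theta_star_obj, sigma_r, n_agents, T,
            seed=int(rng_seeds[2 + i]),
        )
        fit_agents(agents, models=(model,), methods=("bi-la",),
                   optimizer_config=fit_config, seed=int(rng_seeds[4 + i]))
        fits = [a.fits[(model, "bi-la")] for a in agents]
        truths = [a.dataset.true_params for a in agents]
        diag = evaluation.recovery_diagnostics(fits, truths)
        results[model] = diag
        per_param[model] = dict(zip(diag.param_names, diag.coverage))
    mean_coverage = float(
        np.mean(np.concatenate([results[m].coverage for m in results]))
    )
    return {
        "mean_coverage": mean_coverage,
        "per_model": results,
        "per_param": per_param,
        "n_agents": n_agents,
        "seed": seed,
    }


@dataclass
class ExperimentConfig:
    """Shape of a full factorial experiment run."""

    env_kinds: tuple[str, ...] = ("switching", "diffusive")
    models: tuple[str, ...] = ("hgf", "cpm")
    T_list: tuple[int, ...] = (50, 100)
    sigma_r_list: tuple[float, ...] = (1.0, 5.0)
    methods: tuple[str, ...] = ("bi-la", "mle")
    n_agents: int = 50
    k: int = 20
    n_groups: int = 500
    n_train_blocks: int = 500
    train_T: int = 100
    master_seed: int = 0
    out_dir: str = "experiment_out"
    max_evals: int = 3000
    restarts: int = 2

    def __post_init__(self) -> None:
        for name in ("env_kinds", "models", "T_list", "sigma_r_list", "methods"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run train -> simulate -> fit -> evaluate; write artifacts + manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    opt = OptimizerConfig(max_evals=config.max_evals, restarts=config.restarts)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": []}
    seeds = _derive_seeds(config.master_seed, 1000)
    seed_iter = iter(int(s) for s in seeds)

    # --- stage 1: training -------------------------------------------------
    trained: dict = {}
    train_rows = []
    for env_kind in config.env_kinds:
        for model in config.models:
            s = next(seed_iter)
            try:
                result = train_in_environment(
                    model, ENVIRONMENTS[env_kind],
                    n_blocks=config.n_train_blocks, T=config.train_T,
                    seed=s, optimizer_config=opt,
                )
            except Exception as exc:  # noqa: BLE001 - recorded in manifest
                manifest["stages"].setdefault("train_failures", []).append(
                    {"model": model, "env": env_kind, "seed": s, "error": str(exc)}
                )
                continue
            trained[(model, env_kind)] = result
            train_rows.append(
                {"model": model, "env": env_kind, "seed": s,
                 "objective": result.objective_value, **result.theta_star}
            )
    pd.DataFrame(train_rows).to_csv(
        os.path.join(config.out_dir, "training.csv"), index=False
    )
    manifest["artifacts"].append("training.csv")

    # --- stages 2-3: simulate + fit ----------------------------------------
    pools: dict = {}
    fit_rows = []
    for env_kind in config.env_kinds:
        for gen_model in config.models:
            if (gen_model, env_kind) not in trained:
                continue
            theta = trained[(gen_model, env_kind)].theta_star_obj
            for T in config.T_list:
                for sigma_r in config.sigma_r_list:
                    s_sim, s_fit = next(seed_iter), next(seed_iter)
                    agents = simulate_agents(
                        ENVIRONMENTS[env_kind], gen_model, theta, sigma_r,
                        config.n_agents, T, seed=s_sim,
                    )
                    fit_agents(agents, models=config.models,
                               methods=config.methods,
                               optimizer_config=opt, seed=s_fit)
                    pools[(env_kind, gen_model, T, sigma_r)] = agents
                    for i, a in enumerate(agents):
                        for (m, meth), fit in a.fits.items():
                            fit_rows.append(
                                {"env": env_kind, "gen_model": gen_model,
                                 "T": T, "sigma_r": sigma_r, "agent": i,
                                 "fit_model": m, "method": meth,
                                 "log_evidence": fit.log_evidence,
                                 **{f"rho_{n}": v for n, v in
                                    zip(fit.param_names, fit.rho_star)}}
                            )
    pd.DataFrame(fit_rows).to_csv(
        os.path.join(config.out_dir, "fits.csv"), index=False
    )
    manifest["artifacts"].append("fits.csv")

    # --- stage 4: evaluation ------------------------------------------------
    confusion_rows, recovery_rows = [], []
    for T in config.T_list:
        for sigma_r in config.sigma_r_list:
            for env_kind in config.env_kinds:
                for method in config.methods:
                    try:
                        pool = {
                            gm: np.array(
                                [[a.fits[(m, method)].log_evidence
                                  for m in config.models]
                                 for a in pools[(env_kind, gm, T, sigma_r)]]
                            )
                            for gm in config.models
                        }
                        s_conf = next(seed_iter)
                        cm = evaluation.confusion_experiment(
                            pool, k=min(config.k, config.n_agents),
                            n_groups=config.n_groups, seed=s_conf,
                            labels=config.models,
                            condition={"env": env_kind, "T": T,
                                       "sigma_r": sigma_r, "method": method},
                        )
                    except KeyError:
                        continue
                    for i, true_m in enumerate(config.models):
                        for j, inf_m in enumerate(config.models):
                            confusion_rows.append(
                                {"env": env_kind, "T": T, "sigma_r": sigma_r,
                                 "method": method, "true_model": true_m,
                                 "inferred_model": inf_m,
                                 "proportion": cm.proportions[i, j],
                                 "count": int(cm.counts[i, j]),
                                 "seed": s_conf}
                            )
            # recovery on matched-model fits in each environment
            for env_kind in config.env_kinds:
                for gm in config.models:
                    key = (env_kind, gm, T, sigma_r)
                    if key not in pools:
                        continue
                    for method in config.methods:
                        agents = pools[key]
                        diag = evaluation.recovery_diagnostics(
                            [a.fits[(gm, method)] for a in agents],
                            [a.dataset.true_params for a in agents],
                        )
                        for name, rmse, cov in zip(diag.param_names, diag.rmse,
                                                   diag.coverage):
                            recovery_rows.append(
                                {"env": env_kind, "gen_model": gm, "T": T,
                                 "sigma_r": sigma_r, "method": method,
                                 "parameter": name, "rmse": rmse,
                                 "coverage": cov}
                            )
    pd.DataFrame(confusion_rows).to_csv(
        os.path.join(config.out_dir, "confusion.csv"), index=False
    )
    pd.DataFrame(recovery_rows).to_csv(
        os.path.join(config.out_dir, "recovery.csv"), index=False
    )
    manifest["artifacts"] += ["confusion.csv", "recovery.csv"]

    # trajectory correlations (matched and crossed inference models)
    corr_rows = []
    for key, agents in pools.items():
        env_kind, gm, T, sigma_r = key
        for a in agents:
            for inf_m in config.models:
                for method in config.methods:
                    fit = a.fits[(inf_m, method)]
                    corr = evaluation.trajectory_correlation(
                        a.dataset, a.generating_trajectory, fit.params, inf_m
                    )
                    corr_rows.append(
                        {"env": env_kind, "gen_model": gm, "T": T,
                         "sigma_r": sigma_r, "inference_model": inf_m,
                         "method": method, **corr}
                    )
    pd.DataFrame(corr_rows).to_csv(
        os.path.join(config.out_dir, "correlations.csv"), index=False
    )
    manifest["artifacts"].append("correlations.csv")

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ---------------------------------------------------------------------------
# named test fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    "cpm-switching-easy": dict(
        model="cpm", env=SWITCHING_DEFAULT, sigma_r=1.0,
        theta=CPMParams(mu0_1=0.0, sigma0_1=2.0, s=1.0, w1=0.01, w2=10.0, h=0.1),
    ),
    "cpm-switching-noisy": dict(
        model="cpm", env=SWITCHING_DEFAULT, sigma_r=5.0,
        theta=CPMParams(mu0_1=0.0, sigma0_1=2.0, s=1.0, w1=0.01, w2=10.0, h=0.1),
    ),
    "hgf-diffusive-easy": dict(
        model="hgf", env=DIFFUSIVE_DEFAULT, sigma_r=1.0,
        theta=HGFParams(mu0_1=0.0, sigma0_1=2.0, s=1.0, mu0_2=-2.0,
                        sigma0_2=1.0, eta=0.1),
    ),
    "hgf-diffusive-noisy": dict(
        model="hgf", env=DIFFUSIVE_DEFAULT, sigma_r=5.0,
        theta=HGFParams(mu0_1=0.0, sigma0_1=2.0, s=1.0, mu0_2=-2.0,
                        sigma0_2=1.0, eta=0.1),
    ),
    "kalman-limit": dict(
        model="cpm",
        env=SwitchingEnvParams(h=0.0, w1=0.1, w2=10.0, s=1.0),
        sigma_r=1.0,
        theta=CPMParams(mu0_1=0.0, sigma0_1=2.0, s=1.0, w1=0.1, w2=10.0, h=0.0),
    ),
}

FIXTURE_KINDS = tuple(_FIXTURES)


def make_fixture(kind: str, seed: int = 0, T: int = 50) -> AgentRecord:
    """Deterministic small dataset with known truths, for unit tests."""
    if kind not in _FIXTURES:
        raise KeyError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    spec = _FIXTURES[kind]
    if T > 50:
        raise ValueError("fixtures are capped at T=50")
    return simulate_agent(spec["env"], spec["model"], spec["theta"],
                          spec["sigma_r"], T, seed)
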