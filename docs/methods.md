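# Methods

This note documents the models, the simulated study design, the numerical
choices, and what the package's tests do and do not establish.

## Generative environments

Two scalar-stimulus environments are simulated; both corrupt the hidden
state with Gaussian observation noise of variance `s` (default 1, i.e., a
standard-normal deviate).

**Switching.**  Per trial, with probability `h` the hidden state is redrawn
from `N(0, w2)`; otherwise it continues a random walk with increment
variance `w1`.  Standard parameterization: `h = 0.1`, `w1 = 0.01`,
`w2 = 10`.

**Diffusive.**  The hidden state performs a random walk whose increment
variance is `exp(x_t(2))`, where the log-volatility `x(2)` itself performs
a random walk with diffusion variance `eta = 0.1`.

**Initial states.**  Blocks are treated as windows into an ongoing process,
not as restarts from a known origin.  In the switching environment each
block's initial state is drawn from the redraw distribution `N(0, w2)` —
the process's natural stationary start ("a change just occurred") — and the
diffusive environment uses an initial draw with the same variance (10) so
the two environments present comparable state ranges.  The diffusive
initial log-volatility is 0, making the volatility excursions within a
100-trial block substantial (per-trial state steps of order 1) and the
level-1 excursions (±10 over 100 trials) comparable between environments.
These choices matter: with a *fixed, known* initial state the training
session drives the prior-uncertainty parameter `sigma0(1)` toward zero
(there is nothing to be uncertain about), which degenerates the
parameter-recovery analyses; and with a near-zero initial volatility the
diffusive environment reduces to a slow random walk on which the
change-point model's jump detector is not challenged.  Both `x0_var` and
`x0_2` are plain fields on the environment dataclasses; setting
`x0_var = 0` recovers the bare textbook processes (which is what the
degenerate-limit unit tests exercise).

## Perceptual filters

Both filters are exact transcriptions of their published update equations
(verified against independently written oracles to 1e-10 in the test
suite); per-trial surprise is the negative variational free energy for the
HGF and the exact negative marginal log-likelihood of the two-component
predictive mixture for the CPM.

Numerical guard rails, all recorded per trajectory:

* **HGF level-2 fallback.**  The printed volatility update can produce a
  non-positive posterior precision for extreme inputs (it requires
  `r_t(2) delta_t(2) < -w_t(2)`, reachable when level-1 uncertainty exceeds
  the volatility estimate and a large prediction error arrives).  On such
  trials the level-2 belief falls back to its prior-predictive value
  (`sigma2 <- sigma2 + eta`, `mu2` unchanged) and the trial is counted
  (`BeliefTrajectory.n_fallbacks`); `run_filter(strict=True)` raises
  instead.  At the trained parameter values used throughout the study the
  fallback essentially never triggers (zero occurrences across hundreds of
  fresh blocks); it exists so that likelihood surfaces and forward
  simulation are defined for arbitrary parameter proposals.
* **CPM logit stability.**  The logit-scaled change probability
  `mu(2) = ln(Omega/(1-Omega))/a` is computed as the difference of the two
  weighted component log-densities (exact, and well-conditioned when
  `Omega` saturates), clamped to the logit of `[1e-12, 1-1e-12]`.  The
  scaling constant `a` is 1 by default; correlation analyses are invariant
  to it.  The initial `mu0(2)` is the logit of the believed hazard, the
  change probability expected before any data.
* The CPM conditional uncertainty uses the approximation
  `sigma(1)|change ≈ s` (valid for `w2 >> s`), matching the published
  update equations exactly rather than the exact conditional form.

## Training session

Training emulates task familiarization: maximize
`ln p(theta) + sum_blocks sum_trials F_t(theta)` over the six perceptual
parameters in the transformed space, with beliefs reset to the prior at
each block start.  The same Gaussian prior is used as in inversion (one
coherent parameter space).  The package default uses 500 blocks of 100
trials, which makes the training optimum stable to third-digit accuracy
while keeping a full four-environment training pass around a minute of CPU;
the block count is a plain argument.

The trained optimum is *not* the generative parameter vector: the HGF's
variational surrogate systematically prefers a smaller believed volatility
diffusion than the generative `eta`, and the CPM trained on the diffusive
environment approximates volatility bursts with rare large redraws
(`w2` in the hundreds, `h` below 0.01).  Both are genuine properties of
surprise minimization within a mismatched or approximate filter family, not
optimizer failures (verified by objective comparisons at hand-picked
alternatives).

## Parameter space, priors, inversion

All seven free parameters per model (six perceptual plus the response-noise
variance `sigma_r`) are mapped to an unconstrained space: identity for
`mu0(1)`, `mu0(2)`; `ln` for all variance-like parameters, including
`sigma_r`; logit for `h`.  The prior is independent Gaussian in that space:
mean 0, variance 5 everywhere except mean −2 for `ln eta`, mean 7 for
`ln w2`, and mean −3 / variance 2 for `logit h` (encoding the expectations
of a rare hazard, a small volatility diffusion, and a redraw variance far
above the observation noise).

**BI-LA** maximizes the log-joint and approximates the posterior by a
Gaussian at the mode with covariance `(-H)^{-1}`; the log evidence is
`log-joint(mode) + (1/2) ln |2 pi S|`.  **MLE** maximizes the likelihood
alone in the same space; the BIC value `loglik − (d/2) ln T` stands in for
the evidence and the inverse negative likelihood Hessian for the estimate's
uncertainty.

Numerical choices:

* **Optimizer.**  Seeded multi-start Nelder-Mead (one start at the prior
  mean plus randomized restarts, default 3, perturbation SD 1.0 in
  transformed units, total budget 5000 evaluations) followed by a tight
  simplex polish and an L-BFGS-B gradient polish.  Invalid or overflowing
  parameter proposals score `-inf` and are simply ranked worst.  Modes are
  budget- and method-stable on these surfaces (checked against independent
  Powell and L-BFGS-B runs).
* **Hessian.**  Central finite differences with per-coordinate steps
  proportional to coordinate magnitude; steps shrink automatically at the
  edge of invalid regions.  Because sequential-filter likelihoods can be
  locally *rough* (trajectories become chaotic in parameters where the
  volatility update nears blow-up, making the fine-step Hessian at a
  maximum indefinite — pure noise), the step is coarsened
  (1e-3 → 0.05 → 0.2 → 0.5) until the negative Hessian is positive
  definite; if no scale achieves that, the coarsest-step matrix is
  eigenvalue-floored at the prior precision (the log-joint's curvature can
  not genuinely fall below the prior's contribution at a smooth mode) and
  the fit is flagged (`pd_repaired`).  Flooring, not ridge shifting, is
  used throughout so well-measured directions are untouched.
* Degenerate inputs: `T = 0` gives an empty trajectory with zero surprise;
  `h ∈ {0, 1}` is handled as an exact limit of the change probability;
  boundary parameter values (`h = 0`, `s = 0`) are domain errors for the
  transform.

## Evaluation

* Tracking performance is the RMSE of `mu_t(1)` against the hidden state.
* Group-level model attribution uses the random-effects variational
  Dirichlet scheme with a uniform Dirichlet prior; for two models the
  exceedance probability is the regularized incomplete beta function
  (cross-checked against 1e6-sample Dirichlet Monte Carlo).  Confusion
  matrices resample groups of `k = 20` agents with replacement from pools
  of fitted agents; the group winner is the model with exceedance
  probability above 1/2.
* Recovery diagnostics report per-parameter RMSE (transformed space) and
  the fraction of agents whose truth lies within two posterior standard
  deviations of the mode (nominal 0.9545 for a calibrated Gaussian).
* Trajectory correlations are Pearson correlations between generating and
  inferred per-trial variables (`mu1`, `alpha1`, `eps1`, `mu2`, `eps2`),
  skipping the first trial (the level-2 prediction error is undefined
  before the first update for the CPM); zero-variance trajectories give
  NaN and are excluded from summaries.

## Desk-scale study design and what it shows

The study-level tests and the acceptance script run the full pipeline at
reduced size: training on 500 blocks, 50 agents per environment × model
cell at `T = 100` and response-noise variance 1, each fit with both models
by both methods, 500 resampled groups of 20 for confusion matrices.  At
this scale the qualitative results are stable across seeds: each filter
wins tracking RMSE and free energy in its own environment (with a smaller
margin in the diffusive one), Bayesian modes beat maximum-likelihood
estimates on per-parameter RMSE for all seven parameters, group-level model
recovery is near-perfect for BI-LA in both environments, and
learning-rate trajectories are recovered far better by the matched model.

Known limitations:

* **Per-parameter calibration is not uniform.**  The CPM redraw variance
  `w2` is nearly unidentified from responses at `T = 100` (it enters only
  through the change-point probability), so its per-agent posterior stays
  close to the prior while the trained truth sits about two prior SD from
  the prior mean; its ±2 SD coverage is therefore far below nominal
  (~0.3).  The believed observation noise `s` has a skewed posterior at
  this block length whose Gaussian approximation undercovers (~0.75).  The
  remaining twelve of fourteen parameters are calibrated at 0.88–1.0, and
  the average over all parameters lands near 0.85–0.90 depending on the
  training realization.
* The generator produces idealized behavior: Gaussian response noise that
  is white across trials, no lapses, no autocorrelated motor noise, no
  learning during the test session.  Passing tests show the *inference
  machinery* is correct and calibrated in-model; they do not show that real
  participants' data identify these models equally well.
* Only the easy condition (`sigma_r = 1`, `T = 100`) is exercised by the
  default test tier; at that ceiling the MLE-BIC group classification is
  also near-perfect, so the Bayesian advantage in model attribution — which
  concentrates at short experiments and high response noise — is not
  visible there.  `run_experiment` exposes the full factorial
  (`T ∈ {50, 100}`, `sigma_r ∈ {1, 5}`) for studying exactly that.
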