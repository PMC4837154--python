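"""Perceptual-filter updates checked against independently written oracles.

The oracles below re-derive each update directly from the model definitions
(using scipy distributions and precision-form algebra) and are kept
deliberately separate from the package's kernels.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from beliefmodels.filters import (
    BeliefState,
    CPMParams,
    HGFParams,
    InvalidUpdateError,
    cpm_change_probability,
    cpm_step,
    cpm_trial_surprise,
    hgf_step,
    hgf_trial_free_energy,
    run_filter,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def hgf_update_oracle(mu1, s1, mu2, s2, o, s, eta):
    """Direct precision-form evaluation of the two-level HGF update."""
    pred_var_1 = s1 + np.exp(mu2)  # level-1 predictive variance
    post_prec_1 = 1.0 / s + 1.0 / pred_var_1
    sigma1 = post_prec_1**-1
    alpha1 = sigma1 / s
    eps1 = alpha1 * (o - mu1)
    mu1_new = mu1 + eps1

    delta2 = (sigma1 + eps1**2) / pred_var_1 - 1.0
    w2 = np.exp(mu2) / pred_var_1
    r2 = (np.exp(mu2) - s1) / pred_var_1
    post_prec_2 = 1.0 / (s2 + eta) + 0.5 * w2 * (w2 + r2 * delta2)
    if post_prec_2 <= 0:
        return None
    sigma2 = post_prec_2**-1
    eps2 = 0.5 * sigma2 * w2 * delta2
    return dict(
        mu1=mu1_new, sigma1=sigma1, mu2=mu2 + eps2, sigma2=sigma2,
        alpha1=alpha1, eps1=eps1, eps2=eps2, delta2=delta2, w2t=w2, r2t=r2,
    )


def hgf_free_energy_oracle(prev, new, o, s, eta):
    """Term-by-term free energy: three Gaussian cross-entropy blocks plus the
    posterior entropies (Gaussian entropy = 1/2 ln(2 pi e sigma))."""
    pv1 = prev["sigma1"] + np.exp(new["mu2"])
    pv2 = prev["sigma2"] + eta
    obs_term = -0.5 * np.log(2 * np.pi * s) - (new["sigma1"] + (o - new["mu1"]) ** 2) / (2 * s)
    lvl1_term = -0.5 * np.log(2 * np.pi * pv1) - (new["sigma1"] + (new["mu1"] - prev["mu1"]) ** 2) / (2 * pv1)
    lvl2_term = -0.5 * np.log(2 * np.pi * pv2) - (new["sigma2"] + (new["mu2"] - prev["mu2"]) ** 2) / (2 * pv2)
    ent = 0.5 * np.log(2 * np.pi * np.e * new["sigma1"]) + 0.5 * np.log(
        2 * np.pi * np.e * new["sigma2"]
    )
    return obs_term + lvl1_term + lvl2_term + ent


def cpm_omega_oracle(o, mu1, s1, s, w1, w2, h):
    """Change-point probability from plain scipy normal densities."""
    num = stats.norm.pdf(o, 0.0, np.sqrt(s + w2)) * h
    den = stats.norm.pdf(o, mu1, np.sqrt(s1 + w1 + s)) * (1 - h) + num
    return num / den


def cpm_update_oracle(mu1, s1, mu2, o, s, w1, w2, h, a=1.0):
    om = cpm_omega_oracle(o, mu1, s1, s, w1, w2, h)
    sigma1 = 1.0 / ((1.0 - om) / (s1 + w1) + 1.0 / s)
    alpha1 = sigma1 / s
    eps1 = alpha1 * (o - mu1)
    # logit(om) via weighted component log-densities (well-conditioned when
    # om saturates), clamped to the logit of [1e-12, 1 - 1e-12]
    logit = (
        stats.norm.logpdf(o, 0.0, np.sqrt(s + w2)) + np.log(h)
        - stats.norm.logpdf(o, mu1, np.sqrt(s1 + w1 + s)) - np.log(1 - h)
    )
    bound = np.log((1 - 1e-12) / 1e-12)
    mu2_new = np.clip(logit, -bound, bound) / a
    return dict(
        mu1=mu1 + eps1, sigma1=sigma1, mu2=mu2_new, alpha1=alpha1,
        eps1=eps1, eps2=mu2_new - mu2, omega=om,
    )


def kalman_reference(obs, mu0, v0, drift, noise):
    """Plain random-walk Kalman filter (written independently of the CPM)."""
    mus, vs = [], []
    m, v = mu0, v0
    for o in obs:
        pred = v + drift
        gain = pred / (pred + noise)
        m = m + gain * (o - m)
        v = (1.0 - gain) * pred
        mus.append(m)
        vs.append(v)
    return np.array(mus), np.array(vs)


def _random_hgf_inputs(rng, n):
    for _ in range(n):
        yield dict(
            mu1=rng.normal(0, 3),
            s1=rng.uniform(0.05, 5),
            mu2=rng.uniform(-3, 2),
            s2=rng.uniform(0.05, 5),
            o=rng.normal(0, 4),
            s=rng.uniform(0.1, 4),
            eta=rng.uniform(0.01, 2),
        )


# ---------------------------------------------------------------------------
# HGF
# ---------------------------------------------------------------------------


class TestHGFStep:
    def test_matches_oracle_on_random_inputs(self, rng):
        checked = 0
        for inp in _random_hgf_inputs(rng, 1000):
            expected = hgf_update_oracle(**inp)
            state = BeliefState(inp["mu1"], inp["s1"], inp["mu2"], inp["s2"])
            params = HGFParams(s=inp["s"], eta=inp["eta"])
            if expected is None:
                # oracle says the level-2 precision turns non-positive here
                with pytest.raises(InvalidUpdateError):
                    hgf_step(state, inp["o"], params)
                continue
            new, intr = hgf_step(state, inp["o"], params)
            got = dict(
                mu1=new.mu1, sigma1=new.sigma1, mu2=new.mu2, sigma2=new.sigma2,
                alpha1=intr.alpha1, eps1=intr.eps1, eps2=intr.eps2,
                delta2=intr.delta2, w2t=intr.w2t, r2t=intr.r2t,
            )
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k
            checked += 1
        assert checked > 800  # vast majority of random states are valid

    def test_hand_computed_precision_update(self):
        """s=1, sigma1_prev=1, mu2_prev=0: posterior precision 1 + 1/2."""
        state = BeliefState(mu1=0.0, sigma1=1.0, mu2=0.0, sigma2=1.0)
        new, intr = hgf_step(state, 0.5, HGFParams(s=1.0, eta=0.1))
        assert new.sigma1 == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert intr.alpha1 == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_zero_prediction_error(self):
        state = BeliefState(mu1=1.3, sigma1=0.8, mu2=-0.5, sigma2=0.6)
        new, intr = hgf_step(state, 1.3, HGFParams(s=1.0, eta=0.1))
        assert intr.eps1 == 0.0
        assert new.mu1 == 1.3
        assert intr.delta2 < 0  # only the uncertainty term remains

    def test_invalid_level2_precision_raises_in_step(self):
        # sigma1 >> exp(mu2) makes r2 negative; a large prediction error then
        # drives the level-2 precision negative
        state = BeliefState(mu1=0.0, sigma1=5.0, mu2=0.0, sigma2=100.0)
        params = HGFParams(s=1.0, sigma0_1=5.0, sigma0_2=100.0, eta=1.0)
        assert hgf_update_oracle(0.0, 5.0, 0.0, 100.0, 5.0, 1.0, 1.0) is None
        with pytest.raises(InvalidUpdateError):
            hgf_step(state, 5.0, params)

    def test_strict_filter_reports_fallback_trial(self):
        params = HGFParams(mu0_1=0.0, sigma0_1=5.0, s=1.0, mu0_2=0.0,
                           sigma0_2=100.0, eta=1.0)
        obs = np.array([0.0, 5.0, 0.0])
        with pytest.raises(InvalidUpdateError) as err:
            run_filter("hgf", params, obs, strict=True)
        assert err.value.trial == 2
        traj = run_filter("hgf", params, obs)  # non-strict: fallback + count
        assert traj.n_fallbacks >= 1
        assert np.all(traj.sigma2 > 0)


class TestHGFFreeEnergy:
    def test_matches_oracle_on_random_inputs(self, rng):
        params_pool = list(_random_hgf_inputs(rng, 300))
        for inp in params_pool:
            if hgf_update_oracle(**inp) is None:
                continue
            prev = BeliefState(inp["mu1"], inp["s1"], inp["mu2"], inp["s2"])
            params = HGFParams(s=inp["s"], eta=inp["eta"])
            new, intr = hgf_step(prev, inp["o"], params)
            f = hgf_trial_free_energy(prev, new, inp["o"], params)
            expected = hgf_free_energy_oracle(
                dict(mu1=prev.mu1, sigma1=prev.sigma1, mu2=prev.mu2, sigma2=prev.sigma2),
                dict(mu1=new.mu1, sigma1=new.sigma1, mu2=new.mu2, sigma2=new.sigma2),
                inp["o"], inp["s"], inp["eta"],
            )
            assert f == pytest.approx(expected, rel=1e-10, abs=1e-10)
            assert intr.surprise == pytest.approx(-f, rel=1e-12)

    def test_exact_in_pinned_volatility_limit(self):
        """With level 2 frozen the free energy equals the Kalman predictive
        log-density exactly."""
        mu0_2 = -1.0
        params = HGFParams(mu0_1=0.3, sigma0_1=2.0, s=1.3, mu0_2=mu0_2,
                           sigma0_2=1e-12, eta=1e-14)
        obs = np.random.default_rng(0).normal(0, 2, 60)
        traj = run_filter("hgf", params, obs)
        m, v = params.mu0_1, params.sigma0_1
        drift = math.exp(mu0_2)
        for t, o in enumerate(obs):
            pv = v + drift + params.s
            exact = stats.norm.logpdf(o, m, np.sqrt(pv))
            assert -traj.surprise[t] == pytest.approx(exact, abs=1e-9)
            gain = (v + drift) / pv
            m, v = m + gain * (o - m), (1 - gain) * (v + drift)

    def test_block_surprise_is_sum_of_trials(self):
        params = HGFParams()
        obs = np.random.default_rng(1).normal(0, 2, 40)
        traj = run_filter("hgf", params, obs)
        assert traj.total_surprise == pytest.approx(traj.surprise.sum(), rel=1e-12)
        assert traj.total_free_energy == pytest.approx(-traj.total_surprise)


# ---------------------------------------------------------------------------
# CPM
# ---------------------------------------------------------------------------


class TestCPMChangeProbability:
    def test_matches_density_oracle_on_random_inputs(self, rng):
        for _ in range(1000):
            mu1 = rng.normal(0, 3)
            s1 = rng.uniform(0.05, 5)
            o = rng.normal(0, 4)
            p = CPMParams(
                s=rng.uniform(0.1, 3), w1=rng.uniform(0.001, 2),
                w2=rng.uniform(3, 50), h=rng.uniform(0.01, 0.99),
            )
            state = BeliefState(mu1, s1, 0.0)
            om = cpm_change_probability(state, o, p)
            expected = cpm_omega_oracle(o, mu1, s1, p.s, p.w1, p.w2, p.h)
            assert om == pytest.approx(expected, rel=1e-10, abs=1e-13)

    def test_exact_limits_and_symmetry(self):
        state = BeliefState(1.0, 0.5, 0.0)
        assert cpm_change_probability(state, 2.0, CPMParams(h=0.0)) == 0.0
        assert cpm_change_probability(state, 2.0, CPMParams(h=1.0)) == 1.0
        # equal weighted densities -> 1/2: put both components equal by symmetry
        p = CPMParams(mu0_1=0.0, s=1.0, w1=8.0, w2=8.5, h=0.5)
        sym = BeliefState(0.0, 0.5, 0.0)  # s1+w1+s == s+w2, means both 0
        assert cpm_change_probability(sym, 1.7, p) == pytest.approx(0.5, rel=1e-12)

    def test_monotone_in_distance_from_origin(self):
        """With w2 >> sigma+w1 the change probability grows with |o| for
        observations farther from zero than from the current expectation."""
        p = CPMParams(s=1.0, w1=0.01, w2=100.0, h=0.1)
        state = BeliefState(0.0, 0.1, 0.0)
        grid = np.linspace(0, 15, 40)
        om = [cpm_change_probability(state, o, p) for o in grid]
        assert np.all(np.diff(om) > -1e-12)


class TestCPMStep:
    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(1000):
            mu1 = rng.normal(0, 3)
            s1 = rng.uniform(0.05, 5)
            mu2 = rng.normal(0, 2)
            o = rng.normal(0, 4)
            p = CPMParams(
                s=rng.uniform(0.1, 3), w1=rng.uniform(0.001, 2),
                w2=rng.uniform(3, 50), h=rng.uniform(0.01, 0.99),
                a=rng.uniform(0.5, 2),
            )
            expected = cpm_update_oracle(mu1, s1, mu2, o, p.s, p.w1, p.w2, p.h, p.a)
            new, intr = cpm_step(BeliefState(mu1, s1, mu2), o, p)
            got = dict(
                mu1=new.mu1, sigma1=new.sigma1, mu2=new.mu2,
                alpha1=intr.alpha1, eps1=intr.eps1, eps2=intr.eps2,
                omega=intr.omega,
            )
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k

    def test_h0_reduces_to_kalman_filter(self):
        p = CPMParams(mu0_1=0.2, sigma0_1=2.0, s=1.5, w1=0.3, w2=10.0, h=0.0)
        obs = np.random.default_rng(3).normal(0, 2, 80)
        traj = run_filter("cpm", p, obs)
        mus, vs = kalman_reference(obs, p.mu0_1, p.sigma0_1, p.w1, p.s)
        np.testing.assert_allclose(traj.mu1, mus, atol=1e-10)
        np.testing.assert_allclose(traj.sigma1, vs, atol=1e-10)
        # closed-form gain (sigma+w1)/(sigma+w1+s)
        gain0 = (p.sigma0_1 + p.w1) / (p.sigma0_1 + p.w1 + p.s)
        assert traj.alpha1[0] == pytest.approx(gain0, rel=1e-12)

    def test_logit_reparametrization_center(self):
        """Omega = 1/2 with a = 1 maps to mu2 = 0."""
        p = CPMParams(mu0_1=0.0, s=1.0, w1=8.0, w2=8.5, h=0.5)
        new, intr = cpm_step(BeliefState(0.0, 0.5, 0.3), 1.7, p)
        assert intr.omega == pytest.approx(0.5, rel=1e-12)
        assert new.mu2 == pytest.approx(0.0, abs=1e-10)


class TestCPMSurprise:
    def test_matches_mixture_density_oracle(self, rng):
        for _ in range(300):
            mu1 = rng.normal(0, 2)
            s1 = rng.uniform(0.05, 4)
            o = rng.normal(0, 4)
            p = CPMParams(s=rng.uniform(0.1, 3), w1=rng.uniform(0.01, 1),
                          w2=rng.uniform(3, 40), h=rng.uniform(0.01, 0.95))
            expected = -np.log(
                stats.norm.pdf(o, mu1, np.sqrt(s1 + p.w1 + p.s)) * (1 - p.h)
                + stats.norm.pdf(o, 0, np.sqrt(p.s + p.w2)) * p.h
            )
            got = cpm_trial_surprise(BeliefState(mu1, s1, 0.0), o, p)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_predictive_density_normalizes(self):
        """exp(-surprise) is a proper mixture density over o."""
        p = CPMParams(s=1.0, w1=0.1, w2=12.0, h=0.2)
        state = BeliefState(1.5, 0.7, 0.0)
        val, _ = integrate.quad(
            lambda o: math.exp(-cpm_trial_surprise(state, o, p)), -60, 60
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_h0_is_gaussian_predictive(self):
        p = CPMParams(s=1.0, w1=0.1, w2=12.0, h=0.0)
        state = BeliefState(1.5, 0.7, 0.0)
        expected = -stats.norm.logpdf(2.3, 1.5, np.sqrt(0.7 + 0.1 + 1.0))
        assert cpm_trial_surprise(state, 2.3, p) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# run_filter and shared invariants
# ---------------------------------------------------------------------------


class TestRunFilter:
    def test_empty_input(self):
        traj = run_filter("cpm", CPMParams(), np.array([]))
        assert traj.T == 0 and traj.total_surprise == 0.0

    @pytest.mark.parametrize("model,params", [
        ("hgf", HGFParams(mu0_1=2.0)),
        ("cpm", CPMParams(mu0_1=2.0)),
    ])
    def test_constant_observations_at_prior_mean(self, model, params):
        traj = run_filter(model, params, np.full(30, 2.0))
        np.testing.assert_allclose(traj.mu1, 2.0, atol=1e-12)

    def test_unknown_model_and_nonfinite_obs(self):
        with pytest.raises(ValueError):
            run_filter("kalman", CPMParams(), np.zeros(3))
        with pytest.raises(ValueError):
            run_filter("cpm", CPMParams(), np.array([1.0, np.inf]))

    def test_states_and_internals_lengths(self, cpm_fixture):
        traj = cpm_fixture.generating_trajectory
        assert len(traj.states) == traj.T == len(traj.internals)
        assert traj.total_surprise == pytest.approx(
            sum(i.surprise for i in traj.internals)
        )


@settings(max_examples=60, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    s=st.floats(0.2, 4.0),
    eta=st.floats(0.01, 1.0),
    w1=st.floats(0.001, 1.0),
    h=st.floats(0.0, 0.9),
)
def test_learning_rate_and_uncertainty_invariants(seed, s, eta, w1, h):
    """alpha1 in (0, 1]; posterior level-1 uncertainty never exceeds the
    believed observation noise (strictly below it for the HGF)."""
    tol = 1 + 1e-12  # alpha -> 1 exactly in the omega -> 1 limit, up to rounding
    obs = np.random.default_rng(seed).normal(0, 3, 60)
    hgf = run_filter("hgf", HGFParams(s=s, eta=eta), obs)
    assert np.all(hgf.alpha1 > 0) and np.all(hgf.alpha1 <= tol)
    assert np.all(hgf.sigma1 < s * tol)
    cpm = run_filter("cpm", CPMParams(s=s, w1=w1, w2=20.0, h=h), obs)
    assert np.all(cpm.alpha1 > 0) and np.all(cpm.alpha1 <= tol)
    assert np.all(cpm.sigma1 <= s * tol)
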