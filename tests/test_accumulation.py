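"""Adaptation, analytic moments, choice probability, and likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from dynclicks.accumulation import (ModelParams, PriorConfig, adapt_clicks,
                                    choice_prob, fit_parameters,
                                    forward_moments, merge_clicks,
                                    negative_log_likelihood, pack_trials)
from dynclicks.synth import generate_trial, simulate_agent_ensemble


def ode_adaptation_oracle(times, phi, tau_phi, dt=1e-6):
    """Microscopic Euler integration of the adaptation ODE between clicks."""
    mags = []
    c = 1.0
    t = 0.0
    for s in times:
        n = int(round((s - t) / dt))
        for _ in range(n):
            c += (1.0 - c) / tau_phi * dt
        mags.append(c)
        c *= phi
        t = s
    return np.array(mags)


class TestAdaptClicks:
    def test_no_adaptation_all_magnitudes_one(self, trial_factory):
        tr = trial_factory(right=[0.1, 0.11, 0.2], left=[0.105])
        ac = adapt_clicks(tr, phi=1.0, tau_phi=0.05)
        assert np.allclose(ac.magnitudes, 1.0)

    def test_two_click_closed_form(self, trial_factory):
        # second magnitude = 1 + (phi - 1) e^{-dt/tau}
        tr = trial_factory(right=[0.1, 0.3])
        ac = adapt_clicks(tr, phi=0.5, tau_phi=0.2)
        assert ac.magnitudes[0] == pytest.approx(1.0)
        assert ac.magnitudes[1] == pytest.approx(1.0 - 0.5 * math.exp(-1.0), abs=1e-12)

    def test_matches_fine_ode_integration(self, trial_factory):
        times = [0.05, 0.09, 0.3, 0.31, 0.7]
        tr = trial_factory(right=times)
        for phi in (0.4, 1.7):
            ac = adapt_clicks(tr, phi=phi, tau_phi=0.12)
            oracle = ode_adaptation_oracle(times, phi, 0.12)
            assert np.allclose(ac.magnitudes, oracle, atol=1e-4)

    def test_full_recovery_for_wide_spacing(self, trial_factory):
        tr = trial_factory(duration=10.0, right=[1.0, 5.0, 9.0])
        ac = adapt_clicks(tr, phi=0.3, tau_phi=0.05)
        assert np.allclose(ac.magnitudes, 1.0, atol=1e-9)

    def test_unordered_clicks_rejected(self):
        with pytest.raises(ValueError):
            merge_clicks([0.3, 0.1], [])

    def test_ties_processed_left_then_right(self, trial_factory):
        tr = trial_factory(left=[0.2], right=[0.2])
        ac = adapt_clicks(tr, phi=0.5, tau_phi=0.1)
        assert ac.signs[0] == -1 and ac.signs[1] == 1
        assert ac.magnitudes[0] == pytest.approx(1.0)
        assert ac.magnitudes[1] == pytest.approx(0.5)  # phi * 1, zero gap

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=0, max_size=8),
           st.floats(0.1, 3.0), st.floats(0.02, 0.5))
    def test_magnitudes_positive_and_bounded(self, times, phi, tau_phi):
        from conftest import make_trial

        tr = make_trial(right=sorted(times))
        ac = adapt_clicks(tr, phi=phi, tau_phi=tau_phi)
        assert np.all(ac.magnitudes > 0)
        if phi <= 1:  # depression never exceeds the fully recovered state
            assert np.all(ac.magnitudes <= 1.0 + 1e-12)


class TestForwardMoments:
    def test_no_clicks_zero_mean(self, trial_factory, theta):
        tr = trial_factory(duration=1.2)
        fm = forward_moments(tr, theta)
        assert np.allclose(fm.mu, 0.0)

    def test_lambda_zero_linear_variance(self, trial_factory):
        tr = trial_factory(duration=1.0)
        th = ModelParams(sigma_i2=0.4, sigma_a2=2.0, sigma_s2=0, lam=0.0,
                         phi=1.0, tau_phi=0.1, lapse=0.0)
        fm = forward_moments(tr, th)
        assert np.allclose(fm.var, 0.4 + 2.0 * fm.times, atol=1e-10)

    def test_single_click_exponential_decay(self, trial_factory):
        tr = trial_factory(duration=0.6, right=[0.1])
        th = ModelParams(sigma_i2=0, sigma_a2=0, sigma_s2=0, lam=-2.0, phi=1.0,
                         tau_phi=0.1, lapse=0.0)
        fm = forward_moments(tr, th, t_grid=np.array([0.6]))
        assert fm.mu[0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_lambda_limit_continuity(self, trial_factory, theta):
        tr = trial_factory(duration=1.0, right=[0.2, 0.5], left=[0.7])
        a = forward_moments(tr, theta.with_(lam=0.0))
        b = forward_moments(tr, theta.with_(lam=1e-9))
        assert np.allclose(a.var, b.var, rtol=1e-6)
        assert np.allclose(a.mu, b.mu, rtol=1e-6)

    def test_matches_sde_monte_carlo(self, task, theta):
        """Core oracle equivalence on a random trial at 25 ms checkpoints."""
        tr = generate_trial(task, np.random.default_rng(21), 0)
        fm = forward_moments(tr, theta)
        ck = np.arange(0.0, tr.duration, 0.025)
        st_t, samples, _, _ = simulate_agent_ensemble(tr, theta, seed=22,
                                                      n_paths=30000, store_times=ck)
        idx = np.searchsorted(fm.times, st_t)
        n = samples.shape[0]
        z_mu = (samples.mean(0) - fm.mu[idx]) / (samples.std(0) / np.sqrt(n))
        var_se = samples.var(0) * np.sqrt(2.0 / (n - 1))
        z_var = (samples.var(0) - fm.var[idx]) / var_se
        assert np.abs(z_mu).max() < 4.0
        assert np.abs(z_var).max() < 4.0


class TestChoiceProb:
    def test_mean_at_boundary_gives_half(self, trial_factory):
        for lapse in (0.0, 0.3, 1.0):
            th = ModelParams(B=0.0, lapse=lapse)
            tr = trial_factory(duration=1.0)  # no clicks, mu = 0 = B
            assert choice_prob(tr, th) == pytest.approx(0.5)

    def test_pure_lapse_is_half_for_any_stimulus(self, trial_factory):
        tr = trial_factory(duration=1.0, right=np.linspace(0.05, 0.95, 30))
        th = ModelParams(lapse=1.0)
        assert choice_prob(tr, th) == pytest.approx(0.5)

    def test_standard_normal_tail(self, trial_factory):
        # mu = 1, sigma = 1, B = 0, no lapse -> Phi(1)
        tr = trial_factory(duration=0.5, right=[0.5])
        th = ModelParams(sigma_i2=1.0, sigma_a2=0, sigma_s2=0, lam=0.0, phi=1.0,
                         tau_phi=0.1, B=0.0, lapse=0.0)
        assert choice_prob(tr, th) == pytest.approx(float(ndtr(1.0)), abs=1e-12)


def numpy_nll_oracle(trials, choices, th: ModelParams, priors=None):
    """Independent per-trial NLL via the module's public moment functions."""
    total = 0.0
    for tr, y in zip(trials, choices):
        p = choice_prob(tr, th)
        p = p if y == 1 else 1.0 - p
        total -= math.log(min(max(p, 1e-10), 1 - 1e-10))
    if priors is not None:
        total += priors.penalty(th.sigma_i2, th.sigma_a2)
    return total


class TestLikelihood:
    def test_pure_lapse_closed_form(self, trial_factory):
        trials = [trial_factory(duration=1.0, right=[0.5], trial_id=i) for i in range(7)]
        th = ModelParams(lapse=1.0)
        nll = negative_log_likelihood(trials, th, choices=[1, -1, 1, 1, -1, -1, 1])
        assert nll == pytest.approx(7 * math.log(2), abs=1e-9)

    def test_additivity_of_duplicated_trial(self, trial_factory, theta):
        tr = trial_factory(duration=0.8, right=[0.2, 0.4], left=[0.6])
        one = negative_log_likelihood([tr], theta, choices=[1])
        two = negative_log_likelihood([tr, tr], theta, choices=[1, 1])
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_order_invariance(self, task, theta):
        rng = np.random.default_rng(23)
        trials = [generate_trial(task, rng, i) for i in range(20)]
        choices = list(rng.choice([-1, 1], 20))
        a = negative_log_likelihood(trials, theta, choices=choices)
        b = negative_log_likelihood(trials[::-1], theta, choices=choices[::-1])
        assert a == pytest.approx(b, rel=1e-12)

    def test_missing_choice_raises(self, trial_factory, theta):
        tr = trial_factory(duration=1.0)
        with pytest.raises(ValueError):
            negative_log_likelihood([tr], theta)

    def test_kernel_matches_independent_oracle(self, task):
        """The jitted likelihood equals a per-trial implementation built
        from choice_prob, including prior terms, at random parameters."""
        rng = np.random.default_rng(24)
        trials = [generate_trial(task, rng, i) for i in range(15)]
        choices = list(rng.choice([-1, 1], 15))
        priors = PriorConfig(sigma_i2_scale=10.0, sigma_a2_scale=20.0)
        for seed in range(3):
            r = np.random.default_rng(seed)
            th = ModelParams(sigma_i2=r.uniform(0, 2), sigma_a2=r.uniform(0, 3),
                             sigma_s2=r.uniform(0, 3), lam=r.uniform(-4, 1),
                             phi=r.uniform(0.2, 1.8), tau_phi=r.uniform(0.05, 0.4),
                             B=r.uniform(-1, 1), lapse=r.uniform(0, 0.4))
            a = negative_log_likelihood(trials, th, choices=choices, priors=priors)
            b = numpy_nll_oracle(trials, choices, th, priors)
            assert a == pytest.approx(b, rel=1e-9)


class TestFit:
    def test_recovery_on_small_synthetic_set(self, task):
        theta_true = ModelParams(sigma_i2=0.3, sigma_a2=1.0, sigma_s2=1.5,
                                 lam=-3.0, phi=0.6, tau_phi=0.15, B=0.2, lapse=0.05)
        rng = np.random.default_rng(25)
        trials = [generate_trial(task, rng, i) for i in range(4000)]
        choices = []
        for i, tr in enumerate(trials):
            _, _, _, c = simulate_agent_ensemble(tr, theta_true, seed=2600 + i,
                                                 n_paths=1, store_times=np.array([0.0]))
            choices.append(int(c[0]))
        fit = fit_parameters(pack_trials(trials, choices), theta0=ModelParams(),
                             n_starts=1, seed=0)
        assert np.isfinite(fit.nll)
        assert fit.theta_hat.lam < 0  # leaky regime recovered
        se = fit.se["lam"] if np.isfinite(fit.se["lam"]) else 0.5
        assert abs(fit.theta_hat.lam - theta_true.lam) < 4 * se + 0.5

    def test_zero_lapse_recovered_near_boundary(self, task):
        theta_true = ModelParams(sigma_i2=0.1, sigma_a2=0.5, sigma_s2=0.5,
                                 lam=-1.0, phi=1.0, tau_phi=0.1, B=0.0, lapse=0.0)
        rng = np.random.default_rng(27)
        trials = [generate_trial(task, rng, i) for i in range(2000)]
        choices = []
        for i, tr in enumerate(trials):
            _, _, _, c = simulate_agent_ensemble(tr, theta_true, seed=2800 + i,
                                                 n_paths=1, store_times=np.array([0.0]))
            choices.append(int(c[0]))
        fit = fit_parameters(pack_trials(trials, choices),
                             theta0=ModelParams(lapse=0.2), n_starts=1, seed=1)
        assert fit.theta_hat.lapse < 0.05

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters([], theta0=ModelParams())
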