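"""Sampler correctness, diagnostics, DIC and posterior summaries."""

import numpy as np
import pytest
from scipy.stats import kstest

from mmnathist.inference import (ChainSet, McmcSettings, dic, gelman_rubin,
                                 posterior_predictive, posterior_summary, run_mcmc)


def _mock_chainset(draws, names=None):
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    settings = McmcSettings(n_iterations=2 * draws.shape[1], burn_in=draws.shape[1],
                            thin=1, n_chains=draws.shape[0])
    return ChainSet(draws=draws, log_posterior=np.zeros(draws.shape[:2]),
                    acceptance=np.full(draws.shape[0], np.nan),
                    param_names=names or [f"x{i}" for i in range(draws.shape[2])],
                    settings=settings)


class TestRunMcmc:
    def test_standard_normal_target_moments(self):
        """Known-target oracle: sampled mean/variance of a 1-D standard
        normal within Monte-Carlo error of 0 and 1."""
        log_post = lambda x: float(-0.5 * x[0] ** 2)
        settings = McmcSettings(n_iterations=60_000, burn_in=20_000, thin=4,
                                n_chains=2, seed=3)
        chains = run_mcmc(log_post, settings, init=[np.array([1.5]), np.array([-1.5])])
        pooled = chains.pooled()[:, 0]
        # ~20,000 correlated draws; allow 3x a conservative effective SE
        assert abs(pooled.mean()) < 0.06
        assert abs(pooled.var() - 1.0) < 0.09
        assert gelman_rubin(chains).max() < 1.05

    def test_same_seed_is_bit_identical(self, context):
        settings = McmcSettings(n_iterations=2_000, burn_in=1_000, thin=10,
                                n_chains=2, seed=9)
        a = run_mcmc(context, settings)
        b = run_mcmc(context, settings)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.log_posterior, b.log_posterior)

    def test_flat_target_on_box_is_uniform(self):
        """Kolmogorov-Smirnov check of marginal uniformity on [0,1]^2."""
        def log_post(x):
            return 0.0 if np.all((x >= 0) & (x <= 1)) else -np.inf

        settings = McmcSettings(n_iterations=120_000, burn_in=20_000, thin=100,
                                n_chains=2, seed=12)
        chains = run_mcmc(log_post, settings,
                          init=[np.array([0.3, 0.6]), np.array([0.7, 0.2])])
        pooled = chains.pooled()
        for axis in range(2):
            assert kstest(pooled[:, axis], "uniform").pvalue > 0.01

    def test_retained_count_formula(self, context):
        settings = McmcSettings(n_iterations=3_000, burn_in=1_000, thin=20,
                                n_chains=2, seed=1)
        chains = run_mcmc(context, settings)
        assert chains.draws.shape[1] == (3_000 - 1_000) // 20

    def test_misconfigured_settings_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcSettings(n_iterations=100, burn_in=50, thin=7)


class TestGelmanRubin:
    def test_iid_chains_from_same_target_converge(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 10_000))
        assert gelman_rubin(chains) < 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 5_000)) + np.array([[0.0], [10.0]])
        assert gelman_rubin(chains) > 3.0

    def test_matches_textbook_formula(self):
        """Independent oracle: the between/within variance formula
        written out longhand."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 100, 4)) * [1.0, 2.0, 0.5, 3.0]
        m, n, d = x.shape
        for j in range(d):
            means = [x[c, :, j].mean() for c in range(m)]
            W = np.mean([x[c, :, j].var(ddof=1) for c in range(m)])
            B = n * np.var(means, ddof=1)
            expected = np.sqrt(((n - 1) / n * W + B / n) / W)
            assert gelman_rubin(x)[j] == pytest.approx(expected, abs=1e-12)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestDic:
    @staticmethod
    def _quad_loglik(theta):
        return float(-0.5 * np.sum((np.asarray(theta) - 1.0) ** 2))

    def test_degenerate_posterior_has_zero_pd(self):
        chains = _mock_chainset(np.full((2, 200, 3), 0.7))
        res = dic(chains, self._quad_loglik)
        assert res.p_d == pytest.approx(0.0, abs=1e-12)
        assert res.dic == pytest.approx(-2 * self._quad_loglik(np.full(3, 0.7)))

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        draws = rng.normal(1.0, 0.3, size=(2, 500, 3))
        chains = _mock_chainset(draws)
        res = dic(chains, self._quad_loglik)
        pooled = draws.reshape(-1, 3)
        dbar = np.mean([-2 * self._quad_loglik(t) for t in pooled])
        pd_ = dbar - (-2 * self._quad_loglik(pooled.mean(axis=0)))
        assert res.dic == pytest.approx(dbar + pd_, abs=1e-8)
        assert res.p_d > 0


class TestPosteriorSummary:
    def test_odd_length_median(self):
        chains = _mock_chainset(np.array([[1.0, 2, 3, 4, 5]]).reshape(1, 5, 1))
        med, lo, hi = posterior_summary(chains, 0)
        assert med == 3.0

    def test_constant_draws_collapse_interval(self):
        chains = _mock_chainset(np.full((2, 50, 1), 2.5))
        assert posterior_summary(chains, 0) == (2.5, 2.5, 2.5)

    def test_matches_sort_based_quantiles(self):
        rng = np.random.default_rng(4)
        draws = rng.gamma(2.0, size=(3, 400, 1))
        chains = _mock_chainset(draws)
        med, lo, hi = posterior_summary(chains, lambda t: float(np.exp(t[0])))
        vals = np.sort(np.exp(draws.reshape(-1)))
        assert med == pytest.approx(np.quantile(vals, 0.5))
        assert lo == pytest.approx(np.quantile(vals, 0.025))
        assert hi == pytest.approx(np.quantile(vals, 0.975))

    def test_invariant_to_chain_order(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(size=(3, 200, 2))
        a = posterior_summary(_mock_chainset(draws), 1)
        b = posterior_summary(_mock_chainset(draws[::-1]), 1)
        assert a == b


class TestPosteriorPredictive:
    def test_bands_are_nested(self, context, design):
        theta = context.active_vector(design.truth.to_array())
        rng = np.random.default_rng(6)
        draws = theta[None, None, :] * (1 + 0.01 * rng.normal(size=(2, 100, theta.size)))
        chains = _mock_chainset(draws, names=context.active_names)
        bands = posterior_predictive(chains, context, seed=0, require_converged=False)
        for q in (bands.prevalence, bands.incidence):
            assert np.all(q[:, 0] <= q[:, 1]) and np.all(q[:, 1] <= q[:, 3]) \
                and np.all(q[:, 3] <= q[:, 4])

    def test_vanishing_noise_collapses_to_model_prediction(self, design, mortality,
                                                           population):
        """tau^2 -> 0 and n -> infinity: the bands shrink onto the
        deterministic bin predictions."""
        from mmnathist.cohort import AgeGrid
        from mmnathist.likelihood import ModelContext, PrevalenceObservation
        from mmnathist.synthetic import generate_truth_curves, sample_observations

        curves = generate_truth_curves(design)
        prev, inc = sample_observations(curves, design)
        prev_big = [PrevalenceObservation(o.a_lo, o.a_hi, o.stratum,
                                          y=o.y, n=1_000_000_000) for o in prev]
        ctx = ModelContext(mortality, population, AgeGrid(), prev_big, inc)
        theta = design.truth.to_array()
        theta[-1] = 1e-12  # tau2 -> 0
        draws = np.tile(ctx.active_vector(theta), (1, 50, 1))
        chains = _mock_chainset(draws, names=ctx.active_names)
        bands = posterior_predictive(chains, ctx, seed=1, require_converged=False)
        pbar, ibar = ctx.predicted_bins(theta)
        assert np.allclose(bands.prevalence[:, 2], pbar, rtol=1e-3)
        assert np.allclose(bands.prevalence[:, 4] - bands.prevalence[:, 0], 0.0,
                           atol=5e-5)
        assert np.allclose(bands.incidence[:, 2], ibar, rtol=1e-6)

    def test_unconverged_chains_refused(self, context, design):
        theta = context.active_vector(design.truth.to_array())
        rng = np.random.default_rng(7)
        noise = 1 + 1e-4 * rng.normal(size=(2, 50, theta.size))
        draws = np.stack([np.tile(theta, (50, 1)), np.tile(theta * 1.5, (50, 1))]) * noise
        chains = _mock_chainset(draws, names=context.active_names)
        with pytest.raises(RuntimeError):
            posterior_predictive(chains, context, seed=0)
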