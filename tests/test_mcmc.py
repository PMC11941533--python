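import numpy as np
import pytest
from scipy.stats import norm

from spatialfrailty import (
    BaselineParams,
    GeneratorConfig,
    ParameterState,
    PriorSpec,
    SamplerConfig,
    cohort_from_frame,
    generate_cohort,
    geyer_ess,
    gibbs_sigma2,
    log_posterior,
    loglik,
    run_mcmc,
    trace_summary,
)

from conftest import make_frame

QUICK = SamplerConfig(n_burn=200, n_keep=200, seed=5)


class TestLogPosterior:
    def test_beta_difference_is_loglik_plus_prior_difference(self, tiny_cohort):
        b = BaselineParams.weibull(1.0, 20.0)
        priors = PriorSpec()
        w = np.zeros(2)
        s0 = ParameterState(baseline=b, beta=np.zeros(5), frailty=w)
        beta1 = np.array([0.0, 0.3, 0.0, 0.0, 0.0])
        s1 = ParameterState(baseline=b, beta=beta1, frailty=w)
        got = log_posterior(s1, tiny_cohort, priors) - log_posterior(s0, tiny_cohort, priors)
        sd = np.sqrt(priors.beta_variance)
        expected = (
            loglik(tiny_cohort, s1)
            - loglik(tiny_cohort, s0)
            + norm.logpdf(0.3, 0, sd)
            - norm.logpdf(0.0, 0, sd)
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_frailty_prior_term_at_zero_frailties(self, tiny_cohort):
        # moving one w_g off zero changes the posterior by the loglik change
        # plus the Gaussian prior log-density change at scale sigma
        b = BaselineParams.weibull(1.0, 20.0)
        sigma = 0.5
        s0 = ParameterState(baseline=b, beta=np.zeros(5), frailty=np.zeros(2),
                            frailty_sd=sigma)
        s1 = ParameterState(baseline=b, beta=np.zeros(5),
                            frailty=np.array([0.4, 0.0]), frailty_sd=sigma)
        got = log_posterior(s1, tiny_cohort) - log_posterior(s0, tiny_cohort)
        expected = (
            loglik(tiny_cohort, s1)
            - loglik(tiny_cohort, s0)
            + norm.logpdf(0.4, 0, sigma)
            - norm.logpdf(0.0, 0, sigma)
        )
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invalid_state_returns_minus_inf_not_raise(self, tiny_cohort):
        s = ParameterState(
            baseline=BaselineParams.weibull(1.0, 1.0),
            beta=np.array([np.inf, 0, 0, 0, 0]),
            frailty=np.zeros(2),
        )
        assert log_posterior(s, tiny_cohort) == -np.inf


class TestGibbsSigma2:
    def test_zero_frailties_reduce_to_prior_parameters(self):
        # w = 0 => draw from InvGamma(a0 + G/2, b0); check via the MC mean
        rng = np.random.default_rng(0)
        a0, b0, G = 3.0, 2.0, 6
        draws = np.array(
            [gibbs_sigma2(np.zeros(G), a0, b0, rng) for _ in range(100_000)]
        )
        expected_mean = b0 / (a0 + G / 2 - 1)
        assert np.mean(draws) == pytest.approx(expected_mean, rel=0.02)

    def test_moment_oracle_with_nonzero_frailties(self):
        rng = np.random.default_rng(1)
        w = np.array([0.5, -0.2, 0.1])
        a0, b0 = 4.0, 1.0
        a_post = a0 + 1.5
        b_post = b0 + np.sum(w**2) / 2
        draws = np.array([gibbs_sigma2(w, a0, b0, rng) for _ in range(100_000)])
        assert np.mean(draws) == pytest.approx(b_post / (a_post - 1), rel=0.02)

    def test_seeded_reproducibility(self):
        d1 = gibbs_sigma2(np.ones(4), 2.5, 1.0, np.random.default_rng(7))
        d2 = gibbs_sigma2(np.ones(4), 2.5, 1.0, np.random.default_rng(7))
        assert d1 == d2

    def test_prior_only_chain_recovers_prior_moments(self):
        # alternate w | sigma2 and sigma2 | w with the likelihood switched
        # off: the sigma2 marginal must be its InvGamma(a0, b0) prior
        rng = np.random.default_rng(11)
        a0, b0, G = 4.0, 2.0, 6
        sigma2 = b0 / (a0 - 1)
        vals = np.empty(40_000)
        for i in range(vals.size):
            w = np.sqrt(sigma2) * rng.standard_normal(G)
            sigma2 = gibbs_sigma2(w, a0, b0, rng)
            vals[i] = sigma2
        assert np.mean(vals) == pytest.approx(b0 / (a0 - 1), rel=0.05)


class TestRunMcmc:
    def test_seeded_determinism_bit_identical(self, tiny_cohort):
        cohort = cohort_from_frame(
            make_frame(
                list(np.linspace(5, 100, 30)),
                [1, 0] * 15,
                blocks=["A", "B", "C"] * 10,
            )
        )
        s1 = run_mcmc(cohort, "weibull", config=QUICK)
        s2 = run_mcmc(cohort, "weibull", config=QUICK)
        np.testing.assert_array_equal(s1.beta_draws, s2.beta_draws)
        np.testing.assert_array_equal(s1.frailty_draws, s2.frailty_draws)
        np.testing.assert_array_equal(s1.sigma2_draws, s2.sigma2_draws)
        assert s1.acceptance_rate == s2.acceptance_rate

    def test_zero_event_cohort_raises_informative_error(self):
        cohort = cohort_from_frame(make_frame([1.0, 2.0], [0, 0]))
        with pytest.raises(ValueError, match="uninformative"):
            run_mcmc(cohort, "weibull", config=QUICK)

    def test_pointwise_ll_rows_match_state_at_draw(self, fitted_weibull, default_cohort):
        from spatialfrailty import pointwise_loglik

        m = 17
        np.testing.assert_allclose(
            fitted_weibull.pointwise_ll[m],
            pointwise_loglik(default_cohort, fitted_weibull.state_at(m)),
            rtol=1e-10,
        )

    def test_posterior_matches_ensemble_sampler_cross_check(self):
        # independent route: emcee's affine-invariant ensemble sampler on
        # the identical unconstrained log posterior; posterior means of the
        # coefficients must agree within combined Monte-Carlo error
        emcee = pytest.importorskip("emcee")
        cohort, _ = generate_cohort(GeneratorConfig(n=120, seed=9))
        priors = PriorSpec()
        ours = run_mcmc(
            cohort, "weibull",
            config=SamplerConfig(n_burn=1500, n_keep=4000, seed=2),
        )

        from spatialfrailty.mcmc import _Workspace

        ws = _Workspace(cohort, "weibull")
        G = ws.G

        def logpost(x):
            theta_b, beta, w, log_s2 = x[:2], x[2:7], x[7 : 7 + G], x[7 + G]
            s2 = np.exp(log_s2)
            ll = ws.loglik(theta_b, beta, w)
            if not np.isfinite(ll):
                return -np.inf
            lp = (
                ll
                - np.sum(theta_b**2) / (2 * priors.baseline_variance)
                - np.sum(beta**2) / (2 * priors.beta_variance)
                - np.sum(w**2) / (2 * s2)
                - G / 2 * log_s2
                # InvGamma(a0,b0) on s2 plus the log-scale Jacobian
                - (priors.sigma2_a0) * log_s2
                - priors.sigma2_b0 / s2
            )
            return lp if np.isfinite(lp) else -np.inf

        ndim = 8 + G
        rng = np.random.default_rng(0)
        center = np.concatenate(
            [ours.baseline_draws.mean(0), ours.beta_draws.mean(0),
             ours.frailty_draws.mean(0), [np.mean(np.log(ours.sigma2_draws))]]
        )
        p0 = center + 0.05 * rng.standard_normal((4 * ndim, ndim))
        sampler = emcee.EnsembleSampler(4 * ndim, ndim, logpost)
        state = sampler.run_mcmc(p0, 2500, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)

        ours_mean = ours.beta_draws.mean(0)
        ref_mean = chain[:, 2:7].mean(0)
        ref_sd = chain[:, 2:7].std(0)
        n_eff = 200.0  # conservative effective sizes for both chains
        tol = 3.0 * ref_sd * np.sqrt(2.0 / n_eff)
        assert np.all(np.abs(ours_mean - ref_mean) < np.maximum(tol, 0.05))

    def test_weibull_shape_posterior_covers_one_on_exponential_data(self):
        # exponential data are Weibull with shape 1: the 95% interval for
        # the shape should cover 1 in most seeded replicates
        hits = 0
        for rep in range(5):
            config = GeneratorConfig(
                n=400,
                seed=300 + rep,
                baseline=BaselineParams.weibull(1.0, 1000.0),
            )
            cohort, _ = generate_cohort(config)
            s = run_mcmc(cohort, "weibull",
                         config=SamplerConfig(n_burn=500, n_keep=500, seed=rep))
            shape_chain = np.exp(s.baseline_draws[:, 0])
            lo, hi = np.quantile(shape_chain, [0.025, 0.975])
            hits += lo <= 1.0 <= hi
        assert hits >= 4


class TestTraceSummary:
    def test_iid_normal_chain_ess_near_n(self, fitted_weibull):
        rng = np.random.default_rng(123)
        ess, flag = geyer_ess(rng.standard_normal(1000))
        assert flag == ""
        assert 600 <= ess <= 1400

    def test_alternating_chain_flagged_superefficient(self):
        chain = np.tile([1.0, -1.0], 500)
        ess, flag = geyer_ess(chain)
        assert flag == "superefficient"
        assert ess > 1000
        assert np.mean(chain) == pytest.approx(0.0)

    def test_constant_chain_flagged_degenerate(self):
        ess, flag = geyer_ess(np.full(500, 2.5))
        assert flag == "degenerate"
        assert ess == 500

    def test_summary_covers_all_monitored_parameters(self, fitted_weibull):
        tab = trace_summary(fitted_weibull)
        names = set(tab["parameter"])
        assert {"shape", "scale", "sigma"} <= names
        assert set(fitted_weibull.covariate_names) <= names
        assert {f"w_{b}" for b in fitted_weibull.blocks} <= names
        assert (tab["ess"] > 0).all()

    def test_too_short_chain_rejected(self, fitted_weibull):
        import dataclasses

        short = dataclasses.replace(
            fitted_weibull,
            baseline_draws=fitted_weibull.baseline_draws[:5],
            beta_draws=fitted_weibull.beta_draws[:5],
            frailty_draws=fitted_weibull.frailty_draws[:5],
            sigma2_draws=fitted_weibull.sigma2_draws[:5],
            pointwise_ll=fitted_weibull.pointwise_ll[:5],
        )
        with pytest.raises(ValueError):
            trace_summary(short)
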