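import numpy as np
import pytest
from scipy import stats, optimize

import riaftbart as rb
from riaftbart.model import (center_responses, sample_truncated_normal_lower,
                             solve_lambda, update_alpha, update_random_intercepts,
                             update_tau2)

from conftest import make_lognormal_data


class TestTruncatedNormal:
    def test_support_constraint(self, rng):
        lo = rng.standard_normal(500)
        d = sample_truncated_normal_lower(0.0, 1.0, lo, rng)
        assert np.all(d > lo)

    def test_untruncated_limit_mean(self, rng):
        d = sample_truncated_normal_lower(np.full(100_000, 2.0), 1.0, -50.0, rng)
        assert d.mean() == pytest.approx(2.0, abs=3 * 1 / np.sqrt(100_000))

    def test_truncation_at_mean_matches_analytic_moments(self, rng):
        # E[X | X > mu] = mu + sigma phi(0)/(1 - Phi(0))
        mu, sd = 1.0, 2.0
        d = sample_truncated_normal_lower(np.full(100_000, mu), sd, mu, rng)
        expected = mu + sd * stats.norm.pdf(0) / 0.5
        assert d.mean() == pytest.approx(expected, abs=0.02)

    def test_far_tail_is_finite_and_ordered(self, rng):
        d = sample_truncated_normal_lower(0.0, 1.0, np.full(20_000, 8.0), rng)
        assert np.all(np.isfinite(d)) and np.all(d > 8.0)
        # tail draws concentrate just above the truncation point
        assert np.quantile(d, 0.9) < 8.5

    def test_monotone_in_truncation_point_at_matched_seed(self):
        d_lo = sample_truncated_normal_lower(
            np.zeros(1000), 1.0, 0.5, np.random.default_rng(4))
        d_hi = sample_truncated_normal_lower(
            np.zeros(1000), 1.0, 1.5, np.random.default_rng(4))
        assert np.all(d_hi >= d_lo)


class TestCentering:
    def test_uncensored_mle_is_sample_moments(self):
        y = np.exp(np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0]))
        data = rb.ClusteredSurvivalData(
            y=y, delta=np.ones(6, int), a=[1, 2, 1, 2, 1, 2],
            cluster=[1, 1, 1, 2, 2, 2], x=np.zeros((6, 1)))
        cent = center_responses(data)
        assert cent.mu_hat == pytest.approx(0.0, abs=1e-5)
        assert cent.sigma_hat == pytest.approx(np.sqrt(2 / 3), abs=1e-4)

    def test_centered_log_mean_identity(self):
        data, _ = make_lognormal_data(n=200, seed=1)
        cent = center_responses(data)
        ev = data.delta == 1
        assert np.log(cent.y_cent[ev]).mean() == pytest.approx(
            np.log(data.y[ev]).mean() - cent.mu_hat, abs=1e-12)

    def test_all_censored_errors(self):
        data, _ = make_lognormal_data(n=50, seed=1)
        data.delta[:] = 0
        with pytest.raises(ValueError, match="censored"):
            center_responses(data)

    def test_matches_censored_likelihood_grid_oracle(self):
        rng = np.random.default_rng(8)
        n = 500
        logT = 1.0 + 0.8 * rng.standard_normal(n)
        C = np.exp(1.0 + 0.8 * rng.standard_normal(n) + 0.4)
        y = np.minimum(np.exp(logT), C)
        delta = (np.exp(logT) < C).astype(int)
        data = rb.ClusteredSurvivalData(y=y, delta=delta, a=1 + np.arange(n) % 2,
                                        cluster=1 + np.arange(n) % 3,
                                        x=rng.standard_normal((n, 1)))
        cent = center_responses(data)

        def nll(p):
            mu, ls = p
            s = np.exp(ls)
            z = (np.log(y) - mu) / s
            return -(np.sum(stats.norm.logpdf(z[delta == 1]) - ls)
                     + np.sum(stats.norm.logsf(z[delta == 0])))

        opt = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10})
        assert cent.mu_hat == pytest.approx(opt.x[0], abs=1e-3)
        assert cent.sigma_hat == pytest.approx(np.exp(opt.x[1]), abs=1e-3)


class TestInitialization:
    def test_lambda_solution_satisfies_cdf_identity(self):
        for sigma0, nu in [(1.0, 3.0), (0.5, 3.0), (2.0, 5.0)]:
            lam = solve_lambda(sigma0, nu, 0.9)
            p = stats.invgamma.cdf(sigma0 ** 2, nu / 2, scale=nu * lam / 2)
            assert p == pytest.approx(0.9, abs=1e-10)

    def test_initial_constants_and_z_offset(self):
        data, _ = make_lognormal_data(n=200, seed=2, censor_frac=0.3)
        model = rb.RiAFTBART(data, n_trees=5)
        state, hyper, cent = model.initialize_state(np.random.default_rng(0))
        assert state.tau2 == 1.0 and state.alpha == 1.0
        cens = data.delta == 0
        sigma0 = np.sqrt(state.sigma2)
        np.testing.assert_allclose(state.z[cens],
                                   np.log(cent.y_cent[cens]) + 0.1 * sigma0)
        np.testing.assert_allclose(state.z[~cens], np.log(cent.y_cent[~cens]))
        assert hyper.xi == pytest.approx(4 * cent.sigma_hat)

    def test_b0_is_cluster_mean_residual(self):
        data, _ = make_lognormal_data(n=200, K=4, seed=2, censor_frac=0.0)
        model = rb.RiAFTBART(data, n_trees=5)
        state, _, _ = model.initialize_state(np.random.default_rng(0))
        from riaftbart.model import _aft_linear_residuals
        resid = _aft_linear_residuals(data)
        for k in range(4):
            assert state.b[k] == pytest.approx(resid[data.cluster == k + 1].mean())


class TestConditionals:
    def test_random_intercept_plug_in_moments(self, rng):
        # n_k=1, residual 1, tau2*alpha=1, sigma2=1 -> N(1/2, 1/2)
        draws = np.array([update_random_intercepts(
            np.array([1.0, 0.0]), np.zeros(2), np.array([0, 1]), 2,
            1.0, 1.0, 1.0, rng)[0] for _ in range(50_000)])
        assert draws.mean() == pytest.approx(0.5, abs=0.01)
        assert draws.var() == pytest.approx(0.5, abs=0.01)

    def test_random_intercept_shrinks_to_zero_as_tau2_vanishes(self, rng):
        b = update_random_intercepts(np.full(50, 3.0), np.zeros(50),
                                     np.zeros(50, int), 1, 1e-12, 1.0, 1.0, rng)
        assert abs(b[0]) < 1e-4

    def test_alpha_conditional_is_conjugate_inverse_gamma(self, rng):
        # b of length K: IG(K/2 + 1, 1 + sum b^2 / (2 tau2))
        b = np.array([1.0, -1.0, 0.5])
        draws = np.array([update_alpha(b, 2.0, rng) for _ in range(20_000)])
        scale = 1 + (b @ b) / 4.0
        p = stats.kstest(draws, stats.invgamma(len(b) / 2 + 1, scale=scale).cdf).pvalue
        assert p > 0.01

    def test_tau2_conditional_scale(self, rng):
        b = np.array([1.0, 2.0])
        draws = np.array([update_tau2(b, 0.5, rng) for _ in range(20_000)])
        p = stats.kstest(draws, stats.invgamma(2.0, scale=(b @ b) / 1.0 + 1).cdf).pvalue
        assert p > 0.01

    def test_alpha_tau2_product_stable_across_initializations(self):
        # parameter-expansion invariance: the Gibbs marginal of alpha*tau2 at
        # fixed b does not depend on the starting parameterization
        b = np.array([0.8, -0.5, 1.2, 0.1])

        def chain(a0, t0, seed):
            rng = np.random.default_rng(seed)
            a, t = a0, t0
            out = []
            for _ in range(10_000):
                a = update_alpha(b, t, rng)
                t = update_tau2(b, a, rng)
                out.append(a * t)
            return np.array(out[1000:])

        c1, c2 = chain(1.0, 1.0, 0), chain(10.0, 0.1, 1)
        assert stats.ks_2samp(c1[::10], c2[::10]).pvalue > 0.01

    def test_domain_errors(self, rng):
        with pytest.raises(ValueError):
            update_alpha(np.ones(2), -1.0, rng)
        with pytest.raises(ValueError):
            update_tau2(np.ones(2), 0.0, rng)


class TestFit:
    def test_same_seed_identical_draws(self):
        data, _ = make_lognormal_data(n=120, K=3, seed=5)
        r1 = rb.RiAFTBART(data, n_trees=10).fit(draws=30, burn=10, seed=42)
        r2 = rb.RiAFTBART(data, n_trees=10).fit(draws=30, burn=10, seed=42)
        np.testing.assert_array_equal(r1.f_draws, r2.f_draws)
        np.testing.assert_array_equal(r1.tau2_draws, r2.tau2_draws)

    def test_fit_recovers_linear_signal(self, small_fit):
        data, truth, res = small_fit
        # posterior mean of f correlates with the true regression surface
        f_hat = np.zeros(data.n)
        for j, a in enumerate(res.treatments):
            in_a = data.a == a
            f_hat[in_a] = res.f_draws[:, j, :].mean(axis=0)[in_a]
        r = np.corrcoef(f_hat, truth["f_true"])[0, 1]
        assert r > 0.9

    def test_sigma_recovered(self, small_fit):
        _, truth, res = small_fit
        sig = np.sqrt(res.sigma2_draws)
        assert abs(sig.mean() - truth["sigma"]) < 3 * sig.std() + 0.05

    def test_draws_include_centering_offset(self, small_fit):
        data, _, res = small_fit
        # f draws are on the absolute log-month scale: their average must sit
        # near the mean observed log time, not near zero
        assert abs(res.f_draws.mean() - np.log(data.y).mean()) < 1.5

    def test_invalid_draws_rejected(self):
        data, _ = make_lognormal_data(n=60, K=2, seed=5)
        with pytest.raises(ValueError):
            rb.RiAFTBART(data).fit(draws=0, seed=1)

    def test_results_save_load_round_trip(self, small_fit, tmp_path):
        _, _, res = small_fit
        path = tmp_path / "draws.npz"
        res.save(path)
        res2 = rb.RiAFTBARTResults.load(path)
        np.testing.assert_array_equal(res2.f_draws, res.f_draws)
        r1 = res.cate(1, 3)
        r2 = res2.cate(1, 3)
        assert r1.estimate == r2.estimate and r1.ci == r2.ci
        c1, c2 = res.catt(1, 3), res2.catt(1, 3)
        assert c1.estimate == c2.estimate


class TestDiagnostics:
    def test_iid_draws_have_unit_rhat(self):
        data, _ = make_lognormal_data(n=80, K=2, seed=6)
        res = rb.RiAFTBART(data, n_trees=5).fit(draws=200, burn=50, seed=0)
        res.tau2_draws = np.random.default_rng(0).gamma(2.0, size=200)  # iid fake
        diag = res.diagnostics()
        rhat = diag.loc[diag.parameter == "tau", "rhat"].item()
        assert abs(rhat - 1.0) < 0.05

    def test_correlated_chain_has_small_ess(self):
        data, _ = make_lognormal_data(n=80, K=2, seed=6)
        res = rb.RiAFTBART(data, n_trees=5).fit(draws=400, burn=50, seed=0)
        t = np.linspace(0, 1, 400)
        res.sigma2_draws = 1.0 + t + 0.001 * np.random.default_rng(0).standard_normal(400)
        diag = res.diagnostics()
        ess = diag.loc[diag.parameter == "sigma", "ess"].item()
        assert ess < 40

    def test_ess_matches_autocorrelation_sum_oracle(self):
        rng = np.random.default_rng(3)
        # AR(1) chain with known autocorrelation
        rho, n = 0.6, 20_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.standard_normal()

        import arviz as az
        ess_az = float(az.ess(x.reshape(2, -1)))
        # oracle: n / (1 + 2 sum_k rho_k), truncated at first negative pair sum
        xc = x - x.mean()
        acf = np.correlate(xc, xc, "full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
        s, k = 0.0, 1
        while k + 1 < 500 and acf[k] + acf[k + 1] > 0:
            s += acf[k] + acf[k + 1]
            k += 2
        ess_oracle = n / (1 + 2 * s)
        assert ess_az == pytest.approx(ess_oracle, rel=0.10)

    def test_too_few_draws_rejected(self, small_fit):
        _, _, res = small_fit
        import copy
        short = copy.copy(res)
        short.f_draws = res.f_draws[:5]
        short.tau2_draws = res.tau2_draws[:5]
        with pytest.raises(ValueError):
            short.diagnostics()


def test_param_expansion_improves_tau2_mixing():
    # ESS of tau^2 with the alpha expansion should not be worse than without
    import arviz as az
    data, _ = make_lognormal_data(n=200, K=8, tau=0.3, seed=9)
    r_px = rb.RiAFTBART(data, n_trees=10).fit(draws=400, burn=100, seed=1)
    r_no = rb.RiAFTBART(data, n_trees=10).fit(draws=400, burn=100, seed=1,
                                              param_expansion=False)
    ess_px = float(az.ess(np.log(r_px.tau2_draws * r_px.alpha_draws).reshape(2, -1)))
    ess_no = float(az.ess(np.log(r_no.tau2_draws).reshape(2, -1)))
    assert ess_px > 0.5 * ess_no  # expansion must not hurt mixing materially


def test_censoring_coherence_in_imputation():
    # increasing a subject's censoring time never decreases the posterior mean
    # of its imputed latent log time (matched seeds)
    data, _ = make_lognormal_data(n=150, K=3, seed=11, censor_frac=0.4)
    cens_idx = int(np.flatnonzero(data.delta == 0)[0])
    means = []
    for factor in (1.0, 2.0):
        d2 = data.replace_times(np.where(np.arange(data.n) == cens_idx,
                                         data.y * factor, data.y))
        res = rb.RiAFTBART(d2, n_trees=10).fit(draws=100, burn=50, seed=3)
        j = res.arm_index(d2.a[cens_idx])
        means.append(res.f_draws[:, j, cens_idx].mean())
    # higher censoring point -> imputations truncated higher -> fitted value
    # for that subject cannot decrease materially
    assert means[1] >= means[0] - 0.1


def test_extreme_value_residuals_give_comparable_cate_bias():
    # fitting data whose residuals are extreme-value (Weibull AFT) yields
    # log-time CATE bias comparable to lognormal-residual data
    from dataclasses import replace
    biases = {}
    for residual in ("weibull", "lognormal"):
        cfg = replace(rb.DGPConfig(K=5, n_k=120), residual=residual,
                      xi0=(2.0, 1.25), censoring_target=0.2)
        sim = rb.simulate_dataset(cfg, np.random.default_rng(21))
        truth = rb.dgp.sample_true_cate(sim, scale="logtime")
        res = rb.RiAFTBART(sim.data, n_trees=30).fit(draws=250, burn=150, seed=2)
        biases[residual] = np.mean([abs(res.cate(*p).estimate - truth[p])
                                    for p in truth])
    assert biases["weibull"] < biases["lognormal"] + 0.25
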