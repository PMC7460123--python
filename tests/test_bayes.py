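import math

import numpy as np
import pytest
from scipy import integrate, stats

from pvsignal.core import DrugEventTable, TwoByTwo
from pvsignal.bayes import (
    GPS_DEFAULT_START,
    GpsPrior,
    bcpnn,
    fit_gps_prior,
    gps_eb05,
    gps_fit,
    gps_marginal_loglik,
    new_ic,
    sb,
)


class TestGpsFit:
    def test_recovers_single_gamma_prior(self, rng):
        # lambda ~ Gamma(2, 2) everywhere: the mixture should put nearly all
        # weight on a component close to (2, 2)
        e = rng.gamma(1.5, 2.0, size=(300, 500))
        lam = rng.gamma(2.0, 1 / 2.0, size=(300, 500))
        n = rng.poisson(lam * e)
        prior = fit_gps_prior(n, e)
        shape, rate = (
            (prior.alpha1, prior.beta1) if prior.w >= 0.5 else (prior.alpha2, prior.beta2)
        )
        assert shape == pytest.approx(2.0, rel=0.2)
        assert rate == pytest.approx(2.0, rel=0.2)

    def test_fit_beats_default_start(self, rng):
        e = rng.gamma(2, 1, size=(40, 50)) + 0.05
        n = rng.poisson(e * rng.gamma(1.0, 1.0, size=(40, 50)))
        prior = fit_gps_prior(n, e, starts=3)
        assert prior.loglik >= gps_marginal_loglik(n, e, GpsPrior(*GPS_DEFAULT_START)) - 1e-6

    def test_loglik_invariant_under_component_swap(self, rng):
        e = rng.gamma(2, 1, size=(20, 20)) + 0.05
        n = rng.poisson(e)
        p = GpsPrior(0.4, 0.3, 2.5, 3.5, 0.27)
        swapped = GpsPrior(2.5, 3.5, 0.4, 0.3, 1 - 0.27)
        assert gps_marginal_loglik(n, e, p) == pytest.approx(
            gps_marginal_loglik(n, e, swapped), rel=1e-12
        )

    def test_table_wrapper_uses_all_cells(self, rng):
        counts = rng.poisson(2.0, size=(15, 12))
        table = DrugEventTable(counts, [f"a{i}" for i in range(15)],
                               [f"d{j}" for j in range(12)])
        prior = gps_fit(table, starts=2)
        assert prior.loglik < 0 and 0 < prior.w < 1

    def test_empty_table_rejected(self):
        table = DrugEventTable(np.zeros((2, 2)), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            gps_fit(table)

    def test_compiled_and_reference_likelihood_paths_agree(self, rng):
        import pvsignal.bayes as bayes_mod
        from scipy import special

        if not bayes_mod._HAVE_NUMBA:
            pytest.skip("compiled kernel not available")
        e = rng.gamma(2, 1, size=2000) + 0.05
        n = rng.poisson(e * rng.gamma(1.0, 1.0, size=2000)).astype(float)
        n_, e_, nu, inv, const = bayes_mod._prepare_cells(n, e)
        log_e = np.where(n_ > 0, np.log(np.where(e_ > 0, e_, 1.0)), 0.0)
        theta = np.array([np.log(0.3), np.log(0.2), np.log(1.5), np.log(3.0),
                          special.logit(0.4)])
        args = (n_, e_, log_e, nu, inv, const)
        f1, g1 = bayes_mod._mixture_negloglik_grad(theta, *args)
        bayes_mod._HAVE_NUMBA = False
        try:
            f2, g2 = bayes_mod._mixture_negloglik_grad(theta, *args)
        finally:
            bayes_mod._HAVE_NUMBA = True
        assert f1 == pytest.approx(f2, rel=1e-10)
        assert np.allclose(g1, g2, rtol=1e-8)


class TestGpsPosterior:
    def test_degenerate_prior_matches_gamma_quantile(self):
        # w ~ 1, no data, vanishing expected count: posterior = prior Gamma(2,2)
        prior = GpsPrior(2.0, 2.0, 2.0, 2.0, 0.5)
        post = gps_eb05(0, 1e-12, prior)
        assert post.eb05 == pytest.approx(stats.gamma.ppf(0.05, 2, scale=0.5), abs=1e-9)

    def test_eb05_strictly_increasing_in_count(self):
        prior = GpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        values = [gps_eb05(n, 2.0, prior).eb05 for n in range(51)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_posterior_cdf_at_eb05_is_five_percent(self, rng):
        # oracle: independent numerical integration of the mixture density
        for _ in range(30):
            prior = GpsPrior(*np.exp(rng.normal(0, 1, size=4)),
                             float(rng.uniform(0.05, 0.95)))
            n = int(rng.integers(0, 30))
            e = float(rng.gamma(2, 2) + 0.01)
            post = gps_eb05(n, e, prior)
            cdf, err = integrate.quad(
                lambda lam: post.w_star * stats.gamma.pdf(lam, post.shape1, scale=1 / post.rate1)
                + (1 - post.w_star) * stats.gamma.pdf(lam, post.shape2, scale=1 / post.rate2),
                0.0, post.eb05,
            )
            assert abs(cdf - 0.05) < 1e-6

    def test_posterior_parameters_are_conjugate_updates(self):
        prior = GpsPrior(0.5, 0.7, 3.0, 4.0, 0.4)
        post = gps_eb05(7, 1.3, prior)
        assert (post.shape1, post.rate1) == (0.5 + 7, 0.7 + 1.3)
        assert (post.shape2, post.rate2) == (3.0 + 7, 4.0 + 1.3)

    def test_nonpositive_expected_count_rejected(self):
        with pytest.raises(ValueError):
            gps_eb05(1, 0.0, GpsPrior(1, 1, 1, 1, 0.5))

    def test_signal_rule_monotone_in_count(self):
        prior = GpsPrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        flags = [gps_eb05(n, 1.0, prior).is_signal(2.0) for n in range(0, 40, 5)]
        assert flags == sorted(flags)


class TestBcpnn:
    def test_all_zero_counts_give_zero_ic(self):
        res = bcpnn(TwoByTwo(0, 0, 0, 0))
        assert res.gamma_term == pytest.approx(4.0)
        assert res.mean_ic == pytest.approx(0.0)

    def test_mean_vanishes_under_asymptotic_independence(self):
        # n_ij n_.. = n_i. n_.j scaled up by powers of 10
        means = [
            bcpnn(TwoByTwo(5 * 10**k, 10 * 10**k, 10 * 10**k, 20 * 10**k)).mean_ic
            for k in range(1, 5)
        ]
        assert abs(means[-1]) < 1e-3
        assert all(abs(b) <= abs(a) + 1e-12 for a, b in zip(means, means[1:]))

    def test_matches_posterior_sampling(self, rng):
        # oracle: direct MC from the three independent beta posteriors
        for _ in range(10):
            n = int(rng.integers(500, 5000))
            ni = int(rng.integers(20, n // 4))
            nj = int(rng.integers(20, n // 4))
            a = int(rng.integers(1, min(ni, nj) // 2 + 2))
            res = bcpnn(TwoByTwo(a, ni, nj, n))
            gamma = res.gamma_term
            m = 200_000
            tij = rng.beta(1 + a, (gamma - 1) + n - a, size=m)
            ti = rng.beta(1 + ni, 1 + n - ni, size=m)
            tj = rng.beta(1 + nj, 1 + n - nj, size=m)
            ic_draws = np.log2(tij / (ti * tj))
            assert res.mean_ic == pytest.approx(ic_draws.mean(), abs=0.1)
            assert res.var_ic == pytest.approx(ic_draws.var(), abs=0.1)

    def test_lower_bound_construction(self):
        res = bcpnn(TwoByTwo(8, 40, 30, 5000))
        z = stats.norm.ppf(0.975)
        assert res.lower == pytest.approx(res.mean_ic - z * math.sqrt(res.var_ic))

    def test_signal_monotone_in_count(self):
        flags = [
            bcpnn(TwoByTwo(n, 100, 50, 10000)).is_signal(1.0) for n in range(0, 50, 5)
        ]
        assert flags == sorted(flags)


class TestGammaPosteriors:
    def test_new_ic_flat_case(self):
        post = new_ic(0, 0.0)
        assert (post.shape, post.rate) == (0.5, 0.5)
        assert post.mean_log2 == pytest.approx(0.0)

    def test_new_ic_hand_value(self):
        post = new_ic(15, 0.39)
        assert post.mean_log2 == pytest.approx(math.log2(15.5 / 0.89), rel=1e-9)
        # oracle: numeric quantile inversion
        assert stats.gamma.cdf(post.q025, 15.5, scale=1 / 0.89) == pytest.approx(0.025, abs=1e-9)
        assert stats.gamma.cdf(post.q975, 15.5, scale=1 / 0.89) == pytest.approx(0.975, abs=1e-9)

    def test_quantiles_bracket_mean(self, rng):
        for _ in range(25):
            post = new_ic(int(rng.integers(0, 40)), float(rng.gamma(2, 2)))
            assert post.q025 < post.mean < post.q975

    def test_sb_moment_bound_hand_values(self):
        p0 = sb(0, 0.0, alpha=0.5)
        assert p0.mean == pytest.approx(1.0)
        assert p0.shape / p0.rate**2 == pytest.approx(2.0)  # posterior variance
        assert p0.sb_lower == pytest.approx(1 - 1.645 * math.sqrt(2), rel=1e-9)
        p1 = sb(15, 0.39, alpha=0.5)
        assert p1.mean == pytest.approx(15.5 / 0.89, rel=1e-9)
        assert p1.sb_lower == pytest.approx(15.5 / 0.89 - 1.645 * math.sqrt(15.5) / 0.89, rel=1e-9)

    def test_sb_half_shares_new_ic_posterior(self, rng):
        # identical posterior distribution; only the interval rule differs
        for _ in range(20):
            n = int(rng.integers(0, 50))
            e = float(rng.gamma(2, 2))
            a, b = sb(n, e, alpha=0.5), new_ic(n, e)
            assert (a.shape, a.rate) == (b.shape, b.rate)

    def test_sb_signal_monotone_in_count(self):
        flags = [sb(n, 2.0).sb_lower > 2 for n in range(0, 40, 4)]
        assert flags == sorted(flags)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sb(1, 1.0, alpha=0.0)
        with pytest.raises(ValueError):
            new_ic(-1, 1.0)
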