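"""MCMC bookkeeping, diagnostics, DIC and model comparison."""

import numpy as np
import pandas as pd
import pytest

from multicity.inference import (
    DicResult,
    McmcSettings,
    compare_models,
    check_convergence,
    dic,
    dic_difference_band,
    effective_sample_size,
    preset,
    rhat,
    run_mcmc,
)
from multicity.models import ModelSpec
from multicity.priors import PriorConfig

from conftest import make_table


@pytest.fixture(scope="module")
def small_fit():
    rng = np.random.default_rng(10)
    table, adj = make_table(3, 6, rng)
    spec = ModelSpec("M2", PriorConfig())
    settings = McmcSettings(n_chains=2, n_iter=400, n_burnin=100, thin=3, seed=42)
    draws = run_mcmc(table, adj, spec, settings)
    return table, adj, spec, settings, draws


class TestSettings:
    def test_retained_bookkeeping_exact(self):
        s = McmcSettings(n_chains=2, n_iter=1003, n_burnin=100, thin=7, seed=0)
        assert s.n_retained == (1003 - 100) // 7

    def test_zero_retained_rejected(self):
        with pytest.raises(ValueError):
            McmcSettings(n_chains=1, n_iter=10, n_burnin=9, thin=5, seed=0)

    def test_paper_protocol_preset(self):
        s = preset("paper-protocol", seed=3)
        assert (s.n_chains, s.n_iter, s.n_burnin, s.thin) == (7, 100_000, 10_000, 126)
        assert s.n_retained == (100_000 - 10_000) // 126

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            preset("nope")


class TestRunMcmc:
    def test_draw_shapes_match_settings(self, small_fit):
        table, _, _, settings, draws = small_fit
        nd = settings.n_retained
        assert draws.get("b2").shape == (2, nd, 3)
        assert draws.get("alpha").shape == (2, nd)
        assert draws.deviance.shape == (2, nd)

    def test_same_seed_bit_identical(self, small_fit):
        table, adj, spec, settings, draws = small_fit
        again = run_mcmc(table, adj, spec, settings)
        for name in draws.params:
            assert np.array_equal(draws.get(name), again.get(name))
        assert np.array_equal(draws.deviance, again.deviance)

    def test_different_seed_differs(self, small_fit):
        table, adj, spec, settings, draws = small_fit
        other = run_mcmc(table, adj, spec, McmcSettings(
            n_chains=2, n_iter=400, n_burnin=100, thin=3, seed=43))
        assert not np.array_equal(draws.get("beta"), other.get("beta"))

    def test_m3_requires_distances(self, small_fit):
        table, adj, _, settings, _ = small_fit
        spec3 = ModelSpec("M3", PriorConfig(), decay_bounds=(0.001, 0.1))
        with pytest.raises(ValueError, match="distance"):
            run_mcmc(table, adj, spec3, settings)

    def test_draws_inside_prior_support(self, small_fit):
        _, _, spec, _, draws = small_fit
        l = spec.prior_config.sd_upper
        for name in ("sd_icar", "sd_het", "sd_b1", "sd_b2"):
            arr = draws.get(name)
            assert np.all(arr > 0) and np.all(arr < l)

    def test_prior_only_sd_matches_uniform_moments(self):
        rng = np.random.default_rng(11)
        table, adj = make_table(2, 4, rng)
        l = 2.0
        spec = ModelSpec("M2", PriorConfig(sd_upper=l, coef_prior_sd=0.5))
        settings = McmcSettings(n_chains=2, n_iter=3000, n_burnin=500, thin=1, seed=1)
        draws = run_mcmc(table, adj, spec, settings, prior_only=True)
        s = draws.get("sd_b2", flat=True)
        # Uniform(0, l): mean l/2, sd l/sqrt(12)
        assert s.mean() == pytest.approx(l / 2, abs=4 * l / np.sqrt(12 * 200))
        assert s.std() == pytest.approx(l / np.sqrt(12), rel=0.1)
        a = draws.get("alpha", flat=True)
        assert a.mean() == pytest.approx(0.0, abs=0.1)
        assert a.std() == pytest.approx(0.5, rel=0.1)

    def test_single_city_intercept_matches_quadrature_posterior(self):
        # one city, covariate forced to zero, no spatial field in truth:
        # the intercept posterior given the fields ~ integrates to a
        # Poisson-loglinear posterior checkable by 1-D quadrature when the
        # field variances are pinned near zero by a tight prior bound.
        import pandas as pd

        from multicity.data import TractTable, build_adjacency

        rng = np.random.default_rng(12)
        n = 40
        E = rng.uniform(1, 3, n)
        O = rng.poisson(E * np.exp(0.3))
        df = pd.DataFrame({"city": "a", "tract": np.arange(1, n + 1), "observed": O,
                           "expected": E, "covariate": 0.0})
        table = TractTable.from_frame(df)
        adj = build_adjacency([("a", i, i + 1) for i in range(1, n)], table)
        spec = ModelSpec("M1", PriorConfig(sd_upper=0.01))  # fields pinned ~ 0
        draws = run_mcmc(table, adj, spec, McmcSettings(
            n_chains=2, n_iter=4000, n_burnin=1000, thin=1, seed=5))
        b1 = draws.get("b1", flat=True)[:, 0]
        # quadrature oracle for flat-prior posterior of the log rate
        grid = np.linspace(-1, 1.5, 4000)
        logp = grid * O.sum() - E.sum() * np.exp(grid)
        w = np.exp(logp - logp.max())
        w /= w.sum()
        post_mean = float((grid * w).sum())
        post_sd = float(np.sqrt((grid**2 * w).sum() - post_mean**2))
        mc_se = post_sd / np.sqrt(effective_sample_size(b1))
        assert b1.mean() == pytest.approx(post_mean, abs=max(3 * mc_se, 0.02))


class TestRhat:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(500)
        chains = np.vstack([c, c])
        n = 500
        # plain B/W form: identical chains give sqrt((n-1)/n), just below 1
        assert rhat(chains) == pytest.approx(np.sqrt((n - 1) / n), abs=1e-12)

    def test_separated_chains_flagged(self):
        chains = np.array([[0.0, 0.0, 0.0, 0.0], [5.0, 5.0, 5.0, 5.0]])
        assert rhat(chains) > 10

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 1000))
        assert 0.99 < rhat(chains) < 1.02

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz_on_iid_draws(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 2000))
        ours = rhat(chains)
        theirs = float(az.rhat(chains))
        assert ours == pytest.approx(theirs, abs=0.01)


class TestEss:
    def test_iid_within_20_percent(self):
        rng = np.random.default_rng(3)
        draws = rng.standard_normal((4, 1000))
        assert effective_sample_size(draws) == pytest.approx(4000, rel=0.2)

    def test_ar1_analytic_factor(self):
        rng = np.random.default_rng(4)
        rho = 0.9
        n = 40_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_constant_chain_warns_and_reports_total(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert effective_sample_size(np.full((2, 50), 3.0)) == 100

    def test_agrees_with_arviz_on_ar1(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        rho = 0.6
        x = np.empty((4, 2000))
        x[:, 0] = rng.standard_normal(4)
        for t in range(1, 2000):
            x[:, t] = rho * x[:, t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(4)
        ours = effective_sample_size(x)
        theirs = float(az.ess(x))
        assert ours == pytest.approx(theirs, rel=0.25)


class TestCheckConvergence:
    def test_iid_draws_pass(self):
        rng = np.random.default_rng(6)
        from multicity.inference import PosteriorDraws

        draws = PosteriorDraws(
            params={"alpha": rng.standard_normal((4, 500)),
                    "b2": rng.standard_normal((4, 500, 2))},
            deviance=np.zeros((4, 500)),
            mean_log_theta=np.zeros(4),
            variant="M2",
            settings=McmcSettings(n_chains=4, n_iter=500, n_burnin=0, thin=1, seed=0),
            city_ids=["a", "b"],
        )
        report = check_convergence(draws)
        assert report.all_pass
        assert set(report.table.index) == {"alpha", "b2[a]", "b2[b]"}

    def test_frozen_parameter_fails_overall(self):
        rng = np.random.default_rng(7)
        from multicity.inference import PosteriorDraws

        bad = np.vstack([np.zeros((2, 500)), np.ones((2, 500)) * 5])
        draws = PosteriorDraws(
            params={"alpha": rng.standard_normal((4, 500)), "beta": bad},
            deviance=np.zeros((4, 500)),
            mean_log_theta=np.zeros(4),
            variant="M2",
            settings=McmcSettings(n_chains=4, n_iter=500, n_burnin=0, thin=1, seed=0),
            city_ids=[],
        )
        report = check_convergence(draws)
        assert not report.all_pass
        assert report.failures() == ["beta"]


class TestDic:
    def test_degenerate_draws_pd_zero(self, small_fit):
        table, _, _, _, draws = small_fit
        from multicity.inference import PosteriorDraws
        from multicity.models import poisson_log_likelihood

        log_theta = np.zeros(table.n_tracts)
        dev = -2 * poisson_log_likelihood(log_theta, table)
        frozen = PosteriorDraws(
            params={}, deviance=np.full((2, 10), dev), mean_log_theta=log_theta,
            variant="M1", settings=draws.settings, city_ids=draws.city_ids,
        )
        res = dic(frozen, table)
        assert res.p_d == pytest.approx(0.0, abs=1e-10)
        assert res.dic == pytest.approx(dev)

    def test_identity_holds(self, small_fit):
        table, _, _, _, draws = small_fit
        res = dic(draws, table)
        assert res.dic == pytest.approx(res.dbar + res.p_d, abs=1e-12)
        assert res.p_d > 0

    def test_poisson_gamma_quadrature_oracle(self):
        # single tract, draws taken exactly from the Gamma posterior:
        # Dbar and p_D computable by quadrature over that posterior
        import pandas as pd
        from scipy import integrate, special, stats

        from multicity.data import TractTable
        from multicity.inference import PosteriorDraws

        O, E = 7, 2.0
        a0, b0 = 2.0, 1.0  # Gamma(shape, rate) prior on theta
        post = stats.gamma(a=a0 + O, scale=1.0 / (b0 + E))
        rng = np.random.default_rng(8)
        theta = post.rvs(200_000, random_state=rng)
        table = TractTable.from_frame(pd.DataFrame(
            {"city": ["a"], "tract": [1], "observed": [O], "expected": [E],
             "covariate": [0.0]}))
        dev_draws = -2 * (O * np.log(E * theta) - E * theta - special.gammaln(O + 1))
        draws = PosteriorDraws(
            params={}, deviance=dev_draws.reshape(1, -1),
            mean_log_theta=np.array([np.log(theta).mean()]),
            variant="M1",
            settings=McmcSettings(n_chains=1, n_iter=10, n_burnin=0, thin=1, seed=0),
            city_ids=["a"],
        )
        res = dic(draws, table)
        dev = lambda t: -2 * (O * np.log(E * t) - E * t - float(special.gammaln(O + 1)))
        dbar_exact, _ = integrate.quad(lambda t: dev(t) * post.pdf(t), 1e-9, 60)
        logt_exact, _ = integrate.quad(lambda t: np.log(t) * post.pdf(t), 1e-9, 60)
        d_at_mean_exact = dev(np.exp(logt_exact))
        assert res.dbar == pytest.approx(dbar_exact, rel=2e-3)
        assert res.p_d == pytest.approx(dbar_exact - d_at_mean_exact, rel=0.05)


class TestCompareModels:
    def test_study_scale_ordering_and_bands(self):
        # DIC values on the scale of a large multi-city mortality dataset:
        # M3 best, moderate edge over M2, clear edge over M1
        res = [
            ("M1", DicResult(dbar=36408.6, d_at_mean=36408.6)),
            ("M2", DicResult(dbar=36392.1, d_at_mean=36392.1)),
            ("M3", DicResult(dbar=36389.0, d_at_mean=36389.0)),
        ]
        df = compare_models(res)
        assert list(df["model"]) == ["M3", "M2", "M1"]
        assert df.loc[1, "band"] == "moderate"  # M2 - M3 = 3.1
        assert df.loc[2, "band"] == "clear"  # M1 - M3 = 19.6
        assert dic_difference_band(36408.6 - 36389.0) == "clear"

    def test_tie_is_negligible(self):
        res = [("a", DicResult(10.0, 10.0)), ("b", DicResult(10.0, 10.0))]
        df = compare_models(res)
        assert df.loc[1, "band"] == "negligible"

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            compare_models([("a", DicResult(1.0, 1.0))])


class TestPersistence:
    def test_save_load_round_trip(self, small_fit, tmp_path):
        _, _, _, _, draws = small_fit
        draws.save(tmp_path / "d")
        again = type(draws).load(tmp_path / "d")
        for name in draws.params:
            assert np.allclose(again.get(name), draws.get(name))
        assert np.allclose(again.deviance, draws.deviance)
        assert np.allclose(again.mean_log_theta, draws.mean_log_theta)
        assert again.variant == draws.variant
        assert again.fingerprint == draws.fingerprint
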