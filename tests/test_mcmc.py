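"""Posterior sampler: distributional correctness, reproducibility, plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.tsa.stattools import acf

from otaria.abundance import ObservedIndexSeries
from otaria.mcmc import FitData, MCMCConfig, PosteriorSamples, sample_posterior
from otaria.model import ModelParams, ModelVariant, Prior, PriorSpec
from otaria.removals import BycatchSeries, HarvestSeries, RemovalSchedule


def _no_removals():
    return RemovalSchedule(HarvestSeries(pd.Series(dtype=float)), BycatchSeries.zero())


def _mc_se(draws):
    """Monte-Carlo standard error of the mean from the autocorrelation time."""
    draws = np.asarray(draws)
    rho = acf(draws, nlags=min(50, len(draws) // 3), fft=True)[1:]
    tau = 1 + 2 * np.sum(rho[np.cumsum(rho < 0.05) == 0])  # initial positive window
    tau = max(tau, 1.0)
    return draws.std(ddof=1) * np.sqrt(tau / len(draws))


class TestConjugateCheck:
    def test_lognormal_k_posterior_matches_closed_form(self, rng):
        # all parameters but K frozen, latents frozen at zero (P = 1), no
        # removals: ln K has a conjugate normal posterior
        q0, tau2, b_true = 0.5, 0.05, 5.8
        years = np.arange(1985, 2011)
        obs_years = np.arange(1990, 2010)
        log_i = np.log(q0) + b_true + np.sqrt(tau2) * rng.standard_normal(len(obs_years))
        vals = np.full(len(years), np.nan)
        vals[obs_years - years[0]] = np.exp(log_i)
        data = FitData(
            _no_removals(),
            ObservedIndexSeries(years, vals),
            start_year=int(years[0]),
            end_year=int(years[-1]),
        )
        priors = (
            PriorSpec.default()
            .with_prior("q", Prior("fixed", q0))
            .with_prior("tau2", Prior("fixed", tau2))
            .with_prior("r_max", Prior("fixed", 0.05))
            .with_prior("sigma2", Prior("fixed", 0.02))
        )
        cfg = MCMCConfig(n_iter=30_000, burn_in=3_000, thin=5, seed=7)
        samples = sample_posterior(
            data,
            priors,
            ModelVariant("linear", "none"),
            cfg,
            update_params={n: False for n in ("r_max", "q", "sigma2", "tau2")},
            fix_latents=True,
        )
        b_draws = np.log(samples.flat("k"))
        # closed form: prior N(5.7, 0.8^2), each obs ln I ~ N(ln q + b, tau2)
        prec = 1 / 0.8**2 + len(obs_years) / tau2
        mean = (5.7 / 0.8**2 + np.sum(log_i - np.log(q0)) / tau2) / prec
        sd = np.sqrt(1 / prec)
        assert abs(b_draws.mean() - mean) < 3 * _mc_se(b_draws)
        assert b_draws.std(ddof=1) == pytest.approx(sd, rel=0.1)


class TestPriorIdentity:
    def test_no_data_run_reproduces_priors(self, rng):
        # with no observations the posterior is the joint prior restricted to
        # feasible state paths (every pre-noise bracket positive).  The
        # parameters outside that constraint (K, q, tau2: with no removals
        # the bracket involves none of them) must match their priors exactly;
        # the constrained ones (r_max, z, sigma2) must match the truncated
        # prior, rejection-sampled here as an independent oracle.
        years = np.arange(1995, 2014)
        T = len(years)
        data = FitData(
            _no_removals(),
            ObservedIndexSeries(years, np.full(T, np.nan)),
            start_year=1995,
            end_year=2013,
        )
        cfg = MCMCConfig(n_iter=30_000, burn_in=3_000, thin=50, seed=5)
        samples = sample_posterior(data, config=cfg)

        marginals = {
            "k": stats.lognorm(s=0.8, scale=np.exp(5.7)),
            "q": stats.beta(2.2, 2.0),
            "tau2": stats.invgamma(3.0, scale=0.8),
        }
        for name, dist in marginals.items():
            res = stats.kstest(samples.flat(name), dist.cdf)
            assert res.pvalue > 0.01, f"{name}: KS p={res.pvalue:.4f}"

        # rejection-sample the feasibility-truncated prior (vectorized walk
        # of the no-removal state recursion; horizon starts after the
        # equilibrium block so the path has T free deviations)
        n_ref = 40_000
        r = stats.lognorm(s=0.5, scale=np.exp(-2.9)).rvs(n_ref, random_state=rng)
        z = stats.uniform(0.0001, 10 - 0.0001).rvs(n_ref, random_state=rng)
        s2 = stats.invgamma(1.0, scale=0.4).rvs(n_ref, random_state=rng)
        u = np.sqrt(s2)[:, None] * rng.standard_normal((n_ref, T))
        p = np.exp(u[:, 0])
        ok = np.ones(n_ref, dtype=bool)
        for t in range(1, T):
            with np.errstate(over="ignore", invalid="ignore"):
                bracket = p + r * p * (1.0 - p**z)
            ok &= np.nan_to_num(bracket, nan=-1.0) > 0
            p = np.where(ok, bracket * np.exp(u[:, t]), 1.0)
        assert 0.05 < ok.mean() < 1.0  # the truncation is real but not total
        for name, ref in (("r_max", r[ok]), ("z", z[ok]), ("sigma2", s2[ok])):
            res = stats.ks_2samp(samples.flat(name), ref)
            assert res.pvalue > 0.01, f"{name}: two-sample KS p={res.pvalue:.4f}"


class TestKalmanCrossCheck:
    def test_state_means_track_linear_gaussian_smoother(self, rng):
        # z = 1, small noise, parameters fixed at truth: the model is nearly
        # the linear-Gaussian AR(1) x_t = (1 - R) x_{t-1} + u_t observed with
        # noise, for which the RTS smoother is exact
        r, k0, q0, s2, t2 = 0.1, 300.0, 0.5, 0.005, 0.005
        phi = 1 - r
        T = 30
        years = np.arange(1990, 1990 + T)
        x = np.empty(T)
        x[0] = np.sqrt(s2) * rng.standard_normal()
        for t in range(1, T):
            x[t] = phi * x[t - 1] + np.sqrt(s2) * rng.standard_normal()
        y = x + np.sqrt(t2) * rng.standard_normal(T)
        vals = np.exp(np.log(q0 * k0) + y)
        data = FitData(
            _no_removals(),
            ObservedIndexSeries(years, vals),
            start_year=int(years[0]),
            end_year=int(years[-1]),
        )
        priors = (
            PriorSpec.default()
            .with_prior("r_max", Prior("fixed", r))
            .with_prior("k", Prior("fixed", k0))
            .with_prior("q", Prior("fixed", q0))
            .with_prior("sigma2", Prior("fixed", s2))
            .with_prior("tau2", Prior("fixed", t2))
        )
        cfg = MCMCConfig(n_iter=20_000, burn_in=2_000, thin=5, seed=13)
        samples = sample_posterior(
            data,
            priors,
            ModelVariant("linear", "none"),
            cfg,
            update_params={n: False for n in ("r_max", "k", "q", "sigma2", "tau2")},
        )
        post_mean = np.log(samples.p.reshape(-1, T)).mean(axis=0)

        # independent RTS smoother oracle
        mf = np.empty(T)
        vf = np.empty(T)
        m_pred, v_pred = 0.0, s2
        for t in range(T):
            if t > 0:
                m_pred, v_pred = phi * mf[t - 1], phi**2 * vf[t - 1] + s2
            kgain = v_pred / (v_pred + t2)
            mf[t] = m_pred + kgain * (y[t] - m_pred)
            vf[t] = (1 - kgain) * v_pred
        ms = mf.copy()
        for t in range(T - 2, -1, -1):
            c = vf[t] * phi / (phi**2 * vf[t] + s2)
            ms[t] = mf[t] + c * (ms[t + 1] - phi * mf[t])
        assert np.max(np.abs(post_mean - ms)) < 0.02
        assert np.corrcoef(post_mean, ms)[0, 1] > 0.99


class TestPlumbing:
    def test_reproducible_and_seed_sensitive(self, fit_data):
        cfg = MCMCConfig(n_iter=2000, burn_in=400, thin=10, seed=3)
        a = sample_posterior(fit_data, config=cfg)
        b = sample_posterior(fit_data, config=cfg)
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.deviance, b.deviance)
        c = sample_posterior(
            fit_data, config=MCMCConfig(n_iter=2000, burn_in=400, thin=10, seed=4)
        )
        assert not np.array_equal(a.params, c.params)

    def test_infeasible_data_prior_combination_aborts(self):
        years = np.arange(1929, 1961)
        harvest = HarvestSeries(pd.Series(1e8, index=years))
        data = FitData(
            RemovalSchedule(harvest, BycatchSeries.zero()),
            ObservedIndexSeries(np.array([1990]), np.array([100.0])),
        )
        with pytest.raises(RuntimeError, match="feasible"):
            sample_posterior(data, config=MCMCConfig.scaled(seed=0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)

    def test_draw_counts_equal_across_chains(self, small_fit):
        assert small_fit.params.shape[0] == 3
        assert small_fit.params.shape[1] == small_fit.config.n_keep
        assert np.isfinite(small_fit.deviance).all()
        # every draw satisfies the parameter invariants
        for j, name in enumerate(small_fit.param_names):
            ModelParams.from_array(small_fit.params[0, 0])
        assert (small_fit.params[:, :, 3] > 0).all()
        assert (small_fit.params[:, :, 3] < 1).all()

    def test_summary_layout_and_correlation(self, small_fit):
        s = small_fit.summary()
        assert list(s.columns) == ["mean", "sd", "2.5%", "median", "97.5%"]
        corr = small_fit.correlation()
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.shape == (6, 6)

    def test_persistence_round_trip(self, small_fit, tmp_path):
        small_fit.to_dir(tmp_path / "fit")
        back = PosteriorSamples.from_dir(tmp_path / "fit")
        assert np.allclose(back.params, small_fit.params)
        assert np.allclose(back.p, small_fit.p)
        assert np.allclose(back.deviance, small_fit.deviance)
        assert back.variant == small_fit.variant
        assert np.array_equal(back.years, small_fit.years)

    def test_linear_variant_freezes_z_at_one(self, fit_data):
        cfg = MCMCConfig(n_iter=1500, burn_in=300, thin=10, seed=9)
        s = sample_posterior(
            fit_data, variant=ModelVariant("linear", "TC"), config=cfg
        )
        assert np.all(s.params[:, :, 2] == 1.0)
        assert "z" not in s.estimated_names()
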