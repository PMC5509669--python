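"""Core model layer: production function, transitions, likelihoods, priors."""

import numpy as np
import pytest
from scipy import optimize, stats

from otaria.model import (
    LatentTrajectory,
    ModelParams,
    ModelVariant,
    Prior,
    PriorSpec,
    SENSITIVITY_PRESETS,
    joint_log_density,
    log_prior,
    observation_loglik,
    process_loglik,
    production_peak_abundance,
    state_transition,
    surplus_production,
)
from otaria.abundance import ObservedIndexSeries
from otaria.mcmc import FitData
from otaria.removals import BycatchSeries, HarvestSeries, RemovalSchedule

import pandas as pd


def params(**kw):
    base = dict(r_max=0.055, k=319.3, z=5.817, q=0.566, sigma2=0.084, tau2=0.098)
    base.update(kw)
    return ModelParams(**base)


class TestSurplusProduction:
    def test_zero_at_carrying_capacity(self):
        p = params()
        assert surplus_production(p.k, p) == pytest.approx(0.0, abs=1e-12)

    def test_per_capita_growth_approaches_rmax_at_low_density(self):
        p = params()
        n = 1e-8
        assert surplus_production(n, p) / n == pytest.approx(p.r_max, rel=1e-6)

    @pytest.mark.parametrize("z", [0.5, 1.0, 2.4, 5.817])
    def test_peak_matches_numerical_optimum(self, z):
        p = params(z=z)
        res = optimize.minimize_scalar(
            lambda n: -surplus_production(n, p), bounds=(1e-6, p.k), method="bounded"
        )
        assert production_peak_abundance(p) == pytest.approx(res.x, rel=1e-5)

    def test_nonlinear_shape_peaks_above_half_k(self):
        # z = 5.817 puts peak production at ~0.72 K, i.e. above K/2
        p = params()
        peak = production_peak_abundance(p)
        assert peak / p.k == pytest.approx((1 + p.z) ** (-1 / p.z), rel=1e-12)
        assert peak > 0.5 * p.k

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            surplus_production(-1.0, params())


class TestStateTransition:
    def test_equilibrium_fixed_point(self):
        assert state_transition(1.0, 0.0, 0.0, params(), 0.0) == pytest.approx(1.0)

    def test_matches_independent_schaefer_update(self, rng):
        # z = 1: independent discrete-logistic-with-harvest oracle
        for _ in range(25):
            p_prev = rng.uniform(0.05, 1.3)
            r, k = rng.uniform(0.01, 0.5), rng.uniform(50, 500)
            h, m = rng.uniform(0, 2000), rng.uniform(0, 500)
            mp = params(r_max=r, k=k, z=1.0)
            expected = (
                p_prev + r * p_prev * (1 - p_prev) - (h + m) / 1000.0 / k
            )
            if expected <= 0:
                continue
            got = state_transition(p_prev, h, m, mp, 0.0)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_log_state_linear_in_deviation(self):
        p = params()
        base = np.log(state_transition(0.7, 100.0, 0.0, p, 0.0))
        for u in (0.1, 0.2, -0.3):
            assert np.log(state_transition(0.7, 100.0, 0.0, p, u)) == pytest.approx(
                base + u, abs=1e-12
            )

    def test_schaefer_continuity_in_z(self):
        lo = state_transition(0.6, 500.0, 0.0, params(z=1 - 1e-6), 0.0)
        hi = state_transition(0.6, 500.0, 0.0, params(z=1 + 1e-6), 0.0)
        at = state_transition(0.6, 500.0, 0.0, params(z=1.0), 0.0)
        assert lo == pytest.approx(at, rel=1e-6)
        assert hi == pytest.approx(at, rel=1e-6)

    def test_infeasible_removals_raise(self):
        with pytest.raises(ValueError, match="exceed"):
            state_transition(0.01, 1e6, 0.0, params(), 0.0)


class TestObservationLoglik:
    def test_matches_textbook_lognormal_density(self, rng):
        p = params()
        for _ in range(20):
            p_t = rng.uniform(0.05, 1.2)
            i_t = rng.uniform(1.0, 300.0)
            expected = stats.lognorm.logpdf(
                i_t, s=np.sqrt(p.tau2), scale=p.q * p.k * p_t
            )
            assert observation_loglik(i_t, p_t, p) == pytest.approx(
                expected, abs=1e-12
            )

    def test_zero_residual_value(self):
        p = params()
        i_t = p.q * p.k * 0.8
        expected = -np.log(i_t * np.sqrt(2 * np.pi * p.tau2))
        assert observation_loglik(i_t, 0.8, p) == pytest.approx(expected, abs=1e-12)

    def test_all_missing_years_contribute_zero(self):
        assert observation_loglik([np.nan, np.nan], [0.5, 0.8], params()) == 0.0


class TestPriors:
    def test_rmax_prior_median(self):
        assert PriorSpec.default()["r_max"].median() == pytest.approx(
            np.exp(-2.9), rel=1e-9
        )
        assert np.exp(-2.9) == pytest.approx(0.055, abs=0.0003)

    def test_k_prior_cv_is_one(self):
        # lognormal CV = sqrt(e^{sigma^2} - 1); sigma = 0.8 gives 0.947,
        # the "coefficient of variation of 100%" in round terms
        cv = np.sqrt(np.exp(0.8**2) - 1)
        assert cv == pytest.approx(0.9468, abs=1e-4)
        assert abs(cv - 1.0) < 0.1

    def test_q_prior_mean(self):
        prior = PriorSpec.default()["q"]
        assert prior.a / (prior.a + prior.b) == pytest.approx(0.524, abs=0.001)

    def test_log_prior_matches_scipy_sum(self):
        p = params()
        spec = PriorSpec.default()
        expected = (
            stats.lognorm.logpdf(p.r_max, s=0.5, scale=np.exp(-2.9))
            + stats.lognorm.logpdf(p.k, s=0.8, scale=np.exp(5.7))
            + stats.uniform.logpdf(p.z, 0.0001, 10 - 0.0001)
            + stats.beta.logpdf(p.q, 2.2, 2.0)
            + stats.invgamma.logpdf(p.sigma2, 1.0, scale=0.4)
            + stats.invgamma.logpdf(p.tau2, 3.0, scale=0.8)
        )
        assert log_prior(p, spec) == pytest.approx(expected, abs=1e-10)

    def test_out_of_support_is_minus_inf(self):
        assert log_prior(params(z=20.0), PriorSpec.default()) == -np.inf

    def test_presets_alter_exactly_one_prior(self):
        base = PriorSpec.default()
        for name in SENSITIVITY_PRESETS:
            alt = PriorSpec.preset(name)
            changed = [
                p for p in base.priors if base[p] != alt[p]
            ]
            assert len(changed) == 1
            assert changed[0] == SENSITIVITY_PRESETS[name][0]

    def test_invgamma_mode_convention(self):
        # shape-scale convention: invgamma(1, 0.4) has mode scale/(shape+1) = 0.2
        prior = PriorSpec.default()["sigma2"]
        x = np.linspace(0.01, 2, 4000)
        dens = stats.invgamma.pdf(x, prior.a, scale=prior.b)
        assert x[np.argmax(dens)] == pytest.approx(0.2, abs=0.01)


def _toy_problem():
    """5-year toy dataset with hand-checkable structure."""
    years = np.arange(1926, 1931)
    p = np.array([1.1, 1.1, 1.1, 0.95, 0.9])
    u = np.array([0.0953101798043, 0.0953101798043, 0.0953101798043, -0.05, -0.02])
    traj = LatentTrajectory(years, p, u)
    harvest = HarvestSeries(pd.Series({1929: 30000.0}))
    removals = RemovalSchedule(harvest, BycatchSeries.zero())
    idx = ObservedIndexSeries(
        np.array([1927, 1929, 1930]), np.array([200.0, np.nan, 150.0])
    )
    data = FitData(removals, idx, start_year=1926, end_year=1930)
    return traj, data


class TestJointLogDensity:
    def test_equals_sum_of_independent_terms(self):
        p = params()
        spec = PriorSpec.default()
        traj, data = _toy_problem()
        # independent oracle: scipy priors + normal process terms + lognormal obs
        prior_term = (
            stats.lognorm.logpdf(p.r_max, s=0.5, scale=np.exp(-2.9))
            + stats.lognorm.logpdf(p.k, s=0.8, scale=np.exp(5.7))
            + stats.uniform.logpdf(p.z, 0.0001, 10 - 0.0001)
            + stats.beta.logpdf(p.q, 2.2, 2.0)
            + stats.invgamma.logpdf(p.sigma2, 1.0, scale=0.4)
            + stats.invgamma.logpdf(p.tau2, 3.0, scale=0.8)
        )
        free_u = [traj.u[0], traj.u[3], traj.u[4]]  # shared pre-block draw + 2
        process_term = sum(
            stats.norm.logpdf(v, 0, np.sqrt(p.sigma2)) for v in free_u
        )
        obs_term = sum(
            stats.lognorm.logpdf(i, s=np.sqrt(p.tau2), scale=p.q * p.k * pt)
            for i, pt in [(200.0, traj.p[1]), (150.0, traj.p[4])]
        )
        expected = prior_term + process_term + obs_term
        got = joint_log_density(p, traj, data, spec)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_removing_one_observation_changes_density_by_its_term(self):
        p = params()
        spec = PriorSpec.default()
        traj, data = _toy_problem()
        full = joint_log_density(p, traj, data, spec)
        reduced_idx = ObservedIndexSeries(
            np.array([1927, 1929, 1930]), np.array([200.0, np.nan, np.nan])
        )
        data2 = FitData(data.removals, reduced_idx, start_year=1926, end_year=1930)
        dropped_term = stats.lognorm.logpdf(
            150.0, s=np.sqrt(p.tau2), scale=p.q * p.k * traj.p[4]
        )
        assert joint_log_density(p, traj, data2, spec) == pytest.approx(
            full - dropped_term, abs=1e-10
        )

    def test_linear_variant_rejects_z_not_one(self):
        traj, data = _toy_problem()
        lin = ModelVariant("linear", "TC")
        assert joint_log_density(params(), traj, data, PriorSpec.default(), lin) == -np.inf

    def test_linear_and_forced_z1_agree(self):
        traj, data = _toy_problem()
        spec = PriorSpec.default()
        p1 = params(z=1.0)
        lin = joint_log_density(p1, traj, data, spec, ModelVariant("linear", "TC"))
        non = joint_log_density(p1, traj, data, spec, ModelVariant("non-linear", "TC"))
        assert lin == pytest.approx(non, abs=1e-12)

    def test_out_of_support_params_give_minus_inf_not_exception(self):
        traj, data = _toy_problem()
        assert (
            joint_log_density(params(z=15.0), traj, data, PriorSpec.default())
            == -np.inf
        )

    def test_all_six_variants_evaluate(self, scenario):
        from otaria.model import ALL_VARIANTS

        spec = PriorSpec.default()
        st = scenario.true_states
        keep = st.years <= 2013
        traj = LatentTrajectory(st.years[keep], st.p[keep], st.u[keep])
        for v in ALL_VARIANTS:
            data = FitData(
                scenario.removals_for_mode(v.bycatch_mode),
                scenario.observations.restrict(2013),
            )
            p = params(z=1.0) if v.z_fixed else params()
            val = joint_log_density(p, traj, data, spec, v)
            assert np.isfinite(val)


class TestLatentTrajectory:
    def test_free_u_shares_pre_block_draw(self):
        years = np.arange(1927, 1932)
        u = np.array([0.2, 0.2, 0.1, -0.1, 0.05])
        traj = LatentTrajectory(years, np.exp(u), u)
        assert len(traj.free_u()) == 4  # one shared + 1929..1931

    def test_positive_states_enforced(self):
        with pytest.raises(ValueError):
            LatentTrajectory(np.array([2000, 2001]), np.array([1.0, 0.0]), np.zeros(2))

    def test_n_scales_with_k(self):
        traj = LatentTrajectory(np.array([2000]), np.array([0.5]), np.zeros(1))
        assert traj.n(300.0) == pytest.approx([150.0])
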