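"""Synthetic-data generator: determinism, dynamics, noise calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from otaria.model import ModelParams
from otaria.removals import BycatchSeries, HarvestSeries, RemovalSchedule, gompertz
from otaria.simulate import (
    ScenarioConfig,
    default_truth,
    generate_scenario,
    simulate_gompertz_exports,
    simulate_observations,
    simulate_states,
    write_scenario,
)


def no_removals():
    return RemovalSchedule(HarvestSeries(pd.Series(dtype=float)), BycatchSeries.zero())


class TestSimulateStates:
    @pytest.mark.parametrize("r,z", [(0.02, 1.0), (0.055, 5.817), (0.3, 0.5)])
    def test_zero_noise_zero_removals_constant_at_k(self, r, z):
        truth = ModelParams(r, 300.0, z, 0.5, 1e-300, 1e-300)
        traj = simulate_states(truth, no_removals(), (1900, 2013), seed=0)
        assert np.allclose(traj.p, 1.0, atol=1e-9)

    def test_constant_harvest_converges_to_bisection_root(self):
        # sigma -> 0, z = 1: the trajectory settles at the upper root of
        # P + R P (1 - P) - H/K = P, found independently by bisection
        r, k, h = 0.2, 300.0, 3000.0  # H/K = 0.01 < R/4
        truth = ModelParams(r, k, 1.0, 0.5, 1e-300, 1e-300)
        years = np.arange(1900, 2300)
        harvest = HarvestSeries(pd.Series(h, index=years))
        traj = simulate_states(
            truth, RemovalSchedule(harvest, BycatchSeries.zero()), (1900, 2299), 0
        )
        root = optimize.bisect(
            lambda p: r * p * (1 - p) - h / 1000.0 / k, 0.5, 1.0, xtol=1e-12
        )
        assert traj.p[-1] == pytest.approx(root, abs=1e-9)

    def test_default_scenario_depletion_and_recovery(self, scenario):
        # qualitative trajectory: collapse below 10% of K inside/after the
        # pulse, then recovery
        st = scenario.true_states
        years = st.years
        pulse = (years >= 1929) & (years <= 1965)
        assert st.p[pulse].min() < 0.10
        assert st.at(2013) > 3 * st.p[pulse].min()

    def test_pre_block_shares_single_deviation(self, scenario):
        st = scenario.true_states
        pre = st.years <= 1928
        assert np.allclose(st.u[pre], st.u[pre][0])
        assert np.allclose(st.p[pre], np.exp(st.u[pre][0]))

    def test_independent_pre_block_option(self):
        truth = default_truth()
        traj = simulate_states(
            truth, no_removals(), (1900, 1950), seed=5, shared_pre_block=False
        )
        pre_u = traj.u[traj.years <= 1928]
        assert len(np.unique(pre_u)) > 1

    def test_infeasible_schedule_raises(self):
        truth = ModelParams(0.02, 10.0, 1.0, 0.5, 1e-300, 1e-300)
        harvest = HarvestSeries(pd.Series(50_000.0, index=np.arange(1929, 1940)))
        with pytest.raises(ValueError, match="infeasible"):
            simulate_states(
                truth, RemovalSchedule(harvest, BycatchSeries.zero()), (1900, 1950), 0
            )

    def test_all_states_positive(self, scenario):
        assert (scenario.true_states.p > 0).all()


class TestSimulateObservations:
    def test_noise_free_proportionality(self):
        truth = ModelParams(0.055, 300.0, 1.0, 0.5, 1e-300, 1e-300)
        traj = simulate_states(truth, no_removals(), (1970, 1980), seed=0)
        obs = simulate_observations(traj, truth, [1975], seed=0)
        val = obs.values[obs.years == 1975][0]
        assert val == pytest.approx(0.5 * 300.0 * traj.at(1975), rel=1e-6)

    def test_lognormal_moment_check(self):
        # 1e4 replicate draws at one state: mean of ln I within 3 SE of ln(qKP)
        truth = default_truth()
        traj = simulate_states(
            ModelParams(0.055, 319.3, 5.817, 0.566, 1e-300, 0.098),
            no_removals(),
            (2000, 2001),
            seed=0,
        )
        draws = [
            simulate_observations(traj, truth, [2000], seed=s).values[0]
            for s in range(10_000)
        ]
        log_draws = np.log(draws)
        expected = np.log(truth.q * truth.k * traj.at(2000))
        se = np.sqrt(truth.tau2 / len(draws))
        assert abs(log_draws.mean() - expected) < 3 * se

    def test_observation_noise_distribution(self, scenario):
        # KS of ln(I) - ln(qKP) against Normal(0, tau2) at n = 1e4
        truth = scenario.truth
        traj = scenario.true_states
        resid = []
        for s in range(10_000 // 24 + 1):
            obs = simulate_observations(traj, truth, scenario.config.obs_years, seed=s)
            ok = ~np.isnan(obs.values)
            resid.extend(
                np.log(obs.values[ok]) - np.log(truth.q * truth.k * traj.p[ok])
            )
        resid = np.array(resid)[:10_000]
        stat = stats.kstest(resid, "norm", args=(0, np.sqrt(truth.tau2)))
        assert stat.pvalue > 0.01

    def test_gap_pattern_matches_default_coverage(self, scenario):
        obs = scenario.observations
        missing_years = {1986, 1987, 1988, 1993, 2002, 2003, 2004, 2010, 2011, 2013}
        for y in missing_years:
            assert np.isnan(obs.values[obs.years == y][0])
        assert len(obs.observed_years) == 24

    def test_observed_years_strict_subset_of_state_years(self, scenario):
        state_years = set(scenario.true_states.years.tolist())
        obs_years = set(scenario.observations.observed_years.tolist())
        assert obs_years < state_years

    def test_years_outside_states_rejected(self):
        truth = default_truth()
        traj = simulate_states(truth, no_removals(), (1970, 1980), seed=0)
        with pytest.raises(ValueError, match="outside"):
            simulate_observations(traj, truth, [1990], seed=0)


class TestGompertzExports:
    def test_noise_free_points_on_curve(self):
        pts = simulate_gompertz_exports(1e5, 0.25, 1940.0, 0.0, range(1929, 1961, 5), 0)
        for y, c in pts:
            assert c == pytest.approx(gompertz(y, 1e5, 0.25, 1940.0), rel=1e-12)

    def test_asymptote_limit(self):
        pts = simulate_gompertz_exports(1e5, 0.25, 1940.0, 0.0, [2500], 0)
        assert pts[0][1] == pytest.approx(1e5, rel=1e-9)

    def test_noisy_points_clamped_nondecreasing(self):
        pts = simulate_gompertz_exports(1e4, 0.3, 1940.0, 5e3, range(1929, 1961, 2), 7)
        vals = [c for _, c in pts]
        assert all(v >= 0 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_gompertz_exports(-1.0, 0.25, 1940.0, 0.0, [1930, 1935], 0)
        with pytest.raises(ValueError):
            simulate_gompertz_exports(1e5, 0.25, 1940.0, 0.0, [1935, 1930], 0)


class TestScenario:
    def test_default_truth_values(self):
        t = default_truth()
        assert t.r_max == 0.055
        assert t.k == 319.3
        assert t.z == 5.817
        assert t.q == 0.566
        assert t.sigma2 == 0.084
        assert t.tau2 == 0.098
        # passes ModelParams invariants by construction (no exception above)

    def test_byte_identical_reproduction(self, tmp_path, scenario):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario(scenario, d1)
        write_scenario(generate_scenario(seed=0), d2)
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_scenario(seed=1)
        b = generate_scenario(seed=2)
        assert not np.array_equal(a.true_states.p, b.true_states.p)

    def test_substreams_are_stable(self, scenario):
        # observation draws must not depend on the state-path retry count
        obs1 = simulate_observations(
            scenario.true_states, scenario.truth, scenario.config.obs_years, seed=0
        )
        assert np.array_equal(obs1.values, scenario.observations.values, equal_nan=True)

    def test_bycatch_series_in_study_range(self, scenario):
        # annual totals across the three rate assumptions span a few hundred
        # to ~1,500 animals, matching the reconstructed fishery record
        ac = scenario.removals_for_mode("AC").bycatch.series
        mc = scenario.removals_for_mode("MC").bycatch.series
        assert 100 < ac.min() < ac.max() < 2000
        assert 100 < mc.min() < mc.max() < 2000
        assert (scenario.bycatch.series.index >= 1989).all()
        assert (scenario.bycatch.series.index <= 2013).all()
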