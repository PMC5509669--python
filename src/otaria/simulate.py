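"""Seeded synthetic depletion-recovery scenarios with known true parameters.

The generator emulates the data regime of the real study system: a ~30-year
commercial-harvest pulse whose only record is a handful of cumulative export
totals (Gompertz-shaped), a low-level bycatch series from 1989 onward built
from per-fishing-type effort and constant catch rates, and sparse surveys
(1972 onward, with the historical gap pattern) observed with lognormal noise.
Everything downstream — removals reconstruction, index assembly, model
fitting, evaluation — can then be tested against known truth.

One master seed expands into fixed per-component substreams (states,
observations, exports, effort) via ``numpy.random.SeedSequence`` spawn keys,
so adding a component never shifts existing draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .abundance import (
    DEFAULT_COVERAGE,
    CorrectionFactors,
    ObservedIndexSeries,
    SurveyRecord,
    default_observation_years,
    non4b_from_4b,
)
from .model import EQUILIBRIUM_END, LatentTrajectory, ModelParams, state_transition
from .removals import (
    BycatchRateTable,
    BycatchSeries,
    EffortTable,
    HarvestSeries,
    RemovalSchedule,
    compute_bycatch,
    gompertz,
)

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "default_truth",
    "default_rate_table",
    "simulate_states",
    "simulate_observations",
    "simulate_gompertz_exports",
    "simulate_effort",
    "generate_scenario",
    "write_scenario",
    "read_scenario",
    "synthetic_survey_records",
]

# substream ids for the counter-based seed expansion
_STREAM_STATES = 0
_STREAM_OBS = 1
_STREAM_EXPORTS = 2
_STREAM_EFFORT = 3


def _rng(master_seed: int, stream: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=(stream, int(attempt)))
    )


def default_truth() -> ModelParams:
    """Reference parameter set used as the generator's true values.

    These are the posterior medians estimated for the study population under
    the non-linear density-dependence model with the Total Catch bycatch
    series, so that synthetic scenarios live in the empirically relevant
    parameter regime.
    """
    return ModelParams(r_max=0.055, k=319.3, z=5.817, q=0.566, sigma2=0.084, tau2=0.098)


def default_rate_table() -> BycatchRateTable:
    """Nine fishing types with catch rates spanning 0.002-0.02 animals per
    boat-day (two types never caught a sea lion); average rates sit below and
    maximum rates above the total-catch rates."""
    types = [
        "bottom_trawl_hake_day",
        "pelagic_trawl_shrimp_night",
        "bottom_trawl_hake_night",
        "bottom_trawl_shrimp_day",
        "midwater_trawl_day",
        "midwater_trawl_night",
        "bottom_trawl_other",
        "jigging",
        "longline",
    ]
    tcr = np.array([0.020, 0.018, 0.010, 0.008, 0.006, 0.004, 0.002, 0.0, 0.0])
    table = pd.DataFrame(
        {
            "fishing_type": types,
            "TCR": tcr,
            "ACR": 0.55 * tcr,
            "MCR": 1.8 * tcr,
        }
    )
    return BycatchRateTable(table)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults mirror the real data regime: model years 1900-2015 with the
    pre-removal equilibrium block ending in 1928; a harvest era 1929-1960
    whose cumulative exports follow a Gompertz curve peaking (in annual
    differences) near 17,900 animals/yr around 1939-1940; small isolated
    harvest events outside the export records; bycatch 1989-2013; surveys at
    the historical coverage years with the historical gaps.
    """

    start_year: int = 1900
    end_year: int = 2015
    fit_end_year: int = 2013
    harvest_era: tuple[int, int] = (1929, 1960)
    gompertz_asymptote: float = 460_000.0
    gompertz_rate: float = 0.18
    gompertz_inflection: float = 1939.5
    export_noise_sd: float = 2_000.0
    export_years: tuple[int, ...] = (1929, 1934, 1939, 1944, 1949, 1954, 1959)
    extra_harvest_events: tuple[tuple[int, float], ...] = (
        (1921, 500.0),
        (1938, 500.0),
        (1939, 500.0),
        (1940, 500.0),
    )
    bycatch_era: tuple[int, int] = (1989, 2013)
    effort_base_days: float = 10_000.0
    effort_ramp: tuple[float, float] = (0.6, 1.3)
    effort_jitter_sd: float = 0.1
    bycatch_mode: str = "TC"
    obs_years: tuple[int, ...] = tuple(int(y) for y in default_observation_years())
    shared_pre_block: bool = True  # one deviation for the whole pre-1929 block


@dataclass
class SyntheticScenario:
    """A complete generated scenario: truth, latent states, removal inputs,
    and noisy observations, reproducible bit-for-bit from (config, seed)."""

    truth: ModelParams
    config: ScenarioConfig
    true_states: LatentTrajectory
    harvest: HarvestSeries
    effort: EffortTable
    rates: BycatchRateTable
    bycatch: BycatchSeries
    observations: ObservedIndexSeries
    exports: list[tuple[int, float]]
    seed: int
    state_attempt: int = 0

    @property
    def removals(self) -> RemovalSchedule:
        return RemovalSchedule(self.harvest, self.bycatch)

    def removals_for_mode(self, mode: str) -> RemovalSchedule:
        if mode == self.bycatch.mode:
            return self.removals
        if mode == "none":
            return RemovalSchedule(self.harvest, BycatchSeries.zero())
        return RemovalSchedule(self.harvest, compute_bycatch(self.effort, self.rates, mode))


def simulate_states(
    truth: ModelParams,
    removals: RemovalSchedule,
    year_range: tuple[int, int],
    seed: int,
    *,
    shared_pre_block: bool = True,
    attempt: int = 0,
) -> LatentTrajectory:
    """Simulate the latent relative-abundance trajectory.

    Years up to the equilibrium end get ``P = e^{U_1}`` (a single shared draw
    by default; ``shared_pre_block=False`` switches to independent yearly
    draws).  Later years follow the stochastic transition; a removal schedule
    that drives the pre-noise bracket non-positive raises a ``ValueError``
    (the schedule is infeasible for this truth, not merely unlucky noise).
    """
    rng = _rng(seed, _STREAM_STATES, attempt)
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    sd = np.sqrt(truth.sigma2)
    p = np.empty(len(years))
    u = np.empty(len(years))
    pre = years <= EQUILIBRIUM_END
    n_pre = int(pre.sum())
    if n_pre:
        if shared_pre_block:
            u[:n_pre] = rng.normal(0.0, sd)
        else:
            u[:n_pre] = rng.normal(0.0, sd, size=n_pre)
        p[:n_pre] = np.exp(u[:n_pre])
    else:  # horizon starts after the equilibrium block
        u[0] = rng.normal(0.0, sd)
        p[0] = np.exp(u[0])
    for i in range(max(n_pre, 1), len(years)):
        u[i] = rng.normal(0.0, sd)
        year_prev = int(years[i - 1])
        try:
            p[i] = state_transition(
                p[i - 1],
                removals.h(year_prev),
                removals.m(year_prev),
                truth,
                u[i],
                on_infeasible="raise",
            )
        except ValueError as err:
            raise ValueError(
                f"infeasible removal schedule at year {years[i]}: {err}"
            ) from err
    return LatentTrajectory(years, p, u)


def simulate_observations(
    states: LatentTrajectory,
    truth: ModelParams,
    obs_years,
    seed: int,
) -> ObservedIndexSeries:
    """Observe I_t = q K P_t e^{V_t} at the requested years; all other state
    years are marked missing."""
    obs_years = np.asarray(sorted(int(y) for y in obs_years))
    state_years = set(int(y) for y in states.years)
    bad = [y for y in obs_years if y not in state_years]
    if bad:
        raise ValueError(f"observation years outside state years: {bad}")
    rng = _rng(seed, _STREAM_OBS)
    sd = np.sqrt(truth.tau2)
    vals = np.full(len(states.years), np.nan)
    y0 = int(states.years[0])
    for y in obs_years:
        v = rng.normal(0.0, sd)
        p_t = states.p[y - y0]
        vals[y - y0] = truth.q * truth.k * p_t * np.exp(v)
    return ObservedIndexSeries(states.years.copy(), vals)


def simulate_gompertz_exports(
    asymptote: float,
    rate: float,
    inflection_year: float,
    noise_sd: float,
    report_years,
    seed: int,
) -> list[tuple[int, float]]:
    """Cumulative-export points on the Gompertz curve with additive normal
    error, clamped non-negative and non-decreasing."""
    if asymptote <= 0:
        raise ValueError("asymptote must be > 0")
    report_years = [int(y) for y in report_years]
    if any(b <= a for a, b in zip(report_years, report_years[1:])):
        raise ValueError("report_years must be strictly increasing")
    rng = _rng(seed, _STREAM_EXPORTS)
    curve = gompertz(np.array(report_years, dtype=float), asymptote, rate, inflection_year)
    noisy = curve + rng.normal(0.0, noise_sd, size=len(report_years))
    clamped = np.maximum.accumulate(np.clip(noisy, 0.0, None))
    return [(y, float(c)) for y, c in zip(report_years, clamped)]


def simulate_effort(config: ScenarioConfig, seed: int) -> EffortTable:
    """Per-type effort: a linear ramp over the fishery era with lognormal
    jitter around it."""
    rng = _rng(seed, _STREAM_EFFORT)
    y0, y1 = config.bycatch_era
    years = np.arange(y0, y1 + 1)
    ramp = np.linspace(*config.effort_ramp, len(years))
    rows = []
    for ft in default_rate_table().table["fishing_type"]:
        jitter = np.exp(rng.normal(0.0, config.effort_jitter_sd, size=len(years)))
        days = config.effort_base_days * ramp * jitter
        rows.append(pd.DataFrame({"year": years, "fishing_type": ft, "days": days}))
    return EffortTable(pd.concat(rows, ignore_index=True))


def _true_harvest(config: ScenarioConfig) -> HarvestSeries:
    y0, y1 = config.harvest_era
    years = np.arange(y0, y1 + 1)
    a, k, t0 = (
        config.gompertz_asymptote,
        config.gompertz_rate,
        config.gompertz_inflection,
    )
    h = gompertz(years, a, k, t0) - gompertz(years - 1, a, k, t0)
    s = pd.Series(np.clip(h, 0.0, None), index=years)
    for year, pulse in config.extra_harvest_events:
        s.loc[int(year)] = s.get(int(year), 0.0) + float(pulse)
    return HarvestSeries(s.sort_index())


def generate_scenario(
    config: ScenarioConfig | None = None,
    seed: int = 0,
    *,
    max_attempts: int = 400,
) -> SyntheticScenario:
    """Generate a full scenario from the study conditions in ``config``.

    The state process is drawn conditioned on feasibility of the whole path:
    a deep harvest pulse combined with large multiplicative process noise
    makes most unconditional paths cross zero, so infeasible draws are
    discarded and redrawn from deterministic per-attempt substreams.  The
    accepted attempt index is recorded; identical (config, seed) always yield
    the identical scenario.
    """
    cfg = config or ScenarioConfig()
    truth = default_truth()
    harvest = _true_harvest(cfg)
    effort = simulate_effort(cfg, seed)
    rates = default_rate_table()
    bycatch = compute_bycatch(effort, rates, cfg.bycatch_mode)
    removals = RemovalSchedule(harvest, bycatch)
    states = None
    attempt = 0
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        try:
            states = simulate_states(
                truth,
                removals,
                (cfg.start_year, cfg.end_year),
                seed,
                shared_pre_block=cfg.shared_pre_block,
                attempt=attempt,
            )
            break
        except ValueError as err:
            last_err = err
    if states is None:
        raise ValueError(
            f"no feasible state path in {max_attempts} attempts "
            f"(seed {seed}); last failure: {last_err}"
        )
    obs = simulate_observations(states, truth, cfg.obs_years, seed)
    exports = simulate_gompertz_exports(
        cfg.gompertz_asymptote,
        cfg.gompertz_rate,
        cfg.gompertz_inflection,
        cfg.export_noise_sd,
        cfg.export_years,
        seed,
    )
    return SyntheticScenario(
        truth=truth,
        config=cfg,
        true_states=states,
        harvest=harvest,
        effort=effort,
        rates=rates,
        bycatch=bycatch,
        observations=obs,
        exports=exports,
        seed=int(seed),
        state_attempt=attempt,
    )


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> None:
    """Write the scenario as plain CSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = scenario.true_states
    pd.DataFrame(
        {
            "year": st.years,
            "P": st.p,
            "N": st.n(scenario.truth.k),
            "U": st.u,
        }
    ).to_csv(out / "states.csv", index=False)
    scenario.observations.to_frame().to_csv(out / "observations.csv", index=False)
    scenario.harvest.series.rename("H").rename_axis("year").reset_index().to_csv(
        out / "harvest.csv", index=False
    )
    scenario.effort.table.to_csv(out / "effort.csv", index=False)
    scenario.rates.table.to_csv(out / "rates.csv", index=False)
    pd.DataFrame(scenario.exports, columns=["year", "cumulative_catch"]).to_csv(
        out / "exports.csv", index=False
    )
    truth = asdict(scenario.truth)
    (out / "truth.json").write_text(
        json.dumps({"truth": truth, "seed": scenario.seed}, indent=2) + "\n"
    )


def read_scenario_inputs(in_dir: str | Path):
    """Read the fit inputs (harvest, effort, rates, observations) written by
    :func:`write_scenario` or prepared by hand."""
    d = Path(in_dir)
    harvest = HarvestSeries(
        pd.read_csv(d / "harvest.csv").set_index("year")["H"]
    )
    effort = EffortTable(pd.read_csv(d / "effort.csv"))
    rates = BycatchRateTable(pd.read_csv(d / "rates.csv"))
    obs = ObservedIndexSeries.from_frame(pd.read_csv(d / "observations.csv"))
    return harvest, effort, rates, obs


read_scenario = read_scenario_inputs


def synthetic_survey_records(
    index: ObservedIndexSeries,
    factors: CorrectionFactors | None = None,
    coverage: dict | None = None,
) -> list[SurveyRecord]:
    """Back-generate noise-free survey records consistent with an index series
    and a coverage pattern, for exercising the assembly stage end to end.

    For years where the non-4B expansion applies, the 4B total solves
    ``t + exp(a + b ln t) = northern`` (bracketed root).  Synthetic: these are
    constructed counts, not survey data.
    """
    f = factors or CorrectionFactors()
    cov = coverage if coverage is not None else DEFAULT_COVERAGE
    records = []
    for year, value in zip(index.years, index.values):
        year = int(year)
        if year not in cov:
            continue
        pup_only, corrections = cov[year]
        if corrections is None or np.isnan(value):
            records.append(
                SurveyRecord(year=year, pups_4b=0.0, missing=True)
            )
            continue
        total = value * 1000.0
        use2 = 2 in corrections
        use3 = 3 in corrections
        northern = total / f.north_to_total_slope if use3 else total / 1.5
        central = None if use3 else total - northern
        if use2:
            g = lambda t: t + non4b_from_4b(t, f) - northern
            t4b = brentq(g, 1e-6, northern)
            other = None
        else:
            t4b = 0.75 * northern
            other = northern - t4b
        rec = dict(
            year=year,
            other_sites_total=other,
            central_total=central,
            apply_pup_correction=pup_only,
            apply_non4b_correction=use2,
            apply_central_correction=use3,
        )
        if pup_only:
            rec["pups_4b"] = t4b / (1.0 + f.pup_to_nonpup_slope)
        else:
            rec["total_4b"] = t4b
        records.append(SurveyRecord(**rec))
    return records
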