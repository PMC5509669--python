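"""End-to-end analysis pipeline driven by a single YAML/JSON config.

Stages (in order): ``simulate`` (or load input files), ``reconstruct``
(harvest from cumulative exports, bycatch from effort x rates), ``assemble``
(survey records -> corrected index), ``fit`` (MCMC per requested variant),
``evaluate`` (DIC, posterior predictive check, residuals, convergence
diagnostics, comparison table), ``project`` (one-step-ahead index forecast),
``sensitivity`` (alternative-prior refits).  Every stage writes its artifacts
under the output directory and the run ends with a manifest (inputs, seeds,
stage timings, file hashes) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .abundance import assemble_index
from .evaluation import (
    bayesian_pvalue,
    compare_models,
    project_one_step,
    run_sensitivity,
    sensitivity_table,
    standardized_residuals,
)
from .diagnostics import diagnose
from .mcmc import FitData, MCMCConfig, sample_posterior
from .model import ALL_VARIANTS, ModelVariant, PriorSpec
from .removals import (
    RemovalSchedule,
    annual_harvest_from_fit,
    compute_bycatch,
    fit_gompertz_cumulative,
)
from .simulate import (
    ScenarioConfig,
    generate_scenario,
    read_scenario_inputs,
    synthetic_survey_records,
    write_scenario,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    scenario_source: str = "synthetic"  # or "files"
    scenario_path: Path | None = None
    variants: list[ModelVariant] = field(
        default_factory=lambda: [ModelVariant()]
    )
    priors: PriorSpec = field(default_factory=PriorSpec.default)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig.scaled)
    projection_horizon: int | None = 2015
    sensitivity_presets: list[str] = field(default_factory=list)
    fit_end_year: int = 2013
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        try:
            scenario = raw.get("scenario", {})
            source = scenario.get("source", "synthetic")
            if source not in ("synthetic", "files"):
                raise ValueError(f"unknown scenario source {source!r}")
            path = scenario.get("path")
            if source == "files":
                if path is None:
                    raise ValueError("scenario source 'files' needs a path")
                path = (base / path).resolve()
                if not Path(path).exists():
                    raise ValueError(f"scenario path {path} does not exist")
            if raw.get("variants") == "all":
                variants = list(ALL_VARIANTS)
            elif "variants" in raw:
                variants = [ModelVariant(**v) for v in raw["variants"]]
            else:
                variants = [ModelVariant(**raw.get("variant", {}))]
            prior_cfg = raw.get("priors", "default")
            if prior_cfg == "default":
                priors = PriorSpec.default()
            elif isinstance(prior_cfg, str):
                priors = PriorSpec.preset(prior_cfg)
            else:
                from .model import Prior

                priors = PriorSpec.default()
                for name, spec in prior_cfg.items():
                    priors = priors.with_prior(
                        name, Prior(spec["dist"], spec["a"], spec.get("b", 0.0))
                    )
            mcmc_raw = dict(raw.get("mcmc", {}))
            preset = mcmc_raw.pop("preset", "scaled")
            seed = int(raw.get("seed", 0))
            mcmc_raw.setdefault("seed", seed)
            if preset == "full":
                base_cfg = MCMCConfig(seed=mcmc_raw["seed"])
            else:
                base_cfg = MCMCConfig.scaled(seed=mcmc_raw["seed"])
            mcmc = MCMCConfig(**{**base_cfg.__dict__, **mcmc_raw})
            presets = list(raw.get("sensitivity", []) or [])
            from .model import SENSITIVITY_PRESETS

            bad = [p for p in presets if p not in SENSITIVITY_PRESETS and p != "base"]
            if bad:
                raise ValueError(f"unknown sensitivity presets {bad}")
            return cls(
                out_dir=(base / raw["out"]).resolve()
                if "out" in raw
                else Path("pipeline_out").resolve(),
                seed=seed,
                scenario_source=source,
                scenario_path=Path(path) if path else None,
                variants=variants,
                priors=priors,
                mcmc=mcmc,
                projection_horizon=raw.get("project", {}).get("horizon", 2015)
                if raw.get("project", True) is not False
                else None,
                sensitivity_presets=presets,
                fit_end_year=int(raw.get("fit_end_year", 2013)),
                log_level=raw.get("log_level", "INFO"),
            )
        except (KeyError, TypeError, ValueError) as err:
            raise ValueError(f"invalid pipeline config: {err}") from err


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; return (and write) the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start (seed %s)", name, config.seed)
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, str(exc)) from exc
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = {"seconds": round(dt, 3)}
                logger.info("stage %s: done in %.2fs", name, dt)

        return _Ctx()

    # -- simulate / load ---------------------------------------------------
    with stage("simulate"):
        if config.scenario_source == "synthetic":
            scenario = generate_scenario(ScenarioConfig(), seed=config.seed)
            scen_dir = out / "scenario"
            write_scenario(scenario, scen_dir)
            exports = scenario.exports
            effort, rates = scenario.effort, scenario.rates
            observations = scenario.observations
            manifest["scenario"] = {
                "source": "synthetic",
                "seed": config.seed,
                "state_attempt": scenario.state_attempt,
            }
        else:
            scen_dir = config.scenario_path
            harvest_in, effort, rates, observations = read_scenario_inputs(scen_dir)
            exports_df = pd.read_csv(scen_dir / "exports.csv")
            exports = list(
                zip(exports_df["year"], exports_df["cumulative_catch"])
            )
            manifest["scenario"] = {"source": "files", "path": str(scen_dir)}

    # -- reconstruct removals ---------------------------------------------
    with stage("reconstruct"):
        gfit = fit_gompertz_cumulative(exports)
        era = (
            scenario.config.harvest_era
            if config.scenario_source == "synthetic"
            else (1929, 1960)
        )
        events = (
            dict(scenario.config.extra_harvest_events)
            if config.scenario_source == "synthetic"
            else None
        )
        harvest = annual_harvest_from_fit(gfit, era, extra_events=events)
        harvest.series.rename("H").rename_axis("year").reset_index().to_csv(
            out / "harvest_reconstructed.csv", index=False
        )
        bycatch = {
            mode: compute_bycatch(effort, rates, mode) for mode in ("TC", "AC", "MC")
        }
        for mode, b in bycatch.items():
            b.series.rename("M").rename_axis("year").reset_index().to_csv(
                out / f"bycatch_{mode}.csv", index=False
            )
        manifest["gompertz_fit"] = {
            "asymptote": gfit.asymptote,
            "rate": gfit.rate,
            "inflection": gfit.inflection,
            "residual_sd": gfit.residual_sd,
        }

    # -- assemble the index -------------------------------------------------
    with stage("assemble"):
        if config.scenario_source == "synthetic":
            records = synthetic_survey_records(observations)
            index = assemble_index(records)
        else:
            index = observations
        index.to_frame().to_csv(out / "index.csv", index=False)

    # -- fit ----------------------------------------------------------------
    fits = []
    with stage("fit"):
        for variant in config.variants:
            removals = RemovalSchedule(harvest, bycatch[variant.bycatch_mode])
            data = FitData(
                removals, index.restrict(config.fit_end_year),
                end_year=config.fit_end_year,
            )
            samples = sample_posterior(data, config.priors, variant, config.mcmc)
            tag = variant.label().replace("/", "_").replace("-", "")
            samples.to_dir(out / f"fit_{tag}")
            fits.append((variant, data, samples))
        manifest["outputs"]["fits"] = [v.label() for v, _, _ in fits]

    # -- evaluate -----------------------------------------------------------
    with stage("evaluate"):
        evaluated = []
        for variant, data, samples in fits:
            ppc = bayesian_pvalue(samples, data, seed=config.seed)
            evaluated.append((samples, ppc))
            tag = variant.label().replace("/", "_").replace("-", "")
            standardized_residuals(samples, data).to_csv(
                out / f"residuals_{tag}.csv", index=False
            )
            report = diagnose(samples)
            report.summary().to_csv(out / f"diagnostics_{tag}.csv")
        table = compare_models(evaluated)
        table.to_csv(out / "model_comparison.csv", index=False)
        manifest["outputs"]["model_comparison"] = table.to_dict(orient="records")

    # -- project ------------------------------------------------------------
    if config.projection_horizon is not None:
        with stage("project"):
            variant, data, samples = fits[0]
            proj = project_one_step(
                samples, None, config.projection_horizon, seed=config.seed
            )
            proj.to_csv(out / "projection.csv", index=False)
            manifest["outputs"]["projection"] = proj.to_dict(orient="records")

    # -- sensitivity --------------------------------------------------------
    if config.sensitivity_presets:
        with stage("sensitivity"):
            variant, data, samples = fits[0]
            runs = run_sensitivity(
                data, samples, config.sensitivity_presets, variant, config.mcmc
            )
            sensitivity_table(runs).to_csv(out / "sensitivity.csv", index=False)

    manifest["outputs"]["files"] = {
        p.name: _hash_file(p) for p in sorted(out.glob("*.csv"))
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )
    logging.getLogger().removeHandler(fh)
    return manifest
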