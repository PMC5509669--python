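"""Posterior sampling for the state-space production model.

The target is the joint posterior of the six parameters and the free process
deviations (see :mod:`otaria.model`); the kernel is an adaptive
Metropolis-within-Gibbs scan (:mod:`otaria._kernels`).  The chain design
mirrors the study: several independent chains, long runs with burn-in and
thinning, over-dispersed initial values drawn from the priors.  The full-run
configuration (3 x 1,000,000 iterations, burn-in 100,000, thin 50) is the
default; ``MCMCConfig.scaled()`` gives the reduced design used for simulation
studies and tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import run_chain
from .abundance import ObservedIndexSeries
from .model import (
    EQUILIBRIUM_END,
    MODEL_END,
    MODEL_START,
    PARAM_NAMES,
    ModelParams,
    ModelVariant,
    Prior,
    PriorSpec,
)
from .removals import RemovalSchedule

__all__ = ["MCMCConfig", "FitData", "PosteriorSamples", "sample_posterior"]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain design: number of chains, iterations, burn-in, thinning, seed."""

    n_chains: int = 3
    n_iter: int = 1_000_000
    burn_in: int = 100_000
    thin: int = 50
    seed: int = 0
    adapt_batch: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for between-chain diagnostics")

    @classmethod
    def full(cls, seed: int = 0) -> "MCMCConfig":
        return cls(seed=seed)

    @classmethod
    def scaled(cls, seed: int = 0) -> "MCMCConfig":
        """Reduced design for simulation studies: 3 x 20,000, burn-in 2,000,
        thin 10."""
        return cls(n_iter=20_000, burn_in=2_000, thin=10, seed=seed)

    @property
    def n_keep(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class FitData:
    """Everything the likelihood needs: removal schedule and observed index.

    ``index`` years falling outside [start_year, end_year] are ignored in the
    fit (the held-out final survey, for instance).
    """

    removals: RemovalSchedule
    index: ObservedIndexSeries
    start_year: int = MODEL_START
    end_year: int = MODEL_END

    def h(self, year: int) -> float:
        return self.removals.h(year)

    def m(self, year: int) -> float:
        return self.removals.m(year)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def arrays(self):
        """(removals in thousands per year index, obs indices, log I)."""
        years = self.years
        h, m = self.removals.as_arrays(years)
        rem = (h + m) / 1000.0
        oy = self.index.observed_years
        ov = self.index.observed_values
        keep = (oy >= self.start_year) & (oy <= self.end_year)
        obs_idx = (oy[keep] - self.start_year).astype(np.int64)
        obs_logi = np.log(ov[keep])
        return rem, obs_idx, obs_logi

    @property
    def n_pre(self) -> int:
        return int(np.sum(self.years <= EQUILIBRIUM_END))


_PRIOR_CODE = {
    # transformed-coordinate prior codes per (param, dist family)
    ("lognormal", "log"): _kernels.PRIOR_NORMAL_LOG,
    ("uniform", "log"): _kernels.PRIOR_UNIF_EXP,
    ("beta", "logit"): _kernels.PRIOR_BETA_LOGIT,
    ("invgamma", "log"): _kernels.PRIOR_INVGAMMA_EXP,
    ("uniform", "raw"): _kernels.PRIOR_UNIF_RAW,
    ("fixed", "any"): _kernels.PRIOR_FIXED,
}

# transform used for each parameter slot
_TRANSFORMS = ("log", "log", "raw", "logit", "log", "log")


def _encode_priors(priors: PriorSpec, variant: ModelVariant):
    codes = np.empty(6, dtype=np.int64)
    pa = np.empty(6)
    pb = np.empty(6)
    for j, name in enumerate(PARAM_NAMES):
        prior: Prior = priors[name]
        dist = prior.dist
        if name == "z" and variant.z_fixed:
            dist = "fixed"
        tf = _TRANSFORMS[j]
        key = (dist, "any") if dist == "fixed" else (dist, tf)
        if key not in _PRIOR_CODE:
            raise ValueError(
                f"prior family {dist!r} not supported for parameter {name!r}"
            )
        codes[j] = _PRIOR_CODE[key]
        pa[j] = prior.a
        pb[j] = prior.b
    return codes, pa, pb


def _transform(params: ModelParams) -> np.ndarray:
    q = min(max(params.q, 1e-9), 1 - 1e-9)
    return np.array(
        [
            np.log(params.r_max),
            np.log(params.k),
            params.z,
            np.log(q / (1 - q)),
            np.log(params.sigma2),
            np.log(params.tau2),
        ]
    )


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws from all chains.

    ``params`` has shape (chains, draws, 6) on the natural scale in the order
    r_max, k, z, q, sigma2, tau2; ``u`` the free deviations; ``p`` the state
    path per draw; ``deviance`` is -2 x observation log-likelihood per draw.
    """

    params: np.ndarray
    u: np.ndarray
    p: np.ndarray
    deviance: np.ndarray
    years: np.ndarray
    variant: ModelVariant
    config: MCMCConfig
    accept_rates: np.ndarray
    provenance: str = ""
    param_names: tuple = PARAM_NAMES

    @property
    def n_chains(self) -> int:
        return self.params.shape[0]

    @property
    def n_draws(self) -> int:
        return self.params.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        j = self.param_names.index(name)
        return self.params[:, :, j].reshape(-1)

    def chain(self, name: str, c: int) -> np.ndarray:
        j = self.param_names.index(name)
        return self.params[c, :, j]

    def estimated_names(self) -> tuple:
        names = list(self.param_names)
        if self.variant.z_fixed:
            names.remove("z")
        return tuple(names)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD and 2.5/50/97.5 percentiles per parameter."""
        rows = []
        for name in self.param_names:
            d = self.flat(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "sd": d.std(ddof=1),
                    "2.5%": np.percentile(d, 2.5),
                    "median": np.percentile(d, 50),
                    "97.5%": np.percentile(d, 97.5),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        d = self.flat(name)
        a = 100 * (1 - level) / 2
        return float(np.percentile(d, a)), float(np.percentile(d, 100 - a))

    def median(self, name: str) -> float:
        return float(np.median(self.flat(name)))

    def correlation(self) -> pd.DataFrame:
        """Correlation matrix of the estimated parameters' posterior draws."""
        names = self.estimated_names()
        mat = np.column_stack([self.flat(n) for n in names])
        return pd.DataFrame(np.corrcoef(mat.T), index=names, columns=names)

    def abundance(self) -> np.ndarray:
        """Absolute abundance N_t = K P_t per draw, (chains, draws, years)."""
        k = self.params[:, :, 1][..., None]
        return k * self.p

    def trajectory_summary(self) -> pd.DataFrame:
        """Per-year posterior quantiles of absolute abundance (thousands)."""
        n = self.abundance().reshape(-1, len(self.years))
        qs = np.percentile(n, [2.5, 25, 50, 75, 97.5], axis=0)
        return pd.DataFrame(
            {
                "year": self.years,
                "mean": n.mean(axis=0),
                "2.5%": qs[0],
                "25%": qs[1],
                "median": qs[2],
                "75%": qs[3],
                "97.5%": qs[4],
            }
        )

    def to_dir(self, out_dir: str | Path) -> None:
        """Persist draws as columnar CSVs plus JSON metadata and summary."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        c, d, _ = self.params.shape
        frame = pd.DataFrame(
            self.params.reshape(c * d, 6), columns=list(self.param_names)
        )
        frame.insert(0, "chain", np.repeat(np.arange(c), d))
        frame.insert(1, "draw", np.tile(np.arange(d), c))
        frame["deviance"] = self.deviance.reshape(-1)
        frame.to_csv(out / "params.csv", index=False)
        pd.DataFrame(
            self.p.reshape(c * d, -1), columns=[str(y) for y in self.years]
        ).to_csv(out / "states.csv", index=False)
        pd.DataFrame(self.u.reshape(c * d, -1)).to_csv(out / "u.csv", index=False)
        self.trajectory_summary().to_csv(out / "trajectory.csv", index=False)
        meta = {
            "variant": {
                "density_dependence": self.variant.density_dependence,
                "bycatch_mode": self.variant.bycatch_mode,
            },
            "config": self.config.__dict__,
            "years": [int(self.years[0]), int(self.years[-1])],
            "n_chains": int(c),
            "provenance": self.provenance,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        summ = self.summary().reset_index().to_dict(orient="records")
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "variant": self.variant.label(),
                    "provenance": self.provenance,
                    "summary": summ,
                },
                indent=2,
                default=float,
            )
            + "\n"
        )

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "PosteriorSamples":
        """Reload draws persisted by :meth:`to_dir`."""
        d = Path(in_dir)
        meta = json.loads((d / "meta.json").read_text())
        c = meta["n_chains"]
        params = pd.read_csv(d / "params.csv")
        dev = params["deviance"].to_numpy()
        mat = params[list(PARAM_NAMES)].to_numpy()
        n = mat.shape[0] // c
        p = pd.read_csv(d / "states.csv").to_numpy()
        u = pd.read_csv(d / "u.csv").to_numpy()
        y0, y1 = meta["years"]
        return cls(
            params=mat.reshape(c, n, 6),
            u=u.reshape(c, n, -1),
            p=p.reshape(c, n, -1),
            deviance=dev.reshape(c, n),
            years=np.arange(y0, y1 + 1),
            variant=ModelVariant(**meta["variant"]),
            config=MCMCConfig(**meta["config"]),
            accept_rates=np.zeros((c, 6)),
            provenance=meta.get("provenance", ""),
        )


def _config_hash(config: MCMCConfig, variant: ModelVariant, priors: PriorSpec) -> str:
    blob = json.dumps(
        {
            "config": config.__dict__,
            "variant": variant.__dict__,
            "priors": {k: (p.dist, p.a, p.b) for k, p in sorted(priors.priors.items())},
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _initial_values(
    priors: PriorSpec,
    variant: ModelVariant,
    rng: np.random.Generator,
    data_arrays,
    n_pre: int,
    m: int,
    codes,
    pa,
    pb,
    max_tries: int = 500,
):
    """Over-dispersed chain initials: parameter draws from the priors,
    retried until the joint density is finite (deep removal schedules make
    small-K draws infeasible)."""
    rem, obs_idx, obs_logi = data_arrays
    p_work = np.empty(len(rem))
    u0 = np.zeros(m)
    # best-of-k among feasible prior draws: chains stay over-dispersed
    # (independent draws) without starting in pathological corners
    best = None
    n_feasible = 0
    for _ in range(max_tries):
        params = priors.sample_params(rng)
        if variant.z_fixed:
            params = ModelParams(
                params.r_max, params.k, 1.0, params.q, params.sigma2, params.tau2
            )
        x0 = _transform(params)
        lp, _ = _kernels._logpost(
            x0, u0, codes, pa, pb, rem, obs_idx, obs_logi, n_pre, p_work
        )
        if np.isfinite(lp):
            n_feasible += 1
            if best is None or lp > best[0]:
                best = (lp, x0)
            if n_feasible >= 10:
                return best[1], u0
    if best is not None:
        return best[1], u0
    raise RuntimeError(
        "could not find a feasible initial value: the removal schedule may be "
        "incompatible with the prior (every sampled parameter set drives the "
        "population non-positive)"
    )


def sample_posterior(
    data: FitData,
    priors: PriorSpec | None = None,
    variant: ModelVariant | None = None,
    config: MCMCConfig | None = None,
    *,
    update_params: dict[str, bool] | None = None,
    fix_latents: bool = False,
) -> PosteriorSamples:
    """Run the MCMC and return thinned post-burn-in draws from all chains.

    ``update_params`` can freeze individual parameters at their initial value
    (used for degenerate-model checks); ``fix_latents`` freezes the deviation
    vector at zero.  Reproducible: identical (data, priors, variant, config)
    give identical draws.
    """
    priors = priors or PriorSpec.default()
    variant = variant or ModelVariant()
    config = config or MCMCConfig()

    codes, pa, pb = _encode_priors(priors, variant)
    arrays = data.arrays()
    rem, obs_idx, obs_logi = arrays
    n_pre = data.n_pre
    T = len(data.years)
    m = 1 + (T - n_pre) if n_pre > 0 else T

    update = np.ones(6, dtype=np.bool_)
    if variant.z_fixed:
        update[2] = False
    for name, flag in (update_params or {}).items():
        update[PARAM_NAMES.index(name)] = bool(flag)

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = [int(s) for s in ss.generate_state(config.n_chains) % (2**31 - 1)]
    init_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))

    out_x, out_u, out_p, out_dev, accs = [], [], [], [], []
    for c in range(config.n_chains):
        x0, u0 = _initial_values(
            priors, variant, init_rng, arrays, n_pre, m, codes, pa, pb
        )
        xs, us, ps, dev, acc = run_chain(
            chain_seeds[c],
            config.n_iter,
            config.burn_in,
            config.thin,
            x0,
            u0,
            codes,
            pa,
            pb,
            update,
            fix_latents,
            rem,
            obs_idx,
            obs_logi,
            n_pre,
            config.adapt_batch,
            config.target_accept,
        )
        stuck = [
            PARAM_NAMES[j]
            for j in np.where(update)[0]
            if acc[j] == 0.0
        ]
        if stuck:
            raise RuntimeError(
                f"chain {c}: no accepted proposals for {stuck} after burn-in; "
                "the data/prior combination appears infeasible"
            )
        out_x.append(xs)
        out_u.append(us)
        out_p.append(ps)
        out_dev.append(dev)
        accs.append(acc)

    return PosteriorSamples(
        params=np.stack(out_x),
        u=np.stack(out_u),
        p=np.stack(out_p),
        deviance=np.stack(out_dev),
        years=data.years,
        variant=variant,
        config=config,
        accept_rates=np.stack(accs),
        provenance=_config_hash(config, variant, priors),
    )
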