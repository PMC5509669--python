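"""Model evaluation: DIC comparison, posterior predictive checks, residuals,
projection, and prior-sensitivity runs.

Model complexity is measured by pV = Var(D)/2, half the posterior variance of
the deviance, rather than pD (which is unstable for this model class), so
DIC = mean(D) + pV.  Deviance here is -2 x the observation log-likelihood
with the latent states treated as parameters, which is the convention under
which the study-scale DIC magnitudes (~180 for ~24 surveys) are comparable.

The posterior predictive check simulates replicate survey sets from the
observation equation at each retained draw's states and compares a
discrepancy statistic between replicate and observed data; the Bayesian
p-value is the fraction of replicates at least as extreme.  A reasonable fit
keeps the p-value inside (0.1, 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mcmc import FitData, MCMCConfig, PosteriorSamples, sample_posterior
from .model import ModelVariant, PriorSpec, SENSITIVITY_PRESETS

__all__ = [
    "DevianceSummary",
    "PPCResult",
    "SensitivityRun",
    "compute_dic",
    "bayesian_pvalue",
    "standardized_residuals",
    "project_one_step",
    "run_sensitivity",
    "compare_models",
    "DISCREPANCIES",
]


@dataclass(frozen=True)
class DevianceSummary:
    """Posterior mean deviance, complexity penalty pV, and their sum DIC."""

    mean_deviance: float
    p_v: float

    @property
    def dic(self) -> float:
        return self.mean_deviance + self.p_v

    def __post_init__(self) -> None:
        if self.p_v < 0:
            raise ValueError("pV must be >= 0")


def compute_dic(samples: PosteriorSamples | np.ndarray) -> DevianceSummary:
    """DIC = mean(D) + pV with pV = sample variance of the deviance draws / 2.

    Accepts posterior samples or a bare deviance array; invariant to draw and
    chain order.
    """
    dev = samples.deviance if hasattr(samples, "deviance") else np.asarray(samples)
    dev = dev.reshape(-1).astype(float)
    if dev.size == 0:
        raise ValueError("no deviance draws")
    if not np.all(np.isfinite(dev)):
        raise ValueError("deviance draws must be finite")
    p_v = 0.5 * dev.var(ddof=1) if dev.size > 1 else 0.0
    return DevianceSummary(float(dev.mean()), float(p_v))


# --------------------------------------------------------------------------
# posterior predictive checking


def _chi2_log_discrepancy(log_obs, mu, tau2):
    """Sum of squared standardized log residuals."""
    return np.sum((log_obs - mu) ** 2 / tau2, axis=-1)


#: Registry of discrepancy functions: (log I, log-mean, tau2) -> statistic.
DISCREPANCIES: dict[str, Callable] = {
    "chi2_log": _chi2_log_discrepancy,
}


@dataclass(frozen=True)
class PPCResult:
    """Bayesian p-value for one discrepancy."""

    p_value: float
    discrepancy: str
    n_replicates: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must be in [0, 1]")

    @property
    def reasonable_fit(self) -> bool:
        return 0.1 < self.p_value < 0.9


def bayesian_pvalue(
    samples: PosteriorSamples,
    data: FitData,
    discrepancy_id: str = "chi2_log",
    seed: int = 0,
) -> PPCResult:
    """Posterior predictive p-value.

    For every retained draw, a replicate survey set is simulated from the
    observation equation at that draw's states and parameters; the p-value is
    the fraction of draws whose replicate discrepancy is at least the
    observed one.  Invariant to draw order (each draw's replicate noise is
    independent of its position only through the seeded generator, applied
    after pooling chains in a fixed layout).
    """
    disc = DISCREPANCIES[discrepancy_id]
    rem, obs_idx, obs_logi = data.arrays()
    c, d, _ = samples.params.shape
    n = c * d
    q = samples.params[:, :, 3].reshape(n)
    k = samples.params[:, :, 1].reshape(n)
    tau2 = samples.params[:, :, 5].reshape(n)
    p_obs = samples.p[:, :, obs_idx].reshape(n, len(obs_idx))
    # attach replicate noise in a content-sorted order so the p-value does
    # not depend on how draws or chains happen to be arranged
    order = np.lexsort((p_obs[:, 0], tau2, k, q))
    mu = np.log(q[order, None] * k[order, None] * p_obs[order])
    t2 = tau2[order, None]
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(9,)))
    rep = mu + np.sqrt(t2) * rng.standard_normal(mu.shape)
    d_obs = disc(obs_logi[None, :], mu, t2)
    d_rep = disc(rep, mu, t2)
    p = float(np.mean(d_rep >= d_obs))
    return PPCResult(p, discrepancy_id, n)


def standardized_residuals(samples: PosteriorSamples, data: FitData) -> pd.DataFrame:
    """Per-survey-year standardized log residuals, averaged over draws.

    residual_t = (ln I_t - ln(q K P_t)) / tau, posterior-mean standardized;
    one row per observed year.
    """
    rem, obs_idx, obs_logi = data.arrays()
    if len(obs_idx) == 0:
        return pd.DataFrame(columns=["year", "residual"])
    c, d, _ = samples.params.shape
    n = c * d
    q = samples.params[:, :, 3].reshape(n, 1)
    k = samples.params[:, :, 1].reshape(n, 1)
    tau = np.sqrt(samples.params[:, :, 5].reshape(n, 1))
    p_obs = samples.p[:, :, obs_idx].reshape(n, len(obs_idx))
    res = (obs_logi[None, :] - np.log(q * k * p_obs)) / tau
    return pd.DataFrame(
        {"year": data.years[obs_idx], "residual": res.mean(axis=0)}
    )


# --------------------------------------------------------------------------
# projection


def project_one_step(
    samples: PosteriorSamples,
    future_removals: dict[int, float] | None,
    horizon_year: int,
    seed: int = 0,
    *,
    floor: float = 1e-6,
) -> pd.DataFrame:
    """Forward-simulate each draw to ``horizon_year`` and observe it.

    ``future_removals`` maps each gap year (last fitted year onward) to total
    removals in animals.  Per draw, states advance with fresh process noise
    and the survey index is observed with fresh observation noise.  Draws
    whose projected bracket hits the positivity floor are floored and
    flagged.  Returns one row per projected year with the predictive mean,
    SD and percentiles of the index I (thousands).
    """
    last = int(samples.years[-1])
    if horizon_year <= last:
        raise ValueError("horizon_year must be after the last fitted year")
    removals = {int(y): float(v) for y, v in (future_removals or {}).items()}
    c, d, _ = samples.params.shape
    n = c * d
    rmax = samples.params[:, :, 0].reshape(n)
    k = samples.params[:, :, 1].reshape(n)
    z = samples.params[:, :, 2].reshape(n)
    q = samples.params[:, :, 3].reshape(n)
    s = np.sqrt(samples.params[:, :, 4].reshape(n))
    tau = np.sqrt(samples.params[:, :, 5].reshape(n))
    p = samples.p[:, :, -1].reshape(n).copy()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(10,)))
    rows = []
    n_floored = 0
    for year in range(last + 1, horizon_year + 1):
        rem_k = removals.get(year - 1, 0.0) / 1000.0 / k
        bracket = p + rmax * p * (1.0 - p**z) - rem_k
        floored = bracket <= floor
        n_floored += int(floored.sum())
        bracket = np.where(floored, floor, bracket)
        p = bracket * np.exp(s * rng.standard_normal(n))
        i_pred = q * k * p * np.exp(tau * rng.standard_normal(n))
        qs = np.percentile(i_pred, [2.5, 50, 97.5])
        rows.append(
            {
                "year": year,
                "mean": i_pred.mean(),
                "sd": i_pred.std(ddof=1),
                "2.5%": qs[0],
                "median": qs[1],
                "97.5%": qs[2],
                "n_floored": int(floored.sum()),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# sensitivity analysis


@dataclass
class SensitivityRun:
    """One alternative-prior fit and its deltas against the base case."""

    preset: str
    altered_parameter: str
    summary: pd.DataFrame
    deltas: pd.Series
    quantiles: pd.DataFrame | None = None
    samples: PosteriorSamples | None = None


def run_sensitivity(
    data: FitData,
    base_samples: PosteriorSamples,
    preset_ids: Sequence[str],
    variant: ModelVariant | None = None,
    config: MCMCConfig | None = None,
    *,
    keep_samples: bool = False,
) -> list[SensitivityRun]:
    """Refit under each named alternative prior, same data and seed policy.

    Each preset changes exactly one marginal prior from the base case.
    Deltas are differences of posterior medians against the base-case fit.
    """
    variant = variant or base_samples.variant
    config = config or base_samples.config
    base_med = base_samples.summary()["median"]
    runs = []
    for pid in preset_ids:
        if pid == "base":
            priors = PriorSpec.default()
            altered = "none"
        else:
            altered, _ = SENSITIVITY_PRESETS[pid]
            priors = PriorSpec.preset(pid)
        fit = sample_posterior(data, priors, variant, config)
        summ = fit.summary()
        qs = pd.DataFrame(
            {
                name: np.percentile(fit.flat(name), [2.5, 25, 50, 75, 97.5])
                for name in fit.param_names
            },
            index=["2.5%", "25%", "50%", "75%", "97.5%"],
        ).T
        runs.append(
            SensitivityRun(
                preset=pid,
                altered_parameter=altered,
                summary=summ,
                deltas=summ["median"] - base_med,
                quantiles=qs,
                samples=fit if keep_samples else None,
            )
        )
    return runs


def sensitivity_table(runs: Sequence[SensitivityRun]) -> pd.DataFrame:
    """Quantile table (2.5/25/50/75/97.5%) per preset and parameter."""
    rows = []
    for run in runs:
        q = run.quantiles
        for name in q.index:
            row = {"preset": run.preset, "parameter": name}
            row.update({c: q.loc[name, c] for c in q.columns})
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# model comparison


def compare_models(
    fits: Sequence[tuple[PosteriorSamples, PPCResult]],
    *,
    tie_threshold: float = 2.0,
) -> pd.DataFrame:
    """Rank variant fits by DIC; ties within ``tie_threshold`` are flagged.

    All fits must share the data horizon.  Returns one row per fit with the
    variant label, Bayesian p-value, mean deviance, pV and DIC, sorted by
    DIC.
    """
    if not fits:
        raise ValueError("no fits supplied")
    years0 = fits[0][0].years
    rows = []
    for samples, ppc in fits:
        if not np.array_equal(samples.years, years0):
            raise ValueError("fits cover different data horizons")
        d = compute_dic(samples)
        rows.append(
            {
                "variant": samples.variant.label(),
                "bayesian_p": ppc.p_value,
                "mean_deviance": d.mean_deviance,
                "pV": d.p_v,
                "DIC": d.dic,
            }
        )
    out = pd.DataFrame(rows).sort_values("DIC").reset_index(drop=True)
    out["tied_with_best"] = out["DIC"] - out["DIC"].iloc[0] < tie_threshold
    return out
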