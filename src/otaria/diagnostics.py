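"""MCMC convergence diagnostics: Gelman-Rubin, Geweke, Heidelberger-Welch,
autocorrelation.

The numerical procedures follow the classical CODA formulations (spectral
density at frequency zero estimated from a Yule-Walker AR fit with AIC order
selection; the Cramer-von-Mises stationarity test with Brownian-bridge
statistic), so results are directly comparable with the R reference
implementations to floating precision.

Thresholds used by :func:`diagnose`: R-hat <= 1.05 per parameter, two-sided
Geweke p > 0.05 per chain-parameter, Heidelberger-Welch stationarity pass per
chain-parameter, and thinned-scale lag-1 autocorrelation below a configured
bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.tsa.stattools import acf as _sm_acf

__all__ = [
    "gelman_rubin",
    "geweke",
    "heidelberger_welch",
    "autocorrelation",
    "spectral_density_zero",
    "DiagnosticsReport",
    "diagnose",
]


# --------------------------------------------------------------------------
# spectral density at frequency zero (AR/AIC estimator)

def _ar_yulewalker_aic(x: np.ndarray):
    """Yule-Walker AR fit with AIC order selection.

    Returns (order, coefficients, prediction variance) with the small-sample
    variance correction n/(n - (order+1)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    order_max = int(min(n - 1, np.floor(10 * np.log10(n))))
    if order_max < 1:
        raise ValueError("series too short for AR fit")
    # autocovariances with denominator n
    r = np.array(
        [np.dot(xc[: n - k], xc[k:]) / n for k in range(order_max + 1)]
    )
    if r[0] == 0:
        raise ValueError("zero-variance series")
    # Levinson-Durbin recursion
    var_pred = np.empty(order_max + 1)
    var_pred[0] = r[0]
    phi_prev = np.zeros(0)
    coefs = []
    for m in range(1, order_max + 1):
        if m == 1:
            k_m = r[1] / r[0]
            phi = np.array([k_m])
        else:
            num = r[m] - np.dot(phi_prev, r[m - 1 : 0 : -1])
            k_m = num / var_pred[m - 1]
            phi = np.concatenate([phi_prev - k_m * phi_prev[::-1], [k_m]])
        var_pred[m] = var_pred[m - 1] * (1.0 - k_m * k_m)
        coefs.append(phi)
        phi_prev = phi
    aic = n * np.log(var_pred) + 2 * np.arange(order_max + 1) + 2
    order = int(np.argmin(aic))
    ar = coefs[order - 1] if order else np.zeros(0)
    vp = var_pred[order] * n / (n - (order + 1))
    return order, ar, vp


def spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of the series at frequency zero, var_pred/(1-sum ar)^2.

    Returns 0.0 for a series that is exactly constant (or an exact linear
    trend), mirroring the reference behaviour.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    # residual sd of a linear-trend fit ~ 0 -> degenerate
    t = np.arange(1, n + 1, dtype=float)
    beta = np.polyfit(t, x, 1)
    resid = x - np.polyval(beta, t)
    if np.allclose(resid.std(ddof=1), 0.0, atol=1.5e-8):
        return 0.0
    order, ar, vp = _ar_yulewalker_aic(x)
    return float(vp / (1.0 - ar.sum()) ** 2)


# --------------------------------------------------------------------------
# input adapters

def _param_chain_matrix(samples, name=None) -> dict[str, np.ndarray]:
    """Return {parameter: (n_chains, n_draws) array} from PosteriorSamples or
    a raw 2-D/3-D array."""
    if hasattr(samples, "params") and hasattr(samples, "param_names"):
        names = samples.estimated_names()
        if name is not None:
            names = [name]
        out = {}
        for nm in names:
            j = samples.param_names.index(nm)
            out[nm] = samples.params[:, :, j]
        return out
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 2:
        return {"param": arr}
    if arr.ndim == 3:
        return {f"param{j}": arr[:, :, j] for j in range(arr.shape[2])}
    raise ValueError("expected PosteriorSamples or a (chains, draws[, k]) array")


# --------------------------------------------------------------------------
# Gelman-Rubin

def gelman_rubin(samples) -> pd.Series:
    """Potential scale reduction factor per parameter (point estimate).

    Uses the classical between/within decomposition with the
    degrees-of-freedom adjustment.  Exactly identical chains give 1.0; the
    estimate is floored at 1.0.  Requires >= 2 chains.
    """
    mats = _param_chain_matrix(samples)
    out = {}
    for nm, mat in mats.items():
        m, n = mat.shape
        if m < 2:
            raise ValueError("Gelman-Rubin needs at least two chains")
        s2 = mat.var(axis=1, ddof=1)
        xbar = mat.mean(axis=1)
        w = s2.mean()
        b = n * xbar.var(ddof=1)
        if b == 0 and w == 0:
            out[nm] = 1.0
            continue
        if w == 0:
            out[nm] = np.inf
            continue
        muhat = xbar.mean()
        var_w = s2.var(ddof=1) / m
        var_b = 2 * b**2 / (m - 1)
        cov_ws = np.cov(s2, xbar**2, ddof=1)[0, 1]
        cov_wx = np.cov(s2, xbar, ddof=1)[0, 1]
        cov_wb = (n / m) * (cov_ws - 2 * muhat * cov_wx)
        V = (n - 1) * w / n + (1 + 1 / m) * b / n
        var_V = (
            (n - 1) ** 2 * var_w
            + (1 + 1 / m) ** 2 * var_b
            + 2 * (n - 1) * (1 + 1 / m) * cov_wb
        ) / n**2
        if var_V <= 0:
            df_adj = 1.0
        else:
            df_V = 2 * V**2 / var_V
            df_adj = (df_V + 3) / (df_V + 1)
        r2 = (n - 1) / n + (1 + 1 / m) * b / (n * w)
        out[nm] = max(1.0, float(np.sqrt(df_adj * r2)))
    return pd.Series(out, name="rhat")


# --------------------------------------------------------------------------
# Geweke

def geweke(samples, frac_first: float = 0.1, frac_last: float = 0.5) -> pd.DataFrame:
    """Geweke's spectral z-test comparing early and late window means.

    One row per (parameter, chain) with the z-score and the two-sided p-value.
    The window variances use the AR spectral estimator, so the test is valid
    for autocorrelated chains.  Raises on a constant chain.
    """
    if not 0 < frac_first < 1 or not 0 < frac_last < 1:
        raise ValueError("fractions must lie in (0, 1)")
    if frac_first + frac_last > 1:
        raise ValueError("windows overlap")
    mats = _param_chain_matrix(samples)
    rows = []
    for nm, mat in mats.items():
        for c, x in enumerate(mat):
            n = len(x)
            first = x[: int(np.ceil(1 + frac_first * (n - 1)))]
            last = x[int(np.floor(n - frac_last * (n - 1))) - 1 :]
            if np.ptp(x) == 0:
                raise ValueError(f"constant chain for {nm!r}")
            v1 = spectral_density_zero(first) / len(first)
            v2 = spectral_density_zero(last) / len(last)
            if v1 + v2 == 0:
                raise ValueError(f"degenerate windows for {nm!r}")
            z = (first.mean() - last.mean()) / np.sqrt(v1 + v2)
            rows.append(
                {
                    "parameter": nm,
                    "chain": c,
                    "z": z,
                    "p": 2 * stats.norm.sf(abs(z)),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Heidelberger-Welch

def _pcramer(q: float, eps: float = 1e-5) -> float:
    """CDF of the Cramer-von-Mises limiting distribution (series expansion)."""
    total = 0.0
    for k in range(4):
        u = (4 * k + 1) ** 2 / (16 * q)
        if u > -np.log(eps):
            continue
        zc = (
            special.gamma(k + 0.5)
            * np.sqrt(4 * k + 1)
            / (special.gamma(k + 1.0) * np.pi ** 1.5 * np.sqrt(q))
        )
        with np.errstate(invalid="ignore", over="ignore"):
            term = zc * np.exp(-u) * special.kv(0.25, u)
        if np.isfinite(term):
            total += term
    return float(total)


def heidelberger_welch(
    samples, eps: float = 0.1, pvalue: float = 0.05
) -> pd.DataFrame:
    """Two-stage stationarity and halfwidth test per chain-parameter.

    Stage 1 applies the Cramer-von-Mises test to the chain, discarding
    leading 10% blocks until it passes (or half the chain is gone); stage 2
    checks that the 95% halfwidth of the retained mean is within ``eps`` of
    the mean.  Columns mirror the classical report: stationarity pass, start
    iteration, p-value, halfwidth pass, mean, halfwidth.
    """
    mats = _param_chain_matrix(samples)
    rows = []
    for nm, mat in mats.items():
        for c, x in enumerate(mat):
            n1 = len(x)
            if np.ptp(x) == 0:
                raise ValueError(f"constant chain for {nm!r}")
            s0 = spectral_density_zero(x[int(np.ceil(n1 / 2)) - 1 :])
            start_vec = np.arange(1, n1 / 2 + 1, n1 / 10)
            converged = False
            pval = np.nan
            y = x
            nstart = None
            for s in start_vec:
                y = x[int(np.ceil(s)) - 1 :]
                n = len(y)
                ybar = y.mean()
                bridge = np.cumsum(y) - ybar * np.arange(1, n + 1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    stat = np.sum(bridge**2 / (n * s0)) / n
                if np.isnan(stat):
                    break
                pval = 1 - _pcramer(stat)
                if pval > pvalue:
                    converged = True
                    nstart = int(np.ceil(s))
                    break
            if converged:
                n = len(y)
                s0ci = spectral_density_zero(y)
                halfwidth = 1.96 * np.sqrt(s0ci / n)
                ybar = y.mean()
                passed_hw = bool(abs(halfwidth / ybar) <= eps) if ybar != 0 else False
            else:
                halfwidth = np.nan
                ybar = np.nan
                passed_hw = None
                nstart = None
            rows.append(
                {
                    "parameter": nm,
                    "chain": c,
                    "stationarity": converged,
                    "start": nstart,
                    "p": pval,
                    "halfwidth_ok": passed_hw,
                    "mean": ybar,
                    "halfwidth": halfwidth,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# autocorrelation

def autocorrelation(samples, max_lag: int = 20, flag_bound: float = 0.1) -> pd.DataFrame:
    """Per-parameter autocorrelation of the pooled thinned draws.

    One row per (parameter, chain, lag); ``flagged`` marks parameters whose
    absolute lag-1 autocorrelation (at the thinned scale) exceeds
    ``flag_bound``.
    """
    mats = _param_chain_matrix(samples)
    rows = []
    for nm, mat in mats.items():
        for c, x in enumerate(mat):
            if max_lag >= len(x):
                raise ValueError("max_lag must be below the number of draws")
            a = _sm_acf(x, nlags=max_lag, fft=True)
            for lag, val in enumerate(a):
                rows.append(
                    {
                        "parameter": nm,
                        "chain": c,
                        "lag": lag,
                        "acf": val,
                        "flagged": bool(lag == 1 and abs(val) > flag_bound),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# combined report

@dataclass
class DiagnosticsReport:
    """The full diagnostic battery with an overall pass flag."""

    rhat: pd.Series
    geweke: pd.DataFrame
    heidelberger: pd.DataFrame
    acf: pd.DataFrame
    rhat_threshold: float
    geweke_alpha: float
    acf_bound: float

    @property
    def passed(self) -> bool:
        return (
            bool((self.rhat <= self.rhat_threshold).all())
            and bool((self.geweke["p"] > self.geweke_alpha).all())
            and bool(self.heidelberger["stationarity"].all())
            and not bool(
                self.acf.loc[self.acf["lag"] == 1, "flagged"].any()
            )
        )

    def summary(self) -> pd.DataFrame:
        g = self.geweke.groupby("parameter")["p"].min()
        h = self.heidelberger.groupby("parameter")["stationarity"].all()
        a = (
            self.acf[self.acf["lag"] == 1]
            .groupby("parameter")["acf"]
            .apply(lambda s: s.abs().max())
        )
        return pd.DataFrame(
            {
                "rhat": self.rhat,
                "geweke_min_p": g,
                "hw_stationary": h,
                "acf1_max": a,
            }
        )


def diagnose(
    samples,
    rhat_threshold: float = 1.05,
    geweke_alpha: float = 0.05,
    acf_bound: float = 0.1,
    max_lag: int = 20,
) -> DiagnosticsReport:
    """Run the full battery on posterior samples."""
    return DiagnosticsReport(
        rhat=gelman_rubin(samples),
        geweke=geweke(samples),
        heidelberger=heidelberger_welch(samples),
        acf=autocorrelation(samples, max_lag=max_lag, flag_bound=acf_bound),
        rhat_threshold=rhat_threshold,
        geweke_alpha=geweke_alpha,
        acf_bound=acf_bound,
    )
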