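"""Theta-logistic state-space model: parameters, priors, and log-densities.

The population model couples a discrete-time surplus-production process with
lognormal observation error.  The latent state is relative abundance
``P_t = N_t / K`` and the state equation is

    P_t = (P_{t-1} + R_max P_{t-1} (1 - P_{t-1}^z) - H_{t-1}/K - M_{t-1}/K) e^{U_t}

with i.i.d. process deviations ``U_t ~ Normal(0, sigma2)``.  The population is
assumed to sit at carrying capacity before removals begin, so the whole
pre-harvest block shares a single deviation: ``P_t = e^{U_1}`` for all years up
to ``EQUILIBRIUM_END``.  Survey indices are noisy proportional measurements,

    I_t = q K P_t e^{V_t},   V_t ~ Normal(0, tau2).

Units: ``K``, ``N_t`` and ``I_t`` are in thousands of animals; removals ``H_t``
and ``M_t`` are entered in animals and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "EQUILIBRIUM_END",
    "MODEL_START",
    "MODEL_END",
    "PARAM_NAMES",
    "ModelParams",
    "Prior",
    "PriorSpec",
    "ModelVariant",
    "LatentTrajectory",
    "surplus_production",
    "state_transition",
    "observation_loglik",
    "log_prior",
    "joint_log_density",
]

#: Last year of the assumed pre-removal equilibrium block (N_t = K before this).
EQUILIBRIUM_END = 1928
#: Default model horizon.
MODEL_START = 1900
MODEL_END = 2013

PARAM_NAMES = ("r_max", "k", "z", "q", "sigma2", "tau2")


@dataclass(frozen=True)
class ModelParams:
    """The six estimable quantities of the production model.

    Attributes
    ----------
    r_max : float
        Maximum per-capita rate of increase (1/yr), the growth rate as N -> 0.
    k : float
        Carrying capacity, in thousands of animals.
    z : float
        Shape parameter of the theta-logistic; z = 1 is the Schaefer
        (ordinary logistic) model, z > 1 pushes peak production above K/2.
    q : float
        Detectability coefficient: fraction of the population a survey sees.
    sigma2 : float
        Process variance on the log scale.
    tau2 : float
        Observation variance on the log scale.
    """

    r_max: float
    k: float
    z: float
    q: float
    sigma2: float
    tau2: float

    def __post_init__(self) -> None:
        if not (self.r_max > 0):
            raise ValueError(f"r_max must be > 0, got {self.r_max}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.z > 0):
            raise ValueError(f"z must be > 0, got {self.z}")
        if not (0 < self.q < 1):
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if not (self.sigma2 > 0):
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")
        if not (self.tau2 > 0):
            raise ValueError(f"tau2 must be > 0, got {self.tau2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_max, self.k, self.z, self.q, self.sigma2, self.tau2])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "ModelParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class ModelVariant:
    """One of the six model formulations: density dependence x bycatch series."""

    density_dependence: Literal["linear", "non-linear"] = "non-linear"
    bycatch_mode: Literal["TC", "AC", "MC", "none"] = "TC"

    def __post_init__(self) -> None:
        if self.density_dependence not in ("linear", "non-linear"):
            raise ValueError(f"unknown density dependence {self.density_dependence!r}")
        if self.bycatch_mode not in ("TC", "AC", "MC", "none"):
            raise ValueError(f"unknown bycatch mode {self.bycatch_mode!r}")

    @property
    def z_fixed(self) -> bool:
        return self.density_dependence == "linear"

    def label(self) -> str:
        return f"{self.density_dependence}/{self.bycatch_mode}"


ALL_VARIANTS = tuple(
    ModelVariant(dd, bm)
    for dd in ("linear", "non-linear")
    for bm in ("TC", "AC", "MC")
)


@dataclass(frozen=True)
class Prior:
    """One marginal prior: a distribution family name plus its two arguments.

    Families: ``lognormal(mu, sigma)`` (log-scale mean/sd), ``uniform(lo, hi)``,
    ``beta(a, b)``, ``invgamma(shape, scale)`` with density proportional to
    ``x^-(shape+1) exp(-scale/x)``, and ``fixed(value, .)``.
    """

    dist: Literal["lognormal", "uniform", "beta", "invgamma", "fixed"]
    a: float
    b: float = 0.0

    def _frozen(self):
        if self.dist == "lognormal":
            return stats.lognorm(s=self.b, scale=np.exp(self.a))
        if self.dist == "uniform":
            return stats.uniform(loc=self.a, scale=self.b - self.a)
        if self.dist == "beta":
            return stats.beta(self.a, self.b)
        if self.dist == "invgamma":
            return stats.invgamma(self.a, scale=self.b)
        raise ValueError(f"no scipy distribution for {self.dist!r}")

    def logpdf(self, x: float) -> float:
        if self.dist == "fixed":
            return 0.0 if x == self.a else -np.inf
        return float(self._frozen().logpdf(x))

    def sample(self, rng: np.random.Generator, size=None):
        if self.dist == "fixed":
            return np.full(size, self.a) if size is not None else self.a
        return self._frozen().rvs(size=size, random_state=rng)

    def median(self) -> float:
        if self.dist == "fixed":
            return self.a
        return float(self._frozen().median())


def _default_priors() -> dict:
    return {
        "r_max": Prior("lognormal", -2.9, 0.5),
        "k": Prior("lognormal", 5.7, 0.8),
        "z": Prior("uniform", 0.0001, 10.0),
        "q": Prior("beta", 2.2, 2.0),
        "sigma2": Prior("invgamma", 1.0, 0.4),
        "tau2": Prior("invgamma", 3.0, 0.8),
    }


@dataclass(frozen=True)
class PriorSpec:
    """Joint prior over the six parameters (independent marginals).

    The default is the base-case specification: vague lognormals for R_max
    (median e^-2.9 ~= 0.055, CV 50%) and K (median e^5.7 ~= 299 thousand,
    CV 100%), uniform z on (1e-4, 10), beta(2.2, 2) for q (mean ~= 0.52), and
    diffuse inverse-gammas for the two variances.  ``preset(name)`` returns the
    sen1-sen9 single-prior alternatives used in the sensitivity analysis.
    """

    priors: Mapping[str, Prior] = field(default_factory=_default_priors)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.priors)
        if missing:
            raise ValueError(f"priors missing for {sorted(missing)}")

    def __getitem__(self, name: str) -> Prior:
        return self.priors[name]

    def with_prior(self, name: str, prior: Prior) -> "PriorSpec":
        if name not in PARAM_NAMES:
            raise KeyError(name)
        d = dict(self.priors)
        d[name] = prior
        return PriorSpec(d)

    @classmethod
    def default(cls) -> "PriorSpec":
        return cls()

    @classmethod
    def preset(cls, name: str) -> "PriorSpec":
        try:
            param, prior = SENSITIVITY_PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; valid: {sorted(SENSITIVITY_PRESETS)}"
            ) from None
        return cls().with_prior(param, prior)

    def sample_params(self, rng: np.random.Generator) -> ModelParams:
        """Draw one ModelParams from the joint prior (used for chain inits)."""
        vals = {}
        for name in PARAM_NAMES:
            p = self.priors[name]
            v = float(p.sample(rng))
            if name == "q":
                v = min(max(v, 1e-6), 1 - 1e-6)
            vals[name] = max(v, 1e-8)
        return ModelParams(**vals)


#: Alternative single-prior specifications for the sensitivity analysis.
SENSITIVITY_PRESETS: dict[str, tuple[str, Prior]] = {
    "sen1": ("z", Prior("uniform", 0.0001, 20.0)),
    "sen2": ("k", Prior("uniform", 0.0001, 1000.0)),
    "sen3": ("k", Prior("lognormal", 7.4, 0.8)),
    "sen4": ("k", Prior("lognormal", 4.0, 0.8)),
    "sen5": ("k", Prior("lognormal", 5.7, 1.25)),
    "sen6": ("sigma2", Prior("invgamma", 2.0, 0.8)),
    "sen7": ("sigma2", Prior("invgamma", 0.5, 0.2)),
    "sen8": ("tau2", Prior("invgamma", 6.0, 1.6)),
    "sen9": ("tau2", Prior("invgamma", 1.5, 0.4)),
}


@dataclass
class LatentTrajectory:
    """Relative-abundance states P_t with their process deviations U_t.

    ``years`` is a contiguous integer array; ``p`` holds P_t = N_t/K and ``u``
    the per-year log-scale deviation actually applied in that year's update.
    Years up to EQUILIBRIUM_END share one deviation (stored repeated).
    """

    years: np.ndarray
    p: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.p = np.asarray(self.p, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if not (len(self.years) == len(self.p) == len(self.u)):
            raise ValueError("years, p, u must have equal length")
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        if np.any(self.p <= 0):
            raise ValueError("all states must be strictly positive")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("deviations must be finite")

    def n(self, k: float) -> np.ndarray:
        """Absolute abundance N_t = K * P_t (thousands)."""
        return k * self.p

    def free_u(self) -> np.ndarray:
        """The free deviation vector: one shared pre-equilibrium draw, then
        one per year after EQUILIBRIUM_END."""
        pre = self.years <= EQUILIBRIUM_END
        out = []
        if pre.any():
            u_pre = self.u[pre]
            if not np.allclose(u_pre, u_pre[0]):
                raise ValueError("pre-equilibrium block must share one deviation")
            out.append(u_pre[:1])
        out.append(self.u[~pre])
        return np.concatenate(out)

    def at(self, year: int) -> float:
        i = int(year) - int(self.years[0])
        if not 0 <= i < len(self.years):
            raise KeyError(f"year {year} outside trajectory")
        return float(self.p[i])


def surplus_production(n, params: ModelParams):
    """Theta-logistic (Pella-Tomlinson) production R_max N (1 - (N/K)^z).

    ``n`` in the same units as ``params.k`` (thousands); vectorized over n.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("abundance must be >= 0")
    out = params.r_max * n * (1.0 - (n / params.k) ** params.z)
    return float(out) if out.ndim == 0 else out


def production_peak_abundance(params: ModelParams) -> float:
    """Abundance maximizing surplus production: K (1+z)^(-1/z)."""
    return params.k * (1.0 + params.z) ** (-1.0 / params.z)


def state_transition(
    p_prev: float,
    h_prev: float,
    m_prev: float,
    params: ModelParams,
    u_t: float,
    *,
    on_infeasible: Literal["raise", "neginf"] = "raise",
) -> float:
    """One step of the state equation.  Removals are in animals.

    The pre-noise bracket ``P + R_max P (1 - P^z) - H/K - M/K`` must be
    positive; what happens otherwise depends on the caller.  Simulation
    rejects the schedule (``raise``); inference treats the proposal as having
    zero density (``neginf`` returns nan, which the density layer maps to
    -inf).
    """
    if p_prev <= 0:
        raise ValueError("p_prev must be > 0")
    rem = (h_prev + m_prev) / 1000.0 / params.k  # animals -> relative units
    bracket = p_prev + params.r_max * p_prev * (1.0 - p_prev**params.z) - rem
    if bracket <= 0:
        if on_infeasible == "raise":
            raise ValueError(
                f"removals exceed pre-removal population (bracket={bracket:.4g})"
            )
        return float("nan")
    return bracket * np.exp(u_t)


def observation_loglik(i_t, p_t, params: ModelParams) -> float:
    """Lognormal log-density of index I_t (thousands) given state P_t.

    log I_t ~ Normal(log(q K P_t), tau2).  NaN observations (missing survey
    years) contribute zero.  Vectorized; returns the sum over entries.
    """
    i_t = np.atleast_1d(np.asarray(i_t, dtype=float))
    p_t = np.atleast_1d(np.asarray(p_t, dtype=float))
    p_t = np.broadcast_to(p_t, i_t.shape)
    obs = ~np.isnan(i_t)
    if not obs.any():
        return 0.0
    i_obs, p_obs = i_t[obs], p_t[obs]
    if np.any(i_obs <= 0) or np.any(p_obs <= 0):
        raise ValueError("observed indices and states must be > 0")
    mu = np.log(params.q * params.k * p_obs)
    resid = np.log(i_obs) - mu
    tau2 = params.tau2
    ll = -np.log(i_obs) - 0.5 * np.log(2 * np.pi * tau2) - resid**2 / (2 * tau2)
    return float(ll.sum())


def log_prior(params: ModelParams, priors: PriorSpec) -> float:
    """Sum of marginal prior log-densities; -inf off support."""
    total = 0.0
    for name in PARAM_NAMES:
        lp = priors[name].logpdf(getattr(params, name))
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


def process_loglik(trajectory: LatentTrajectory, params: ModelParams) -> float:
    """Gaussian log-density of the free process deviations under N(0, sigma2)."""
    u = trajectory.free_u()
    s2 = params.sigma2
    return float(
        -0.5 * len(u) * np.log(2 * np.pi * s2) - np.sum(u**2) / (2 * s2)
    )


def joint_log_density(
    params: ModelParams,
    trajectory: LatentTrajectory,
    data,
    priors: PriorSpec,
    variant: ModelVariant | None = None,
) -> float:
    """Joint log-density log p(params) + log p(U | params) + log p(I | P, params).

    ``data`` needs attributes ``index`` (ObservedIndexSeries-like with
    ``years`` and ``values`` where missing years are NaN) and removal series
    accessors ``h(year)``/``m(year)``; see :class:`otaria.mcmc.FitData`.
    Returns -inf (never raises) for out-of-support parameters or a trajectory
    whose pre-noise bracket goes non-positive.
    """
    if variant is not None and variant.z_fixed and params.z != 1.0:
        return -np.inf
    lp = log_prior(params, priors)
    if not np.isfinite(lp):
        return -np.inf
    # infeasibility check: replay the deterministic bracket along the trajectory
    yrs = trajectory.years
    for i in range(1, len(yrs)):
        if yrs[i] <= EQUILIBRIUM_END:
            continue
        y_prev = int(yrs[i - 1])
        try:
            val = state_transition(
                float(trajectory.p[i - 1]),
                data.h(y_prev),
                data.m(y_prev),
                params,
                float(trajectory.u[i]),
                on_infeasible="neginf",
            )
        except ValueError:
            return -np.inf
        if not np.isfinite(val):
            return -np.inf
    lproc = process_loglik(trajectory, params)
    idx = data.index
    # align observation years to trajectory years
    vals = np.full(len(yrs), np.nan)
    for y, v in zip(idx.years, idx.values):
        if not np.isnan(v) and yrs[0] <= y <= yrs[-1]:
            vals[int(y) - int(yrs[0])] = v
    lobs = observation_loglik(vals, trajectory.p, params)
    return lp + lproc + lobs
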