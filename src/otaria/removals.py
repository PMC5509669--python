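"""Reconstruction of removal series: commercial harvest and fisheries bycatch.

The only record of the commercial harvest is cumulative leather-export totals
reported at roughly five-year intervals.  A Gompertz curve with additive normal
error is fitted to those cumulative points and annual harvests are read off as
consecutive-year differences of the fitted curve.  Bycatch is reconstructed
from nominal fishing effort (boat-days per year, by fishing type) multiplied by
a constant per-type catch rate, under three alternative rate assumptions:
Total (TC), Average (AC) and Maximum (MC) catch sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HarvestSeries",
    "BycatchSeries",
    "EffortTable",
    "BycatchRateTable",
    "RemovalSchedule",
    "GompertzFit",
    "gompertz",
    "fit_gompertz_cumulative",
    "annual_harvest_from_fit",
    "compute_bycatch",
]

logger = logging.getLogger(__name__)

BYCATCH_ERA = (1989, 2013)
HARVEST_ERA = (1929, 1960)

RATE_COLUMNS = {"TC": "TCR", "AC": "ACR", "MC": "MCR"}


@dataclass(frozen=True)
class HarvestSeries:
    """Annual commercial harvest H_t (animals/yr), indexed by year."""

    series: pd.Series

    def __post_init__(self) -> None:
        s = self.series.astype(float)
        if (s < 0).any():
            raise ValueError("harvest must be >= 0 in every year")
        object.__setattr__(self, "series", s)

    def at(self, year: int) -> float:
        return float(self.series.get(year, 0.0))

    def total(self) -> float:
        return float(self.series.sum())


@dataclass(frozen=True)
class BycatchSeries:
    """Annual incidental catch M_t (animals/yr) under one rate assumption."""

    series: pd.Series
    mode: str = "TC"

    def __post_init__(self) -> None:
        if self.mode not in ("TC", "AC", "MC", "none"):
            raise ValueError(f"unknown bycatch mode {self.mode!r}")
        s = self.series.astype(float)
        if (s < 0).any():
            raise ValueError("bycatch must be >= 0 in every year")
        object.__setattr__(self, "series", s)

    def at(self, year: int) -> float:
        return float(self.series.get(year, 0.0))

    @classmethod
    def zero(cls) -> "BycatchSeries":
        return cls(pd.Series(dtype=float), mode="none")


@dataclass(frozen=True)
class EffortTable:
    """Nominal fishing effort E_it (boat-days/yr): DataFrame with columns
    ``year``, ``fishing_type``, ``days``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"year", "fishing_type", "days"}
        if missing := required - set(t.columns):
            raise ValueError(f"effort table missing columns {sorted(missing)}")
        if (t["days"] < 0).any():
            raise ValueError("effort must be >= 0")

    def types(self) -> list[str]:
        return sorted(self.table["fishing_type"].unique())


@dataclass(frozen=True)
class BycatchRateTable:
    """Per-type catch rates (sea lions per boat per day): DataFrame with
    columns ``fishing_type``, ``TCR``, ``ACR``, ``MCR``."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"fishing_type", "TCR", "ACR", "MCR"}
        if missing := required - set(t.columns):
            raise ValueError(f"rate table missing columns {sorted(missing)}")
        for col in ("TCR", "ACR", "MCR"):
            if (t[col] < 0).any() or not np.isfinite(t[col]).all():
                raise ValueError(f"{col} must be finite and >= 0")
        if (t["ACR"] > t["MCR"]).any():
            raise ValueError("average catch rate cannot exceed maximum")

    def rate(self, fishing_type: str, mode: str) -> float:
        col = RATE_COLUMNS[mode]
        row = self.table[self.table["fishing_type"] == fishing_type]
        if row.empty:
            raise KeyError(f"no bycatch rate for fishing type {fishing_type!r}")
        return float(row[col].iloc[0])


@dataclass(frozen=True)
class RemovalSchedule:
    """Combined removal inputs to the state equation: H_t plus M_t."""

    harvest: HarvestSeries
    bycatch: BycatchSeries

    def h(self, year: int) -> float:
        return self.harvest.at(year)

    def m(self, year: int) -> float:
        return self.bycatch.at(year)

    def total_animals(self, year: int) -> float:
        return self.h(year) + self.m(year)

    def as_arrays(self, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.array([self.h(int(y)) for y in years])
        m = np.array([self.m(int(y)) for y in years])
        return h, m


def gompertz(t, asymptote: float, rate: float, inflection: float):
    """Cumulative Gompertz curve A exp(-exp(-k (t - t0)))."""
    t = np.asarray(t, dtype=float)
    out = asymptote * np.exp(-np.exp(-rate * (t - inflection)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GompertzFit:
    """Least-squares Gompertz fit to cumulative-catch points.

    Parameter names (asymptote A, rate k, inflection year t0) are this
    package's own; only the curve family is prescribed by the source records.
    """

    asymptote: float
    rate: float
    inflection: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.asymptote <= 0 or self.rate <= 0:
            raise ValueError("asymptote and rate must be > 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def __call__(self, t):
        return gompertz(t, self.asymptote, self.rate, self.inflection)


class GompertzFitError(RuntimeError):
    """Raised when no multi-start candidate converges; carries the best try."""

    def __init__(self, message: str, best: tuple | None = None):
        super().__init__(message)
        self.best = best


def fit_gompertz_cumulative(
    points: Sequence[tuple[float, float]],
    *,
    already_annual: bool = False,
    n_rate_grid: int = 8,
    n_inflection_grid: int = 8,
) -> GompertzFit:
    """Fit the cumulative Gompertz curve by multi-start least squares.

    ``points`` are (year, cumulative catch) pairs with strictly increasing
    years (>= 4 points); a source table that stores per-period catches
    instead of running totals is accepted with ``already_annual=True`` and
    accumulated first.  The asymptote is initialized at the largest
    cumulative value; rate and inflection start from a grid spanning the
    year range.  Raises :class:`GompertzFitError` naming the best candidate
    if no start converges to a usable optimum.
    """
    pts = sorted(points)
    if already_annual:
        acc = 0.0
        cum = []
        for y, c in pts:
            acc += c
            cum.append((y, acc))
        pts = cum
    if len(pts) < 4:
        raise ValueError("need at least 4 cumulative-catch points")
    years = np.array([p[0] for p in pts], dtype=float)
    catch = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    if np.ptp(catch) <= 0:
        raise GompertzFitError(
            f"cumulative catch shows no growth (constant at {catch[0]:.6g}); "
            "a sigmoid cannot be identified",
            (float(catch[0]), 0.0, float(years[0]), 0.0),
        )

    span = years[-1] - years[0]
    a0 = max(catch.max(), 1e-9)

    def resid(theta):
        la, k, t0 = theta
        return gompertz(years, np.exp(la), k, t0) - catch

    best = None
    for k0 in np.geomspace(0.5 / span, 8.0 / span, n_rate_grid):
        for t0 in np.linspace(years[0], years[-1], n_inflection_grid):
            try:
                sol = least_squares(
                    resid,
                    x0=[np.log(a0 * 1.05), k0, t0],
                    bounds=([np.log(a0 * 0.2), 1e-6, years[0] - 2 * span],
                            [np.log(a0 * 50), 10.0, years[-1] + 2 * span]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.isfinite(best.cost):
        raise GompertzFitError("Gompertz fit failed from every start", None)

    la, k, t0 = best.x
    a = float(np.exp(la))
    dof = max(len(pts) - 3, 1)
    sd = float(np.sqrt(2 * best.cost / dof))
    # degenerate (flat) inputs push the rate to its bound; surface that
    if not best.success or k <= 2e-6:
        raise GompertzFitError(
            f"Gompertz fit degenerate (best: A={a:.6g}, k={k:.3g}, t0={t0:.5g}, "
            f"residual SD={sd:.4g})",
            (a, float(k), float(t0), sd),
        )
    return GompertzFit(a, float(k), float(t0), sd)


def annual_harvest_from_fit(
    fit: GompertzFit,
    year_range: tuple[int, int],
    *,
    extra_events: dict[int, float] | None = None,
) -> HarvestSeries:
    """Annual harvest as consecutive-year differences of the fitted curve.

    H_t = C(t) - C(t-1), clamped at zero (clamping is logged).  Isolated
    harvest events outside the export records (e.g. single-rookery pulses)
    are added on top via ``extra_events``.
    """
    y0, y1 = year_range
    years = np.arange(y0, y1 + 1)
    h = fit(years) - fit(years - 1)
    if (h < 0).any():
        logger.warning(
            "clamping %d negative annual differences to zero", int((h < 0).sum())
        )
        h = np.clip(h, 0.0, None)
    s = pd.Series(h, index=years)
    for year, pulse in (extra_events or {}).items():
        s.loc[int(year)] = s.get(int(year), 0.0) + float(pulse)
    return HarvestSeries(s.sort_index())


def compute_bycatch(
    effort: EffortTable, rates: BycatchRateTable, mode: str
) -> BycatchSeries:
    """Annual bycatch M_t = sum_i rate_i(mode) * E_it.

    ``mode`` selects the rate column (TC/AC/MC); ``none`` returns zeros over
    the effort years.  Every fishing type present in the effort table must
    have a rate row.
    """
    if mode == "none":
        years = sorted(effort.table["year"].unique())
        return BycatchSeries(pd.Series(0.0, index=years), mode="none")
    if mode not in RATE_COLUMNS:
        raise ValueError(f"unknown bycatch mode {mode!r}")
    rate_map = {}
    for ft in effort.types():
        rate_map[ft] = rates.rate(ft, mode)  # KeyError names missing type
    t = effort.table
    m = (
        t.assign(catch=t["fishing_type"].map(rate_map) * t["days"])
        .groupby("year")["catch"]
        .sum()
        .sort_index()
    )
    return BycatchSeries(m, mode=mode)
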