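"""Assembly of the corrected total-abundance index from raw survey counts.

Shore-based surveys rarely covered the whole coast in one season.  Three
empirical regressions, estimated once from the years with best coverage, fill
the gaps:

1. non-pups from pups in the four key breeding rookeries ("4B"):
   ``y = 1.1152 x`` (early surveys counted only pups);
2. animals at non-4B rookeries and haul-outs from the 4B total (log-log):
   ``ln y = -19.982 + 3.1236 ln x``;
3. combined northern + central abundance from the northern total:
   ``y = 1.815 x``.

Each survey year carries flags saying which corrections apply; years whose 4B
rookeries were not all surveyed yield no estimate at all.  The assembled index
is reported in thousands of animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionFactors",
    "SurveyRecord",
    "ObservedIndexSeries",
    "nonpups_from_pups",
    "non4b_from_4b",
    "total_from_northern",
    "assemble_index",
    "DEFAULT_COVERAGE",
    "default_observation_years",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """The three printed regression coefficients (re-fittable, but fixed by
    default)."""

    pup_to_nonpup_slope: float = 1.1152
    non4b_intercept: float = -19.982
    non4b_slope: float = 3.1236
    north_to_total_slope: float = 1.815

    def __post_init__(self) -> None:
        if self.pup_to_nonpup_slope <= 0 or self.non4b_slope <= 0:
            raise ValueError("slopes must be > 0")
        if self.north_to_total_slope <= 0:
            raise ValueError("slopes must be > 0")


def nonpups_from_pups(pups: float, factors: CorrectionFactors | None = None) -> float:
    """Non-pup count in the 4B rookeries predicted from the pup count."""
    if pups < 0:
        raise ValueError("pups must be >= 0")
    f = factors or CorrectionFactors()
    return f.pup_to_nonpup_slope * pups


def non4b_from_4b(total_4b: float, factors: CorrectionFactors | None = None) -> float:
    """Animals at non-4B sites in northern Patagonia predicted from the 4B
    total (log-log regression; excludes the 4B animals themselves)."""
    if total_4b <= 0:
        raise ValueError("total_4b must be > 0 (log-log regression)")
    f = factors or CorrectionFactors()
    return float(np.exp(f.non4b_intercept + f.non4b_slope * np.log(total_4b)))


def total_from_northern(
    northern_total: float, factors: CorrectionFactors | None = None
) -> float:
    """Northern + central Patagonia abundance predicted from the northern
    total (fixed proportionality)."""
    if northern_total < 0:
        raise ValueError("northern_total must be >= 0")
    f = factors or CorrectionFactors()
    return f.north_to_total_slope * northern_total


@dataclass(frozen=True)
class SurveyRecord:
    """One survey year: whichever counts exist plus coverage flags.

    Counts are animals.  ``missing=True`` marks years whose 4B rookeries were
    not all surveyed; these produce no index value.  The ``apply_*`` flags say
    which correction regressions stand in for strata that were not counted.
    """

    year: int
    pups_4b: float | None = None
    nonpups_4b: float | None = None
    total_4b: float | None = None
    other_sites_total: float | None = None
    central_total: float | None = None
    apply_pup_correction: bool = False
    apply_non4b_correction: bool = False
    apply_central_correction: bool = False
    missing: bool = False

    def __post_init__(self) -> None:
        counts = [
            self.pups_4b,
            self.nonpups_4b,
            self.total_4b,
            self.other_sites_total,
            self.central_total,
        ]
        if not self.missing and all(c is None for c in counts):
            raise ValueError(f"year {self.year}: no counts present")
        for c in counts:
            if c is not None and c < 0:
                raise ValueError(f"year {self.year}: negative count")


@dataclass
class ObservedIndexSeries:
    """Corrected total-abundance index I_t in thousands; NaN marks missing
    years."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.years) != len(self.values):
            raise ValueError("years and values must have equal length")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        obs = ~np.isnan(self.values)
        if np.any(self.values[obs] <= 0):
            raise ValueError("observed index values must be > 0")

    @property
    def observed_years(self) -> np.ndarray:
        return self.years[~np.isnan(self.values)]

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    def restrict(self, last_year: int) -> "ObservedIndexSeries":
        keep = self.years <= last_year
        return ObservedIndexSeries(self.years[keep], self.values[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "I": self.values,
                "missing": np.isnan(self.values).astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedIndexSeries":
        df = df.sort_values("year")
        vals = df["I"].to_numpy(dtype=float)
        if "missing" in df.columns:
            vals = np.where(df["missing"].to_numpy(dtype=int) == 1, np.nan, vals)
        return cls(df["year"].to_numpy(dtype=int), vals)


def _total_4b(rec: SurveyRecord, f: CorrectionFactors) -> float:
    if rec.apply_pup_correction:
        if rec.pups_4b is None:
            raise ValueError(
                f"year {rec.year}: pup correction requested without a pup count"
            )
        return rec.pups_4b + nonpups_from_pups(rec.pups_4b, f)
    if rec.total_4b is not None:
        return rec.total_4b
    if rec.pups_4b is not None and rec.nonpups_4b is not None:
        return rec.pups_4b + rec.nonpups_4b
    raise ValueError(f"year {rec.year}: no usable 4B total")


def assemble_index(
    records: Iterable[SurveyRecord],
    factors: CorrectionFactors | None = None,
) -> ObservedIndexSeries:
    """Apply the per-year correction subset and return the index in thousands.

    Composition for fully corrected (pup-only) years: pups -> non-pups
    (factor 1) -> 4B total -> non-4B expansion (factor 2, excluding the 4B
    animals, then summed) -> central scaling (factor 3).  Years flagged
    ``missing`` yield NaN.  Fully surveyed years with no flags pass through as
    the raw summed count.  Deterministic and invariant to record order.
    """
    f = factors or CorrectionFactors()
    recs = sorted(records, key=lambda r: r.year)
    years = [r.year for r in recs]
    if len(set(years)) != len(years):
        dup = sorted({y for y in years if years.count(y) > 1})
        raise ValueError(f"duplicate survey years {dup}")

    out = []
    for rec in recs:
        if rec.missing:
            out.append(np.nan)
            continue
        t4b = _total_4b(rec, f)
        if rec.apply_non4b_correction:
            non4b = non4b_from_4b(t4b, f)
        else:
            if rec.other_sites_total is None:
                raise ValueError(
                    f"year {rec.year}: non-4B count absent and no correction flagged"
                )
            non4b = rec.other_sites_total
        northern = t4b + non4b
        if rec.apply_central_correction:
            total = total_from_northern(northern, f)
        else:
            if rec.central_total is None:
                raise ValueError(
                    f"year {rec.year}: central count absent and no correction flagged"
                )
            total = northern + rec.central_total
        out.append(total / 1000.0)
    return ObservedIndexSeries(np.array(years), np.array(out))


# Survey-coverage pattern of the real monitoring record: year -> (pup_only,
# corrections applied).  Corrections: 1 = pups->non-pups, 2 = non-4B expansion,
# 3 = central scaling; None marks years whose 4B rookeries were not all
# surveyed (no estimate).
DEFAULT_COVERAGE: dict[int, tuple[bool, tuple[int, ...] | None]] = {
    1972: (True, (1, 2, 3)),
    1973: (True, (1, 2, 3)),
    1974: (True, (1, 2, 3)),
    1975: (True, (1, 2, 3)),
    1981: (True, (1, 2, 3)),
    1982: (True, (1, 2, 3)),
    1983: (False, (2, 3)),
    1984: (False, (2, 3)),
    1985: (False, (3,)),
    1986: (False, None),
    1987: (False, None),
    1988: (False, None),
    1989: (False, (2, 3)),
    1990: (False, (3,)),
    1993: (False, None),
    1994: (False, (2, 3)),
    1995: (False, (3,)),
    1996: (False, (3,)),
    1997: (False, (2, 3)),
    1998: (False, (3,)),
    1999: (False, (2, 3)),
    2000: (False, (3,)),
    2001: (False, (2, 3)),
    2002: (False, None),
    2003: (False, None),
    2004: (False, None),
    2005: (False, (3,)),
    2006: (False, (3,)),
    2007: (False, (3,)),
    2009: (False, (3,)),
    2010: (False, None),
    2011: (False, None),
    2013: (False, None),
    2015: (False, (3,)),
}


def default_observation_years(last_year: int | None = None) -> np.ndarray:
    """Years with a usable survey estimate under the default coverage
    pattern (24 years between 1972 and 2015)."""
    years = np.array(
        sorted(y for y, (_, corr) in DEFAULT_COVERAGE.items() if corr is not None)
    )
    if last_year is not None:
        years = years[years <= last_year]
    return years
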