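"""Single-age period life tables.

The central exchange object is :class:`LifeTable`: age-specific central death
rates ``mx``, death probabilities ``qx`` (the probability of dying between
exact ages x and x+1), survivorship ``lx`` on a radix of 1.0, and the death
distribution ``dx``.  Everything downstream — spline smoothing, relational
models, expected hazards for net survival — consumes this object.

Death probabilities are obtained from central rates by the exponential
conversion ``qx = 1 − exp(−mx)`` (constant hazard within each one-year age
interval), the convention used by the EUROCARE life-table methodology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .exceptions import CoverageError, DegenerateDataError, InvalidInputError

__all__ = [
    "MortalityCounts",
    "LifeTable",
    "qx_from_mx_exponential",
    "build_lifetable_from_qx",
    "build_lifetable_from_counts",
    "median_age_of_deaths",
    "pool_years",
]


@dataclass(frozen=True)
class MortalityCounts:
    """Deaths and person-years at risk by single age for one calendar year."""

    year: int
    age: np.ndarray
    deaths: np.ndarray
    person_years: np.ndarray

    def __post_init__(self):
        age = np.asarray(self.age, dtype=int)
        deaths = np.asarray(self.deaths, dtype=float)
        py = np.asarray(self.person_years, dtype=float)
        if not (age.shape == deaths.shape == py.shape):
            raise InvalidInputError("age, deaths and person_years must align")
        if age.size == 0:
            raise InvalidInputError("empty mortality counts")
        if np.any(np.diff(age) != 1):
            raise InvalidInputError("ages must be contiguous and increasing")
        if np.any(deaths < 0) or not np.all(np.isfinite(deaths)):
            raise InvalidInputError("deaths must be finite and non-negative")
        if np.any(py <= 0) or not np.all(np.isfinite(py)):
            raise InvalidInputError("person_years must be finite and positive")
        object.__setattr__(self, "age", age)
        object.__setattr__(self, "deaths", deaths)
        object.__setattr__(self, "person_years", py)

    @property
    def rates(self) -> np.ndarray:
        """Central death rates deaths / person-years."""
        return self.deaths / self.person_years


@dataclass(frozen=True)
class LifeTable:
    """Period life table for one calendar year, ages 0..max_age, radix 1.0."""

    year: int
    max_age: int
    qx: np.ndarray
    mx: np.ndarray = field(default=None)  # type: ignore[assignment]
    lx: np.ndarray = field(default=None)  # type: ignore[assignment]
    dx: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        qx = np.asarray(self.qx, dtype=float)
        n = self.max_age + 1
        if qx.shape != (n,):
            raise InvalidInputError(
                f"qx must have one entry per age 0..{self.max_age}"
            )
        if np.any(qx < 0) or np.any(qx > 1) or not np.all(np.isfinite(qx)):
            raise InvalidInputError("qx values must lie in [0, 1]")
        mx = self.mx
        if mx is None:
            # exponential-consistent central rate; q=1 maps to +inf, cap it
            with np.errstate(divide="ignore"):
                mx = -np.log1p(-np.clip(qx, 0.0, 1.0 - 1e-15))
        mx = np.asarray(mx, dtype=float)
        if mx.shape != (n,):
            raise InvalidInputError("mx must align with qx")
        lx = np.empty(n)
        lx[0] = 1.0
        np.cumprod(1.0 - qx[:-1], out=lx[1:])
        dx = lx * qx
        object.__setattr__(self, "qx", qx)
        object.__setattr__(self, "mx", mx)
        object.__setattr__(self, "lx", lx)
        object.__setattr__(self, "dx", dx)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.max_age + 1)

    def annual_hazard(self, age: int) -> float:
        """Constant within-interval hazard −ln(1−qx) at an integer age."""
        if age < 0 or age > self.max_age:
            raise CoverageError(
                f"age {age} outside life table range 0..{self.max_age}"
            )
        q = self.qx[age]
        if q >= 1.0:
            return np.inf
        return -np.log1p(-q)


def qx_from_mx_exponential(mx) -> np.ndarray:
    """Convert central death rates to death probabilities, qx = 1 − e^(−mx).

    Assumes survival time is exponential within each one-year interval, i.e.
    a constant death rate over the interval.
    """
    mx = np.asarray(mx, dtype=float)
    if np.any(mx < 0) or not np.all(np.isfinite(mx)):
        raise InvalidInputError("mx must be finite and non-negative")
    return -np.expm1(-mx)


def build_lifetable_from_qx(qx, year: int, max_age: int | None = None,
                            mx=None) -> LifeTable:
    """Build a full life table from a vector of death probabilities.

    Standard actuarial recursion: ``lx[0]=1``, ``lx[x+1]=lx[x]·(1−qx[x])``,
    ``dx[x]=lx[x]·qx[x]``.
    """
    qx = np.asarray(qx, dtype=float)
    if max_age is None:
        max_age = qx.size - 1
    return LifeTable(year=year, max_age=max_age, qx=qx, mx=mx)


def build_lifetable_from_counts(counts: MortalityCounts,
                                max_age: int | None = None) -> LifeTable:
    """Unsmoothed life table straight from observed rates.

    This is the EUROCARE construction: central rates deaths/person-years,
    exponential conversion to qx, no smoothing.
    """
    rates = counts.rates
    if max_age is not None:
        if counts.age[-1] < max_age:
            raise CoverageError(
                f"counts end at age {counts.age[-1]}, need {max_age}"
            )
        rates = rates[: max_age + 1 - counts.age[0]]
    qx = qx_from_mx_exponential(rates)
    return build_lifetable_from_qx(qx, year=counts.year, mx=rates)


def median_age_of_deaths(lt: LifeTable) -> int:
    """Median of the life-table death distribution dx.

    Convention: the smallest age at which the cumulative death mass reaches
    half of the total.  Invariant to rescaling dx by a positive constant.
    """
    dx = np.asarray(lt.dx, dtype=float)
    total = dx.sum()
    if total <= 0:
        raise DegenerateDataError("death distribution is identically zero")
    cum = np.cumsum(dx) / total
    return int(np.searchsorted(cum, 0.5, side="left"))


def pool_years(counts: Mapping[int, MortalityCounts] | Iterable[MortalityCounts],
               central_year: int) -> MortalityCounts:
    """Pool deaths and exposures over the three years around a central year.

    A centered three-calendar-year window damps year-to-year fluctuations
    before smoothing; all three years must be present with identical age
    ranges.
    """
    if not isinstance(counts, Mapping):
        counts = {c.year: c for c in counts}
    window = (central_year - 1, central_year, central_year + 1)
    missing = [y for y in window if y not in counts]
    if missing:
        raise CoverageError(
            f"missing year(s) {missing} for window centered on {central_year}"
        )
    first = counts[window[0]]
    deaths = np.zeros_like(first.deaths)
    py = np.zeros_like(first.person_years)
    for y in window:
        c = counts[y]
        if not np.array_equal(c.age, first.age):
            raise InvalidInputError(
                f"year {y} has a different age range than year {window[0]}"
            )
        deaths += c.deaths
        py += c.person_years
    return MortalityCounts(year=central_year, age=first.age.copy(),
                           deaths=deaths, person_years=py)
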