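"""Multivariable flexible model: spline-smoothed mortality rates.

Death counts are modelled in the generalized linear model framework with a
Poisson error and log link, person-years entering as an offset of their
logarithm, and age entering through a restricted (natural) cubic spline:
piecewise cubic between the knots, twice continuously differentiable at the
knots, and constrained to be linear beyond the boundary knots.  The default
knot set (ages 0, 1, 2, 10, 20, 35, 50, 95) targets the age profile of
female mortality; the classic male set (0, 1, 2, 14, 15, 27, 50, 88) ships
as a named alternative.

The basis is the Harrell truncated-power parameterization.  That choice is
internal: predictions are invariant to the basis parameterization, which is
the tested contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import (DegenerateDataError, FittingError,
                         InvalidInputError)
from .lifetables import (LifeTable, MortalityCounts, build_lifetable_from_qx,
                         qx_from_mx_exponential)

__all__ = [
    "FEMALE_KNOTS",
    "MALE_KNOTS",
    "SplineSpec",
    "rcs_basis",
    "fit_mfm_lifetable",
]

FEMALE_KNOTS = (0, 1, 2, 10, 20, 35, 50, 95)
MALE_KNOTS = (0, 1, 2, 14, 15, 27, 50, 88)


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations for the restricted cubic spline in age."""

    knots: tuple = FEMALE_KNOTS

    def __post_init__(self):
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 3:
            raise InvalidInputError("a restricted cubic spline needs >= 3 knots")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise InvalidInputError("knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        """Number of non-intercept columns: k knots give k−1."""
        return len(self.knots) - 1


def rcs_basis(ages, spec: SplineSpec = SplineSpec()) -> np.ndarray:
    """Restricted-cubic-spline design columns evaluated at given ages.

    Returns an (n_ages, k−1) matrix: the linear term plus k−2 restricted
    cubic terms, normalized by the squared knot span (Harrell's convention).
    The resulting curves are linear outside the boundary knots.
    """
    x = np.asarray(ages, dtype=float)
    t = np.asarray(spec.knots)
    k = t.size
    span2 = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + cube(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / span2
        cols.append(term)
    return np.column_stack(cols)


def fit_mfm_lifetable(counts: MortalityCounts,
                      spec: SplineSpec = SplineSpec(),
                      year: int | None = None,
                      max_age: int = 99) -> LifeTable:
    """Fit the Poisson spline model and return a smoothed life table.

    Deaths at each single age are Poisson with mean
    ``person_years · exp(basis(age)·coef)``; fitted single-age rates are
    converted to death probabilities by the exponential formula and assembled
    into a life table for ages 0..max_age.
    """
    if year is None:
        year = counts.year
    if counts.deaths.sum() == 0:
        raise DegenerateDataError("all death counts are zero; nothing to fit")
    t = spec.knots
    if t[0] < counts.age[0] or t[-1] > counts.age[-1]:
        raise InvalidInputError(
            f"knots {t} fall outside the data age range "
            f"{counts.age[0]}..{counts.age[-1]}"
        )
    X = sm.add_constant(rcs_basis(counts.age, spec), prepend=True)
    model = sm.GLM(counts.deaths, X, family=sm.families.Poisson(),
                   offset=np.log(counts.person_years))
    res = model.fit(maxiter=200)
    if not res.converged:
        raise FittingError(
            f"Poisson spline fit did not converge after {res.fit_history['iteration']} iterations"
        )
    pred_ages = np.arange(max_age + 1)
    Xp = sm.add_constant(rcs_basis(pred_ages, spec), prepend=True)
    mx = np.exp(Xp @ res.params)
    qx = qx_from_mx_exponential(mx)
    return build_lifetable_from_qx(qx, year=year, max_age=max_age, mx=mx)
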