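"""Relational life-table systems: Brass logit and the Ewbank extension.

The Brass system relates an observed survivorship schedule to a standard
through a linear relation in logit space::

    Y(l) = ½·ln((1−l)/l),      Y_obs(x) = α + β·Y_std(x)

α moves the overall level of mortality, β the relative slope.  The Ewbank
system generalizes the logit to a Box–Cox power transform of the survival
odds r = (1−l)/l::

    Y_c(l) = (r^c − 1) / (2c),     Y_0(l) = ½·ln r  (the Brass logit)

with two shape exponents applied tail-wise: κ at ages below the split age
(the median age of the death distribution) and λ at or above it.  As κ, λ → 0
the system reduces to Brass.  The transform has the closed-form inverse
``l = 1/(1 + (1 + 2cY)^(1/c))``, which exists only while ``1 + 2cY > 0`` —
for strongly negative exponents the oldest ages can become uninvertible,
which is surfaced as :class:`~netlife.exceptions.InversionError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import (InsufficientDataError, InvalidInputError,
                         InversionError)
from .lifetables import LifeTable, build_lifetable_from_qx

__all__ = [
    "BrassFit",
    "EwbankParams",
    "brass_logit",
    "brass_logit_inv",
    "fit_brass",
    "ewbank_transform",
    "ewbank_transform_inv",
    "build_relational_lifetable",
    "fit_ewbank_profile",
]

KAPPA_RANGE = (-0.7, 0.7)
LAMBDA_RANGE = (-0.5, 0.5)

# below this magnitude an exponent is treated as exactly zero (Brass limit)
_ZERO_EXPONENT = 1e-12


@dataclass(frozen=True)
class BrassFit:
    """Result of the logit-logit regression of observed on standard."""

    alpha: float
    beta: float
    r_squared: float


@dataclass(frozen=True)
class EwbankParams:
    """Four relational parameters plus the age splitting the κ/λ regimes.

    κ shapes the transform for ages strictly below ``split_age``, λ for ages
    at or above it.  Values outside the simulation ranges κ ∈ [−0.7, 0.7],
    λ ∈ [−0.5, 0.5] are allowed (sweeps may probe edges) but warned about.
    """

    alpha: float = 0.0
    beta: float = 1.0
    kappa: float = 0.0
    lambda_: float = 0.0
    split_age: int = 80

    def __post_init__(self):
        if self.beta <= 0:
            raise InvalidInputError("beta must be positive")
        if not KAPPA_RANGE[0] <= self.kappa <= KAPPA_RANGE[1]:
            warnings.warn(
                f"kappa={self.kappa} outside the usual range {KAPPA_RANGE}",
                stacklevel=2,
            )
        if not LAMBDA_RANGE[0] <= self.lambda_ <= LAMBDA_RANGE[1]:
            warnings.warn(
                f"lambda={self.lambda_} outside the usual range {LAMBDA_RANGE}",
                stacklevel=2,
            )


def _check_unit_interval(l) -> np.ndarray:
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0) or np.any(l >= 1):
        raise InvalidInputError("survivorship values must lie strictly in (0, 1)")
    return l


def brass_logit(l):
    """Half-logit of the death odds, Y = ½·ln((1−l)/l)."""
    l = _check_unit_interval(l)
    return 0.5 * (np.log1p(-l) - np.log(l))


def brass_logit_inv(y):
    """Inverse of :func:`brass_logit`: l = 1/(1+e^(2y))."""
    y = np.asarray(y, dtype=float)
    return 1.0 / (1.0 + np.exp(2.0 * y))


def _boxcox_logit(l, c: float):
    """Box–Cox power transform of the survival odds; c=0 is the Brass logit."""
    l = _check_unit_interval(l)
    if abs(c) < _ZERO_EXPONENT:
        return brass_logit(l)
    logr = np.log1p(-l) - np.log(l)
    return np.expm1(c * logr) / (2.0 * c)


def _boxcox_logit_inv(y, c: float, age=None):
    y = np.asarray(y, dtype=float)
    if abs(c) < _ZERO_EXPONENT:
        return brass_logit_inv(y)
    base = 1.0 + 2.0 * c * y
    if np.any(base <= 0):
        where = ""
        if age is not None:
            bad = np.atleast_1d(np.asarray(age))[np.atleast_1d(base <= 0)]
            where = f" at age(s) {bad.tolist()}"
        raise InversionError(
            f"no survivorship in (0,1) solves the transform (exponent {c}){where}"
        )
    logr = np.log(base) / c
    return 1.0 / (1.0 + np.exp(logr))


def _exponent_for_ages(ages, params: EwbankParams) -> np.ndarray:
    ages = np.atleast_1d(np.asarray(ages))
    return np.where(ages < params.split_age, params.kappa, params.lambda_)


def ewbank_transform(l, params: EwbankParams, age=None):
    """Tail-wise Box–Cox logit with exponent κ or λ.

    The branch is selected by ``age`` against ``params.split_age`` when an age
    is supplied; otherwise by the survivorship value itself (l > 0.5, the
    young/high-survivorship half, takes κ — at the split age of a life table
    the survivorship is close to 0.5, so the two rules agree there).
    """
    l = _check_unit_interval(l)
    scalar = np.isscalar(l) or np.ndim(l) == 0
    l = np.atleast_1d(l)
    if age is None:
        use_kappa = l > 0.5
    else:
        use_kappa = np.atleast_1d(np.asarray(age)) < params.split_age
        if use_kappa.shape != l.shape:
            use_kappa = np.broadcast_to(use_kappa, l.shape)
    out = np.empty_like(l)
    out[use_kappa] = _boxcox_logit(l[use_kappa], params.kappa) \
        if use_kappa.any() else out[use_kappa]
    out[~use_kappa] = _boxcox_logit(l[~use_kappa], params.lambda_) \
        if (~use_kappa).any() else out[~use_kappa]
    return float(out[0]) if scalar else out


def ewbank_transform_inv(y, params: EwbankParams, age=None):
    """Inverse of :func:`ewbank_transform` (branch by age, or by sign of y)."""
    scalar = np.isscalar(y) or np.ndim(y) == 0
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if age is None:
        # y < 0 corresponds to l > 0.5 under either exponent
        use_kappa = y < 0
        ages = None
    else:
        ages = np.atleast_1d(np.asarray(age))
        use_kappa = ages < params.split_age
        if use_kappa.shape != y.shape:
            use_kappa = np.broadcast_to(use_kappa, y.shape)
    out = np.empty_like(y)
    if use_kappa.any():
        out[use_kappa] = _boxcox_logit_inv(
            y[use_kappa], params.kappa,
            None if ages is None else ages[use_kappa])
    if (~use_kappa).any():
        out[~use_kappa] = _boxcox_logit_inv(
            y[~use_kappa], params.lambda_,
            None if ages is None else ages[~use_kappa])
    return float(out[0]) if scalar else out


def fit_brass(observed: LifeTable, standard: LifeTable,
              age_range: tuple[int, int] = (1, 99)) -> BrassFit:
    """Ordinary least squares of observed logits on standard logits.

    Age 0 is excluded by default: infant mortality does not follow the
    log-linear relation the system assumes.  Ages where either table has
    survivorship outside (0, 1) are dropped.
    """
    lo, hi = age_range
    hi = min(hi, observed.max_age, standard.max_age)
    ages = np.arange(max(lo, 0), hi + 1)
    ls = standard.lx[ages]
    lo_ = observed.lx[ages]
    ok = (ls > 0) & (ls < 1) & (lo_ > 0) & (lo_ < 1)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"only {int(ok.sum())} usable ages in {age_range}; need >= 3"
        )
    x = brass_logit(ls[ok])
    y = brass_logit(lo_[ok])
    beta, alpha = np.polyfit(x, y, 1)
    resid = y - (alpha + beta * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return BrassFit(alpha=float(alpha), beta=float(beta), r_squared=r2)


def build_relational_lifetable(standard: LifeTable, params: EwbankParams,
                               year: int | None = None) -> LifeTable:
    """Map a standard table through α + β·Y and invert to a smoothed table.

    With α=0, β=1, κ=λ=0 the standard is reproduced exactly.  The terminal
    death probability is carried over from the standard (the open-ended
    terminal interval is outside the relational system).
    """
    if year is None:
        year = standard.year
    ages = np.arange(1, standard.max_age + 1)
    ls = standard.lx[ages]
    if np.any(ls[:-1] <= 0) or np.any(ls >= 1):
        raise InvalidInputError(
            "standard survivorship must lie in (0,1) at ages 1..max_age"
        )
    usable = ls > 0
    # branch by survivorship value (l ≷ 0.5): at the split age the standard's
    # survivorship crosses one half, so this coincides with the age rule
    # while keeping the transform continuous across the boundary
    y = ewbank_transform(ls[usable], params)
    y_out = params.alpha + params.beta * np.atleast_1d(y)
    l_out = np.empty_like(ls)
    l_out[usable] = ewbank_transform_inv(y_out, params)
    l_out[~usable] = 0.0
    lx = np.concatenate(([1.0], l_out))
    if np.any(np.diff(lx) > 0):
        bad = int(np.argmax(np.diff(lx) > 0))
        raise InversionError(
            f"transformed survivorship not monotone near age {bad}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = np.where(lx[:-1] > 0, 1.0 - lx[1:] / np.where(lx[:-1] > 0,
                                                           lx[:-1], 1.0), 1.0)
    qx = np.append(np.clip(qx, 0.0, 1.0), standard.qx[standard.max_age])
    return build_lifetable_from_qx(qx, year=year, max_age=standard.max_age)


def fit_ewbank_profile(observed: LifeTable, standard: LifeTable,
                       kappa_grid, lambda_grid,
                       split_age: int,
                       age_range: tuple[int, int] = (1, 99)):
    """Profile least-squares over a (κ, λ) grid, refitting α, β per point.

    An extension beyond the sweep workflow: for each grid pair, observed and
    standard survivorships are transformed tail-wise, α and β are estimated
    by OLS, and the pair minimizing the residual sum of squares is returned
    as an :class:`EwbankParams` together with the fit.
    """
    lo, hi = age_range
    hi = min(hi, observed.max_age, standard.max_age)
    ages = np.arange(max(lo, 0), hi + 1)
    ls, lo_ = standard.lx[ages], observed.lx[ages]
    ok = (ls > 0) & (ls < 1) & (lo_ > 0) & (lo_ < 1)
    if ok.sum() < 3:
        raise InsufficientDataError("need >= 3 usable ages")
    ages, ls, lo_ = ages[ok], ls[ok], lo_[ok]
    best = None
    for k in np.atleast_1d(kappa_grid):
        for lam in np.atleast_1d(lambda_grid):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = EwbankParams(kappa=float(k), lambda_=float(lam),
                                 split_age=split_age)
            x = ewbank_transform(ls, p, age=ages)
            y = ewbank_transform(lo_, p, age=ages)
            beta, alpha = np.polyfit(x, y, 1)
            sse = float(np.sum((y - alpha - beta * x) ** 2))
            if best is None or sse < best[0]:
                best = (sse, float(alpha), float(beta), float(k), float(lam))
    sse, alpha, beta, k, lam = best
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = EwbankParams(alpha=alpha, beta=beta, kappa=k, lambda_=lam,
                              split_age=split_age)
    return params, sse
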