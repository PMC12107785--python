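"""Cohort preparation, expected hazards, and Pohar Perme net survival.

Net survival is the survival the cohort would experience if the cancer under
study were the only possible cause of death.  It is estimable without cause
of death information: each patient's expected (population) mortality is read
off period life tables along their attained age and calendar time, and the
Pohar Perme estimator re-weights the counting processes by the inverse of
each patient's expected survival probability,

    w_i(t) = 1 / S_Pi(t),    S_Pi(t) = exp(−Λ_Pi(t)).

The cumulative excess hazard accumulates increments

    dΛ_E(t) = [Σ w_i dN_i(t) − Σ w_i Y_i(t) dΛ_Pi(t)] / Σ w_i Y_i(t)

on a fine time grid (daily by default), and the survival curve is the
product-limit of those increments, so that with zero population hazard the
estimator reduces exactly to Kaplan–Meier.  Variance follows the Poisson-type
form Σ w_i² dN_i / (Σ w_i Y_i)².

Time is continuous in years at day precision (365.25 days per year).
Estimates above 1 are a known property of the estimator (observed mortality
below population mortality) and are reported unclipped, with a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (CoverageError, IncompleteFollowupError,
                         InvalidInputError, InvalidWeightsError)
from .lifetables import LifeTable

__all__ = [
    "DAYS_PER_YEAR",
    "PatientRecord",
    "ExclusionLog",
    "NetSurvivalCurve",
    "SurvivalEstimate",
    "ICSSWeights",
    "ICSS_BREAST",
    "ICSS_OVARY",
    "ICSS_CERVIX",
    "ICSS_GROUPS",
    "apply_exclusions",
    "expected_cumhaz",
    "pohar_perme",
    "overall_survival",
    "overall_survival_from_counts",
    "age_standardize",
    "assign_icss_group",
    "standardized_net_survival",
    "constant_series",
]

logger = logging.getLogger("netlife")

DAYS_PER_YEAR = 365.25

ICSS_GROUPS = ((15, 44), (45, 54), (55, 64), (65, 74), (75, None))
ICSS_GROUP_LABELS = ("15-44", "45-54", "55-64", "65-74", "75+")


@dataclass(frozen=True)
class PatientRecord:
    """One registry case."""

    id: str
    diagnosis_date: date
    age_at_diagnosis: float
    vital_status: str  # "dead" | "alive"
    outcome_date: date  # death date, or the follow-up cutoff if alive
    site: str = ""
    dco: bool = False

    def __post_init__(self):
        if self.vital_status not in ("dead", "alive"):
            raise InvalidInputError(
                f"vital_status must be 'dead' or 'alive', got {self.vital_status!r}"
            )
        if self.age_at_diagnosis < 0:
            raise InvalidInputError("age_at_diagnosis must be >= 0")

    @property
    def followup_days(self) -> int:
        return (self.outcome_date - self.diagnosis_date).days

    @property
    def followup_years(self) -> float:
        return self.followup_days / DAYS_PER_YEAR


@dataclass
class ExclusionLog:
    negative_duration: int = 0
    dco: int = 0
    age_limit: int = 0

    def as_dict(self) -> dict:
        return {"negative_duration": self.negative_duration,
                "dco": self.dco, "age_limit": self.age_limit}

    @property
    def total(self) -> int:
        return self.negative_duration + self.dco + self.age_limit


def apply_exclusions(cohort: Sequence[PatientRecord],
                     lifetable_max_age: int = 99,
                     horizon: float = 5.0):
    """Drop records the analysis cannot use; count each reason.

    Removed: death before diagnosis (negative survival duration), death
    certificate-only cases (no usable survival time), and — when the life
    tables stop at age 99 — patients who would turn 100 within the follow-up
    horizon.  Tables extending to age 110 retain everyone in practice.
    """
    retained: list[PatientRecord] = []
    log = ExclusionLog()
    for p in cohort:
        if p.followup_days < 0:
            log.negative_duration += 1
        elif p.dco:
            log.dco += 1
        elif lifetable_max_age <= 99 and p.age_at_diagnosis + horizon >= 100:
            log.age_limit += 1
        else:
            retained.append(p)
    return retained, log


def _table_for_year(lt_series: Mapping[int, LifeTable], year: int):
    if year in lt_series:
        return lt_series[year], False
    last = max(lt_series)
    if year > last:
        return lt_series[last], True
    raise CoverageError(f"no life table for calendar year {year}")


def _cumhaz_knots(patient: PatientRecord,
                  lt_series: Mapping[int, LifeTable],
                  t_max: float):
    """Piecewise-linear nodes of the patient's cumulative population hazard.

    The hazard is constant between birthday and January-1 crossings:
    h = −ln(1−qx[attained age]) from the table of the calendar year being
    traversed.  Returns (times, cumulative hazard at those times); the
    cumulative hazard between nodes is linear, so the value at any t is a
    plain linear interpolation.
    """
    eps = 1e-9
    breaks = {0.0, t_max}
    a0 = patient.age_at_diagnosis
    # birthday crossings
    t = (np.floor(a0) + 1.0) - a0
    while t < t_max:
        if t > 0:
            breaks.add(t)
        t += 1.0
    # calendar-year crossings
    y = patient.diagnosis_date.year + 1
    while True:
        ty = (date(y, 1, 1) - patient.diagnosis_date).days / DAYS_PER_YEAR
        if ty >= t_max:
            break
        if ty > 0:
            breaks.add(ty)
        y += 1
    ts = np.array(sorted(breaks))
    cum = np.zeros_like(ts)
    reused = False
    for k in range(len(ts) - 1):
        mid_offset = ts[k] + eps
        age = int(np.floor(a0 + mid_offset))
        yr = (patient.diagnosis_date
              + timedelta(days=round(mid_offset * DAYS_PER_YEAR))).year
        lt, re_used = _table_for_year(lt_series, yr)
        reused = reused or re_used
        if age > lt.max_age:
            raise CoverageError(
                f"patient {patient.id} reaches age {age} beyond the life "
                f"table limit {lt.max_age}; should have been excluded"
            )
        h = lt.annual_hazard(age)
        cum[k + 1] = cum[k] + h * (ts[k + 1] - ts[k])
    if reused:
        logger.debug("patient %s traverses years beyond the last life table; "
                     "last table reused", patient.id)
    return ts, cum


def expected_cumhaz(patient: PatientRecord,
                    lt_series: Mapping[int, LifeTable],
                    t) -> float | np.ndarray:
    """Cumulative expected (population) hazard at years since diagnosis."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be non-negative")
    t_max = float(t_arr.max()) if t_arr.size else 0.0
    if t_max == 0.0:
        out = np.zeros_like(t_arr)
        return float(out[0]) if np.ndim(t) == 0 else out
    ts, cum = _cumhaz_knots(patient, lt_series, t_max)
    out = np.interp(t_arr, ts, cum)
    return float(out[0]) if np.ndim(t) == 0 else out


@dataclass
class NetSurvivalCurve:
    """Pohar Perme net survival on a time grid, with variance and 95% CI."""

    times: np.ndarray  # years since diagnosis, starting at 0
    estimate: np.ndarray  # NS(t), estimate[0] == 1
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    truncated: bool = False
    exceeds_one: bool = False
    n: int = 0

    def at(self, t: float) -> float:
        """Step-function value at time t (last estimate at or before t)."""
        idx = int(np.searchsorted(self.times, t + 1e-12, side="right")) - 1
        if idx < 0:
            raise InvalidInputError(f"time {t} precedes the curve start")
        if t > self.times[-1] + 1e-9 and self.truncated:
            warnings.warn(f"curve truncated at {self.times[-1]:.3f} years; "
                          f"value at t={t} extrapolates the last step")
        return float(self.estimate[idx])

    def var_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t + 1e-12, side="right")) - 1
        return float(self.variance[max(idx, 0)])


def pohar_perme(cohort: Sequence[PatientRecord],
                lt_series: Mapping[int, LifeTable],
                horizon: float = 5.0,
                step_days: int = 1,
                time_grid=None) -> NetSurvivalCurve:
    """Pohar Perme net-survival curve up to a follow-up horizon.

    ``step_days`` controls the integration precision of the continuous
    population-hazard term; 1 day is essentially exact, wider steps trade a
    little accuracy for speed on large cohorts.  Same-day outcomes are
    counted at day 1.  Event ties are processed simultaneously.
    """
    n = len(cohort)
    if n == 0:
        raise InvalidInputError("empty cohort")
    horizon_days = int(round(horizon * DAYS_PER_YEAR))

    exit_days = np.empty(n, dtype=int)
    event = np.zeros(n, dtype=bool)
    for i, p in enumerate(cohort):
        fd = p.followup_days
        if fd < 0:
            raise InvalidInputError(
                f"patient {p.id} has negative follow-up; run apply_exclusions"
            )
        fd = max(fd, 1)
        exit_days[i] = min(fd, horizon_days)
        event[i] = (p.vital_status == "dead") and fd <= horizon_days

    max_exit = int(exit_days.max())
    truncated = max_exit < horizon_days
    regular = np.arange(step_days, max_exit + step_days, step_days)
    grid = np.unique(np.concatenate([regular[regular <= max_exit],
                                     exit_days]))
    grid_years = grid / DAYS_PER_YEAR
    m = grid.size

    # cumulative population hazard of each patient at every grid time
    lam = np.zeros((n, m))
    for i, p in enumerate(cohort):
        ts, cum = _cumhaz_knots(p, lt_series, exit_days[i] / DAYS_PER_YEAR)
        lam[i] = np.interp(grid_years, ts, cum)  # flat beyond own exit
    w = np.exp(lam)
    dlam = np.diff(lam, axis=1, prepend=0.0)

    at_risk = exit_days[:, None] >= grid[None, :]
    denom = np.einsum("ij,ij->j", w, at_risk)
    num_pop = np.einsum("ij,ij,ij->j", w, dlam, at_risk)
    is_event_at = (exit_days[:, None] == grid[None, :]) & event[:, None]
    num_d = np.einsum("ij,ij->j", w, is_event_at)
    num_d2 = np.einsum("ij,ij,ij->j", w, w, is_event_at)

    ok = denom > 0
    if not ok.all():
        cut = int(np.argmin(ok))
        grid_years, m = grid_years[:cut], cut
        denom, num_pop, num_d, num_d2 = (a[:cut] for a in
                                         (denom, num_pop, num_d, num_d2))
        truncated = True
        warnings.warn("risk set empty before the requested horizon; "
                      "curve truncated")

    inc = (num_d - num_pop) / denom
    surv_factors = 1.0 - inc
    dead_from = surv_factors <= 0
    ns = np.cumprod(np.where(dead_from, 1.0, surv_factors))
    if dead_from.any():
        ns[np.argmax(dead_from):] = 0.0
    cumvar = np.cumsum(num_d2 / denom**2)
    var_ns = ns**2 * cumvar

    times = np.concatenate(([0.0], grid_years))
    est = np.concatenate(([1.0], ns))
    var = np.concatenate(([0.0], var_ns))
    se = np.sqrt(var)
    curve = NetSurvivalCurve(
        times=times, estimate=est, variance=var,
        ci_low=est - 1.959963984540054 * se,
        ci_high=est + 1.959963984540054 * se,
        truncated=truncated, exceeds_one=bool(np.any(est > 1.0)), n=n,
    )
    if time_grid is not None:
        keep = np.array([curve.at(t) for t in time_grid])
        varg = np.array([curve.var_at(t) for t in time_grid])
        seg = np.sqrt(varg)
        curve = NetSurvivalCurve(
            times=np.asarray(time_grid, dtype=float), estimate=keep,
            variance=varg, ci_low=keep - 1.959963984540054 * seg,
            ci_high=keep + 1.959963984540054 * seg,
            truncated=curve.truncated, exceeds_one=curve.exceeds_one, n=n,
        )
    return curve


@dataclass(frozen=True)
class SurvivalEstimate:
    """A proportion with a normal-approximation 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n: int
    deaths: int | None = None

    @property
    def percent(self) -> float:
        return round(100.0 * self.estimate, 1)


def overall_survival_from_counts(n: int, deaths: int) -> SurvivalEstimate:
    """Proportion alive at the horizon from total and death counts."""
    if n <= 0:
        raise InvalidInputError("n must be positive")
    p = 1.0 - deaths / n
    se = np.sqrt(p * (1.0 - p) / n)
    return SurvivalEstimate(estimate=p, ci_low=p - 1.96 * se,
                            ci_high=p + 1.96 * se, n=n, deaths=deaths)


def overall_survival(cohort: Sequence[PatientRecord],
                     horizon: float = 5.0) -> SurvivalEstimate:
    """Proportion of patients alive ``horizon`` years after diagnosis.

    All-cause: deaths count regardless of cause.  Every record must be
    followed to death or at least to the horizon (the registry setting:
    no loss to follow-up).
    """
    if len(cohort) == 0:
        raise InvalidInputError("empty cohort: overall survival undefined")
    horizon_days = int(round(horizon * DAYS_PER_YEAR))
    deaths = 0
    for p in cohort:
        fd = p.followup_days
        if p.vital_status == "dead" and fd <= horizon_days:
            deaths += 1
        elif p.vital_status == "alive" and fd < horizon_days:
            raise IncompleteFollowupError(
                f"patient {p.id} censored at {fd} days, before the "
                f"{horizon}-year horizon"
            )
    return overall_survival_from_counts(len(cohort), deaths)


@dataclass(frozen=True)
class ICSSWeights:
    """International Cancer Survival Standard age-group weights.

    Groups 15–44, 45–54, 55–64, 65–74, 75+; fractions summing to one.
    """

    weights: tuple

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        if len(w) != len(ICSS_GROUPS):
            raise InvalidWeightsError(f"need {len(ICSS_GROUPS)} weights")
        if any(x <= 0 for x in w):
            raise InvalidWeightsError("weights must be positive")
        if abs(sum(w) - 1.0) > 1e-12:
            raise InvalidWeightsError(f"weights sum to {sum(w)}, not 1")
        object.__setattr__(self, "weights", w)

    @property
    def labels(self) -> tuple:
        return ICSS_GROUP_LABELS


ICSS_BREAST = ICSSWeights((0.07, 0.12, 0.23, 0.29, 0.29))
ICSS_OVARY = ICSS_BREAST
ICSS_CERVIX = ICSSWeights((0.28, 0.17, 0.21, 0.20, 0.14))


def assign_icss_group(age: float) -> int | None:
    """Index of the ICSS age group for an age at diagnosis; None below 15."""
    a = int(np.floor(age))
    if a < 15:
        return None
    for j, (lo, hi) in enumerate(ICSS_GROUPS):
        if hi is None or a <= hi:
            if a >= lo:
                return j
    return None


def age_standardize(per_group, weights: ICSSWeights) -> SurvivalEstimate:
    """ICSS-weighted combination of age-group estimates.

    ``per_group`` maps group label to a scalar estimate or an
    (estimate, variance) pair; the standardized estimate is Σ w_j·s_j with
    variance Σ w_j²·var_j and a normal-approximation CI.
    """
    est = 0.0
    var = 0.0
    n = 0
    for label, w in zip(weights.labels, weights.weights):
        if label not in per_group:
            raise InvalidInputError(f"missing estimate for age group {label}")
        value = per_group[label]
        if np.iterable(value):
            s, v = value[0], value[1]
        else:
            s, v = float(value), 0.0
        est += w * s
        var += w * w * v
    se = np.sqrt(var)
    return SurvivalEstimate(estimate=est, ci_low=est - 1.96 * se,
                            ci_high=est + 1.96 * se, n=n)


def standardized_net_survival(cohort: Sequence[PatientRecord],
                              lt_series: Mapping[int, LifeTable],
                              weights: ICSSWeights,
                              horizon: float = 5.0,
                              step_days: int = 1):
    """Per-age-group Pohar Perme NS(horizon) and its ICSS-standardized value.

    Patients younger than 15 at diagnosis fall outside the ICSS groups and
    are left out of the standardized estimate.
    """
    groups: dict[str, list[PatientRecord]] = {lab: [] for lab
                                              in ICSS_GROUP_LABELS}
    for p in cohort:
        j = assign_icss_group(p.age_at_diagnosis)
        if j is not None:
            groups[ICSS_GROUP_LABELS[j]].append(p)
    per_group: dict[str, tuple] = {}
    for label, members in groups.items():
        if not members:
            continue
        curve = pohar_perme(members, lt_series, horizon=horizon,
                            step_days=step_days)
        per_group[label] = (curve.at(horizon), curve.var_at(horizon),
                            len(members))
    std = age_standardize({k: v[:2] for k, v in per_group.items()}, weights)
    return per_group, std


def constant_series(lt: LifeTable, years=None) -> dict[int, LifeTable]:
    """A life-table series that repeats one table across calendar years."""
    if years is None:
        years = range(lt.year, lt.year + 1)
    return {int(y): lt for y in years}
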