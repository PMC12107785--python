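"""Synthetic population mortality and registry cohorts with known truth.

Real registry record-level data and national life tables are not shipped;
this module generates inputs with the same statistical structure so that
every stage of the pipeline is testable end to end:

* a Gompertz–Makeham mortality law, hazard ``a + b·exp(c·age)``, standing in
  for a national female population;
* single-age life tables from the law, optionally with Poisson sampling
  noise on death counts, so the smoothing models see realistic inputs;
* record-level cancer cohorts whose all-cause hazard is the population
  hazard plus a known constant excess (net) hazard per ICSS age group, with
  uniform diagnosis dates and administrative censoring at a cutoff — so the
  true net survival is exp(−excess·t) by construction.

Default laws: the observed population uses (a=3e-4, b=8e-6, c=0.115), which
places the median age of death near 80 years, matching a present-day
European female population; the relational standard uses a lighter law
(a=2e-4, b=6e-6, c=0.115), median near 82.  The packaged "standard" table is
synthetic — a stand-in for an external national standard that is not
publicly printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping

import numpy as np
from scipy.special import wrightomega

from .exceptions import InvalidInputError
from .lifetables import LifeTable, MortalityCounts, build_lifetable_from_qx
from .netsurv import (ICSS_GROUP_LABELS, ICSS_GROUPS, ICSSWeights,
                      PatientRecord, _cumhaz_knots)

__all__ = [
    "PopulationLaw",
    "ExcessModel",
    "DEFAULT_LAW",
    "STANDARD_LAW",
    "synth_lifetable",
    "standard_table",
    "synth_cohort",
    "breast_like_excess",
    "fixture_cohort",
    "micro_cohort",
    "constant_qx_table",
]


@dataclass(frozen=True)
class PopulationLaw:
    """Siler-type hazard a + b·exp(c·age) + a_inf·exp(−b_inf·age).

    The Gompertz–Makeham core (a, b, c) carries adult and old-age mortality;
    the decaying infant component (a_inf, b_inf) reproduces the steep fall of
    mortality over the first years of life, without which relational and
    spline smoothing see an unrealistically featureless young-age profile.
    Set ``infant_a=0`` for a plain Gompertz–Makeham law.
    """

    makeham_a: float = 2.5e-4
    gompertz_b: float = 5.7e-6
    gompertz_c: float = 0.115
    infant_a: float = 8e-3
    infant_b: float = 1.4

    def __post_init__(self):
        if (self.makeham_a < 0 or self.gompertz_b <= 0
                or self.gompertz_c <= 0 or self.infant_a < 0
                or self.infant_b <= 0):
            raise InvalidInputError("require a >= 0, b > 0, c > 0, "
                                    "a_inf >= 0, b_inf > 0")

    def hazard(self, age):
        age = np.asarray(age, dtype=float)
        return (self.makeham_a
                + self.gompertz_b * np.exp(self.gompertz_c * age)
                + self.infant_a * np.exp(-self.infant_b * age))

    def cumhaz(self, age0, age1):
        """∫ hazard between two exact ages, closed form."""
        a0 = np.asarray(age0, dtype=float)
        a1 = np.asarray(age1, dtype=float)
        b, c = self.gompertz_b, self.gompertz_c
        ai, bi = self.infant_a, self.infant_b
        return (self.makeham_a * (a1 - a0)
                + (b / c) * (np.exp(c * a1) - np.exp(c * a0))
                + (ai / bi) * (np.exp(-bi * a0) - np.exp(-bi * a1)))


# observed population: heavier, steeper schedule, median age of death ~82
DEFAULT_LAW = PopulationLaw()
# relational standard: lighter, shallower schedule, median ~85
STANDARD_LAW = PopulationLaw(makeham_a=1.2e-4, gompertz_b=8.7e-6,
                             gompertz_c=0.105, infant_a=5.5e-3,
                             infant_b=1.6)


def synth_lifetable(law: PopulationLaw = DEFAULT_LAW,
                    year: int = 2012,
                    max_age: int = 99,
                    noise: str | None = None,
                    exposure: float = 50_000.0,
                    seed: int | None = None):
    """Life table from a mortality law, exact or with Poisson noise.

    Exact: ``qx[a] = 1 − exp(−∫_a^{a+1} hazard)``.  With ``noise='poisson'``
    death counts are drawn Poisson(rate·exposure) per age and the table is
    rebuilt from the noisy rates; the (table, counts) pair is returned so the
    smoothing models have realistic inputs.  Deterministic given the seed.
    """
    ages = np.arange(max_age + 1)
    integrated = law.cumhaz(ages, ages + 1)  # average hazard over [a, a+1)
    if noise is None:
        qx = -np.expm1(-integrated)
        return build_lifetable_from_qx(qx, year=year, max_age=max_age,
                                       mx=integrated)
    if noise != "poisson":
        raise InvalidInputError(f"unknown noise model {noise!r}")
    rng = np.random.default_rng(seed)
    py = np.full(ages.shape, float(exposure))
    deaths = rng.poisson(integrated * py).astype(float)
    counts = MortalityCounts(year=year, age=ages, deaths=deaths,
                             person_years=py)
    noisy_mx = counts.rates
    qx = -np.expm1(-noisy_mx)
    table = build_lifetable_from_qx(qx, year=year, max_age=max_age,
                                    mx=noisy_mx)
    return table, counts


def standard_table(year: int = 2010, max_age: int = 99) -> LifeTable:
    """The packaged synthetic relational standard (lighter mortality law)."""
    return synth_lifetable(STANDARD_LAW, year=year, max_age=max_age)


@dataclass(frozen=True)
class ExcessModel:
    """Constant excess (net) hazard and cohort size per ICSS age group."""

    excess: tuple  # per-year excess hazard per group
    sizes: tuple  # patients per group
    diag_start: date = date(2010, 1, 1)
    diag_end: date = date(2014, 12, 31)
    cutoff: date = date(2019, 12, 31)
    max_entry_age: float = 94.0  # cap on the open 75+ group
    open_group_scale: float = 4.5  # decay (years) of the 75+ age density

    def __post_init__(self):
        if len(self.excess) != len(ICSS_GROUPS) or \
                len(self.sizes) != len(ICSS_GROUPS):
            raise InvalidInputError(
                f"need {len(ICSS_GROUPS)} excess rates and sizes")
        if any(e < 0 for e in self.excess) or any(s < 0 for s in self.sizes):
            raise InvalidInputError("excess rates and sizes must be >= 0")

    def true_net_survival(self, t: float) -> dict[str, float]:
        return {lab: float(np.exp(-e * t))
                for lab, e in zip(ICSS_GROUP_LABELS, self.excess)}

    def true_standardized(self, t: float, weights: ICSSWeights) -> float:
        per = self.true_net_survival(t)
        return float(sum(w * per[lab] for lab, w
                         in zip(weights.labels, weights.weights)))


def breast_like_excess(n_total: int = 2000) -> ExcessModel:
    """Default cohort conditions shaped like a breast-cancer registry cohort.

    Group sizes follow the diagnosis-share profile of breast cancer (about
    10/16/29/24/21 percent across the ICSS groups) and the excess hazards
    give 5-year net survival declining from ~0.90 in the youngest group to
    ~0.60 in the oldest.
    """
    shares = np.array([0.097, 0.157, 0.289, 0.245, 0.212])
    sizes = np.maximum(np.round(shares * n_total).astype(int), 1)
    ns5 = np.array([0.90, 0.88, 0.84, 0.77, 0.60])
    excess = -np.log(ns5) / 5.0
    return ExcessModel(excess=tuple(excess), sizes=tuple(int(s)
                                                         for s in sizes))


def _invert_law_cumhaz(law: PopulationLaw, age0, extra_rate, target):
    """Solve Λ_pop(age0, age0+t) + extra_rate·t = target for t, vectorized.

    With α = a + extra_rate, B = (b/c)·e^(c·age0) the equation is
    α·t + B·(e^(c·t) − 1) = target, solved in closed form through the Wright
    omega function (the numerically stable W(e^x)).  The infant component of
    the law is negligible at the entry ages cancer cohorts use (15+), so it
    is dropped from the inversion; a guard enforces that regime.
    """
    a0 = np.asarray(age0, dtype=float)
    if np.any(a0 < 10):
        raise InvalidInputError("closed-form inversion requires entry age >= 10")
    e = np.asarray(target, dtype=float)
    alpha = law.makeham_a + np.asarray(extra_rate, dtype=float)
    b, c = law.gompertz_b, law.gompertz_c
    B = (b / c) * np.exp(c * a0)
    D = e + B
    out = np.empty(np.broadcast(a0, e, alpha).shape)
    alpha, B, D = np.broadcast_arrays(alpha, np.broadcast_to(B, out.shape),
                                      np.broadcast_to(D, out.shape))
    zero = alpha <= 0
    if zero.any():
        out[zero] = np.log1p(e[zero] / B[zero]) / c
    nz = ~zero
    if nz.any():
        A = alpha[nz] / c
        v = wrightomega(np.log(B[nz] / A) + D[nz] / A).real
        out[nz] = (D[nz] / A - v) / c
    return out


def _invert_table_cumhaz(patient: PatientRecord,
                         lt_series: Mapping[int, LifeTable],
                         extra_rate: float, target: float,
                         t_max: float) -> float:
    """Solve Λ_pop(t) + extra_rate·t = target using a life-table series."""
    ts, cum = _cumhaz_knots(patient, lt_series, t_max)
    total = cum + extra_rate * ts
    if target > total[-1]:
        return np.inf
    return float(np.interp(target, total, ts))


def synth_cohort(pop, excess: ExcessModel, seed: int | None = None,
                 site: str = "C50"):
    """Generate a registry cohort with known net survival.

    ``pop`` is either a :class:`PopulationLaw` (death times solved in closed
    form) or a life-table series mapping year → LifeTable (piecewise-constant
    hazards; ages beyond the table limit reuse the terminal hazard, which
    only matters past the analysis horizon).  Each patient draws an age at
    diagnosis uniformly within their group, a diagnosis date uniformly within
    the range, and a death time from total hazard = population + group
    excess; administrative censoring applies at the cutoff.  Returns
    (records, truth) where truth carries the analytic net survival.
    """
    rng = np.random.default_rng(seed)
    span_days = (excess.diag_end - excess.diag_start).days
    records: list[PatientRecord] = []
    counter = 0
    ext = None if isinstance(pop, PopulationLaw) else _extended_series(pop)
    for j, ((lo, hi), rate, size) in enumerate(
            zip(ICSS_GROUPS, excess.excess, excess.sizes)):
        if size == 0:
            continue
        if hi is None:
            # registry age profiles fall steeply past 80: truncated
            # exponential density over [75, max_entry_age]
            scale = excess.open_group_scale
            u = rng.uniform(0.0, 1.0, size)
            width = excess.max_entry_age - lo
            ages = lo - scale * np.log1p(-u * -np.expm1(-width / scale))
        else:
            ages = rng.uniform(lo, hi + 1.0, size)
        dx_offsets = rng.integers(0, span_days + 1, size)
        e_draw = rng.exponential(1.0, size)
        if isinstance(pop, PopulationLaw):
            t_death = _invert_law_cumhaz(pop, ages, rate, e_draw)
        else:
            t_death = np.empty(size)
        for k in range(size):
            dx_date = excess.diag_start + timedelta(days=int(dx_offsets[k]))
            cens_days = (excess.cutoff - dx_date).days
            pid = f"S{counter:05d}"
            counter += 1
            if not isinstance(pop, PopulationLaw):
                probe = PatientRecord(id=pid, diagnosis_date=dx_date,
                                      age_at_diagnosis=float(ages[k]),
                                      vital_status="alive",
                                      outcome_date=excess.cutoff, site=site)
                t_death[k] = _invert_table_cumhaz(
                    probe, ext, rate, e_draw[k],
                    cens_days / 365.25 + 1e-6)
            death_days = (int(round(t_death[k] * 365.25))
                          if np.isfinite(t_death[k]) else cens_days + 1)
            if death_days <= cens_days:
                records.append(PatientRecord(
                    id=pid, diagnosis_date=dx_date,
                    age_at_diagnosis=float(ages[k]), vital_status="dead",
                    outcome_date=dx_date + timedelta(days=max(death_days, 0)),
                    site=site))
            else:
                records.append(PatientRecord(
                    id=pid, diagnosis_date=dx_date,
                    age_at_diagnosis=float(ages[k]), vital_status="alive",
                    outcome_date=excess.cutoff, site=site))
    truth = {
        "net_survival_5y": excess.true_net_survival(5.0),
        "excess": {lab: float(e) for lab, e
                   in zip(ICSS_GROUP_LABELS, excess.excess)},
    }
    return records, truth


class _ExtendedTable:
    """Wraps a LifeTable so ages past max_age reuse the terminal hazard.

    Generation-only convenience: censoring at the cutoff can require hazards
    a few years past the table limit, which never enters estimation (the
    analysis horizon keeps attained ages within the table).
    """

    def __init__(self, lt: LifeTable):
        self._lt = lt
        self.year = lt.year
        self.max_age = 200
        self.qx = lt.qx

    def annual_hazard(self, age: int) -> float:
        return self._lt.annual_hazard(min(age, self._lt.max_age))


def _extended_series(lt_series: Mapping[int, LifeTable]):
    return {y: _ExtendedTable(t) if not isinstance(t, _ExtendedTable) else t
            for y, t in lt_series.items()}


def fixture_cohort():
    """The packaged fixture cohort: 2000 breast-like records, fixed seed.

    Deterministic; used by the sensitivity-structure checks and the worked
    examples.  Returns (records, truth).
    """
    return synth_cohort(DEFAULT_LAW, breast_like_excess(2000), seed=3)


def constant_qx_table(q: float, year: int = 2012,
                      max_age: int = 99) -> LifeTable:
    """Flat-hazard life table, handy as a degenerate test case."""
    return build_lifetable_from_qx(np.full(max_age + 1, float(q)), year=year,
                                   max_age=max_age)


def micro_cohort() -> list[PatientRecord]:
    """A fixed 20-record cohort with hand-checkable event times.

    Thirteen deaths at round day counts and seven administratively censored
    records, ages spanning all ICSS groups; diagnosis dates within 2012.
    """
    spec = [
        # (age, diagnosis, status, days of follow-up)
        (42.5, date(2012, 1, 10), "dead", 200),
        (38.0, date(2012, 2, 1), "alive", 2890),
        (47.3, date(2012, 3, 15), "dead", 730),
        (52.0, date(2012, 4, 1), "alive", 2830),
        (50.5, date(2012, 5, 20), "dead", 1461),
        (58.9, date(2012, 6, 1), "dead", 365),
        (61.2, date(2012, 6, 15), "alive", 2755),
        (63.0, date(2012, 7, 1), "dead", 1096),
        (59.7, date(2012, 8, 10), "dead", 100),
        (66.6, date(2012, 9, 1), "alive", 2677),
        (68.1, date(2012, 9, 20), "dead", 400),
        (70.0, date(2012, 10, 1), "dead", 1500),
        (72.4, date(2012, 10, 15), "alive", 2633),
        (74.9, date(2012, 11, 1), "dead", 900),
        (77.5, date(2012, 11, 20), "dead", 250),
        (79.0, date(2012, 12, 1), "alive", 2586),
        (81.3, date(2012, 12, 10), "dead", 600),
        (84.8, date(2012, 1, 25), "dead", 1200),
        (87.2, date(2012, 2, 14), "alive", 2877),
        (90.1, date(2012, 3, 3), "dead", 50),
    ]
    records = []
    for i, (age, dx, status, days) in enumerate(spec):
        records.append(PatientRecord(
            id=f"M{i:02d}", diagnosis_date=dx, age_at_diagnosis=age,
            vital_status=status, outcome_date=dx + timedelta(days=days),
            site="C50"))
    return records
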