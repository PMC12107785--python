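"""Exclusions, expected hazards, Pohar Perme, and standardization."""

from datetime import date, timedelta

import numpy as np
import pytest

from netlife.exceptions import (IncompleteFollowupError, InvalidInputError,
                                InvalidWeightsError)
from netlife.lifetables import build_lifetable_from_qx
from netlife.netsurv import (ICSS_BREAST, ICSSWeights, PatientRecord,
                             age_standardize, apply_exclusions,
                             constant_series, expected_cumhaz,
                             overall_survival, overall_survival_from_counts,
                             pohar_perme)
from netlife.synthetic import (DEFAULT_LAW, breast_like_excess,
                               constant_qx_table, synth_cohort)


def _patient(age=60.0, dx=date(2012, 3, 1), status="dead", days=365,
             pid="P0", dco=False):
    return PatientRecord(id=pid, diagnosis_date=dx, age_at_diagnosis=age,
                         vital_status=status,
                         outcome_date=dx + timedelta(days=days), dco=dco)


class TestExclusions:
    def test_reasons_are_counted(self):
        cohort = [
            _patient(pid="a"),
            _patient(pid="b", days=-30),           # death before diagnosis
            _patient(pid="c", dco=True),           # death certificate only
            _patient(pid="d", status="alive", days=2000),
            _patient(pid="e"),
        ]
        kept, log = apply_exclusions(cohort)
        assert len(kept) == 3
        assert log.as_dict() == {"negative_duration": 1, "dco": 1,
                                 "age_limit": 0}

    def test_age_100_rule_depends_on_table_limit(self):
        p = _patient(age=96.0, status="alive", days=2000)
        kept99, log99 = apply_exclusions([p], lifetable_max_age=99)
        kept110, log110 = apply_exclusions([p], lifetable_max_age=110)
        assert kept99 == [] and log99.age_limit == 1
        assert kept110 == [p] and log110.age_limit == 0

    def test_empty_cohort(self):
        kept, log = apply_exclusions([])
        assert kept == [] and log.total == 0


class TestExpectedCumhaz:
    def test_zero_hazard_table(self):
        series = constant_series(constant_qx_table(0.0, year=2010))
        p = _patient(dx=date(2012, 3, 1))
        assert expected_cumhaz(p, series, 4.5) == 0.0

    def test_constant_qx_closed_form(self):
        q = 0.02
        series = constant_series(constant_qx_table(q, year=2010))
        # diagnosis on an exact birthday: age is integral at every crossing
        p = _patient(age=60.0)
        h = -np.log1p(-q)
        assert expected_cumhaz(p, series, 3.0) == pytest.approx(3 * h,
                                                                abs=1e-12)

    def test_half_year_at_each_age(self):
        qx = np.zeros(100)
        qx[60], qx[61] = 0.10, 0.30
        series = constant_series(build_lifetable_from_qx(qx, year=2010))
        p = _patient(age=60.5)
        h60, h61 = -np.log1p(-0.10), -np.log1p(-0.30)
        expected = 0.5 * h60 + 0.5 * h61
        assert expected_cumhaz(p, series, 1.0) == pytest.approx(expected,
                                                                abs=1e-12)

    def test_additive_over_adjacent_intervals(self, population_table):
        series = constant_series(population_table)
        p = _patient(age=57.3, dx=date(2011, 7, 19))
        full = expected_cumhaz(p, series, 4.8)
        part = expected_cumhaz(p, series, 2.1)
        rest = full - part
        # recompute the tail by shifting the origin
        q = PatientRecord(id="x", diagnosis_date=p.diagnosis_date
                          + timedelta(days=round(2.1 * 365.25)),
                          age_at_diagnosis=57.3 + 2.1,
                          vital_status="alive",
                          outcome_date=p.outcome_date)
        tail = expected_cumhaz(q, series, 2.7)
        assert rest == pytest.approx(tail, abs=1e-9)

    def test_monotone_in_time(self, population_table):
        series = constant_series(population_table)
        p = _patient(age=70.2, dx=date(2010, 11, 5))
        grid = np.linspace(0.0, 5.0, 101)
        values = expected_cumhaz(p, series, grid)
        assert np.all(np.diff(values) >= 0)


class TestPoharPerme:
    def test_zero_population_hazard_equals_kaplan_meier(self):
        from lifelines import KaplanMeierFitter

        cohort, _ = synth_cohort(DEFAULT_LAW, breast_like_excess(400),
                                 seed=17)
        series = constant_series(constant_qx_table(0.0, year=2010))
        curve = pohar_perme(cohort, series, horizon=5.0)
        horizon_days = 1826
        T = np.array([min(max(p.followup_days, 1), horizon_days)
                      for p in cohort]) / 365.25
        E = np.array([p.vital_status == "dead"
                      and p.followup_days <= horizon_days for p in cohort])
        km = KaplanMeierFitter().fit(T, E)
        for t in np.unique(T[E]):
            assert curve.at(t) == pytest.approx(float(km.predict(t)),
                                                abs=1e-12)

    def test_single_patient_death(self):
        series = constant_series(constant_qx_table(0.0, year=2010))
        p = _patient(days=365)
        curve = pohar_perme([p], series, horizon=5.0)
        assert curve.at(0.5) == 1.0
        assert curve.at(365 / 365.25) == 0.0
        assert curve.at(4.9) == 0.0

    def test_matches_discrete_time_oracle_on_micro_cohort(self, micro):
        # brute-force daily-step estimator, written independently:
        # constant-qx tables make each patient's hazard exactly h·t
        q = 0.03
        series = constant_series(constant_qx_table(q, year=2010))
        curve = pohar_perme(micro, series, horizon=5.0)

        h = -np.log1p(-q)
        horizon_days = 1826
        exits, events = [], []
        for p in micro:
            fd = max(p.followup_days, 1)
            exits.append(min(fd, horizon_days))
            events.append(p.vital_status == "dead" and fd <= horizon_days)
        ns = 1.0
        for day in range(1, max(exits) + 1):
            t1, t0 = day / 365.25, (day - 1) / 365.25
            num_d = num_p = den = 0.0
            for i in range(len(micro)):
                if exits[i] >= day:
                    w = np.exp(h * t1)
                    den += w
                    num_p += w * h * (t1 - t0)
                    if exits[i] == day and events[i]:
                        num_d += w
            if den > 0:
                ns *= 1.0 - (num_d - num_p) / den
        assert curve.at(5.0) == pytest.approx(ns, abs=1e-6)

    def test_record_order_invariance(self, micro, population_table):
        series = constant_series(population_table)
        a = pohar_perme(micro, series, horizon=5.0)
        b = pohar_perme(list(reversed(micro)), series, horizon=5.0)
        assert np.allclose(a.estimate, b.estimate, atol=1e-12)

    def test_estimate_starts_at_one_and_ci_brackets(self, micro,
                                                    population_table):
        series = constant_series(population_table)
        curve = pohar_perme(micro, series, horizon=5.0)
        assert curve.estimate[0] == 1.0
        assert np.all(curve.variance >= 0)
        assert np.all(curve.ci_low <= curve.estimate + 1e-15)
        assert np.all(curve.ci_high >= curve.estimate - 1e-15)

    def test_truncation_warns_beyond_last_exit(self, population_table):
        series = constant_series(population_table)
        p = _patient(days=300)
        with pytest.warns(UserWarning, match="truncated"):
            curve = pohar_perme([p], series, horizon=5.0)
            curve.at(4.0)


class TestOverallSurvival:
    @pytest.mark.parametrize("n, deaths, pct", [
        (37858, 10679, 71.8),  # breast
        (5369, 2485, 53.7),    # cervix
        (6541, 4103, 37.3),    # ovary
    ])
    def test_registry_scale_proportions(self, n, deaths, pct):
        est = overall_survival_from_counts(n, deaths)
        assert est.percent == pct

    def test_no_deaths_is_certain_survival(self):
        cohort = [_patient(status="alive", days=2000, pid=str(i))
                  for i in range(10)]
        est = overall_survival(cohort)
        assert est.estimate == 1.0

    def test_empty_cohort_undefined(self):
        with pytest.raises(InvalidInputError):
            overall_survival([])

    def test_incomplete_followup_rejected(self):
        cohort = [_patient(status="alive", days=400)]
        with pytest.raises(IncompleteFollowupError):
            overall_survival(cohort, horizon=5.0)


class TestAgeStandardize:
    def test_identical_groups_return_common_value(self):
        per = {g: 0.62 for g in ICSS_BREAST.labels}
        assert age_standardize(per, ICSS_BREAST).estimate == pytest.approx(
            0.62, abs=1e-15)

    def test_breast_weights_on_printed_age_group_survivals(self):
        values = (86.1, 85.0, 81.1, 71.4, 43.4)
        per = dict(zip(ICSS_BREAST.labels, values))
        expected = sum(w * v for w, v in zip(ICSS_BREAST.weights, values))
        result = age_standardize(per, ICSS_BREAST)
        assert result.estimate == pytest.approx(expected, abs=1e-12)
        assert result.estimate == pytest.approx(68.172, abs=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidWeightsError):
            ICSSWeights((0.5, 0.5, 0.5, 0.0, 0.0))

    def test_missing_group_named(self):
        per = {g: 0.5 for g in ICSS_BREAST.labels[:-1]}
        with pytest.raises(InvalidInputError, match="75"):
            age_standardize(per, ICSS_BREAST)

    def test_variance_combines_quadratically(self):
        per = {g: (0.5, 0.01) for g in ICSS_BREAST.labels}
        result = age_standardize(per, ICSS_BREAST)
        expected_var = sum(w * w * 0.01 for w in ICSS_BREAST.weights)
        half_width = result.ci_high - result.estimate
        assert half_width == pytest.approx(1.96 * np.sqrt(expected_var),
                                           abs=1e-12)
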