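"""Brass and Ewbank relational life-table systems."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netlife.exceptions import (InsufficientDataError, InvalidInputError,
                                InversionError)
from netlife.lifetables import build_lifetable_from_qx
from netlife.relational import (EwbankParams, brass_logit, brass_logit_inv,
                                build_relational_lifetable, ewbank_transform,
                                ewbank_transform_inv, fit_brass,
                                fit_ewbank_profile)


def _table_from_lx(lx_interior, template):
    """Build a LifeTable whose lx at ages 1..max_age equals the given values."""
    lx = np.concatenate(([1.0], lx_interior))
    qx = 1.0 - lx[1:] / lx[:-1]
    qx = np.append(qx, template.qx[template.max_age])
    return build_lifetable_from_qx(qx, year=template.year,
                                   max_age=template.max_age)


class TestBrassLogit:
    def test_symmetry_point(self):
        assert brass_logit(0.5) == pytest.approx(0.0, abs=1e-15)

    def test_hand_value(self):
        assert brass_logit(0.1) == pytest.approx(0.5 * np.log(9.0),
                                                 abs=1e-12)

    def test_round_trip(self):
        assert brass_logit_inv(brass_logit(0.73)) == pytest.approx(0.73,
                                                                   abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.7])
    def test_domain_errors(self, bad):
        with pytest.raises(InvalidInputError):
            brass_logit(bad)

    @given(st.floats(1e-6, 1.0 - 1e-6))
    def test_bijection_on_unit_interval(self, l):
        y = brass_logit(l)
        assert brass_logit_inv(y) == pytest.approx(l, abs=1e-12)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.01, 0.99, 200)
        assert np.all(np.diff(brass_logit(grid)) < 0)


class TestFitBrass:
    def test_self_fit_is_identity(self, std_table):
        fit = fit_brass(std_table, std_table)
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)
        assert fit.beta == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_recovery_of_constructed_parameters(self, std_table):
        y = brass_logit(std_table.lx[1:100])
        observed = _table_from_lx(brass_logit_inv(0.3 + 1.2 * y), std_table)
        fit = fit_brass(observed, std_table)
        assert fit.alpha == pytest.approx(0.3, abs=1e-10)
        assert fit.beta == pytest.approx(1.2, abs=1e-10)

    def test_noisy_recovery_within_three_standard_errors(self, std_table,
                                                         rng):
        sd = 0.005
        y = brass_logit(std_table.lx[1:100])
        noisy = 0.1 + 1.05 * y + rng.normal(0.0, sd, y.size)
        # enforce a monotone survivorship so the noisy schedule is a table
        lx = np.minimum.accumulate(brass_logit_inv(noisy))
        observed = _table_from_lx(lx, std_table)
        fit = fit_brass(observed, std_table)
        x = y
        se_beta = sd / np.sqrt(np.sum((x - x.mean()) ** 2))
        se_alpha = sd * np.sqrt(1.0 / x.size
                                + x.mean() ** 2 / np.sum((x - x.mean()) ** 2))
        assert abs(fit.alpha - 0.1) < 3 * se_alpha
        assert abs(fit.beta - 1.05) < 3 * se_beta

    def test_shift_equivariance(self, std_table):
        y = brass_logit(std_table.lx[1:100])
        base = _table_from_lx(brass_logit_inv(0.05 + 1.1 * y), std_table)
        shifted = _table_from_lx(brass_logit_inv(0.05 + 0.2 + 1.1 * y),
                                 std_table)
        f0, f1 = fit_brass(base, std_table), fit_brass(shifted, std_table)
        assert f1.alpha - f0.alpha == pytest.approx(0.2, abs=1e-10)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-10)

    def test_too_few_ages(self, std_table):
        with pytest.raises(InsufficientDataError):
            fit_brass(std_table, std_table, age_range=(50, 51))


class TestEwbankTransform:
    def test_reduces_to_brass_at_tiny_exponents(self):
        params = EwbankParams(kappa=1e-8, lambda_=1e-8)
        for l in (0.1, 0.5, 0.9):
            assert ewbank_transform(l, params) == pytest.approx(
                brass_logit(l), abs=1e-6)

    @pytest.mark.parametrize("kappa,lam", [(0.3, -0.2), (0.7, 0.5),
                                           (-0.7, -0.5)])
    def test_fixed_point_at_one_half(self, kappa, lam):
        params = EwbankParams(kappa=kappa, lambda_=lam)
        assert ewbank_transform(0.5, params) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_at_l09_kappa005(self):
        # (r^κ − 1)/(2κ) with r = (1−0.9)/0.9 = 1/9, evaluated directly
        params = EwbankParams(kappa=0.05, lambda_=0.0)
        r = (1.0 - 0.9) / 0.9
        expected = (r**0.05 - 1.0) / (2 * 0.05)
        assert ewbank_transform(0.9, params) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_out_of_range_parameters_warn_not_error(self):
        with pytest.warns(UserWarning):
            EwbankParams(kappa=0.9)
        with pytest.warns(UserWarning):
            EwbankParams(lambda_=-0.8)

    def test_domain_error(self):
        with pytest.raises(InvalidInputError):
            ewbank_transform(1.2, EwbankParams())

    @pytest.mark.parametrize("l", [0.15, 0.5, 0.92])
    def test_continuity_in_exponents_at_zero(self, l):
        target = brass_logit(l)
        values = []
        for eps in (1e-2, 1e-4, 1e-6):
            p = EwbankParams(kappa=eps, lambda_=-eps)
            values.append(ewbank_transform(l, p))
        gaps = np.abs(np.array(values) - target)
        assert gaps[-1] < 1e-5
        assert np.all(np.diff(gaps) < 0) or gaps[0] < 1e-12

    def test_inverse_round_trip(self):
        params = EwbankParams(kappa=0.4, lambda_=-0.3)
        for l in (0.05, 0.3, 0.5, 0.8, 0.99):
            y = ewbank_transform(l, params)
            assert ewbank_transform_inv(y, params) == pytest.approx(
                l, abs=1e-10)


class TestBuildRelational:
    def test_identity_reproduces_standard(self, std_table):
        out = build_relational_lifetable(std_table, EwbankParams())
        assert np.abs(out.lx - std_table.lx).max() < 1e-10
        assert np.abs(out.qx - std_table.qx).max() < 1e-10

    def test_alpha_raises_mortality(self, std_table):
        out = build_relational_lifetable(
            std_table, EwbankParams(alpha=0.2))
        interior = slice(1, std_table.max_age)
        assert np.all(out.lx[interior] <= std_table.lx[interior])

    def test_matches_brute_force_recomputation(self, std_table):
        params = EwbankParams(alpha=0.15, beta=1.08, kappa=0.05,
                              lambda_=0.3, split_age=85)
        out = build_relational_lifetable(std_table, params)
        # independent recomputation: transform, scale, invert, difference
        ls = std_table.lx[1:]
        y = np.empty_like(ls)
        for i, l in enumerate(ls):
            r = (1.0 - l) / l
            c = params.kappa if l > 0.5 else params.lambda_
            y[i] = (r**c - 1.0) / (2 * c) if c != 0 else 0.5 * np.log(r)
        yo = params.alpha + params.beta * y
        l_out = np.empty_like(yo)
        for i, v in enumerate(yo):
            c = params.kappa if v < 0 else params.lambda_
            r = (1.0 + 2 * c * v) ** (1.0 / c) if c != 0 else np.exp(2 * v)
            l_out[i] = 1.0 / (1.0 + r)
        lx = np.concatenate(([1.0], l_out))
        qx_ref = 1.0 - lx[1:] / lx[:-1]
        assert np.allclose(out.qx[:-1], qx_ref, atol=1e-12)

    def test_uninvertible_parameters_raise(self, std_table):
        with pytest.raises(InversionError):
            build_relational_lifetable(
                std_table, EwbankParams(alpha=0.4, beta=1.1, kappa=0.05,
                                        lambda_=-0.5))

    @settings(max_examples=40, deadline=None)
    @given(alpha=st.floats(-0.25, 0.25), beta=st.floats(0.85, 1.2),
           kappa=st.floats(-0.7, 0.7), lam=st.floats(-0.5, 0.5))
    def test_output_satisfies_lifetable_invariants(self, std_table, alpha,
                                                   beta, kappa, lam):
        params = EwbankParams(alpha=alpha, beta=beta, kappa=kappa,
                              lambda_=lam)
        try:
            out = build_relational_lifetable(std_table, params)
        except InversionError:
            return  # legitimate for strongly negative exponents
        assert out.lx[0] == 1.0
        assert np.all(np.diff(out.lx) <= 1e-15)
        assert np.all((out.qx >= 0) & (out.qx <= 1))


def test_profile_fit_prefers_true_exponents(std_table):
    true = EwbankParams(alpha=0.1, beta=1.05, kappa=0.25, lambda_=0.2,
                        split_age=85)
    observed = build_relational_lifetable(std_table, true)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params, sse = fit_ewbank_profile(
            observed, std_table, kappa_grid=[0.0, 0.25, 0.5],
            lambda_grid=[0.0, 0.2, 0.4], split_age=85)
    assert params.kappa == pytest.approx(0.25)
    assert params.lambda_ == pytest.approx(0.2)
    assert params.alpha == pytest.approx(0.1, abs=1e-3)
    assert params.beta == pytest.approx(1.05, abs=1e-3)
    assert sse < 1e-6
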