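"""Bivariate normal CDF, joint likelihood, biprobit MLE and the Wald test."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.stats import norm

from ancdelivery.biprobit import (
    average_predicted_probability_biprobit,
    biprobit_loglik,
    bvn_cdf,
    fit_biprobit,
    wald_exogeneity_test,
)
from ancdelivery.design import build_design_matrix
from ancdelivery.exceptions import DataError, ExclusionRestrictionError
from ancdelivery.probit import fit_probit, probit_loglik
from ancdelivery.simulate import SimulationConfig, generate_dataset


def bvn_quad_oracle(x, y, rho, lo=-10.0):
    """Brute-force adaptive 2-D quadrature of the bivariate normal density."""
    s2 = 1.0 - rho * rho

    def density(v, u):
        return np.exp(-(u * u - 2 * rho * u * v + v * v) / (2 * s2)) / (
            2 * np.pi * np.sqrt(s2))

    val, _ = integrate.dblquad(density, lo, x, lo, y, epsabs=1e-12, epsrel=1e-12)
    return val


def analysis_arrays(table, covariates=("residence", "wealth_quintile")):
    d1 = pd.Series((table["anc_visits"] >= 3).astype(int).to_numpy(), name="d1")
    X = build_design_matrix(table, None, list(covariates))
    return (table["place_of_delivery"].to_numpy(), d1.to_numpy(), X,
            table["first_trimester"].to_numpy())


class TestBvnCdf:
    def test_independence_at_origin(self):
        assert bvn_cdf(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-14)

    def test_arcsine_closed_form_at_origin(self):
        assert bvn_cdf(0.0, 0.0, 0.5) == pytest.approx(1 / 3, abs=1e-14)

    @pytest.mark.parametrize("x,y,rho", [
        (1.2, -0.3, -0.4),
        (0.7, 0.7, 0.9),
        (-2.0, 1.5, 0.6),
        (0.0, 1.3, -0.8),
    ])
    def test_matches_adaptive_quadrature(self, x, y, rho):
        assert bvn_cdf(x, y, rho) == pytest.approx(bvn_quad_oracle(x, y, rho),
                                                   abs=1e-10)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.8, 0.3, 1.0) == pytest.approx(norm.cdf(0.3), abs=1e-14)
        assert bvn_cdf(0.8, 0.3, -1.0) == pytest.approx(
            max(0.0, norm.cdf(0.8) + norm.cdf(0.3) - 1), abs=1e-14)

    def test_infinite_arguments(self):
        assert bvn_cdf(np.inf, 0.4, 0.3) == pytest.approx(norm.cdf(0.4), abs=1e-14)
        assert bvn_cdf(-np.inf, 0.4, 0.3) == 0.0
        assert bvn_cdf(np.inf, np.inf, -0.2) == 1.0

    def test_out_of_range_rho_rejected(self):
        with pytest.raises(ValueError):
            bvn_cdf(0.0, 0.0, 1.2)

    @given(
        st.floats(-4, 4), st.floats(-4, 4),
        st.floats(-0.99, 0.99),
    )
    def test_symmetry_in_arguments(self, x, y, rho):
        assert bvn_cdf(x, y, rho) == pytest.approx(bvn_cdf(y, x, rho), abs=1e-13)

    @given(
        st.floats(-3, 3), st.floats(-3, 3),
        st.floats(-0.95, 0.95), st.floats(0.01, 0.5),
    )
    def test_monotone_in_each_argument_and_rho(self, x, y, rho, eps):
        base = bvn_cdf(x, y, rho)
        assert bvn_cdf(x + eps, y, rho) >= base - 1e-13
        assert bvn_cdf(x, y + eps, rho) >= base - 1e-13
        if rho + eps <= 1.0:
            assert bvn_cdf(x, y, rho + eps) >= base - 1e-13


class TestBiprobitLoglik:
    @pytest.fixture
    def tiny_system(self):
        X = np.column_stack([np.ones(3), [0.5, -1.0, 0.2]])
        O = np.array([1, 0, 1])
        E = np.array([0, 1, 1])
        Z = np.array([1, 0, 1])
        return O, E, X, Z

    def test_three_row_worked_example(self, tiny_system):
        O, E, X, Z = tiny_system
        params = np.array([0.8, -0.2, 0.4, 1.1, 0.3, -0.1, np.arctanh(-0.3)])
        k = 2
        delta, beta1 = params[0], params[1:3]
        gamma, beta2 = params[3], params[4:6]
        rho = -0.3
        expected = 0.0
        for i in range(3):
            w1 = delta * E[i] + X[i] @ beta1
            w2 = gamma * Z[i] + X[i] @ beta2
            q1, q2 = 2 * O[i] - 1, 2 * E[i] - 1
            expected += np.log(bvn_cdf(q1 * w1, q2 * w2, q1 * q2 * rho))
        assert biprobit_loglik(params, O, E, X, Z) == pytest.approx(expected,
                                                                    abs=1e-12)

    def test_all_zero_parameters_give_log_quarter(self, tiny_system):
        O, E, X, Z = tiny_system
        assert biprobit_loglik(np.zeros(7), O, E, X, Z) == pytest.approx(
            3 * np.log(0.25), abs=1e-12)

    def test_factorizes_at_zero_rho(self, tiny_system):
        O, E, X, Z = tiny_system
        params = np.array([0.8, -0.2, 0.4, 1.1, 0.3, -0.1, 0.0])
        ll_out = probit_loglik(np.array([-0.2, 0.4, 0.8]), O,
                               np.column_stack([X, E]))
        ll_trt = probit_loglik(np.array([0.3, -0.1, 1.1]), E,
                               np.column_stack([X, Z]))
        assert biprobit_loglik(params, O, E, X, Z) == pytest.approx(
            ll_out + ll_trt, abs=1e-10)

    def test_cell_probabilities_sum_to_one(self, tiny_system):
        _, _, X, Z = tiny_system
        params = np.array([0.8, -0.2, 0.4, 1.1, 0.3, -0.1, np.arctanh(0.55)])
        total = np.zeros(3)
        for o in (0, 1):
            for e in (0, 1):
                O = np.full(3, o)
                E = np.full(3, e)
                w1 = params[0] * E + X @ params[1:3]
                w2 = params[3] * Z + X @ params[4:6]
                q1, q2 = 2.0 * O - 1, 2.0 * E - 1
                total += bvn_cdf(q1 * w1, q2 * w2, q1 * q2 * 0.55)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)

    def test_instrument_in_outcome_design_rejected(self, tiny_system):
        O, E, X, Z = tiny_system
        X_bad = np.column_stack([X, Z])
        with pytest.raises(ExclusionRestrictionError):
            biprobit_loglik(np.zeros(9), O, E, X_bad, Z)


class TestFitBiprobit:
    def test_reduces_to_independent_probits_when_rho_fixed_zero(self):
        config = replace(SimulationConfig(), n=4_000, rho=-0.3, seed=17)
        table, _ = generate_dataset(config)
        y, d1, X, z = analysis_arrays(table)
        fit = fit_biprobit(y, d1, X, z, fix_rho=0.0, dimension_name="d1")

        dm_out = build_design_matrix(table, pd.Series(d1, name="d1"),
                                     ["residence", "wealth_quintile"])
        aug = table.assign(iv=table["first_trimester"])
        dm_trt = build_design_matrix(aug, pd.Series(z, name="iv"),
                                     ["residence", "wealth_quintile"])
        ref_out = fit_probit(y, dm_out)
        ref_trt = fit_probit(d1, dm_trt)
        np.testing.assert_allclose(
            np.concatenate([[fit.delta], fit.beta_outcome]),
            np.concatenate([[ref_out.params[-1]], ref_out.params[:-1]]),
            atol=1e-6)
        np.testing.assert_allclose(
            np.concatenate([[fit.gamma], fit.beta_treatment]),
            np.concatenate([[ref_trt.params[-1]], ref_trt.params[:-1]]),
            atol=1e-6)

    def test_matches_naive_probit_under_exogeneity(self):
        config = replace(SimulationConfig(), n=20_000, rho=0.0, seed=23)
        table, _ = generate_dataset(config)
        y, d1, X, z = analysis_arrays(
            table, ("residence", "mother_education", "wealth_quintile"))
        fit = fit_biprobit(y, d1, X, z, dimension_name="d1")
        dm_out = build_design_matrix(
            table, pd.Series(d1, name="d1"),
            ["residence", "mother_education", "wealth_quintile"])
        naive = fit_probit(y, dm_out)
        # the gap between the two estimators is driven by rho-hat noise, so
        # the corrected estimator's (larger) SE is the right yardstick
        assert abs(fit.delta - naive.coef("d1")) < 2 * fit.se_delta()

    def test_loglik_not_below_independent_probit_start(self):
        config = replace(SimulationConfig(), n=4_000, rho=-0.4, seed=29)
        table, _ = generate_dataset(config)
        y, d1, X, z = analysis_arrays(table)
        fit = fit_biprobit(y, d1, X, z, dimension_name="d1")
        fixed = fit_biprobit(y, d1, X, z, fix_rho=0.0, dimension_name="d1")
        assert fit.loglik >= fixed.loglik - 1e-8

    def test_corrects_attenuated_exposure_effect(self, medium_dataset):
        table, truth = medium_dataset
        y, d1, X, z = analysis_arrays(
            table, ("residence", "mother_education", "wealth_quintile"))
        fit = fit_biprobit(y, d1, X, z, dimension_name="d1")
        dm_out = build_design_matrix(
            table, pd.Series(d1, name="d1"),
            ["residence", "mother_education", "wealth_quintile"])
        naive = fit_probit(y, dm_out)
        # negative rho: naive probit understates the exposure effect
        assert naive.coef("d1") < fit.delta
        assert fit.delta == pytest.approx(truth.config.delta, abs=0.15)
        assert fit.rho == pytest.approx(truth.config.rho, abs=0.1)

    def test_weak_instrument_flagged(self):
        config = replace(SimulationConfig(), n=2_000, gamma_iv=0.0, seed=3)
        table, _ = generate_dataset(config)
        y, d1, X, z = analysis_arrays(table)
        with pytest.warns(UserWarning, match="weak instrument"):
            fit = fit_biprobit(y, d1, X, z, dimension_name="d1")
        assert fit.weak_instrument

    def test_constant_instrument_rejected(self):
        config = replace(SimulationConfig(), n=500, seed=3)
        table, _ = generate_dataset(config)
        y, d1, X, _ = analysis_arrays(table)
        with pytest.raises(DataError):
            fit_biprobit(y, d1, X, np.ones(len(y)), dimension_name="d1")


@pytest.fixture(scope="module")
def fitted():
    config = replace(SimulationConfig(), n=20_000, seed=7)
    table, truth = generate_dataset(config)
    y, d1, X, z = analysis_arrays(
        table, ("residence", "mother_education", "wealth_quintile"))
    return fit_biprobit(y, d1, X, z, dimension_name="d1"), X, truth


class TestWaldAndPrediction:
    def test_wald_statistic_definition(self, fitted):
        fit, _, _ = fitted
        stat, p, label = wald_exogeneity_test(fit)
        assert stat == pytest.approx((fit.atanh_rho / fit.se_atanh_rho) ** 2)
        assert label == "rho<0"
        assert p < 0.05

    def test_rho_delta_method_se(self, fitted):
        fit, _, _ = fitted
        assert fit.se_rho == pytest.approx((1 - fit.rho**2) * fit.se_atanh_rho)

    def test_counterfactual_probabilities_bracket_truth(self, fitted):
        fit, X, truth = fitted
        p0 = average_predicted_probability_biprobit(fit, X, 0)
        p1 = average_predicted_probability_biprobit(fit, X, 1)
        assert 0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0
        assert p1 > p0  # delta > 0
        assert p0 == pytest.approx(truth.true_average_probability(0), abs=0.05)
        assert p1 == pytest.approx(truth.true_average_probability(1), abs=0.05)

    def test_invalid_counterfactual_value_rejected(self, fitted):
        fit, X, _ = fitted
        with pytest.raises(DataError):
            average_predicted_probability_biprobit(fit, X, 2)

    def test_serialization_roundtrip(self, fitted):
        fit, _, _ = fitted
        d = fit.to_dict()
        assert d["rho"] == pytest.approx(fit.rho)
        assert d["wald_p"] == pytest.approx(fit.wald_p)
        assert len(d["coefficients"]) == len(fit.params)
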