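"""Regression-with-interactions rule, composite rule fit, and screening."""

import numpy as np
import pytest

from ptrkit import (
    DegenerateCompositeError,
    InsufficientDataError,
    SingularFitError,
    composite_values,
    fit_composite_ptr,
    fit_kraemer_ptr,
    fit_regression_ptr,
    get_scenario,
    load_rule,
    make_train_test,
    moderator_interaction_pvalues,
    save_rule,
    screen_moderators,
)

from conftest import make_trial, random_trial


def _noise_free_trial(n=20, seed=0, b0=2.0, b1=2.0):
    """Data exactly from Y = a*X1 + A*(b0 + b1*Z1), no error term."""
    rng = np.random.default_rng(seed)
    Z1 = rng.standard_normal(n)
    X1 = rng.standard_normal(n)
    A = np.array([0.5, -0.5] * (n // 2))
    Y = 1.5 * X1 + A * (b0 + b1 * Z1)
    return make_trial(Y, A, {"Z1": Z1, "X1": X1},
                      {"Z1": "moderator", "X1": "prognostic"})


class TestRegressionPTR:
    def test_noise_free_recovery_is_exact(self):
        rule = fit_regression_ptr(_noise_free_trial())
        assert rule.intercept == pytest.approx(2.0, abs=1e-8)
        assert rule.coefficients["Z1"] == pytest.approx(2.0, abs=1e-8)

    def test_duplicated_moderator_raises_naming_columns(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal(20)
        data = make_trial(rng.standard_normal(20), [0.5, -0.5] * 10,
                          {"Z1": Z, "Z2": Z},
                          {"Z1": "moderator", "Z2": "moderator"})
        with pytest.raises(SingularFitError) as err:
            fit_regression_ptr(data)
        assert err.value.columns  # names the collinear columns

    def test_more_parameters_than_subjects_raises(self):
        rng = np.random.default_rng(2)
        data = random_trial(rng, n=6, n_mod=2, n_prog=1)
        with pytest.raises(InsufficientDataError):
            fit_regression_ptr(data)

    def test_recommendations_track_true_effect_sign_on_test_draw(self):
        spec = get_scenario("1a")
        train, test = make_train_test(spec, 2000, 7)
        rule = fit_regression_ptr(train.data)
        agree = np.mean(rule.recommend(test.data) == test.optimal)
        assert agree >= 0.95

    def test_rule_recommend_is_strict_at_zero(self):
        rule = fit_regression_ptr(_noise_free_trial())
        rule.intercept, rule.coefficients["Z1"] = 0.0, 0.0
        data = _noise_free_trial(n=8, seed=3)
        assert np.all(rule.recommend(data) == -0.5)

    def test_scale_equivariance_of_recommendations(self):
        data = _noise_free_trial(n=30, seed=4)
        rule = fit_regression_ptr(data)
        before = rule.recommend(data)
        rule.intercept *= 7.5
        rule.coefficients = {k: 7.5 * v for k, v in rule.coefficients.items()}
        assert np.array_equal(rule.recommend(data), before)


class TestCompositePTR:
    def test_zero_slope_positive_intercept_treats_everyone(self):
        # Y depends on A only => beta* ~ 0 and beta0* = 2 > 0
        rng = np.random.default_rng(6)
        Z1 = rng.standard_normal(40)
        A = np.array([0.5, -0.5] * 20)
        data = make_trial(2.0 * A, A, {"Z1": Z1}, {"Z1": "moderator"})
        zstar = composite_values(data, {"Z1": 1.0})
        rule = fit_composite_ptr(data, zstar)
        assert rule.intercept == pytest.approx(2.0, abs=1e-8)
        assert np.all(rule.recommend(data) == 0.5)

    def test_composite_expands_to_raw_moderator_rule(self):
        spec = get_scenario("1a")
        train, _ = make_train_test(spec, 400, 3)
        rule = fit_kraemer_ptr(train.data)
        expanded = rule.expanded_coefficients()
        z = train.data.biomarkers
        manual = rule.intercept + sum(c * z[k].to_numpy() for k, c in expanded.items())
        assert np.allclose(manual, rule.decision_values(train.data))

    def test_positive_affine_transform_of_zstar_keeps_recommendations(self):
        spec = get_scenario("1a")
        train, test = make_train_test(spec, 500, 9)
        rule = fit_kraemer_ptr(train.data)
        w = rule.weights
        from ptrkit.methods import CompositeModerator

        z = composite_values(train.data, w)
        z_aff = CompositeModerator(weights=w, values=3.0 * z.values + 5.0)
        rule_aff = fit_composite_ptr(train.data, z_aff)
        # compare on the training subjects via each rule's own composite
        d1 = rule.intercept + rule.coefficients["Z*"] * z.values
        d2 = rule_aff.intercept + rule_aff.coefficients["Z*"] * z_aff.values
        assert np.array_equal(d1 > 0, d2 > 0)

    def test_agreement_with_true_effect_sign_from_kraemer_pipeline(self):
        spec = get_scenario("1a")
        train, test = make_train_test(spec, 2000, 7)
        rule = fit_kraemer_ptr(train.data)
        agree = np.mean(rule.recommend(test.data) == test.optimal)
        assert agree >= 0.85

    def test_constant_composite_raises_degenerate(self, toy):
        zstar = composite_values(toy, {"Z1": 0.0})
        with pytest.raises(DegenerateCompositeError):
            fit_composite_ptr(toy, zstar)


class TestRuleBoundaryConvergence:
    def test_kraemer_and_regression_boundaries_agree_at_large_n(self):
        """Single moderator, no prognostic variables: both methods estimate
        the same decision boundary -b0/b1 as n grows."""
        rng = np.random.default_rng(15)
        n = 5000
        Z1 = rng.standard_normal(n)
        A = np.where(rng.random(n) < 0.5, 0.5, -0.5)
        Y = 0.5 * Z1 + A * (1.0 + 2.0 * Z1) + rng.standard_normal(n)
        data = make_trial(Y, A, {"Z1": Z1}, {"Z1": "moderator"})
        reg = fit_regression_ptr(data)
        kra = fit_kraemer_ptr(data)
        b_reg = -reg.intercept / reg.coefficients["Z1"]
        kc = kra.expanded_coefficients()
        b_kra = -kra.intercept / kc["Z1"]
        assert abs(b_reg - b_kra) / abs(b_reg) < 0.10


class TestRuleSerialisation:
    def test_round_trip_regression_rule(self, tmp_path):
        rule = fit_regression_ptr(_noise_free_trial())
        path = tmp_path / "rule.txt"
        save_rule(rule, path)
        again = load_rule(path)
        assert again.kind == rule.kind
        assert again.intercept == rule.intercept
        assert again.coefficients == rule.coefficients

    def test_round_trip_composite_rule_preserves_weights(self, tmp_path):
        spec = get_scenario("1a")
        train, _ = make_train_test(spec, 300, 2)
        rule = fit_kraemer_ptr(train.data)
        path = tmp_path / "rule.txt"
        save_rule(rule, path)
        again = load_rule(path)
        assert again.weights == rule.weights
        assert np.array_equal(again.recommend(train.data),
                              rule.recommend(train.data))


class TestScreening:
    @staticmethod
    def _screening_trial(seed, n=400, strong=2.0, noise=0.1):
        rng = np.random.default_rng(seed)
        Z = {f"Z{j + 1}": rng.standard_normal(n) for j in range(3)}
        X1 = rng.standard_normal(n)
        A = np.where(rng.random(n) < 0.5, 0.5, -0.5)
        Y = X1 + A * (0.5 + strong * Z["Z1"]) + noise * rng.standard_normal(n)
        roles = {k: "moderator" for k in Z}
        roles["X1"] = "prognostic"
        return make_trial(Y, A, {**Z, "X1": X1}, roles)

    def test_strong_moderator_separates_from_nulls(self):
        data = self._screening_trial(1)
        assert screen_moderators(data) == ["Z1"]
        p = moderator_interaction_pvalues(data)
        assert p["Z1"] < 1e-6
        assert p["Z2"] > 0.01 and p["Z3"] > 0.01

    def test_thresholds_of_one_retain_everything(self):
        data = self._screening_trial(1)
        assert screen_moderators(data, p_uni=1.0, p_multi=1.0) == \
            ["Z1", "Z2", "Z3"]

    def test_no_retained_moderators_is_empty_list_not_error(self):
        data = self._screening_trial(2, strong=0.0, noise=5.0)
        assert screen_moderators(data, p_uni=1e-12) == []
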