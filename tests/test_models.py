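import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from oracles import auc_pair_counting, bh_step_up, dominance_by_orderings
from sdcmap import (
    auc,
    category_free_nri,
    chi_square_test,
    compare_models,
    dominance_general,
    fdr_correct,
    fit_logistic,
    group_tests,
    idi,
    model_specs,
    rank_sum_test,
    vif,
)
from sdcmap.models import _mcfadden_subsets


def expanded_table(a, b, c, d):
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return pd.DataFrame({"x": x}), y


class TestFitLogistic:
    def test_agrees_with_statsmodels(self, rng):
        n = 200
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        eta = 0.8 * X["a"] - 0.5 * X["c"] - 0.3
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), ref.params.drop("const"), atol=1e-6
        )
        np.testing.assert_allclose(fit.intercept, ref.params["const"], atol=1e-6)
        np.testing.assert_allclose(fit.llf, ref.llf, atol=1e-8)
        np.testing.assert_allclose(
            fit.p_values.to_numpy(), ref.pvalues.drop("const"), atol=1e-5
        )

    def test_null_predictor_or_near_one(self, rng):
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.3).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y, compute_vif=False)
        assert fit.odds_ratios.loc["x", "or"] == pytest.approx(1.0, abs=0.25)
        assert fit.p_values["x"] > 0.01

    @pytest.mark.parametrize(
        "table", [(3, 5, 2, 7), (1, 9, 9, 1), (10, 2, 5, 20), (4, 4, 4, 4)]
    )
    def test_or_equals_cross_product(self, table):
        a, b, c, d = table
        X, y = expanded_table(a, b, c, d)
        fit = fit_logistic(X, y, compute_vif=False)
        assert fit.odds_ratios.loc["x", "or"] == pytest.approx(
            (a * d) / (b * c), rel=1e-6
        )

    def test_perfect_separation_named(self):
        X = pd.DataFrame({"good": [0.1, 0.4, 0.2, 0.9, 0.8, 0.7],
                          "sep": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]})
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="sep"):
            fit_logistic(X, y)

    def test_zero_variance_predictor_rejected(self):
        X = pd.DataFrame({"x": np.ones(10)})
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="zero variance"):
            fit_logistic(X, y)

    def test_parameter_recovery_on_planted_effect(self):
        # planted log-odds recovered within 2 SE in most replicates
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 697
            x = r.normal(size=n)
            y = (r.random(n) < 1 / (1 + np.exp(-(-1.0 + 0.25 * x)))).astype(int)
            fit = fit_logistic(pd.DataFrame({"x": x}), y, compute_vif=False)
            se = (
                np.log(fit.odds_ratios.loc["x", "ci_high"])
                - np.log(fit.odds_ratios.loc["x", "or"])
            ) / 1.96
            hits += abs(fit.coefficients["x"] - 0.25) <= 2 * se
        assert hits >= 9


class TestModelSpecs:
    @pytest.fixture()
    def cohort(self, tiny_study):
        return tiny_study.cohort

    def test_predictor_counts(self, cohort, rng):
        scores = rng.normal(size=len(cohort))
        specs = model_specs(cohort, scores)
        assert specs["model1"].shape[1] == 1
        assert specs["basic"].shape[1] == 8
        assert specs["enhanced"].shape[1] == 9

    def test_model3_superset_of_model2(self, cohort, rng):
        specs = model_specs(cohort, rng.normal(size=len(cohort)))
        assert set(specs["model2"].columns) <= set(specs["model3"].columns)

    def test_missing_column_named(self, cohort, rng):
        broken = cohort.drop(columns=["moca"])
        with pytest.raises(ValueError, match="moca"):
            model_specs(broken, rng.normal(size=len(cohort)))

    def test_low_epv_warns(self, cohort, rng):
        with pytest.warns(UserWarning, match="events-per-variable"):
            model_specs(cohort, rng.normal(size=len(cohort)))


class TestVif:
    def test_orthogonal_predictors_unity(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        np.testing.assert_allclose(vif(X).to_numpy(), 1.0, atol=1e-12)

    def test_duplicate_predictor_infinite(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": x})
        assert np.isinf(vif(X)).all()

    def test_matches_auxiliary_regressions(self, rng):
        Z = rng.normal(size=(50, 3))
        X = pd.DataFrame(
            {"a": Z[:, 0], "b": Z[:, 0] * 0.7 + Z[:, 1], "c": Z[:, 2]}
        )
        got = vif(X)
        for col in X.columns:
            others = sm.add_constant(X.drop(columns=col))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert got[col] == pytest.approx(1 / (1 - r2), rel=1e-10)


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_random_predictions_near_half(self, rng):
        p = rng.random(4000)
        y = (rng.random(4000) < 0.4).astype(int)
        assert auc(p, y) == pytest.approx(0.5, abs=0.05)

    def test_pair_counting_oracle_with_ties(self, rng):
        p = rng.integers(0, 4, size=10) / 4.0  # forced ties
        y = np.array([1, 0, 1, 1, 0, 0, 0, 1, 0, 1])
        assert auc(p, y) == pytest.approx(auc_pair_counting(p, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        p = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        assert auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestNriIdi:
    def test_identical_models_zero(self, rng):
        p = rng.random(20)
        y = (np.arange(20) % 2).astype(int)
        nri, _, _ = category_free_nri(p, p, y)
        idi_v, _, _ = idi(p, p, y)
        assert nri == 0.0 and idi_v == 0.0

    def test_nri_bound_attained(self):
        y = np.array([1, 1, 0, 0])
        p_base = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.9, 0.8, 0.1, 0.2])
        nri, _, p = category_free_nri(p_base, p_new, y)
        assert nri == 2.0

    def test_idi_extreme_is_one(self):
        y = np.array([1, 1, 0, 0])
        value, _, _ = idi(np.full(4, 0.5), y.astype(float), y)
        assert value == pytest.approx(1.0)

    def test_counting_oracle_eight_patients(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        pb = np.array([0.3, 0.6, 0.5, 0.2, 0.4, 0.8, 0.3, 0.5])
        pn = np.array([0.4, 0.5, 0.5, 0.1, 0.5, 0.6, 0.3, 0.9])
        # events: up, down, tie, up -> (2-1)/4; nonevents: down, up, down, tie
        expected = (2 - 1) / 4 + (2 - 1) / 4
        nri, _, _ = category_free_nri(pb, pn, y)
        assert nri == pytest.approx(expected)

    def test_idi_arithmetic_oracle(self):
        y = np.array([1, 0, 1, 0])
        pb = np.array([0.6, 0.4, 0.5, 0.3])
        pn = np.array([0.8, 0.3, 0.6, 0.4])
        expected = (np.mean([0.8, 0.6]) - np.mean([0.3, 0.4])) - (
            np.mean([0.6, 0.5]) - np.mean([0.4, 0.3])
        )
        value, _, _ = idi(pb, pn, y)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_improving_model_positive_on_planted_data(self):
        positives = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 400
            x1, x2 = r.normal(size=n), r.normal(size=n)
            y = (r.random(n) < 1 / (1 + np.exp(-(x1 + x2)))).astype(int)
            base = fit_logistic(pd.DataFrame({"x1": x1}), y, compute_vif=False)
            new = fit_logistic(
                pd.DataFrame({"x1": x1, "x2": x2}), y, compute_vif=False
            )
            res = compare_models(base, new, y)
            positives += (res.nri > 0) and (res.idi > 0)
        assert positives >= 9


class TestDominance:
    def test_single_predictor_equals_full_r2(self, rng):
        n = 150
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        X = pd.DataFrame({"x": x})
        res = dominance_general(X, y)
        fit = fit_logistic(X, y, compute_vif=False)
        assert res.general_dominance["x"] == pytest.approx(fit.mcfadden_r2)

    def test_interchangeable_predictors_near_equal(self, rng):
        n = 300
        x = rng.normal(size=n)
        X = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.01, n)})
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        res = dominance_general(X, y)
        assert res.general_dominance["a"] == pytest.approx(
            res.general_dominance["b"], abs=0.01
        )

    def test_sum_identity_and_ordering_oracle(self, rng):
        n = 250
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        eta = 0.9 * X["a"] + 0.4 * X["b"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        res = dominance_general(X, y)
        assert res.general_dominance.sum() == pytest.approx(
            res.full_model_fit, abs=1e-10
        )
        r2 = _mcfadden_subsets(X, y.astype(float))
        expected = dominance_by_orderings(r2, list(X.columns))
        for col in X.columns:
            assert res.general_dominance[col] == pytest.approx(
                expected[col], abs=1e-10
            )
        assert res.ranking[0] == "a"

    def test_too_many_predictors_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 16)))
        y = (np.arange(40) % 2).astype(int)
        with pytest.raises(ValueError, match="15"):
            dominance_general(X, y)


class TestGroupTests:
    def test_laterality_from_printed_counts(self):
        # left: 67 of 244 with the outcome; right: 85 of 274
        table = [[67, 244 - 67], [85, 274 - 85]]
        stat, p = chi_square_test(table)
        assert 67 / 244 * 100 == pytest.approx(27.5, abs=0.05)
        assert 85 / 274 * 100 == pytest.approx(31.0, abs=0.05)
        assert p == pytest.approx(0.374, abs=0.0005)

    def test_chi_square_hand_computed_2x3(self):
        table = np.array([[10, 20, 30], [30, 20, 10]])
        expected_counts = np.outer(
            table.sum(1), table.sum(0)
        ) / table.sum()
        expected_stat = ((table - expected_counts) ** 2 / expected_counts).sum()
        stat, _ = chi_square_test(table)
        assert stat == pytest.approx(expected_stat, rel=1e-12)

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [1, 2]])

    def test_identical_groups_null(self, rng):
        x = rng.normal(size=200)
        _, p = rank_sum_test(x, x)
        assert p > 0.9

    def test_three_group_rank_test(self, rng):
        values = np.r_[rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(3, 1, 50)]
        groups = np.r_[np.zeros(50), np.ones(50), np.full(50, 2)]
        _, p = group_tests(values, groups)
        assert p < 1e-6

    def test_categorical_dispatch(self, rng):
        values = rng.choice(["x", "y"], size=100)
        groups = rng.choice(["g1", "g2"], size=100)
        stat, p = group_tests(values, groups, kind="categorical")
        assert 0 <= p <= 1


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_all_equal_stay_equal(self):
        out = fdr_correct(np.full(7, 0.02))
        assert np.all(out == out[0])

    def test_matches_step_up_oracle(self, rng):
        p = rng.random(70)
        np.testing.assert_allclose(fdr_correct(p), bh_step_up(p), atol=1e-12)
        assert np.all(fdr_correct(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])
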