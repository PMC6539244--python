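import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivestress.errors import DegenerateLabelsError, SchemaError, SeparationWarning
from drivestress.models import (
    ConfusionCounts,
    LogisticClassifier,
    auc,
    confusion,
    evaluate_classifiers,
    fit_logistic,
    metrics,
    predict,
    pseudo_r2,
)


from _grid_oracle import grid_mle


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        m = fit_logistic(np.empty((100, 0)), y, feature_names=[])
        assert m.constant == pytest.approx(math.log(0.3 / 0.7), abs=1e-6)
        assert m.ll_full == pytest.approx(m.ll_null, abs=1e-6)

    def test_single_feature_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(40, 1))
        eta = -0.5 + 1.2 * X[:, 0]
        y = (rng.random(40) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_logistic(X, y)
        oracle = grid_mle(X, y)
        assert abs(m.constant - oracle[0]) < 1e-3
        assert abs(m.coefficients["x0"] - oracle[1]) < 1e-3

    def test_two_feature_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 2))
        eta = 0.3 + 0.8 * X[:, 0] - 1.1 * X[:, 1]
        y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_logistic(X, y)
        oracle = grid_mle(X, y)
        assert abs(m.constant - oracle[0]) < 1e-3
        assert abs(m.coefficients["x0"] - oracle[1]) < 1e-3
        assert abs(m.coefficients["x1"] - oracle[2]) < 1e-3

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            fit_logistic(np.random.default_rng(0).normal(size=(20, 1)), np.ones(20))

    def test_perfect_separation_warns_and_caps(self):
        X = np.r_[np.full((10, 1), -1.0), np.full((10, 1), 1.0)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(SeparationWarning):
            m = fit_logistic(X, y)
        assert m.separation
        p, _ = predict(m, X)
        assert np.all(np.isfinite(p))

    def test_pseudo_r2_stored_and_bounded(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 2))
        y = (rng.random(80) < 0.5).astype(float)
        m = fit_logistic(X, y)
        assert 0 <= m.r2_cox_snell < 1
        assert m.r2_cox_snell <= m.r2_nagelkerke <= 1


class TestPredict:
    @staticmethod
    def _model(coefs, const):
        from drivestress.models import LogisticModel

        return LogisticModel(
            coefficients=coefs, constant=const,
            ll_null=-10.0, ll_full=-5.0, n=10,
        )

    def test_printed_constant_evaluates_correctly(self):
        # all features zero: p depends on the constant term 5.444 alone
        m = self._model({"n": 0.0}, 5.444)
        p, label = predict(m, pd.DataFrame({"n": [0.0]}))
        assert p[0] == pytest.approx(1 / (1 + math.exp(-5.444)), abs=1e-9)
        assert p[0] == pytest.approx(0.99569, abs=1e-4)
        assert bool(label[0]) is True

    def test_probability_exactly_half_is_low_stress(self):
        m = self._model({"x": 1.0}, 0.0)
        p, label = predict(m, pd.DataFrame({"x": [0.0]}))
        assert p[0] == 0.5
        assert bool(label[0]) is False  # strictly greater than 0.5 required

    def test_positive_coefficient_is_monotone(self):
        m = self._model({"x": 2.0}, -1.0)
        p, _ = predict(m, pd.DataFrame({"x": np.linspace(-3, 3, 50)}))
        assert (np.diff(p) > 0).all()

    def test_missing_feature_is_schema_error(self):
        m = self._model({"x": 1.0}, 0.0)
        with pytest.raises(SchemaError):
            predict(m, pd.DataFrame({"y": [1.0]}))


class TestConfusionAndMetrics:
    def test_perfect_agreement(self):
        y = np.array([1, 0, 1, 1, 0], bool)
        c = confusion(y, y)
        assert c.fp == 0 and c.fn == 0
        m = metrics(c)
        assert m.accuracy == m.sensitivity == m.specificity == m.ppv == 1.0

    def test_total_disagreement(self):
        y = np.array([1, 0, 1], bool)
        c = confusion(y, ~y)
        assert c.tp == 0 and c.tn == 0

    def test_counts_match_brute_force_tally(self, rng):
        y_true = rng.random(1000) < 0.4
        y_pred = rng.random(1000) < 0.5
        c = confusion(y_true, y_pred)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for t, p in zip(y_true, y_pred):
            key = ("t" if t == p else "f") + ("p" if p else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"]
        )

    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=17, fn=3, tn=21, fp=4))
        assert m.sensitivity == pytest.approx(0.85)
        assert m.specificity == pytest.approx(0.84)
        assert m.accuracy == pytest.approx(38 / 45)
        assert m.ppv == pytest.approx(17 / 21)

    def test_undefined_metrics_are_none_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert m.ppv is None
        assert m.sensitivity == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True, False], [True])

    @settings(max_examples=100, deadline=None)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_metric_identities_exact(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        c = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        m = metrics(c)
        # each defined metric equals its exact rational value
        if m.sensitivity is not None:
            assert m.sensitivity == float(Fraction(tp, tp + fn))
        if m.specificity is not None:
            assert m.specificity == float(Fraction(tn, tn + fp))
        if m.ppv is not None:
            assert m.ppv == float(Fraction(tp, tp + fp))
        assert m.accuracy == float(Fraction(tp + tn, c.total))


class TestPseudoR2:
    def test_no_improvement_gives_zero(self):
        assert pseudo_r2(-50.0, -50.0, 100) == (0.0, 0.0)

    def test_worked_example(self):
        cs, ng = pseudo_r2(-69.3147, -50.0, 100)
        assert cs == pytest.approx(0.3204, abs=1e-4)
        assert ng == pytest.approx(0.4272, abs=1e-4)

    def test_perfect_fit_nagelkerke_reaches_one(self):
        cs, ng = pseudo_r2(-69.3147, -1e-12, 100)
        assert ng == pytest.approx(1.0, abs=1e-9)

    def test_inconsistent_likelihoods_rejected(self):
        with pytest.raises(ValueError):
            pseudo_r2(-10.0, -20.0, 50)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(2, 500),
        ll_null=st.floats(-500.0, -0.1),
        frac=st.floats(0.0, 1.0),
    )
    def test_bounds_hold_for_all_valid_inputs(self, n, ll_null, frac):
        ll_full = ll_null * (1 - frac)  # between ll_null and 0
        cs, ng = pseudo_r2(ll_null, ll_full, n)
        # cs < 1 strictly unless the likelihood ratio falls below the
        # resolution of a double next to 1.0
        saturated = np.exp(2.0 * (ll_null - ll_full) / n) < 1e-15
        assert 0.0 <= cs <= 1.0
        assert cs < 1.0 or saturated
        assert cs <= ng <= 1.0 + 1e-12


class TestAuc:
    def test_perfect_separation(self):
        y = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        assert auc(np.arange(10), y) == 1.0

    def test_all_tied_scores_give_half(self):
        y = np.r_[np.zeros(5), np.ones(5)].astype(bool)
        assert auc(np.ones(10), y) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(11)
        y = np.r_[np.zeros(1000), np.ones(1000)].astype(bool)
        assert auc(rng.random(2000), y) == pytest.approx(0.5, abs=0.03)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.random(200) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        s = rng.normal(size=200)
        assert auc(s, y) == auc(np.exp(s), y)
        assert auc(s, y) == auc(3 * s + 7, y)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            auc([0.1, 0.2], [True, True])


class _ConstantClassifier:
    """Always predicts the negative class with one fixed score."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=bool)

    def predict_proba(self, X):
        return np.tile([0.7, 0.3], (len(X), 1))


class TestEvaluateClassifiers:
    @staticmethod
    def _data(n=240, signal=1.5, seed=5):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2 == 0
        X = rng.normal(size=(n, 3))
        X[y, 0] += signal
        return pd.DataFrame(X, columns=["a", "b", "c"]), y

    def test_constant_classifier_baseline(self):
        X, y = self._data()
        out = evaluate_classifiers(X, y, {"const": _ConstantClassifier()})
        row = out.iloc[0]
        assert row["sensitivity"] == 0.0
        assert row["auc"] == 50.0

    def test_shuffled_labels_give_chance_auc(self):
        X, y = self._data(signal=0.0)
        out = evaluate_classifiers(X, y, {"logit": LogisticClassifier()}, seed=1)
        assert out["auc"].iloc[0] == pytest.approx(50.0, abs=5.0)

    def test_strong_signal_detected_by_both_schemes(self):
        X, y = self._data(signal=2.0)
        cv = evaluate_classifiers(X, y, {"logit": LogisticClassifier()})
        sp = evaluate_classifiers(
            X, y, {"logit": LogisticClassifier()}, scheme="split70_30"
        )
        assert cv["auc"].iloc[0] > 90.0
        assert sp["auc"].iloc[0] > 90.0

    def test_grouped_folds_keep_groups_together(self):
        X, y = self._data(signal=2.0, n=400)
        groups = np.repeat(np.arange(20), 20)
        out = evaluate_classifiers(
            X, y, {"logit": LogisticClassifier()}, groups=groups
        )
        assert out["auc"].iloc[0] > 85.0

    def test_too_few_cases_for_cv_rejected(self):
        X, y = self._data(n=30)
        with pytest.raises(ValueError, match="10-fold CV"):
            evaluate_classifiers(X, y, {"logit": LogisticClassifier()})

    def test_unknown_scheme_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="scheme"):
            evaluate_classifiers(
                X, y, {"logit": LogisticClassifier()}, scheme="loocv"
            )
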