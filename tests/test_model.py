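"""Logistic response-model tests.

Oracles: the closed-form 2x2 cross-product odds ratio, explicit
per-fold enumeration of leave-one-out predictions, parameter-recovery
and permutation-null simulations.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dwiresponse import (
    backward_stepwise,
    dichotomize,
    fit_logistic,
    loocv_metrics,
    model_roc,
    roc,
)
from dwiresponse.exceptions import ConfigurationError, InsufficientDataError


def _design_from_counts(n11, n10, n01, n00):
    """Binary predictor/outcome data with the given 2x2 counts
    (predictor=1&y=1, predictor=1&y=0, predictor=0&y=1, predictor=0&y=0)."""
    x = [1] * (n11 + n10) + [0] * (n01 + n00)
    y = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    return pd.DataFrame({"x": x}), np.asarray(y)


class TestDichotomize:
    def test_above_positive(self):
        out = dichotomize([0.50, 0.20], threshold=0.33, direction="above")
        assert out.tolist() == [1, 0]

    def test_boundary_goes_to_reference(self):
        # printed convention "> t vs. <= t": the boundary is reference
        assert dichotomize([0.33], 0.33, "above").tolist() == [0]

    def test_at_or_below_positive(self):
        out = dichotomize([-30.0, -20.0], threshold=-26.6, direction="at_or_below")
        assert out.tolist() == [1, 0]

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            dichotomize([1.0], np.nan, "above")
        with pytest.raises(ConfigurationError):
            dichotomize([1.0], 0.0, "sideways")


class TestFitLogistic:
    def test_binary_predictor_or_equals_cross_product(self):
        X, y = _design_from_counts(35, 18, 19, 72)
        m = fit_logistic(X, y)
        expected = (35 * 72) / (19 * 18)
        or_, lo, hi = m.odds_ratios["x"]
        assert or_ == pytest.approx(expected, rel=1e-6)
        assert lo < expected < hi
        assert not m.separation

    def test_null_predictor_ci_covers_one(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame({"x": rng.normal(size=2000)})
        y = rng.random(2000) < 0.4
        m = fit_logistic(X, y.astype(int))
        or_, lo, hi = m.odds_ratios["x"]
        assert lo < 1.0 < hi
        assert or_ == pytest.approx(1.0, abs=0.15)

    def test_coefficient_recovery_within_two_se(self):
        rng = np.random.default_rng(0)
        n = 5000
        x1 = rng.normal(size=n)
        x2 = rng.random(n) < 0.5
        eta = -0.5 + 0.8 * x1 + 1.2 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        m = fit_logistic(pd.DataFrame({"x1": x1, "x2": x2.astype(int)}), y.astype(int))
        for name, truth in (("x1", 0.8), ("x2", 1.2)):
            assert abs(m.coefficients[name] - truth) < 2 * m.std_errors[name]

    def test_separation_flagged_not_silent(self):
        X = pd.DataFrame({"x": [0, 1, 2, 3, 10, 11, 12, 13]})
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = fit_logistic(X, y)
        assert m.separation
        # predictions still land on the correct side
        assert (m.predict(X) >= 0.5).astype(int).tolist() == y.tolist()

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_logistic(pd.DataFrame({"x": [1, 2, 3, 4]}), [1, 1, 1, 1])


class TestBackwardStepwise:
    def test_single_significant_candidate_retained(self):
        X, y = _design_from_counts(35, 18, 19, 72)
        m, removed = backward_stepwise(X, y)
        assert m is not None and m.variables == ("x",)
        assert removed == []

    def test_noise_variable_removed(self):
        rng = np.random.default_rng(33)
        n = 1000
        signal = (rng.random(n) < 0.5).astype(int)
        noise = rng.normal(size=n)
        eta = -1.0 + 1.5 * signal
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        m, removed = backward_stepwise(
            pd.DataFrame({"signal": signal, "noise": noise}), y
        )
        assert removed == ["noise"]
        assert m.variables == ("signal",)

    def test_empty_candidates_no_model(self):
        m, removed = backward_stepwise(pd.DataFrame(index=range(5)), [0, 1, 0, 1, 0])
        assert m is None and removed == []

    def test_recovers_signal_set_with_redundant_correlates(self):
        # outcome depends on two biomarkers and a dichotomized imaging
        # change; two further imaging categories are noisy copies of the
        # informative one and carry no independent signal
        rng = np.random.default_rng(24)
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 200
            er_neg = (rng.random(n) < 0.37).astype(int)
            her2 = (rng.random(n) < 0.44).astype(int)
            adc = (rng.random(n) < 0.5).astype(int)
            flip = rng.random(n) < 0.15
            size = np.where(flip, 1 - adc, adc)
            flip = rng.random(n) < 0.15
            rer = np.where(flip, 1 - adc, adc)
            eta = -2.6 + 2.4 * er_neg + 1.7 * her2 + 2.2 * adc
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            if y.sum() < 10 or y.sum() > n - 10:
                continue
            X = pd.DataFrame(
                {"er_neg": er_neg, "her2": her2, "adc_cat": adc,
                 "size_cat": size, "rer_cat": rer}
            )
            m, _ = backward_stepwise(X, y)
            if m is not None and {"er_neg", "her2", "adc_cat"} <= set(m.variables):
                hits += 1
        assert hits / reps >= 0.90


class TestLoocv:
    def test_perfectly_separable_toy_data(self):
        x = np.r_[np.zeros(10), np.ones(10) * 10]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        cv = loocv_metrics(pd.DataFrame({"x": x}), y)
        assert cv.sensitivity == cv.specificity == cv.accuracy == 1.0

    def test_matches_hand_enumerated_folds(self):
        # n=8 toy table; every fold recomputed explicitly with the
        # reference maximum-likelihood fit
        X = pd.DataFrame({"x": [0.1, 0.4, 0.35, 0.8, 0.9, 0.3, 0.7, 0.2]})
        y = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        cv = loocv_metrics(X, y, cutoff=0.5)

        calls, labels = [], []
        for i in range(8):
            keep = [j for j in range(8) if j != i]
            Xt = sm.add_constant(X.iloc[keep].astype(float), has_constant="add")
            res = sm.Logit(y[keep], Xt).fit(disp=0)
            xi = sm.add_constant(X.iloc[[i]].astype(float), has_constant="add")
            xi = xi.reindex(columns=Xt.columns, fill_value=1.0)
            prob = float(np.asarray(res.predict(xi))[0])
            calls.append(int(prob >= 0.5))
            labels.append(y[i])
        calls, labels = np.asarray(calls), np.asarray(labels)
        tp = ((calls == 1) & (labels == 1)).sum()
        tn = ((calls == 0) & (labels == 0)).sum()
        assert cv.sensitivity == pytest.approx(tp / labels.sum())
        assert cv.specificity == pytest.approx(tn / (1 - labels).sum())
        assert cv.accuracy == pytest.approx((tp + tn) / 8)

    def test_accuracy_consistent_with_confusion_counts(self):
        rng = np.random.default_rng(25)
        X = pd.DataFrame({"x": rng.normal(size=40)})
        y = (rng.random(40) < 0.5).astype(int)
        cv = loocv_metrics(X, y)
        pred = cv.predictions
        acc = (pred["label"] == pred["call"]).mean()
        assert cv.accuracy == pytest.approx(acc)

    def test_label_permutation_null_accuracy(self):
        # with permuted labels the cross-validated classifier cannot
        # beat the majority-class rate by much
        rng = np.random.default_rng(26)
        n = 100
        x = rng.normal(size=n)
        y = np.r_[np.ones(40), np.zeros(60)].astype(int)
        accs = []
        for _ in range(10):
            yp = rng.permutation(y)
            accs.append(loocv_metrics(pd.DataFrame({"x": x}), yp).accuracy)
        assert abs(np.mean(accs) - 0.6) < 0.12


class TestModelRoc:
    def test_single_predictor_model_equals_predictor_roc(self):
        rng = np.random.default_rng(27)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-x))).astype(int)
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model_roc(m, pd.DataFrame({"x": x}), y).auc == pytest.approx(
            roc(x, y.astype(bool)).auc
        )

    def test_noise_predictors_auc_near_half(self):
        rng = np.random.default_rng(28)
        n = 2000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = (rng.random(n) < 0.4).astype(int)
        m = fit_logistic(X, y)
        assert model_roc(m, X, y).auc == pytest.approx(0.5, abs=0.05)

    def test_combined_model_beats_single_category(self):
        # qualitative analogue of the multivariate-model gain over the
        # single dichotomized imaging predictor
        rng = np.random.default_rng(29)
        wins = 0
        reps = 100
        for _ in range(reps):
            n = 150
            er = (rng.random(n) < 0.37).astype(int)
            her2 = (rng.random(n) < 0.44).astype(int)
            adc = (rng.random(n) < 0.5).astype(int)
            eta = -2.4 + 2.4 * er + 1.7 * her2 + 2.2 * adc
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
            if len(set(y)) < 2:
                continue
            X = pd.DataFrame({"er": er, "her2": her2, "adc": adc})
            m = fit_logistic(X, y)
            full = model_roc(m, X, y).auc
            single = roc(adc.astype(float), y.astype(bool)).auc
            wins += full > single
        assert wins / reps >= 0.90
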