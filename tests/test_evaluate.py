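"""Metric closed forms, bootstrap behaviour, NaN rescue, baseline comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

import microvoe as mv
from microvoe.errors import ConfigurationError
from microvoe.evaluate import accuracy


class TestRSquared:
    def test_closed_forms(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert mv.r_squared(y, y) == pytest.approx(1.0)
        assert mv.r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)
        assert mv.r_squared([0.0, 1.0], [1.0, 0.0]) == pytest.approx(-3.0)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            mv.r_squared([1.0, 1.0], [1.0, 2.0])


class TestRocAuc:
    def test_closed_forms(self):
        assert mv.roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)
        assert mv.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(1.0)
        assert mv.roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(0.0)

    def test_matches_sklearn_with_ties(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 5, 30).astype(float)  # heavy ties
            assert mv.roc_auc(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            y = rng.integers(0, 2, 25)
            if y.min() == y.max():
                continue
            s = rng.normal(0, 1, 25)
            assert mv.roc_auc(y, s) + mv.roc_auc(y, -s) == pytest.approx(1.0)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            mv.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestMeanClassAccuracy:
    def test_closed_forms(self):
        y = np.array(["A"] * 100 + ["B"] * 20)
        yhat = np.array(["A"] * 90 + ["B"] * 10 + ["A"] * 10 + ["B"] * 10)
        assert mv.mean_class_accuracy(y, yhat) == pytest.approx(0.7)
        assert mv.mean_class_accuracy(y, y) == pytest.approx(1.0)
        majority = np.full_like(y, "A")
        assert mv.mean_class_accuracy(y, majority) == pytest.approx(0.5)

    def test_uniform_random_predictor_near_one_over_k(self):
        rng = np.random.default_rng(2)
        k, n, reps = 4, 400, 30
        vals = []
        classes = np.array(list("abcd"))
        y = np.repeat(classes, n // k)
        for _ in range(reps):
            vals.append(mv.mean_class_accuracy(y, rng.choice(classes, n)))
        mc_sd = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - 1 / k) < 3 * max(mc_sd, 1e-3)

    def test_unknown_predicted_label_counts_wrong(self):
        y = np.array(["a", "a", "b", "b"])
        yhat = np.array(["a", "zzz", "b", "b"])
        assert mv.mean_class_accuracy(y, yhat) == pytest.approx(0.75)


class TestBootstrap:
    def test_perfect_predictions_zero_sd(self):
        y = np.array(["a", "b", "a", "b"])
        res = mv.bootstrap_ci(y, y, accuracy, B=200, seed=0)
        assert res.point == 1.0 and res.sd == 0.0

    def test_matches_exhaustive_enumeration(self):
        """n=4 accuracy: all 4^4 = 256 resamples are equally likely, so the
        exact bootstrap SD is computable by enumeration."""
        y = np.array([1, 1, 0, 0])
        yhat = np.array([1, 0, 0, 0])  # accuracy 0.75
        vals = [
            accuracy(y[list(idx)], yhat[list(idx)])
            for idx in itertools.product(range(4), repeat=4)
        ]
        exact_sd = np.std(vals)  # population SD over the 256 outcomes
        res = mv.bootstrap_ci(y, yhat, accuracy, B=100_000, seed=1)
        assert res.point == pytest.approx(0.75)
        assert abs(res.sd - exact_sd) < 0.01

    def test_degenerate_resamples_redrawn(self):
        y = np.array([0, 0, 0, 1])  # single-class draws are common
        s = np.array([0.1, 0.2, 0.3, 0.9])
        res = mv.bootstrap_ci(y, s, mv.roc_auc, B=300, seed=2)
        assert res.redraws > 0
        assert np.isfinite(res.sd)

    def test_row_order_invariant(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 50)
        yhat = y + rng.normal(0, 0.5, 50)
        r1 = mv.bootstrap_ci(y, yhat, mv.r_squared, B=500, seed=4)
        perm = rng.permutation(50)
        r2 = mv.bootstrap_ci(y[perm], yhat[perm], mv.r_squared, B=500, seed=4)
        assert r1.point == pytest.approx(r2.point)
        assert abs(r1.sd - r2.sd) < 0.02

    def test_undefined_on_full_set_error(self):
        with pytest.raises(ValueError):
            mv.bootstrap_ci([1, 1], [0.5, 0.6], mv.roc_auc, B=10, seed=0)


class TestRescue:
    def test_poison_sample_excluded(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])

        def predict(Xq):
            # 'b' poisons any batch it belongs to
            if "b" in Xq.index:
                return np.full(len(Xq), np.nan)
            return Xq["x"].to_numpy()

        preds, excluded = mv.rescue_nan_predictions(predict, X)
        assert excluded == ["b"]
        assert preds[0] == 1.0 and preds[2] == 3.0

    def test_clean_batch_identity(self):
        X = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        calls = []

        def predict(Xq):
            calls.append(len(Xq))
            return Xq["x"].to_numpy()

        preds, excluded = mv.rescue_nan_predictions(predict, X)
        assert excluded == [] and calls == [2]  # rescue not invoked


class TestCompareToBaseline:
    def test_significant_difference(self):
        e = mv.ModelResult("age", "cag+demographics", "rf", "r_squared", 0.625, 0.021)
        b = mv.ModelResult("age", "demographics", "rf2", "r_squared", 0.120, 0.013)
        delta, sig = mv.compare_to_baseline(e, b)
        assert delta == pytest.approx(0.505)
        assert sig

    def test_overlapping_intervals_not_significant(self):
        e = mv.ModelResult("antibiotics", "gene+demographics", "elastic_net", "roc_auc", 0.796, 0.013)
        b = mv.ModelResult("antibiotics", "demographics", "rf2", "roc_auc", 0.786, 0.013)
        delta, sig = mv.compare_to_baseline(e, b)
        assert delta == pytest.approx(0.010)
        assert not sig

    def test_identical_results_not_significant(self):
        e = mv.ModelResult("sex", "cag", "rf", "roc_auc", 0.6, 0.02)
        delta, sig = mv.compare_to_baseline(e, e)
        assert delta == 0.0 and not sig

    def test_metric_mismatch_error(self):
        e = mv.ModelResult("sex", "cag", "rf", "roc_auc", 0.6, 0.02)
        b = mv.ModelResult("sex", "demographics", "rf", "accuracy", 0.6, 0.02)
        with pytest.raises(ConfigurationError):
            mv.compare_to_baseline(e, b)


class TestPCA:
    def test_perfectly_correlated_features(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"a": x, "b": 2 * x})
        _, ratios = mv.pca_overview(table)
        assert ratios[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one_and_constant_dropped(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.normal(0, 1, (30, 4)))
        table["const"] = 1.0
        with pytest.warns(UserWarning):
            scores, ratios = mv.pca_overview(table)
        assert ratios.sum() == pytest.approx(1.0, abs=1e-9)
        assert scores.shape[0] == 30
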