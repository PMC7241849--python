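"""Tuner behaviour against deterministic oracle losses; estimator adapters."""

import numpy as np
import pandas as pd
import pytest

import microvoe as mv
from microvoe.errors import ConfigurationError, EvaluationFailure
from microvoe.models import (
    HyperSpec,
    PseudoGradientTuner,
    coarse_grid,
    decide_gbm2_escalation,
    default_config,
    fit_predict,
    make_inner_evaluator,
    rf2_config,
    tune,
)


class TestCoarseGrid:
    def test_arithmetic_sequence(self):
        grid = coarse_grid([HyperSpec("h", 0, 4, 2)])
        assert [g["h"] for g in grid] == [0, 2, 4]

    def test_pow2_transform(self):
        grid = coarse_grid([HyperSpec("h", 0, 3, 1, "pow2")])
        assert [g["h"] for g in grid] == [1, 2, 4, 8]

    def test_product_size(self):
        grid = coarse_grid([HyperSpec("a", 0, 2, 1), HyperSpec("b", 0, 3, 1)])
        assert len(grid) == 12


def quad_score(center):
    """Deterministic unimodal score: maximized at ``center``."""
    return lambda values: -((values["h"] - center) ** 2)


class TestPseudoGradient:
    def test_extends_to_optimum_outside_grid(self):
        spec = HyperSpec("h", 0, 4, 1, hard_lo=-20, hard_hi=20, n_fine=5)
        best, trace = tune(quad_score(7), [spec])
        assert best["h"] == pytest.approx(7, abs=0.51)
        raws = {e.raw["h"] for e in trace.entries}
        assert {5, 6, 7, 8} <= raws  # walked past the boundary until interior

    def test_interior_optimum_no_extension(self):
        spec = HyperSpec("h", 0, 4, 1, hard_lo=-20, hard_hi=20)
        _, trace = tune(quad_score(2), [spec])
        assert not any(e.stage == "pgd" for e in trace.entries)

    def test_failure_shrinks_limit(self):
        spec = HyperSpec("h", 0, 4, 1, hard_lo=-20, hard_hi=20)

        def evaluate(values):
            if values["h"] >= 6:
                raise EvaluationFailure("injected memory error")
            return values["h"]  # increasing: pushes the upper boundary

        best, trace = tune(evaluate, [spec])
        assert best["h"] == 5
        assert trace.limits["h"]["hi"] == 5
        assert trace.limits["h"]["reasons"]

    def test_all_failures_error_carries_trace(self):
        spec = HyperSpec("h", 0, 2, 1)

        def evaluate(values):
            raise EvaluationFailure("nope")

        with pytest.raises(EvaluationFailure):
            tuner = PseudoGradientTuner(evaluate, [spec])
            tuner.run_coarse()
            tuner.trace.best()

    def test_trace_completeness_and_reproducible_best(self):
        spec = HyperSpec("h", 0, 4, 1, hard_lo=-20, hard_hi=20, n_fine=4)
        best, trace = tune(quad_score(7), [spec])
        keys = [tuple(sorted(e.raw.items())) for e in trace.entries]
        assert len(keys) == len(set(keys))  # every combination exactly once
        rescored = max(trace.ok_entries(), key=lambda e: e.score)
        assert rescored.values == best


class TestFineTune:
    def test_tie_spans_extrema(self):
        spec = HyperSpec("h", 0, 4, 1, n_fine=5)

        def evaluate(values):
            return 1.0 if values["h"] in (2, 4) else 0.0

        _, trace = tune(evaluate, [spec])
        fine = [e.raw["h"] for e in trace.entries if e.stage == "fine"]
        assert fine and all(2 <= v <= 4 for v in fine)

    def test_unique_best_spans_second_best_direction(self):
        # best 7, second best 8 (stride 1): fine grid lives in (6.5, 8)
        spec = HyperSpec("h", 0, 8, 1, n_fine=5)

        def evaluate(values):
            h = values["h"]
            return {7: 0.0, 8: -1.0}.get(h, -2.0 - 0.1 * abs(h - 7))

        _, trace = tune(evaluate, [spec])
        fine = [e.raw["h"] for e in trace.entries if e.stage == "fine"]
        assert fine and all(6.5 < v < 8 for v in fine)

    @pytest.mark.parametrize("dims", [1, 2])
    def test_oracle_equivalence_random_surfaces(self, dims):
        """Tuner loss within one fine-grid step of exhaustive search."""
        rng = np.random.default_rng(42)
        n_surfaces = 50 if dims == 1 else 25
        for _ in range(n_surfaces):
            centers = rng.uniform(-5, 12, size=dims)
            scales = rng.uniform(0.2, 3.0, size=dims)
            hard_lo, hard_hi = -10.0, 15.0
            specs = [
                HyperSpec(f"h{d}", 0, 4, 1, hard_lo=hard_lo, hard_hi=hard_hi, n_fine=5)
                for d in range(dims)
            ]

            def loss(values):
                return sum(
                    scales[d] * (values[f"h{d}"] - centers[d]) ** 2 for d in range(dims)
                )

            best, _ = tune(lambda v: -loss(v), specs)
            delta = 1.0 / 6.0  # stride / (n_fine + 1)
            axis = np.arange(hard_lo, hard_hi + delta / 2, delta)
            exh_best = sum(
                scales[d] * (axis[np.argmin(scales[d] * (axis - centers[d]) ** 2)] - centers[d]) ** 2
                for d in range(dims)
            )
            opt = [float(np.clip(centers[d], hard_lo, hard_hi)) for d in range(dims)]
            tol = sum(
                max(
                    scales[d] * (opt[d] + s * delta - centers[d]) ** 2
                    - scales[d] * (opt[d] - centers[d]) ** 2
                    for s in (-1, 1)
                )
                for d in range(dims)
            )
            assert loss(best) <= exh_best + tol + 1e-9


class TestGuard:
    def test_rejected_candidate_keeps_incumbent(self):
        spec = HyperSpec("h", 0, 4, 1, hard_lo=0, hard_hi=4)

        def evaluate(values):
            h = values["h"]
            return 10.0 if h == 4 else -((h - 1) ** 2)

        best, trace = tune(evaluate, [spec], guard=lambda v: v["h"] != 4)
        assert best["h"] == 1  # the NaN-predicting "winner" never replaces it
        assert trace.guard_rejections and trace.guard_rejections[0]["values"]["h"] == 4

    def test_first_rejection_without_incumbent_continues(self):
        spec = HyperSpec("h", 0, 2, 1, hard_lo=0, hard_hi=2)

        def evaluate(values):
            return 1.0 if values["h"] == 0 else 0.5

        best, trace = tune(evaluate, [spec], guard=lambda v: v["h"] != 0)
        assert best["h"] == 1  # h=0 (best score) rejected, search continued
        assert len(trace.guard_rejections) == 1

    def test_all_finite_accepts(self):
        spec = HyperSpec("h", 0, 2, 1, hard_lo=0, hard_hi=2)
        best, trace = tune(lambda v: v["h"], [spec], guard=lambda v: True)
        assert best["h"] == 2
        assert not trace.guard_rejections


class TestGBM2Escalation:
    def test_best_in_tail_with_improvement_doubles(self):
        perf = np.concatenate([np.linspace(0, 0.8, 900), np.linspace(0.8, 0.9, 100)])
        assert decide_gbm2_escalation(perf)

    def test_best_mid_run_stops(self):
        perf = np.concatenate([np.linspace(0, 1, 500), np.linspace(1, 0.5, 500)])
        assert not decide_gbm2_escalation(perf)

    def test_tiny_improvement_stops(self):
        # best in last decile but only 0.05% mean improvement over the decile before
        perf = np.concatenate([np.linspace(0, 1.0, 800), np.full(100, 1.0), np.full(100, 1.0005)])
        assert not decide_gbm2_escalation(perf)


class TestRF2Config:
    def test_regression_sampsize(self):
        plan = rf2_config("regression", n_rows=1000, n_features=50)
        assert plan.sampsize == 632
        assert plan.n_estimators == 1001

    def test_classification_min_class(self):
        plan = rf2_config("binary", n_rows=1000, class_counts={"a": 700, "b": 300}, n_features=5)
        assert plan.per_class_sampsize == 300

    def test_mtry_ladder_geometric(self):
        plan = rf2_config("regression", n_rows=100, n_features=10)
        ladder = plan.mtry_candidates
        assert ladder[0] == 10 and ladder[-1] == 1
        assert all(a > b for a, b in zip(ladder, ladder[1:]))

    def test_empty_class_error(self):
        with pytest.raises(ConfigurationError):
            rf2_config("binary", n_rows=10, class_counts={"a": 5, "b": 0}, n_features=2)


class TestFitPredict:
    def test_elastic_net_ridge_limit_matches_ols(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (60, 3)), columns=list("abc"))
        y = pd.Series(X @ np.array([1.0, -2.0, 0.5]) + 0.3 + 0.01 * rng.normal(0, 1, 60))
        cfg = default_config("elastic_net", "regression")
        fp = fit_predict(cfg, {"lambda": 1e-12, "l1_ratio": 0.0}, X, y, None, X)
        A = np.column_stack([np.ones(60), X.to_numpy()])
        beta = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fp.predictions, A @ beta, atol=1e-6)

    def test_knn1_memorizes_training_labels(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (20, 4)))
        y = pd.Series(rng.choice(["a", "b"], 20))
        cfg = default_config("knn", "binary")
        fp = fit_predict(cfg, {"k": 1}, X, y, None, X)
        assert list(fp.predictions) == list(y.astype(str))

    def test_failure_is_structured_not_raised(self):
        X = pd.DataFrame([[np.nan, 1.0], [2.0, 3.0]])
        y = pd.Series([0.1, 0.2])
        cfg = default_config("svm_linear", "regression")
        fp = fit_predict(cfg, cfg.defaults, X, y, None, X)
        assert fp.failure is not None and fp.predictions is None

    def test_naive_bayes_regression_incompatible(self):
        with pytest.raises(ConfigurationError):
            default_config("naive_bayes", "regression")

    def test_binary_scores_are_positive_class_probability(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(0, 1, (60, 2)))
        y = pd.Series(np.where(X.iloc[:, 0] > 0, "yes", "no"))
        cfg = default_config("rf", "binary")
        fp = fit_predict(cfg, {"max_features": 0.5}, X, y, None, X, seed=0)
        assert fp.scores is not None
        assert ((fp.scores >= 0) & (fp.scores <= 1)).all()
        from microvoe.evaluate import roc_auc

        assert roc_auc(y.to_numpy(), fp.scores) > 0.9


class TestInnerEvaluator:
    def test_mean_over_inner_folds(self):
        rng = np.random.default_rng(3)
        n = 60
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), index=[f"s{i}" for i in range(n)])
        y = pd.Series(X.iloc[:, 0] * 2 + rng.normal(0, 0.1, n), index=X.index)
        inner = pd.Series([i % 3 for i in range(n)], index=X.index)
        cfg = default_config("elastic_net", "regression")
        evaluate = make_inner_evaluator(cfg, X, y, None, inner)
        score = evaluate({"lambda": 1e-6, "l1_ratio": 0.5})
        assert 0.9 < score <= 1.0
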