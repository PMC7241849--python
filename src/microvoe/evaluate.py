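"""Pooled out-of-fold evaluation: metrics, bootstrap SDs and comparisons.

Headline performance is computed on the concatenation of every outer fold's
test predictions (no sample is ever scored by a model whose training set
contained its subject).  Uncertainty comes from a nonparametric bootstrap of
the pooled prediction set: the metric is recomputed on resamples drawn with
replacement and its SD across resamples reported as the ``+-`` value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSet",
    "ModelResult",
    "BootstrapResult",
    "r_squared",
    "roc_auc",
    "accuracy",
    "mean_class_accuracy",
    "metric_for_task",
    "rescue_nan_predictions",
    "bootstrap_ci",
    "compare_to_baseline",
    "pca_overview",
]


def r_squared(truth: np.ndarray, predictions: np.ndarray) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Computed out of sample it can be negative (the model is worse than
    predicting the mean of the truth).
    """
    y = np.asarray(truth, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if y.size < 2:
        raise ValueError("r_squared needs at least 2 observations")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("truth has zero variance")
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def roc_auc(truth: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formula.

    Equals the probability that a random positive outranks a random negative,
    ties counting one half.  ``truth`` must contain exactly two classes; the
    positive class is 1 (or the lexicographically larger label).
    """
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"roc_auc needs exactly 2 classes, got {len(classes)}")
    pos = y == classes[-1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(s)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def accuracy(truth: np.ndarray, predicted: np.ndarray) -> float:
    y = np.asarray(truth, dtype=object)
    yhat = np.asarray(predicted, dtype=object)
    if y.size == 0:
        raise ValueError("empty prediction set")
    return float((y == yhat).mean())


def mean_class_accuracy(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Unweighted mean of per-class recall (robust to class imbalance).

    Predicted labels outside the truth alphabet count as errors (warned).
    """
    y = np.asarray(truth, dtype=object)
    yhat = np.asarray(predicted, dtype=object)
    classes = np.unique(y)
    if y.size == 0:
        raise ValueError("empty prediction set")
    unknown = set(np.unique(yhat)) - set(classes)
    if unknown:
        logger.warning("predicted labels outside truth alphabet: %s", sorted(unknown))
    recalls = [float((yhat[y == c] == c).mean()) for c in classes]
    return float(np.mean(recalls))


def metric_for_task(task: str) -> tuple[str, Callable]:
    """Headline metric per task: R2 / ROC AUC / mean class accuracy."""
    if task == "regression":
        return "r_squared", r_squared
    if task == "binary":
        return "roc_auc", roc_auc
    if task == "multiclass":
        return "mean_class_accuracy", mean_class_accuracy
    raise ConfigurationError(f"unknown task {task!r}")


@dataclass
class PredictionSet:
    """Pooled out-of-fold predictions for one (phenotype, data type, model)."""

    frame: pd.DataFrame  # index sample_id; columns: fold, truth, prediction[, score]
    task: str
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (sample, reason)

    def metric_inputs(self) -> tuple[np.ndarray, np.ndarray]:
        truth = self.frame["truth"].to_numpy()
        if self.task == "binary" and "score" in self.frame.columns and self.frame["score"].notna().all():
            return truth, self.frame["score"].to_numpy(float)
        return truth, self.frame["prediction"].to_numpy()

    @property
    def has_scores(self) -> bool:
        return "score" in self.frame.columns and self.frame["score"].notna().all()


@dataclass
class ModelResult:
    """Point estimate, bootstrap SD, importances and provenance for one cell."""

    phenotype: str
    data_type: str
    estimator: str
    metric_name: str
    point: float
    sd: float
    importances: pd.Series | None = None
    trace: object = None
    predictions: PredictionSet | None = None
    best_hypers: dict | None = None
    failure: str | None = None


@dataclass
class BootstrapResult:
    point: float
    sd: float
    redraws: int = 0


def rescue_nan_predictions(
    predict_fn: Callable[[pd.DataFrame], np.ndarray],
    X_test: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Recover from batch predictions containing NaN.

    If the batch prediction holds NaN, every sample is re-predicted
    individually ("poison" samples can make a whole batch fail); samples that
    are still NaN are excluded and their ids returned.
    """
    batch = np.asarray(predict_fn(X_test))
    bad = pd.isna(batch)
    if not bad.any():
        return batch, []
    out = np.array(batch, dtype=object)
    excluded: list[str] = []
    for i in range(len(X_test)):
        single = np.asarray(predict_fn(X_test.iloc[[i]]))[0]
        out[i] = single
        if pd.isna(single):
            excluded.append(str(X_test.index[i]))
    if len(excluded) == len(X_test):
        logger.error("rescue failed: every sample predicted NaN")
    elif excluded:
        logger.warning("excluded %d samples with NaN predictions", len(excluded))
    return out, excluded


def bootstrap_ci(
    truth: Sequence,
    predictions: Sequence,
    metric: Callable[[np.ndarray, np.ndarray], float],
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 100_000,
) -> BootstrapResult:
    """Point estimate plus bootstrap SD of a pooled-prediction metric.

    ``B`` resamples of size n with replacement; resamples on which the metric
    is undefined (e.g. a single class drawn) are redrawn, with the redraw
    count reported.
    """
    y = np.asarray(truth)
    yhat = np.asarray(predictions)
    if y.size == 0:
        raise ValueError("empty prediction set")
    point = metric(y, yhat)  # raises if undefined on the full set
    rng = np.random.default_rng(seed)
    n = y.size
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                values[b] = metric(y[idx], yhat[idx])
                break
            except ValueError:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError("bootstrap metric undefined on too many resamples")
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    return BootstrapResult(point=float(point), sd=float(values.std(ddof=1)), redraws=redraws)


def compare_to_baseline(
    experimental: ModelResult, baseline: ModelResult
) -> tuple[float, bool]:
    """Delta of point estimates and a +-1-SD non-overlap significance flag."""
    if experimental.phenotype != baseline.phenotype:
        raise ConfigurationError("comparing results for different phenotypes")
    if experimental.metric_name != baseline.metric_name:
        raise ConfigurationError(
            f"metric mismatch: {experimental.metric_name} vs {baseline.metric_name}"
        )
    delta = experimental.point - baseline.point
    lo_e, hi_e = experimental.point - experimental.sd, experimental.point + experimental.sd
    lo_b, hi_b = baseline.point - baseline.sd, baseline.point + baseline.sd
    significant = (lo_e > hi_b) or (lo_b > hi_e)
    return float(delta), bool(significant)


def pca_overview(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA on unit-variance-scaled columns; explained fractions sum to one.

    Constant columns are dropped with a warning.  Returns (component scores,
    explained-variance ratios).
    """
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant column(s) before PCA")
    keep = sd > 0
    if keep.sum() < 2:
        raise ConfigurationError("PCA needs at least 2 non-constant features")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(Xs.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xs)
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return pd.DataFrame(scores, index=table.index, columns=cols), pca.explained_variance_ratio_
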