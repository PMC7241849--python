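"""Estimator registry and the three-stage pseudo-gradient hyperparameter tuner.

The benchmark compares 8 algorithm families in 11 configurations: two elastic
net implementations, two random forests, two gradient boosted machines, three
SVM kernels (linear, degree-2 polynomial, radial), K-nearest neighbours and
Gaussian naive Bayes.  Each is exposed through one uniform contract
(:func:`fit_predict`) so the tuner and the pipeline never touch estimator
internals.

Tuning proceeds in three stages on each hyperparameter's *raw* axis (a
monotone transform maps raw grid points to actual values, e.g. ``2**x``):

1. **coarse grid** — Cartesian product of ``lo, lo+stride, ..., hi``;
2. **pseudo-gradient exploration** — while the best value of any
   hyperparameter sits on the boundary of the explored range (and that
   boundary is not a hard limit), the range is extended one stride in that
   direction, holding the other hyperparameters at values drawn from the
   best-scoring combinations; evaluation failures shrink the explorable
   limit of the offending hyperparameter;
3. **fine tuning** — a finer grid around the best value: between the tied
   best values when there are several, otherwise between the best value and
   the second-best value on one side and half a stride on the other.

A candidate combination only replaces the incumbent best if a guard confirms
the fitted model can produce non-NaN predictions on its own training rows.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, LogisticRegression, SGDClassifier, SGDRegressor
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import ConfigurationError, EvaluationFailure
from .evaluate import accuracy, mean_class_accuracy, r_squared, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "FAMILIES",
    "HyperSpec",
    "EstimatorConfig",
    "TunerTrace",
    "TraceEntry",
    "FitPrediction",
    "RF2Plan",
    "coarse_grid",
    "PseudoGradientTuner",
    "tune",
    "fit_predict",
    "default_config",
    "rf2_config",
    "decide_gbm2_escalation",
    "gbm2_final_n_trees",
    "extract_importances",
    "make_inner_evaluator",
    "make_train_guard",
]

FAMILIES = [
    "elastic_net",
    "elastic_net2",
    "rf",
    "rf2",
    "gbm",
    "gbm2",
    "svm_linear",
    "svm_poly2",
    "svm_radial",
    "knn",
    "naive_bayes",
]

TRANSFORMS: dict[str, Callable[[float], float]] = {
    "identity": lambda x: x,
    "pow2": lambda x: 2.0**x,
    "pow10": lambda x: 10.0**x,
}

_ROUND = 6  # decimals at which two scores count as "equal performance"


@dataclass(frozen=True)
class HyperSpec:
    """One tunable hyperparameter: a raw grid plus a monotone transform."""

    name: str
    lo: float
    hi: float
    stride: float
    transform: str | Callable[[float], float] = "identity"
    hard_lo: float = -np.inf
    hard_hi: float = np.inf
    n_fine: int = 3
    integer: bool = False  # round the transformed value to an int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ConfigurationError(f"{self.name}: lo > hi")
        if self.stride <= 0:
            raise ConfigurationError(f"{self.name}: stride must be positive")
        if self.n_fine < 2:
            raise ConfigurationError(f"{self.name}: n_fine must be >= 2")

    def apply(self, raw: float) -> float:
        fn = TRANSFORMS[self.transform] if isinstance(self.transform, str) else self.transform
        v = fn(raw)
        return int(round(v)) if self.integer else float(v)

    def raw_grid(self) -> list[float]:
        n = int(round((self.hi - self.lo) / self.stride))
        vals = [self.lo + i * self.stride for i in range(n + 1)]
        if vals[-1] < self.hi - 1e-9 * self.stride:
            vals.append(self.hi)
        return [round(v, 10) for v in vals]


def coarse_grid(specs: Sequence[HyperSpec]) -> list[dict[str, float]]:
    """Cartesian product of each spec's transformed grid values."""
    if not specs:
        raise ConfigurationError("coarse_grid needs at least one hyperparameter spec")
    axes = [[s.apply(r) for r in s.raw_grid()] for s in specs]
    return [dict(zip([s.name for s in specs], combo)) for combo in itertools.product(*axes)]


@dataclass
class TraceEntry:
    raw: dict[str, float]
    values: dict[str, float]
    score: float | None
    failure: str | None
    stage: str
    guard_failed: bool = False


@dataclass
class TunerTrace:
    """Complete record of a tuning run (every combination exactly once)."""

    entries: list[TraceEntry] = field(default_factory=list)
    limits: dict[str, dict] = field(default_factory=dict)
    best_per_stage: dict[str, dict | None] = field(default_factory=dict)
    guard_rejections: list[dict] = field(default_factory=list)

    def ok_entries(self) -> list[TraceEntry]:
        return [e for e in self.entries if e.score is not None and not e.guard_failed]

    def best(self) -> TraceEntry:
        ok = self.ok_entries()
        if not ok:
            raise EvaluationFailure("every hyperparameter combination failed")
        return max(ok, key=lambda e: (e.score, tuple(sorted(e.raw.items()))))

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "values": e.values,
                    "score": e.score,
                    "failure": e.failure,
                    "stage": e.stage,
                    "guard_failed": e.guard_failed,
                }
                for e in self.entries
            ],
            "limits": self.limits,
            "best_per_stage": self.best_per_stage,
            "guard_rejections": self.guard_rejections,
        }


class PseudoGradientTuner:
    """Grid-extend-refine hyperparameter search over a score to maximize.

    ``evaluate`` maps a dict of transformed hyperparameter values to a score
    (higher is better) and raises :class:`EvaluationFailure` when a
    combination cannot be evaluated.  ``guard`` (optional) vetoes candidate
    best combinations that cannot reproduce predictions on the training set.
    """

    def __init__(
        self,
        evaluate: Callable[[Mapping[str, float]], float],
        specs: Sequence[HyperSpec],
        guard: Callable[[Mapping[str, float]], bool] | None = None,
        max_extensions: int = 200,
    ) -> None:
        self.evaluate = evaluate
        self.specs = list(specs)
        self.guard = guard
        self.max_extensions = max_extensions
        self.trace = TunerTrace(
            limits={
                s.name: {"lo": s.hard_lo, "hi": s.hard_hi, "reasons": []} for s in self.specs
            }
        )
        self._cache: dict[tuple, TraceEntry] = {}
        self._incumbent: TraceEntry | None = None

    # -- internals ---------------------------------------------------------
    def _eval(self, raw: dict[str, float], stage: str) -> TraceEntry:
        key = tuple(sorted((k, round(v, 10)) for k, v in raw.items()))
        if key in self._cache:
            return self._cache[key]
        values = {s.name: s.apply(raw[s.name]) for s in self.specs}
        try:
            score = float(self.evaluate(values))
            entry = TraceEntry(dict(raw), values, round(score, 12), None, stage)
        except EvaluationFailure as exc:
            entry = TraceEntry(dict(raw), values, None, str(exc), stage)
        self._cache[key] = entry
        self.trace.entries.append(entry)
        if entry.score is not None:
            self._maybe_promote(entry)
        return entry

    def _maybe_promote(self, entry: TraceEntry) -> None:
        if self._incumbent is not None and entry.score <= self._incumbent.score:
            return
        if self.guard is not None and not self.guard(entry.values):
            entry.guard_failed = True
            self.trace.guard_rejections.append(
                {"values": entry.values, "score": entry.score, "stage": entry.stage}
            )
            logger.info("guard rejected candidate %s (score %.4f)", entry.values, entry.score)
            return
        self._incumbent = entry

    def _best_entries(self) -> list[TraceEntry]:
        ok = self.trace.ok_entries()
        if not ok:
            raise EvaluationFailure("every hyperparameter combination failed")
        best = max(round(e.score, _ROUND) for e in ok)
        return [e for e in ok if round(e.score, _ROUND) == best]

    def _shrink(self, name: str, direction: int, boundary: float, reason: str) -> None:
        lim = self.trace.limits[name]
        if direction > 0:
            lim["hi"] = min(lim["hi"], boundary)
        else:
            lim["lo"] = max(lim["lo"], boundary)
        lim["reasons"].append(reason)

    # -- stages ------------------------------------------------------------
    def run_coarse(self) -> None:
        for combo in itertools.product(*[s.raw_grid() for s in self.specs]):
            self._eval(dict(zip([s.name for s in self.specs], combo)), "coarse")
        self.trace.best_per_stage["coarse"] = dict(self.trace.best().values)

    def run_pseudo_gradient(self) -> None:
        extensions = 0
        while extensions < self.max_extensions:
            changed = False
            for spec in self.specs:
                name = spec.name
                explored = sorted({e.raw[name] for e in self.trace.entries})
                best_vals = {e.raw[name] for e in self._best_entries()}
                lim = self.trace.limits[name]
                for direction in (-1, 1):
                    boundary = explored[0] if direction < 0 else explored[-1]
                    if boundary not in best_vals:
                        continue
                    candidate = round(boundary + direction * spec.stride, 10)
                    if direction < 0 and candidate < lim["lo"] - 1e-9:
                        continue
                    if direction > 0 and candidate > lim["hi"] + 1e-9:
                        continue
                    partners = []
                    seen = set()
                    for e in self._best_entries():
                        others = tuple(
                            sorted((k, v) for k, v in e.raw.items() if k != name)
                        )
                        if others not in seen:
                            seen.add(others)
                            partners.append(dict(others))
                    for p in partners:
                        entry = self._eval({**p, name: candidate}, "pgd")
                        if entry.failure is not None:
                            self._shrink(
                                name, direction, boundary, f"failure at {candidate}: {entry.failure}"
                            )
                    changed = True
                    extensions += 1
            if not changed:
                break
        self.trace.best_per_stage["pgd"] = dict(self.trace.best().values)

    def _fine_values(self, spec: HyperSpec) -> list[float]:
        name = spec.name
        best_entries = self._best_entries()
        vs = sorted({e.raw[name] for e in best_entries})
        if len(vs) >= 2:
            fine = np.linspace(vs[0], vs[-1], spec.n_fine)
        else:
            v = vs[0]
            ok = self.trace.ok_entries()
            best_r = max(round(e.score, _ROUND) for e in ok)
            below = [e for e in ok if round(e.score, _ROUND) < best_r]
            v2 = None
            if below:
                second_r = max(round(e.score, _ROUND) for e in below)
                cand = sorted(
                    {e.raw[name] for e in below if round(e.score, _ROUND) == second_r}
                )
                distinct = [c for c in cand if abs(c - v) > 1e-12]
                if distinct:
                    v2 = min(distinct, key=lambda c: abs(c - v))
            if v2 is None:
                lo, hi = v - spec.stride / 2, v + spec.stride / 2
            elif v2 > v:
                lo, hi = v - spec.stride / 2, v2
            else:
                lo, hi = v2, v + spec.stride / 2
            fine = np.linspace(lo, hi, spec.n_fine + 2)[1:-1]
        lim = self.trace.limits[name]
        fine = np.clip(fine, lim["lo"], lim["hi"])
        return sorted({round(float(f), 10) for f in fine})

    def run_fine(self, max_combos: int = 1000) -> None:
        if not self.specs:
            return
        axes = {s.name: self._fine_values(s) for s in self.specs}
        base = self.trace.best().raw
        total = int(np.prod([len(a) for a in axes.values()]))
        if total <= max_combos:
            combos = [
                dict(zip(axes.keys(), vals)) for vals in itertools.product(*axes.values())
            ]
        else:  # coordinate-wise fallback around the incumbent best
            combos = []
            for name, vals in axes.items():
                for v in vals:
                    combos.append({**base, name: v})
        for raw in combos:
            self._eval(raw, "fine")
        self.trace.best_per_stage["fine"] = dict(self.trace.best().values)

    def run(self) -> tuple[dict[str, float], TunerTrace]:
        if not self.specs:
            try:
                score = float(self.evaluate({}))
                self.trace.entries.append(TraceEntry({}, {}, score, None, "coarse"))
            except EvaluationFailure as exc:
                self.trace.entries.append(TraceEntry({}, {}, None, str(exc), "coarse"))
                raise
            return {}, self.trace
        self.run_coarse()
        self.run_pseudo_gradient()
        self.run_fine()
        best = self._incumbent if self._incumbent is not None else self.trace.best()
        return dict(best.values), self.trace


def tune(
    evaluate: Callable[[Mapping[str, float]], float],
    specs: Sequence[HyperSpec],
    guard: Callable[[Mapping[str, float]], bool] | None = None,
    stages: str = "full",
) -> tuple[dict[str, float], TunerTrace]:
    """Run the tuner: ``stages`` = 'full' (all three) or 'coarse' (grid only)."""
    tuner = PseudoGradientTuner(evaluate, specs, guard=guard)
    if not specs:
        return tuner.run()
    tuner.run_coarse()
    if stages == "full":
        tuner.run_pseudo_gradient()
        tuner.run_fine()
    best = tuner._incumbent if tuner._incumbent is not None else tuner.trace.best()
    return dict(best.values), tuner.trace


# ---------------------------------------------------------------------------
# estimator registry
# ---------------------------------------------------------------------------


@dataclass
class EstimatorConfig:
    """A concrete (family, task) estimator with its tuning space."""

    family: str
    task: str
    specs: list[HyperSpec]
    fixed: dict = field(default_factory=dict)
    defaults: dict = field(default_factory=dict)
    supports_weights: bool = True
    scale: bool = True


@dataclass
class RF2Plan:
    """Fixed settings and mtry search ladder for the second random forest."""

    n_estimators: int
    sampsize: int | None  # regression: round(0.632 * n_rows)
    per_class_sampsize: int | None  # classification: smallest class count
    mtry_candidates: list[int]


def rf2_config(
    task: str,
    n_rows: int,
    class_counts: Mapping[str, int] | None = None,
    n_features: int = 1,
    step: float = 0.9,
) -> RF2Plan:
    """Fixed RF2 settings: 1001 trees, 0.632/min-class sampling, mtry ladder.

    The mtry ladder is geometric: ``round(p), round(step*p), round(step^2*p),
    ...`` down to 1, deduplicated, with ``p`` the number of features.
    """
    if task == "regression":
        sampsize, per_class = int(round(0.632 * n_rows)), None
    else:
        if not class_counts:
            raise ConfigurationError("classification RF2 needs class counts")
        if min(class_counts.values()) == 0:
            raise ConfigurationError("empty class in RF2 sampling plan")
        sampsize, per_class = None, int(min(class_counts.values()))
    ladder: list[int] = []
    v = float(max(1, n_features))
    while True:
        r = int(round(v))
        if r < 1:
            break
        if not ladder or r != ladder[-1]:
            ladder.append(r)
        if r == 1:
            break
        v *= step
    return RF2Plan(
        n_estimators=1001, sampsize=sampsize, per_class_sampsize=per_class, mtry_candidates=ladder
    )


def default_config(
    family: str,
    task: str,
    fast: bool = False,
    n_features: int | None = None,
    n_rows: int | None = None,
    class_counts: Mapping[str, int] | None = None,
) -> EstimatorConfig:
    """Registry entry for one of the 11 estimator configurations.

    ``fast=True`` swaps in smaller coarse grids and fewer trees; the tuning
    spaces themselves can also be overridden from YAML via
    :func:`specs_from_table`.
    """
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown family {family!r}")
    if task not in ("regression", "binary", "multiclass"):
        raise ConfigurationError(f"unknown task {task!r}")
    if family == "naive_bayes" and task == "regression":
        raise ConfigurationError("naive Bayes does not support regression")

    if family == "elastic_net":
        specs = [
            HyperSpec("lambda", -4, 0, 2 if fast else 1, "pow10", hard_hi=4, n_fine=3),
            HyperSpec(
                "l1_ratio", 0.25 if fast else 0.1, 0.75 if fast else 0.9,
                0.25 if fast else 0.2, hard_lo=0.0, hard_hi=1.0, n_fine=3,
            ),
        ]
        return EstimatorConfig(family, task, specs, defaults={"lambda": 1e-2, "l1_ratio": 0.5})
    if family == "elastic_net2":
        specs = [HyperSpec("lambda", -5, 0, 2 if fast else 1, "pow10", hard_hi=4, n_fine=3)]
        return EstimatorConfig(family, task, specs, defaults={"lambda": 1e-3})
    if family == "rf":
        specs = [
            HyperSpec(
                "max_features", 0.1, 0.9, 0.4 if fast else 0.2,
                hard_lo=0.01, hard_hi=1.0, n_fine=3,
            )
        ]
        return EstimatorConfig(
            family, task, specs,
            fixed={"n_estimators": 150 if fast else 300},
            defaults={"max_features": 0.33 if task == "regression" else 0.1},
            scale=False,
        )
    if family == "rf2":
        plan = rf2_config(
            task, n_rows or 100, class_counts=class_counts, n_features=n_features or 10
        )
        ladder = plan.mtry_candidates
        if fast and len(ladder) > 5:
            ladder = ladder[:: max(1, len(ladder) // 5)]
        specs = [
            HyperSpec(
                "mtry", 0, len(ladder) - 1, 1,
                transform=lambda i, L=ladder: L[min(len(L) - 1, max(0, int(round(i))))],
                hard_lo=0, hard_hi=len(ladder) - 1, n_fine=2, integer=True,
            )
        ] if len(ladder) > 1 else []
        return EstimatorConfig(
            family, task, specs,
            fixed={"plan": plan},
            defaults={"mtry": ladder[len(ladder) // 2]},
            scale=False,
        )
    if family == "gbm":
        specs = [
            HyperSpec("n_trees", 50, 150, 100 if fast else 50, hard_lo=10, integer=True, n_fine=2),
            HyperSpec("depth", 1, 3 if fast else 5, 2, hard_lo=1, hard_hi=8, integer=True, n_fine=2),
        ]
        return EstimatorConfig(
            family, task, specs, defaults={"n_trees": 100, "depth": 3}, scale=False
        )
    if family == "gbm2":
        return EstimatorConfig(
            family, task, [],
            fixed={"max_depth": 1, "min_samples_leaf": 10, "learning_rate": 0.1, "n_estimators": 1000},
            scale=False,
        )
    if family in ("svm_linear", "svm_poly2", "svm_radial"):
        specs = [HyperSpec("C", -4, 4, 4 if fast else 2, "pow2", n_fine=3)]
        if family == "svm_radial":
            specs.append(HyperSpec("gamma", -6, -2 if fast else 0, 4 if fast else 2, "pow2", n_fine=3))
        defaults = {"C": 1.0}
        if family == "svm_radial":
            defaults["gamma"] = 2.0**-4
        return EstimatorConfig(family, task, specs, defaults=defaults)
    if family == "knn":
        specs = [
            HyperSpec("k", 1, 21, 10 if fast else 4, hard_lo=1, integer=True, n_fine=3)
        ]
        return EstimatorConfig(
            family, task, specs, defaults={"k": 11}, supports_weights=False
        )
    if family == "naive_bayes":
        specs = [HyperSpec("var_smoothing", -11, -5, 3, "pow10", n_fine=3)]
        return EstimatorConfig(family, task, specs, defaults={"var_smoothing": 1e-9}, scale=False)
    raise ConfigurationError(f"unhandled family {family!r}")


def specs_from_table(rows: Sequence[Mapping]) -> list[HyperSpec]:
    """Hyperparameter specs from a YAML-style table of rows.

    Each row carries ``name, lo, hi, stride`` and optionally ``transform,
    hard_lo, hard_hi, n_fine, integer`` — mirroring the published tuning
    tables (two extremum values, stride, transform, N fine tuning).
    """
    return [
        HyperSpec(
            name=r["name"],
            lo=float(r["lo"]),
            hi=float(r["hi"]),
            stride=float(r["stride"]),
            transform=r.get("transform", "identity"),
            hard_lo=float(r.get("hard_lo", -np.inf)),
            hard_hi=float(r.get("hard_hi", np.inf)),
            n_fine=int(r.get("n_fine", 3)),
            integer=bool(r.get("integer", False)),
        )
        for r in rows
    ]


def _build_estimator(config: EstimatorConfig, values: Mapping[str, float], seed: int):
    family, task = config.family, config.task
    reg = task == "regression"
    v = {**config.defaults, **values}
    if family == "elastic_net":
        lam, mix = float(v["lambda"]), float(np.clip(v["l1_ratio"], 0.0, 1.0))
        if reg:
            est = ElasticNet(alpha=lam, l1_ratio=mix, max_iter=5000)
        else:
            est = LogisticRegression(
                solver="saga", C=1.0 / max(lam, 1e-12),
                l1_ratio=mix, max_iter=2000, tol=1e-3, random_state=seed,
            )
    elif family == "elastic_net2":
        lam = float(v["lambda"])
        if reg:
            est = SGDRegressor(
                penalty="elasticnet", alpha=lam, l1_ratio=0.5, max_iter=2000,
                tol=1e-4, random_state=seed,
            )
        else:
            est = SGDClassifier(
                loss="log_loss", penalty="elasticnet", alpha=lam, l1_ratio=0.5,
                max_iter=2000, tol=1e-4, random_state=seed,
            )
    elif family == "rf":
        cls = RandomForestRegressor if reg else RandomForestClassifier
        est = cls(
            n_estimators=config.fixed.get("n_estimators", 300),
            max_features=float(np.clip(v["max_features"], 0.01, 1.0)),
            random_state=seed, n_jobs=1,
        )
    elif family == "rf2":
        plan: RF2Plan = config.fixed["plan"]
        mtry = int(v.get("mtry", 1))
        if reg:
            est = RandomForestRegressor(
                n_estimators=plan.n_estimators, max_features=mtry,
                max_samples=plan.sampsize, bootstrap=True, random_state=seed, n_jobs=1,
            )
        else:
            n_classes = 2  # refined at fit time via class counts in max_samples
            est = RandomForestClassifier(
                n_estimators=plan.n_estimators, max_features=mtry,
                class_weight="balanced_subsample", bootstrap=True,
                max_samples=(plan.per_class_sampsize or 1) * n_classes,
                random_state=seed, n_jobs=1,
            )
    elif family == "gbm":
        cls = GradientBoostingRegressor if reg else GradientBoostingClassifier
        est = cls(
            n_estimators=int(v["n_trees"]), max_depth=int(v["depth"]),
            learning_rate=0.1, random_state=seed,
        )
    elif family == "gbm2":
        cls = GradientBoostingRegressor if reg else GradientBoostingClassifier
        est = cls(
            n_estimators=int(v.get("n_trees", config.fixed["n_estimators"])),
            max_depth=config.fixed["max_depth"],
            min_samples_leaf=config.fixed["min_samples_leaf"],
            learning_rate=config.fixed["learning_rate"], random_state=seed,
        )
    elif family in ("svm_linear", "svm_poly2", "svm_radial"):
        kernel = {"svm_linear": "linear", "svm_poly2": "poly", "svm_radial": "rbf"}[family]
        kw = {"kernel": kernel, "C": float(v["C"])}
        if family == "svm_poly2":
            kw.update(degree=2, coef0=1.0)
        if family == "svm_radial":
            kw.update(gamma=float(v["gamma"]))
        est = SVR(**kw) if reg else SVC(**kw, random_state=seed)
    elif family == "knn":
        cls = KNeighborsRegressor if reg else KNeighborsClassifier
        est = cls(n_neighbors=max(1, int(v["k"])))
    elif family == "naive_bayes":
        est = GaussianNB(var_smoothing=float(v["var_smoothing"]))
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    if config.scale:
        return Pipeline([("scaler", StandardScaler()), ("model", est)])
    return Pipeline([("model", est)])


@dataclass
class FitPrediction:
    """Outcome of one fit/predict call — a structured failure, never a crash."""

    predictions: np.ndarray | None
    scores: np.ndarray | None  # binary: P(positive class); else None/matrix
    classes: np.ndarray | None
    model: object | None
    failure: str | None = None


def fit_predict(
    config: EstimatorConfig,
    values: Mapping[str, float],
    X_train: pd.DataFrame,
    y_train: pd.Series,
    weights: pd.Series | None,
    X_test: pd.DataFrame,
    seed: int = 0,
) -> FitPrediction:
    """Uniform fit/predict adapter over the registry's estimators.

    Classification additionally returns scores for ROC AUC: the positive
    class probability when ``predict_proba`` is finite, otherwise the decision
    function; a model whose probabilities are NaN still contributes labels,
    with probability-based metrics marked missing (the naive Bayes case).
    """
    try:
        est = _build_estimator(config, values, seed)
        fit_kw = {}
        if weights is not None and config.supports_weights:
            fit_kw["model__sample_weight"] = np.asarray(weights.loc[X_train.index], float)
        if config.family == "rf2" and config.task != "regression":
            plan: RF2Plan = config.fixed["plan"]
            n_classes = y_train.nunique()
            cap = min((plan.per_class_sampsize or 1) * n_classes, len(X_train))
            est.named_steps["model"].set_params(max_samples=cap)
        y = y_train.to_numpy(float) if config.task == "regression" else y_train.astype(str).to_numpy()
        est.fit(X_train.to_numpy(float), y, **fit_kw)
        preds = est.predict(X_test.to_numpy(float))
        scores = None
        classes = None
        if config.task != "regression":
            model = est.named_steps["model"]
            classes = model.classes_
            if hasattr(model, "predict_proba"):
                proba = est.predict_proba(X_test.to_numpy(float))
                if np.isfinite(proba).all():
                    scores = proba[:, -1] if config.task == "binary" else proba
                else:
                    logger.warning(
                        "%s produced NaN probabilities; probability metrics marked missing",
                        config.family,
                    )
            elif config.task == "binary" and hasattr(model, "decision_function"):
                scores = est.decision_function(X_test.to_numpy(float))
        return FitPrediction(preds, scores, classes, est)
    except EvaluationFailure:
        raise
    except Exception as exc:  # noqa: BLE001 — structured failure by contract
        return FitPrediction(None, None, None, None, failure=f"{type(exc).__name__}: {exc}")


# ---------------------------------------------------------------------------
# GBM2 tree escalation
# ---------------------------------------------------------------------------


def decide_gbm2_escalation(perf: Sequence[float], min_improvement: float = 0.001) -> bool:
    """Double the tree count iff the best iteration sits in the last 10% of
    iterations AND the mean performance of that last decile improves on the
    preceding decile by at least ``min_improvement`` (0.1%), relatively."""
    p = np.asarray(perf, dtype=float)
    T = len(p)
    d = max(1, T // 10)
    if T < 2 * d:
        return False
    last, prev = p[-d:], p[-2 * d : -d]
    best_in_tail = int(np.argmax(p)) >= T - d
    denom = max(abs(float(prev.mean())), 1e-12)
    improved = (float(last.mean()) - float(prev.mean())) / denom >= min_improvement
    return bool(best_in_tail and improved)


def _staged_performance(est, X_val, y_val, task: str) -> list[float]:
    out = []
    for pred in est.staged_predict(X_val):
        try:
            if task == "regression":
                out.append(r_squared(y_val, pred))
            elif task == "binary":
                out.append(accuracy(y_val, pred))
            else:
                out.append(mean_class_accuracy(y_val, pred))
        except ValueError:
            out.append(np.nan)
    return out


def gbm2_final_n_trees(
    config: EstimatorConfig,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    weights: pd.Series | None,
    X_val: pd.DataFrame,
    y_val: pd.Series,
    seed: int = 0,
    cap_factor: int = 16,
) -> tuple[int, list[list[float]]]:
    """Tree count for the second GBM: keep doubling while the escalation rule
    fires, capped at ``cap_factor`` times the initial 1000 trees."""
    initial = config.fixed["n_estimators"]
    n = initial
    history: list[list[float]] = []
    while True:
        fp = fit_predict(config, {"n_trees": n}, X_train, y_train, weights, X_val, seed)
        if fp.failure:
            raise EvaluationFailure(fp.failure)
        y_val_arr = (
            y_val.to_numpy(float) if config.task == "regression" else y_val.astype(str).to_numpy()
        )
        perf = _staged_performance(
            fp.model.named_steps["model"],
            fp.model.named_steps.get("scaler", _Identity()).transform(X_val.to_numpy(float))
            if "scaler" in fp.model.named_steps
            else X_val.to_numpy(float),
            y_val_arr,
            config.task,
        )
        history.append(perf)
        if not decide_gbm2_escalation(perf):
            break
        if n * 2 > initial * cap_factor:
            logger.warning("GBM2 escalation cap (%dx) reached at %d trees", cap_factor, n)
            break
        n *= 2
    return n, history


class _Identity:
    def transform(self, X):
        return X


# ---------------------------------------------------------------------------
# importances, inner-CV evaluation, training-set guard
# ---------------------------------------------------------------------------


def extract_importances(
    fitted,
    config: EstimatorConfig,
    feature_names: Sequence[str],
    X: pd.DataFrame | None = None,
    y: pd.Series | None = None,
    metric: Callable | None = None,
    seed: int = 0,
    allow_permutation: bool = True,
    n_repeats: int = 3,
) -> pd.Series:
    """Per-feature relative importance for a fitted estimator.

    Linear families report |standardized coefficients| (inputs are scaled);
    tree families report impurity importance; other families fall back to
    permutation importance (mean metric degradation over ``n_repeats``
    shuffles) when allowed, else raise.
    """
    model = fitted.named_steps["model"]
    if hasattr(model, "coef_"):
        coef = np.atleast_2d(model.coef_)
        imp = np.abs(coef).mean(axis=0)
    elif hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_, dtype=float)
    elif allow_permutation:
        if X is None or y is None or metric is None:
            raise ConfigurationError(
                f"{config.family} has no native importance; permutation needs X, y, metric"
            )
        rng = np.random.default_rng(seed)
        Xv = X.to_numpy(float)
        yv = y.to_numpy(float) if config.task == "regression" else y.astype(str).to_numpy()
        base = metric(yv, fitted.predict(Xv))
        imp = np.zeros(Xv.shape[1])
        for j in range(Xv.shape[1]):
            drops = []
            for _ in range(n_repeats):
                Xp = Xv.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                drops.append(base - metric(yv, fitted.predict(Xp)))
            imp[j] = np.mean(drops)
        imp = np.clip(imp, 0.0, None)
    else:
        raise ConfigurationError(f"{config.family} exposes no feature importance")
    return pd.Series(imp, index=list(feature_names), dtype=float)


def make_inner_evaluator(
    config: EstimatorConfig,
    X: pd.DataFrame,
    y: pd.Series,
    weights: pd.Series | None,
    inner_folds: pd.Series,
    seed: int = 0,
) -> Callable[[Mapping[str, float]], float]:
    """Inner-CV score function for the tuner: mean task metric over inner folds.

    Folds where the metric is undefined (e.g. a single truth class) are
    skipped; if no fold yields a score, the combination counts as a failure.
    Binary tasks score by ROC AUC when scores are available, falling back to
    accuracy when probabilities are missing.
    """
    folds = sorted(inner_folds.unique())

    def evaluate(values: Mapping[str, float]) -> float:
        scores = []
        for f in folds:
            tr = inner_folds.index[inner_folds != f]
            te = inner_folds.index[inner_folds == f]
            fp = fit_predict(config, values, X.loc[tr], y.loc[tr], weights, X.loc[te], seed)
            if fp.failure:
                raise EvaluationFailure(fp.failure)
            y_te = y.loc[te]
            try:
                if config.task == "regression":
                    s = r_squared(y_te.to_numpy(float), fp.predictions)
                elif config.task == "binary":
                    truth = y_te.astype(str).to_numpy()
                    if fp.scores is not None and np.isfinite(np.asarray(fp.scores, float)).all():
                        s = roc_auc(truth, fp.scores)
                    else:
                        s = accuracy(truth, fp.predictions)
                else:
                    s = mean_class_accuracy(y_te.astype(str).to_numpy(), fp.predictions)
            except ValueError:
                continue
            scores.append(s)
        if not scores:
            raise EvaluationFailure("no inner fold produced a defined score")
        return float(np.mean(scores))

    return evaluate


def make_train_guard(
    config: EstimatorConfig,
    X: pd.DataFrame,
    y: pd.Series,
    weights: pd.Series | None,
    seed: int = 0,
) -> Callable[[Mapping[str, float]], bool]:
    """Accept a hyperparameter combination only if the model refit on the full
    training set yields non-NaN predictions for every training row."""

    def guard(values: Mapping[str, float]) -> bool:
        fp = fit_predict(config, values, X, y, weights, X, seed)
        if fp.failure or fp.predictions is None:
            return False
        return not pd.isna(pd.Series(fp.predictions)).any()

    return guard
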