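"""Configuration-driven end-to-end runs: simulate -> features -> folds ->
tune/fit -> evaluate -> concordance.

The unit of work is a *cell* of the model grid — one (phenotype, data type,
estimator) triple.  Every cell is evaluated with the same subject-grouped
outer folds, its own univariate feature filter per training fold, inner-CV
hyperparameter tuning, pooled out-of-fold scoring and a bootstrap SD.  A
demographics-only baseline is always materialized for each phenotype so that
microbiome-inclusive models can be compared against it.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import synthetic_data
from .concordance import ConcordanceMatrix, average_concordance, importance_vector, pairwise_spearman
from .crossval import FoldPlan, clean_samples, encode_demographics, plan_folds
from .errors import ConfigurationError, EvaluationFailure
from .evaluate import (
    BootstrapResult,
    ModelResult,
    PredictionSet,
    accuracy,
    bootstrap_ci,
    compare_to_baseline,
    mean_class_accuracy,
    metric_for_task,
    r_squared,
    rescue_nan_predictions,
    roc_auc,
)
from .features import (
    CAGAssignment,
    canopy_cluster,
    class_weights,
    extract_genes_from_top_cags,
    filter_features,
)
from .features import aggregate_quantile
from .models import (
    default_config,
    extract_importances,
    fit_predict,
    gbm2_final_n_trees,
    make_inner_evaluator,
    make_train_guard,
    tune,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultsBundle", "run_experiment", "summarize", "cell_seed"]

#: phenotype name -> (metadata column, task)
PHENOTYPE_TASKS = {
    "age": ("age_days", "regression"),
    "sex": ("sex", "binary"),
    "delivery": ("delivery", "binary"),
    "breastfed": ("breastfed", "binary"),
    "antibiotics": ("antibiotics", "binary"),
    "country": ("country", "multiclass"),
}


def cell_seed(master: int, *parts: str) -> int:
    """Deterministic per-cell seed derived from the master seed (< 2**31)."""
    h = zlib.crc32("|".join(parts).encode()) & 0x7FFFFFFF
    return (h ^ (master & 0x7FFFFFFF)) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Either a simulation (``design`` + ``signal``) or pre-built inputs
    (``metadata`` + ``tables``) must be supplied.  ``tuning`` selects the
    hyperparameter search depth: ``off`` (per-family defaults), ``coarse``
    (initial grid only) or ``full`` (coarse grid, pseudo-gradient
    exploration, fine tuning).
    """

    phenotypes: list[str]
    estimators: list[str]
    data_types: list[str] = field(default_factory=lambda: ["cag"])
    design: synthetic_data.StudyDesign | None = None
    signal: synthetic_data.SignalSpec | None = None
    metadata: pd.DataFrame | None = None
    tables: dict[str, pd.DataFrame] | None = None
    truth: CAGAssignment | None = None
    k: int = 10
    k_inner: int = 10
    B: int = 1000
    seed: int = 0
    tuning: str = "full"  # off | coarse | full
    max_features: int = 1000
    alpha: float = 0.05
    n_top_cags: int = 10
    use_ground_truth_cags: bool = False
    compute_importances: bool = True
    permutation_importance: bool = False
    outdir: str | None = None

    def validate(self) -> None:
        if not self.phenotypes:
            raise ConfigurationError("at least one phenotype required")
        if not self.estimators:
            raise ConfigurationError("at least one estimator required")
        unknown = [p for p in self.phenotypes if p not in PHENOTYPE_TASKS]
        if unknown:
            raise ConfigurationError(f"unknown phenotypes: {unknown}")
        if self.tuning not in ("off", "coarse", "full"):
            raise ConfigurationError(f"unknown tuning mode {self.tuning!r}")
        if (self.design is None or self.signal is None) and (
            self.metadata is None or self.tables is None
        ):
            raise ConfigurationError("provide a simulation design or input tables")


@dataclass
class ResultsBundle:
    """All ModelResults of a run plus the shared artefacts."""

    config: RunConfig
    results: list[ModelResult]
    assignment: CAGAssignment | None
    fold_plans: dict[str, FoldPlan]
    failures: list[dict] = field(default_factory=list)

    def get(self, phenotype: str, data_type: str, estimator: str) -> ModelResult:
        for r in self.results:
            if (r.phenotype, r.data_type, r.estimator) == (phenotype, data_type, estimator):
                return r
        raise KeyError((phenotype, data_type, estimator))

    def summary(self) -> pd.DataFrame:
        return summarize(self.results)

    def algorithm_concordance(self, phenotype: str, data_type: str) -> ConcordanceMatrix:
        """Pairwise Spearman between estimators' importance vectors for one
        (phenotype, data type)."""
        cells = [
            r
            for r in self.results
            if r.phenotype == phenotype
            and r.data_type == data_type
            and r.importances is not None
            and r.importances.sum() > 0
        ]
        if len(cells) < 2:
            raise ConfigurationError(
                f"need >= 2 models with importances for {phenotype}/{data_type}"
            )
        universe = sorted(set().union(*[set(r.importances.index) for r in cells]))
        vectors = []
        for r in cells:
            v = importance_vector(r, universe)
            v.provenance["label"] = r.estimator
            vectors.append(v)
        return pairwise_spearman(vectors, grouping={"phenotype": phenotype, "data_type": data_type})

    def data_type_consistency(self, phenotype: str) -> pd.Series:
        """Mean cross-algorithm Spearman per data type (gene excluded: each
        phenotype is analyzed with a different gene set)."""
        out = {}
        for dt in self.config.data_types:
            if dt.startswith("gene"):
                continue
            try:
                m = self.algorithm_concordance(phenotype, dt)
            except ConfigurationError:
                continue
            out[dt] = float(average_concordance(m).mean())
        if not out:
            raise ConfigurationError("no data type has enough importance vectors")
        return pd.Series(out, name="mean_rho")

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.tsv", "w") as fh:
            fh.write(self.summary().to_csv(sep="\t", index=False, float_format="%.6f"))
        cells = []
        for r in self.results:
            cells.append(
                {
                    "phenotype": r.phenotype,
                    "data_type": r.data_type,
                    "estimator": r.estimator,
                    "metric": r.metric_name,
                    "point": r.point,
                    "sd": r.sd,
                    "best_hypers": r.best_hypers,
                    "failure": r.failure,
                }
            )
        (out / "cells.json").write_text(json.dumps(cells, indent=1, default=str))
        cfg = {
            "phenotypes": self.config.phenotypes,
            "estimators": self.config.estimators,
            "data_types": self.config.data_types,
            "k": self.config.k,
            "k_inner": self.config.k_inner,
            "B": self.config.B,
            "seed": self.config.seed,
            "tuning": self.config.tuning,
            "schema_version": 1,
        }
        (out / "config.json").write_text(json.dumps(cfg, indent=1))


def target_series(metadata: pd.DataFrame, phenotype: str) -> tuple[pd.Series, str]:
    col, task = PHENOTYPE_TASKS[phenotype]
    y = metadata[col]
    return (y.astype(float) if task == "regression" else y.astype(str)), task


def _assemble_parts(
    data_type: str, tables: Mapping[str, pd.DataFrame], demo: pd.DataFrame
) -> tuple[pd.DataFrame | None, bool]:
    """Split a data-type label into (microbiome table, include-demographics)."""
    if data_type == "demographics":
        return None, True
    parts = data_type.split("+")
    with_demo = "demographics" in parts
    micro_names = [p for p in parts if p != "demographics"]
    if data_type == "combined":
        micro_names, with_demo = [t for t in tables], True
    frames = []
    for name in micro_names:
        if name not in tables:
            raise ConfigurationError(f"data type {name!r} has no table")
        frames.append(tables[name])
    micro = pd.concat(frames, axis=1) if frames else None
    return micro, with_demo


def _run_cell(
    phenotype: str,
    data_type: str,
    estimator: str,
    micro: pd.DataFrame | None,
    demo: pd.DataFrame | None,
    y: pd.Series,
    task: str,
    plan: FoldPlan,
    cfg: RunConfig,
) -> ModelResult:
    seed = cell_seed(cfg.seed, phenotype, data_type, estimator)
    name_metric, metric = metric_for_task(task)
    rows = []
    fold_importances: list[pd.Series] = []
    for f in range(plan.k):
        tr, te = plan.outer_split(f)
        X_parts = []
        if micro is not None:
            rep = filter_features(
                micro.loc[tr], y.loc[tr], max_features=cfg.max_features,
                alpha=cfg.alpha, task=task,
            )
            X_parts.append(micro[rep.selected])
        if demo is not None:
            X_parts.append(demo)
        X = pd.concat(X_parts, axis=1)
        w = class_weights(y.loc[tr]) if task != "regression" else None

        config = default_config(
            estimator, task, fast=(cfg.tuning != "full"),
            n_features=X.shape[1], n_rows=len(tr),
            class_counts=y.loc[tr].value_counts().to_dict() if task != "regression" else None,
        )
        inner = plan.inner[f]
        values = dict(config.defaults)
        trace = None
        if cfg.tuning != "off" and config.specs:
            evaluate = make_inner_evaluator(config, X, y, w, inner, seed=seed)
            guard = make_train_guard(config, X.loc[tr], y.loc[tr], w, seed=seed)
            try:
                values, trace = tune(
                    evaluate, config.specs, guard=guard,
                    stages="full" if cfg.tuning == "full" else "coarse",
                )
            except EvaluationFailure as exc:
                logger.warning("fold %d tuning failed (%s); using defaults", f, exc)
                values = dict(config.defaults)
        if estimator == "gbm2" and cfg.tuning != "off":
            val_fold = sorted(inner.unique())[0]
            val_idx = inner.index[inner == val_fold]
            fit_idx = inner.index[inner != val_fold]
            n_trees, _ = gbm2_final_n_trees(
                config, X.loc[fit_idx], y.loc[fit_idx],
                w, X.loc[val_idx], y.loc[val_idx], seed=seed,
            )
            values = {**values, "n_trees": n_trees}

        fp = fit_predict(config, values, X.loc[tr], y.loc[tr], w, X.loc[te], seed)
        if fp.failure:
            raise EvaluationFailure(f"fold {f}: {fp.failure}")
        preds, excluded = rescue_nan_predictions(
            lambda Xq: fp.model.predict(Xq.to_numpy(float)), X.loc[te]
        )
        keep_te = [s for s in te if s not in set(excluded)]
        scores = None
        if task == "binary" and fp.scores is not None:
            scores = pd.Series(np.asarray(fp.scores, float), index=te)
        for s in keep_te:
            i = list(te).index(s)
            rows.append(
                {
                    "sample_id": s,
                    "fold": f,
                    "truth": y.loc[s],
                    "prediction": preds[i],
                    "score": float(scores.loc[s]) if scores is not None else np.nan,
                }
            )
        if cfg.compute_importances:
            try:
                imp = extract_importances(
                    fp.model, config, X.columns,
                    X=X.loc[tr], y=y.loc[tr], metric=metric, seed=seed,
                    allow_permutation=cfg.permutation_importance,
                )
                fold_importances.append(imp)
            except ConfigurationError:
                pass

    frame = pd.DataFrame(rows).set_index("sample_id")
    pset = PredictionSet(frame=frame, task=task)
    truth = frame["truth"].to_numpy()
    if task == "regression":
        boot = bootstrap_ci(
            truth.astype(float), frame["prediction"].to_numpy(float), r_squared,
            B=cfg.B, seed=seed,
        )
        metric_name = "r_squared"
    elif task == "binary":
        if frame["score"].notna().all():
            boot = bootstrap_ci(
                truth, frame["score"].to_numpy(float), roc_auc, B=cfg.B, seed=seed
            )
            metric_name = "roc_auc"
        else:  # probabilities missing (naive Bayes case): label-based metric
            boot = bootstrap_ci(
                truth, frame["prediction"].to_numpy(), mean_class_accuracy,
                B=cfg.B, seed=seed,
            )
            metric_name = "mean_class_accuracy"
    else:
        boot = bootstrap_ci(
            truth, frame["prediction"].to_numpy(), mean_class_accuracy,
            B=cfg.B, seed=seed,
        )
        metric_name = "mean_class_accuracy"

    importances = None
    if fold_importances:
        aligned = pd.concat(fold_importances, axis=1).fillna(0.0)
        importances = aligned.mean(axis=1)
    return ModelResult(
        phenotype=phenotype,
        data_type=data_type,
        estimator=estimator,
        metric_name=metric_name,
        point=boot.point,
        sd=boot.sd,
        importances=importances,
        trace=trace,
        predictions=pset,
        best_hypers=values,
    )


def run_experiment(config: RunConfig) -> ResultsBundle:
    """Execute the declared grid of (phenotype x data type x estimator) cells.

    Cell failures are isolated: a failed cell is reported in the bundle and
    the run continues.  Reruns with the same config and seed are bit-identical
    for deterministic estimators.
    """
    config.validate()
    t0 = time.time()

    if config.metadata is not None and config.tables is not None:
        metadata, tables, truth = config.metadata, dict(config.tables), config.truth
        assignment = config.truth
    else:
        design, signal = config.design, config.signal
        metadata = synthetic_data.generate_metadata(design)
        gene_table, truth = synthetic_data.generate_gene_abundances(design, signal, metadata)
        if config.use_ground_truth_cags:
            assignment = truth
        else:
            assignment = canopy_cluster(gene_table)
        tables = {
            "cag": aggregate_quantile(gene_table, assignment),
            "taxa": synthetic_data.generate_taxa_abundances(gene_table, truth),
        }
        tables["_gene_catalog"] = gene_table
    gene_catalog = tables.pop("_gene_catalog", None)
    logger.info("inputs ready in %.1fs (%d samples)", time.time() - t0, len(metadata))

    results: list[ModelResult] = []
    failures: list[dict] = []
    fold_plans: dict[str, FoldPlan] = {}
    for phenotype in config.phenotypes:
        col, task = PHENOTYPE_TASKS[phenotype]
        ds = clean_samples(tables, metadata)
        y, task = target_series(ds.metadata, phenotype)
        plan = plan_folds(ds.metadata, col, k=config.k, seed=config.seed, k_inner=config.k_inner)
        fold_plans[phenotype] = plan
        demo = encode_demographics(ds.metadata, col)

        data_types = ["demographics"] + [d for d in config.data_types if not d.startswith("gene")]
        gene_types = [d for d in config.data_types if d.startswith("gene")]
        for data_type in data_types:
            micro, with_demo = _assemble_parts(data_type, ds.tables, demo)
            for estimator in config.estimators:
                t1 = time.time()
                try:
                    res = _run_cell(
                        phenotype, data_type, estimator, micro,
                        demo if with_demo else None, y, task, plan, config,
                    )
                    results.append(res)
                    logger.info(
                        "cell %s/%s/%s: %s=%.3f+-%.3f (%.1fs)",
                        phenotype, data_type, estimator, res.metric_name,
                        res.point, res.sd, time.time() - t1,
                    )
                except (EvaluationFailure, ConfigurationError, ValueError) as exc:
                    logger.error("cell %s/%s/%s failed: %s", phenotype, data_type, estimator, exc)
                    failures.append(
                        {"phenotype": phenotype, "data_type": data_type,
                         "estimator": estimator, "error": str(exc)}
                    )

        # gene data types: genes pulled from the top CAGs of the best CAG model
        if gene_types and gene_catalog is not None and assignment is not None:
            cag_cells = [
                r for r in results
                if r.phenotype == phenotype and "cag" in r.data_type.split("+")
                and r.importances is not None
            ]
            if cag_cells:
                best_cag = max(cag_cells, key=lambda r: (r.point, -r.sd, r.estimator))
                gene_sub = extract_genes_from_top_cags(
                    best_cag.importances, assignment, gene_catalog.loc[ds.samples],
                    y, task=task, n_cags=config.n_top_cags,
                )
                for data_type in gene_types:
                    if gene_sub.shape[1] == 0:
                        logger.warning("no genes survive Bonferroni; skipping %s", data_type)
                        continue
                    with_demo = "demographics" in data_type.split("+")
                    for estimator in config.estimators:
                        try:
                            res = _run_cell(
                                phenotype, data_type, estimator, gene_sub,
                                demo if with_demo else None, y, task, plan, config,
                            )
                            results.append(res)
                        except (EvaluationFailure, ConfigurationError, ValueError) as exc:
                            failures.append(
                                {"phenotype": phenotype, "data_type": data_type,
                                 "estimator": estimator, "error": str(exc)}
                            )

    bundle = ResultsBundle(
        config=config, results=results, assignment=assignment,
        fold_plans=fold_plans, failures=failures,
    )
    if config.outdir:
        bundle.write(config.outdir)
    logger.info("run complete: %d cells, %d failures, %.1fs", len(results), len(failures), time.time() - t0)
    return bundle


def summarize(results: list[ModelResult]) -> pd.DataFrame:
    """Best-per-phenotype table: best experimental vs best baseline, delta,
    and a +-1-SD significance flag.

    Ties on the point estimate break by smaller bootstrap SD, then
    lexicographic estimator name.
    """
    rows = []
    phenotypes = sorted({r.phenotype for r in results})
    for phenotype in phenotypes:
        cells = [r for r in results if r.phenotype == phenotype and r.failure is None]
        baseline = [r for r in cells if r.data_type == "demographics"]
        experimental = [r for r in cells if r.data_type != "demographics"]
        if not baseline or not experimental:
            continue

        def rank(r: ModelResult):
            return (-r.point, r.sd, r.estimator, r.data_type)

        best_e = min(experimental, key=rank)
        # compare on a common metric where possible
        base_same = [r for r in baseline if r.metric_name == best_e.metric_name]
        best_b = min(base_same or baseline, key=rank)
        if best_b.metric_name == best_e.metric_name:
            delta, significant = compare_to_baseline(best_e, best_b)
        else:
            delta, significant = np.nan, False
        rows.append(
            {
                "phenotype": phenotype,
                "metric": best_e.metric_name,
                "best_predictor_set": best_e.data_type,
                "best_algorithm_experimental": best_e.estimator,
                "experimental_performance": best_e.point,
                "experimental_sd": best_e.sd,
                "best_algorithm_baseline": best_b.estimator,
                "baseline_performance": best_b.point,
                "baseline_sd": best_b.sd,
                "difference": delta,
                "significant": significant,
            }
        )
    return pd.DataFrame(rows)
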