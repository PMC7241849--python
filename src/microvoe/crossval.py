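"""Complete-case cleaning, demographic encoding and subject-grouped fold plans.

Repeated samples from the same infant carry a strong personal signature, so a
model trained and tested on the same subject would look spuriously accurate.
All samples of a subject are therefore confined to a single outer fold, and —
within each outer training set — to a single inner fold.  Categorical targets
are stratified at the subject level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "FoldPlan", "clean_samples", "encode_demographics", "plan_folds"]

PHENOTYPES = ["age_days", "sex", "country", "delivery", "breastfed", "antibiotics"]


@dataclass
class Dataset:
    """Aligned abundance tables and metadata after complete-case cleaning."""

    tables: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> pd.Index:
        return self.metadata.index


@dataclass
class FoldPlan:
    """Sample -> fold maps for outer CV and, per outer fold, inner CV."""

    k: int
    outer: pd.Series  # sample_id -> outer fold (0..k-1)
    inner: dict[int, pd.Series]  # outer fold -> (sample_id -> inner fold)
    seed: int

    def outer_split(self, fold: int) -> tuple[pd.Index, pd.Index]:
        test = self.outer.index[self.outer == fold]
        train = self.outer.index[self.outer != fold]
        return train, test

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "outer": {s: int(f) for s, f in self.outer.items()},
            "inner": {
                str(f): {s: int(g) for s, g in m.items()} for f, m in self.inner.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            k=payload["k"],
            outer=pd.Series(payload["outer"]),
            inner={int(f): pd.Series(m) for f, m in payload["inner"].items()},
            seed=payload["seed"],
        )


def clean_samples(
    tables: Mapping[str, pd.DataFrame],
    metadata: pd.DataFrame,
    phenotypes: list[str] | None = None,
) -> Dataset:
    """Keep the samples present in every table with complete phenotypes."""
    if phenotypes is None:
        phenotypes = [p for p in PHENOTYPES if p in metadata.columns]
    removed: dict[str, int] = {}
    keep = metadata.index
    complete = metadata[phenotypes].notna().all(axis=1)
    removed["missing_phenotype"] = int((~complete).sum())
    keep = keep[complete.loc[keep]]
    for name, table in tables.items():
        before = len(keep)
        keep = keep.intersection(table.index)
        removed[f"absent_from_{name}"] = before - len(keep)
    if len(keep) == 0:
        raise ConfigurationError("no samples survive complete-case cleaning")
    keep = metadata.index[metadata.index.isin(keep)]  # preserve metadata order
    for reason, n in removed.items():
        if n:
            logger.info("clean_samples: removed %d samples (%s)", n, reason)
    return Dataset(
        tables={name: t.loc[keep] for name, t in tables.items()},
        metadata=metadata.loc[keep],
        removed=removed,
    )


def encode_demographics(
    metadata: pd.DataFrame,
    target: str,
    drop_first: bool = False,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Demographic predictor matrix: one-hot categoricals, age passed through.

    The target phenotype is never among the predictors.  ``drop_first`` drops
    a reference level per categorical (the convention for linear models);
    tree and distance models keep all indicator columns.
    """
    if columns is None:
        columns = [p for p in PHENOTYPES if p in metadata.columns]
    if target in columns:
        columns = [c for c in columns if c != target]
    elif target not in metadata.columns and target not in PHENOTYPES:
        raise ConfigurationError(f"unknown target {target!r}")
    if not columns:
        raise ConfigurationError("no demographic predictors left after excluding target")
    sub = metadata[columns].copy()
    num_cols = [c for c in sub.columns if pd.api.types.is_numeric_dtype(sub[c])]
    cat_cols = [c for c in sub.columns if c not in num_cols]
    parts = [sub[num_cols].astype(float)] if num_cols else []
    if cat_cols:
        dummies = pd.get_dummies(
            sub[cat_cols].astype(str), drop_first=drop_first, dtype=float
        )
        parts.append(dummies)
    out = pd.concat(parts, axis=1)
    assert not any(c == target or c.startswith(f"{target}_") for c in out.columns)
    return out


def _assign_subjects(
    subjects: pd.DataFrame, k: int, rng: np.random.Generator, stratify: bool
) -> dict[str, int]:
    """Greedy bin packing: biggest subjects first, into the emptiest
    class-compatible fold; ties broken by permuted order then fold index."""
    perm = {s: r for s, r in zip(subjects.index, rng.permutation(len(subjects)))}
    order = sorted(subjects.index, key=lambda s: (-subjects.loc[s, "n"], perm[s]))
    fold_samples = np.zeros(k, dtype=int)
    fold_class: dict[object, np.ndarray] = {}
    out: dict[str, int] = {}
    for s in order:
        label = subjects.loc[s, "label"] if stratify else None
        if label is not None:
            counts = fold_class.setdefault(label, np.zeros(k, dtype=int))
            key = [(counts[f], fold_samples[f], f) for f in range(k)]
        else:
            key = [(fold_samples[f], 0, f) for f in range(k)]
        f = min(range(k), key=lambda i: key[i])
        out[s] = f
        fold_samples[f] += subjects.loc[s, "n"]
        if label is not None:
            fold_class[label][f] += 1
    return out


def plan_folds(
    metadata: pd.DataFrame,
    target: str,
    k: int = 10,
    seed: int = 0,
    k_inner: int | None = None,
) -> FoldPlan:
    """Subject-grouped, stratified fold plan for nested cross-validation.

    Every sample of a subject shares an outer fold; within each outer training
    set, inner folds are built the same way.  Categorical targets are
    stratified on the subject's majority class; continuous targets balance
    subject counts only.
    """
    if "subject_id" not in metadata.columns:
        raise ConfigurationError("metadata must carry a subject_id column")
    if k_inner is None:
        k_inner = k
    subj_groups = metadata.groupby("subject_id", sort=True)
    n_subjects = subj_groups.ngroups
    if n_subjects < k:
        raise ConfigurationError(f"{n_subjects} subjects but k={k} outer folds")

    stratify = target in metadata.columns and not pd.api.types.is_numeric_dtype(
        metadata[target]
    )

    def subject_frame(meta: pd.DataFrame) -> pd.DataFrame:
        g = meta.groupby("subject_id", sort=True)
        frame = g.size().to_frame("n")
        if stratify:
            frame["label"] = g[target].agg(lambda v: v.astype(str).mode().iloc[0])
        else:
            frame["label"] = None
        return frame

    rng = np.random.default_rng(seed)
    subj = subject_frame(metadata)
    subj_fold = _assign_subjects(subj, k, rng, stratify)
    outer = metadata["subject_id"].map(subj_fold).astype(int)
    outer.index = metadata.index

    inner: dict[int, pd.Series] = {}
    for f in range(k):
        train_meta = metadata[outer != f]
        n_train_subj = train_meta["subject_id"].nunique()
        ki = min(k_inner, n_train_subj)
        rng_f = np.random.default_rng(np.random.SeedSequence([seed, 1 + f]))
        sf = subject_frame(train_meta)
        sub_fold = _assign_subjects(sf, ki, rng_f, stratify)
        s = train_meta["subject_id"].map(sub_fold).astype(int)
        s.index = train_meta.index
        inner[f] = s
    return FoldPlan(k=k, outer=outer, inner=inner, seed=seed)
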