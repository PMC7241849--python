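"""Vibration-of-effects concordance: do different models rank features alike?

Each (phenotype, data type, algorithm) cell yields an importance-weighted
ranking vector over the filtered feature universe; pairwise Spearman
correlation between those vectors quantifies how much the analytic choice
(algorithm or data type) perturbs which features look important.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .evaluate import ModelResult

__all__ = [
    "ImportanceVector",
    "ConcordanceMatrix",
    "importance_vector",
    "pairwise_spearman",
    "average_concordance",
]


@dataclass
class ImportanceVector:
    """Normalized per-feature importance weights on a fixed feature universe."""

    weights: pd.Series  # index: feature universe; values >= 0, sum 1
    provenance: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        p = self.provenance
        return p.get("label") or "|".join(
            str(p[k]) for k in ("phenotype", "data_type", "estimator") if k in p
        )


def importance_vector(
    result: ModelResult, feature_universe: list[str] | pd.Index
) -> ImportanceVector:
    """Importance weights aligned to a common feature universe.

    Features absent from the model's importance output get weight zero;
    weights are the estimator's native relative importance normalized to sum
    to one.  A model with no usable importances is an explicit error, never a
    silent zero vector.
    """
    if result.importances is None:
        raise ConfigurationError(
            f"{result.estimator} carries no feature importances"
        )
    w = result.importances.reindex(list(feature_universe)).fillna(0.0).astype(float)
    if (w < 0).any():
        raise ConfigurationError("importances must be non-negative")
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ConfigurationError(
            f"degenerate (all-zero) importances for {result.estimator}"
        )
    return ImportanceVector(
        weights=w / total,
        provenance={
            "phenotype": result.phenotype,
            "data_type": result.data_type,
            "estimator": result.estimator,
        },
    )


@dataclass
class ConcordanceMatrix:
    """Symmetric pairwise Spearman matrix with unit diagonal."""

    frame: pd.DataFrame
    grouping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if not f.index.equals(f.columns):
            raise ConfigurationError("concordance matrix must be square and labelled")
        if not np.allclose(f.to_numpy(), f.to_numpy().T, atol=1e-12, equal_nan=True):
            raise ConfigurationError("concordance matrix must be symmetric")
        if not np.allclose(np.diag(f.to_numpy()), 1.0):
            raise ConfigurationError("concordance matrix must have a unit diagonal")


def pairwise_spearman(vectors: list[ImportanceVector], grouping: dict | None = None) -> ConcordanceMatrix:
    """Pairwise Spearman rho between importance vectors (average-rank ties).

    All vectors must share an identical feature universe.
    """
    if len(vectors) < 2:
        raise ConfigurationError("need at least 2 importance vectors")
    universe = vectors[0].weights.index
    for v in vectors[1:]:
        if not v.weights.index.equals(universe):
            raise ConfigurationError("importance vectors on mismatched feature universes")
    labels = [v.label for v in vectors]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate vector labels: {labels}")
    n = len(vectors)
    rho = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = stats.spearmanr(vectors[i].weights.to_numpy(), vectors[j].weights.to_numpy()).statistic
            rho[i, j] = rho[j, i] = r
    return ConcordanceMatrix(
        frame=pd.DataFrame(rho, index=labels, columns=labels), grouping=grouping or {}
    )


def average_concordance(matrix: ConcordanceMatrix) -> pd.Series:
    """Per-label mean of the off-diagonal Spearman rhos involving that label."""
    f = matrix.frame
    if len(f) < 2:
        raise ConfigurationError("average concordance undefined for a single label")
    vals = f.to_numpy().copy()
    np.fill_diagonal(vals, np.nan)
    return pd.Series(np.nanmean(vals, axis=1), index=f.index, name="mean_rho")
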