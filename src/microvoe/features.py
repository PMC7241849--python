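"""Feature engineering: length normalization, canopy co-abundance clustering,
quantile aggregation, univariate filtering and class weighting.

Co-Abundance Groups (CAGs) are clusters of genes whose relative-abundance
profiles co-vary across samples (Pearson correlation >= 0.9 at the default
parameters).  A CAG is summarised into a single feature by taking the 0.75
quantile of its member genes' abundances per sample; pathway features use the
same rule over a many-to-many gene->pathway map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "CanopyParams",
    "CAGAssignment",
    "FilterReport",
    "normalize_counts",
    "canopy_cluster",
    "aggregate_quantile",
    "filter_features",
    "extract_genes_from_top_cags",
    "class_weights",
    "univariate_associations",
]


@dataclass(frozen=True)
class CanopyParams:
    """Canopy clustering parameters (distance = 1 - Pearson correlation)."""

    max_canopy_dist: float = 0.1
    max_close_dist: float = 0.4
    max_merge_dist: float = 0.1
    min_step_dist: float = 0.005
    max_num_canopy_walks: int = 5
    stop_fraction: float = 1.0
    min_correlation: float = 0.9

    def __post_init__(self) -> None:
        for name in ("max_canopy_dist", "max_close_dist", "max_merge_dist", "min_step_dist"):
            v = getattr(self, name)
            if not (0.0 <= v <= 2.0):
                raise ConfigurationError(f"{name} must lie in [0, 2], got {v}")
        if self.max_num_canopy_walks < 0:
            raise ConfigurationError("max_num_canopy_walks must be >= 0")


@dataclass
class CAGAssignment:
    """Many-to-one gene -> group map plus the clustering parameters used."""

    mapping: dict[str, str]
    params: CanopyParams | None = None

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, grp in self.mapping.items():
            out.setdefault(grp, []).append(gene)
        for grp in out:
            out[grp].sort()
        return out

    def sizes(self) -> pd.Series:
        return pd.Series({g: len(m) for g, m in self.groups().items()}).sort_values(
            ascending=False
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.mapping.items()), columns=["gene", "group"]
        )

    def params_dict(self) -> dict | None:
        return asdict(self.params) if self.params is not None else None


@dataclass
class FilterReport:
    """Outcome of univariate feature filtering on a training fold."""

    table: pd.DataFrame  # columns: coef, p_value (index = feature)
    selected: list[str]
    rule: str  # coef-top | p-top | all
    dropped_zero_variance: list[str] = field(default_factory=list)


def normalize_counts(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Length- and depth-normalized relative abundances.

    ``a(g, s) = (c(g, s) / L(g)) / sum_k c(k, s) / L(k)`` — read counts divided
    by gene length, closed to sum to one within each sample.
    """
    lengths = gene_lengths.reindex(counts.columns)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ConfigurationError(f"missing gene lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ConfigurationError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ConfigurationError("counts must be non-negative")
    rate = counts.div(lengths, axis=1)
    totals = rate.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ConfigurationError(
            f"sample(s) with all-zero counts: {zero.index.tolist()[:5]}"
        )
    return rate.div(totals, axis=0)


def _pearson_to_centroid(z: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Correlation of unit-normalized centered rows ``z`` with a raw profile."""
    c = centroid - centroid.mean()
    norm = np.linalg.norm(c)
    if norm == 0:
        return np.zeros(z.shape[0])
    return z @ (c / norm)


def canopy_cluster(gene_table: pd.DataFrame, params: CanopyParams | None = None) -> CAGAssignment:
    """Cluster co-abundant genes into CAGs with canopy clustering.

    Candidate seed genes are processed in order of decreasing mean abundance
    (ties broken lexicographically by gene id).  A canopy collects every gene
    within ``max_canopy_dist`` of its centroid; the centroid (the element-wise
    mean profile of the members) is re-walked up to ``max_num_canopy_walks``
    times, stopping early once it moves less than ``min_step_dist``.  Genes
    within ``max_close_dist`` of a canopy origin are removed from the seed
    pool; canopies whose centroids lie within ``max_merge_dist`` are merged.
    Genes caught by several canopies go to the closest centroid, and
    singleton groups are dropped.
    """
    if params is None:
        params = CanopyParams()
    if gene_table.shape[0] < 2:
        raise ConfigurationError("canopy clustering needs at least 2 samples")

    X = gene_table.to_numpy(float).T  # genes x samples
    genes = np.array(gene_table.columns, dtype=object)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = genes[~keep].tolist()
        logger.warning("excluding %d zero-variance genes from clustering", len(dropped))
        X, genes = X[keep], genes[keep]
    n_genes = X.shape[0]
    if n_genes == 0:
        return CAGAssignment(mapping={}, params=params)

    # unit-normalized centered profiles: correlation is a dot product
    Xc = X - X.mean(axis=1, keepdims=True)
    Z = Xc / np.linalg.norm(Xc, axis=1, keepdims=True)

    mean_ab = X.mean(axis=1)
    order = sorted(range(n_genes), key=lambda i: (-mean_ab[i], genes[i]))

    consumed = np.zeros(n_genes, dtype=bool)  # removed from the seed pool
    canopies: list[tuple[np.ndarray, np.ndarray]] = []  # (member mask, centroid)
    for i in order:
        if consumed[i]:
            continue
        if params.stop_fraction < 1.0 and consumed.mean() >= params.stop_fraction:
            break
        centroid = X[i].copy()
        members = None
        for _ in range(max(1, params.max_num_canopy_walks)):
            corr = _pearson_to_centroid(Z, centroid)
            members = (1.0 - corr) <= params.max_canopy_dist
            new_centroid = X[members].mean(axis=0)
            step = 1.0 - _pearson_to_centroid(
                (new_centroid - new_centroid.mean())[None, :]
                / max(np.linalg.norm(new_centroid - new_centroid.mean()), 1e-30),
                centroid,
            )[0]
            centroid = new_centroid
            if step < params.min_step_dist:
                break
        corr_origin = _pearson_to_centroid(Z, X[i])
        consumed |= (1.0 - corr_origin) <= params.max_close_dist
        consumed[i] = True
        canopies.append((members, centroid))

    if not canopies:
        return CAGAssignment(mapping={}, params=params)

    # merge canopies whose centroids are within max_merge_dist (transitively)
    k = len(canopies)
    cents = np.array([c for _, c in canopies])
    cc = cents - cents.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(cc, axis=1, keepdims=True)
    norms[norms == 0] = 1e-30
    zc = cc / norms
    dist = 1.0 - zc @ zc.T
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(k):
        for b in range(a + 1, k):
            if dist[a, b] <= params.max_merge_dist:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    merged: dict[int, np.ndarray] = {}
    for a in range(k):
        r = find(a)
        mask = canopies[a][0]
        merged[r] = mask if r not in merged else (merged[r] | mask)
    final = []
    for r, mask in merged.items():
        centroid = X[mask].mean(axis=0)
        final.append((mask, centroid))

    # resolve multi-canopy genes to the closest centroid
    fc = np.array([c for _, c in final])
    fcc = fc - fc.mean(axis=1, keepdims=True)
    fnorm = np.linalg.norm(fcc, axis=1, keepdims=True)
    fnorm[fnorm == 0] = 1e-30
    corr_all = Z @ (fcc / fnorm).T  # genes x canopies
    assign = np.full(n_genes, -1)
    for ci, (mask, _) in enumerate(final):
        idx = np.where(mask)[0]
        for g in idx:
            if assign[g] < 0 or corr_all[g, ci] > corr_all[g, assign[g]]:
                assign[g] = ci

    # name groups by decreasing size, drop singletons
    members_by_canopy: dict[int, list[int]] = {}
    for g, ci in enumerate(assign):
        if ci >= 0:
            members_by_canopy.setdefault(ci, []).append(g)
    groups = [m for m in members_by_canopy.values() if len(m) >= 2]
    groups.sort(key=lambda m: (-len(m), genes[min(m, key=lambda g: genes[g])]))
    digits = max(4, len(str(len(groups))))
    mapping: dict[str, str] = {}
    for gi, members in enumerate(groups):
        name = f"CAG{gi:0{digits}d}"
        for g in members:
            mapping[genes[g]] = name
    return CAGAssignment(mapping=mapping, params=params)


def aggregate_quantile(
    gene_table: pd.DataFrame,
    membership: CAGAssignment | Mapping[str, Sequence[str]],
    q: float = 0.75,
) -> pd.DataFrame:
    """Per-sample group abundance: the ``q`` quantile of member-gene abundances.

    Quantiles use linear interpolation between order statistics (the rule
    under which the 0.75 quantile of {0.1, 0.2, 0.3, 0.4} is 0.325).  The
    membership map may be many-to-one (CAGs) or many-to-many (pathways).
    """
    if isinstance(membership, CAGAssignment):
        groups = membership.groups()
    else:
        groups = {g: list(m) for g, m in membership.items()}
    if not groups:
        raise ConfigurationError("empty membership map")
    cols = {}
    for grp in sorted(groups):
        genes = groups[grp]
        if not genes:
            raise ConfigurationError(f"group {grp!r} is empty")
        missing = [g for g in genes if g not in gene_table.columns]
        if missing:
            raise ConfigurationError(f"group {grp!r} refers to unknown genes {missing[:5]}")
        cols[grp] = np.quantile(
            gene_table[genes].to_numpy(float), q, axis=1, method="linear"
        )
    return pd.DataFrame(cols, index=gene_table.index)


def _univariate_linear(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature simple OLS of y on a unit-SD feature; Wald t p-values."""
    n, p = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sxx = (Xc**2).sum(axis=0)
    sxy = Xc.T @ yc
    beta = sxy / sxx
    ss_res = (yc**2).sum() - beta * sxy
    dof = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.maximum(ss_res, 0.0) / dof / sxx)
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, pvals


def _univariate_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature univariate logistic regression, vectorized IRLS.

    Each feature gets its own (intercept, slope) fit; p-values are Wald tests
    on the slope.  Slopes are capped at |b| = 30 to tame perfect separation.
    """
    n, p = X.shape
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    b0 = np.full(p, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + X * b1[None, :], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (X * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X**2).sum(axis=0)
        det = np.maximum(h00 * h11 - h01**2, 1e-12)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        np.clip(b0, -30, 30, out=b0)
        np.clip(b1, -30, 30, out=b1)
        if max(np.abs(d0).max(initial=0), np.abs(d1).max(initial=0)) < tol:
            break
    eta = np.clip(b0[None, :] + X * b1[None, :], -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    h00 = w.sum(axis=0)
    h01 = (w * X).sum(axis=0)
    h11 = (w * X**2).sum(axis=0)
    det = np.maximum(h00 * h11 - h01**2, 1e-12)
    se = np.sqrt(h00 / det)
    z = b1 / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return b1, pvals


def univariate_associations(
    table: pd.DataFrame, target: pd.Series, task: str | None = None
) -> pd.DataFrame:
    """Per-feature scaled coefficient and p-value against the target.

    Every feature is scaled to unit SD first.  Continuous targets use simple
    linear regression (Wald t test); categorical targets use univariate
    logistic regression (Wald z test); multinomial targets use one-vs-rest
    logistic fits, keeping each feature's minimum p-value and the coefficient
    of largest magnitude.  Zero-variance features are excluded.
    """
    target = target.loc[table.index]
    if task is None:
        task = infer_task(target)
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = table.columns[~keep].tolist()
    if dropped:
        logger.warning("excluding %d zero-variance features from filtering", len(dropped))
    Xs = X[:, keep] / sd[keep]
    names = table.columns[keep]

    if task == "regression":
        coef, pvals = _univariate_linear(Xs, target.to_numpy(float))
    elif task == "binary":
        classes = sorted(pd.unique(target.astype(str)))
        if len(classes) != 2:
            raise ConfigurationError(f"binary target has {len(classes)} classes")
        y = (target.astype(str) == classes[1]).to_numpy(float)
        coef, pvals = _univariate_logistic(Xs, y)
    elif task == "multiclass":
        classes = sorted(pd.unique(target.astype(str)))
        coef = np.zeros(Xs.shape[1])
        pvals = np.ones(Xs.shape[1])
        for cls in classes:
            y = (target.astype(str) == cls).to_numpy(float)
            c, p = _univariate_logistic(Xs, y)
            better = p < pvals
            pvals = np.where(better, p, pvals)
            coef = np.where(np.abs(c) > np.abs(coef), c, coef)
    else:
        raise ConfigurationError(f"unknown task {task!r}")

    out = pd.DataFrame({"coef": coef, "p_value": pvals}, index=names)
    out.attrs["dropped_zero_variance"] = dropped
    return out


def infer_task(target: pd.Series) -> str:
    """regression for numeric targets with >2 levels, else binary/multiclass."""
    if pd.api.types.is_numeric_dtype(target) and target.nunique() > 2:
        return "regression"
    return "binary" if target.nunique() == 2 else "multiclass"


def filter_features(
    train_table: pd.DataFrame,
    target: pd.Series,
    max_features: int = 1000,
    alpha: float = 0.05,
    task: str | None = None,
    bonferroni: bool = False,
) -> FilterReport:
    """Univariate dimension-reduction filter, computed on training rows only.

    Selection rules (in order):

    * if fewer than ``max_features`` candidate features exist, keep all;
    * if more than ``max_features`` are associated at ``p < alpha``, keep the
      ``max_features`` with the largest |scaled coefficient| among them;
    * otherwise keep the ``max_features`` smallest p-values (which may include
      non-significant features).

    With ``bonferroni=True`` the significance cut becomes ``alpha / n_features``.
    """
    assoc = univariate_associations(train_table, target, task=task)
    alpha_eff = alpha / len(assoc) if (bonferroni and len(assoc)) else alpha
    n = len(assoc)
    if n <= max_features:
        rule = "all"
        selected = assoc.index.tolist()
    else:
        n_sig = int((assoc["p_value"] < alpha_eff).sum())
        if n_sig > max_features:
            rule = "coef-top"
            sig = assoc[assoc["p_value"] < alpha_eff]
            order = sig.reindex(
                sig["coef"].abs().sort_values(ascending=False, kind="mergesort").index
            )
            selected = order.index[:max_features].tolist()
        else:
            rule = "p-top"
            order = assoc.sort_values(
                ["p_value"], kind="mergesort"
            )
            selected = order.index[:max_features].tolist()
    return FilterReport(
        table=assoc,
        selected=selected,
        rule=rule,
        dropped_zero_variance=assoc.attrs.get("dropped_zero_variance", []),
    )


def extract_genes_from_top_cags(
    importances: pd.Series,
    assignment: CAGAssignment,
    gene_table: pd.DataFrame,
    target: pd.Series,
    task: str | None = None,
    n_cags: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes from the most predictive CAGs, Bonferroni-filtered.

    Takes the ``n_cags`` CAGs with the highest model importance, pools their
    member genes, and keeps genes whose univariate association p-value beats
    ``alpha / n_candidate_genes``.  May return an empty table (with a warning)
    when nothing survives correction.
    """
    nonzero = importances[importances > 0].sort_values(ascending=False, kind="mergesort")
    if len(nonzero) < n_cags:
        logger.warning(
            "only %d CAGs with nonzero importance (requested %d); using all",
            len(nonzero),
            n_cags,
        )
    top = nonzero.index[:n_cags].tolist()
    groups = assignment.groups()
    genes = sorted({g for cag in top for g in groups.get(cag, []) if g in gene_table.columns})
    if not genes:
        logger.warning("top CAGs contribute no genes present in the table")
        return gene_table.iloc[:, :0]
    assoc = univariate_associations(gene_table[genes], target, task=task)
    cut = alpha / len(genes)
    keep = assoc.index[assoc["p_value"] < cut].tolist()
    if not keep:
        logger.warning("no gene passes Bonferroni at %.3g / %d", alpha, len(genes))
    return gene_table[keep]


def class_weights(labels: pd.Series) -> pd.Series:
    """Per-sample weights inversely proportional to class frequency, mean 1.

    ``w(c) = (n / n_c) / k`` for ``k`` classes, so the weights of an 80/20
    split are 0.625 and 2.5 and the weighted sample count equals ``n``.
    """
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ConfigurationError("class weighting needs at least 2 classes")
    n, k = len(labels), len(counts)
    per_class = (n / counts) / k
    return labels.map(per_class).astype(float)
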