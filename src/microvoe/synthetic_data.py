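"""Synthetic infant-gut metagenomics study generator.

Emulates the statistical structure of a longitudinal, multi-cohort infant
microbiome study: repeated stool samples per infant across four European
cohorts, block-structured co-abundant gene groups on a compositional scale,
and planted (linear, threshold or unimodal) phenotype effects.  It produces
the three inputs every downstream stage consumes — a sample-metadata table, a
gene relative-abundance matrix, and a taxon-level matrix — together with the
ground-truth gene→block assignment, so the whole pipeline is testable without
any sequencing data.

Generative model
----------------
Each co-abundance block ``k`` has a latent per-sample log-factor

    f_k(s) = u_k(subject(s)) + e_k(s) + sum of planted effect terms,

with a subject-level random intercept ``u`` (repeated-measures correlation)
and sample-level noise ``e``.  A member gene ``g`` of block ``k`` has

    log x_g(s) = a_g + f_k(s) + sigma_g * eps_g(s),

where ``a_g`` is a heavy-tailed gene baseline and ``sigma_g`` is set from the
block's within-block correlation target.  Abundances are exponentiated and
closed to sum to one per sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .features import CAGAssignment

__all__ = [
    "StudyDesign",
    "Block",
    "Effect",
    "SignalSpec",
    "generate_metadata",
    "generate_gene_abundances",
    "generate_taxa_abundances",
    "write_tables",
]

#: cohort label -> (country, sampling probability); mirrors a four-cohort
#: European infant study (Sweden, Finland, Russia, Estonia).
DEFAULT_COHORTS: dict[str, tuple[str, float]] = {
    "cohort_sweden": ("Sweden", 0.30),
    "cohort_finland": ("Finland", 0.30),
    "cohort_russia": ("Russia", 0.20),
    "cohort_estonia": ("Estonia", 0.20),
}

#: class used as the "exposed" level when a binary phenotype drives a block.
POSITIVE_CLASS = {
    "sex": "male",
    "delivery": "cesarean",
    "breastfed": "yes",
    "antibiotics": "yes",
}

DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "sex": {"female": 0.5, "male": 0.5},
    # cesarean deliveries are the rare class (~10% of samples in the cohorts
    # this generator emulates)
    "delivery": {"cesarean": 0.1, "vaginal": 0.9},
    "antibiotics": {"no": 0.6, "yes": 0.4},
}

# latent block-factor standard deviation on the log scale; the subject random
# intercept accounts for ``SUBJECT_SHARE`` of the factor variance
FACTOR_SD = 0.5
SUBJECT_SHARE = 0.3


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout of the simulated study."""

    n_subjects: int = 300
    samples_per_subject: tuple[int, int] = (2, 8)
    cohorts: Mapping[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COHORTS)
    )
    age_range_days: tuple[float, float] = (30.0, 1095.0)
    phenotype_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PREVALENCES.items()}
    )
    #: exclusive breastfeeding stops at a subject-level weaning age drawn
    #: uniformly from this range (days)
    weaning_range_days: tuple[float, float] = (60.0, 360.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        lo, hi = self.samples_per_subject
        if not (1 <= lo <= hi):
            raise ConfigurationError("samples_per_subject must satisfy 1 <= lo <= hi")
        if self.age_range_days[0] >= self.age_range_days[1]:
            raise ConfigurationError("age_range_days must be increasing")
        probs = [p for _, p in self.cohorts.values()]
        if abs(sum(probs) - 1.0) > 1e-8:
            raise ConfigurationError("cohort probabilities must sum to 1")
        for phen, prev in self.phenotype_prevalences.items():
            total = sum(prev.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"prevalences for {phen!r} sum to {total}, expected 1"
                )


@dataclass(frozen=True)
class Block:
    """A planted co-abundance block of genes."""

    block_id: str
    n_genes: int
    rho: float = 0.95  # within-block Pearson correlation target

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ConfigurationError("within-block correlation target must be in (0,1]")
        if self.n_genes < 1:
            raise ConfigurationError("block must contain at least one gene")


@dataclass(frozen=True)
class Effect:
    """A planted phenotype effect on a block's latent factor.

    ``size`` is the shift of the block log-factor in units of the factor SD:
    for a binary phenotype it is the (approximate) log-odds shift per SD of
    block abundance; for age, ``linear`` adds ``size * z(age)``, ``threshold``
    a step at mid-age and ``unimodal`` a Gaussian bump centred at mid-age.
    """

    block_id: str
    phenotype: str
    size: float
    form: str = "linear"  # linear | threshold | unimodal
    center: float | None = None  # unimodal bump location (age days); default mid-range
    width: float | None = None  # unimodal bump SD (age days); default range/8

    def __post_init__(self) -> None:
        if not np.isfinite(self.size):
            raise ConfigurationError("effect size must be finite")
        if self.form not in ("linear", "threshold", "unimodal"):
            raise ConfigurationError(f"unknown effect form {self.form!r}")


@dataclass(frozen=True)
class SignalSpec:
    """Block structure and planted signal of the gene matrix."""

    blocks: Sequence[Block] = ()
    effects: Sequence[Effect] = ()
    noise_sd: float = 1.0  # gene baseline spread (log scale)
    n_background_genes: int = 0  # unblocked, independent genes
    null: bool = False

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.null and self.effects:
            raise ConfigurationError("null spec must carry no effects")
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate block ids")
        known = set(ids)
        for e in self.effects:
            if e.block_id not in known:
                raise ConfigurationError(f"effect refers to unknown block {e.block_id!r}")

    @property
    def n_genes(self) -> int:
        return sum(b.n_genes for b in self.blocks) + self.n_background_genes


def _draw_categorical(rng: np.random.Generator, prev: Mapping[str, float], n: int) -> np.ndarray:
    labels = sorted(prev)
    probs = np.array([prev[k] for k in labels], dtype=float)
    return rng.choice(np.array(labels, dtype=object), size=n, p=probs)


def generate_metadata(design: StudyDesign) -> pd.DataFrame:
    """Per-sample metadata table for a simulated study.

    Subject-level attributes (cohort, country, sex, delivery type) are
    constant across a subject's repeated samples; age increases strictly
    within each subject; exclusive breastfeeding switches off at a
    subject-level weaning age; antibiotic exposure switches on at a random
    onset for ever-exposed subjects.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    prev = design.phenotype_prevalences

    cohort_labels = list(design.cohorts)
    cohort_probs = np.array([design.cohorts[c][1] for c in cohort_labels])

    lo, hi = design.samples_per_subject
    n_samples = rng.integers(lo, hi + 1, size=design.n_subjects)
    cohort = rng.choice(np.array(cohort_labels, dtype=object), size=design.n_subjects, p=cohort_probs)
    sex = _draw_categorical(rng, prev.get("sex", DEFAULT_PREVALENCES["sex"]), design.n_subjects)
    delivery = _draw_categorical(
        rng, prev.get("delivery", DEFAULT_PREVALENCES["delivery"]), design.n_subjects
    )
    ab_prev = prev.get("antibiotics", DEFAULT_PREVALENCES["antibiotics"])
    ever_antibiotics = rng.random(design.n_subjects) < ab_prev.get("yes", 0.4)

    a_lo, a_hi = design.age_range_days
    w_lo, w_hi = design.weaning_range_days
    weaning = rng.uniform(w_lo, w_hi, size=design.n_subjects)
    ab_onset = rng.uniform(a_lo, a_hi, size=design.n_subjects)

    rows = []
    counter = 0
    for j in range(design.n_subjects):
        subject = f"subj{j:04d}"
        m = int(n_samples[j])
        ages = np.sort(rng.uniform(a_lo, a_hi, size=m))
        # enforce strictly increasing ages within the subject
        ages = np.maximum.accumulate(ages + np.arange(m) * 1e-6)
        for t in range(m):
            rows.append(
                {
                    "sample_id": f"S{counter:05d}",
                    "subject_id": subject,
                    "cohort": cohort[j],
                    "country": design.cohorts[cohort[j]][0],
                    "age_days": float(round(ages[t], 3)),
                    "sex": sex[j],
                    "delivery": delivery[j],
                    "breastfed": "yes" if ages[t] < weaning[j] else "no",
                    "antibiotics": "yes" if (ever_antibiotics[j] and ages[t] >= ab_onset[j]) else "no",
                }
            )
            counter += 1
    return pd.DataFrame(rows).set_index("sample_id")


def _age_covariate(ages: np.ndarray, design: StudyDesign, eff: Effect) -> np.ndarray:
    a_lo, a_hi = design.age_range_days
    mid = 0.5 * (a_lo + a_hi)
    if eff.form == "linear":
        # standardized against the uniform age distribution of the design
        return (ages - mid) / ((a_hi - a_lo) / np.sqrt(12.0))
    if eff.form == "threshold":
        return (ages > mid).astype(float)
    if eff.form == "unimodal":
        center = mid if eff.center is None else eff.center
        width = (a_hi - a_lo) / 8.0 if eff.width is None else eff.width
        return np.exp(-((ages - center) ** 2) / (2.0 * width**2))
    raise ConfigurationError(f"unknown effect form {eff.form!r}")


def _effect_covariate(eff: Effect, metadata: pd.DataFrame, design: StudyDesign) -> np.ndarray:
    if eff.phenotype in ("age", "age_days"):
        return _age_covariate(metadata["age_days"].to_numpy(float), design, eff)
    col = metadata[eff.phenotype].to_numpy(object)
    positive = POSITIVE_CLASS.get(eff.phenotype)
    if positive is None:
        # fall back to the lexicographically last level
        positive = sorted(set(col))[-1]
    return (col == positive).astype(float)


def generate_gene_abundances(
    design: StudyDesign,
    signal: SignalSpec,
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CAGAssignment]:
    """Gene relative-abundance matrix plus the ground-truth block assignment.

    Returns a (samples x genes) DataFrame whose rows sum to one, and a
    :class:`~microvoe.features.CAGAssignment` mapping each blocked gene to its
    generating block (background genes are unassigned).
    """
    design.validate()
    signal.validate()
    if metadata is None:
        metadata = generate_metadata(design)
    if signal.n_genes < 1:
        raise ConfigurationError("signal spec describes no genes")

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7_919]))
    n = len(metadata)
    subjects = metadata["subject_id"].to_numpy(object)
    subj_ids, subj_idx = np.unique(subjects, return_inverse=True)

    n_blocked = sum(b.n_genes for b in signal.blocks)
    n_genes = signal.n_genes
    digits = max(4, len(str(n_genes)))
    gene_names = [f"gene{g:0{digits}d}" for g in range(n_genes)]

    # precompute effect covariates per block
    block_effect = {b.block_id: np.zeros(n) for b in signal.blocks}
    for eff in signal.effects:
        cov = _effect_covariate(eff, metadata, design)
        block_effect[eff.block_id] = block_effect[eff.block_id] + eff.size * FACTOR_SD * cov

    log_x = np.empty((n, n_genes))
    mapping: dict[str, str] = {}
    gene_pos = 0
    sd_subj = FACTOR_SD * np.sqrt(SUBJECT_SHARE)
    sd_samp = FACTOR_SD * np.sqrt(1.0 - SUBJECT_SHARE)
    for b in signal.blocks:
        u = rng.normal(0.0, sd_subj, size=len(subj_ids))
        f = u[subj_idx] + rng.normal(0.0, sd_samp, size=n) + block_effect[b.block_id]
        # latent (log-scale) correlation target, lifted above the abundance
        # scale target to survive exponentiation and closure
        rho_latent = b.rho + 0.5 * (1.0 - b.rho)
        sigma_g = FACTOR_SD * np.sqrt((1.0 - rho_latent) / rho_latent)
        base = rng.normal(0.0, signal.noise_sd, size=b.n_genes)
        eps = rng.normal(0.0, 1.0, size=(n, b.n_genes))
        log_x[:, gene_pos : gene_pos + b.n_genes] = (
            base[None, :] + f[:, None] + sigma_g * eps
        )
        for g in range(b.n_genes):
            mapping[gene_names[gene_pos + g]] = b.block_id
        gene_pos += b.n_genes

    if signal.n_background_genes:
        base = rng.normal(0.0, signal.noise_sd, size=signal.n_background_genes)
        eps = rng.normal(0.0, FACTOR_SD, size=(n, signal.n_background_genes))
        log_x[:, n_blocked:] = base[None, :] + eps

    x = np.exp(log_x)
    x /= x.sum(axis=1, keepdims=True)
    table = pd.DataFrame(x, index=metadata.index, columns=gene_names)
    truth = CAGAssignment(mapping=mapping, params=None)
    return table, truth


def generate_taxa_abundances(gene_table: pd.DataFrame, truth: CAGAssignment) -> pd.DataFrame:
    """Taxon-level matrix: one taxon per ground-truth block.

    A taxon's abundance is the sum of its member genes' relative abundances,
    renormalized so every row sums to one (background genes outside any block
    are dropped by the renormalization).
    """
    groups = truth.groups()
    if not groups:
        raise ConfigurationError("assignment contains no blocks")
    cols = {}
    for block_id in sorted(groups):
        genes = [g for g in groups[block_id] if g in gene_table.columns]
        if not genes:
            raise ConfigurationError(f"block {block_id!r} has no genes in the table")
        cols[f"taxon_{block_id}"] = gene_table[genes].sum(axis=1)
    taxa = pd.DataFrame(cols, index=gene_table.index)
    taxa = taxa.div(taxa.sum(axis=1), axis=0)
    return taxa


def write_tables(
    out_dir: str | Path,
    metadata: pd.DataFrame,
    tables: Mapping[str, pd.DataFrame],
    truth: CAGAssignment | None = None,
) -> None:
    """Write metadata/abundance tables as TSV (samples as rows) and truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    for name, table in tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t")
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(truth.mapping, indent=0, sort_keys=True))
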