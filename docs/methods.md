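# Methods

This note documents the statistical procedures the package implements, the
assumptions behind the synthetic-data generator, the numerical choices that
were genuinely open, and what the validation studies do and do not show.

## Feature engineering

**Length/depth normalization.** Raw read counts `c(g, s)` are converted to
relative abundances `a(g, s) = (c(g, s)/L(g)) / Σ_k c(k, s)/L(k)` with `L(g)`
the gene length in bp: longer genes attract proportionally more reads, and
dividing by the per-sample total removes sequencing-depth differences.  Every
abundance table is compositional (rows sum to one).

**Canopy clustering into CAGs.** Genes whose abundance profiles co-vary are
grouped with canopy clustering on the distance `d = 1 − Pearson(r)`.
Parameters (defaults): `max_canopy_dist 0.1`, `max_close_dist 0.4`,
`max_merge_dist 0.1`, `min_step_dist 0.005`, `max_num_canopy_walks 5`,
`stop_fraction 1` — so members correlate with their canopy centroid at
`r ≥ 0.9`.  Choices the published parameterization leaves open, fixed here
for determinism: candidate seed genes are processed in order of decreasing
mean abundance (ties lexicographic by gene id); the centroid is the
element-wise mean profile of the members, re-walked until it moves less than
`min_step_dist`; canopies whose centroids lie within `max_merge_dist` are
merged transitively; a gene caught by several canopies is assigned to the
closest centroid; singleton groups are dropped.  Zero-variance genes (Pearson
undefined) are excluded with a warning.  The contract is validated against a
brute-force oracle — connected components of the `r ≥ 0.9` graph — on
planted two-block matrices, not against any external implementation's
internals.

**Quantile aggregation.** A CAG's (or pathway's) per-sample abundance is the
0.75 quantile of its member genes, using linear interpolation between order
statistics (the rule under which the 0.75 quantile of {0.1, 0.2, 0.3, 0.4}
is 0.325).  This convention is declared once and used everywhere.  Pathway
membership may be many-to-many.

**Univariate filtering.** On each training fold only, every feature is scaled
to unit SD and regressed one-at-a-time against the target (linear regression
with a Wald t test for continuous targets; univariate logistic regression
with a Wald z test for binary; one-vs-rest logistic for multinomial, keeping
each feature's smallest p and largest |coefficient|).  Selection: all
features if fewer than 1,000 exist; the 1,000 largest |scaled coefficient|
among those with p < 0.05 when more than 1,000 are significant; otherwise
the 1,000 smallest p-values.  A Bonferroni variant (`alpha/n_features`) is
selectable and is the default for the gene-extraction step.  The per-feature
logistic fits use a vectorized IRLS over all features simultaneously, with
slopes capped at |b| = 30 to tame perfect separation.

**Class weights.** Classification samples are weighted inversely to their
class frequency, normalized to mean one: `w(c) = (n/n_c)/k` for `k` classes,
so an 80/20 split weights samples 0.625 and 2.5 and `Σ w(c)·n_c = n`.

## Cross-validation design

Repeated samples of one infant share a strong personal signature; grouping by
subject is therefore primary.  Fold planning is greedy bin packing: subjects
sorted by decreasing sample count (ties broken by a seeded permutation) are
assigned to the fold with the fewest subjects of their class, then the
fewest samples.  Stratification uses the subject's majority class, since
breastfeeding and antibiotic status can change across a subject's samples;
continuous targets balance subject counts only.  Inner folds are built the
same way inside each outer training set with a seed derived from the outer
seed and fold index.  Demographic predictors are one-hot encoded (with an
optional reference-level drop for linear models); the target phenotype is
never among the predictors.

## Estimators and tuning

Eleven configurations over eight families, all behind one fit/predict
adapter: elastic net (coordinate-descent / saga solvers; λ and the l1 ratio
tuned), a second elastic net (SGD-based, λ only, l1 ratio 0.5), random
forest (mtry fraction tuned), RF2 (1001 trees; sample size 0.632·n for
regression, per-class sampling capped at the smallest class for
classification; mtry selected by inner CV over the geometric ladder
`round(p·0.9^j)` down to 1), GBM (tree count and depth tuned), GBM2 (depth 1,
≥10 observations per leaf, shrinkage 0.1, 1000 trees initially — doubled
while the best validation iteration falls in the last 10% of iterations *and*
the last decile's mean performance improves on the previous decile by ≥0.1%,
capped at 16× to bound runtime), SVMs with linear / degree-2 polynomial /
radial kernels (C, and γ for RBF, tuned on log₂ grids), KNN (k tuned), and
Gaussian naive Bayes (variance smoothing tuned; classification only).
Linear, SVM and KNN models standardize inputs inside the fold; tree models
and naive Bayes see raw abundances.

Tuning happens on each hyperparameter's *raw* axis; a monotone transform
(identity, 2^x, 10^x, or custom) maps raw grid points to estimator values,
so log-scale parameters get log-scale fine grids.  The three stages:

1. **Coarse grid** — the Cartesian product of `lo, lo+stride, …, hi` per
   hyperparameter, transformed.
2. **Pseudo-gradient exploration** — while the best value of any
   hyperparameter sits on the boundary of its explored range and that
   boundary is not a (possibly shrunken) hard limit, the range is extended
   one stride outward; the other hyperparameters are held at the values
   occurring in combinations tied for the best score (scores compared after
   rounding to 6 decimals).  An evaluation failure at an extension point
   shrinks that hyperparameter's explorable limit to the last good value.
   A safety cap of 200 extensions bounds the walk when a hyperparameter has
   no finite hard limit.
3. **Fine tuning** — per hyperparameter: if several values tie for best, the
   fine grid spans their extrema inclusively; otherwise it spans the open
   interval between half a stride below the best value and the second-best
   value (or half a stride on both sides when no distinct second-best
   exists), with `n_fine` points.

The inner objective is the mean task metric (R² / ROC AUC / mean class
accuracy) over subject-grouped inner folds; folds where the metric is
undefined are skipped.  Whenever a better combination is found, the model is
refitted on the full training set and must produce non-NaN predictions on
its own training rows; otherwise the incumbent best is retained and the
rejection recorded in the trace.  The trace keeps every evaluated
combination exactly once, the per-hyperparameter explored ranges, shrunken
limits with reasons, and the best combination per stage.

## Evaluation

Headline performance is computed on the concatenation of all outer test-fold
predictions — the non-leaking reading of a nested design (an alternative
"test the final model on the entire dataset" reading would score samples
with models that saw them in training, and is deliberately not implemented).
Uncertainty is the SD of the metric over 1,000 bootstrap resamples of the
pooled predictions; resamples on which the metric is undefined (a single
class drawn) are redrawn and counted.  Binary tasks score by ROC AUC
(Mann–Whitney form, ties counting ½) on probabilities or decision values;
when a model yields class labels but NaN probabilities (the naive Bayes
case) the label-based mean class accuracy is reported instead and the
probability metric marked missing.  Multiclass tasks report mean class
accuracy (unweighted mean of per-class recall) as the headline, with plain
accuracy available.  If a batch prediction contains NaN, each sample is
re-predicted individually and samples that remain NaN are excluded with
their ids recorded.  An experimental model "significantly" beats the
baseline when the two `point ± 1 bootstrap SD` intervals do not overlap — a
deliberately simple heuristic matching the `±` convention of the summary
table, not a formal test.

## Concordance

For each (phenotype, data type, algorithm) cell, per-fold importances —
|standardized coefficients| for the elastic nets, impurity importances for
the tree families, permutation importance (metric degradation) as an opt-in
fallback for SVM/KNN/NB — are averaged over outer folds, aligned to the
union feature universe (absent features get weight 0) and normalized to sum
to one.  Pairwise Spearman correlation with average-rank ties gives the
concordance matrix; a data type's consistency is the mean off-diagonal
correlation of its cross-algorithm matrix.  Gene features are excluded from
concordance, because the gene set is re-derived per phenotype from that
phenotype's top CAGs and therefore not comparable across models.

## Synthetic-data generator

The generator emulates a longitudinal four-cohort infant study: subjects
drawn into cohorts (country tied to cohort), subject-constant sex and
delivery type (cesarean prevalence 0.10 — the rare class), strictly
increasing ages within subject over the first three years, exclusive
breastfeeding ending at a subject-level weaning age, and antibiotic exposure
switching on at a subject-level onset.

Gene abundances follow a log-normal block-factor model: block `k` has a
latent per-sample log-factor with a subject random intercept (30% of the
factor variance, giving repeated-measures correlation) plus sample noise;
member genes add a heavy-tailed baseline and gene-level noise calibrated so
that the *abundance-scale* within-block Pearson correlation meets the target
(the latent log-scale correlation is lifted above the target to survive
exponentiation and closure).  Planted effects shift a block's log-factor by
`size` factor-SDs: linearly in standardized age, as a step at mid-age, as a
Gaussian bump (configurable centre and width), or between the classes of a
binary phenotype — in which case `size` approximates the log-odds shift per
SD of block abundance.  All rows are closed to sum to one.

Known limitations: taxa are one-per-block sums (no phylogeny, no shared
genes between taxa); no strain-level variation, no sequencing error, no
zero-inflation; closure makes a block spanning the *whole* composition lose
its shared factor to the denominator, so correlation targets apply to blocks
embedded in a larger gene background — the regime the study designs use.
Passing tests on these data show the pipeline's machinery is correct and
calibrated, not that real metagenomes satisfy the generative assumptions.

## Validation studies (frozen designs)

Scaled to run in minutes on one CPU; sizes are stated with each result.

* **Null calibration** — 70 subjects × 2–3 samples, 200 genes in 40 blocks,
  no effects, 4 seed replicates (3 in the acceptance script), 5 outer folds,
  per-family default hyperparameters.  Check: each family's seed-mean pooled
  AUC within 2 bootstrap SDs of 0.5 (the seed-mean is used because a
  per-seed check at 2 SDs would fail ~5% of the 110 family×seed combinations
  by construction even for a perfect pipeline), and seed-mean age R² ≤ 0.05.
* **Signal recovery** — 80 subjects, 100 blocks × 4 genes, 10 blocks shifted
  by 1.5 factor-SDs between sex classes; elastic net / RF / GBM with coarse
  tuning.  Check: best microbiome model beats the demographics baseline with
  non-overlapping ±1-SD intervals, and ≥7 of the 10 driven blocks appear in
  the top-25 CAG importances (CAGs mapped to generating blocks by majority
  gene membership).
* **Non-linear advantage** — 110 subjects, 20 blocks × 6 genes; 8 blocks
  carry a Gaussian age bump (size 5, width = range/6) and 2 blocks a strong
  log-linear trend (size 2.5) whose abundance-scale response is exponential.
  Recovering age requires combining a curved monotone response with the
  bumps' distance-from-mid information; the random forest's pooled R²
  exceeds the elastic net's by well over 0.05 on the same folds.  A design
  with only mid-centred bumps is uninformative for *every* model (the
  inverse map is two-valued), and weak linear side-channels are absorbed by
  the elastic net as efficiently as by trees, so this combined design is the
  smallest one where the non-linear advantage is identifiable at desk scale.
* **Oracle checks** — canopy vs. exhaustive threshold clustering on planted
  two-block matrices (100 seeds); quantile aggregation vs. direct
  order-statistics interpolation (1,000 random groups); bootstrap SD at
  B = 100,000 vs. exact enumeration of all 4⁴ resamples of a 4-prediction
  set; tuner vs. exhaustive search at fine-grid resolution on 50 random
  unimodal 1-D/2-D loss surfaces; 100 fold plans with zero subjects spanning
  outer folds; byte-identical summary tables on re-run.

## Degenerate inputs and numerical choices

Pearson correlation requires ≥2 samples and nonzero variance (zero-variance
features are excluded, logged).  R² requires nonzero truth variance and may
be negative out of sample.  ROC AUC requires both classes; bootstrap
resamples violating this are redrawn.  Logistic slopes are capped at |b|=30;
2×2 IRLS solves are regularized by a 1e-12 determinant floor.  Scores are
compared for ties after rounding to 6 decimals.  All randomness flows from
explicit integer seeds; per-cell seeds derive from the master seed by CRC32
hashing of the cell label, keeping every seed below 2³¹.
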