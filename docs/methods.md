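# Methods

`qsarselect` implements a wrapper-style descriptor-selection pipeline for
small, imbalanced QSAR classification problems: a few dozen to a few
hundred assayed molecules described by ~1500 computed molecular
descriptors, with a binary endpoint such as toxic/non-toxic or circadian
period lengthener/no-changer. The goal is not a single fitted model but a
small, stable descriptor subset whose cross-validated accuracy is
defensible given n << p.

## Model and procedure

**Cleaning.** Descriptors with non-finite entries are removed (not
imputed), then descriptors taking a single value across all molecules are
removed. Constancy is exact-equality: descriptors are deterministic
computations, so a tolerance would only mask distinct values.

**Class weighting.** With n molecules, n₊ positive and n₋ negative, each
training example receives the balanced inverse-class-size weight

    w₊ = n / (2 n₊),    w₋ = n / (2 n₋)

so each class carries exactly half of the training mass
(n₊w₊ = n₋w₋ = n/2). For 56 positives of 171 this gives (1.53, 0.74) at
two decimals; for 27 of 90, (1.67, 0.71). Weights are used at full
precision during training and rounded only in reports. They enter every
learner through `fit(sample_weight=...)`, including gradient boosting, so
the mechanism is uniform across families. Evaluation accuracy is always
the unweighted fraction of correct test predictions — weights shape
training, not the metric.

**Recursive feature elimination.** Four tree-based families act both as
RFE estimators and as final classifiers: a single decision tree (DTC),
random forest (RFC), extremely randomized trees (ETC), and
gradient-boosted trees (XGBC). Each RFE round fits the estimator on the
surviving descriptors and eliminates the one with the smallest split-gain
importance (the only importance all four expose natively). One feature
per round maximizes ranking resolution and makes the tail slices of the
elimination order a nested family of sets, which the cardinality sweep
(|S| = 2..20, 19 sets) exploits. Importance ties eliminate the
lexicographically last name — an arbitrary but auditable rule; it is
exercised constantly because trees assign zero importance to unused
features.

**Tuning and replicated CV.** Per feature set, hyperparameters are tuned
by exhaustive grid search scored by mean accuracy over stratified 10-fold
CV; the default grids are wide for the single tree (max_depth 1..10/None,
min_samples_split 2..10, min_samples_leaf 1..10, max_features
1..|S|), narrower for the forests (max_depth 1..6/None,
min_samples_split 2..5, min_samples_leaf 1..5, max_features
1..⌊√|S|⌋, 100/200 trees), and cover learning rate 0.01/0.1, depth
3/5/7/10, min_child_weight 1/3/5, row/column subsampling 0.5/0.7 and
100/200 rounds for boosting. Grid ties prefer the smaller model (lower
depth, then fewer trees, then grid order). The tuned model is then scored
by replicated stratified 10-fold CV: replication r reshuffles folds and
reseeds the learner with `base_seed + r`, and the replication's accuracy
is the pooled percent of correct test predictions. Folds are stratified
because with 27 positives in 90 molecules an unstratified split can
produce positive-free folds; a draw that leaves a training fold
single-class is discarded and redrawn with an offset seed.

**Selection rule.** The sweep yields a cardinality × family matrix of
mean accuracies. Human judgment calls of the form "nearly as accurate
with fewer descriptors" are encoded as an explicit parsimony tolerance
(default 0.5 percentage points): among all cells within the tolerance of
the matrix maximum, the smallest cardinality wins, then the higher mean,
then family order. The winner is therefore never more than the tolerance
below the maximum.

**Greedy backward pruning.** RFE sets are not optimal, so the selected
set is refined: at each step every single-descriptor deletion is scored
by replicated CV and the deletion with the highest mean accuracy is
committed. All candidates within a step share the same replication
seeds, so comparisons are paired (a large variance reduction at zero
cost). Ties prune the candidate with the smaller standard deviation,
then the lexicographically first name. Pruning deliberately continues
past the accuracy peak — by default until the mean has declined for two
consecutive steps (`extra_steps`), or cardinality 2 — so the trace
documents the decline; the returned set is the argmax over the trace.
Optionally a named hyperparameter (typically `max_depth`, whose optimum
shrinks with the set) is retuned by a 1-D sweep at each step, and the
recorded row reflects the retuned estimator.

**Final validation.** The chosen model/set is re-scored with a high
replication count (default 10,000). The accuracy distribution is
summarized by a histogram and a moment-fitted normal: μ is the sample
mean, σ the sample standard deviation (ddof=1).

## Synthetic data

Real descriptor matrices for specific assay campaigns are rarely
published, so the generator produces tables with the structure the
pipeline assumes, plus recorded ground truth:

- exact class counts: the positive count is `round(positive_fraction·n)`
  (presets: 56 of 171 at 33%, 27 of 90 at 30%);
- a constant block (presets 334 or 360 of 1538) mimicking descriptors
  undefined for the chemistry at hand;
- a small informative subset driving the label through one of three
  boundaries: `axis_threshold` (quantile cut on one descriptor —
  separable by a depth-1 tree), `additive_threshold` (default; quantile
  cut on the sum of the informative block — learnable by shallow trees
  but not by any single split), and `xor_pair` (cut on a two-descriptor
  product — invisible to stumps, used to test that tuning can tell depths
  apart). Informative descriptors outside the boundary score get a
  class-conditional mean shift of 1.5 SD;
- redundant descriptors: noisy copies of informative ones with
  population correlation equal to `block_correlation` (default 0.9),
  emulating the heavily collinear autocorrelation/Burden families;
- pure-noise descriptors, standard normal except a 20% minority of
  integer count-like (Poisson) columns echoing the mixed descriptor
  types;
- label noise as **count-preserving swaps**: `round(noise·n/2)` positives
  and equally many negatives exchange labels, so printed imbalances stay
  exact while ~`noise·n` molecules are mislabeled.

What the generator does *not* emulate: real descriptor marginals and
their heavy tails, structure-driven correlation beyond pairwise copies,
activity cliffs, assay-specific label error structure. Passing the
recovery benchmarks therefore shows the selection machinery works on
data with planted, recoverable signal — not that any particular accuracy
level transfers to a real campaign.

`recovery_score` is the fraction of a selected set that is informative
or a redundant copy of an informative descriptor.

## Drug-likeness filter

The docking pre-filter eliminates a molecule iff hbd > 7, hba > 12,
mw > 600 Da, logP > 7, rotatable bonds > 8, aromatic rings < 3, or total
rings < 4. Inequalities are strict (values exactly at a bound pass); the
ring *minima* reflect that the targeted pockets are large and favor
multi-ring scaffolds. Molecules with missing or invalid properties are
reported as errors, never silently kept. Property computation from
SMILES is an optional RDKit adapter; the core filter consumes a plain
property table.

## Reproducibility and numerical choices

Every random decision derives arithmetically from one base seed
(`workflow.derive_seed`: stage offset plus index mixing, mod 2³¹);
replication r of any CV uses `base_seed + r`. All learners run
single-threaded. Two runs with the same config and seed produce
byte-identical CSV/JSON artifacts — this is asserted in the tests.
Accuracy is reported on the 0–100 percent scale. Summary statistics are
always recomputable from the stored per-replication record. Standard
deviations use ddof=1; single-replication results report std 0.

## Benchmark scales

Two frozen configurations (`workflow.shape_benchmark_config`,
`workflow.recovery_benchmark_config`) exercise the pipeline on a
171 × 300 synthetic table (8 informative + 20 redundant descriptors, 30
constant, 5% label swaps, 33% positive). The shape benchmark runs all
four families with small ensembles (20 trees; 30-round boosting) and 2
sweep replications, ~1 minute end to end. The recovery benchmark runs
the extremely-randomized-trees family (20 trees, 3 sweep/pruning
replications, 50 final replications), ~1 minute per seed, averaged over
10 seeds. Single decision trees rank features too unstably at this n/p
to recover the planted subset reliably, which is itself the expected
behavior — ensembles are the appropriate RFE estimator at this scale;
the full grids and 100/10,000-replication counts remain the package
defaults for full-scale runs.

## Known limitations

- Grid search at the default grids is exhaustive and expensive for the
  single-tree family at large max_features ranges; use `grid_overrides`
  or `tune=False` + `fixed_params` for exploratory runs.
- The pruning stopping rule (consecutive-decline count) is a heuristic;
  the argmax set over the trace is returned regardless, so the rule only
  bounds how far past the peak the trace documents.
- Accuracy is the only metric, by design; with heavier imbalance than
  ~1:2 a weighted or rank-based metric would be more appropriate.
- The generator's exact-count label swaps make per-molecule flip
  probability slightly different from the nominal rate for small n.
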