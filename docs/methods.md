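# Methods

This note records the models the package implements, the conventions and
defaults it commits to, and what its synthetic benchmarks do and do not
demonstrate.

## Problem setting

A binary clinical table: n patients, p numeric features, two classes of
unequal size.  Classifiers trained on such tables favour the majority
class; the package's subject is the data-level remedy — resample the table
so the classes balance, then clean the boundary — and the evaluation and
comparison machinery needed to say whether one resampler beats another.

All distances are plain Euclidean on raw feature values.  The source
protocol is silent on scaling, and clinical tables in this literature are
routinely used unscaled, so unscaled is the default; exact distance ties
are broken by ascending row index, which makes every neighbour query
deterministic and seed-independent.

## Resamplers

**SMOTE** (`k_neighbors=5`, `target_ratio=1.0`).  Minority seeds are cycled
round-robin in dataset row order; for each synthetic point the generator
draws a uniform neighbour slot among the seed's k minority-class nearest
neighbours, then a coefficient r ~ U(0,1), and emits
x_new = x_seed + r·(x_nb − x_seed).  Synthesis stops when the minority
count reaches round(target_ratio × majority count), so a 500/268 table
becomes exactly 500/500.  The widely reprinted variant of the synthesis
formula with the difference reversed (x_seed − x_nb) extrapolates *away*
from the neighbour, contradicting the accompanying prose that the sample is
synthesised *between* the two points; the package implements the
interpolation and keeps the printed variant behind `strict_formula=True`
for comparison.  The draw order (neighbour slot, then r) is part of the
reproducibility contract and is verified by replaying the seeded stream in
the tests.

**ENN** (`k_neighbors=3`).  One simultaneous pass: every eligible row whose
label loses the strict-majority vote of its k nearest neighbours (self
excluded, neighbours from the full table) is marked, then all marked rows
are deleted together.  Simultaneous marking makes the deletion set
independent of row order, unlike sequential editing.  `unanimity=True`
requires all k neighbours to disagree.  Eligibility is the one genuinely
ambiguous point in the source protocol, whose printed tables show
standalone ENN shrinking only the majority class while the hybrid shrinks
both; the package therefore exposes `edit_target` and defaults it to
`majority_only` for standalone ENN and `both_classes` inside SMOTE-ENN,
matching both printed behaviours.  Editing can in principle empty a class;
that raises a warning flag on the result, not an exception.

**Tomek links.**  Standard definition (the source names the method without
defining it): mutual single-nearest-neighbour pairs of opposite class; the
majority member of each link is deleted.  Deterministic.

**Hybrids.**  SMOTE-ENN and SMOTE-Tomek are literal stage compositions —
the tests assert row-for-row equality with running the stages separately.
Provenance (origin tags, deleted indices against the post-SMOTE table,
before/after counts) survives the composition.  Each stochastic component
draws from an RNG stream derived from the top-level seed with a distinct
spawn key, so adding an editing stage never perturbs the SMOTE draws.

## Classifiers

One CART-style tree stands in for the assorted decision-tree dialects used
in resampling benchmarks, because the claims under test concern resampling,
not tree flavour.  It minimises weighted Gini impurity, places thresholds
at midpoints of adjacent observed values, supports a per-split random
feature subset of size m (drawn from the tree's own stream), and honours
true sample weights in the impurity computation — AdaBoost reweights, never
resamples, so its rounds are exactly reproducible.

Ensembles (default T = 100): bagging draws T bootstrap resamples of size n;
random forest adds per-split feature subsets (default ⌈√p⌉); AdaBoost.M1
uses β_t = ε_t/(1−ε_t), multiplies misclassified weights by 1/β_t,
renormalises, and votes with ln(1/β_t).  A perfect member (ε_t = 0) is kept
with a capped weight ln(1e10) and stops training; ε_t ≥ 0.5 discards the
member and stops, degenerating to a flagged constant majority predictor if
it happens in round one.  Prediction is weighted-vote argmax; an exact vote
tie goes to the positive class, a deliberate bias that never sacrifices
sensitivity silently.  The reported score is the weighted positive-vote
share (leaf positive fraction for a single tree).

## Evaluation

The source text defines TP as "majority correctly predicted" yet labels
TP/(TP+FN) the sensitivity of the *minority* — an internal inconsistency.
The package does not imitate it: every metric is computed with respect to
an explicit `positive_class`.  The study-shaped presets mark the disease
class (the majority there) positive; the generator's `positive="minority"`
switch covers the rare-disease convention.  Degenerate 0/0 cells return 0
and are flagged rather than raising, so result tables stay total.  AUC is
the rank-based Mann-Whitney statistic with average ranks for ties.

Cross-validation is stratified and seeded.  `paper_faithful` (default)
resamples the whole table once and cross-validates the resampled data —
the protocol the benchmark literature actually uses.  It leaks: synthetic
points in a test fold have interpolation parents in training folds, so
scores are optimistic.  `leakage_safe` resamples inside each training fold
only.  Both are first-class; reproducing the published protocol is the
default, honesty is a flag away.

## Comparison statistics

Wilcoxon signed-rank: zero differences dropped, tied absolute differences
get averaged ranks, T = min(R+, R−), decision from embedded exact tables
(no normal approximation; n ≤ 25).  The benchmark protocol rejects at
T ≤ 2 for six paired values at α = 0.05 — that is the *one-sided* critical
value; the standard two-sided table gives 0.  Both decisions are computed
on every call and `follow_paper=True` selects the one-sided convention, so
the published pairwise table reproduces while the stricter decision stays
visible.

Friedman: per-row ranks (rank 1 = best, ties averaged), average rank per
column, then the χ² and F formulas above, with the F compared against the
exact-df critical value F(k−1, (k−1)(N−1)) from scipy.  Published write-ups
of this machinery print average ranks to two decimals, square the printed
values, and plug the printed two-decimal χ² into the F transform; the
package mirrors both roundings by default (`rank_precision=2`,
`stat_precision=2`) — that is what makes the fixture tables yield 57.69,
34.71, 30.45 and 49.28 exactly — and always reports the exact-arithmetic
χ² alongside.  The published look-up also uses F(12, 60) ≈ 1.917 where the
formula's degrees of freedom are (11, 55); both thresholds are reported,
and every conclusion here is unaffected (the statistics exceed either by an
order of magnitude).  When χ²_F = N(k−1) the F transform divides by zero;
the package reports +∞ and rejects.

## Synthetic data

The generator emulates shape only: two spherical unit-variance Gaussians,
means `class_sep` standard deviations apart along the first axis.  A
planted *noisy* row keeps its label but draws its features around the
opposite class's mean — operationally a mislabeled point sitting in the
wrong region, which is what neighbourhood-based editors can detect — so
class counts stay exact (the presets must deliver exactly 249/112 and
500/268).  A planted *boundary* row is redrawn centred at the midpoint.
Both counts are exact (round(frac·n), allocated to classes proportionally),
not binomial, so tests assert them directly; indices live in the dataset's
provenance.  The presets use class_sep 2.0 (substantial overlap, as the
published scatter plots show), 5% noise and 10% boundary rows — chosen once
as a realistic regime for these tables.

What passing tests show, and what they do not: the real feature semantics,
marginals and covariances are *not* simulated, so synthetic results
demonstrate that the algorithms behave as specified (counts, geometry,
noise removal, the direction of the sensitivity effect), not that any
particular published percentage would replicate on the private clinical
data.

## Problem sizes and numerical choices

The stochastic acceptance checks run at desk scale, sizes chosen as the
package's own test regime: ENN noise recovery pools 20 seeds of a 450-row,
4-feature instance at class_sep 6; the headline-effect check uses a 500/100
two-feature table with 5% noise, tenfold CV, and 20-tree forests over 10
seeds (T is not pinned by the source protocol; 20 is plenty for a
qualitative direction at this n).  Collinearity of synthetic SMOTE points
is asserted to 1e-9; AdaBoost weight vectors to 1e-12; Friedman oracle
agreement to 1e-9.  CSV round-trips are lossless (17 significant digits on
write, round-trip float parsing on read).

## Known limitations

Binary labels only; numeric features only (no categorical distance
handling); no probability calibration, pruning, or post-hoc multiple-
comparison procedures (Nemenyi/Holm); Wilcoxon tables stop at n = 25 and no
normal approximation is provided; the comparator samplers that appear as
columns of the printed fixtures (Borderline-SMOTE, ADASYN, k-means-SMOTE,
instance-hardness undersampling, …) are deliberately not implemented — the
fixtures exist so the comparison machinery can be exercised on the
published numbers.
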