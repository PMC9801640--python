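# hybridsample

Hybrid resampling for imbalanced binary clinical tables: SMOTE
over-sampling, edited-nearest-neighbour (ENN) and Tomek-link cleaning, the
hybrids **SMOTE-ENN** and **SMOTE-Tomek**, decision-tree ensembles
(bagging, AdaBoost.M1, random forest), imbalance-aware evaluation
(sensitivity, specificity, F-measure, MCC, AUC under stratified tenfold
cross-validation), and the nonparametric machinery used to compare sampling
algorithms (pairwise Wilcoxon signed-rank, Friedman test over
metric-by-algorithm result tables).

It is written for biostatisticians and ML practitioners who work with small
case/control tables — think a few hundred patients, a handful of numeric
features, and a disease class that machine-learned classifiers quietly
sacrifice because it is outnumbered.

## The methods in brief

**SMOTE** synthesises minority points on the segment between a minority
seed x<sub>i</sub> and one of its k (default 5) minority-class nearest
neighbours, x<sub>new</sub> = x<sub>i</sub> + r·(x<sub>ik</sub> −
x<sub>i</sub>) with r ~ U(0,1), until the classes balance.  **ENN** deletes
every point whose label disagrees with the majority vote of its k (default
3) nearest neighbours — a single simultaneous mark-then-delete pass.  A
**Tomek link** is an opposite-class pair that are each other's single
nearest neighbour; the majority member is removed.  The hybrids run SMOTE
first and then clean the over-sampled table, so the synthetic "noisy" and
"boundary" points that plain SMOTE scatters into the opposite class are
edited back out.

Ensembles vote by H(x) = argmax<sub>y</sub> Σ<sub>t</sub> w<sub>t</sub>
I(h<sub>t</sub>(x) = y) over T CART-style Gini trees, with w<sub>t</sub> = 1
for bagging/random forest and w<sub>t</sub> = ln(1/β<sub>t</sub>) for
AdaBoost.  Result tables (N metric rows × k algorithm columns) are compared
with the Friedman statistic
χ²<sub>F</sub> = 12N/(k(k+1)) · [Σ<sub>j</sub>R<sub>j</sub>² − k(k+1)²/4]
and its F transform F<sub>F</sub> = (N−1)χ²<sub>F</sub> / (N(k−1) −
χ²<sub>F</sub>), and pairwise with exact small-sample Wilcoxon signed-rank
tables.

## Worked example

```python
import hybridsample as hs

ds = hs.preset("diabetes_like", seed=1)          # 500 case / 268 normal, 8 features
res = hs.smote_enn(ds, hs.ResamplerConfig(seed=1))
print(ds.counts(), res.counts_after_oversample, res.counts_after)

rf = hs.RandomForestGini(n_estimators=50)
base = hs.cross_validate(ds, None, rf, folds=10, seed=1)
hyb  = hs.cross_validate(ds, hs.SMOTEENN(), rf, folds=10, seed=1)
for name, rep in [("original", base), ("smote_enn", hyb)]:
    print(name, {k: round(v, 1) for k, v in rep.as_dict(percent=True).items()})
```

prints

```
counts before: {'case': 500, 'normal': 268}
after SMOTE:   {'case': 500, 'normal': 500}
after ENN:     {'case': 334, 'normal': 422} (244 rows edited out)
original   precision=76.9  sensitivity=83.0  specificity=52.9  f_measure=79.7  mcc=37.7  auc=76.2
smote_enn  precision=89.0  sensitivity=85.0  specificity=91.9  f_measure=86.8  mcc=77.5  auc=95.7
```

SMOTE first balances the table to 500/500; ENN then deletes 244 points
whose neighbourhoods vote against them (both classes shrink — cleaning, not
balancing).  The random forest's specificity and MCC jump because the
minority "normal" class is no longer drowned out; note that these
cross-validation scores follow the field's customary protocol of resampling
*before* the fold split, which leaks synthetic neighbours across folds and
is therefore optimistic — pass `mode="leakage_safe"` for the honest
variant.

The same pipeline is scriptable:

```bash
hybridsample resample --preset diabetes_like --resampler smote_enn --seed 1 --out out/res.csv
hybridsample benchmark --preset diabetes_like --resampler none --resampler smote_enn \
    --classifier random_forest --trees 50 --out out/bench
hybridsample compare out/bench/results_random_forest.csv --baseline smote_enn --out out/cmp
```

## Layout

```
src/hybridsample/
  dataset.py     LabeledDataset, CSV ingestion, Euclidean kNN queries
  resampling.py  SMOTE, ENN, Tomek links, SMOTE-ENN, SMOTE-Tomek
  tree.py        weighted-Gini CART tree
  ensemble.py    bagging, AdaBoost.M1, random forest
  evaluation.py  confusion metrics, AUC, stratified k-fold CV
  stats.py       Wilcoxon signed-rank, average ranks, Friedman
  synthetic.py   seeded generator, study-shaped presets, printed fixtures
  cli.py         simulate / resample / benchmark / compare
docs/methods.md  models, conventions, parameter choices, limitations
```
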