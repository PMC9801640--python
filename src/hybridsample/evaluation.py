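"""Imbalance-aware evaluation: confusion metrics, rank-based AUC, k-fold CV.

All metrics are computed with respect to an explicit positive class::

    sensitivity (= recall) = TP / (TP + FN)
    specificity            = TN / (FP + TN)
    precision              = TP / (TP + FP)
    F-measure              = 2 * recall * precision / (recall + precision)
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

Any 0/0 cell returns 0 by convention and is flagged.  AUC is the rank-based
(Mann-Whitney) statistic with half credit for score ties.

Cross-validation supports two protocols.  ``paper_faithful`` resamples the
whole dataset once and then runs stratified k-fold CV on the resampled data;
this matches the headline protocol of resampling benchmarks in the clinical
literature but lets synthetic points share neighbours across folds, so the
scores are optimistic.  ``leakage_safe`` resamples inside each training fold
only and evaluates on untouched test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .dataset import LabeledDataset, derived_int

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics",
           "auc", "cross_validate", "METRIC_NAMES"]

METRIC_NAMES = ("precision", "sensitivity", "specificity",
                "f_measure", "mcc", "auc")

_STREAM_CV = 5
_STREAM_RESAMPLE = 6
_STREAM_LEARNER = 7


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN cell counts of a binary confusion matrix."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass
class MetricReport:
    """Metric values in [0, 1] (MCC in [-1, 1]) plus optional per-fold detail."""

    precision: float
    sensitivity: float
    specificity: float
    f_measure: float
    mcc: float
    auc: Optional[float] = None
    per_fold: Optional[dict] = None
    counts: Optional[ConfusionCounts] = None
    degenerate: tuple = ()
    mode: Optional[str] = None
    counts_after_resampling: Optional[dict] = field(default=None, repr=False)

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        out = {}
        for name in METRIC_NAMES:
            v = getattr(self, name)
            out[name] = None if v is None else v * scale
        return out


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Count TP/TN/FP/FN with TP = positive-class rows predicted positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    known = set(np.unique(y_true)) | {positive_class}
    unknown = [v for v in np.unique(y_pred) if v not in known]
    if unknown:
        raise ValueError(f"predicted labels {unknown} not among known classes")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def _safe_div(num: float, den: float, flags: list, name: str) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricReport:
    """Confusion-based metric report; 0/0 cells return 0 and are flagged."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    flags: list = []
    sens = _safe_div(c.TP, c.TP + c.FN, flags, "sensitivity")
    spec = _safe_div(c.TN, c.FP + c.TN, flags, "specificity")
    prec = _safe_div(c.TP, c.TP + c.FP, flags, "precision")
    f = _safe_div(2 * sens * prec, sens + prec, flags, "f_measure")
    denom = np.sqrt(float(c.TN + c.FN) * (c.TN + c.FP) *
                    (c.TP + c.FN) * (c.TP + c.FP))
    mcc = _safe_div(c.TP * c.TN - c.FP * c.FN, denom, flags, "mcc")
    return MetricReport(precision=prec, sensitivity=sens, specificity=spec,
                        f_measure=f, mcc=mcc, counts=c,
                        degenerate=tuple(flags))


def auc(scores, y_true, positive_class) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for tied scores."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    pos = y_true == positive_class
    n_pos = int(pos.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties with half credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _eval_split(learner, train_ds: LabeledDataset, test_X, test_y,
                positive_class, seed_int):
    model = clone(learner)
    if "random_state" in model.get_params():
        model.set_params(random_state=seed_int)
    if "positive_label" in model.get_params():
        model.set_params(positive_label=positive_class)
    model.fit(train_ds.X, train_ds.y)
    y_pred = model.predict(test_X)
    scores = model.predict_score(test_X)
    c = confusion(test_y, y_pred, positive_class)
    rep = metrics(c)
    try:
        rep.auc = auc(scores, test_y, positive_class)
    except ValueError:
        rep.auc = 0.0
        rep.degenerate = rep.degenerate + ("auc",)
    return rep


def cross_validate(ds: LabeledDataset, resampler, learner, folds: int = 10,
                   mode: str = "paper_faithful",
                   seed: Optional[int] = None) -> MetricReport:
    """Stratified k-fold cross-validation of a (resampler, learner) pair.

    Parameters
    ----------
    resampler : estimator with ``fit_resample(ds)`` or None
        None (or an identity resampler) evaluates the raw dataset, in which
        case the two modes coincide.
    learner : classifier estimator
        Cloned per fold; its ``random_state`` and ``positive_label`` are set
        from the CV seed and the dataset's positive class.
    mode : "paper_faithful" or "leakage_safe"
        See the module docstring.

    Returns a :class:`MetricReport` whose headline values are the means of
    the per-fold values.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if mode not in ("paper_faithful", "leakage_safe"):
        raise ValueError(f"unknown cv mode {mode!r}")
    pos = ds.positive_class
    counts_after = None

    def _resample(sub_ds: LabeledDataset, key: int) -> LabeledDataset:
        if resampler is None:
            return sub_ds
        rs = clone(resampler)
        if "random_state" in rs.get_params():
            rs.set_params(random_state=derived_int(seed, _STREAM_RESAMPLE, key))
        return rs.fit_resample(sub_ds)

    if mode == "paper_faithful":
        res = _resample(ds, 0)
        if resampler is not None:
            counts_after = res.counts_after
            eval_ds = res.dataset
        else:
            eval_ds = ds
    else:
        eval_ds = ds

    min_count = min(eval_ds.counts().values())
    if min_count < folds:
        raise ValueError(
            f"smallest class ({min_count}) too small for {folds} stratified folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=derived_int(seed, _STREAM_CV))
    per_fold: dict = {name: [] for name in METRIC_NAMES}
    fold_counts = []
    for f, (tr, te) in enumerate(skf.split(eval_ds.X, eval_ds.y.astype(str))):
        train_sub = eval_ds.subset(tr)
        if mode == "leakage_safe" and resampler is not None:
            res = _resample(train_sub, 100 + f)
            train_sub = res.dataset
        rep = _eval_split(learner, train_sub, eval_ds.X[te], eval_ds.y[te],
                          pos, derived_int(seed, _STREAM_LEARNER, f))
        for name in METRIC_NAMES:
            per_fold[name].append(getattr(rep, name))
        fold_counts.append(rep.counts)

    total = fold_counts[0]
    for c in fold_counts[1:]:
        total = total + c
    means = {name: float(np.mean(per_fold[name])) for name in METRIC_NAMES}
    return MetricReport(per_fold=per_fold, counts=total, mode=mode,
                        counts_after_resampling=counts_after, **means)
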