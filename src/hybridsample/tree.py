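"""A binary CART-style decision tree with weighted Gini impurity.

One configurable tree learner stands in for the assorted decision-tree
dialects used in imbalanced-classification benchmarks: greedy top-down
induction, thresholds at midpoints of adjacent observed values, optional
per-split random feature subsets (which turns bagged trees into a random
forest), and true sample-weight support in the impurity computation (needed
by AdaBoost).
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import derived_rng

__all__ = ["DecisionTreeGini", "gini_impurity"]


def gini_impurity(counts) -> float:
    """Gini impurity 1 - sum(p_c^2) of a vector of class counts/weights."""
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts / tot
    return float(1.0 - np.sum(p**2))


class DecisionTreeGini(BaseEstimator, ClassifierMixin):
    """Binary classification tree minimising weighted Gini impurity.

    Parameters
    ----------
    max_depth : int or None
        Depth limit; None grows until purity or the leaf-size floor.
    min_samples_leaf : int
        Every leaf must hold at least this many (unweighted) training rows.
    max_features : int or None
        Features considered per split; None means all.  When smaller than p,
        each split draws a random subset from the tree's RNG stream.
    positive_label : label value or None
        Class reported by :meth:`predict_score`; defaults to the minority
        class of the training labels.  Prediction ties break toward it.
    random_state : int or None
        Seeds the per-split feature subsets.

    Fitted attributes: ``classes_``, ``positive_label_``, ``n_features_in_``
    and the flat node arrays ``feature_``, ``threshold_``, ``left_``,
    ``right_``, ``leaf_counts_``, ``leaf_value_``, ``leaf_score_``.
    """

    def __init__(self, max_depth: Optional[int] = None, min_samples_leaf: int = 1,
                 max_features: Optional[int] = None, positive_label=None,
                 random_state: Optional[int] = None):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.positive_label = positive_label
        self.random_state = random_state

    # -- induction --------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if n == 0:
            raise ValueError("empty training set")
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError("sample weights must be non-negative, not all zero")

        labels, counts = np.unique(y, return_counts=True)
        if len(labels) > 2:
            raise ValueError("binary classification only")
        if self.positive_label is not None:
            pos = self.positive_label
            if pos not in labels and len(labels) == 2:
                raise ValueError(f"positive_label {pos!r} not among training labels")
        elif len(labels) == 2:
            pos = labels[int(np.argmin(counts))]  # minority convention
        else:
            pos = labels[0]
        self.classes_ = labels
        self.positive_label_ = pos
        self.n_features_in_ = p

        m = p if self.max_features is None else min(int(self.max_features), p)
        if m < 1:
            raise ValueError("max_features must be >= 1")
        rng = derived_rng(self.random_state, 3) if m < p else None

        y01 = (y == pos).astype(float)
        # flat node arrays, grown during recursion
        self.feature_: list = []
        self.threshold_: list = []
        self.left_: list = []
        self.right_: list = []
        self.leaf_counts_: list = []   # (n_neg, n_pos) unweighted
        self.leaf_value_: list = []
        self.leaf_score_: list = []    # weighted positive fraction

        def new_node():
            self.feature_.append(-1)
            self.threshold_.append(np.nan)
            self.left_.append(-1)
            self.right_.append(-1)
            self.leaf_counts_.append((0, 0))
            self.leaf_value_.append(None)
            self.leaf_score_.append(0.0)
            return len(self.feature_) - 1

        if len(labels) == 2:
            neg_label = labels[0] if labels[1] == pos else labels[1]
        else:
            neg_label = labels[0]

        def make_leaf(node, idx):
            wp = float((w[idx] * y01[idx]).sum())
            wt = float(w[idx].sum())
            npos = int(y01[idx].sum())
            nneg = len(idx) - npos
            score = wp / wt if wt > 0 else 0.0
            # weighted majority; exact tie breaks toward the positive class
            self.leaf_value_[node] = pos if wp >= wt - wp else neg_label
            self.leaf_score_[node] = score
            self.leaf_counts_[node] = (nneg, npos)

        msl = int(self.min_samples_leaf)

        def build(idx, depth):
            node = new_node()
            wt = w[idx].sum()
            wp = (w[idx] * y01[idx]).sum()
            pure = wp <= 0 or wp >= wt
            if pure or len(idx) < 2 * msl or \
               (self.max_depth is not None and depth >= self.max_depth):
                make_leaf(node, idx)
                return node
            feats = np.arange(p) if rng is None else \
                np.sort(rng.choice(p, size=m, replace=False))
            split = _best_split(X[idx], y01[idx], w[idx], feats, msl)
            if split is None:
                make_leaf(node, idx)
                return node
            j, thr = split
            mask = X[idx, j] <= thr
            self.feature_[node] = int(j)
            self.threshold_[node] = float(thr)
            self.left_[node] = build(idx[mask], depth + 1)
            self.right_[node] = build(idx[~mask], depth + 1)
            return node

        build(np.arange(n), 0)
        self.feature_ = np.asarray(self.feature_)
        self.threshold_ = np.asarray(self.threshold_)
        self.left_ = np.asarray(self.left_)
        self.right_ = np.asarray(self.right_)
        return self

    # -- prediction -------------------------------------------------------
    def _leaf_of(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        node = np.zeros(X.shape[0], dtype=int)
        while True:
            internal = self.feature_[node] >= 0
            if not internal.any():
                return node
            rows = np.flatnonzero(internal)
            j = self.feature_[node[rows]]
            thr = self.threshold_[node[rows]]
            go_left = X[rows, j] <= thr
            node[rows] = np.where(go_left, self.left_[node[rows]],
                                  self.right_[node[rows]])

    def predict(self, X):
        leaves = self._leaf_of(X)
        return np.asarray([self.leaf_value_[i] for i in leaves])

    def predict_score(self, X) -> np.ndarray:
        """Positive-class fraction of the leaf each row lands in."""
        leaves = self._leaf_of(X)
        return np.asarray([self.leaf_score_[i] for i in leaves])

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "tree",
            "params": self.get_params(),
            "classes": [_json_label(c) for c in self.classes_],
            "positive_label": _json_label(self.positive_label_),
            "n_features": int(self.n_features_in_),
            "feature": self.feature_.tolist(),
            "threshold": [None if np.isnan(t) else float(t) for t in self.threshold_],
            "left": self.left_.tolist(),
            "right": self.right_.tolist(),
            "leaf_counts": [list(c) for c in self.leaf_counts_],
            "leaf_value": [_json_label(v) for v in self.leaf_value_],
            "leaf_score": [float(s) for s in self.leaf_score_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTreeGini":
        obj = cls(**d["params"])
        obj.classes_ = np.asarray(d["classes"])
        obj.positive_label_ = d["positive_label"]
        obj.n_features_in_ = d["n_features"]
        obj.feature_ = np.asarray(d["feature"])
        obj.threshold_ = np.asarray(
            [np.nan if t is None else t for t in d["threshold"]])
        obj.left_ = np.asarray(d["left"])
        obj.right_ = np.asarray(d["right"])
        obj.leaf_counts_ = [tuple(c) for c in d["leaf_counts"]]
        obj.leaf_value_ = list(d["leaf_value"])
        obj.leaf_score_ = list(d["leaf_score"])
        return obj

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _json_label(v):
    if isinstance(v, (np.generic,)):
        return v.item()
    return v


def _best_split(X, y01, w, feats, min_leaf):
    """Best (feature, midpoint threshold) by weighted Gini; None if no gain.

    Candidate thresholds are midpoints of adjacent distinct observed values;
    a split is admissible only when both children keep at least ``min_leaf``
    rows.  Ties across features resolve to the first feature in ``feats``
    (ascending index) and the smallest admissible threshold.
    """
    n = len(y01)
    w_tot = w.sum()
    w_pos = (w * y01).sum()
    parent = 2.0 * w_pos * (w_tot - w_pos) / w_tot if w_tot > 0 else 0.0
    best = None
    best_g = parent - 1e-12
    for j in feats:
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        wy = ws * y01[order]
        cw = np.cumsum(ws)
        cwp = np.cumsum(wy)
        cnt = np.arange(1, n)
        valid = (xs[:-1] < xs[1:]) & (cnt >= min_leaf) & (n - cnt >= min_leaf)
        if not valid.any():
            continue
        wl, wpl = cw[:-1], cwp[:-1]
        wr, wpr = w_tot - wl, w_pos - wpl
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(wl > 0, 2.0 * wpl * (wl - wpl) / wl, 0.0) + \
                np.where(wr > 0, 2.0 * wpr * (wr - wpr) / wr, 0.0)
        g = np.where(valid, g, np.inf)
        i = int(np.argmin(g))
        if g[i] < best_g:
            best_g = g[i]
            best = (int(j), float((xs[i] + xs[i + 1]) / 2.0))
    return best
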