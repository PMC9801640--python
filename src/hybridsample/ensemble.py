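"""Decision-tree ensembles: bagging, AdaBoost.M1 and random forest.

All three combiners share one voting rule: the predicted class is the
weighted-vote argmax over members,

    H(x) = argmax_y  sum_t  w_t * I(h_t(x) = y),

with unit weights w_t = 1 for bagging and random forest and
w_t = ln(1/beta_t) for AdaBoost.  The reported score is the weighted share
of votes for the positive class; an exact vote tie breaks toward the
positive class so that sensitivity is never silently sacrificed.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import derived_int, derived_rng
from .tree import DecisionTreeGini

__all__ = ["BaggingTrees", "AdaBoostTrees", "RandomForestGini",
           "load_model", "CLASSIFIERS"]

_STREAM_BOOTSTRAP = 2
_STREAM_ADABOOST = 4
# vote weight assigned to a member with zero weighted training error
_PERFECT_WEIGHT = float(np.log(1e10))


class _TreeEnsembleBase(BaseEstimator, ClassifierMixin):
    """Shared fitting scaffold and weighted-vote prediction."""

    rule = "base"

    def _tree_params(self, p: int) -> dict:
        return dict(max_depth=self.max_depth,
                    min_samples_leaf=self.min_samples_leaf,
                    max_features=None)

    def _resolve_labels(self, y):
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) > 2:
            raise ValueError("binary classification only")
        if self.positive_label is not None:
            pos = self.positive_label
        elif len(labels) == 2:
            pos = labels[int(np.argmin(counts))]
        else:
            pos = labels[0]
        if len(labels) == 2:
            neg = labels[0] if labels[1] == pos else labels[1]
        else:
            neg = labels[0]
        self.classes_ = labels
        self.positive_label_ = pos
        self.negative_label_ = neg

    # -- voting -----------------------------------------------------------
    def predict_score(self, X) -> np.ndarray:
        """Weighted share of member votes for the positive class, in [0, 1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w = np.asarray(self.estimator_weights_, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree, wt in zip(self.estimators_, w):
            votes += wt * (tree.predict(X) == self.positive_label_)
        return votes / w.sum()

    def predict(self, X):
        score = self.predict_score(X)
        # tie at exactly 0.5 resolves to the positive class
        return np.where(score >= 0.5, self.positive_label_, self.negative_label_)

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.rule,
            "params": self.get_params(),
            "classes": [c.item() if isinstance(c, np.generic) else c
                        for c in self.classes_],
            "positive_label": (self.positive_label_.item()
                               if isinstance(self.positive_label_, np.generic)
                               else self.positive_label_),
            "weights": [float(w) for w in self.estimator_weights_],
            "flags": dict(getattr(self, "flags_", {})),
            "members": [t.to_dict() for t in self.estimators_],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def _from_members(cls, members, weights, pos_label, neg_label, **params):
        """Assemble an ensemble from pre-built trees (testing/deserialising)."""
        obj = cls(**params)
        obj.estimators_ = list(members)
        obj.estimator_weights_ = list(weights)
        obj.positive_label_ = pos_label
        obj.negative_label_ = neg_label
        obj.classes_ = np.asarray(sorted({pos_label, neg_label}, key=str))
        obj.flags_ = {}
        return obj


class BaggingTrees(_TreeEnsembleBase):
    """Bootstrap-aggregated trees with unit vote weights.

    Each of the ``n_estimators`` members is trained on a bootstrap resample
    of size n (with replacement, seeded); ``bootstrap=False`` is a
    diagnostic switch that trains every member on the full data.
    """

    rule = "bagging"

    def __init__(self, n_estimators: int = 100, max_depth: Optional[int] = None,
                 min_samples_leaf: int = 1, bootstrap: bool = True,
                 positive_label=None, random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.bootstrap = bootstrap
        self.positive_label = positive_label
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        self._resolve_labels(y)
        n, p = X.shape
        self.estimators_, self.estimator_weights_ = [], []
        self.flags_ = {}
        for t in range(int(self.n_estimators)):
            rng = derived_rng(self.random_state, _STREAM_BOOTSTRAP, t)
            idx = rng.integers(n, size=n) if self.bootstrap else np.arange(n)
            tree = DecisionTreeGini(
                positive_label=self.positive_label_,
                random_state=derived_int(self.random_state, _STREAM_BOOTSTRAP, t),
                **self._tree_params(p))
            tree.fit(X[idx], y[idx])
            self.estimators_.append(tree)
            self.estimator_weights_.append(1.0)
        return self


class RandomForestGini(BaggingTrees):
    """Bagging plus a random feature subset of size m at every split.

    ``max_features=None`` uses the customary ceil(sqrt(p)).
    """

    rule = "random_forest"

    def __init__(self, n_estimators: int = 100, max_features: Optional[int] = None,
                 max_depth: Optional[int] = None, min_samples_leaf: int = 1,
                 bootstrap: bool = True, positive_label=None,
                 random_state: Optional[int] = None):
        super().__init__(n_estimators=n_estimators, max_depth=max_depth,
                         min_samples_leaf=min_samples_leaf, bootstrap=bootstrap,
                         positive_label=positive_label, random_state=random_state)
        self.max_features = max_features

    def _tree_params(self, p: int) -> dict:
        m = int(np.ceil(np.sqrt(p))) if self.max_features is None \
            else int(self.max_features)
        if m > p:
            raise ValueError(f"max_features={m} exceeds feature count {p}")
        return dict(max_depth=self.max_depth,
                    min_samples_leaf=self.min_samples_leaf, max_features=m)


class AdaBoostTrees(_TreeEnsembleBase):
    """AdaBoost.M1 over the package's weighted Gini tree.

    Round t trains a tree on the current weight vector (uniform 1/n at the
    start), computes the weighted error eps_t, sets beta_t = eps_t/(1-eps_t),
    multiplies every misclassified row's weight by 1/beta_t, renormalises,
    and records the member with vote weight ln(1/beta_t).  A perfect member
    (eps_t = 0) is kept with a large capped weight and training stops; a
    member with eps_t >= 0.5 is discarded and training stops (if it is the
    very first round the model degenerates to a flagged majority-class
    predictor).
    """

    rule = "adaboost"

    def __init__(self, n_estimators: int = 100, max_depth: Optional[int] = None,
                 min_samples_leaf: int = 1, positive_label=None,
                 random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.positive_label = positive_label
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        self._resolve_labels(y)
        n, p = X.shape
        w = np.full(n, 1.0 / n)
        self.estimators_, self.estimator_weights_ = [], []
        self.estimator_errors_, self.estimator_betas_ = [], []
        self.weight_history_ = [w.copy()]
        self.flags_ = {}
        for t in range(int(self.n_estimators)):
            tree = DecisionTreeGini(
                positive_label=self.positive_label_,
                random_state=derived_int(self.random_state, _STREAM_ADABOOST, t),
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf)
            tree.fit(X, y, sample_weight=w)
            miss = tree.predict(X) != y
            eps = float(w[miss].sum())
            if eps >= 0.5:
                if not self.estimators_:
                    # degenerate: best-effort constant majority predictor
                    maj = self.classes_[int(np.argmax(
                        [np.sum(y == c) for c in self.classes_]))]
                    stump = DecisionTreeGini(positive_label=self.positive_label_,
                                             max_depth=0)
                    stump.fit(X, np.full(n, maj, dtype=y.dtype))
                    self.estimators_.append(stump)
                    self.estimator_weights_.append(1.0)
                    self.flags_["degenerate_first_round"] = True
                self.flags_["stopped_early"] = True
                break
            self.estimator_errors_.append(eps)
            if eps == 0.0:
                self.estimators_.append(tree)
                self.estimator_weights_.append(_PERFECT_WEIGHT)
                self.estimator_betas_.append(0.0)
                self.flags_["perfect_member"] = True
                break
            beta = eps / (1.0 - eps)
            self.estimators_.append(tree)
            self.estimator_weights_.append(float(np.log(1.0 / beta)))
            self.estimator_betas_.append(beta)
            w = w.copy()
            w[miss] *= 1.0 / beta
            w /= w.sum()
            self.weight_history_.append(w.copy())
        return self


def load_model(path_or_dict):
    """Rebuild a serialised tree or ensemble; round-trips predictions."""
    d = path_or_dict
    if not isinstance(d, dict):
        with open(d) as fh:
            d = json.load(fh)
    if d["kind"] == "tree":
        return DecisionTreeGini.from_dict(d)
    cls = {c.rule: c for c in (BaggingTrees, AdaBoostTrees, RandomForestGini)}[d["kind"]]
    members = [DecisionTreeGini.from_dict(m) for m in d["members"]]
    pos = d["positive_label"]
    neg = [c for c in d["classes"] if c != pos]
    obj = cls._from_members(members, d["weights"], pos,
                            neg[0] if neg else pos, **d["params"])
    obj.flags_ = d.get("flags", {})
    return obj


CLASSIFIERS = {
    "tree": DecisionTreeGini,
    "bagging": BaggingTrees,
    "adaboost": AdaBoostTrees,
    "random_forest": RandomForestGini,
}
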