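"""Core dataset container, CSV ingestion and Euclidean k-nearest-neighbour queries.

Every resampler in this package operates on a :class:`LabeledDataset`: a dense
numeric feature matrix with a binary label column, which knows which of its two
classes is the majority and which the minority.  Distances are plain Euclidean
on the raw feature values (no standardisation) unless ``scale=True`` is
requested, because clinical tables are routinely used unscaled in this setting;
a min-max switch is provided for features with wildly different ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "NeighborSpec",
    "load_csv",
    "class_counts",
    "nearest_neighbors",
]


def derived_rng(seed: Optional[int], *key: int) -> np.random.Generator:
    """Return an RNG stream derived from a top-level seed and a component key.

    Each stochastic component of the package draws from its own derived
    stream, so adding or removing one stage never perturbs another stage's
    draws.  ``seed=None`` yields a nondeterministic stream.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def derived_int(seed: Optional[int], *key: int) -> int:
    """A small integer seed derived from (seed, key), below 2**31."""
    if seed is None:
        return int(np.random.default_rng().integers(2**31))
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class LabeledDataset:
    """A numeric feature table with binary labels.

    Parameters
    ----------
    X : (n, p) float array
        Feature matrix; all values must be finite.
    y : (n,) array
        Class label per row; at most two distinct values.
    feature_names : sequence of str, optional
        Defaults to ``f0 … f{p-1}``.
    label_name : str
        Name of the label column for CSV round-trips.
    positive_class : label value, optional
        The class treated as "case" by the metrics.  Defaults to the
        minority class (the rare-disease convention); the study-shaped
        presets override it because there the disease class is the majority.
    provenance : dict, optional
        Free-form metadata (generator config, planted-noise indices, …).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: Sequence[str] = None
    label_name: str = "label"
    positive_class: Any = None
    provenance: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        self.y = np.asarray(self.y)
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features contain missing or non-finite values")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")

        labels, counts = np.unique(self.y, return_counts=True)
        if len(labels) > 2:
            raise ValueError(f"more than two distinct labels: {list(labels)}")
        #: True when only one class is present (constructible but flagged).
        self.degenerate = len(labels) < 2
        #: True when the two class counts tie exactly; roles still assigned.
        self.balanced = (not self.degenerate) and counts[0] == counts[1]
        if self.degenerate:
            maj = mino = labels[0] if len(labels) else None
        elif self.balanced:
            # declared tie rule: majority role goes to the smaller label
            # in np.unique sort order (lexicographic / numeric ascending)
            maj, mino = labels[0], labels[1]
        else:
            order = np.argsort(counts, kind="stable")
            mino, maj = labels[order[0]], labels[order[1]]
        self._majority = maj
        self._minority = mino
        if self.positive_class is None:
            self.positive_class = mino
        elif not self.degenerate and self.positive_class not in labels:
            raise ValueError(f"positive_class {self.positive_class!r} not among labels")

    # -- basic shape ------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def majority_label(self):
        return self._majority

    @property
    def minority_label(self):
        return self._minority

    @property
    def majority_count(self) -> int:
        return int(np.sum(self.y == self._majority))

    @property
    def minority_count(self) -> int:
        if self.degenerate:
            return 0
        return int(np.sum(self.y == self._minority))

    @property
    def negative_class(self):
        labels = [self._majority, self._minority]
        return labels[0] if self.positive_class == labels[1] else labels[1]

    def counts(self) -> dict:
        labels, counts = np.unique(self.y, return_counts=True)
        return {lab: int(c) for lab, c in zip(labels, counts)}

    # -- conversion -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[self.label_name] = self.y
        return df

    def to_csv(self, path) -> None:
        """Write as comma-separated UTF-8 with a header row.

        Floats are printed at 17 significant digits so that write→read
        round-trips are lossless.
        """
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices)
        return LabeledDataset(
            self.X[indices],
            self.y[indices],
            feature_names=self.feature_names,
            label_name=self.label_name,
            positive_class=self.positive_class,
        )


@dataclass
class NeighborSpec:
    """How to run a k-nearest-neighbour query.

    ``restrict_class`` limits the candidate pool to one class;
    ``exclude_self`` removes the query row from its own candidate pool.
    """

    k: int
    restrict_class: Any = None
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")


def load_csv(path, label_column: str, positive_class=None) -> LabeledDataset:
    """Read a comma-separated table with a header row into a LabeledDataset.

    All non-label cells must parse as numbers; a failure is reported with the
    offending row and column.  ``positive_class`` may be given as a string and
    is matched against the parsed label values.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: file contains no data rows")
    if label_column not in df.columns:
        raise ValueError(f"{path}: no column named {label_column!r} in header")
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        parsed = pd.to_numeric(feats[col], errors="coerce")
        bad = parsed.isna() & feats[col].notna()
        if bad.any() or feats[col].isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise ValueError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"data row {row} (value {feats[col].iloc[row]!r})"
            )
        feats[col] = parsed
    y = df[label_column].to_numpy()
    if positive_class is not None and positive_class not in y:
        # tolerate a string spelling of a numeric label
        matches = [v for v in np.unique(y) if str(v) == str(positive_class)]
        if matches:
            positive_class = matches[0]
    return LabeledDataset(
        feats.to_numpy(dtype=float),
        y,
        feature_names=list(feats.columns),
        label_name=label_column,
        positive_class=positive_class,
    )


def class_counts(ds: LabeledDataset):
    """(majority label, majority count, minority label, minority count)."""
    return ds.majority_label, ds.majority_count, ds.minority_label, ds.minority_count


def _pairwise_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    # plain expanded form; exact ties matter more than the last ulp here,
    # so compute the full difference rather than the dot-product identity
    return ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)


def knn_indices(
    X: np.ndarray,
    query_rows: np.ndarray,
    k: int,
    candidate_rows: np.ndarray,
    exclude_self: bool = True,
) -> np.ndarray:
    """k nearest candidate rows for each query row, ties by ascending index.

    Returns an (n_query, k) array of indices into ``X`` (global row indices),
    each row sorted by ascending Euclidean distance; exact distance ties are
    broken by ascending row index (stable argsort over index-sorted
    candidates).
    """
    query_rows = np.asarray(query_rows)
    candidate_rows = np.sort(np.asarray(candidate_rows))
    D = _pairwise_sq_dists(X[query_rows], X[candidate_rows])
    if exclude_self:
        self_pos = np.searchsorted(candidate_rows, query_rows)
        for qi, (pos, q) in enumerate(zip(self_pos, query_rows)):
            if pos < len(candidate_rows) and candidate_rows[pos] == q:
                D[qi, pos] = np.inf
    n_eligible = (np.isfinite(D)).sum(axis=1).min()
    if k > n_eligible:
        raise ValueError(f"k={k} exceeds the eligible candidate count {n_eligible}")
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    return candidate_rows[order]


def nearest_neighbors(ds: LabeledDataset, index: int, spec: NeighborSpec) -> list:
    """Ordered k-nearest-neighbour row indices of ``ds.X[index]``.

    Neighbours sorted by ascending Euclidean distance; exact ties broken by
    ascending row index.  With ``spec.restrict_class`` set, only rows of that
    class are eligible.
    """
    if not (0 <= index < ds.n):
        raise IndexError(f"row index {index} out of range for n={ds.n}")
    if spec.restrict_class is None:
        cand = np.arange(ds.n)
    else:
        cand = np.flatnonzero(ds.y == spec.restrict_class)
    out = knn_indices(ds.X, np.array([index]), spec.k, cand, exclude_self=spec.exclude_self)
    return [int(i) for i in out[0]]
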