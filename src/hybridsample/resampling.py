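"""Hybrid resampling of imbalanced binary tables.

The core contribution of the package: SMOTE over-sampling, edited-nearest-
neighbour (ENN) cleaning, Tomek-link removal, and the two hybrids SMOTE-ENN
and SMOTE-Tomek.  Each resampler is an estimator class in the scikit-learn
style (parameters in ``__init__``, :meth:`fit_resample`, fitted provenance
attributes with a trailing underscore); thin module-level functions wrap them
for the dataclass-config call style.

SMOTE synthesises a new minority point on the segment between a minority seed
``x_seed`` and one of its ``k`` minority-class nearest neighbours::

    x_new = x_seed + r * (x_neighbor - x_seed),   r ~ Uniform(0, 1)

(the commonly printed variant with the difference reversed extrapolates away
from the neighbour; ``strict_formula=True`` reproduces it for comparison).
ENN deletes every eligible row whose label disagrees with the majority vote
of its ``k`` nearest neighbours, in a single simultaneous mark-then-delete
pass.  A Tomek link is a pair of opposite-class points that are each other's
single nearest neighbour; the majority-class member of each link is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import LabeledDataset, derived_rng, knn_indices

__all__ = [
    "ResamplerConfig",
    "ResampledDataset",
    "SMOTE",
    "EditedNearestNeighbours",
    "TomekLinks",
    "SMOTEENN",
    "SMOTETomek",
    "smote",
    "enn",
    "tomek_link",
    "smote_enn",
    "smote_tomek",
    "RESAMPLERS",
]

# component ids for derived RNG streams
_STREAM_SMOTE = 1


@dataclass
class ResamplerConfig:
    """Shared resampler knobs.

    k_smote : neighbours used for synthesis (the field's customary 5)
    k_enn : neighbours used for editing (customary 3)
    edit_target : "majority_only" (standalone ENN) or "both_classes"
        (the editing stage inside SMOTE-ENN)
    seed : top-level RNG seed
    target_ratio : desired minority/majority ratio after over-sampling
    """

    k_smote: int = 5
    k_enn: int = 3
    edit_target: str = "majority_only"
    seed: Optional[int] = None
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k_smote < 1 or self.k_enn < 1:
            raise ValueError("neighbour counts must be >= 1")
        if not (0 < self.target_ratio <= 1):
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.edit_target not in ("majority_only", "both_classes"):
            raise ValueError(f"unknown edit_target {self.edit_target!r}")


@dataclass
class ResampledDataset:
    """A resampled dataset plus provenance.

    ``origin`` tags each row of ``dataset`` as "original" or "synthetic";
    ``deleted_indices`` refer to rows of the dataset the editing stage saw
    (the input for plain editors, the post-SMOTE dataset for hybrids).
    """

    dataset: LabeledDataset
    origin: np.ndarray
    deleted_indices: np.ndarray
    counts_before: dict
    counts_after: dict
    config: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def provenance_dict(self) -> dict:
        return {
            "counts_before": {str(k): v for k, v in self.counts_before.items()},
            "counts_after": {str(k): v for k, v in self.counts_after.items()},
            "synthetic_row_indices": [int(i) for i in np.flatnonzero(self.origin == "synthetic")],
            "deleted_indices": [int(i) for i in self.deleted_indices],
            "config": self.config,
            "warnings": list(self.warnings),
        }


def _result(ds_out, origin, deleted, ds_in, config, warnings=()):
    return ResampledDataset(
        dataset=ds_out,
        origin=np.asarray(origin, dtype=object),
        deleted_indices=np.asarray(deleted, dtype=int),
        counts_before=ds_in.counts(),
        counts_after=ds_out.counts(),
        config=config,
        warnings=list(warnings),
    )


class SMOTE(BaseEstimator):
    """Synthetic minority over-sampling.

    Seeds are cycled round-robin over the minority rows in dataset order;
    for each synthetic row the generator draws first the neighbour slot
    (uniform over the ``k_neighbors`` minority nearest neighbours of the
    seed), then the interpolation coefficient ``r`` — this draw order is part
    of the reproducibility contract.  Synthesis stops when the minority count
    reaches ``round(target_ratio * majority_count)``.
    """

    def __init__(self, k_neighbors: int = 5, target_ratio: float = 1.0,
                 strict_formula: bool = False, random_state: Optional[int] = None):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.strict_formula = strict_formula
        self.random_state = random_state

    def fit_resample(self, ds: LabeledDataset) -> ResampledDataset:
        k = int(self.k_neighbors)
        min_lab, maj_lab = ds.minority_label, ds.majority_label
        min_rows = np.flatnonzero(ds.y == min_lab)
        n_min = len(min_rows)
        if n_min < 2:
            raise ValueError("SMOTE needs at least two minority samples")
        if k >= n_min:
            raise ValueError(f"k_neighbors={k} must be < minority count {n_min}")
        target = int(round(self.target_ratio * ds.majority_count))
        n_new = max(0, target - n_min)

        origin = ["original"] * ds.n
        if n_new == 0:
            out = LabeledDataset(ds.X.copy(), ds.y.copy(), ds.feature_names,
                                 ds.label_name, ds.positive_class)
            return _result(out, origin, [], ds, self.get_params())

        nn = knn_indices(ds.X, min_rows, k, min_rows, exclude_self=True)
        rng = derived_rng(self.random_state, _STREAM_SMOTE)
        new_rows = np.empty((n_new, ds.p))
        for i in range(n_new):
            seed_pos = i % n_min
            nb_slot = int(rng.integers(k))
            r = float(rng.random())
            x_seed = ds.X[min_rows[seed_pos]]
            x_nb = ds.X[nn[seed_pos, nb_slot]]
            if self.strict_formula:
                new_rows[i] = x_seed + r * (x_seed - x_nb)
            else:
                new_rows[i] = x_seed + r * (x_nb - x_seed)

        X_out = np.vstack([ds.X, new_rows])
        y_out = np.concatenate([ds.y, np.full(n_new, min_lab, dtype=ds.y.dtype)])
        out = LabeledDataset(X_out, y_out, ds.feature_names, ds.label_name,
                             ds.positive_class)
        origin += ["synthetic"] * n_new
        return _result(out, origin, [], ds, self.get_params())


class EditedNearestNeighbours(BaseEstimator):
    """ENN cleaning: single simultaneous mark-then-delete pass.

    A row is marked when its label disagrees with the vote of its
    ``k_neighbors`` nearest neighbours drawn from the full dataset (self
    excluded): strict-majority vote by default, unanimous disagreement when
    ``unanimity=True``.  ``edit_target`` restricts eligibility to the
    majority class or opens it to both classes.
    """

    def __init__(self, k_neighbors: int = 3, edit_target: str = "majority_only",
                 unanimity: bool = False, random_state: Optional[int] = None):
        self.k_neighbors = k_neighbors
        self.edit_target = edit_target
        self.unanimity = unanimity
        self.random_state = random_state  # unused; ENN is deterministic

    def fit_resample(self, ds: LabeledDataset) -> ResampledDataset:
        k = int(self.k_neighbors)
        if k >= ds.n - 1:
            raise ValueError(f"k_neighbors={k} must be < n-1 = {ds.n - 1}")
        maj_lab = ds.majority_label
        if self.edit_target == "majority_only":
            eligible = np.flatnonzero(ds.y == maj_lab)
        elif self.edit_target == "both_classes":
            eligible = np.arange(ds.n)
        else:
            raise ValueError(f"unknown edit_target {self.edit_target!r}")

        nn = knn_indices(ds.X, eligible, k, np.arange(ds.n), exclude_self=True)
        same = (ds.y[nn] == ds.y[eligible][:, None]).sum(axis=1)
        if self.unanimity:
            marked = eligible[same == 0]
        else:
            # deleted when the opposite label holds a strict majority
            marked = eligible[same < (k - same)]

        keep = np.setdiff1d(np.arange(ds.n), marked)
        out = ds.subset(keep)
        warnings = []
        if len(np.unique(out.y)) < 2:
            warnings.append("editing emptied one class")
        return _result(out, ["original"] * len(keep), marked, ds,
                       self.get_params(), warnings)


class TomekLinks(BaseEstimator):
    """Remove the majority member of every Tomek link.

    A link is an opposite-class pair (a, b) where a is b's single nearest
    neighbour and b is a's (distance ties broken by ascending row index).
    Deterministic; no randomness involved.
    """

    def __init__(self, random_state: Optional[int] = None):
        self.random_state = random_state  # unused; kept for API uniformity

    def fit_resample(self, ds: LabeledDataset) -> ResampledDataset:
        if ds.degenerate:
            raise ValueError("Tomek-link removal needs both classes present")
        all_rows = np.arange(ds.n)
        nn1 = knn_indices(ds.X, all_rows, 1, all_rows, exclude_self=True)[:, 0]
        maj_lab = ds.majority_label
        to_delete = set()
        for a in range(ds.n):
            b = int(nn1[a])
            if a < b and nn1[b] == a and ds.y[a] != ds.y[b]:
                victim = a if ds.y[a] == maj_lab else b
                to_delete.add(victim)
        marked = np.array(sorted(to_delete), dtype=int)
        keep = np.setdiff1d(all_rows, marked)
        out = ds.subset(keep)
        return _result(out, ["original"] * len(keep), marked, ds, self.get_params())


class _HybridBase(BaseEstimator):
    """SMOTE followed by an editing stage, with shared provenance.

    Origin tags from the SMOTE stage survive the edit; deleted indices are
    reported against the post-SMOTE dataset.
    """

    def _edit_stage(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit_resample(self, ds: LabeledDataset) -> ResampledDataset:
        sm = SMOTE(k_neighbors=self.k_neighbors, target_ratio=self.target_ratio,
                   strict_formula=self.strict_formula,
                   random_state=self.random_state).fit_resample(ds)
        edited = self._edit_stage().fit_resample(sm.dataset)
        keep = np.setdiff1d(np.arange(sm.dataset.n), edited.deleted_indices)
        origin = sm.origin[keep]
        res = ResampledDataset(
            dataset=edited.dataset,
            origin=origin,
            deleted_indices=edited.deleted_indices,
            counts_before=ds.counts(),
            counts_after=edited.dataset.counts(),
            config=self.get_params(),
            warnings=list(sm.warnings) + list(edited.warnings),
        )
        res.counts_after_oversample = sm.counts_after
        return res


class SMOTEENN(_HybridBase):
    """SMOTE over-sampling followed by ENN editing of both classes."""

    def __init__(self, k_neighbors: int = 5, k_edit: int = 3,
                 edit_target: str = "both_classes", target_ratio: float = 1.0,
                 unanimity: bool = False, strict_formula: bool = False,
                 random_state: Optional[int] = None):
        self.k_neighbors = k_neighbors
        self.k_edit = k_edit
        self.edit_target = edit_target
        self.target_ratio = target_ratio
        self.unanimity = unanimity
        self.strict_formula = strict_formula
        self.random_state = random_state

    def _edit_stage(self):
        return EditedNearestNeighbours(k_neighbors=self.k_edit,
                                       edit_target=self.edit_target,
                                       unanimity=self.unanimity)


class SMOTETomek(_HybridBase):
    """SMOTE over-sampling followed by Tomek-link removal."""

    def __init__(self, k_neighbors: int = 5, target_ratio: float = 1.0,
                 strict_formula: bool = False, random_state: Optional[int] = None):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.strict_formula = strict_formula
        self.random_state = random_state

    def _edit_stage(self):
        return TomekLinks()


class IdentityResampler(BaseEstimator):
    """No-op resampler (the "Original" column of a benchmark grid)."""

    def __init__(self, random_state: Optional[int] = None):
        self.random_state = random_state

    def fit_resample(self, ds: LabeledDataset) -> ResampledDataset:
        out = LabeledDataset(ds.X.copy(), ds.y.copy(), ds.feature_names,
                             ds.label_name, ds.positive_class)
        return _result(out, ["original"] * ds.n, [], ds, self.get_params())


# ---------------------------------------------------------------------------
# dataclass-config wrappers

def smote(ds: LabeledDataset, cfg: ResamplerConfig = ResamplerConfig()) -> ResampledDataset:
    return SMOTE(k_neighbors=cfg.k_smote, target_ratio=cfg.target_ratio,
                 random_state=cfg.seed).fit_resample(ds)


def enn(ds: LabeledDataset, cfg: ResamplerConfig = ResamplerConfig()) -> ResampledDataset:
    return EditedNearestNeighbours(k_neighbors=cfg.k_enn,
                                   edit_target=cfg.edit_target).fit_resample(ds)


def tomek_link(ds: LabeledDataset) -> ResampledDataset:
    return TomekLinks().fit_resample(ds)


def smote_enn(ds: LabeledDataset, cfg: ResamplerConfig = ResamplerConfig()) -> ResampledDataset:
    # the editing stage of the hybrid cleans both classes
    return SMOTEENN(k_neighbors=cfg.k_smote, k_edit=cfg.k_enn,
                    edit_target="both_classes", target_ratio=cfg.target_ratio,
                    random_state=cfg.seed).fit_resample(ds)


def smote_tomek(ds: LabeledDataset, cfg: ResamplerConfig = ResamplerConfig()) -> ResampledDataset:
    return SMOTETomek(k_neighbors=cfg.k_smote, target_ratio=cfg.target_ratio,
                      random_state=cfg.seed).fit_resample(ds)


RESAMPLERS = {
    "none": IdentityResampler,
    "smote": SMOTE,
    "enn": EditedNearestNeighbours,
    "tomek": TomekLinks,
    "smote_enn": SMOTEENN,
    "smote_tomek": SMOTETomek,
}
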