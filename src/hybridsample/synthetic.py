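"""Seeded generator of imbalanced binary tables with planted structure.

The generator emulates the *shape* of small clinical case/control tables —
class imbalance, feature count, mislabeled "noisy" rows and near-frontier
"boundary" rows — not the marginals or covariance of any real dataset.  Each
class is a spherical Gaussian with unit within-class spread; the class mean
vectors sit ``class_sep`` apart along the first axis, so ``class_sep`` is
expressed in within-class standard deviations.

A planted *noisy* row keeps its class label but has its features drawn from
the opposite class's distribution — i.e. a mislabeled point sitting inside
the other class's region.  A planted *boundary* row is redrawn centred at
the midpoint between the class means.  Both counts are exact
(``round(frac * n)``), not binomial, so tests can assert them directly; the
planted indices are recorded in the dataset's provenance.

Two presets mirror the shapes of the study tables this package benchmarks
against: a 249/112-by-7 table and a 500/268-by-8 table.  The printed
benchmark result tables (six metrics by thirteen sampler columns per
classifier and dataset) ship as read-only CSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .stats import ResultsTable

__all__ = ["GeneratorConfig", "generate", "preset", "printed_results",
           "PRESETS", "PRINTED_CLASSIFIERS", "PRINTED_DATASETS"]

PRINTED_CLASSIFIERS = ("c45", "randomtree", "reptree",
                       "random_forest", "adaboost", "bagging")
PRINTED_DATASETS = ("missed_abortion", "diabetes")


@dataclass
class GeneratorConfig:
    """Shape and noise structure of a generated dataset.

    n_maj, n_min : class sizes (majority first)
    p : feature count
    class_sep : distance between class means, in within-class SD units
    noise_frac : fraction of all rows planted as mislabeled points
    boundary_frac : fraction of rows redrawn at the inter-class midpoint
    labels : (majority label, minority label)
    positive : which role is the metrics' positive class
        ("majority" mirrors the study tables, where the disease class is
        the larger one; "minority" is the rare-disease convention)
    """

    n_maj: int
    n_min: int
    p: int = 2
    class_sep: float = 2.0
    noise_frac: float = 0.0
    boundary_frac: float = 0.0
    seed: Optional[int] = 0
    labels: tuple = ("case", "normal")
    positive: str = "majority"

    def __post_init__(self) -> None:
        if not (self.n_maj >= self.n_min >= 2):
            raise ValueError("need n_maj >= n_min >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        for name in ("noise_frac", "boundary_frac"):
            v = getattr(self, name)
            if not (0 <= v <= 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if self.positive not in ("majority", "minority"):
            raise ValueError("positive must be 'majority' or 'minority'")


def generate(cfg: GeneratorConfig) -> LabeledDataset:
    """Draw a dataset; deterministic per seed, byte-identical on replay."""
    ss = np.random.SeedSequence(0 if cfg.seed is None else int(cfg.seed))
    rng_feat, rng_pick, rng_shuffle = (np.random.default_rng(c)
                                       for c in ss.spawn(3))
    n = cfg.n_maj + cfg.n_min
    maj_lab, min_lab = cfg.labels
    mean_maj = np.zeros(cfg.p)
    mean_min = np.zeros(cfg.p)
    mean_min[0] = cfg.class_sep
    mean_mid = (mean_maj + mean_min) / 2.0

    X = np.empty((n, cfg.p))
    X[:cfg.n_maj] = rng_feat.standard_normal((cfg.n_maj, cfg.p)) + mean_maj
    X[cfg.n_maj:] = rng_feat.standard_normal((cfg.n_min, cfg.p)) + mean_min
    y = np.array([maj_lab] * cfg.n_maj + [min_lab] * cfg.n_min, dtype=object)
    is_maj = np.arange(n) < cfg.n_maj

    # planted mislabeled rows: exact count, allocated proportionally by class,
    # features redrawn around the opposite class's mean
    n_noise = int(round(cfg.noise_frac * n))
    n_noise_maj = min(int(round(n_noise * cfg.n_maj / n)), cfg.n_maj)
    n_noise_min = n_noise - n_noise_maj
    noise_idx = np.concatenate([
        rng_pick.choice(cfg.n_maj, size=n_noise_maj, replace=False),
        cfg.n_maj + rng_pick.choice(cfg.n_min, size=n_noise_min, replace=False),
    ]).astype(int)
    for i in noise_idx:
        opposite = mean_min if is_maj[i] else mean_maj
        X[i] = rng_feat.standard_normal(cfg.p) + opposite

    # planted boundary rows: redrawn centred at the midpoint, labels kept
    n_bnd = int(round(cfg.boundary_frac * n))
    candidates = np.setdiff1d(np.arange(n), noise_idx)
    bnd_idx = np.sort(rng_pick.choice(candidates, size=n_bnd, replace=False)) \
        if n_bnd else np.empty(0, dtype=int)
    for i in bnd_idx:
        X[i] = rng_feat.standard_normal(cfg.p) + mean_mid

    perm = rng_shuffle.permutation(n)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    pos_class = maj_lab if cfg.positive == "majority" else min_lab
    return LabeledDataset(
        X[perm], y[perm],
        feature_names=[f"f{j}" for j in range(cfg.p)],
        positive_class=pos_class,
        provenance={
            "config": asdict(cfg),
            "noise_indices": sorted(int(inv[i]) for i in noise_idx),
            "boundary_indices": sorted(int(inv[i]) for i in bnd_idx),
        },
    )


PRESETS = {
    # 249 disease / 112 normal rows, 7 features
    "missed_abortion_like": GeneratorConfig(
        n_maj=249, n_min=112, p=7, class_sep=2.0,
        noise_frac=0.05, boundary_frac=0.10),
    # 500 disease / 268 normal rows, 8 features
    "diabetes_like": GeneratorConfig(
        n_maj=500, n_min=268, p=8, class_sep=2.0,
        noise_frac=0.05, boundary_frac=0.10),
}


def preset(name: str, seed: Optional[int] = 0) -> LabeledDataset:
    """A study-shaped dataset: moderate overlap, 5% noise, 10% boundary rows."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return generate(GeneratorConfig(**{**asdict(cfg), "seed": seed}))


def printed_results(classifier: str, dataset: str) -> ResultsTable:
    """The published benchmark table for one classifier on one dataset.

    Six metric rows (Precision, Sensitivity, Specificity, F-measure, MCC,
    AUC, as percentages with one decimal) by thirteen columns (Original plus
    twelve sampling algorithms).  Read-only fixture.
    """
    if classifier not in PRINTED_CLASSIFIERS:
        raise ValueError(f"unknown classifier key {classifier!r}")
    if dataset not in PRINTED_DATASETS:
        raise ValueError(f"unknown dataset key {dataset!r}")
    ref = resources.files("hybridsample") / "fixtures" / \
        f"printed_{classifier}_{dataset}.csv"
    with resources.as_file(ref) as path:
        return ResultsTable(pd.read_csv(path, index_col=0))
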