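import numpy as np
import pytest

from hybridsample import GeneratorConfig, LabeledDataset, generate


@pytest.fixture
def separated_clusters():
    """Two well-separated pure clusters, 12 majority + 6 minority rows."""
    rng = np.random.default_rng(42)
    Xa = rng.normal(0.0, 0.3, size=(12, 2))
    Xb = rng.normal(10.0, 0.3, size=(6, 2)) + np.array([0.0, 10.0])
    X = np.vstack([Xa, Xb])
    y = np.array(["maj"] * 12 + ["min"] * 6, dtype=object)
    return LabeledDataset(X, y, positive_class="min")


@pytest.fixture
def planted_noise_instance():
    """10-point planted instance: one majority row sits inside the minority
    cluster and one minority row inside the majority cluster."""
    X = np.array([
        [0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1], [0.05, 0.05],  # maj cluster
        [5.0, 5.0], [5.1, 5.0], [5.0, 5.1],                            # min cluster
        [5.05, 5.05],   # majority-labeled, deep in the minority cluster
        [0.05, 0.02],   # minority-labeled, deep in the majority cluster
    ])
    y = np.array(["A"] * 5 + ["B"] * 3 + ["A", "B"], dtype=object)
    return LabeledDataset(X, y, positive_class="B")


def random_dataset(seed, n=60, p=3, imbalance=0.7):
    """Generic random two-class dataset for oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.where(rng.random(n) < imbalance, "a", "b").astype(object)
    # guarantee both classes
    y[0], y[1] = "a", "b"
    return LabeledDataset(X, y)


@pytest.fixture
def overlap_dataset():
    return generate(GeneratorConfig(n_maj=80, n_min=40, p=3, class_sep=2.0,
                                    noise_frac=0.05, seed=7))
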