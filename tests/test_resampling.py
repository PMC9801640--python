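import numpy as np
import pytest

from hybridsample import (LabeledDataset, ResamplerConfig, SMOTE, SMOTEENN,
                          SMOTETomek, EditedNearestNeighbours, TomekLinks,
                          enn, preset, smote, smote_enn, smote_tomek,
                          tomek_link)
from conftest import random_dataset


def naive_knn(X, q, k, candidates):
    d = [(float(np.sum((X[c] - X[q]) ** 2)), c) for c in candidates if c != q]
    return [c for _, c in sorted(d)[:k]]


def naive_enn_deletions(ds, k, edit_target):
    """Loop-based re-implementation of the mark-then-delete edit."""
    marked = []
    for i in range(ds.n):
        if edit_target == "majority_only" and ds.y[i] != ds.majority_label:
            continue
        nb = naive_knn(ds.X, i, k, range(ds.n))
        same = sum(ds.y[j] == ds.y[i] for j in nb)
        if same < k - same:
            marked.append(i)
    return marked


def naive_tomek_deletions(ds):
    marked = set()
    for a in range(ds.n):
        for b in range(a + 1, ds.n):
            if ds.y[a] == ds.y[b]:
                continue
            if naive_knn(ds.X, a, 1, range(ds.n)) == [b] and \
               naive_knn(ds.X, b, 1, range(ds.n)) == [a]:
                marked.add(a if ds.y[a] == ds.majority_label else b)
    return sorted(marked)


class TestSmote:
    def test_balanced_input_is_identity(self):
        rng = np.random.default_rng(0)
        ds = LabeledDataset(rng.normal(size=(10, 2)),
                            np.array(["a"] * 5 + ["b"] * 5))
        res = smote(ds, ResamplerConfig(k_smote=2, seed=1))
        assert res.dataset.n == 10
        assert (res.origin == "original").all()
        np.testing.assert_array_equal(res.dataset.X, ds.X)

    def test_diabetes_shape_balances_to_500_500(self):
        ds = preset("diabetes_like", seed=2)
        res = smote(ds, ResamplerConfig(seed=5))
        assert res.counts_after == {"case": 500, "normal": 500}
        assert res.counts_before == {"case": 500, "normal": 268}

    def test_synthetic_rows_replay_from_seeded_stream(self):
        # two minority points on the x axis: every synthetic point is (r, 0),
        # and replaying the derived RNG stream through the interpolation
        # formula reproduces each row exactly
        X = np.array([[0.0, 0.0], [1.0, 0.0],
                      [10.0, 10.0], [11.0, 10.0], [10.0, 11.0], [11.0, 11.0]])
        y = np.array(["min", "min", "maj", "maj", "maj", "maj"])
        ds = LabeledDataset(X, y)
        seed = 123
        res = smote(ds, ResamplerConfig(k_smote=1, seed=seed))
        synth = res.dataset.X[res.origin == "synthetic"]
        assert len(synth) == 2
        assert np.all(synth[:, 1] == 0.0)
        assert np.all((synth[:, 0] > 0) & (synth[:, 0] < 1))
        # independent replay of the documented draw order
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        min_rows = [0, 1]
        neighbor = {0: 1, 1: 0}  # k=1: the other minority point
        for i in range(2):
            s = min_rows[i % 2]
            _ = rng.integers(1)  # neighbour slot draw (k=1)
            r = rng.random()
            expected = X[s] + r * (X[neighbor[s]] - X[s])
            np.testing.assert_array_equal(synth[i], expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_synthetic_rows_lie_on_seed_neighbor_segments(self, seed):
        ds = random_dataset(seed, n=80, p=3, imbalance=0.75)
        k = 3
        res = smote(ds, ResamplerConfig(k_smote=k, seed=seed))
        min_rows = np.flatnonzero(ds.y == ds.minority_label)
        synth = res.dataset.X[res.origin == "synthetic"]
        for i, x_new in enumerate(synth):
            s = min_rows[i % len(min_rows)]
            ok = False
            for nb in naive_knn(ds.X, s, k, min_rows):
                seg = ds.X[nb] - ds.X[s]
                diff = x_new - ds.X[s]
                t = np.dot(diff, seg) / np.dot(seg, seg)
                if 0.0 <= t <= 1.0 and np.linalg.norm(diff - t * seg) < 1e-9:
                    ok = True
                    break
            assert ok, f"synthetic row {i} not on any seed-neighbour segment"

    def test_counts_and_original_rows_preserved(self):
        ds = random_dataset(3, n=70, imbalance=0.8)
        res = smote(ds, ResamplerConfig(k_smote=3, seed=9))
        out = res.dataset
        assert out.minority_count == out.majority_count
        np.testing.assert_array_equal(out.X[:ds.n], ds.X)
        np.testing.assert_array_equal(out.y[:ds.n], ds.y)
        assert set(out.y[res.origin == "synthetic"]) == {ds.minority_label}

    def test_strict_formula_extrapolates(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0], [7.0]])
        y = np.array(["min", "min", "maj", "maj", "maj"])
        ds = LabeledDataset(X, y)
        res = SMOTE(k_neighbors=1, strict_formula=True,
                    random_state=0).fit_resample(ds)
        synth = res.dataset.X[res.origin == "synthetic", 0]
        # x_seed + r (x_seed - x_nb) leaves the segment [0, 1]
        assert np.all((synth < 0) | (synth > 1))

    def test_errors(self):
        ds = LabeledDataset(np.arange(8.0).reshape(-1, 1),
                            np.array(["a"] * 7 + ["b"]))
        with pytest.raises(ValueError, match="two minority"):
            smote(ds, ResamplerConfig(k_smote=1))
        ds2 = LabeledDataset(np.arange(8.0).reshape(-1, 1),
                             np.array(["a"] * 6 + ["b"] * 2))
        with pytest.raises(ValueError, match="minority count"):
            smote(ds2, ResamplerConfig(k_smote=2))


class TestEnn:
    def test_separated_clusters_untouched(self, separated_clusters):
        res = enn(separated_clusters, ResamplerConfig(k_enn=3))
        assert len(res.deleted_indices) == 0
        np.testing.assert_array_equal(res.dataset.X, separated_clusters.X)

    def test_planted_majority_noise_deleted(self, planted_noise_instance):
        res = enn(planted_noise_instance,
                  ResamplerConfig(k_enn=3, edit_target="majority_only"))
        assert list(res.deleted_indices) == [8]

    def test_minority_noise_needs_both_classes_mode(self, planted_noise_instance):
        maj_only = enn(planted_noise_instance,
                       ResamplerConfig(k_enn=3, edit_target="majority_only"))
        assert 9 not in maj_only.deleted_indices
        both = enn(planted_noise_instance,
                   ResamplerConfig(k_enn=3, edit_target="both_classes"))
        assert set(both.deleted_indices) == {8, 9}

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("target", ["majority_only", "both_classes"])
    def test_matches_naive_oracle(self, seed, target):
        ds = random_dataset(seed, n=60, p=2, imbalance=0.65)
        res = EditedNearestNeighbours(k_neighbors=3,
                                      edit_target=target).fit_resample(ds)
        assert sorted(res.deleted_indices) == naive_enn_deletions(ds, 3, target)

    def test_idempotent_on_separated_clusters(self, separated_clusters):
        once = enn(separated_clusters, ResamplerConfig(k_enn=3))
        twice = enn(once.dataset, ResamplerConfig(k_enn=3))
        np.testing.assert_array_equal(once.dataset.X, twice.dataset.X)

    def test_empty_class_warns_not_raises(self):
        # minority pair engulfed by the majority: both_classes edit removes it
        X = np.vstack([np.zeros((8, 1)) + np.arange(8)[:, None] * 0.1,
                       [[0.35], [0.45]]])
        y = np.array(["a"] * 8 + ["b"] * 2)
        res = EditedNearestNeighbours(
            k_neighbors=3, edit_target="both_classes").fit_resample(
                LabeledDataset(X, y))
        assert "editing emptied one class" in res.warnings

    def test_k_too_large(self):
        ds = random_dataset(0, n=5)
        with pytest.raises(ValueError, match="k_neighbors"):
            EditedNearestNeighbours(k_neighbors=4).fit_resample(ds)


class TestTomek:
    def test_separated_clusters_have_no_links(self, separated_clusters):
        res = tomek_link(separated_clusters)
        assert len(res.deleted_indices) == 0

    def test_planted_link_deletes_majority_member(self):
        X = np.array([[0.0], [0.1], [2.0], [3.0], [-2.0], [4.0]])
        y = np.array(["maj", "min", "maj", "maj", "maj", "min"])
        ds = LabeledDataset(X, y)
        res = tomek_link(ds)
        assert list(res.deleted_indices) == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        ds = random_dataset(seed, n=50, p=2, imbalance=0.7)
        res = tomek_link(ds)
        assert sorted(res.deleted_indices) == naive_tomek_deletions(ds)


class TestHybrids:
    def test_balanced_separated_identity(self, separated_clusters):
        ds = separated_clusters.subset(list(range(6)) + list(range(12, 18)))
        res = smote_enn(ds, ResamplerConfig(k_smote=2, k_enn=3, seed=0))
        np.testing.assert_array_equal(res.dataset.X, ds.X)
        res2 = smote_tomek(ds, ResamplerConfig(k_smote=2, seed=0))
        np.testing.assert_array_equal(res2.dataset.X, ds.X)

    @pytest.mark.parametrize("seed", range(3))
    def test_smote_enn_equals_stage_composition(self, seed, overlap_dataset):
        cfg = ResamplerConfig(k_smote=5, k_enn=3, seed=seed)
        hybrid = smote_enn(overlap_dataset, cfg)
        stage1 = smote(overlap_dataset, cfg)
        stage2 = enn(stage1.dataset,
                     ResamplerConfig(k_enn=3, edit_target="both_classes"))
        np.testing.assert_array_equal(hybrid.dataset.X, stage2.dataset.X)
        np.testing.assert_array_equal(hybrid.dataset.y, stage2.dataset.y)
        np.testing.assert_array_equal(hybrid.deleted_indices,
                                      stage2.deleted_indices)

    @pytest.mark.parametrize("seed", range(3))
    def test_smote_tomek_equals_stage_composition(self, seed, overlap_dataset):
        cfg = ResamplerConfig(k_smote=5, seed=seed)
        hybrid = smote_tomek(overlap_dataset, cfg)
        stage2 = tomek_link(smote(overlap_dataset, cfg).dataset)
        np.testing.assert_array_equal(hybrid.dataset.X, stage2.dataset.X)
        np.testing.assert_array_equal(hybrid.dataset.y, stage2.dataset.y)

    def test_planted_mislabeled_point_removed(self, planted_noise_instance):
        res = smote_enn(planted_noise_instance,
                        ResamplerConfig(k_smote=2, k_enn=3, seed=4))
        bad_row = planted_noise_instance.X[8]  # majority point in min cluster
        assert not any(np.array_equal(r, bad_row) for r in res.dataset.X)

    def test_origin_tags_survive_editing(self, overlap_dataset):
        res = smote_enn(overlap_dataset, ResamplerConfig(seed=1))
        assert set(res.origin) <= {"original", "synthetic"}
        assert res.counts_after == res.dataset.counts()


class TestDeterminismAndInvariance:
    def test_bit_reproducible_under_fixed_seed(self, overlap_dataset):
        a = smote_enn(overlap_dataset, ResamplerConfig(seed=77))
        b = smote_enn(overlap_dataset, ResamplerConfig(seed=77))
        np.testing.assert_array_equal(a.dataset.X, b.dataset.X)
        np.testing.assert_array_equal(a.dataset.y, b.dataset.y)

    def test_different_seeds_differ(self, overlap_dataset):
        a = smote(overlap_dataset, ResamplerConfig(seed=1))
        b = smote(overlap_dataset, ResamplerConfig(seed=2))
        assert not np.array_equal(a.dataset.X, b.dataset.X)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 20, size=(50, 4)).astype(float)
        y = np.where(np.arange(50) < 35, "a", "b").astype(object)
        ds = LabeledDataset(X, y)
        perm = [2, 0, 3, 1]
        ds_p = LabeledDataset(X[:, perm], y)
        for op in (lambda d: smote(d, ResamplerConfig(k_smote=3, seed=9)),
                   lambda d: enn(d, ResamplerConfig(k_enn=3)),
                   tomek_link):
            res, res_p = op(ds), op(ds_p)
            np.testing.assert_allclose(res.dataset.X[:, perm], res_p.dataset.X)
            np.testing.assert_array_equal(res.deleted_indices,
                                          res_p.deleted_indices)

    def test_adding_edit_stage_keeps_smote_stream(self, overlap_dataset):
        plain = smote(overlap_dataset, ResamplerConfig(seed=11))
        hybrid = SMOTEENN(random_state=11).fit_resample(overlap_dataset)
        n_synth = (plain.origin == "synthetic").sum()
        assert hybrid.counts_after_oversample == plain.counts_after
        # the hybrid's surviving synthetic rows all appear in the plain run
        synth_plain = {tuple(r) for r in plain.dataset.X[plain.origin == "synthetic"]}
        synth_hybrid = {tuple(r) for r in
                        hybrid.dataset.X[hybrid.origin == "synthetic"]}
        assert synth_hybrid <= synth_plain and n_synth >= len(synth_hybrid)
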