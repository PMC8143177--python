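import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porefilm import (
    RasterImage,
    cluster_masks,
    elbow_scan,
    kmeans_fit,
    labels_to_image,
    select_hole_cluster,
    select_k,
)
from conftest import brute_force_kmeans_wcss


class TestKMeansFit:
    def test_separable_duplicates(self):
        res = kmeans_fit(np.array([0.0, 0.0, 10.0, 10.0]), k=2, seed=0)
        assert res.wcss == pytest.approx(0.0)
        assert sorted(res.centroids[:, 0]) == [0.0, 10.0]

    def test_k1_is_the_mean(self):
        res = kmeans_fit(np.arange(1.0, 7.0), k=1, seed=0)
        assert res.centroids[0, 0] == pytest.approx(3.5)
        assert res.wcss == pytest.approx(17.5)

    def test_two_triplets_global_optimum(self):
        res = kmeans_fit(np.array([0.0, 1, 2, 9, 10, 11]), k=2, seed=0, n_init=10)
        assert res.wcss == pytest.approx(4.0)
        assert sorted(res.centroids[:, 0]) == pytest.approx([1.0, 10.0])

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.arange(3.0), k=4)

    def test_wcss_history_non_increasing(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 2))
        res = kmeans_fit(X, k=4, seed=1, n_init=3)
        h = np.asarray(res.wcss_history)
        assert np.all(np.diff(h) <= 1e-9)
        # stored wcss is recomputable from centroids and labels
        recomputed = float(((X - res.centroids[res.labels]) ** 2).sum())
        assert res.wcss == pytest.approx(recomputed)

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(5).normal(size=(50, 2))
        a = kmeans_fit(X, 3, seed=42)
        b = kmeans_fit(X, 3, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_on_tiny_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        k = int(rng.integers(2, 4))
        X = rng.normal(size=(n, 2)) * 5
        res = kmeans_fit(X, k, seed=trial, n_init=10)
        assert res.wcss == pytest.approx(brute_force_kmeans_wcss(X, k), rel=1e-9, abs=1e-9)

    def test_agrees_with_sklearn_reference(self):
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(11)
        X = np.concatenate([rng.normal(0, 1, (100, 2)), rng.normal(8, 1, (100, 2))])
        ours = kmeans_fit(X, 2, seed=0, n_init=10)
        ref = sklearn_cluster.KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert ours.wcss == pytest.approx(ref.inertia_, rel=1e-6)


class TestSelectK:
    def test_hand_evaluated_knees(self):
        assert select_k([1, 2, 3, 4], [401.5, 101.5, 1.5, 1.0]) == 2
        assert select_k([2, 3, 4, 5, 6], [100, 10, 9, 8, 7]) == 3

    def test_linear_decline_ties_to_smallest(self):
        assert select_k([2, 3, 4, 5], [40, 30, 20, 10]) == 2

    def test_flat_curve_ties_to_smallest(self):
        assert select_k([2, 3, 4, 5], [5.0, 5.0, 5.0, 5.0]) == 2

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            select_k([2, 3], [10, 1])

    @given(
        scale=st.floats(0.1, 1000),
        shift=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_affine_wcss_rescale(self, scale, shift):
        ks = [2, 3, 4, 5, 6]
        ws = np.array([100.0, 30, 12, 8, 7])
        assert select_k(ks, ws) == select_k(ks, ws * scale + shift)


class TestElbowScan:
    def test_three_separated_triplets(self):
        X = np.array([0.0, 1, 2, 50, 51, 52, 100, 101, 102])
        scan = elbow_scan(X, k_min=1, k_max=6, seed=0, n_init=10)
        assert scan.selected_k == 3
        assert np.all(np.diff(scan.wcss_values) <= 1e-9)

    def test_degenerate_cloud_ties_to_smallest_k(self):
        X = np.zeros(20)
        scan = elbow_scan(X, k_min=2, k_max=5, seed=0, n_init=2)
        assert scan.selected_k == 2

    def test_default_range_matches_two_to_six(self):
        X = np.random.default_rng(0).normal(size=(40, 1))
        scan = elbow_scan(X, seed=0, n_init=2)
        assert scan.k_values == (2, 3, 4, 5, 6)

    def test_wcss_non_increasing_in_k(self):
        X = np.random.default_rng(3).normal(size=(60, 2))
        scan = elbow_scan(X, k_min=1, k_max=5, seed=0, n_init=10)
        assert np.all(np.diff(scan.wcss_values) <= 1e-6)


class TestLabelFolding:
    def test_unflatten_and_roundtrip(self):
        res = kmeans_fit(np.array([0.0, 10, 10, 0]), k=2, seed=0)
        img = labels_to_image(res, (2, 2))
        assert img.shape == (2, 2)
        assert img[0, 0] == img[1, 1] and img[0, 1] == img[1, 0]
        assert img[0, 0] != img[0, 1]

    def test_shape_mismatch_rejected(self):
        res = kmeans_fit(np.arange(4.0), k=1)
        with pytest.raises(ValueError):
            labels_to_image(res, (3, 2))

    def test_masks_partition_image(self):
        label_img = np.array([[0, 1], [1, 0]])
        masks = cluster_masks(label_img)
        assert len(masks) == 2
        union = np.zeros((2, 2), dtype=int)
        for m in masks:
            union += m.values.astype(int)
        assert np.all(union == 1)  # disjoint cover

    def test_single_label_full_mask(self):
        masks = cluster_masks(np.zeros((3, 3), dtype=int))
        assert len(masks) == 1 and masks[0].foreground_count == 9

    def test_permuting_labels_preserves_geometry(self):
        label_img = np.array([[0, 1, 2], [2, 1, 0], [0, 0, 1]])
        permuted = np.array([2, 0, 1])[label_img]
        geo = lambda masks: sorted(tuple(m.values.reshape(-1)) for m in masks)
        assert geo(cluster_masks(label_img)) == geo(cluster_masks(permuted))


class TestHoleSelection:
    def test_picks_darkest_cluster(self):
        gray = RasterImage(np.array([[200.0, 200, 30], [200, 30, 30], [200, 200, 200]]))
        label_img = (gray.pixels < 100).astype(int)
        masks = cluster_masks(label_img)
        hole = select_hole_cluster(masks, gray)
        np.testing.assert_array_equal(hole.values, gray.pixels < 100)

    def test_equal_intensity_ties_to_smaller_mask(self, caplog):
        gray = RasterImage(np.full((3, 3), 100.0))
        label_img = np.zeros((3, 3), dtype=int)
        label_img[0, 0] = 1
        hole = select_hole_cluster(cluster_masks(label_img), gray)
        assert hole.foreground_count == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_hole_cluster([], RasterImage(np.zeros((3, 3))))
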