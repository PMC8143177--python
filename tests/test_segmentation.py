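import numpy as np
import pytest

from porefilm import (
    RasterImage,
    apply_threshold,
    label_regions,
    median_filter,
    otsu_threshold,
    remove_small_regions,
    sobel_edges,
)
from porefilm.raster import BinaryMask
from porefilm.segmentation import DegenerateImageError
from conftest import brute_force_otsu


class TestMedianFilter:
    def test_center_impulse_removed(self):
        img = RasterImage(np.array([[1.0, 1, 1], [1, 99, 1], [1, 1, 1]]))
        out = median_filter(img, window=3)
        assert out.pixels[1, 1] == 1.0

    def test_constant_unchanged(self):
        img = RasterImage(np.full((6, 6), 77.0))
        np.testing.assert_array_equal(median_filter(img, 5).pixels, img.pixels)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(RasterImage(np.zeros((5, 5))), window=4)

    def test_removes_all_isolated_impulses(self):
        rng = np.random.default_rng(0)
        base = np.full((50, 50), 200.0)
        # plant isolated impulses at least 3 px apart so each stays isolated
        coords = [(r, c) for r in range(2, 48, 5) for c in range(2, 48, 5)]
        for r, c in coords:
            base[r, c] = 0.0 if rng.random() < 0.5 else 255.0
        out = median_filter(RasterImage(base), window=5)
        assert np.all(out.pixels == 200.0)

    def test_output_range_within_input_range(self):
        rng = np.random.default_rng(1)
        img = RasterImage(rng.integers(10, 90, size=(12, 12)).astype(float))
        out = median_filter(img, 3)
        assert out.pixels.min() >= img.pixels.min()
        assert out.pixels.max() <= img.pixels.max()


class TestOtsu:
    def test_balanced_extremes_tie_to_zero(self):
        px = np.array([0.0] * 10 + [255.0] * 10).reshape(4, 5)
        assert otsu_threshold(RasterImage(px)) == 0

    def test_two_level_tie_to_lower_level(self):
        px = np.array([10.0] * 3 + [200.0] * 3 + [10.0, 200.0, 10.0]).reshape(3, 3)
        # 5x10 + 4x200 histogram: every t in 10..199 ties; smallest returned
        px = np.array([[10.0, 10, 200], [10, 200, 200], [10, 10, 200]])
        assert otsu_threshold(RasterImage(px)) == 10

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(RasterImage(np.full((4, 4), 7.0)))

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        n_levels = int(rng.integers(2, 8))
        levels = rng.choice(256, size=n_levels, replace=False)
        vals = rng.choice(levels, size=400).astype(float)
        img = RasterImage(vals.reshape(20, 20))
        assert otsu_threshold(img) == brute_force_otsu(vals)

    def test_close_to_skimage_reference(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(60, 10, 300), rng.normal(190, 12, 300)])
        vals = np.clip(np.round(vals), 0, 255)
        img = RasterImage(vals.reshape(30, 20))
        ours = otsu_threshold(img)
        ref = threshold_otsu(vals.astype(np.uint8))
        assert abs(ours - ref) <= 1  # same split up to bin-edge convention


class TestApplyThreshold:
    def test_dark_foreground(self):
        img = RasterImage(np.array([[0.0, 255, 0], [255, 0, 255], [0, 0, 0]]))
        m = apply_threshold(img, 0, foreground="dark")
        np.testing.assert_array_equal(m.values, img.pixels == 0)

    def test_complement_property(self):
        rng = np.random.default_rng(2)
        img = RasterImage(rng.integers(0, 256, (8, 8)).astype(float))
        dark = apply_threshold(img, 100, "dark")
        bright = apply_threshold(img, 100, "bright")
        assert np.all(dark.values ^ bright.values)

    def test_otsu_chain_recovers_two_tone(self, two_tone):
        t = otsu_threshold(two_tone)
        m = apply_threshold(two_tone, t, "dark")
        np.testing.assert_array_equal(m.values, two_tone.pixels == 40)


class TestLabelRegions:
    def test_two_disjoint_blocks(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[1:3, 1:3] = True
        mask[5:7, 5:7] = True
        regions = label_regions(BinaryMask(mask), connectivity=8)
        assert regions.n_regions == 2
        assert sorted(regions.areas()) == [4, 4]

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_regions(BinaryMask(mask), 8).n_regions == 1
        assert label_regions(BinaryMask(mask), 4).n_regions == 2

    def test_empty_mask(self):
        assert label_regions(BinaryMask(np.zeros((4, 4), bool))).n_regions == 0

    def test_connectivity4_never_fewer_regions(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            mask = BinaryMask(np.random.default_rng(seed).random((20, 20)) < 0.4)
            assert label_regions(mask, 4).n_regions >= label_regions(mask, 8).n_regions

    def test_raster_scan_id_order(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 4] = True  # encountered first in raster order
        mask[3, 0:2] = True
        regions = label_regions(BinaryMask(mask), 8)
        assert regions.labels[0, 4] == 1
        assert regions.labels[3, 0] == 2

    def test_area_sum_equals_foreground_count(self):
        mask = BinaryMask(np.random.default_rng(8).random((30, 30)) < 0.3)
        regions = label_regions(mask, 8)
        assert regions.areas().sum() == mask.foreground_count


class TestRemoveSmall:
    def test_small_regions_dropped_and_ids_compacted(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0, 0:3] = True  # area 3
        mask[5:10, 5:10] = True  # area 25
        regions = label_regions(BinaryMask(mask), 8)
        out = remove_small_regions(regions, min_area=5)
        assert out.n_regions == 1
        assert out.areas().tolist() == [25]
        assert set(np.unique(out.labels)) == {0, 1}

    def test_zero_min_area_is_identity(self):
        mask = BinaryMask(np.random.default_rng(1).random((10, 10)) < 0.3)
        regions = label_regions(mask, 8)
        out = remove_small_regions(regions, 0)
        np.testing.assert_array_equal(out.labels, regions.labels)

    def test_min_area_above_image_clears_everything(self):
        regions = label_regions(BinaryMask(np.ones((5, 5), bool)), 8)
        assert remove_small_regions(regions, 26).n_regions == 0


class TestSobel:
    def test_constant_zero_magnitude_empty_mask(self):
        em = sobel_edges(RasterImage(np.full((6, 6), 50.0)))
        assert np.all(em.magnitude == 0)
        assert em.n_edge_points == 0

    def test_unit_ramp_interior_magnitude_eight(self):
        px = np.tile(np.arange(10, dtype=float), (10, 1))
        em = sobel_edges(RasterImage(px))
        interior = em.magnitude[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 8.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        px = rng.integers(0, 200, (10, 10)).astype(float)
        a = sobel_edges(RasterImage(px)).magnitude
        b = sobel_edges(RasterImage(px + 50)).magnitude
        np.testing.assert_allclose(a, b)

    def test_edge_point_count_matches_mask(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 200.0
        em = sobel_edges(RasterImage(px), edge_threshold=0.5)
        assert em.n_edge_points == int(em.mask.sum()) > 0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            sobel_edges(RasterImage(np.zeros((4, 4))), edge_threshold=0.0)
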