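"""CIELAB transform and (a, b) k-means with exhaustive oracles."""

import itertools

import numpy as np
import pytest

from hydromorph.colour_cluster import (DegenerateInputError, TrainingRegion,
                                       build_training_mask, kmeans_ab, lloyd_kmeans,
                                       rgb_to_lab, srgb_to_lab)
from hydromorph.classes import FeatureClass
from hydromorph.geo import GeoTransform
from hydromorph.rasters import LabImage, RGBImage

T = GeoTransform(0.0, 100.0, 1.0)


def _lab_image(rgb: np.ndarray, mask=None) -> LabImage:
    return rgb_to_lab(RGBImage(pixels=rgb.astype(np.uint8), transform=T,
                               valid_mask=mask))


class TestSrgbToLab:
    # reference values computed from the sRGB -> XYZ(D65) -> CIELAB formulas
    @pytest.mark.parametrize("rgb, expected", [
        ((255, 255, 255), (100.0, 0.0, 0.0)),
        ((0, 0, 0), (0.0, 0.0, 0.0)),
        ((255, 0, 0), (53.2408, 80.0925, 67.2032)),
    ])
    def test_reference_colours(self, rgb, expected):
        lab = srgb_to_lab(np.array(rgb, dtype=float))
        np.testing.assert_allclose(lab, expected, atol=2e-3)

    def test_greys_are_exactly_neutral_and_l_increasing(self):
        g = np.arange(256)
        lab = srgb_to_lab(np.stack([g, g, g], axis=-1))
        assert np.all(np.abs(lab[:, 1]) <= 1e-6)
        assert np.all(np.abs(lab[:, 2]) <= 1e-6)
        assert np.all(np.diff(lab[:, 0]) > 0)

    def test_agrees_with_skimage_reference(self, rng):
        from skimage.color import rgb2lab

        rgb = rng.integers(0, 256, size=(40, 3))
        ours = srgb_to_lab(rgb.astype(float))
        theirs = rgb2lab(rgb[None, :, :] / 255.0)[0]
        np.testing.assert_allclose(ours, theirs, atol=0.02)


def _exhaustive_inertia(points: np.ndarray, k: int) -> float:
    """Global k-means optimum by enumerating all assignments (n <= 8)."""
    n = len(points)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        assign = np.array(assign)
        inertia = 0.0
        for c in range(k):
            grp = points[assign == c]
            inertia += float(((grp - grp.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best


class TestKmeans:
    def test_two_separated_blobs_recover_means(self, rng):
        blob1 = rng.normal(0, 0.01, (30, 2)) + [-40, 10]
        blob2 = rng.normal(0, 0.01, (30, 2)) + [40, -10]
        model, assign = lloyd_kmeans(np.vstack([blob1, blob2]), 2, seed=3)
        got = sorted(map(tuple, model.centroids))
        np.testing.assert_allclose(got[0], blob1.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(got[1], blob2.mean(axis=0), atol=1e-9)

    def test_k1_closed_form(self, rng):
        pts = rng.normal(size=(50, 2))
        model, assign = lloyd_kmeans(pts, 1, seed=0)
        np.testing.assert_allclose(model.centroids[0], pts.mean(axis=0), atol=1e-12)
        expected = float(((pts - pts.mean(axis=0)) ** 2).sum())
        assert model.inertia == pytest.approx(expected)
        assert (assign == 0).all()

    @pytest.mark.parametrize("n, k", [(6, 2), (7, 2), (8, 3), (6, 3)])
    def test_matches_exhaustive_partition_optimum(self, n, k, rng):
        for trial in range(5):
            pts = rng.normal(size=(n, 2)) * 10
            model, _ = lloyd_kmeans(pts, k, seed=trial)
            assert model.inertia == pytest.approx(_exhaustive_inertia(pts, k),
                                                  rel=1e-9, abs=1e-9)

    def test_agrees_with_sklearn_on_blobs(self, rng):
        from sklearn.cluster import KMeans

        pts = np.vstack([rng.normal(0, 1, (40, 2)) + [20, 0],
                         rng.normal(0, 1, (40, 2)) + [-20, 5],
                         rng.normal(0, 1, (40, 2)) + [0, -25]])
        model, _ = lloyd_kmeans(pts, 3, seed=1)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert model.inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_inertia_history_non_increasing(self, rng):
        pts = rng.normal(size=(200, 2)) * 5
        model, _ = lloyd_kmeans(pts, 4, seed=2, n_init=1)
        hist = np.array(model.inertia_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(100, 2))
        m1, a1 = lloyd_kmeans(pts, 3, seed=9)
        m2, a2 = lloyd_kmeans(pts, 3, seed=9)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_degenerate_input_raises(self):
        pts = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(DegenerateInputError):
            lloyd_kmeans(pts, 2, seed=0)

    def test_luminance_shift_invariance(self, rng):
        rgb = rng.integers(40, 200, size=(12, 12, 3)).astype(np.uint8)
        img = _lab_image(rgb)
        shifted = LabImage(L=np.clip(img.L + 17.0, 0, 100), a=img.a, b=img.b,
                           transform=img.transform, valid_mask=img.valid_mask)
        m1, a1 = kmeans_ab(img, 3, seed=4)
        m2, a2 = kmeans_ab(shifted, 3, seed=4)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_masked_pixels_unassigned(self, rng):
        rgb = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        mask = np.zeros((8, 8), dtype=bool)
        mask[:4] = True
        img = _lab_image(rgb, mask)
        _, assign = kmeans_ab(img, 2, seed=0)
        assert (assign[~mask] == -1).all()
        assert (assign[mask] >= 0).all()


def _best_subset_jaccard(assign, ref, k):
    """Brute-force best Jaccard over all non-empty cluster subsets."""
    best = -1.0
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            sel = np.isin(assign, subset)
            inter = (sel & ref).sum()
            union = (sel | ref).sum()
            best = max(best, inter / union if union else 0.0)
    return best


class TestBuildTrainingMask:
    def _two_colour_window(self):
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        rgb[:, :5] = (200, 40, 40)
        rgb[:, 5:] = (40, 40, 200)
        ref = np.zeros((10, 10), dtype=bool)
        ref[:, :5] = True
        return _lab_image(rgb), ref

    def test_perfect_two_colour_separation(self):
        img, ref = self._two_colour_window()
        # >= 50% coverage needed: pad reference to half the window
        region = TrainingRegion(FeatureClass.SIDE_BAR, (0, 0, 10, 10), ref)
        res = build_training_mask(img, region, seed=0)
        assert res.chosen_k == 2
        assert res.jaccard == pytest.approx(1.0)
        assert res.meets_threshold
        np.testing.assert_array_equal(res.mask, ref)

    def test_all_true_reference_on_two_colours(self):
        img, _ = self._two_colour_window()
        region = TrainingRegion(FeatureClass.SIDE_BAR, (0, 0, 10, 10),
                                np.ones((10, 10), dtype=bool))
        res = build_training_mask(img, region, k_max=2, accept_threshold=0.99, seed=0)
        # best single subset at k=2 is the union of both clusters (Jaccard 1);
        # any single cluster would only reach its own proportion
        assert res.jaccard == pytest.approx(1.0)
        assert res.mask.all()

    @pytest.mark.parametrize("k", [3, 4, 6])
    def test_subset_selection_matches_exhaustive_search(self, k, rng):
        from hydromorph.colour_cluster import lloyd_kmeans

        rgb = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        img = _lab_image(rgb)
        ref = rng.random((16, 16)) < 0.6
        ref[:8] = True  # keep >= 50% coverage
        region = TrainingRegion(FeatureClass.GRASS, (0, 0, 16, 16), ref)
        res = build_training_mask(img, region, k_max=k, accept_threshold=1.1, seed=1)
        pts = np.column_stack([img.a.ravel(), img.b.ravel()])
        best = -1.0
        for kk in range(2, k + 1):
            _, assign = lloyd_kmeans(pts, kk, seed=1)
            best = max(best, _best_subset_jaccard(assign, ref.ravel(), kk))
        assert res.jaccard == pytest.approx(best)

    def test_below_threshold_flag_when_colours_mix(self, rng):
        rgb = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
        ref = np.zeros((12, 12), dtype=bool)
        ref[::2] = True  # interleaved rows cannot be matched by colour clusters
        img = _lab_image(rgb)
        region = TrainingRegion(FeatureClass.SHADOW, (0, 0, 12, 12), ref)
        res = build_training_mask(img, region, accept_threshold=0.999, seed=0)
        assert not res.meets_threshold
        assert 0.0 <= res.jaccard < 0.999

    def test_reference_coverage_below_half_rejected(self):
        ref = np.zeros((10, 10), dtype=bool)
        ref[0, 0] = True
        with pytest.raises(ValueError, match="50%"):
            TrainingRegion(FeatureClass.TREE, (0, 0, 10, 10), ref)
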