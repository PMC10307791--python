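"""Unit tests for the image statistics: focus selection, background,
segmentation, screening, separation factor, enrichment and CV metrics."""

import numpy as np
import pytest

from condquant import image, simulate
from condquant.image import (
    BackgroundStats,
    CondensateSet,
    SegmentationConfig,
)
from condquant.scene import ImageScene


def make_scene(stack):
    return ImageScene(np.asarray(stack, dtype=float)[:, np.newaxis], pixel_size=100.0)


class TestBestFocus:
    def test_single_slice(self):
        assert image.best_focus_slice(make_scene(np.ones((1, 8, 8)))) == 0

    def test_picks_max_stdev_slice(self):
        stack = np.ones((4, 8, 8))
        for z, amp in enumerate([1.0, 1.0, 5.0, 1.0]):
            stack[z, ::2, ::2] += amp
        assert image.best_focus_slice(make_scene(stack)) == 2

    def test_constant_stack_tie_breaks_low(self):
        assert image.best_focus_slice(make_scene(np.full((3, 8, 8), 2.0))) == 0


class TestProjection:
    def test_single_slice_identity(self):
        stack = np.arange(64, dtype=float).reshape(1, 8, 8)
        np.testing.assert_array_equal(
            image.max_intensity_projection(make_scene(stack)), stack[0]
        )

    def test_pixelwise_maximum(self):
        stack = np.stack([np.full((8, 8), 1.0), np.full((8, 8), 3.0)])
        assert image.max_intensity_projection(make_scene(stack))[0, 0] == 3.0

    def test_projection_dominates_slices(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(size=(5, 12, 12))
        proj = image.max_intensity_projection(make_scene(stack))
        assert np.all(proj[np.newaxis] >= stack - 1e-15)


class TestBackground:
    def test_uniform(self):
        stats = image.estimate_background(np.full((16, 16), 5.0), min_pixels=10)
        assert stats.mean == 5.0 and stats.stdev == 0.0

    def test_hand_computed_population_stdev(self):
        img = np.array([[1, 1, 1, 1], [3, 3, 3, 3]], dtype=float)
        stats = image.estimate_background(img, min_pixels=1)
        assert stats.mean == pytest.approx(2.0)
        assert stats.stdev == pytest.approx(1.0)  # population, not sample

    def test_empty_mask_uses_whole_image(self):
        img = np.full((12, 12), 7.0)
        stats = image.estimate_background(img, np.zeros_like(img, bool), min_pixels=10)
        assert stats.n_pixels == 144

    def test_too_few_pixels_raises(self):
        img = np.ones((12, 12))
        mask = np.ones_like(img, bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="background pixels"):
            image.estimate_background(img, mask, min_pixels=100)


class TestSegmentation:
    def test_blank_image_no_objects(self):
        assert image.segment_condensates(np.ones((16, 16))).max() == 0

    def test_recovers_generated_discs(self, noiseless_config):
        sc = simulate.generate_condensate_scene(noiseless_config(seed=4))
        proj = image.max_intensity_projection(sc.scene, 0)
        labels = image.segment_condensates(proj, SegmentationConfig(smooth_sigma_px=0))
        bg = image.estimate_background(proj, labels > 0, min_pixels=10)
        cset = image.screen_condensates(labels, proj, bg)
        assert cset.n_objects == len(sc.truth.radii_nm)
        # centroids within 1 px of the generated sphere centers
        truth_px = sc.truth.centers_nm / sc.scene.pixel_size
        found = np.array([o.centroid for o in cset.objects])
        for c in truth_px:
            assert np.min(np.linalg.norm(found - c, axis=1)) < 1.0

    def test_watershed_splits_touching_discs(self):
        img = np.ones((40, 60))
        rr, cc = np.ogrid[:40, :60]
        img[(rr - 20) ** 2 + (cc - 22) ** 2 <= 64] = 10.0
        img[(rr - 20) ** 2 + (cc - 38) ** 2 <= 64] = 10.0  # touching pair
        merged = image.segment_condensates(img, SegmentationConfig(smooth_sigma_px=0))
        assert merged.max() == 1
        split = image.segment_condensates(
            img, SegmentationConfig(smooth_sigma_px=0, split_touching=True, min_distance_px=5)
        )
        assert split.max() == 2

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(1, 2, size=(32, 32))
        img[8:14, 8:14] = 20.0
        a = image.segment_condensates(img)
        b = image.segment_condensates(img)
        np.testing.assert_array_equal(a, b)


class TestScreening:
    @staticmethod
    def fixture():
        """Labeled objects straddling the 9-px and 3-sigma thresholds."""
        img = np.zeros((40, 40))
        labels = np.zeros((40, 40), dtype=np.int32)
        bg = BackgroundStats(mean=1.0, stdev=0.5, n_pixels=1000)
        cut = bg.mean + 3 * bg.stdev  # 2.5
        specs = [
            (8, 10.0),    # big area, bright: keep
            (8, cut),     # exactly at the intensity cut: keep
            (8, 2.0),     # below cut: remove
            (9, 10.0),    # exactly 9 px: keep
            (8, 10.0),    # bright again: keep
        ]
        areas = [16, 16, 16, 9, 8]
        r, lab = 2, 1
        for (_, value), area in zip(specs, areas):
            cols = slice(2 + (lab - 1) * 7, 2 + (lab - 1) * 7 + (4 if area > 9 else 3))
            rows = slice(2, 2 + (4 if area == 16 else 3))
            block = np.zeros((40, 40), bool)
            block[rows, cols] = True
            # trim to the exact pixel count
            idx = np.argwhere(block)[:area]
            labels[tuple(idx.T)] = lab
            img[tuple(idx.T)] = value
            lab += 1
        return img, labels, bg

    def test_matches_brute_force_predicate(self):
        img, labels, bg = self.fixture()
        cset = image.screen_condensates(labels, img, bg, min_area_px=9, k=3)
        cut = bg.mean + 3 * bg.stdev
        survivors_bf = set()
        for lab in range(1, labels.max() + 1):
            pix = labels == lab
            if pix.sum() >= 9 and img[pix].mean() >= cut:
                survivors_bf.add(lab)
        # compare surviving pixel sets exactly
        np.testing.assert_array_equal(
            cset.mask, np.isin(labels, sorted(survivors_bf))
        )

    def test_eight_pixel_bright_object_removed(self):
        img, labels, bg = self.fixture()
        cset = image.screen_condensates(labels, img, bg)
        assert not cset.mask[labels == 5].any()  # area 8, bright -> removed

    def test_boundary_objects_retained(self):
        img, labels, bg = self.fixture()
        cset = image.screen_condensates(labels, img, bg)
        assert cset.mask[labels == 2].all()  # mean exactly at bg + 3 sigma
        assert cset.mask[labels == 4].all()  # area exactly 9 px

    def test_idempotent(self):
        img, labels, bg = self.fixture()
        once = image.screen_condensates(labels, img, bg)
        twice = image.screen_condensates(once.label_map, img, bg)
        np.testing.assert_array_equal(once.label_map, twice.label_map)

    def test_relabels_contiguously(self):
        img, labels, bg = self.fixture()
        cset = image.screen_condensates(labels, img, bg)
        present = np.unique(cset.label_map)
        np.testing.assert_array_equal(present, np.arange(cset.n_objects + 1))


class TestSeparationFactor:
    def test_no_condensates_zero(self):
        img = np.ones((8, 8))
        cset = CondensateSet(label_map=np.zeros((8, 8), dtype=int))
        assert image.separation_factor(img, cset).separation_factor == 0.0

    def test_all_labeled_hundred(self):
        img = np.ones((8, 8))
        cset = CondensateSet(label_map=np.ones((8, 8), dtype=int))
        assert image.separation_factor(img, cset).separation_factor == 100.0

    def test_direct_summation_example(self):
        # 16-px image: 4 labeled px of value 10, 12 px of value 1 -> 100*40/52
        img = np.ones((4, 4))
        labels = np.zeros((4, 4), dtype=int)
        img[:2, :2] = 10.0
        labels[:2, :2] = 1
        res = image.separation_factor(img, CondensateSet(label_map=labels))
        assert res.separation_factor == pytest.approx(100 * 40 / 52)

    def test_zero_image_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            image.separation_factor(
                np.zeros((8, 8)), CondensateSet(label_map=np.zeros((8, 8), int))
            )


class TestEnrichment:
    def test_uniform_client_is_one(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:5, 2:5] = 1
        res = image.client_enrichment(np.full((10, 10), 4.0), CondensateSet(label_map=labels))
        assert res.raw_enrichment == pytest.approx(1.0)

    def test_hand_ratio_with_bleedthrough(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:5] = 1
        img = np.where(labels > 0, 8.0, 2.0)
        res = image.client_enrichment(img, CondensateSet(label_map=labels), 1.5)
        assert res.raw_enrichment == pytest.approx(4.0)
        assert res.corrected_enrichment == pytest.approx(2.5)

    def test_recovers_partition_on_noiseless_scene(self, noiseless_config, quantify_enrichment):
        sc = simulate.generate_condensate_scene(
            noiseless_config(seed=5),
            simulate.CondensateParams(client_partition=5.0, bleedthrough=0.0),
        )
        res = quantify_enrichment(sc)
        assert res.raw_enrichment == pytest.approx(5.0, rel=1e-6)

    def test_zero_outside_mean_raises(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[:5] = 1
        img = np.where(labels > 0, 8.0, 0.0)
        with pytest.raises(ValueError, match="background"):
            image.client_enrichment(img, CondensateSet(label_map=labels))


class TestLabelingRatio:
    @pytest.mark.parametrize(
        "a,b,expected", [(19, 0.5, 38.0), (3.0, 3.0, 1.0), (2, 0.5, 4.0)]
    )
    def test_fold(self, a, b, expected):
        assert image.expected_labeling_ratio(a, b) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            image.expected_labeling_ratio(0, 1)


class TestImageCV:
    def test_constant_zero(self):
        assert image.image_cv(np.full((8, 8), 3.0))[0] == 0.0

    def test_hand_computed(self):
        cv, _ = image.image_cv(np.array([[1.0, 1.0], [3.0, 3.0]]))
        assert cv == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(1, 5, size=(16, 16))
        assert image.image_cv(img)[0] == pytest.approx(image.image_cv(7 * img)[0])

    def test_normalization(self):
        img = np.array([[1.0, 3.0]])
        cv, norm = image.image_cv(img, reference_cv=0.25)
        assert norm == pytest.approx(cv / 0.25)


class TestNetworkIntensity:
    def test_self_reference_is_one(self):
        stack = np.arange(32, dtype=float).reshape(2, 4, 4)
        scene = make_scene(stack)
        ref = image.max_intensity_projection(scene).mean()
        assert image.network_intensity(scene, 0, ref) == pytest.approx(1.0)

    def test_threefold(self):
        stack = np.full((2, 4, 4), 6.0)
        assert image.network_intensity(make_scene(stack), 0, 2.0) == pytest.approx(3.0)
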