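"""Image-pipeline tests: cropping, segmentation against generator truth,
morphology and color measurement, and the 46-feature extraction."""

import colorsys

import numpy as np
import pytest
from skimage import color as skcolor
from skimage.draw import disk as draw_disk

from kiwifuse.errors import SegmentationError
from kiwifuse.imgfeat import (
    FEATURE_NAMES,
    RegionMasks,
    apply_mask,
    compute_color_means,
    compute_morphology,
    crop_center,
    exg_transform,
    extract_image_features,
    locule_area_rate,
    segment_middle_cut,
    segment_whole_fruit,
)
from kiwifuse.synth import default_scene, render_middle_cut, render_whole_fruit


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestCropCenter:
    def test_centered_block_indices(self):
        img = np.zeros((2000, 2000, 3), dtype=np.uint8)
        img[200, 200] = (1, 2, 3)
        img[1799, 1799] = (4, 5, 6)
        out = crop_center(img, 1600)
        assert out.shape == (1600, 1600, 3)
        assert tuple(out[0, 0]) == (1, 2, 3)
        assert tuple(out[-1, -1]) == (4, 5, 6)

    def test_exact_size_is_identity(self):
        img = np.arange(48).reshape(4, 4, 3)
        np.testing.assert_array_equal(crop_center(img, 4), img)

    def test_odd_margin_uses_floor_split(self):
        img = np.arange(5 * 5).reshape(5, 5)
        out = crop_center(img, 2)
        np.testing.assert_array_equal(out, img[1:3, 1:3])

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            crop_center(np.zeros((1000, 1000, 3)), 1600)


class TestSegmentWholeFruit:
    def test_recovers_truth_mask(self, whole_render):
        img, truth = whole_render
        mask = segment_whole_fruit(img)
        assert iou(mask, truth) >= 0.98

    def test_small_noise_blobs_are_removed(self, whole_render):
        img, truth = whole_render
        base = segment_whole_fruit(img)
        noisy = img.copy()
        rng = np.random.default_rng(0)
        for _ in range(5):
            r, c = rng.integers(10, 80, 2)
            rr, cc = draw_disk((r, c), 3, shape=noisy.shape[:2])
            noisy[rr, cc] = (10, 10, 10)   # dark blobs < 50 px, far from fruit
        np.testing.assert_array_equal(segment_whole_fruit(noisy), base)

    def test_uniform_image_fails(self):
        with pytest.raises(SegmentationError):
            segment_whole_fruit(np.full((64, 64, 3), 200, dtype=np.uint8))


class TestMorphology:
    def test_disk_is_round(self):
        mask = np.zeros((512, 512), dtype=bool)
        rr, cc = draw_disk((256, 256), 200)
        mask[rr, cc] = True
        m = compute_morphology(mask)
        assert 0.95 <= m.roundness <= 1.05
        assert 1.0 <= m.aspect_ratio <= 1.02

    def test_square_roundness_is_pi_over_four(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[50:250, 50:250] = True
        m = compute_morphology(mask)
        assert m.roundness == pytest.approx(np.pi / 4, abs=0.02)
        assert m.area == 200 * 200

    def test_ellipse_aspect_ratio(self, rng):
        scene = default_scene(1024)
        _, mask = render_whole_fruit(scene, rng)
        m = compute_morphology(mask)
        a, b = scene.fruit_axes
        assert m.aspect_ratio == pytest.approx(a / b, abs=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_morphology(np.zeros((10, 10), dtype=bool))


class TestApplyMask:
    def test_identity_annihilation_and_mixture(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        np.testing.assert_array_equal(apply_mask(img, np.ones((8, 8), bool)), img)
        assert apply_mask(img, np.zeros((8, 8), bool)).sum() == 0
        checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
        out = apply_mask(img, checker)
        np.testing.assert_array_equal(out[checker], img[checker])
        assert out[~checker].sum() == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(np.zeros((8, 8, 3)), np.ones((4, 4), bool))


class TestColorMeans:
    def test_pure_red_region(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        img[..., 0] = 255
        cm = compute_color_means(img, np.ones((4, 4), bool))
        assert (cm.r, cm.g, cm.b) == (255.0, 0.0, 0.0)
        assert (cm.h, cm.s, cm.v) == (0.0, 1.0, 1.0)
        # frozen reference sRGB -> CIELAB (D65) values for pure red
        assert cm.l_star == pytest.approx(53.24, abs=0.5)
        assert cm.a_star == pytest.approx(80.09, abs=0.5)
        assert cm.b_star == pytest.approx(67.20, abs=0.5)

    def test_mid_gray_is_achromatic(self):
        img = np.full((4, 4, 3), 128, dtype=np.uint8)
        cm = compute_color_means(img, np.ones((4, 4), bool))
        assert cm.s == 0.0
        # 128/255 gray is not an exact sRGB grid point of the white point,
        # so a*/b* are only numerically near zero
        assert cm.a_star == pytest.approx(0.0, abs=0.01)
        assert cm.b_star == pytest.approx(0.0, abs=0.01)

    def test_means_restricted_to_mask(self, rng):
        img = rng.integers(0, 256, (6, 6, 3)).astype(np.uint8)
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = True
        cm = compute_color_means(img, mask)
        assert (cm.r, cm.g, cm.b) == tuple(img[0, 0].astype(float))

    def test_brute_force_oracle_agreement(self, rng):
        """Vectorized means match an explicit per-pixel accumulation loop."""
        img = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        mask = rng.random((12, 12)) > 0.4
        cm = compute_color_means(img, mask)
        acc = np.zeros(6)
        n = 0
        for i in range(12):
            for j in range(12):
                if mask[i, j]:
                    r, g, b = img[i, j].astype(float)
                    h, s, v = colorsys.rgb_to_hsv(r / 255, g / 255, b / 255)
                    acc += (r, g, b, h, s, v)
                    n += 1
        expected = acc / n
        got = np.array([cm.r, cm.g, cm.b, cm.h, cm.s, cm.v])
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_color_means(np.zeros((4, 4, 3), np.uint8),
                                np.zeros((4, 4), bool))


class TestExg:
    @pytest.mark.parametrize("pixel,expected", [
        ((100, 200, 50), 250.0),
        ((90, 90, 90), 0.0),
        ((255, 0, 0), -255.0),
        ((0, 255, 0), 510.0),
    ])
    def test_formula(self, pixel, expected):
        img = np.array([[pixel]], dtype=np.uint8)
        assert exg_transform(img)[0, 0] == expected


class TestSegmentMiddleCut:
    def test_recovers_truth_masks(self, cut_render):
        img, truth = cut_render
        got = segment_middle_cut(img)
        assert iou(got.section, truth.section) >= 0.95
        assert iou(got.outer, truth.outer) >= 0.95
        assert iou(got.core, truth.core) >= 0.95
        assert iou(got.locule, truth.locule) >= 0.90

    def test_partition_is_exact(self, cut_render):
        got = segment_middle_cut(cut_render[0])
        assert np.array_equal(got.outer | got.core | got.locule, got.section)
        assert not np.any(got.outer & got.core)
        assert not np.any(got.outer & got.locule)
        assert not np.any(got.core & got.locule)

    def test_scene_without_locule_ring_fails(self, scene512, rng):
        # paint the locule ring in core color: core now touches the pericarp
        img, truth = render_middle_cut(scene512, rng)
        img = img.copy()
        img[truth.locule] = scene512.base_colors["core"]
        with pytest.raises(SegmentationError) as err:
            segment_middle_cut(img)
        assert err.value.region in ("locule", "core")


class TestLoculeAreaRate:
    def _masks(self, locule_px, core_px, size=40):
        section = np.zeros((size, size), bool)
        section[:30, :20] = True          # 600 px
        core = np.zeros_like(section)
        core[:core_px // 10, :10] = True
        locule = np.zeros_like(section)
        locule[15:15 + locule_px // 10, :10] = True
        outer = section & ~core & ~locule
        return RegionMasks(section=section, outer=outer, core=core, locule=locule)

    def test_quarter_rate(self):
        m = self._masks(locule_px=150, core_px=100)
        assert locule_area_rate(m) == pytest.approx(150 / 600)

    def test_empty_locule_gives_zero(self):
        m = self._masks(locule_px=0, core_px=100)
        assert locule_area_rate(m) == 0.0

    def test_partition_complement_identity(self, cut_render):
        _, m = cut_render
        rate = locule_area_rate(m)
        assert rate == pytest.approx(
            1 - (m.outer.sum() + m.core.sum()) / m.section.sum(), abs=1e-12)

    def test_empty_section_rejected(self):
        z = np.zeros((4, 4), bool)
        masks = RegionMasks.__new__(RegionMasks)  # bypass partition validation
        object.__setattr__(masks, "section", z)
        object.__setattr__(masks, "outer", z)
        object.__setattr__(masks, "core", z)
        object.__setattr__(masks, "locule", z)
        with pytest.raises(ValueError):
            locule_area_rate(masks)


class TestExtractImageFeatures:
    def test_vector_has_46_finite_named_values(self, whole_render, cut_render):
        vec = extract_image_features(whole_render[0], cut_render[0])
        assert len(vec.values) == 46
        assert len(FEATURE_NAMES) == 46
        assert np.all(np.isfinite(vec.values))
        # block structure: 9 + 3 + 3 + 9 + 9 + 1 + 9 + 3
        assert FEATURE_NAMES[0] == "whole_r"
        assert FEATURE_NAMES[9] == "whole_area"
        assert FEATURE_NAMES[12] == "section_area"
        assert FEATURE_NAMES[15] == "outer_r"
        assert FEATURE_NAMES[24] == "locule_r"
        assert FEATURE_NAMES[33] == "locule_area_rate"
        assert FEATURE_NAMES[34] == "core_r"
        assert FEATURE_NAMES[43] == "core_area"

    def test_extraction_is_deterministic(self, whole_render, cut_render):
        a = extract_image_features(whole_render[0], cut_render[0])
        b = extract_image_features(whole_render[0], cut_render[0])
        np.testing.assert_array_equal(a.values, b.values)

    def test_whole_color_block_is_compositional(self, whole_render, cut_render):
        vec = extract_image_features(whole_render[0], cut_render[0])
        mask = segment_whole_fruit(whole_render[0])
        cm = compute_color_means(whole_render[0], mask)
        np.testing.assert_allclose(vec.values[:9], cm.as_array(), atol=1e-12)

    def test_rotation_robustness(self, whole_render, cut_render):
        base = extract_image_features(whole_render[0], cut_render[0])
        rot = extract_image_features(np.rot90(whole_render[0]).copy(),
                                     np.rot90(cut_render[0]).copy())
        for prefix in ("whole", "section", "core"):
            i = FEATURE_NAMES.index(f"{prefix}_area")
            assert abs(rot.values[i] - base.values[i]) / base.values[i] < 0.01
        for name in FEATURE_NAMES:
            if name.endswith(("_r", "_g", "_b")):
                i = FEATURE_NAMES.index(name)
                assert abs(rot.values[i] - base.values[i]) < 1.0

    def test_larger_locule_ring_increases_rate(self, scene512):
        from dataclasses import replace
        rates = []
        for frac in (0.40, 0.52, 0.64):
            scene = replace(scene512, locule_outer_fraction=frac)
            img, _ = render_middle_cut(scene, np.random.default_rng(2))
            masks = segment_middle_cut(img)
            rates.append(locule_area_rate(masks))
        assert rates[0] < rates[1] < rates[2]
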