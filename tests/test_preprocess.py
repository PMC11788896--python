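"""Threshold segmentation, crop extraction, filtering and dataset splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpfasternet import preprocess as pp


def make_scene(h=40, w=60, boxes=(), level=0.8, bg=0.05):
    """Dark scene with bright filled rectangles at (y0, y1, x0, x1)."""
    rgb = np.full((3, h, w), bg, dtype=np.float32)
    for y0, y1, x0, x1 in boxes:
        rgb[:, y0:y1, x0:x1] = level
    return pp.SeedScene(rgb, label="t")


class TestGrayscale:
    @pytest.mark.parametrize("pixel,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 0.0, 0.0), 0.299),
        ((0.0, 1.0, 0.0), 0.587),
        ((0.0, 0.0, 1.0), 0.114),
    ])
    def test_luma_weights(self, pixel, expected):
        rgb = np.array(pixel, dtype=np.float32).reshape(3, 1, 1)
        assert pp.to_grayscale(pp.SeedScene(rgb))[0, 0] == pytest.approx(
            expected, abs=1e-7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.to_grayscale(np.full((3, 2, 2), 1.5))


class TestThreshold:
    def test_boundary_pixels(self):
        gray = np.array([[0.29, 0.30, 0.31]])
        assert pp.threshold_segment(gray, 0.3).mask.tolist() == [[0, 1, 1]]

    def test_all_dark_gives_empty_mask(self):
        assert pp.threshold_segment(np.zeros((4, 4))).mask.sum() == 0

    def test_invalid_threshold_rejected(self):
        for t in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                pp.threshold_segment(np.zeros((2, 2)), t)

    @given(t1=st.floats(0.05, 0.9), dt=st.floats(0.01, 0.09))
    @settings(max_examples=30, deadline=None)
    def test_raising_threshold_never_adds_foreground(self, t1, dt):
        gray = np.random.default_rng(0).random((16, 16))
        lo = pp.threshold_segment(gray, t1).mask
        hi = pp.threshold_segment(gray, min(0.99, t1 + dt)).mask
        assert not np.any(hi > lo)


class TestMask:
    def test_identity_zero_and_idempotence(self):
        scene = make_scene(boxes=[(5, 15, 5, 20)])
        ones = pp.BinaryMask(np.ones(scene.shape, np.uint8), 0.3)
        zeros = pp.BinaryMask(np.zeros(scene.shape, np.uint8), 0.3)
        assert np.array_equal(pp.apply_mask(scene, ones).rgb, scene.rgb)
        assert pp.apply_mask(scene, zeros).rgb.sum() == 0
        mask = pp.threshold_segment(pp.to_grayscale(scene))
        once = pp.apply_mask(scene, mask)
        twice = pp.apply_mask(once, mask)
        assert np.array_equal(once.rgb, twice.rgb)
        assert (once.rgb[:, mask.mask == 0] == 0).all()

    def test_extent_mismatch_rejected(self):
        scene = make_scene()
        with pytest.raises(ValueError):
            pp.apply_mask(scene, pp.BinaryMask(np.ones((3, 3), np.uint8), 0.3))


class TestExtract:
    def test_two_rectangles_two_padded_boxes(self):
        scene = make_scene(boxes=[(5, 15, 5, 20), (25, 35, 30, 50)])
        mask = pp.threshold_segment(pp.to_grayscale(scene))
        crops = pp.extract_seed_crops(scene, mask, pad=2)
        assert len(crops) == 2
        assert crops[0].box == (3, 3, 22, 17)   # x0,y0,x1,y1 with pad 2
        assert crops[1].box == (28, 23, 52, 37)
        assert crops[0].area == 10 * 15

    def test_component_touching_border_is_clipped(self):
        scene = make_scene(boxes=[(0, 8, 0, 12)])
        mask = pp.threshold_segment(pp.to_grayscale(scene))
        (crop,) = pp.extract_seed_crops(scene, mask, pad=4)
        assert crop.box == (0, 0, 16, 12)

    def test_empty_mask_gives_empty_list(self):
        scene = make_scene()
        mask = pp.threshold_segment(pp.to_grayscale(scene))
        assert pp.extract_seed_crops(scene, mask) == []

    def test_crops_ordered_row_major(self):
        scene = make_scene(h=60, boxes=[(40, 50, 5, 15), (5, 15, 30, 40),
                                        (5, 15, 5, 15)])
        mask = pp.threshold_segment(pp.to_grayscale(scene))
        boxes = [c.box for c in pp.extract_seed_crops(scene, mask, pad=0)]
        assert boxes == sorted(boxes, key=lambda b: (b[1], b[0]))


class TestFilter:
    def test_area_and_sharpness_rules(self, small_scene):
        crops = pp.extract_seed_crops(
            small_scene.scene,
            pp.threshold_segment(pp.to_grayscale(small_scene.scene)))
        speck = make_scene(boxes=[(5, 6, 5, 6)])  # single-pixel speck
        speck_crop = pp.extract_seed_crops(
            speck, pp.threshold_segment(pp.to_grayscale(speck)))[0]
        with pytest.warns(UserWarning):
            kept = pp.filter_crops(crops + [speck_crop], min_area=50)
        assert len(kept) == len(crops)
        assert "area" in speck_crop.flags

    def test_blurred_crop_removed_by_sharpness_floor(self):
        """A heavily defocused rendering falls below a sharpness floor
        calibrated between the generator's sharp and blurred populations."""
        from dataclasses import replace

        from hpfasternet import synth_seeds as ss

        sharp = ss.sample_phenotypes(1, seed=3)[0]
        blurred = replace(sharp, blur_sigma=6.0)
        crops = {}
        for name, ph in (("sharp", sharp), ("blurred", blurred)):
            syn = ss.render_scene(ph, rows=1, cols=3, seed=9)
            crops[name] = pp.segment_scene(syn.scene, min_sharpness=0.0)
        floor = np.mean([np.mean([c.sharpness for c in crops["sharp"]]),
                         np.mean([c.sharpness for c in crops["blurred"]])])
        with pytest.warns(UserWarning):
            kept = pp.filter_crops(crops["sharp"] + crops["blurred"],
                                   min_sharpness=floor)
        assert {id(c) for c in kept} == {id(c) for c in crops["sharp"]}

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            pp.filter_crops([], min_area=100, max_area=50)

    def test_all_pass_is_identity(self, small_scene):
        crops = pp.extract_seed_crops(
            small_scene.scene,
            pp.threshold_segment(pp.to_grayscale(small_scene.scene)))
        assert pp.filter_crops(list(crops), min_area=1) == crops


class TestSplit:
    def test_published_class_count_splits_exactly(self):
        assert pp.split_counts(1945) == (1167, 389, 389)
        assert pp.split_counts(10) == (6, 2, 2)

    def test_partition_and_ratio_contract(self):
        items = {"a": list(range(1945)), "b": list(range(97))}
        split = pp.split_dataset(items, seed=3)
        for cls, n in (("a", 1945), ("b", 97)):
            parts = [split.train[cls], split.val[cls], split.test[cls]]
            union = sum(parts, [])
            assert len(union) == n and len(set(union)) == n
            for part, ratio in zip(parts, (0.6, 0.2, 0.2)):
                assert abs(len(part) - ratio * n) < 1.0 + 1e-9

    def test_determinism_and_seed_sensitivity(self):
        items = {"a": list(range(50)), "b": list(range(40))}
        s1 = pp.split_dataset(items, seed=5)
        s2 = pp.split_dataset(items, seed=5)
        s3 = pp.split_dataset(items, seed=6)
        assert s1.train == s2.train and s1.val == s2.val
        assert s1.counts() == s3.counts()
        assert s1.train != s3.train  # same counts, different membership

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError):
            pp.split_dataset({"a": [1, 2]})

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            pp.split_dataset({"a": [1, 2, 3]}, ratios=(0.5, 0.2, 0.2))


class TestLetterbox:
    def test_aspect_preserved_on_black_canvas(self):
        rgb = np.ones((3, 10, 20), dtype=np.float32)
        out = pp.letterbox(rgb, 64)
        assert out.shape == (3, 64, 64)
        assert out[:, 0, :].max() == 0.0      # top padding black
        assert out[:, 32, :].max() > 0.9      # center row filled
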