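"""Histology image operators against hand-computed oracles."""

import numpy as np
import pytest

from visiumview import image_ops
from visiumview.core_model import RGBAImage


def make_image(rgb_values, shape=None):
    """Image from an explicit per-pixel RGB array (alpha opaque)."""
    rgb = np.asarray(rgb_values, dtype=np.uint8)
    if shape:
        rgb = np.broadcast_to(rgb, shape + (3,)).copy()
    alpha = np.full(rgb.shape[:2] + (1,), 255, np.uint8)
    return RGBAImage(np.concatenate([rgb, alpha], axis=2))


def constant_image(color=(120, 60, 200), shape=(16, 16)):
    return make_image(np.array(color, np.uint8), shape=shape)


ALL_OPS = [lambda im: image_ops.normalize(im),
           lambda im: image_ops.equalize(im),
           lambda im: image_ops.enhance(im),
           lambda im: image_ops.brightness(im, 150.0)]


@pytest.mark.parametrize("op", ALL_OPS,
                         ids=["normalize", "equalize", "enhance",
                              "brightness"])
class TestSharedContracts:
    def test_dimensions_and_alpha_preserved(self, op):
        rng = np.random.default_rng(3)
        img = make_image(rng.integers(0, 256, (20, 24, 3)).astype(np.uint8))
        out = op(img)
        assert out.pixels.shape == img.pixels.shape
        np.testing.assert_array_equal(out.pixels[:, :, 3],
                                      img.pixels[:, :, 3])

    def test_deterministic(self, op):
        rng = np.random.default_rng(4)
        img = make_image(rng.integers(0, 256, (15, 15, 3)).astype(np.uint8))
        np.testing.assert_array_equal(op(img).pixels, op(img).pixels)

    def test_constant_image_unchanged_under_parameter_free_ops(self, op):
        img = constant_image()
        out = op(img)
        if op is ALL_OPS[3]:  # brightness 150% does scale a constant image
            return
        np.testing.assert_array_equal(out.pixels, img.pixels)


class TestNormalize:
    def test_zero_clip_two_level_stretch(self):
        # 50/50 mix of 10 and 200 with 0% clipping -> exactly 0 and 255
        rng = np.random.default_rng(0)
        vals = np.where(rng.random((10, 10)) < 0.5, 10, 200).astype(np.uint8)
        img = make_image(np.stack([vals] * 3, axis=2))
        out = image_ops.normalize(img, low_clip_percent=0.0,
                                  high_clip_percent=0.0)
        assert set(np.unique(out.pixels[:, :, 0])) == {0, 255}
        np.testing.assert_array_equal(out.pixels[:, :, 0] == 255, vals == 200)

    def test_min_to_zero_max_to_255_any_channel(self):
        rng = np.random.default_rng(1)
        img = make_image(rng.integers(30, 220, (12, 12, 3)).astype(np.uint8))
        out = image_ops.normalize(img, 0.0, 0.0)
        for ch in range(3):
            assert out.pixels[:, :, ch].min() == 0
            assert out.pixels[:, :, ch].max() == 255


class TestEqualize:
    def test_two_level_cdf_remap(self):
        # levels {0: 50%, 128: 50%}: cdf(0)=0.5=cdf_min, cdf(128)=1
        # -> 0 stays 0, 128 -> round(255 * 0.5/0.5) = 255
        vals = np.zeros((10, 10), np.uint8)
        vals[:, 5:] = 128
        img = make_image(np.stack([vals] * 3, axis=2))
        out = image_ops.equalize(img)
        assert set(np.unique(out.pixels[:, :, 0])) == {0, 255}
        np.testing.assert_array_equal(out.pixels[:, :, 0] == 255, vals == 128)

    def test_matches_hand_evaluated_cdf_on_random_image(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        img = make_image(np.stack([vals] * 3, axis=2))
        out = image_ops.equalize(img)
        n = vals.size
        hist = np.bincount(vals.ravel(), minlength=256)
        cdf = np.cumsum(hist) / n
        cdf_min = cdf[np.flatnonzero(hist)[0]]
        expected = np.round(255 * (cdf[vals] - cdf_min) / (1 - cdf_min))
        np.testing.assert_array_equal(out.pixels[:, :, 0], expected)

    def test_uniform_histogram_stays_uniform_within_rounding(self):
        # every level 0..255 appearing once per row: already equalized
        vals = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        img = make_image(np.stack([vals] * 3, axis=2))
        out = image_ops.equalize(img)
        diffs = np.abs(out.pixels[:, :, 0].astype(int) - vals.astype(int))
        assert diffs.max() <= 1


class TestEnhance:
    def test_impulse_attenuated_toward_background(self):
        img = constant_image((100, 100, 100), (9, 9)).pixels.copy()
        img[4, 4, :3] = 110  # within the 15% distance threshold
        out = image_ops.enhance(RGBAImage(img))
        direct = np.array([110] * 3, float)
        # weighted mean: (2*110 + 8*100) / 10 = 102
        assert tuple(out.pixels[4, 4, :3]) == (102, 102, 102)
        assert np.abs(out.pixels[4, 4, :3].astype(float) - 100).max() \
            < np.abs(direct - 100).max()

    def test_far_impulse_excluded_from_neighbors(self):
        # impulse far beyond threshold: neighbors ignore it, it ignores them
        img = constant_image((100, 100, 100), (9, 9)).pixels.copy()
        img[4, 4, :3] = 255
        out = image_ops.enhance(RGBAImage(img))
        assert tuple(out.pixels[4, 4, :3]) == (255, 255, 255)
        assert tuple(out.pixels[4, 5, :3]) == (100, 100, 100)

    def test_two_passes_smooth_at_least_as_much_as_one(self):
        img = constant_image((100, 100, 100), (9, 9)).pixels.copy()
        img[4, 4, :3] = 112
        one = image_ops.enhance(RGBAImage(img))
        two = image_ops.enhance(one)
        dev1 = abs(int(one.pixels[4, 4, 0]) - 100)
        dev2 = abs(int(two.pixels[4, 4, 0]) - 100)
        assert dev2 <= dev1 < 12


class TestTransparent:
    def test_zero_fuzz_exact_match_only(self):
        img = make_image(np.array([[[255, 192, 203], [255, 192, 204]]],
                                  np.uint8))
        out = image_ops.transparent(img, "pink", 0.0)
        assert out.pixels[0, 0, 3] == 0
        assert out.pixels[0, 1, 3] == 255

    def test_pink_fuzz_40_distance_rule(self):
        rng = np.random.default_rng(9)
        rgb = rng.integers(0, 256, (12, 12, 3)).astype(np.uint8)
        out = image_ops.transparent(make_image(rgb), "pink", 40.0)
        key = np.array([255, 192, 203], float)
        dist = np.sqrt(((rgb.astype(float) - key) ** 2).sum(axis=2))
        expected = dist <= 0.4 * np.sqrt(3) * 255
        np.testing.assert_array_equal(out.pixels[:, :, 3] == 0, expected)

    def test_fuzz_100_everything_transparent(self):
        rng = np.random.default_rng(10)
        img = make_image(rng.integers(0, 256, (8, 8, 3)).astype(np.uint8))
        out = image_ops.transparent(img, (0, 0, 0), 100.0)
        assert (out.pixels[:, :, 3] == 0).all()

    def test_monotone_in_fuzz(self):
        rng = np.random.default_rng(11)
        img = make_image(rng.integers(0, 256, (16, 16, 3)).astype(np.uint8))
        prev = None
        for fuzz in range(0, 101, 10):
            cur = image_ops.transparent(img, "pink", float(fuzz))
            mask = cur.pixels[:, :, 3] == 0
            if prev is not None:
                assert (mask | ~prev).all()  # prev subset of current
            prev = mask

    def test_fuzz_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            image_ops.transparent(constant_image(), "pink", 101.0)

    def test_unknown_color_name_rejected(self):
        with pytest.raises(ValueError, match="unknown color"):
            image_ops.transparent(constant_image(), "blurple", 10.0)


class TestBrightness:
    def test_identity_at_100(self):
        rng = np.random.default_rng(12)
        img = make_image(rng.integers(0, 256, (10, 10, 3)).astype(np.uint8))
        np.testing.assert_array_equal(
            image_ops.brightness(img, 100.0).pixels, img.pixels)

    def test_zero_blacks_rgb_keeps_alpha(self):
        img = constant_image((50, 100, 150))
        out = image_ops.brightness(img, 0.0)
        assert (out.pixels[:, :, :3] == 0).all()
        assert (out.pixels[:, :, 3] == 255).all()

    def test_scaling_and_clipping(self):
        img = make_image(np.array([[[100, 200, 0]]], np.uint8))
        out = image_ops.brightness(img, 200.0)
        assert tuple(out.pixels[0, 0, :3]) == (200, 255, 0)

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            image_ops.brightness(constant_image(), -1.0)


def test_apply_ops_left_to_right_and_unknown_name():
    rng = np.random.default_rng(13)
    img = make_image(rng.integers(0, 256, (10, 10, 3)).astype(np.uint8))
    chained = image_ops.apply_ops(img, ["enhance", "normalize", "equalize"])
    manual = image_ops.equalize(image_ops.normalize(image_ops.enhance(img)))
    np.testing.assert_array_equal(chained.pixels, manual.pixels)
    with pytest.raises(ValueError, match="unknown image operation"):
        image_ops.apply_ops(img, ["sharpen"])
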