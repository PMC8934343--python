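"""Side-cropping, masking, rejection-sampled crops and deterministic tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barkcam.preprocess import (
    CropConfig,
    CropWindow,
    SamplingExhaustedError,
    apply_background_mask,
    mask_ratio,
    resize_image,
    sample_training_crop,
    side_crop,
    tile_test_crops,
    trim_masked_sides,
)


class TestSideCrop:
    def test_identity(self, random_image):
        np.testing.assert_array_equal(side_crop(random_image, 0, 0), random_image)

    def test_column_shift(self, rng):
        img = rng.integers(0, 256, size=(6, 10, 3)).astype(np.uint8)
        out = side_crop(img, 2, 3)
        assert out.shape == (6, 5, 3)
        for j in range(5):
            np.testing.assert_array_equal(out[:, j], img[:, j + 2])

    def test_matches_independent_slice(self, rng):
        img = rng.integers(0, 256, size=(20, 30, 3)).astype(np.uint8)
        left, right = int(rng.integers(0, 10)), int(rng.integers(0, 10))
        expected = np.stack([img[:, left : 30 - right, k] for k in range(3)], axis=-1)
        np.testing.assert_array_equal(side_crop(img, left, right), expected)

    @given(a=st.integers(0, 5), b=st.integers(0, 5), c=st.integers(0, 5), d=st.integers(0, 5))
    @settings(derandomize=True, max_examples=40)
    def test_composes_additively(self, a, b, c, d):
        img = np.arange(25 * 40 * 3, dtype=np.uint8).reshape(25, 40, 3)
        np.testing.assert_array_equal(
            side_crop(side_crop(img, a, b), c, d), side_crop(img, a + c, b + d)
        )

    def test_bounds_violation(self, random_image):
        w = random_image.shape[1]
        with pytest.raises(ValueError):
            side_crop(random_image, w, 0)
        with pytest.raises(ValueError):
            side_crop(random_image, -1, 0)


class TestBackgroundMask:
    def test_keep_all(self, random_image):
        keep = np.ones(random_image.shape[:2], dtype=bool)
        np.testing.assert_array_equal(apply_background_mask(random_image, keep), random_image)

    def test_keep_none(self, random_image):
        keep = np.zeros(random_image.shape[:2], dtype=bool)
        assert (apply_background_mask(random_image, keep) == 0).all()

    def test_checkerboard_count(self, random_image):
        h, w = random_image.shape[:2]
        keep = (np.add.outer(np.arange(h), np.arange(w)) % 2).astype(bool)
        out = apply_background_mask(random_image, keep)
        n_masked = int(np.all(out == 0, axis=2).sum())
        # legitimately all-zero kept pixels cannot occur: fixture values >= 1
        assert n_masked == int((~keep).sum())

    def test_shape_mismatch(self, random_image):
        with pytest.raises(ValueError):
            apply_background_mask(random_image, np.ones((3, 3), dtype=bool))


class TestMaskRatio:
    def test_unmasked_region_is_zero(self, random_image):
        assert mask_ratio(random_image, CropWindow(0, 0, 20)) == 0.0

    def test_fully_masked_is_one(self, banded_image):
        assert mask_ratio(banded_image, CropWindow(0, 0, 8)) == 1.0

    def test_explicit_count(self, rng):
        img = rng.integers(1, 256, size=(8, 8, 3)).astype(np.uint8)
        img[0, 0] = img[1, 3] = img[5, 5] = img[7, 2] = 0
        assert mask_ratio(img, CropWindow(0, 0, 8)) == pytest.approx(4 / 64)

    def test_invariant_under_value_permutation(self, banded_image, rng):
        win = CropWindow(5, 5, 20)
        before = mask_ratio(banded_image, win)
        shuffled = banded_image.copy()
        unmasked = ~np.all(shuffled == 0, axis=2)
        vals = shuffled[unmasked]
        shuffled[unmasked] = vals[rng.permutation(len(vals))]
        assert mask_ratio(shuffled, win) == before

    def test_out_of_bounds(self, random_image):
        with pytest.raises(ValueError):
            mask_ratio(random_image, CropWindow(0, 0, 100))


def _enumerate_acceptance(img, cfg):
    """Exact per-draw acceptance probability of the two-stage sampler:
    side uniform over its range, then corner uniform given the side."""
    h, w = img.shape[:2]
    masked = np.all(img == 0, axis=2).astype(np.int64)
    csum = np.pad(masked.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
    lo = int(np.floor(cfg.frac_min * w))
    hi = min(int(np.floor(cfg.frac_max * w)), min(h, w))
    probs = []
    for side in range(lo, hi + 1):
        ok = total = 0
        for r in range(h - side + 1):
            for c in range(w - side + 1):
                n = csum[r + side, c + side] - csum[r, c + side] - csum[r + side, c] + csum[r, c]
                total += 1
                ok += n / side**2 <= cfg.mask_threshold
        probs.append(ok / total)
    return float(np.mean(probs))


class TestSampleTrainingCrop:
    def test_degenerate_fraction_always_accepts(self, rng):
        img = rng.integers(1, 256, size=(60, 40, 3)).astype(np.uint8)
        cfg = CropConfig(frac_min=0.5, frac_max=0.5)
        win = sample_training_crop(img, cfg, rng)
        assert win.side == 20

    def test_fully_masked_image_exhausts(self, rng):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        with pytest.raises(SamplingExhaustedError):
            sample_training_crop(img, CropConfig(), rng, name="black")

    def test_every_window_respects_threshold(self, banded_image):
        cfg = CropConfig()
        rng = np.random.default_rng(7)
        for _ in range(1000):
            win = sample_training_crop(banded_image, cfg, rng)
            assert mask_ratio(banded_image, win) <= cfg.mask_threshold

    def test_seeded_reproducibility(self, banded_image):
        cfg = CropConfig()
        wins1 = [sample_training_crop(banded_image, cfg, np.random.default_rng(3)) for _ in range(1)]
        wins2 = [sample_training_crop(banded_image, cfg, np.random.default_rng(3)) for _ in range(1)]
        assert wins1 == wins2

    def test_acceptance_matches_enumeration(self, rng):
        img = rng.integers(1, 256, size=(50, 40, 3)).astype(np.uint8)
        img[:, :7] = 0  # known masked band
        cfg = CropConfig(max_attempts=1)
        p = _enumerate_acceptance(img, cfg)
        n = 10_000
        accepted = 0
        draw_rng = np.random.default_rng(11)
        for _ in range(n):
            try:
                sample_training_crop(img, cfg, draw_rng)
                accepted += 1
            except SamplingExhaustedError:
                pass
        se = np.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) <= 3 * se


class TestTileTestCrops:
    def test_grid_arithmetic(self, rng):
        img = rng.integers(1, 256, size=(400, 200, 3)).astype(np.uint8)
        wins = tile_test_crops(img, CropConfig())
        assert len(wins) == 8
        assert all(w.side == 100 for w in wins)
        assert wins[0] == CropWindow(0, 0, 100) and wins[1] == CropWindow(0, 100, 100)

    def test_partial_row_dropped(self, rng):
        img = rng.integers(1, 256, size=(401, 200, 3)).astype(np.uint8)
        assert len(tile_test_crops(img, CropConfig())) == 8

    def test_masked_tile_dropped_matches_enumeration(self, rng):
        img = rng.integers(1, 256, size=(400, 200, 3)).astype(np.uint8)
        img[100:200, 0:100] = 0  # one fully masked tile
        cfg = CropConfig()
        wins = tile_test_crops(img, cfg)
        assert len(wins) == 7
        expected = {
            (r, c)
            for r in range(0, 301, 100)
            for c in range(0, 101, 100)
            if mask_ratio(img, CropWindow(r, c, 100)) <= cfg.mask_threshold
        }
        assert {(w.row0, w.col0) for w in wins} == expected

    def test_side_taller_than_image_gives_empty(self, rng):
        img = rng.integers(1, 256, size=(30, 100, 3)).astype(np.uint8)
        assert tile_test_crops(img, CropConfig()) == []


class TestResize:
    def test_constant_image_stays_constant(self):
        img = np.full((50, 70, 3), 137, dtype=np.uint8)
        out = resize_image(img, 331)
        assert out.shape == (331, 331, 3)
        assert (out == 137).all()

    def test_native_resolution_is_identity(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8)
        np.testing.assert_array_equal(resize_image(img, 16), img)

    def test_corner_aligned_upsample(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = [[10, 40], [70, 100]]
        out = resize_image(img, 4)
        # corner alignment preserves the four source pixels at the corners
        assert out[0, 0, 0] == 10 and out[0, 3, 0] == 40
        assert out[3, 0, 0] == 70 and out[3, 3, 0] == 100
        # interior follows the bilinear surface 10 + 30*c + 60*r, r,c in {0,1/3,2/3,1}
        assert out[1, 1, 0] == round(10 + 30 / 3 + 60 / 3)


class TestTrimMaskedSides:
    def test_trims_exactly_the_fully_masked_columns(self, rng):
        img = rng.integers(1, 256, size=(30, 40, 3)).astype(np.uint8)
        img[:, :5] = 0
        img[:, -3:] = 0
        img[:10, 5] = 0  # ragged wedge: column 5 only partially masked
        out = trim_masked_sides(img)
        assert out.shape == (30, 32, 3)
        np.testing.assert_array_equal(out, img[:, 5:37])

    def test_entirely_masked_raises(self):
        with pytest.raises(ValueError):
            trim_masked_sides(np.zeros((5, 5, 3), dtype=np.uint8))
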