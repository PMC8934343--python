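"""Sliding-window geometry and coverage-averaged saliency aggregation."""

import numpy as np
import pytest

from barkcam.cam_aggregation import (
    AggregationConfig,
    SaliencyMap,
    aggregate,
    iter_windows,
    pad_for_sliding,
    superimpose,
)
from barkcam._interp import resize_bilinear


class TestPadForSliding:
    def test_square_image_equal_to_window(self, rng):
        img = rng.integers(1, 256, size=(100, 100, 3)).astype(np.uint8)
        padded, (or_, oc) = pad_for_sliding(img, window=100, stride=50)
        assert padded.shape[:2] == (200, 200)
        wins = iter_windows(200, 200, 100, 50)
        assert len(wins) == 9  # 3 positions per axis
        assert (or_, oc) == (50, 50)

    def test_divisible_dims_with_full_stride(self, rng):
        img = rng.integers(1, 256, size=(60, 40, 3)).astype(np.uint8)
        padded, off = pad_for_sliding(img, window=20, stride=20)
        # only the leading stride per side is needed
        assert padded.shape[:2] == (100, 80)
        assert off == (20, 20)

    def test_offset_is_always_stride(self, rng):
        for _ in range(10):
            h, w = int(rng.integers(30, 90)), int(rng.integers(30, 90))
            img = rng.integers(1, 256, size=(h, w, 3)).astype(np.uint8)
            window = int(rng.integers(10, min(h, w)))
            stride = max(1, window // 2)
            padded, off = pad_for_sliding(img, window, stride)
            assert off == (stride, stride)
            # grid tiles exactly
            assert (padded.shape[0] - window) % stride == 0
            assert (padded.shape[1] - window) % stride == 0

    def test_padding_is_black(self, rng):
        img = rng.integers(1, 256, size=(50, 50, 3)).astype(np.uint8)
        padded, (r, c) = pad_for_sliding(img, 25, 12)
        assert (padded[:r] == 0).all() and (padded[:, :c] == 0).all()
        np.testing.assert_array_equal(padded[r : r + 50, c : c + 50], img)


class TestIterWindows:
    def test_three_by_three_grid(self):
        wins = iter_windows(200, 200, 100, 50)
        assert len(wins) == 9
        assert [(w.row0, w.col0) for w in wins[:3]] == [(0, 0), (0, 50), (0, 100)]

    def test_full_stride_tiles_without_overlap(self):
        wins = iter_windows(200, 200, 100, 100)
        cov = np.zeros((200, 200), dtype=int)
        for w in wins:
            cov[w.row0 : w.row0 + 100, w.col0 : w.col0 + 100] += 1
        assert (cov == 1).all()

    def test_every_original_pixel_covered(self, rng):
        h, w, window = 70, 50, 24
        stride = window // 2
        img = rng.integers(1, 256, size=(h, w, 3)).astype(np.uint8)
        padded, (or_, oc) = pad_for_sliding(img, window, stride)
        cov = np.zeros(padded.shape[:2], dtype=int)
        for win in iter_windows(*padded.shape[:2], window, stride):
            cov[win.row0 : win.row0 + window, win.col0 : win.col0 + window] += 1
        inner = cov[or_ : or_ + h, oc : oc + w]
        assert inner.min() >= 1
        # interior pixels see 2 windows per axis
        assert (inner[stride : h - stride, stride : w - stride] == 4).all()

    def test_coverage_sum_identity(self):
        window, stride = 30, 15
        padded_h = padded_w = 90
        wins = iter_windows(padded_h, padded_w, window, stride)
        cov = np.zeros((padded_h, padded_w), dtype=int)
        for w in wins:
            cov[w.row0 : w.row0 + window, w.col0 : w.col0 + window] += 1
        assert cov.sum() == len(wins) * window**2


def _brute_force_saliency(img, cam_fn, cfg):
    """Per-pixel mean of covering windows' upsampled CAMs, computed naively."""
    h, w = img.shape[:2]
    window = max(1, int(np.floor(cfg.window_frac * w)))
    stride = max(1, window // 2)
    padded, (or_, oc) = pad_for_sliding(img, window, stride)
    acc = np.zeros(padded.shape[:2])
    cov = np.zeros(padded.shape[:2])
    for win in iter_windows(*padded.shape[:2], window, stride):
        patch = padded[win.row0 : win.row0 + window, win.col0 : win.col0 + window]
        cam = np.asarray(cam_fn(patch, 0), dtype=float)
        if cam.shape != (window, window):
            cam = np.maximum(resize_bilinear(cam, window, window), 0.0)
        acc[win.row0 : win.row0 + window, win.col0 : win.col0 + window] += cam
        cov[win.row0 : win.row0 + window, win.col0 : win.col0 + window] += 1
    return (acc / cov)[or_ : or_ + h, oc : oc + w]


class TestAggregate:
    def test_constant_cam_conserved(self, rng):
        img = rng.integers(1, 256, size=(64, 48, 3)).astype(np.uint8)
        cam_fn = lambda patch, c: np.full((5, 5), 3.25)
        sal = aggregate(img, model=None, class_index=0, cam_fn=cam_fn)
        np.testing.assert_allclose(sal.values, 3.25, atol=1e-12)
        assert sal.coverage.min() >= 1

    def test_matches_brute_force_for_stub_cams(self, rng):
        """Content-dependent stub CAM (mean green intensity) on 20 random
        geometries: aggregate equals the per-pixel brute-force mean."""
        cam_fn = lambda patch, c: np.full((4, 4), patch[..., 1].mean())
        for _ in range(20):
            h = int(rng.integers(20, 90))
            w = int(rng.integers(20, 90))
            frac = float(rng.uniform(0.3, 1.0))
            img = rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8)
            cfg = AggregationConfig(window_frac=frac)
            sal = aggregate(img, model=None, class_index=0, cfg=cfg, cam_fn=cam_fn)
            expected = _brute_force_saliency(img, cam_fn, cfg)
            assert np.max(np.abs(sal.values - expected)) < 1e-9

    def test_single_window_degenerate_grid(self, rng):
        img = rng.integers(1, 256, size=(40, 40, 3)).astype(np.uint8)
        # window_frac=1 on a square image: central window covers it entirely
        vals = np.abs(rng.normal(size=(40, 40)))
        seen = []
        def cam_fn(patch, c):
            seen.append(patch)
            return vals if np.any(patch) and (patch == img).all() else np.zeros((40, 40))
        sal = aggregate(img, model=None, class_index=0,
                        cfg=AggregationConfig(window_frac=1.0), cam_fn=cam_fn)
        # the window exactly over the image contributes vals once; padding
        # windows contribute zero, so the mean over coverage recovers vals/coverage
        np.testing.assert_allclose(sal.values * sal.coverage, vals, atol=1e-9)

    def test_aggregation_linear_in_cam_values(self, rng):
        img = rng.integers(1, 256, size=(30, 30, 3)).astype(np.uint8)
        f = lambda patch, c: np.full((3, 3), patch.mean())
        g = lambda patch, c: np.outer(patch[:, 0, 0] + 1.0, np.ones(3))[:3, :]
        s_f = aggregate(img, None, 0, cam_fn=f).values
        s_g = aggregate(img, None, 0, cam_fn=g).values
        s_fg = aggregate(img, None, 0, cam_fn=lambda p, c: 2 * f(p, c) + 3 * g(p, c)).values
        np.testing.assert_allclose(s_fg, 2 * s_f + 3 * s_g, atol=1e-9)

    def test_window_coordinates_attached_to_errors(self, rng):
        img = rng.integers(1, 256, size=(30, 30, 3)).astype(np.uint8)
        def bad(patch, c):
            raise FloatingPointError("boom")
        with pytest.raises(RuntimeError, match="row0=0 col0=0"):
            aggregate(img, None, 0, cam_fn=bad)


class TestSuperimpose:
    def _sal(self, values):
        return SaliencyMap(values, np.ones_like(values, dtype=int), 0)

    def test_alpha_zero_returns_original(self, rng):
        img = rng.integers(0, 256, size=(6, 6, 3)).astype(np.uint8)
        sal = self._sal(np.abs(rng.normal(size=(6, 6))))
        np.testing.assert_array_equal(superimpose(sal, img, alpha=0.0), img)

    def test_alpha_one_constant_saliency_is_colormap_zero(self, rng):
        from matplotlib import colormaps

        img = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        sal = self._sal(np.full((4, 4), 5.0))
        out = superimpose(sal, img, alpha=1.0)
        zero_color = np.rint(np.array(colormaps["jet"](0.0)[:3]) * 255)
        assert (out == zero_color.astype(np.uint8)).all()

    def test_blend_formula_on_toy(self, rng):
        from matplotlib import colormaps

        img = rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8)
        vals = rng.uniform(0, 10, size=(4, 4))
        sal = self._sal(vals)
        alpha = 0.3
        out = superimpose(sal, img, alpha)
        norm = (vals - vals.min()) / (vals.max() - vals.min())
        heat = colormaps["jet"](norm)[..., :3] * 255
        expected = np.clip(np.rint((1 - alpha) * img + alpha * heat), 0, 255).astype(np.uint8)
        np.testing.assert_array_equal(out, expected)

    def test_red_end_marks_strongest_activation(self):
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        vals = np.array([[0.0, 1.0]])
        out = superimpose(self._sal(vals), img, alpha=1.0)
        # strongest pixel is red-dominant, weakest blue-dominant under 'jet'
        assert out[0, 1, 0] > out[0, 1, 2]
        assert out[0, 0, 2] > out[0, 0, 0]
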