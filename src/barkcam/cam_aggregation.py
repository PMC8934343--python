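"""Whole-bark saliency by sliding-window CAM aggregation.

A single classifier patch only explains a fragment of a trunk.  To build one
relevance map for the entire photograph, the image is padded with black
pixels, a square window slides over it at half-window stride, Grad-CAM++ is
computed per window, each window's map is upsampled to window size and added
into an accumulator at the window's position, and the accumulator is divided
by the per-pixel coverage count (the number of windows overlapping each
pixel), then cropped back to the original frame.  Dividing by the actual
coverage makes the result a true per-pixel mean even where the window grid
covers pixels unevenly.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from ._interp import resize_bilinear
from .gradcampp import CamMap, compute_cam, upsample_cam
from .model_contract import probe
from .preprocess import CropWindow, extract_window

logger = logging.getLogger(__name__)

__all__ = [
    "AggregationConfig",
    "SaliencyMap",
    "pad_for_sliding",
    "iter_windows",
    "aggregate",
    "superimpose",
    "CamAggregator",
]


@dataclass
class AggregationConfig:
    """window_frac: sliding-window side as a fraction of image width;
    stride is fixed at half the window side; colormap names a matplotlib map
    whose red end marks the strongest activation."""

    window_frac: float = 0.50
    stride_divisor: int = 2
    colormap: str = "jet"

    def __post_init__(self) -> None:
        if not (0.0 < self.window_frac <= 1.0):
            raise ValueError("window_frac must be in (0, 1]")
        if self.stride_divisor != 2:
            raise ValueError("stride is fixed at half the window size")


@dataclass
class SaliencyMap:
    """Mean relevance over the original (unpadded) frame plus the window
    coverage count per pixel."""

    values: np.ndarray
    coverage: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        if self.values.shape != self.coverage.shape:
            raise ValueError("values/coverage shapes differ")
        if np.any(self.coverage < 1):
            raise ValueError("every pixel must be covered by at least one window")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("saliency must be finite and non-negative")


def _pad_amounts(dim: int, window: int, stride: int) -> tuple[int, int]:
    lead = stride
    trail = stride + (-(dim + 2 * stride - window)) % stride
    return lead, trail


def pad_for_sliding(img: np.ndarray, window: int, stride: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Pad with black: `stride` pixels on top/left, and on bottom/right
    `stride` plus whatever makes (dim + padding - window) divisible by stride,
    so the window grid tiles exactly.  Returns (padded image, offset of the
    original frame), the offset being (stride, stride) by construction."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    if window > max(h, w) + 2 * stride:
        raise ValueError("window larger than padded image")
    top, bottom = _pad_amounts(h, window, stride)
    left, right = _pad_amounts(w, window, stride)
    pad = [(top, bottom), (left, right)] + [(0, 0)] * (img.ndim - 2)
    return np.pad(img, pad), (top, left)


def iter_windows(padded_h: int, padded_w: int, window: int, stride: int) -> list[CropWindow]:
    """Row-major grid at multiples of stride; (dim - window)/stride + 1
    positions per axis (exact when dims come from pad_for_sliding)."""
    if padded_h < window or padded_w < window:
        raise ValueError("padded image smaller than window")
    rows = range(0, padded_h - window + 1, stride)
    cols = range(0, padded_w - window + 1, stride)
    return [CropWindow(r, c, window) for r in rows for c in cols]


def _default_cam_fn(model, patch: np.ndarray, class_index: int) -> np.ndarray:
    return compute_cam(probe(model, patch, class_index)).values


def aggregate(
    img: np.ndarray,
    model,
    class_index: int | None = None,
    cfg: AggregationConfig | None = None,
    cam_fn=None,
) -> SaliencyMap:
    """Coverage-averaged Grad-CAM++ over a whole image.

    If class_index is None the explained class is the majority prediction
    across windows (the model's whole-image vote); the choice is logged.
    `cam_fn(patch, class_index) -> 2-D array` overrides the probe ->
    Grad-CAM++ path (used by oracle tests and stub explainers)."""
    cfg = cfg or AggregationConfig()
    img = np.asarray(img)
    h, w = img.shape[:2]
    window = max(1, int(np.floor(cfg.window_frac * w)))
    stride = max(1, window // cfg.stride_divisor)
    padded, (off_r, off_c) = pad_for_sliding(img, window, stride)
    wins = iter_windows(padded.shape[0], padded.shape[1], window, stride)

    if class_index is None:
        if model is None:
            raise ValueError("need a model to choose the explained class")
        votes = Counter(
            int(model.predict_proba(_model_patch(model, extract_window(padded, win))).argmax())
            for win in wins
        )
        class_index = votes.most_common(1)[0][0]
        logger.info("explaining majority-vote class %d (votes: %s)", class_index, dict(votes))

    if cam_fn is None:
        fn = lambda patch, c: _default_cam_fn(model, patch, c)
    else:
        fn = cam_fn

    acc = np.zeros(padded.shape[:2], dtype=np.float64)
    cov = np.zeros(padded.shape[:2], dtype=np.int64)
    for win in wins:
        patch = extract_window(padded, win)
        try:
            cam = np.asarray(fn(patch, class_index), dtype=np.float64)
        except Exception as err:
            raise RuntimeError(
                f"CAM computation failed at window row0={win.row0} col0={win.col0} "
                f"side={win.side}"
            ) from err
        up = upsample_cam(CamMap(cam, class_index), window) if cam.shape != (window, window) \
            else np.maximum(cam, 0.0)
        acc[win.row0 : win.row0 + window, win.col0 : win.col0 + window] += up
        cov[win.row0 : win.row0 + window, win.col0 : win.col0 + window] += 1

    values = acc[off_r : off_r + h, off_c : off_c + w] / cov[off_r : off_r + h, off_c : off_c + w]
    coverage = cov[off_r : off_r + h, off_c : off_c + w]
    return SaliencyMap(values, coverage, class_index)


def _model_patch(model, patch: np.ndarray) -> np.ndarray:
    size = getattr(model, "input_size", None)
    if size is None or patch.shape[0] == size:
        return patch[None] if patch.ndim == 3 else patch
    out = np.clip(np.rint(resize_bilinear(patch.astype(np.float64), size, size)), 0, 255)
    return out.astype(np.uint8)[None]


def superimpose(sal: SaliencyMap, img: np.ndarray, alpha: float, colormap: str = "jet") -> np.ndarray:
    """Min-max normalize the saliency (constant maps -> 0), apply the colormap
    (red end = strongest activation for the default 'jet'), and alpha-blend
    onto the photograph."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    img = np.asarray(img, dtype=np.float64)
    if sal.values.shape != img.shape[:2]:
        raise ValueError("saliency/image shapes differ")
    v = sal.values
    span = v.max() - v.min()
    norm = (v - v.min()) / span if span > 0 else np.zeros_like(v)
    heat = colormaps[colormap](norm)[..., :3] * 255.0
    blend = (1.0 - alpha) * img + alpha * heat
    return np.clip(np.rint(blend), 0, 255).astype(np.uint8)


class CamAggregator:
    """Object-style interface over `aggregate` + `superimpose` bound to one
    model and configuration."""

    def __init__(self, model, cfg: AggregationConfig | None = None) -> None:
        self.model = model
        self.cfg = cfg or AggregationConfig()

    def explain(self, img: np.ndarray, class_index: int | None = None) -> SaliencyMap:
        return aggregate(img, self.model, class_index=class_index, cfg=self.cfg)

    def render(self, sal: SaliencyMap, img: np.ndarray, alpha: float = 0.4) -> np.ndarray:
        return superimpose(sal, img, alpha, colormap=self.cfg.colormap)
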