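"""Image pre-processing for bark photographs.

Trunk photographs arrive with the background flanking the trunk masked to
black.  Training patches are square crops whose side is drawn uniformly from
40-60% of the image width; a candidate crop is rejected and re-drawn whenever
the fraction of masked (all-zero) pixels inside it exceeds a threshold tau
(0.05 by default).  Test patches are a deterministic non-overlapping tiling at
50% of the width under the same mask threshold.  All patches are resized to
the classifier input size with corner-aligned bilinear interpolation.

Conventions: 0-based, half-open window extents; a pixel is "masked" iff all
three channels are exactly zero (bark pixels that are legitimately black are
indistinguishable from mask — an accepted limitation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._interp import resize_bilinear

logger = logging.getLogger(__name__)

__all__ = [
    "CropWindow",
    "CropConfig",
    "SamplingExhaustedError",
    "side_crop",
    "apply_background_mask",
    "mask_ratio",
    "sample_training_crop",
    "tile_test_crops",
    "resize_image",
    "extract_window",
    "trim_masked_sides",
]


class SamplingExhaustedError(RuntimeError):
    """Raised when no crop satisfying the mask threshold is found."""


@dataclass(frozen=True)
class CropWindow:
    """Square region [row0, row0+side) x [col0, col0+side), 0-based."""

    row0: int
    col0: int
    side: int

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError(f"window side must be >= 1, got {self.side}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("window corner must be non-negative")


@dataclass
class CropConfig:
    """Sampling rules for training/test crops.

    frac_min, frac_max : training-crop side as a fraction of image width
    mask_threshold     : max fraction of masked pixels tolerated in a crop (tau)
    test_frac          : deterministic test-crop side as a fraction of width
    target_size        : classifier input resolution (pixels)
    max_attempts       : rejection-sampling budget before raising
    """

    frac_min: float = 0.40
    frac_max: float = 0.60
    mask_threshold: float = 0.05
    test_frac: float = 0.50
    target_size: int = 331
    max_attempts: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_min <= self.frac_max <= 1.0):
            raise ValueError("need 0 < frac_min <= frac_max <= 1")
        if not (0.0 <= self.mask_threshold < 1.0):
            raise ValueError("need 0 <= mask_threshold < 1")
        if self.target_size < 8:
            raise ValueError("target_size must be >= 8")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    return img


def side_crop(img: np.ndarray, left: int, right: int) -> np.ndarray:
    """Trim `left` columns from the left edge and `right` from the right edge."""
    img = _check_image(img)
    w = img.shape[1]
    if left < 0 or right < 0 or left >= w - right:
        raise ValueError(f"invalid side-crop (left={left}, right={right}) for width {w}")
    return img[:, left : w - right, :]


def apply_background_mask(img: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Blacken every pixel where `keep` is False; keep=True pixels unchanged."""
    img = _check_image(img)
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != img.shape[:2]:
        raise ValueError(f"mask shape {keep.shape} does not match image {img.shape[:2]}")
    out = img.copy()
    out[~keep] = 0
    return out


def masked_pixels(img: np.ndarray) -> np.ndarray:
    """Boolean H x W raster: True where all three channels are exactly 0."""
    img = _check_image(img)
    return np.all(img == 0, axis=2)


def mask_ratio(img: np.ndarray, win: CropWindow) -> float:
    """Fraction of masked pixels inside the window, in [0, 1]."""
    img = _check_image(img)
    h, w = img.shape[:2]
    if win.row0 + win.side > h or win.col0 + win.side > w:
        raise ValueError(f"window {win} exceeds image bounds {h}x{w}")
    patch = img[win.row0 : win.row0 + win.side, win.col0 : win.col0 + win.side]
    n_masked = int(np.all(patch == 0, axis=2).sum())
    return n_masked / float(win.side**2)


def _side_bounds(width: int, height: int, cfg: CropConfig) -> tuple[int, int]:
    lo = int(np.floor(cfg.frac_min * width))
    hi = int(np.floor(cfg.frac_max * width))
    if lo < 1:
        raise ValueError(f"frac_min*width = {lo} < 1 pixel for width {width}")
    # side drawn relative to width, clamped so portrait and landscape both work
    cap = min(height, width)
    return min(lo, cap), min(hi, cap)


def sample_training_crop(
    img: np.ndarray,
    cfg: CropConfig,
    rng: np.random.Generator,
    name: str = "<image>",
) -> CropWindow:
    """Rejection-sample one training crop.

    Side uniform over [floor(frac_min*W), floor(frac_max*W)] (clamped to
    min(H, W)), corner uniform over in-bounds positions; windows whose mask
    ratio exceeds the threshold are re-drawn, up to cfg.max_attempts times.
    """
    img = _check_image(img)
    h, w = img.shape[:2]
    lo, hi = _side_bounds(w, h, cfg)
    masked = masked_pixels(img)
    for _ in range(cfg.max_attempts):
        side = int(rng.integers(lo, hi + 1))
        row0 = int(rng.integers(0, h - side + 1))
        col0 = int(rng.integers(0, w - side + 1))
        n_masked = int(masked[row0 : row0 + side, col0 : col0 + side].sum())
        if n_masked / float(side**2) <= cfg.mask_threshold:
            return CropWindow(row0, col0, side)
    raise SamplingExhaustedError(
        f"no crop with mask ratio <= {cfg.mask_threshold} found in "
        f"{cfg.max_attempts} attempts for {name}"
    )


def tile_test_crops(img: np.ndarray, cfg: CropConfig) -> list[CropWindow]:
    """Deterministic row-major tiling: side = floor(test_frac*W), stride = side,
    origin (0, 0); partial tiles and tiles over the mask threshold are dropped."""
    img = _check_image(img)
    h, w = img.shape[:2]
    side = int(np.floor(cfg.test_frac * w))
    if side < 1:
        raise ValueError(f"test_frac*width = {side} < 1 pixel for width {w}")
    if side > h:
        logger.warning("test-crop side %d exceeds image height %d; no tiles", side, h)
        return []
    masked = masked_pixels(img)
    wins: list[CropWindow] = []
    for row0 in range(0, h - side + 1, side):
        for col0 in range(0, w - side + 1, side):
            n_masked = int(masked[row0 : row0 + side, col0 : col0 + side].sum())
            if n_masked / float(side**2) <= cfg.mask_threshold:
                wins.append(CropWindow(row0, col0, side))
    return wins


def trim_masked_sides(img: np.ndarray) -> np.ndarray:
    """Side-crop the fully-masked columns flanking the trunk.

    Only columns that are masked over their entire height are removed; a
    ragged (non-vertical) trunk boundary leaves residual masked wedges, which
    the mask-ratio threshold handles downstream."""
    img = _check_image(img)
    col_masked = np.all(masked_pixels(img), axis=0)
    if col_masked.all():
        raise ValueError("image is entirely masked")
    left = int(np.argmax(~col_masked))
    right = int(np.argmax(~col_masked[::-1]))
    return side_crop(img, left, right)


def extract_window(img: np.ndarray, win: CropWindow) -> np.ndarray:
    """Return the pixel content of a window as a view-copy."""
    img = _check_image(img)
    if win.row0 + win.side > img.shape[0] or win.col0 + win.side > img.shape[1]:
        raise ValueError(f"window {win} exceeds image bounds")
    return img[win.row0 : win.row0 + win.side, win.col0 : win.col0 + win.side].copy()


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Resize to size x size with corner-aligned bilinear interpolation."""
    img = _check_image(img)
    if size < 1:
        raise ValueError("size must be >= 1")
    out = resize_bilinear(img.astype(np.float64), size, size)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
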