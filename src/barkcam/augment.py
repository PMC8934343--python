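"""RandAugment-style stochastic augmentation.

A fixed number of operations is drawn uniformly (with replacement) from a
candidate list — histogram equalization, rotation, solarization, and
contrast/brightness/color adjustment — each applied with a magnitude drawn
uniformly from a configured range.  Magnitude m in [0, 1] maps to each op's
natural parameter:

    rotate      angle = +/- 30 deg * m (sign drawn at random)
    solarize    threshold = 255 * (1 - m)  (pixels above it are inverted)
    contrast / brightness / color
                enhancement factor = 1 +/- m (sign drawn at random)
    equalize    magnitude-free per-channel histogram equalization

Rotation fills exposed corners with black, consistent with background-mask
semantics.  Masked (all-zero) pixels may change under equalize/rotate; crops
are augmented only after the <=5% mask-ratio rejection step, so this is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageEnhance, ImageOps

DEFAULT_OPS = ("equalize", "rotate", "solarize", "contrast", "brightness", "color")

__all__ = ["AugmentConfig", "apply_op", "rand_augment", "DEFAULT_OPS"]


@dataclass
class AugmentConfig:
    n_ops: int = 2
    magnitude_range: tuple[float, float] = (0.1, 0.6)
    candidate_ops: tuple[str, ...] = DEFAULT_OPS

    def __post_init__(self) -> None:
        if self.n_ops < 0:
            raise ValueError("n_ops must be >= 0")
        if not self.candidate_ops:
            raise ValueError("candidate op list must be non-empty")
        lo, hi = self.magnitude_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("magnitude_range must be within [0, 1] and ordered")


def _to_pil(img: np.ndarray) -> Image.Image:
    return Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB")


def apply_op(img: np.ndarray, op_name: str, magnitude: float, sign: int = 1) -> np.ndarray:
    """Apply one named augmentation at the given magnitude in [0, 1].

    `sign` (+1/-1) disambiguates symmetric ops (rotation direction,
    enhancement above/below 1); rand_augment draws it from the rng.
    """
    if not (0.0 <= magnitude <= 1.0):
        raise ValueError("magnitude must be in [0, 1]")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    pil = _to_pil(img)
    if op_name == "equalize":
        out = ImageOps.equalize(pil)
    elif op_name == "rotate":
        out = pil.rotate(sign * 30.0 * magnitude, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    elif op_name == "solarize":
        out = ImageOps.solarize(pil, threshold=int(round(255 * (1.0 - magnitude))))
    elif op_name in ("contrast", "brightness", "color"):
        enhancer = {
            "contrast": ImageEnhance.Contrast,
            "brightness": ImageEnhance.Brightness,
            "color": ImageEnhance.Color,
        }[op_name](pil)
        out = enhancer.enhance(1.0 + sign * magnitude)
    else:
        raise ValueError(f"unknown augmentation op: {op_name!r}")
    return np.asarray(out, dtype=np.uint8)


def rand_augment(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw cfg.n_ops candidate ops uniformly with replacement and apply them
    in draw order, each at a magnitude uniform in cfg.magnitude_range."""
    out = np.asarray(img, dtype=np.uint8)
    lo, hi = cfg.magnitude_range
    for _ in range(cfg.n_ops):
        idx = int(rng.integers(0, len(cfg.candidate_ops)))
        magnitude = float(rng.uniform(lo, hi))
        sign = 1 if rng.random() < 0.5 else -1
        out = apply_op(out, cfg.candidate_ops[idx], magnitude, sign)
    return out
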