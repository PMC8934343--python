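"""Grad-CAM++ saliency for a single classified patch.

Given target-layer activations A^k and the gradient G^k = dS_c/dA^k of the
pre-softmax class score, the class is re-scored as Y_c = exp(S_c) so that all
higher-order derivatives of Y_c reduce to powers of G (the common exp(S_c)
prefactor cancels inside the pixel weights and is omitted):

    alpha_ij^k = G_ij^2 / (2 G_ij^2 + sum_ab A_ab^k * G_ij^3)     (0 where the
                                                               denominator is 0)
    w_k        = sum_ij alpha_ij^k * relu(G_ij)
    L_ij       = relu( sum_k w_k * A_ij^k )

The map is returned raw (no per-window normalization): whole-image aggregation
averages maps across overlapping windows, and normalizing per window first
would destroy their relative scale.  Min-max normalization happens once, at
render time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._interp import resize_bilinear
from .model_contract import ProbeResult
from .preprocess import CropWindow

__all__ = ["CamMap", "compute_cam", "upsample_cam"]


@dataclass
class CamMap:
    """Non-negative relevance at target-layer resolution (u, v)."""

    values: np.ndarray
    class_index: int
    window: CropWindow | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("CAM values must be a 2-D raster")
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError("non-finite CAM values")
        if np.any(self.values < 0):
            raise ValueError("CAM values must be non-negative")


def compute_cam(pr: ProbeResult, window: CropWindow | None = None) -> CamMap:
    """Grad-CAM++ map from one probe result."""
    a = np.asarray(pr.activations, dtype=np.float64)  # (u, v, K)
    g = np.asarray(pr.score_grad, dtype=np.float64)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(g))):
        raise FloatingPointError("non-finite activations/gradients at the target layer")
    g2 = g * g
    denom = 2.0 * g2 + a.sum(axis=(0, 1), keepdims=True) * g2 * g
    alpha = np.divide(g2, denom, out=np.zeros_like(g2), where=denom != 0)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=(0, 1))  # (K,)
    cam = np.maximum((a * weights).sum(axis=2), 0.0)
    return CamMap(cam, pr.class_index, window)


def upsample_cam(cam: CamMap, side: int) -> np.ndarray:
    """Bilinearly upsample a CAM to a side x side raster (corner-aligned);
    non-negativity is preserved and constant maps stay constant."""
    u, v = cam.values.shape
    if side < max(u, v):
        raise ValueError(f"side {side} smaller than CAM resolution {u}x{v}")
    out = resize_bilinear(cam.values, side, side)
    return np.maximum(out, 0.0)
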