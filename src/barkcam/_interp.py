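"""Corner-aligned bilinear resampling shared by preprocessing and CAM upsampling.

Corner alignment means the output grid's first and last samples coincide with
the input's first and last pixels, so corner values are preserved exactly and
resizing to the native resolution is the identity.  This convention is stated
explicitly so golden values in tests remain stable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def _axis_coords(n_in: int, n_out: int) -> np.ndarray:
    if n_out == 1:
        return np.zeros(1)
    return np.linspace(0.0, n_in - 1.0, n_out)


def resize_bilinear(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Resize a 2-D (or 2-D + channel) float array with corner-aligned bilinear
    interpolation. Returns float64; the caller handles dtype conversion."""
    arr = np.asarray(arr, dtype=np.float64)
    in_h, in_w = arr.shape[:2]
    rows = _axis_coords(in_h, out_h)
    cols = _axis_coords(in_w, out_w)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    if arr.ndim == 2:
        out = ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
        return out.reshape(out_h, out_w)
    chans = [
        ndimage.map_coordinates(arr[..., k], coords, order=1, mode="nearest").reshape(out_h, out_w)
        for k in range(arr.shape[2])
    ]
    return np.stack(chans, axis=-1)
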