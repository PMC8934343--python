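"""Glue between whole-photograph datasets and the patch classifier.

Training consumes an endless stream of rejection-sampled random crops that
are resized and augmented on the fly (crops are generated concurrently with
training, never materialized as a dataset).  Testing tiles each photograph
deterministically and evaluates per cropped sample.  Both paths first
side-crop the fully-masked columns flanking the trunk; ragged residual
background is handled by the mask-ratio threshold.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from .augment import AugmentConfig, rand_augment
from .preprocess import (
    CropConfig,
    SamplingExhaustedError,
    extract_window,
    resize_image,
    sample_training_crop,
    tile_test_crops,
    trim_masked_sides,
)

__all__ = ["training_stream", "tiled_test_arrays"]


def training_stream(
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    crop_cfg: CropConfig,
    aug_cfg: AugmentConfig,
    input_size: int,
    seed: int = 0,
) -> Iterator[tuple[np.ndarray, int]]:
    """Endless (augmented crop, label) pairs: pick an image at random, draw a
    rejection-sampled crop, resize to the model input, augment."""
    if len(images) == 0 or len(images) != len(labels):
        raise ValueError("images and labels must be non-empty and equal-length")
    rng = np.random.default_rng(seed)
    trimmed = [trim_masked_sides(img) for img in images]
    while True:
        i = int(rng.integers(0, len(trimmed)))
        try:
            win = sample_training_crop(trimmed[i], crop_cfg, rng, name=f"image[{i}]")
        except SamplingExhaustedError:
            continue  # photographs that are nearly all background are skipped
        crop = resize_image(extract_window(trimmed[i], win), input_size)
        yield rand_augment(crop, aug_cfg, rng), int(labels[i])


def tiled_test_arrays(
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    crop_cfg: CropConfig,
    input_size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic test tiling of every photograph.

    Returns (crops, crop_labels, image_index): stacked resized tiles, the
    label of each tile's source image, and that image's index."""
    crops, crop_labels, owners = [], [], []
    for i, (img, lab) in enumerate(zip(images, labels)):
        img = trim_masked_sides(img)
        for win in tile_test_crops(img, crop_cfg):
            crops.append(resize_image(extract_window(img, win), input_size))
            crop_labels.append(int(lab))
            owners.append(i)
    if not crops:
        raise ValueError("no test tiles survived the mask threshold")
    return np.stack(crops), np.array(crop_labels), np.array(owners)
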