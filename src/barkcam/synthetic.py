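"""Procedural bark-like texture generator with exact ground-truth motif masks.

Real bark species differ by localized diagnostic motifs — blisters, horizontal
lenticels, vertical stripes, crevice-like fissures, scales — set against a
shared noisy ground.  The generator reproduces this structure at desk scale:
a correlated-noise base texture common to all classes, class-specific
axis-aligned motifs drawn on top (so the motif-pixel mask is exact), optional
moss-like green blobs as nuisance content, and all-black side margins that
emulate the masked background flanking a trunk photograph.

Because the base texture is identical across classes, the motifs are the only
class signal: a classifier must attend to them, which makes the pattern mask a
usable ground truth for quantitative saliency-localization checks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw

__all__ = [
    "PatternSpec",
    "SyntheticSample",
    "DEFAULT_CLASSES",
    "generate_sample",
    "generate_dataset",
    "write_dataset",
]

PATTERNS = ("blisters", "horizontal_lenticels", "vertical_stripes", "scaly", "fissures", "smooth")


@dataclass
class PatternSpec:
    """One synthetic species: a motif type plus its density (motif count per
    unit density ~ 50), contrast (intensity offset of motif pixels), base
    color and base-noise standard deviation."""

    pattern: str
    density: float = 0.12
    contrast: float = 60.0
    base_color: tuple[int, int, int] = (110, 95, 80)
    noise_sd: float = 12.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass
class SyntheticSample:
    image: np.ndarray          # H x W x 3 uint8, black side margins
    label: str
    pattern_mask: np.ndarray   # True on drawn motif pixels
    nuisance_mask: np.ndarray  # True on nuisance (moss) pixels; disjoint from pattern


def _base_texture(spec: PatternSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, spec.noise_sd, size=(size, size))
    noise = ndimage.gaussian_filter(noise, sigma=1.2)
    img = np.empty((size, size, 3), dtype=np.float64)
    for k in range(3):
        img[..., k] = spec.base_color[k] + noise
    return img


def _motif_count(density: float) -> int:
    return max(1, int(round(density * 50)))


def _draw_motifs(spec: PatternSpec, size: int, margin: int, rng: np.random.Generator,
                 img: np.ndarray) -> np.ndarray:
    """Draw class motifs in place; return the exact motif-pixel mask."""
    mask = np.zeros((size, size), dtype=bool)
    lo, hi = margin, size - margin
    c = spec.contrast
    n = _motif_count(spec.density)
    if spec.pattern == "smooth":
        return mask
    for _ in range(n):
        if spec.pattern == "blisters":
            r = int(rng.integers(max(2, size // 32), max(3, size // 16)))
            cy = int(rng.integers(lo + r, hi - r))
            cx = int(rng.integers(lo + r, hi - r))
            rr, cc = draw.ellipse(cy, cx, r, r, shape=(size, size))
            delta = +c
        elif spec.pattern == "horizontal_lenticels":
            ry = int(rng.integers(1, 3))
            rx = int(rng.integers(max(3, size // 20), max(4, size // 10)))
            cy = int(rng.integers(lo + ry, hi - ry))
            cx = int(rng.integers(lo + rx, hi - rx))
            rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(size, size))
            delta = -c
        elif spec.pattern == "vertical_stripes":
            width = int(rng.integers(1, 4))
            x0 = int(rng.integers(lo, hi - width))
            rr, cc = np.mgrid[0:size, x0 : x0 + width]
            rr, cc = rr.ravel(), cc.ravel()
            delta = +c
        elif spec.pattern == "scaly":
            h = int(rng.integers(max(3, size // 24), max(4, size // 10)))
            w = int(rng.integers(max(3, size // 24), max(4, size // 10)))
            y0 = int(rng.integers(lo, hi - h))
            x0 = int(rng.integers(lo, hi - w))
            rr, cc = draw.rectangle_perimeter((y0, x0), extent=(h, w), shape=(size, size))
            delta = -c
        else:  # fissures: vertical dark meander
            width = int(rng.integers(1, 3))
            x = int(rng.integers(lo + 2, hi - 2 - width))
            rows, cols = [], []
            for y in range(size):
                x = int(np.clip(x + rng.integers(-1, 2), lo, hi - 1 - width))
                rows.extend([y] * width)
                cols.extend(range(x, x + width))
            rr, cc = np.asarray(rows), np.asarray(cols)
            delta = -1.5 * c
        img[rr, cc] += delta
        mask[rr, cc] = True
    # margins carry no motif ground truth
    mask[:, :margin] = False
    mask[:, size - margin :] = False
    return mask


def _draw_nuisance(size: int, margin: int, rng: np.random.Generator,
                   img: np.ndarray) -> np.ndarray:
    """Moss-like green blobs; returns their pixel mask."""
    mask = np.zeros((size, size), dtype=bool)
    lo, hi = margin, size - margin
    for _ in range(int(rng.integers(1, 4))):
        r = int(rng.integers(max(2, size // 24), max(3, size // 12)))
        cy = int(rng.integers(r, size - r))
        cx = int(rng.integers(lo + r, hi - r))
        rr, cc = draw.ellipse(cy, cx, r, r, shape=(size, size))
        img[rr, cc, 0] = 60.0
        img[rr, cc, 1] = 140.0 + rng.normal(0, 10)
        img[rr, cc, 2] = 60.0
        mask[rr, cc] = True
    return mask


def _wavy_extra(size: int, wedge: int, rng: np.random.Generator) -> np.ndarray:
    """Per-row extra margin width in [0, wedge]: a clipped random walk,
    emulating a non-vertical trunk boundary."""
    walk = np.cumsum(rng.integers(-1, 2, size=size))
    walk = walk - walk.min()
    return np.clip(walk, 0, wedge).astype(int)


def generate_sample(
    spec: PatternSpec,
    size: int = 96,
    margin: int | None = None,
    nuisance_prob: float = 0.3,
    rng: np.random.Generator | None = None,
) -> SyntheticSample:
    """One seeded synthetic bark image with exact motif / nuisance masks and
    black side margins (default margin: 10% of the width per side) whose
    inner boundary is ragged, like a real trunk edge after side-cropping."""
    rng = rng if rng is not None else np.random.default_rng(0)
    if margin is None:
        margin = size // 10
    if size <= 2 * margin:
        raise ValueError("size must exceed twice the margin")
    wedge = 2  # ragged-boundary amplitude: keeps residual mask near the
    # rejection threshold without starving the deterministic test tiling
    img = _base_texture(spec, size, rng)
    nuisance = (
        _draw_nuisance(size, margin + wedge, rng, img)
        if rng.random() < nuisance_prob
        else np.zeros((size, size), dtype=bool)
    )
    pattern = _draw_motifs(spec, size, margin + wedge, rng, img)
    nuisance &= ~pattern
    out = np.clip(np.rint(img), 1, 255).astype(np.uint8)  # bark pixels never all-zero
    extra_l = _wavy_extra(size, wedge, rng)
    extra_r = _wavy_extra(size, wedge, rng)
    for y in range(size):
        out[y, : margin + extra_l[y]] = 0
        out[y, size - margin - extra_r[y] :] = 0
        pattern[y, : margin + extra_l[y]] = False
        pattern[y, size - margin - extra_r[y] :] = False
        nuisance[y, : margin + extra_l[y]] = False
        nuisance[y, size - margin - extra_r[y] :] = False
    return SyntheticSample(out, spec.pattern, pattern, nuisance)


DEFAULT_CLASSES: tuple[PatternSpec, ...] = (
    PatternSpec("blisters"),
    PatternSpec("horizontal_lenticels"),
    PatternSpec("vertical_stripes"),
    PatternSpec("fissures"),
)


@dataclass
class SyntheticDataset:
    train: list[SyntheticSample]
    test: list[SyntheticSample]
    class_names: list[str]
    seeds: dict[str, list[int]]  # per-split per-sample child seeds

    def labels(self, split: str) -> np.ndarray:
        samples = self.train if split == "train" else self.test
        return np.array([self.class_names.index(s.label) for s in samples])


def generate_dataset(
    class_specs: tuple[PatternSpec, ...] = DEFAULT_CLASSES,
    n_per_class: int = 200,
    size: int = 96,
    seed: int = 0,
    margin: int | None = None,
    nuisance_prob: float = 0.3,
) -> SyntheticDataset:
    """Stratified 80/20 train/test split of seeded samples; each sample is
    generated from its own child seed recorded in the manifest."""
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5 for a stratified 80/20 split")
    root = np.random.SeedSequence(seed)
    train, test = [], []
    seeds: dict[str, list[int]] = {"train": [], "test": []}
    n_train = int(round(n_per_class * 0.8))
    for spec in class_specs:
        children = root.spawn(n_per_class)
        for i, child in enumerate(children):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            sample = generate_sample(
                spec, size=size, margin=margin, nuisance_prob=nuisance_prob,
                rng=np.random.default_rng(child_seed),
            )
            if i < n_train:
                train.append(sample)
                seeds["train"].append(child_seed)
            else:
                test.append(sample)
                seeds["test"].append(child_seed)
    return SyntheticDataset(train, test, [s.pattern for s in class_specs], seeds)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Species-per-directory PNG tree with sidecar mask PNGs and a CSV
    manifest; returns the manifest path."""
    out = Path(out_dir)
    rows = []
    for split in ("train", "test"):
        samples = ds.train if split == "train" else ds.test
        for i, (sample, seed) in enumerate(zip(samples, ds.seeds[split])):
            d = out / split / sample.label
            d.mkdir(parents=True, exist_ok=True)
            stem = f"{sample.label}_{split}_{i:04d}"
            Image.fromarray(sample.image).save(d / f"{stem}.png")
            Image.fromarray((sample.pattern_mask * 255).astype(np.uint8)).save(
                d / f"{stem}_pattern_mask.png"
            )
            rows.append({"split": split, "label": sample.label, "file": f"{stem}.png", "seed": seed})
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["split", "label", "file", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest
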