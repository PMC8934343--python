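"""Classifier abstraction: transfer-learning head surgery, training with
early stopping, and the activation/gradient probe Grad-CAM++ consumes.

The paper-scale backbones (VGG-16, EfficientNet-B0) are replaced at desk scale
by a small from-scratch convolutional network; the probe interface is the
contract every backbone must satisfy, so the saliency machinery is
backbone-agnostic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import islice
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from ._interp import resize_bilinear
from .nn import (
    Adam,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool,
    MaxPool2,
    ReLU,
    SequentialClassifier,
)

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "ProbeResult",
    "adapt_head",
    "probe",
    "build_tiny_cnn",
    "fit",
    "write_training_log",
]


@dataclass
class ClassifierSpec:
    """Head-surgery parameters.  n_classes defaults to the 42 species of the
    full study; desk-scale runs use fewer."""

    n_classes: int = 42
    dropout_rate: float = 0.5
    input_size: int = 331
    target_layer: str = "last_activation"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.target_layer != "last_activation":
            raise ValueError(
                f"unknown target layer {self.target_layer!r}; this backbone "
                "exposes only 'last_activation'"
            )


@dataclass
class TrainConfig:
    """Fine-tuning hyper-parameters (defaults follow the full-scale protocol:
    Adam, lr 1e-5, batch 8, patience 10)."""

    learning_rate: float = 1e-5
    batch_size: int = 8
    early_stop_patience: int = 10
    max_epochs: int = 200
    steps_per_epoch: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.early_stop_patience < 0 or self.max_epochs < 1 or self.steps_per_epoch < 1:
            raise ValueError("patience/max_epochs/steps_per_epoch out of range")


@dataclass
class ProbeResult:
    """Target-layer activations A (u, v, K), class-score gradient
    G = dS_c/dA of identical shape, and the pre-softmax score S_c."""

    activations: np.ndarray
    score_grad: np.ndarray
    score: float
    class_index: int

    def __post_init__(self) -> None:
        if self.activations.shape != self.score_grad.shape:
            raise ValueError("activation and gradient shapes differ")
        if not np.isfinite(self.score):
            raise FloatingPointError("non-finite class score")


def adapt_head(base_model: SequentialClassifier, spec: ClassifierSpec) -> SequentialClassifier:
    """Transfer-learning head surgery: keep the feature stack, replace the
    head with flatten -> dropout -> fresh FC sized to the new label set.
    Softmax is applied by predict_proba / the cross-entropy loss."""
    rng = np.random.default_rng(spec.n_classes * 7919 + 13)
    probe_in = np.zeros((1, base_model.input_size, base_model.input_size, 3), dtype=np.uint8)
    feat = base_model._run(base_model.features, base_model._prep(probe_in), False, None)
    if feat.ndim != 4:
        raise ValueError("base model does not expose a convolutional feature stage")
    n_feat = int(np.prod(feat.shape[1:]))
    head = [Flatten(), Dropout(spec.dropout_rate), Dense(n_feat, spec.n_classes, rng)]
    return SequentialClassifier(
        base_model.features, head, base_model.input_size, spec.n_classes
    )


def probe(model: SequentialClassifier, img: np.ndarray, class_index: int) -> ProbeResult:
    """Run one image through the model, returning target-layer activations and
    the gradient of the pre-softmax class score with respect to them."""
    img = np.asarray(img)
    if img.shape[0] != model.input_size or img.shape[1] != model.input_size:
        img = np.clip(
            np.rint(resize_bilinear(img.astype(np.float64), model.input_size, model.input_size)),
            0, 255,
        ).astype(np.uint8)
    a, g, s = model.probe_arrays(img, class_index)
    return ProbeResult(a, g, s, class_index)


def build_tiny_cnn(spec: ClassifierSpec, seed: int = 0,
                   conv_channels: tuple[int, ...] = (16, 32, 64)) -> SequentialClassifier:
    """Three-convolution-block reference network for desk-scale experiments.

    conv-relu-pool / conv-relu-pool / conv-relu (the target layer), then a
    global-average-pool -> dropout -> dense head, the EfficientNet-style head
    shape.  The linear head ties each class score directly to per-map means,
    so saliency-relevant feature maps are exactly the positively-weighted
    ones; a hidden nonlinear layer instead lets classes be scored through
    negative-evidence paths, which destroys CAM localization.  Fully seeded."""
    rng = np.random.default_rng(seed)
    s = spec.input_size
    if s % 4 != 0:
        raise ValueError("tiny CNN input_size must be divisible by 4")
    features = [
        Conv2D(3, conv_channels[0], 3, rng), ReLU(), MaxPool2(),
        Conv2D(conv_channels[0], conv_channels[1], 3, rng), ReLU(), MaxPool2(),
        Conv2D(conv_channels[1], conv_channels[2], 3, rng), ReLU(),
    ]
    head = [
        GlobalAvgPool(), Dropout(spec.dropout_rate),
        Dense(conv_channels[2], spec.n_classes, rng),
    ]
    return SequentialClassifier(features, head, s, spec.n_classes)


def _batched(stream: Iterator, n: int):
    while True:
        batch = list(islice(stream, n))
        if not batch:
            return
        yield batch


def fit(
    model: SequentialClassifier,
    train_stream: Iterable[tuple[np.ndarray, int]],
    test_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[SequentialClassifier, list[dict]]:
    """Train until test overall accuracy stops improving.

    train_stream yields (augmented crop, label) pairs indefinitely; an epoch
    consumes cfg.steps_per_epoch batches.  After each epoch the overall
    accuracy on test_set is logged; the weights of the best epoch are restored
    on return.  Stops once `early_stop_patience` consecutive epochs pass
    without a new maximum (patience 0 trains exactly one epoch).
    """
    x_test, y_test = test_set
    x_test = np.asarray(x_test)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    stream = iter(train_stream)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.layers, lr=cfg.learning_rate)
    log: list[dict] = []
    best_acc, best_state, since = -np.inf, None, 0
    for epoch in range(1, cfg.max_epochs + 1):
        losses = []
        for _ in range(cfg.steps_per_epoch):
            batch = list(islice(stream, cfg.batch_size))
            if not batch:
                raise ValueError("training stream exhausted (empty data)")
            xb = np.stack([b[0] for b in batch])
            yb = np.array([b[1] for b in batch])
            losses.append(model.loss_and_grads(xb, yb, rng))
            opt.step()
        acc = float(np.mean(model.predict(x_test) == y_test))
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": acc})
        if acc > best_acc:
            best_acc = acc
            best_state = [{k: v.copy() for k, v in l.params.items()} for l in model.layers]
            since = 0
        else:
            since += 1
        if since >= cfg.early_stop_patience:
            break
    if best_state is not None:
        for layer, params in zip(model.layers, best_state):
            for k, v in params.items():
                layer.params[k] = v
    return model, log


def write_training_log(log: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "accuracy"])
        writer.writeheader()
        writer.writerows(log)
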