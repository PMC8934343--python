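"""Sequential classifier split into a feature stack and a classification head.

The split point is the "target layer": the output of the final nonlinearity of
the feature stack, whose activations A and class-score gradients dS_c/dA feed
Grad-CAM++.  The head (flatten -> dropout -> dense [-> relu -> dense]) produces
pre-softmax scores; softmax/cross-entropy live in the loss, so the probed score
S_c is the pre-softmax logit.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np

from .layers import Conv2D, Dense, Dropout, Flatten, GlobalAvgPool, Layer, MaxPool2, ReLU

__all__ = ["SequentialClassifier", "softmax", "cross_entropy"]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


class SequentialClassifier:
    """Feature layers + head layers over NHWC uint8 images scaled to [0, 1]."""

    def __init__(self, features: list[Layer], head: list[Layer], input_size: int, n_classes: int) -> None:
        self.features = features
        self.head = head
        self.input_size = input_size
        self.n_classes = n_classes

    # ---- plumbing -------------------------------------------------------
    def _prep(self, imgs: np.ndarray) -> np.ndarray:
        x = np.asarray(imgs, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} input, got {x.shape[1:3]}"
            )
        return x / 255.0

    def _run(self, layers: list[Layer], x: np.ndarray, train: bool, rng) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def _run_back(self, layers: list[Layer], dout: np.ndarray) -> np.ndarray:
        for layer in reversed(layers):
            dout = layer.backward(dout)
        return dout

    @property
    def layers(self) -> list[Layer]:
        return self.features + self.head

    # ---- inference ------------------------------------------------------
    def scores(self, imgs: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        x = self._prep(imgs)
        a = self._run(self.features, x, train, rng)
        return self._run(self.head, a, train, rng)

    def predict_proba(self, imgs: np.ndarray) -> np.ndarray:
        return softmax(self.scores(imgs))

    def predict(self, imgs: np.ndarray) -> np.ndarray:
        return self.scores(imgs).argmax(axis=-1)

    # ---- training step --------------------------------------------------
    def loss_and_grads(self, imgs: np.ndarray, labels: np.ndarray, rng) -> float:
        scores = self.scores(imgs, train=True, rng=rng)
        probs = softmax(scores)
        n = len(labels)
        loss = cross_entropy(probs, labels)
        dscores = probs.copy()
        dscores[np.arange(n), labels] -= 1.0
        dscores /= n
        da = self._run_back(self.head, dscores)
        self._run_back(self.features, da)
        return loss

    # ---- Grad-CAM++ probe ------------------------------------------------
    def probe_arrays(self, img: np.ndarray, class_index: int) -> tuple[np.ndarray, np.ndarray, float]:
        """Return (A, G, S_c): target-layer activations (u, v, K), gradient
        dS_c/dA of the same shape, and the pre-softmax class score."""
        if not (0 <= class_index < self.n_classes):
            raise ValueError(f"class_index {class_index} out of range [0, {self.n_classes})")
        x = self._prep(img)
        a = self._run(self.features, x, train=False, rng=None)
        scores = self._run(self.head, a, train=False, rng=None)
        if not np.all(np.isfinite(scores)):
            raise FloatingPointError("non-finite class scores at the head")
        dscores = np.zeros_like(scores)
        dscores[:, class_index] = 1.0
        da = self._run_back(self.head, dscores)
        if not np.all(np.isfinite(da)):
            raise FloatingPointError("non-finite gradients at the target layer")
        return a[0], da[0], float(scores[0, class_index])

    # ---- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = {
            "input_size": self.input_size,
            "n_classes": self.n_classes,
            "arch": [type(l).__name__ for l in self.layers],
            "meta": self._meta(),
            "params": [{k: v.copy() for k, v in l.params.items()} for l in self.layers],
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    def _meta(self) -> dict:
        meta = {}
        for i, l in enumerate(self.layers):
            if isinstance(l, Dropout):
                meta[i] = l.rate
            elif isinstance(l, Conv2D):
                meta[i] = l.ksize
        return meta

    @classmethod
    def load(cls, path: str | Path) -> "SequentialClassifier":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        rng = np.random.default_rng(0)
        layers: list[Layer] = []
        for i, name in enumerate(state["arch"]):
            params = state["params"][i]
            if name == "Conv2D":
                l = Conv2D(params["W"].shape[2], params["W"].shape[3], state["meta"][i], rng)
            elif name == "Dense":
                l = Dense(params["W"].shape[0], params["W"].shape[1], rng)
            elif name == "Dropout":
                l = Dropout(state["meta"][i])
            else:
                l = {"ReLU": ReLU, "MaxPool2": MaxPool2, "Flatten": Flatten,
                     "GlobalAvgPool": GlobalAvgPool}[name]()
            for k, v in params.items():
                l.params[k] = v.copy()
            layers.append(l)
        # the head starts at the first spatial-collapse layer by construction
        split = min(state["arch"].index(n) for n in ("Flatten", "GlobalAvgPool")
                    if n in state["arch"])
        return cls(layers[:split], layers[split:], state["input_size"], state["n_classes"])
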