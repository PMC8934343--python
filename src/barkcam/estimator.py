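"""Scikit-learn-style estimator over the patch CNN.

`PatchCNNClassifier` trains the reference convolutional network on arrays of
already-cropped, already-resized RGB patches, so it composes with sklearn
model selection.  The crop-sampling/augmentation training stream used for
whole-photograph datasets lives in `barkcam.pipeline`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .model_contract import ClassifierSpec, TrainConfig, build_tiny_cnn, fit

__all__ = ["PatchCNNClassifier"]


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Small from-scratch CNN classifier for square RGB texture patches.

    Parameters
    ----------
    input_size : patch side in pixels (divisible by 4).
    conv_channels : channel widths of the three convolution blocks.
    dropout_rate : dropout before the head, as in transfer-learning surgery.
    learning_rate, batch_size, patience, max_epochs : Adam training schedule
        with early stopping on held-out overall accuracy.
    validation_fraction : stratified fraction of X held out as the
        early-stopping monitor.
    seed : seeds weight init, shuffling and dropout.

    Attributes (after fit)
    ----------------------
    classes_ : sorted unique labels.
    model_ : the fitted SequentialClassifier.
    history_ : per-epoch dicts (epoch, loss, accuracy).
    """

    def __init__(self, input_size: int = 32, conv_channels: tuple[int, ...] = (16, 32, 64),
                 dropout_rate: float = 0.5, learning_rate: float = 1e-3,
                 batch_size: int = 8, patience: int = 10, max_epochs: int = 60,
                 validation_fraction: float = 0.2, seed: int = 0) -> None:
        self.input_size = input_size
        self.conv_channels = conv_channels
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be (n_samples, side, side, 3) RGB patches")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(f"patches must be {self.input_size}x{self.input_size}")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PatchCNNClassifier":
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        x_tr, x_val, y_tr, y_val = train_test_split(
            X, y_enc, test_size=self.validation_fraction,
            stratify=y_enc, random_state=self.seed,
        )
        spec = ClassifierSpec(
            n_classes=len(self.classes_), dropout_rate=self.dropout_rate,
            input_size=self.input_size,
        )
        model = build_tiny_cnn(spec, seed=self.seed,
                               conv_channels=tuple(self.conv_channels))

        def shuffled_stream():
            rng = np.random.default_rng(self.seed + 1)
            while True:
                order = rng.permutation(len(x_tr))
                for i in order:
                    yield x_tr[i], int(y_tr[i])

        steps = max(1, int(np.ceil(len(x_tr) / self.batch_size)))
        cfg = TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            early_stop_patience=self.patience, max_epochs=self.max_epochs,
            steps_per_epoch=steps, seed=self.seed + 2,
        )
        self.model_, self.history_ = fit(model, shuffled_stream(), (x_val, y_val), cfg)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._check_X(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
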