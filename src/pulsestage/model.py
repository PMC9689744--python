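"""Architecture specs and the sklearn-style concatenated 1D CNN classifier.

The family under study: single-input convolutional branches (PPG-only or
ECG-only) and a dual-branch network whose PPG and ECG feature maps are
concatenated along the feature axis before a shared classifier head
(batch normalization, one hidden layer, 5-way softmax).  Depths 1-5 use the
fixed filter progression 8, 16, 32, 64, 128.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import Adam, ConcatNet, softmax

#: Per-layer filter counts; depth-d architectures use the length-d prefix.
FILTER_PROGRESSION = (8, 16, 32, 64, 128)

INPUT_MODES = ("ppg", "ecg", "concat")


@dataclass
class LayerSpec:
    filters: int
    kernel_size: int = 3
    stride: int = 1
    activation: str = "relu"
    pool_size: int = 2

    def __post_init__(self):
        if self.filters <= 0:
            raise ValueError("filters must be > 0")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.stride != 1:
            raise ValueError("stride must be 1")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class FeatureMap:
    """Shape of a branch's final convolutional output: (length, channels)."""

    length: int
    channels: int

    def __post_init__(self):
        if self.length < 1 or self.channels < 1:
            raise ValueError("feature map must have length >= 1 and channels >= 1")


@dataclass
class ModelSpec:
    """Architecture description; ``layers`` is derived from ``depth``."""

    input_mode: str = "concat"
    depth: int = 5
    kernel_size: int = 3
    pool_size: int = 2
    hidden_units: int = 64
    n_classes: int = 5
    input_length: int = 150

    def __post_init__(self):
        if self.input_mode not in INPUT_MODES:
            raise ValueError(f"input_mode must be one of {INPUT_MODES}, got {self.input_mode!r}")
        if not (1 <= self.depth <= 5):
            raise ValueError(f"depth must be in 1..5, got {self.depth}")
        if self.n_classes != 5:
            raise ValueError("n_classes is fixed at 5")

    @property
    def layers(self) -> list[LayerSpec]:
        return [
            LayerSpec(filters=f, kernel_size=self.kernel_size, pool_size=self.pool_size)
            for f in FILTER_PROGRESSION[: self.depth]
        ]

    @property
    def n_branches(self) -> int:
        return 2 if self.input_mode == "concat" else 1

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls(**json.loads(s))


def build_branch(spec: ModelSpec) -> tuple[list[LayerSpec], FeatureMap]:
    """One convolutional branch and its output feature-map shape.

    Same padding keeps the length through each convolution; each max pooling
    floors it by ``pool_size`` (150 -> 75 -> 37 -> 18 -> 9 -> 4 at depth 5).
    """
    layers = spec.layers
    length = spec.input_length
    for _ in layers:
        length //= spec.pool_size
    if length < 1:
        raise ValueError("input too short for this depth/pool_size")
    return layers, FeatureMap(length=length, channels=layers[-1].filters)


def fused_width(spec: ModelSpec) -> int:
    """Width of the flattened, concatenated feature vector entering the head."""
    _, fm = build_branch(spec)
    return spec.n_branches * fm.length * fm.channels


def build_model(spec: ModelSpec, seed: int = 0) -> ConcatNet:
    """Instantiate the network for a spec with seeded fan-in-uniform init."""
    return ConcatNet(
        n_branches=spec.n_branches,
        depth=spec.depth,
        filters=FILTER_PROGRESSION,
        kernel_size=spec.kernel_size,
        pool_size=spec.pool_size,
        hidden_units=spec.hidden_units,
        n_classes=spec.n_classes,
        input_length=spec.input_length,
        seed=seed,
    )


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter count of the built model."""
    return build_model(spec, seed=0).n_parameters()


class ConcatCNNClassifier(ClassifierMixin, BaseEstimator):
    """Concatenated dual-branch 1D CNN blood-pressure stage classifier.

    Scikit-learn estimator interface over the numpy network core.  Trains with
    Adam on categorical cross-entropy and keeps the weights of the epoch with
    the lowest validation loss (checkpoint-on-best); without a validation set
    the final-epoch weights are kept.

    Parameters
    ----------
    input_mode : {"concat", "ppg", "ecg"}
        Two parallel branches (PPG + ECG, feature maps concatenated) or a
        single branch.
    depth : int, 1..5
        Number of conv blocks per branch; filters follow 8, 16, 32, 64, 128.
    learning_rate, max_epochs, batch_size, patience
        Adam step size (default 0.001), epoch budget, minibatch size, and
        early-stopping patience on validation loss.
    class_weight : None or "balanced"
        Optional inverse-frequency loss weights for imbalanced data.
    random_state : int
        Seeds weight init and minibatch shuffling; identical seeds and data
        give bit-identical fits.

    Attributes
    ----------
    classes_ : ndarray of encoded class labels seen (or declared) at fit.
    network_ : the fitted :class:`~pulsestage._nn.ConcatNet`.
    history_ : dict of per-epoch train/val loss and accuracy.
    best_val_loss_ : float, checkpointed validation loss (nan without val set).
    n_parameters_ : trainable parameter count.
    """

    def __init__(self, input_mode="concat", depth=5, kernel_size=3, pool_size=2,
                 hidden_units=64, learning_rate=1e-3, max_epochs=100, batch_size=32,
                 patience=15, class_weight=None, n_classes=5, random_state=0, verbose=0):
        self.input_mode = input_mode
        self.depth = depth
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.class_weight = class_weight
        self.n_classes = n_classes
        self.random_state = random_state
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(
            input_mode=self.input_mode,
            depth=self.depth,
            kernel_size=self.kernel_size,
            pool_size=self.pool_size,
            hidden_units=self.hidden_units,
            n_classes=self.n_classes,
        )

    def _coerce_X(self, X) -> np.ndarray:
        """Accept (n, 150) single-branch, (n, 2, 150) or (n, 300) concat input."""
        X = np.asarray(X, dtype=np.float32)
        nb = 2 if self.input_mode == "concat" else 1
        L = self._spec().input_length
        if X.ndim == 2:
            if X.shape[1] != nb * L:
                raise ValueError(f"expected {nb * L} features for input_mode={self.input_mode!r}, got {X.shape[1]}")
            X = X.reshape(X.shape[0], nb, L)
        elif X.ndim == 3:
            if X.shape[1] != nb or X.shape[2] != L:
                raise ValueError(f"expected shape (n, {nb}, {L}), got {X.shape}")
        else:
            raise ValueError("X must be 2D or 3D")
        return X

    def _encode_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        codes = y.astype(int)
        if codes.min() < 0 or codes.max() >= self.n_classes:
            raise ValueError(f"labels must be integer codes in 0..{self.n_classes - 1}")
        present = np.unique(codes)
        if present.size < self.n_classes:
            warnings.warn(
                f"only {present.size} of {self.n_classes} classes present in training data; "
                "softmax output stays 5-wide",
                UserWarning,
            )
        return codes

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._coerce_X(X)
        y = self._encode_y(y)
        n = X.shape[0]
        K = self.n_classes
        Y = np.zeros((n, K), dtype=np.float32)
        Y[np.arange(n), y] = 1.0
        if X_val is not None:
            Xv = self._coerce_X(X_val)
            yv = self._encode_y(y_val)
        else:
            Xv = yv = None

        sw = None
        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=K).astype(float)
            w = np.where(counts > 0, n / (K * np.maximum(counts, 1)), 0.0)
            sw = w[y].astype(np.float32)
        elif self.class_weight is not None:
            raise ValueError("class_weight must be None or 'balanced'")

        rng = np.random.default_rng(self.random_state)
        net = build_model(self._spec(), seed=int(rng.integers(0, 2**31 - 1)))
        opt = Adam(net.parameters(), lr=self.learning_rate)
        grads = net.gradients()

        history = {"train_loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": []}
        best_loss = np.inf
        best_state = None
        bad_epochs = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses, hits, seen = [], 0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                bs = sw[idx] if sw is not None else None
                loss = net.loss_and_grad(X[idx], Y[idx], sample_weight=bs)
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
                opt.step(grads)
                losses.append(loss * len(idx))
                pred = net.forward(X[idx], train=False).argmax(axis=1)
                hits += int((pred == y[idx]).sum())
                seen += len(idx)
            history["train_loss"].append(float(np.sum(losses) / n))
            history["train_accuracy"].append(hits / seen)
            if Xv is not None:
                vl, va = self._evaluate(net, Xv, yv)
                history["val_loss"].append(vl)
                history["val_accuracy"].append(va)
                if vl < best_loss:
                    best_loss = vl
                    best_state = net.state()
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                if self.verbose:
                    print(f"epoch {epoch}: train_loss={history['train_loss'][-1]:.4f} val_loss={vl:.4f} val_acc={va:.4f}")
                if self.patience and bad_epochs >= self.patience:
                    break
        if best_state is not None:
            net.load_state(best_state)
        self.network_ = net
        self.history_ = history
        self.best_val_loss_ = float(best_loss) if np.isfinite(best_loss) else float("nan")
        self.classes_ = np.arange(K)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self.n_parameters_ = net.n_parameters()
        return self

    @staticmethod
    def _evaluate(net, X, y) -> tuple[float, float]:
        logits = net.forward(X, train=False)
        p = softmax(logits)
        eps = 1e-12
        loss = float(-np.log(p[np.arange(len(y)), y] + eps).mean())
        acc = float((logits.argmax(axis=1) == y).mean())
        return loss, acc

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._coerce_X(X)
        out = []
        for start in range(0, X.shape[0], 512):
            out.append(self.network_.predict_proba(X[start : start + 512]))
        return np.concatenate(out, axis=0)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y).astype(int)).mean())

    # -- persistence --------------------------------------------------------
    def save(self, path):
        """Checkpoint weights + spec to an .npz file."""
        check_is_fitted(self, "network_")
        state = self.network_.state()
        meta = json.dumps({"spec": asdict(self._spec()), "params": self.get_params()})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"arr_{i}": a for i, a in enumerate(state)})

    @classmethod
    def load(cls, path) -> "ConcatCNNClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            state = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
        clf = cls(**meta["params"])
        net = build_model(clf._spec(), seed=0)
        net.load_state(state)
        clf.network_ = net
        clf.classes_ = np.arange(clf.n_classes)
        clf.history_ = {}
        clf.best_val_loss_ = float("nan")
        clf.n_parameters_ = net.n_parameters()
        return clf
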