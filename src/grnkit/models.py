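"""Neural and hybrid models for TF-target pair classification.

A pair's 2S-long feature row (TF expression block then target block) is
either fed directly to a fully connected network (FCN) or reshaped to a
2 x S grid — TF expression in row 0, target expression in row 1 — so that
3 x 3 convolution kernels mix the two genes locally along the sample axis.
The CNN stacks two convolution blocks (ReLU, "same" padding) with (1, 2)
max pooling, so the two-row structure survives both blocks, then flattens
into a dense head ending in a sigmoid unit.

The hybrid architecture reuses a trained CNN's convolutional part as a
fixed feature extractor: the flattened activations train a classical
classifier (random forest, extra trees, AdaBoost, ...), which often beats
both the plain classifier on raw features and the CNN alone.

Everything here is plain NumPy: layers cache their forward pass and
back-propagate analytically; training uses mini-batch RMSprop. Classical
classifiers are scikit-learn estimators behind a thin uniform surface.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pairs import PairFeatureMatrix

log = logging.getLogger("grnkit")

__all__ = [
    "LOSSES",
    "ModelConfig",
    "NeuralNetwork",
    "EncoderFeatures",
    "ClassifierSpec",
    "HybridModel",
    "reshape_pair_input",
    "build_model",
    "train_model",
    "extract_features",
    "fit_hybrid",
    "grid_search",
    "kernel_grid_experiment",
    "load_default_grids",
    "preprocess_features",
    "make_classifier",
    "save_model",
    "load_model",
]

_EPS = 1e-7


# --------------------------------------------------------------------------
# Loss functions (value and elementwise derivative w.r.t. the prediction p)
# --------------------------------------------------------------------------

def _bce(p, y):
    p = np.clip(p, _EPS, 1 - _EPS)
    return -(y * np.log(p) + (1 - y) * np.log(1 - p))


def _bce_grad(p, y):
    p = np.clip(p, _EPS, 1 - _EPS)
    return (p - y) / (p * (1 - p))


def _hinge(p, y):
    t = 2.0 * y - 1.0  # labels mapped to +/-1
    return np.maximum(1.0 - t * p, 0.0)


def _hinge_grad(p, y):
    t = 2.0 * y - 1.0
    return np.where(1.0 - t * p > 0, -t, 0.0)


def _mse(p, y):
    return (p - y) ** 2


def _mse_grad(p, y):
    return 2.0 * (p - y)


def _msle(p, y):
    return (np.log1p(p) - np.log1p(y)) ** 2


def _msle_grad(p, y):
    return 2.0 * (np.log1p(p) - np.log1p(y)) / (1.0 + p)


def _mae(p, y):
    return np.abs(p - y)


def _mae_grad(p, y):
    return np.sign(p - y)


def _poisson(p, y):
    return p - y * np.log(p + _EPS)


def _poisson_grad(p, y):
    return 1.0 - y / (p + _EPS)


def _huber(p, y, delta=1.0):
    e = p - y
    small = np.abs(e) <= delta
    return np.where(small, 0.5 * e**2, delta * (np.abs(e) - 0.5 * delta))


def _huber_grad(p, y, delta=1.0):
    e = p - y
    return np.where(np.abs(e) <= delta, e, delta * np.sign(e))


def _logcosh(p, y):
    e = p - y
    # stable log(cosh(e)) = |e| + log1p(exp(-2|e|)) - log(2)
    return np.abs(e) + np.log1p(np.exp(-2.0 * np.abs(e))) - np.log(2.0)


def _logcosh_grad(p, y):
    return np.tanh(p - y)


#: The eight benchmarked losses: name -> (per-sample value, d/dp).
LOSSES = {
    "bce": (_bce, _bce_grad),
    "hinge": (_hinge, _hinge_grad),
    "mse": (_mse, _mse_grad),
    "msle": (_msle, _msle_grad),
    "mae": (_mae, _mae_grad),
    "poisson": (_poisson, _poisson_grad),
    "huber": (_huber, _huber_grad),
    "logcosh": (_logcosh, _logcosh_grad),
}

_KERNEL_GRID = (8, 16, 32, 64, 128, 256)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters for FCN/CNN models.

    Defaults: two dense layers of 256 and 128 units each followed by
    dropout, learning rate 3e-5, batch size 100, RMSprop, 100 epochs,
    3 x 3 kernels. ``conv_kernels`` gives the kernel counts of the two
    convolution layers (CNN only).
    """

    model_family: str = "cnn"
    loss_name: str = "bce"
    conv_kernels: tuple[int, int] = (32, 32)
    kernel_size: tuple[int, int] = (3, 3)
    dense_units: tuple[int, int] = (256, 128)
    dropout_rate: float = 0.2
    learning_rate: float = 3e-5
    batch_size: int = 100
    epochs: int = 100
    optimizer_name: str = "rmsprop"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in ("fcn", "cnn"):
            raise ValueError(f"model_family must be 'fcn' or 'cnn', got {self.model_family!r}")
        if self.loss_name not in LOSSES:
            raise ValueError(
                f"unknown loss {self.loss_name!r}; valid names: {sorted(LOSSES)}"
            )
        if self.loss_name in ("msle", "poisson"):
            log.warning(
                "loss %r is unconventional for 0/1 targets with sigmoid outputs; "
                "it is supported for benchmarking purposes",
                self.loss_name,
            )
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer_name != "rmsprop":
            raise ValueError("only the 'rmsprop' optimizer is supported")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")

    def to_dict(self) -> dict:
        return {
            "model_family": self.model_family,
            "loss_name": self.loss_name,
            "conv_kernels": list(self.conv_kernels),
            "kernel_size": list(self.kernel_size),
            "dense_units": list(self.dense_units),
            "dropout_rate": self.dropout_rate,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "optimizer_name": self.optimizer_name,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("conv_kernels", "kernel_size", "dense_units"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

class _Layer:
    trainable = True
    has_params = False

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def param_arrays(self):
        return []

    def grad_arrays(self):
        return []


class Dense(_Layer):
    has_params = True

    def __init__(self, n_in: int, n_out: int, activation: Optional[str], rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train: bool):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        else:
            out = z
        self._out = out
        return out

    def backward(self, dout):
        if self.activation == "relu":
            dz = dout * (self._out > 0)
        elif self.activation == "sigmoid":
            dz = dout * self._out * (1.0 - self._out)
        else:
            dz = dout
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def param_arrays(self):
        return [self.W, self.b]

    def grad_arrays(self):
        return [self.dW, self.db]


class Dropout(_Layer):
    has_params = False

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Conv2D(_Layer):
    """3 x 3 convolution with "same" zero padding and ReLU activation."""

    has_params = True

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int], rng: np.random.Generator):
        kh, kw = kernel
        fan_in = c_in * kh * kw
        fan_out = c_out * kh * kw
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.kernel = (kh, kw)
        self.c_in, self.c_out = c_in, c_out
        self.W = rng.uniform(-limit, limit, size=(fan_in, c_out))  # (C*kh*kw, F)
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train: bool):
        n, c, h, w = x.shape
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
        self._cols = cols
        self._shape = (n, c, h, w)
        z = cols @ self.W + self.b
        out = np.maximum(z, 0.0).reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        self._out = out
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        dz = (dout * (self._out > 0)).transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW = self._cols.T @ dz
        self.db = dz.sum(axis=0)
        dcols = (dz @ self.W.T).reshape(n, h, w, c, kh, kw)
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, ph : ph + h, pw : pw + w]

    def param_arrays(self):
        return [self.W, self.b]

    def grad_arrays(self):
        return [self.dW, self.db]


class MaxPool1x2(_Layer):
    """Max pooling of size (1, 2) along the sample axis (valid, stride 2)."""

    has_params = False

    def forward(self, x, train: bool):
        n, c, h, w = x.shape
        w2 = w // 2
        t = x[:, :, :, : 2 * w2].reshape(n, c, h, w2, 2)
        self._argmax = t.argmax(axis=-1)
        self._in_width = w
        return t.max(axis=-1)

    def backward(self, dout):
        n, c, h, w2 = dout.shape
        dt = np.zeros((n, c, h, w2, 2))
        np.put_along_axis(dt, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, self._in_width))
        dx[:, :, :, : 2 * w2] = dt.reshape(n, c, h, 2 * w2)
        return dx


class Flatten(_Layer):
    has_params = False

    def forward(self, x, train: bool):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _RMSprop:
    """RMSprop with Keras-style defaults (rho 0.9, epsilon 1e-7)."""

    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._acc: dict[int, np.ndarray] = {}

    def step(self, layers) -> None:
        for li, layer in enumerate(layers):
            if not (layer.has_params and layer.trainable):
                continue
            for pi, (p, g) in enumerate(zip(layer.param_arrays(), layer.grad_arrays())):
                key = li * 16 + pi
                acc = self._acc.get(key)
                if acc is None:
                    acc = np.zeros_like(p)
                    self._acc[key] = acc
                acc *= self.rho
                acc += (1.0 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(acc) + self.eps)


# --------------------------------------------------------------------------
# Networks
# --------------------------------------------------------------------------

def reshape_pair_input(row: np.ndarray) -> np.ndarray:
    """Reshape a 2S pair feature row into a 2 x S grid (TF row, target row)."""
    row = np.asarray(row)
    if row.ndim != 1 or row.size % 2:
        raise ValueError(f"pair input must be a 1-D vector of even length, got shape {row.shape}")
    return row.reshape(2, row.size // 2)


def cnn_feature_dim(input_width: int, k2: int) -> int:
    """Closed-form flatten width of the two conv/pool blocks for a 2S input."""
    s = input_width // 2
    return 2 * (s // 2 // 2) * k2


class NeuralNetwork:
    """An FCN or CNN pair classifier with a sigmoid output unit.

    Built by :func:`build_model`; trained in place by :func:`train_model`.
    ``history`` holds one ``{"loss", "accuracy"}`` record per trained epoch.
    """

    def __init__(self, config: ModelConfig, input_width: int):
        self.config = config
        self.input_width = input_width
        self.trained = False
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        d1, d2 = config.dense_units
        if config.model_family == "cnn":
            if input_width % 2:
                raise ValueError("CNN input width must be even (TF block + target block)")
            k1, k2 = config.conv_kernels
            self.feature_dim = cnn_feature_dim(input_width, k2)
            if self.feature_dim <= 0:
                raise ValueError(f"input width {input_width} too small for two pooling steps")
            self.layers: list[_Layer] = [
                Conv2D(1, k1, config.kernel_size, rng),
                MaxPool1x2(),
                Conv2D(k1, k2, config.kernel_size, rng),
                MaxPool1x2(),
                Flatten(),
                Dense(self.feature_dim, d1, "relu", rng),
                Dropout(config.dropout_rate, self._dropout_rng),
                Dense(d1, d2, "relu", rng),
                Dropout(config.dropout_rate, self._dropout_rng),
                Dense(d2, 1, "sigmoid", rng),
            ]
            self.encoder_end = 5  # layers[:encoder_end] == conv/pool/flatten encoder
        else:
            self.feature_dim = None
            self.layers = [
                Dense(input_width, d1, "relu", rng),
                Dropout(config.dropout_rate, self._dropout_rng),
                Dense(d1, d2, "relu", rng),
                Dropout(config.dropout_rate, self._dropout_rng),
                Dense(d2, 1, "sigmoid", rng),
            ]
            self.encoder_end = 0

    # -- forward passes ----------------------------------------------------
    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_width:
            raise ValueError(f"expected (n, {self.input_width}) input, got {X.shape}")
        if self.config.model_family == "cnn":
            return X.reshape(X.shape[0], 1, 2, self.input_width // 2)
        return X

    def _forward(self, x, train: bool):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probabilities in [0, 1] (inference mode, dropout off)."""
        return self._forward(self._prepare(X), train=False)[:, 0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Flattened convolutional activations (CNN only, inference mode)."""
        if self.config.model_family != "cnn":
            raise ValueError("feature extraction requires a CNN model")
        x = self._prepare(X)
        for layer in self.layers[: self.encoder_end]:
            x = layer.forward(x, train=False)
        return x

    @property
    def conv_layers(self) -> list[Conv2D]:
        return [l for l in self.layers if isinstance(l, Conv2D)]

    def set_encoder_trainable(self, trainable: bool) -> None:
        for l in self.conv_layers:
            l.trainable = trainable

    def n_parameters(self) -> int:
        return int(
            sum(p.size for l in self.layers if l.has_params for p in l.param_arrays())
        )


def build_model(config: ModelConfig, input_width: int) -> NeuralNetwork:
    """Construct an untrained FCN or CNN for 2S-wide pair feature rows."""
    return NeuralNetwork(config, input_width)


def train_model(
    model: NeuralNetwork,
    X,
    y: np.ndarray,
    epochs: Optional[int] = None,
) -> NeuralNetwork:
    """Train in place with mini-batch RMSprop; returns the model.

    ``X`` may be a :class:`~grnkit.pairs.PairFeatureMatrix` or a 2-D array.
    With ``epochs=0`` the model is returned untouched with empty history.
    Reproducible for a fixed config seed on a single device.
    """
    if isinstance(X, PairFeatureMatrix):
        if y is None:
            y = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} labels")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    cfg = model.config
    n_epochs = cfg.epochs if epochs is None else epochs
    if n_epochs == 0:
        return model
    loss_fn, loss_grad = LOSSES[cfg.loss_name]
    opt = _RMSprop(cfg.learning_rate)
    shuffle_rng = np.random.default_rng(cfg.seed + 2)
    n = X.shape[0]
    for epoch in range(n_epochs):
        perm = shuffle_rng.permutation(n)
        losses, correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb = model._prepare(X[idx])
            yb = y[idx]
            out = model._forward(xb, train=True)
            p = out[:, 0]
            losses += float(loss_fn(p, yb).sum())
            correct += int(((p >= 0.5) == yb).sum())
            dp = loss_grad(p, yb) / idx.size  # mean reduction
            dout = dp[:, None]
            for layer in reversed(model.layers):
                dout = layer.backward(dout)
            opt.step(model.layers)
        model.history.append({"epoch": epoch, "loss": losses / n, "accuracy": correct / n})
    model.trained = True
    return model


@dataclass
class EncoderFeatures:
    """Flattened convolutional activations for a batch of pairs."""

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("encoder features contain non-finite values")


def extract_features(encoder: NeuralNetwork, X) -> EncoderFeatures:
    """Run the convolutional encoder over pair rows (deterministic inference)."""
    if isinstance(X, PairFeatureMatrix):
        X = X.values
    feats = encoder.encode(X)
    prov = f"cnn-k{encoder.config.conv_kernels[0]}x{encoder.config.conv_kernels[1]}-seed{encoder.config.seed}"
    return EncoderFeatures(feats, prov)


# --------------------------------------------------------------------------
# Classical classifiers and hybrids
# --------------------------------------------------------------------------

_FAMILIES = (
    "logistic_regression",
    "svm",
    "decision_tree",
    "knn",
    "random_forest",
    "extra_trees",
    "adaboost",
    "gradient_boosting",
    "bagging",
)


@dataclass
class ClassifierSpec:
    """One of the nine classical classifier families plus hyperparameters."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {list(_FAMILIES)}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator behind a classifier spec."""
    hp = dict(spec.hyperparameters)
    s = spec.seed
    if spec.family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=s, **hp)
    if spec.family == "svm":
        # scores come from decision_function, squashed to [0, 1] monotonically
        return SVC(random_state=s, **hp)
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(random_state=s, **hp)
    if spec.family == "knn":
        return KNeighborsClassifier(**hp)
    if spec.family == "random_forest":
        return RandomForestClassifier(random_state=s, **hp)
    if spec.family == "extra_trees":
        return ExtraTreesClassifier(random_state=s, **hp)
    if spec.family == "adaboost":
        return AdaBoostClassifier(random_state=s, **hp)
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=s, **hp)
    return BaggingClassifier(random_state=s, **hp)


def _estimator_proba(est, X: np.ndarray) -> np.ndarray:
    """Class-1 scores in [0, 1]; margin outputs get a logistic squashing
    (monotone, so rankings are unaffected)."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    margin = est.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


@dataclass
class HybridModel:
    """A classical classifier fitted on convolutional encoder features."""

    spec: ClassifierSpec
    estimator: object
    encoder_id: str = ""

    def predict_proba(self, features) -> np.ndarray:
        X = features.values if isinstance(features, EncoderFeatures) else np.asarray(features)
        return _estimator_proba(self.estimator, X)

    def predict(self, features, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(features) >= threshold).astype(int)


def fit_hybrid(features: EncoderFeatures, y: np.ndarray, spec: ClassifierSpec) -> HybridModel:
    """Fit a classical classifier on encoder features (step 2 of the hybrid)."""
    X = features.values if isinstance(features, EncoderFeatures) else np.asarray(features)
    y = np.asarray(y).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"features have {X.shape[0]} rows but y has {y.shape[0]} labels")
    est = make_classifier(spec)
    est.fit(X, y)
    enc_id = features.provenance if isinstance(features, EncoderFeatures) else ""
    return HybridModel(spec, est, enc_id)


def load_default_grids() -> dict[str, dict[str, list]]:
    """The shipped per-family hyperparameter grids (classifier_grids.yaml)."""
    import yaml
    from importlib import resources

    text = resources.files("grnkit").joinpath("classifier_grids.yaml").read_text()
    return yaml.safe_load(text)


def grid_search(
    spec: ClassifierSpec,
    grid: dict[str, list],
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
):
    """Exhaustive hyperparameter search by stratified k-fold CV mean accuracy.

    Every grid point is evaluated; ties are broken by first-in-grid order.
    Returns ``(best_params, cv_table)`` where the table holds one row per
    grid point with per-fold accuracies and their mean.
    """
    import pandas as pd

    if not grid:
        raise ValueError("grid must be nonempty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(X)
    y = np.asarray(y).ravel()
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds minority class size {counts.min()}")
    names = list(grid)
    combos = list(itertools.product(*(grid[k] for k in names)))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    best, best_score = None, -np.inf
    for combo in combos:
        params = dict(zip(names, combo))
        fold_scores = []
        for tr, te in splits:
            est = make_classifier(replace(spec, hyperparameters={**spec.hyperparameters, **params}))
            est.fit(X[tr], y[tr])
            fold_scores.append(float((est.predict(X[te]) == y[te]).mean()))
        row = dict(params)
        row.update({f"fold_{i}": s for i, s in enumerate(fold_scores)})
        row["mean_accuracy"] = float(np.mean(fold_scores))
        rows.append(row)
        if row["mean_accuracy"] > best_score:  # strict: ties keep earlier combo
            best, best_score = params, row["mean_accuracy"]
    return best, pd.DataFrame(rows)


def kernel_grid_experiment(
    k_values,
    train: tuple[np.ndarray, np.ndarray],
    holdout: tuple[np.ndarray, np.ndarray],
    base_config: Optional[ModelConfig] = None,
    epochs: Optional[int] = None,
):
    """Holdout accuracy of (k1, k2) CNNs with BCE loss over a kernel grid.

    Returns a tidy table with one row per grid cell (k1, k2, accuracy, seed);
    pivot on (k1, k2) for the heat-map matrix.
    """
    import pandas as pd

    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")
    cfg = base_config or ModelConfig()
    Xtr, ytr = train
    Xte, yte = holdout
    rows = []
    for k1 in k_values:
        for k2 in k_values:
            c = replace(cfg, model_family="cnn", loss_name="bce", conv_kernels=(k1, k2))
            model = build_model(c, np.asarray(Xtr).shape[1])
            train_model(model, Xtr, ytr, epochs=epochs)
            acc = float(((model.predict_proba(Xte) >= 0.5) == np.asarray(yte)).mean())
            rows.append({"k1": k1, "k2": k2, "accuracy": acc, "seed": c.seed})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Feature preprocessing and persistence
# --------------------------------------------------------------------------

def preprocess_features(
    X: np.ndarray,
    stats: Optional[tuple[np.ndarray, np.ndarray]] = None,
    log_transform: bool = True,
):
    """log1p + per-column standardization for neural-network training.

    Returns ``(X_transformed, stats)``; pass the returned ``stats`` back in
    to apply the training-set transform to a test set.
    """
    X = np.asarray(X, dtype=float)
    Z = np.log1p(X) if log_transform else X.copy()
    if stats is None:
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        stats = (mu, sd)
    mu, sd = stats
    return (Z - mu) / sd, stats


def save_model(model: NeuralNetwork, path) -> None:
    """Persist weights (.npz) plus a JSON sidecar with config and metadata."""
    path = Path(path)
    arrays = {}
    for i, layer in enumerate(model.layers):
        for j, p in enumerate(layer.param_arrays()):
            arrays[f"layer{i}_p{j}"] = p
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": model.config.to_dict(),
        "input_width": model.input_width,
        "trained": model.trained,
        "history": model.history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> NeuralNetwork:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    model = build_model(ModelConfig.from_dict(sidecar["config"]), sidecar["input_width"])
    with np.load(path.with_suffix(".npz")) as data:
        for i, layer in enumerate(model.layers):
            for j, p in enumerate(layer.param_arrays()):
                p[...] = data[f"layer{i}_p{j}"]
    model.trained = sidecar["trained"]
    model.history = sidecar["history"]
    return model
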