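"""Autoencoder pre-training and the class-weighted feed-forward classifier.

The modelling core is a fully connected network trained in two stages:

1. an autoencoder (one layer, or several stacked greedily layer by
   layer) learns to reconstruct the standardised descriptor matrix,
   capturing the correlation structure among descriptors;
2. its encoder weights initialise a classifier of the same hidden
   architecture, topped with a single sigmoid output unit, which is then
   fine-tuned on the binary drug-likeness labels.

The classifier minimises a class-weighted binary cross-entropy

.. math::

    L = -\\sum_k \\bigl( w\\,y_k \\log a_k
        + (1 - w)(1 - y_k) \\log(1 - a_k) \\bigr)

where :math:`a_k` is the predicted probability that compound *k* is
drug-like and :math:`w \\in (0, 1)` is the weight on the positive-sample
loss.  Raising ``w`` above 0.5 pushes the model towards higher
sensitivity at the cost of specificity; :mod:`druglike.tuning` scans
``w`` for the point where the two meet.

Everything is plain numpy: mini-batch Adam (or SGD), inverted dropout on
hidden activations, L2 weight decay, truncated-normal initialisation,
and early stopping on held-out accuracy with best-weight restoration.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .errors import DataError, TrainingError

#: probabilities are clipped to [EPS, 1-EPS] before any logarithm
EPS = 1e-7

_ACTIVATIONS = {"relu", "linear", "sigmoid"}


# --------------------------------------------------------------------------
# configuration

@dataclass
class TrainingConfig:
    """Hyper-parameters of the autoencoder and classifier.

    Defaults follow the tuned single-hidden-layer setting: 512 ReLU
    units, L2 coefficient 1e-4, dropout 0.14, batch size 128, Adam,
    truncated-normal initialisation, MSE loss for the autoencoder and
    (weighted) binary cross-entropy for the classifier.
    """

    hidden_dims: Sequence[int] = (512,)
    activation: str = "relu"
    l2: float = 1e-4
    dropout: float = 0.14
    batch_size: int = 128
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    init_std: float = 0.05
    ae_epochs: int = 30
    max_epochs: int = 100
    early_stop_patience: int = 10
    pos_weight: float = 0.5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise DataError("dropout must be in [0, 1)")
        if not (0 < self.pos_weight < 1):
            raise DataError("pos_weight must be in (0, 1)")
        if self.batch_size < 1:
            raise DataError("batch_size must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise DataError(f"unknown activation {self.activation!r}")
        if self.optimizer not in {"adam", "sgd"}:
            raise DataError(f"unknown optimizer {self.optimizer!r}")
        self.hidden_dims = tuple(int(d) for d in self.hidden_dims)
        if any(d <= 0 for d in self.hidden_dims):
            raise DataError("hidden dims must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# --------------------------------------------------------------------------
# parameters and primitives

@dataclass
class NetworkParams:
    """Ordered layer weights/biases — the transferable network state."""

    weights: list
    biases: list
    activations: list
    role: str  # {"autoencoder", "classifier"}

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.biases) == len(self.activations)):
            raise DataError("weights, biases and activations must align")
        for l in range(len(self.weights) - 1):
            if self.weights[l].shape[1] != self.weights[l + 1].shape[0]:
                raise DataError("consecutive layer dimensions do not chain")

    @property
    def layer_dims(self) -> list:
        return [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            list(self.activations),
            self.role,
        )

    def save(self, path: str | Path) -> None:
        """Serialise to a directory: ``arrays.npz`` + ``meta.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{l}"] = W
            arrays[f"b{l}"] = b
        np.savez(path / "arrays.npz", **arrays)
        meta = {
            "n_layers": len(self.weights),
            "activations": list(self.activations),
            "role": self.role,
            "layer_dims": self.layer_dims,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        with np.load(path / "arrays.npz") as arrays:
            weights = [arrays[f"W{l}"] for l in range(meta["n_layers"])]
            biases = [arrays[f"b{l}"] for l in range(meta["n_layers"])]
        return cls(weights, biases, meta["activations"], meta["role"])


def init_truncated_normal(shape, stddev: float = 0.05, seed=None) -> np.ndarray:
    """Draws from N(0, stddev²) with values beyond ±2·stddev redrawn.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if stddev <= 0:
        raise DataError("stddev must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.normal(0.0, stddev, size=shape)
    bad = np.abs(out) > 2 * stddev
    while bad.any():
        out[bad] = rng.normal(0.0, stddev, size=int(bad.sum()))
        bad = np.abs(out) > 2 * stddev
    return out


def weighted_bce(labels, probabilities, w: float, reduction: str = "sum") -> float:
    """Class-weighted binary cross-entropy.

    ``reduction="sum"`` returns the loss summed over samples (the
    canonical form); ``"mean"`` divides by the sample count, which is the
    per-batch variant used inside mini-batch training for optimiser-scale
    stability.  Probabilities are clipped to ``[EPS, 1-EPS]``.
    """
    if not (0 < w < 1):
        raise DataError("loss weight w must be in (0, 1)")
    if reduction not in {"sum", "mean"}:
        raise DataError("reduction must be 'sum' or 'mean'")
    y = np.asarray(labels, dtype=float).ravel()
    a = np.clip(np.asarray(probabilities, dtype=float).ravel(), EPS, 1 - EPS)
    if y.shape != a.shape:
        raise DataError("labels and probabilities have different lengths")
    terms = w * y * np.log(a) + (1 - w) * (1 - y) * np.log(1 - a)
    total = -float(terms.sum())
    return total / len(y) if reduction == "mean" else total


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return z


def _act_grad(z: np.ndarray, kind: str) -> np.ndarray:
    # derivative from the pre-activation, so dropout masks never leak in
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "sigmoid":
        s = 1.0 / (1.0 + np.exp(-z))
        return s * (1.0 - s)
    return np.ones_like(z)


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass (dropout disabled)."""
    h = np.asarray(X, dtype=float)
    if h.shape[1] != params.weights[0].shape[0]:
        raise DataError(
            f"input has {h.shape[1]} features, network expects {params.weights[0].shape[0]}"
        )
    for W, b, act in zip(params.weights, params.biases, params.activations):
        h = _act(h @ W + b, act)
    return h


class _Adam:
    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, shapes, lr=1e-3):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


def _make_optimizer(kind: str, shapes, lr: float):
    return _Adam(shapes, lr=lr) if kind == "adam" else _SGD(shapes, lr=lr)


def _net_pass(weights, biases, activations, X, dropout=0.0, drop_hidden=None, rng=None):
    """Forward pass keeping caches; inverted dropout on hidden outputs."""
    hs = [np.asarray(X, dtype=float)]
    zs, masks = [], []
    n_layers = len(weights)
    for l in range(n_layers):
        z = hs[-1] @ weights[l] + biases[l]
        h = _act(z, activations[l])
        is_hidden = drop_hidden[l] if drop_hidden is not None else (l < n_layers - 1)
        if dropout > 0 and is_hidden and rng is not None:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
        else:
            mask = None
        zs.append(z)
        masks.append(mask)
        hs.append(h)
    return hs, zs, masks


def _backprop(weights, biases, activations, hs, zs, masks, delta_out, l2):
    """Backpropagate an output-layer delta; returns (grad_W, grad_b) lists.

    ``delta_out`` is dL/dz for the final layer (already including the
    loss and output-activation derivatives).
    """
    n_layers = len(weights)
    gW = [None] * n_layers
    gb = [None] * n_layers
    delta = delta_out
    for l in range(n_layers - 1, -1, -1):
        gW[l] = hs[l].T @ delta + 2.0 * l2 * weights[l]
        gb[l] = delta.sum(axis=0)
        if l > 0:
            dh = delta @ weights[l].T
            if masks[l - 1] is not None:
                dh = dh * masks[l - 1]
            delta = dh * _act_grad(zs[l - 1], activations[l - 1])
    return gW, gb


# --------------------------------------------------------------------------
# autoencoder

class Autoencoder(BaseEstimator, TransformerMixin):
    """Greedy layerwise autoencoder on a standardised descriptor matrix.

    Each hidden layer is trained as a single-hidden-layer autoencoder
    (encoder with the configured activation, linear decoder, mean squared
    reconstruction error + L2 weight decay) on the codes of the previous
    layer; stacking several entries in ``hidden_dims`` yields a stacked
    autoencoder.  After fitting, :meth:`transform` encodes and
    :meth:`inverse_transform` decodes.

    The fitted encoder initialises the classifier via
    :func:`transfer_weights`.
    """

    def __init__(self, hidden_dims=(512,), activation="relu", l2=1e-4,
                 dropout=0.14, batch_size=128, optimizer="adam",
                 learning_rate=1e-3, init_std=0.05, max_epochs=30, seed=0):
        self.hidden_dims = hidden_dims
        self.activation = activation
        self.l2 = l2
        self.dropout = dropout
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.init_std = init_std
        self.max_epochs = max_epochs
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise DataError("autoencoder input must be finite (standardise first)")
        rng = np.random.default_rng(self.seed)
        enc_W, enc_b, dec_W, dec_b = [], [], [], []
        traces = []
        codes = X
        for dim in tuple(self.hidden_dims):
            W1, b1, W2, b2, trace = self._fit_layer(codes, int(dim), rng)
            enc_W.append(W1); enc_b.append(b1)
            dec_W.append(W2); dec_b.append(b2)
            traces.append(trace)
            codes = _act(codes @ W1 + b1, self.activation)
        self.encoder_weights_ = enc_W
        self.encoder_biases_ = enc_b
        self.decoder_weights_ = dec_W
        self.decoder_biases_ = dec_b
        self.trace_ = traces
        self.n_features_in_ = X.shape[1]
        self.params_ = NetworkParams(
            weights=[W.copy() for W in enc_W],
            biases=[b.copy() for b in enc_b],
            activations=[self.activation] * len(enc_W),
            role="autoencoder",
        )
        return self

    def _fit_layer(self, X, dim, rng):
        n, p = X.shape
        W1 = init_truncated_normal((p, dim), self.init_std, rng)
        b1 = np.zeros(dim)
        W2 = init_truncated_normal((dim, p), self.init_std, rng)
        b2 = np.zeros(p)
        weights, biases = [W1, W2], [b1, b2]
        acts = [self.activation, "linear"]
        flat = weights + biases
        opt = _make_optimizer(self.optimizer, [a.shape for a in flat], self.learning_rate)
        trace = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx]
                hs, zs, masks = _net_pass(weights, biases, acts, xb,
                                          dropout=self.dropout,
                                          drop_hidden=[True, False], rng=rng)
                xhat = hs[-1]
                resid = xhat - xb
                mse = float((resid ** 2).mean())
                loss = mse + self.l2 * sum(float((W ** 2).sum()) for W in weights)
                if not np.isfinite(loss):
                    raise TrainingError(
                        f"non-finite autoencoder loss at epoch {epoch}; "
                        "check standardisation and learning rate"
                    )
                delta = 2.0 * resid / resid.size
                gW, gb = _backprop(weights, biases, acts, hs, zs, masks, delta, self.l2)
                opt.step(flat, gW + gb)
                epoch_loss += loss
                n_batches += 1
            trace.append(epoch_loss / max(n_batches, 1))
        return W1, b1, W2, b2, trace

    def transform(self, X):
        h = np.asarray(X, dtype=float)
        for W, b in zip(self.encoder_weights_, self.encoder_biases_):
            h = _act(h @ W + b, self.activation)
        return h

    def inverse_transform(self, codes):
        h = np.asarray(codes, dtype=float)
        for i in range(len(self.decoder_weights_) - 1, -1, -1):
            h = h @ self.decoder_weights_[i] + self.decoder_biases_[i]
        return h

    def reconstruct(self, X):
        return self.inverse_transform(self.transform(X))

    def reconstruction_mse(self, X) -> float:
        X = np.asarray(X, dtype=float)
        return float(((self.reconstruct(X) - X) ** 2).mean())


def train_autoencoder(X: np.ndarray, cfg: TrainingConfig) -> tuple[NetworkParams, list]:
    """Fit an :class:`Autoencoder` from a config; returns encoder params + trace."""
    ae = Autoencoder(
        hidden_dims=cfg.hidden_dims, activation=cfg.activation, l2=cfg.l2,
        dropout=cfg.dropout, batch_size=cfg.batch_size, optimizer=cfg.optimizer,
        learning_rate=cfg.learning_rate, init_std=cfg.init_std,
        max_epochs=cfg.ae_epochs, seed=cfg.seed,
    ).fit(X)
    return ae.params_, ae.trace_


def transfer_weights(ae: "Autoencoder | NetworkParams", cfg: TrainingConfig,
                     seed: int | None = None) -> NetworkParams:
    """Initialise a classifier from a trained autoencoder's encoder.

    Hidden layers are exact copies of the encoder; the decoder is
    discarded; a fresh single-unit sigmoid output layer is drawn from the
    truncated normal under ``seed`` (default: ``cfg.seed``).
    """
    enc = ae.params_ if isinstance(ae, Autoencoder) else ae
    if enc.role != "autoencoder":
        raise DataError("transfer_weights expects autoencoder params")
    dims = enc.layer_dims
    if tuple(dims[1:]) != tuple(cfg.hidden_dims):
        raise DataError(
            f"architecture mismatch: encoder dims {dims[1:]} vs config {list(cfg.hidden_dims)}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    W_out = init_truncated_normal((dims[-1], 1), cfg.init_std, rng)
    return NetworkParams(
        weights=[W.copy() for W in enc.weights] + [W_out],
        biases=[b.copy() for b in enc.biases] + [np.zeros(1)],
        activations=list(enc.activations) + ["sigmoid"],
        role="classifier",
    )


# --------------------------------------------------------------------------
# classifier

class DrugLikenessClassifier(BaseEstimator, ClassifierMixin):
    """Fully connected binary classifier with the weighted cross-entropy loss.

    Hidden layers may be freshly initialised (truncated normal) or
    transferred from a pre-trained autoencoder via ``init_params``.
    Training uses mini-batch Adam/SGD on the batch-mean weighted BCE plus
    L2 decay, inverted dropout on hidden activations, and — when an
    ``eval_set`` is supplied to :meth:`fit` — early stopping on held-out
    accuracy with restoration of the best snapshot.

    Parameters mirror :class:`TrainingConfig`; ``pos_weight`` is the
    weight ``w`` on the positive-sample loss.
    """

    def __init__(self, hidden_dims=(512,), activation="relu", l2=1e-4,
                 dropout=0.14, batch_size=128, optimizer="adam",
                 learning_rate=1e-3, init_std=0.05, max_epochs=100,
                 early_stop_patience=10, pos_weight=0.5, threshold=0.5,
                 seed=0, init_params=None):
        self.hidden_dims = hidden_dims
        self.activation = activation
        self.l2 = l2
        self.dropout = dropout
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.init_std = init_std
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.pos_weight = pos_weight
        self.threshold = threshold
        self.seed = seed
        self.init_params = init_params

    @classmethod
    def from_config(cls, cfg: TrainingConfig, init_params=None, **overrides):
        kw = dict(
            hidden_dims=cfg.hidden_dims, activation=cfg.activation, l2=cfg.l2,
            dropout=cfg.dropout, batch_size=cfg.batch_size, optimizer=cfg.optimizer,
            learning_rate=cfg.learning_rate, init_std=cfg.init_std,
            max_epochs=cfg.max_epochs, early_stop_patience=cfg.early_stop_patience,
            pos_weight=cfg.pos_weight, threshold=cfg.threshold, seed=cfg.seed,
            init_params=init_params,
        )
        kw.update(overrides)
        return cls(**kw)

    # -- initialisation ----------------------------------------------------
    def _init_params(self, n_features: int) -> NetworkParams:
        if self.init_params is not None:
            params = self.init_params.copy()
            if params.role != "classifier":
                raise DataError("init_params must be classifier params (use transfer_weights)")
            if params.weights[0].shape[0] != n_features:
                raise DataError("init_params input dimension does not match the data")
            return params
        rng = np.random.default_rng(self.seed)
        dims = [n_features] + [int(d) for d in self.hidden_dims] + [1]
        weights = [init_truncated_normal((dims[i], dims[i + 1]), self.init_std, rng)
                   for i in range(len(dims) - 1)]
        biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        acts = [self.activation] * len(self.hidden_dims) + ["sigmoid"]
        return NetworkParams(weights, biases, acts, "classifier")

    # -- loss / gradients --------------------------------------------------
    def loss_and_grads(self, X, y, params: NetworkParams | None = None,
                       reduction: str = "sum"):
        """Weighted BCE + L2 loss and its analytic parameter gradients.

        Dropout is disabled (deterministic).  Used by training (with
        ``reduction="mean"``) and by finite-difference verification.
        """
        params = params if params is not None else self.params_
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        w = self.pos_weight
        hs, zs, masks = _net_pass(params.weights, params.biases, params.activations, X)
        a = hs[-1]
        loss = weighted_bce(y, a, w, reduction=reduction)
        loss += self.l2 * sum(float((W ** 2).sum()) for W in params.weights)
        a_c = np.clip(a, EPS, 1 - EPS)
        delta = (1 - w) * (1 - y) * a_c - w * y * (1 - a_c)
        if reduction == "mean":
            delta = delta / len(y)
        gW, gb = _backprop(params.weights, params.biases, params.activations,
                           hs, zs, masks, delta, self.l2)
        return loss, gW, gb

    # -- training ----------------------------------------------------------
    def fit(self, X, y, eval_set: tuple | None = None):
        if not (0 < self.pos_weight < 1):
            raise DataError("pos_weight must be in (0, 1)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != len(y):
            raise DataError("X and y lengths differ")
        if not np.isfinite(X).all():
            raise DataError("classifier input must be finite (standardise first)")
        params = self._init_params(X.shape[1])
        rng = np.random.default_rng(None if self.seed is None else self.seed + 1)
        flat = params.weights + params.biases
        opt = _make_optimizer(self.optimizer, [a.shape for a in flat], self.learning_rate)

        y_col = y.reshape(-1, 1)
        w = self.pos_weight
        n = len(y)
        best = params.copy()
        best_acc, since_best = -np.inf, 0
        train_trace, eval_trace = [], []

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y_col[idx]
                hs, zs, masks = _net_pass(params.weights, params.biases,
                                          params.activations, xb,
                                          dropout=self.dropout, rng=rng)
                a = np.clip(hs[-1], EPS, 1 - EPS)
                loss = weighted_bce(yb, a, w, reduction="mean")
                loss += self.l2 * sum(float((W ** 2).sum()) for W in params.weights)
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite classifier loss at epoch {epoch}")
                delta = ((1 - w) * (1 - yb) * a - w * yb * (1 - a)) / len(yb)
                gW, gb = _backprop(params.weights, params.biases, params.activations,
                                   hs, zs, masks, delta, self.l2)
                opt.step(flat, gW + gb)
                epoch_loss += loss
                n_batches += 1
            train_trace.append(epoch_loss / max(n_batches, 1))

            if eval_set is not None:
                Xe, ye = eval_set
                pe = forward(params, np.asarray(Xe, dtype=float)).ravel()
                acc = float(((pe >= self.threshold).astype(int)
                             == np.asarray(ye).astype(int)).mean())
                eval_trace.append(acc)
                if acc > best_acc:
                    best_acc, since_best = acc, 0
                    best = params.copy()
                else:
                    since_best += 1
                    if since_best >= self.early_stop_patience:
                        break

        self.params_ = best if eval_set is not None else params
        self.trace_ = {"train_loss": train_trace, "eval_acc": eval_trace}
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X):
        p = forward(self.params_, np.asarray(X, dtype=float)).ravel()
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)


def predict(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Per-row probability of the positive class (deterministic pass)."""
    if params.role != "classifier":
        raise DataError("predict expects classifier params")
    return forward(params, X).ravel()
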