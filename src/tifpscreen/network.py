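"""Feedforward binary classifier over interaction fingerprints.

The network is a fully connected stack: input (211 features, or 212 when a
docking score is appended) -> hidden layers (default 500 x 1000, ReLU,
dropout 0.1) -> 2-unit softmax.  Training minimises softmax cross-entropy
with an L2 weight-decay penalty using Adam, and early-stops when the
validation PRC-AUC (average precision) has not improved for ``patience``
consecutive epochs (default window 15); the parameters of the best
validation epoch are kept.

The network and optimiser are implemented directly in NumPy, which keeps
the fitted state a plain list of arrays and training bit-reproducible from
a single seed (initialisation, shuffling and dropout all derive from it).

:class:`MLPScreenClassifier` exposes the model in scikit-learn estimator
form; :func:`init_model`, :func:`train` and :func:`predict_proba` are the
functional equivalents.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .metrics import confusion_counts, prc_auc, roc_auc

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "EarlyStopping",
    "init_model",
    "train",
    "predict_proba",
    "classify",
    "MLPScreenClassifier",
]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
}


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    Defaults are the selected operating point: two hidden layers of 500 and
    1000 units, ReLU, dropout 0.1, Adam with learning rate 0.001 and weight
    decay 0.0001, early-stopping window 15 on validation PRC-AUC.
    """

    input_dim: int = 211
    hidden_sizes: tuple[int, ...] = (500, 1000)
    dropout: float = 0.1
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    activation: str = "relu"
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must all be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_sizes, 2]
        return list(zip(dims[:-1], dims[1:]))

    @property
    def n_parameters(self) -> int:
        return sum(fi * fo + fo for fi, fo in self.layer_dims)


class _FeedForward:
    """Plain-NumPy MLP with softmax head and Adam optimiser state."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: list[tuple[np.ndarray, np.ndarray]] = []
        for fan_in, fan_out in config.layer_dims:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            self.params.append((w, b))
        self._adam_m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in self.params]
        self._adam_v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in self.params]
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Returns (probabilities, cache); dropout active iff rng given."""
        act, _dact = _ACTIVATIONS[self.config.activation]
        p = self.config.dropout
        cache = {"h": [x], "z": [], "mask": []}
        h = x
        n_layers = len(self.params)
        for li, (w, b) in enumerate(self.params):
            z = h @ w + b
            cache["z"].append(z)
            if li < n_layers - 1:
                h = act(z)
                if rng is not None and p > 0:
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * mask
                else:
                    mask = None
                cache["mask"].append(mask)
                cache["h"].append(h)
        logits = cache["z"][-1]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        proba = e / e.sum(axis=1, keepdims=True)
        cache["proba"] = proba
        return proba, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        _act, dact = _ACTIVATIONS[self.config.activation]
        wd = self.config.weight_decay
        n = x.shape[0]
        proba, cache = self.forward(x, rng=rng)
        onehot = np.zeros_like(proba)
        onehot[np.arange(n), y] = 1.0
        loss = float(-np.mean(np.log(np.clip(proba[np.arange(n), y], 1e-12, None))))
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.params)
        delta = (proba - onehot) / n
        for li in range(len(self.params) - 1, -1, -1):
            h_in = cache["h"][li]
            gw = h_in.T @ delta + wd * self.params[li][0]
            gb = delta.sum(axis=0)
            grads[li] = (gw, gb)
            if li > 0:
                delta = delta @ self.params[li][0].T
                mask = cache["mask"][li - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * dact(cache["z"][li - 1])
        return loss, grads

    def adam_step(self, grads, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        lr = self.config.learning_rate
        t = self._adam_t
        new_params = []
        for li, ((w, b), (gw, gb)) in enumerate(zip(self.params, grads)):
            mw, mb = self._adam_m[li]
            vw, vb = self._adam_v[li]
            mw = beta1 * mw + (1 - beta1) * gw
            mb = beta1 * mb + (1 - beta1) * gb
            vw = beta2 * vw + (1 - beta2) * gw**2
            vb = beta2 * vb + (1 - beta2) * gb**2
            self._adam_m[li] = (mw, mb)
            self._adam_v[li] = (vw, vb)
            mw_hat, mb_hat = mw / (1 - beta1**t), mb / (1 - beta1**t)
            vw_hat, vb_hat = vw / (1 - beta2**t), vb / (1 - beta2**t)
            new_params.append(
                (w - lr * mw_hat / (np.sqrt(vw_hat) + eps),
                 b - lr * mb_hat / (np.sqrt(vb_hat) + eps))
            )
        self.params = new_params

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input has {x.shape[1] if x.ndim == 2 else '?'} features, "
                f"model expects {self.config.input_dim}"
            )
        proba, _ = self.forward(x, rng=None)
        return proba


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without strict improvement."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_value = -np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record one epoch's validation metric; returns True to stop."""
        if value > self.best_value:
            self.best_value = value
            self.best_epoch = epoch
            self.epochs_since_best = 0
        else:
            self.epochs_since_best += 1
        return self.epochs_since_best >= self.patience


@dataclass
class TrainedModel:
    """Fitted classifier state: best-epoch parameters plus provenance."""

    config: ModelConfig
    parameters: list[tuple[np.ndarray, np.ndarray]]
    best_epoch: int
    stopped_epoch: int
    history: pd.DataFrame

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        net = _FeedForward(self.config)
        net.params = self.parameters
        return net.predict_proba(np.asarray(x, dtype=float))


def init_model(config: ModelConfig) -> _FeedForward:
    """Deterministically initialised network (He-scaled normal weights)."""
    return _FeedForward(config)


def _safe_threshold_metrics(proba_pos: np.ndarray, y: np.ndarray, threshold: float = 0.5):
    preds = (proba_pos >= threshold).astype(int)
    c = confusion_counts(y, preds)
    rec = c.n_tp / (c.n_tp + c.n_fn) if (c.n_tp + c.n_fn) else float("nan")
    prec = c.n_tp / (c.n_tp + c.n_fp) if (c.n_tp + c.n_fp) else float("nan")
    return rec, prec


def train(
    model: _FeedForward,
    train_set: tuple[np.ndarray, np.ndarray],
    valid_set: tuple[np.ndarray, np.ndarray],
    config: Optional[ModelConfig] = None,
    valid_scorer: Optional[Callable[[int, _FeedForward], float]] = None,
) -> TrainedModel:
    """Adam / cross-entropy training with early stopping.

    After each epoch the validation PRC-AUC (or the injected
    ``valid_scorer(epoch, net)``) is evaluated; training stops when it has
    not strictly improved on the running best for ``patience`` consecutive
    epochs, and the parameters of the best epoch are returned.  Epochs are
    numbered from 1.
    """
    config = config or model.config
    x_tr, y_tr = (np.asarray(train_set[0], float), np.asarray(train_set[1], int))
    x_va, y_va = (np.asarray(valid_set[0], float), np.asarray(valid_set[1], int))
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    if valid_scorer is None and len(np.unique(y_va)) < 2:
        raise ValueError("validation set must contain both classes for PRC-AUC")

    shuffle_rng = np.random.default_rng([config.seed, 1])
    stopper = EarlyStopping(config.patience)
    best_params = copy.deepcopy(model.params)
    rows = []
    stopped_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(x_tr[idx], y_tr[idx], shuffle_rng)
            model.adam_step(grads)
            losses.append(loss)
        p_tr = model.predict_proba(x_tr)[:, 1]
        p_va = model.predict_proba(x_va)[:, 1]
        if valid_scorer is None:
            val_metric = prc_auc(p_va, y_va)
        else:
            val_metric = float(valid_scorer(epoch, model))
        tr_rec, tr_prec = _safe_threshold_metrics(p_tr, y_tr)
        va_rec, va_prec = _safe_threshold_metrics(p_va, y_va)
        rows.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "train_recall": tr_rec,
            "train_precision": tr_prec,
            "train_roc_auc": roc_auc(p_tr, y_tr) if len(np.unique(y_tr)) == 2 else float("nan"),
            "train_prc_auc": prc_auc(p_tr, y_tr) if y_tr.sum() else float("nan"),
            "valid_recall": va_rec,
            "valid_precision": va_prec,
            "valid_roc_auc": roc_auc(p_va, y_va) if len(np.unique(y_va)) == 2 else float("nan"),
            "valid_prc_auc": prc_auc(p_va, y_va) if y_va.sum() else float("nan"),
            "valid_metric": val_metric,
        })
        improved = val_metric > stopper.best_value
        stop = stopper.update(val_metric, epoch)
        if improved:
            best_params = copy.deepcopy(model.params)
        stopped_epoch = epoch
        if stop:
            break
    history = pd.DataFrame(rows)
    return TrainedModel(
        config=config,
        parameters=best_params,
        best_epoch=stopper.best_epoch,
        stopped_epoch=stopped_epoch,
        history=history,
    )


def predict_proba(model: TrainedModel | _FeedForward, fps: np.ndarray) -> np.ndarray:
    """Positive-class probability per sample (dropout off, deterministic)."""
    return model.predict_proba(np.asarray(fps, dtype=float))[:, 1]


def classify(p: float, threshold: float = 0.5) -> str:
    """Decision rule: positive iff the positive-class probability >= threshold."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability must be in [0, 1]")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return "positive" if p >= threshold else "negative"


class MLPScreenClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator facade over the NumPy feedforward classifier.

    ``fit(X, y, X_valid=, y_valid=)`` trains with early stopping on the
    validation PRC-AUC; without an explicit validation set the training set
    doubles as the stopping monitor (fine for toy fits, not for model
    selection).

    Fitted attributes: ``model_`` (the :class:`TrainedModel`), ``history_``,
    ``best_epoch_``, ``stopped_epoch_``, ``classes_``, ``n_features_in_``,
    ``n_parameters_``.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (500, 1000),
        dropout: float = 0.1,
        learning_rate: float = 0.001,
        weight_decay: float = 0.0001,
        activation: str = "relu",
        batch_size: int = 64,
        max_epochs: int = 200,
        patience: int = 15,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.activation = activation
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.threshold = threshold
        self.random_state = random_state

    def _config(self, n_features: int) -> ModelConfig:
        return ModelConfig(
            input_dim=n_features,
            hidden_sizes=tuple(self.hidden_sizes),
            dropout=self.dropout,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            activation=self.activation,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y, X_valid=None, y_valid=None, valid_scorer=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if not np.all(np.isin(np.unique(y), [0, 1])):
            raise ValueError("y must be binary 0/1")
        if X_valid is None:
            X_valid, y_valid = X, y
        config = self._config(X.shape[1])
        net = init_model(config)
        self.model_ = train(net, (X, y), (np.asarray(X_valid, float), np.asarray(y_valid, int)),
                            config, valid_scorer=valid_scorer)
        self.history_ = self.model_.history
        self.best_epoch_ = self.model_.best_epoch
        self.stopped_epoch_ = self.model_.stopped_epoch
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.n_parameters_ = config.n_parameters
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("MLPScreenClassifier is not fitted yet")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)
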