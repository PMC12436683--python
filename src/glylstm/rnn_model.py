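"""The stacked-LSTM glycation classifier and its training protocol.

Architecture: LSTM(64, tanh, L2 kernel penalty) -> dropout -> LSTM(32, same
configuration) -> dropout -> Dense(16, ReLU) -> dropout -> Dense(2, softmax).
Training minimizes sparse categorical cross-entropy with Adam at batch size
64, stopping early when validation accuracy has not improved for ``patience``
epochs (default 20) and restoring the best-epoch weights (earliest on ties).

Exposed both as functions (:func:`build_model`, :func:`train`,
:func:`predict_proba`, :func:`classify`) and as the scikit-learn estimator
:class:`LSTMClassifier`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._network import Adam, LSTMNetwork
from .encoder import EncodedExample
from .peptide_io import WINDOW_LENGTH

ArrayLike = Union[np.ndarray, Sequence[EncodedExample]]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier and its training loop."""

    input_width: int = 2
    lstm1_units: int = 64
    lstm2_units: int = 32
    dense_units: int = 16
    dropout1: float = 0.2
    dropout2: float = 0.2
    dropout3: float = 0.2
    l2: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    allow_any_width: bool = False

    def __post_init__(self) -> None:
        if self.input_width not in (2, 8) and not self.allow_any_width:
            raise ValueError(
                f"input_width must be 2 or 8 (got {self.input_width}); "
                f"set allow_any_width=True to experiment with other widths"
            )
        for name in ("lstm1_units", "lstm2_units", "dense_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("dropout1", "dropout2", "dropout3"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {rate}")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: Dict) -> "ModelConfig":
        return ModelConfig(**d)


@dataclass
class TrainingHistory:
    """Per-epoch loss/accuracy traces and the selected best epoch."""

    train_loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.val_accuracy)


@dataclass
class TrainedModel:
    """A fitted network together with its config and training history."""

    network: LSTMNetwork
    config: ModelConfig
    history: TrainingHistory


def build_model(config: ModelConfig) -> LSTMNetwork:
    """Instantiate the untrained network; initialization is seeded."""
    return LSTMNetwork(
        input_width=config.input_width,
        units1=config.lstm1_units,
        units2=config.lstm2_units,
        dense_units=config.dense_units,
        dropout_rates=(config.dropout1, config.dropout2, config.dropout3),
        l2=config.l2,
        seed=config.seed,
    )


def _as_arrays(examples: ArrayLike,
               labels: Optional[np.ndarray] = None) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    if isinstance(examples, np.ndarray):
        return examples, labels
    mats = np.stack([ex.matrix for ex in examples]).astype(np.float32)
    labs = [ex.label for ex in examples]
    y = None if any(l is None for l in labs) else np.array(labs, dtype=np.int64)
    return mats, y


def _eval_loss_acc(net: LSTMNetwork, X: np.ndarray, y: np.ndarray,
                   batch: int = 1024) -> Tuple[float, float]:
    losses = []
    correct = 0
    eps = 1e-12
    for start in range(0, len(X), batch):
        xb = X[start:start + batch]
        yb = y[start:start + batch]
        probs = net.forward(xb, training=False)
        losses.append(-np.log(probs[np.arange(len(yb)), yb] + eps))
        correct += int(np.sum(probs.argmax(axis=1) == yb))
    return float(np.mean(np.concatenate(losses))), correct / len(y)


def train(model: LSTMNetwork, train_examples: ArrayLike, val_examples: ArrayLike,
          config: ModelConfig, train_labels: Optional[np.ndarray] = None,
          val_labels: Optional[np.ndarray] = None) -> TrainedModel:
    """Fit with Adam + early stopping on validation accuracy.

    Accepts lists of :class:`EncodedExample` or ``(n, 31, k)`` arrays with
    separate label vectors.  Weights are restored to the best epoch
    (earliest on ties).  Fully deterministic given ``config.seed``.
    """
    Xtr, ytr = _as_arrays(train_examples, train_labels)
    Xval, yval = _as_arrays(val_examples, val_labels)
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if ytr is None or yval is None:
        raise ValueError("all training/validation examples must carry labels")
    for name, X in (("training", Xtr), ("validation", Xval)):
        if X.shape[2] != config.input_width:
            raise ValueError(
                f"{name} input width {X.shape[2]} does not match "
                f"config.input_width={config.input_width}"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = Adam(model.params, learning_rate=config.learning_rate)
    history = TrainingHistory()
    best_acc = -1.0
    best_weights = model.get_weights()
    n = len(Xtr)
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        ep_losses = []
        ep_correct = 0
        for start in range(0, n, config.batch_size):
            sel = perm[start:start + config.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            loss, grads = model.loss_and_grads(xb, yb, rng=rng)
            opt.step(model.params, grads)
            ep_losses.append(loss)
            # training accuracy from the dropout forward pass (pre-update)
            ep_correct += model._last_batch_correct
        vloss, vacc = _eval_loss_acc(model, Xval, yval)
        history.train_loss.append(float(np.mean(ep_losses)))
        history.train_accuracy.append(ep_correct / n)
        history.val_loss.append(vloss)
        history.val_accuracy.append(vacc)
        if vacc > best_acc:
            best_acc = vacc
            history.best_epoch = epoch
            best_weights = model.get_weights()
        elif epoch - history.best_epoch >= config.patience:
            break
    model.set_weights(best_weights)
    return TrainedModel(network=model, config=config, history=history)


def predict_proba(trained: TrainedModel, examples: ArrayLike) -> np.ndarray:
    """``(n, 2)`` array of ``(p_glycated, p_nonglycated)`` pairs.

    Dropout is disabled; pairs are renormalized in float64 so each sums to 1
    within 1e-6.
    """
    X, _ = _as_arrays(examples)
    if X.shape[2] != trained.config.input_width:
        raise ValueError(
            f"input width {X.shape[2]} does not match the trained model "
            f"(expected {trained.config.input_width})"
        )
    probs = trained.network.forward(X, training=False).astype(np.float64)
    probs /= probs.sum(axis=1, keepdims=True)
    # network class order is (nonglycated=0, glycated=1); report (p1, p0)
    return probs[:, [1, 0]]


def classify(probability_pairs: np.ndarray) -> np.ndarray:
    """Label 1 iff p_glycated > p_nonglycated; exact ties resolve to 0."""
    pairs = np.asarray(probability_pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of pairs, got shape {pairs.shape}")
    sums = pairs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"probability pair {bad} sums to {sums[bad]}, expected 1")
    return (pairs[:, 0] > pairs[:, 1]).astype(np.int64)


def save_model(trained: TrainedModel, path, extra_sidecar: Optional[Dict] = None) -> None:
    """Save weights (``.npz``) plus a JSON sidecar with the config.

    ``extra_sidecar`` may carry the scale statistics and case spec so a saved
    model is self-describing for prediction mode.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(path, **trained.network.params)
    sidecar = {
        "config": trained.config.to_dict(),
        "best_epoch": trained.history.best_epoch,
        "epochs_trained": len(trained.history),
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_model(path) -> Tuple[TrainedModel, Dict]:
    """Load a model saved by :func:`save_model`; returns (model, sidecar)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"model sidecar {sidecar_path} is missing; cannot reconstruct the config"
        )
    with open(sidecar_path, "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    config = ModelConfig.from_dict(sidecar["config"])
    net = build_model(config)
    with np.load(path) as data:
        net.set_weights({k: data[k] for k in data.files})
    history = TrainingHistory(best_epoch=sidecar.get("best_epoch", 0))
    return TrainedModel(network=net, config=config, history=history), sidecar


class LSTMClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator around the stacked-LSTM classifier.

    ``fit`` expects ``X`` of shape ``(n, 31, k)`` (k = 2 or 8) and binary
    labels.  A stratified ``validation_fraction`` is carved from the training
    data for early stopping unless ``validation_data=(Xval, yval)`` is
    passed to ``fit``.

    Fitted attributes: ``model_`` (the :class:`TrainedModel`), ``history_``,
    ``classes_``, ``config_``.
    """

    def __init__(self, lstm1_units: int = 64, lstm2_units: int = 32,
                 dense_units: int = 16, dropout1: float = 0.2,
                 dropout2: float = 0.2, dropout3: float = 0.2,
                 l2: float = 0.01, learning_rate: float = 1e-3,
                 batch_size: int = 64, max_epochs: int = 200,
                 patience: int = 20, validation_fraction: float = 0.15,
                 seed: int = 0):
        self.lstm1_units = lstm1_units
        self.lstm2_units = lstm2_units
        self.dense_units = dense_units
        self.dropout1 = dropout1
        self.dropout2 = dropout2
        self.dropout3 = dropout3
        self.l2 = l2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _config(self, width: int) -> ModelConfig:
        return ModelConfig(
            input_width=width, lstm1_units=self.lstm1_units,
            lstm2_units=self.lstm2_units, dense_units=self.dense_units,
            dropout1=self.dropout1, dropout2=self.dropout2,
            dropout3=self.dropout3, l2=self.l2,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, seed=self.seed,
        )

    def fit(self, X, y, validation_data: Optional[Tuple[np.ndarray, np.ndarray]] = None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or X.shape[1] != WINDOW_LENGTH:
            raise ValueError(
                f"X must have shape (n, {WINDOW_LENGTH}, k), got {X.shape}"
            )
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")
        config = self._config(X.shape[2])
        if validation_data is not None:
            Xtr, ytr = X, y
            Xval, yval = validation_data
            Xval = np.asarray(Xval, dtype=np.float32)
            yval = np.asarray(yval, dtype=np.int64)
        else:
            Xtr, Xval, ytr, yval = train_test_split(
                X, y, test_size=self.validation_fraction, stratify=y,
                random_state=self.seed % (2 ** 32),
            )
        net = build_model(config)
        self.model_ = train(net, Xtr, Xval, config,
                            train_labels=ytr, val_labels=yval)
        self.history_ = self.model_.history
        self.config_ = config
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Probabilities in sklearn class order: column 0 = nonglycated."""
        pairs = predict_proba(self.model_, np.asarray(X, dtype=np.float32))
        return pairs[:, [1, 0]]

    def predict(self, X) -> np.ndarray:
        pairs = predict_proba(self.model_, np.asarray(X, dtype=np.float32))
        return classify(pairs)
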