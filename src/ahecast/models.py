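"""Model specifications, the training loop, and mean-feature baselines.

Two recurrent classifiers are provided: a stacked LSTM trained with Adam
under a cosine-annealing warm-restart schedule, L2 of 1e-3 on all
parameters and dropout 0.4 before the dense head; and a single-layer gated
unit with trainable decay (100 units, dropout 0.3, fixed learning rate
1e-4) that consumes the unfilled windows directly. Both minimize binary
cross-entropy and keep the parameters achieving the best validation loss.

The comparative baselines mirror standard critical-care practice: a
logistic regression on the window-mean MAP (raw units, for coefficient
interpretability) and an RBF support-vector machine on the three
channel means (standardized on training statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn import (
    Adam,
    GRUDClassifier,
    LSTMClassifier,
    binary_cross_entropy,
    constant_schedule,
    cosine_warm_restarts,
)
from .windowing import OBS_LENGTHS, WindowDataset


@dataclass
class LSTMSpec:
    layers: int = 2
    units_per_layer: int = 60
    dropout_before_dense: float = 0.4
    l2_penalty: float = 1e-3
    base_lr: float = 3e-3
    restart_period: int = 10


@dataclass
class DecayGRUSpec:
    layers: int = 1
    units: int = 100
    dropout: float = 0.3
    learning_rate: float = 1e-4
    l2_penalty: float = 1e-3


@dataclass
class TrainSpec:
    """Optimization settings shared by both deep families."""

    epochs: int = 100
    batch_size: int = 64
    seed: int = 0
    l2_penalty: float = 1e-3
    lr_schedule: Callable[[int], float] | None = None
    #: Null-calibration experiments: permute training AND validation labels
    #: so the whole procedure (including model selection) is label-blind.
    shuffle_labels: bool = False


@dataclass
class TrainLog:
    epochs: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "lr": self.lr,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


def build_lstm(
    spec: LSTMSpec | None = None, timesteps: int = 60, seed: int = 0
) -> LSTMClassifier:
    """Untrained stacked LSTM for windows of ``timesteps`` minutes."""
    spec = spec or LSTMSpec()
    if timesteps not in OBS_LENGTHS:
        raise ValueError(f"timesteps={timesteps} not in studied grid {OBS_LENGTHS}")
    return LSTMClassifier(
        timesteps=timesteps,
        units=(spec.units_per_layer,) * spec.layers,
        dropout=spec.dropout_before_dense,
        seed=seed,
    )


def build_decay_gru(
    spec: DecayGRUSpec | None = None, timesteps: int = 60, seed: int = 0
) -> GRUDClassifier:
    """Untrained decay-GRU for windows of ``timesteps`` minutes."""
    spec = spec or DecayGRUSpec()
    if timesteps not in OBS_LENGTHS:
        raise ValueError(f"timesteps={timesteps} not in studied grid {OBS_LENGTHS}")
    return GRUDClassifier(
        timesteps=timesteps, units=spec.units, dropout=spec.dropout, seed=seed
    )


def _default_schedule(model) -> Callable[[int], float]:
    if isinstance(model, GRUDClassifier):
        return constant_schedule(DecayGRUSpec().learning_rate)
    spec = LSTMSpec()
    return cosine_warm_restarts(spec.base_lr, period=spec.restart_period)


def _model_inputs(model, dataset: WindowDataset):
    return model.inputs_from(dataset)


def _slice_inputs(inputs, idx):
    if isinstance(inputs, tuple):
        return tuple(a[idx] for a in inputs)
    return inputs[idx]


def fit(
    model,
    train: WindowDataset,
    val: WindowDataset,
    spec: TrainSpec | None = None,
):
    """Train ``model`` on ``train``, select on ``val``; returns (model, log).

    Raises on an empty or single-class training set. Fully reproducible
    given the spec seed (shuffling, dropout and any label shuffling all
    derive from it).
    """
    spec = spec or TrainSpec()
    if len(train) == 0 or len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(spec.seed)
    schedule = spec.lr_schedule or _default_schedule(model)

    if isinstance(model, GRUDClassifier):
        observed = train.mask.astype(bool)
        means = np.array(
            [
                train.X_raw[..., c][observed[..., c]].mean()
                if observed[..., c].any()
                else 0.5
                for c in range(train.X_raw.shape[-1])
            ]
        )
        model.set_feature_means(means)

    X_train = _model_inputs(model, train)
    y_train = train.y.astype(float)
    X_val = _model_inputs(model, val)
    y_val = val.y.astype(float)
    if spec.shuffle_labels:
        y_train = rng.permutation(y_train)
        y_val = rng.permutation(y_val)

    opt = Adam(model.params)
    log = TrainLog()
    best_params = model.get_params()
    n = len(train)
    for epoch in range(spec.epochs):
        lr = schedule(epoch)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb = _slice_inputs(X_train, idx)
            yb = y_train[idx]
            probs, cache = model.forward(xb, train=True, rng=rng)
            loss = binary_cross_entropy(probs, yb)
            grads = model.backward(cache, (probs - yb) / len(yb))
            if spec.l2_penalty > 0:
                for key, g in grads.items():
                    g += 2.0 * spec.l2_penalty * model.params[key]
            opt.step(model.params, grads, lr)
            epoch_losses.append(loss)
        val_probs = model.predict_proba(X_val)
        val_loss = binary_cross_entropy(val_probs, y_val)
        log.epochs.append(epoch)
        log.lr.append(lr)
        log.train_loss.append(float(np.mean(epoch_losses)))
        log.val_loss.append(val_loss)
        if val_loss < log.best_val_loss:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_params = model.get_params()
    model.set_params(best_params)
    return model, log


def predict_proba(model, data) -> np.ndarray:
    """Per-window probabilities, order-preserving and batch-size invariant."""
    if isinstance(data, WindowDataset):
        data = _model_inputs(model, data)
    return model.predict_proba(data)


def _window_mean_raw_map(dataset: WindowDataset) -> np.ndarray:
    """Mean MAP per window in raw mmHg (denormalized from the filled tensor)."""
    from .preprocessing import NormalizationRanges, denormalize

    raw = denormalize(dataset.X, NormalizationRanges())
    return raw[..., 0].mean(axis=1, keepdims=True)


def _window_mean_features(dataset: WindowDataset) -> np.ndarray:
    from .preprocessing import NormalizationRanges, denormalize

    raw = denormalize(dataset.X, NormalizationRanges())
    return raw.mean(axis=1)


def baseline_logreg(
    train: WindowDataset, test: WindowDataset, seed: int = 0
) -> tuple[np.ndarray, LogisticRegression]:
    """Single-feature (window-mean MAP) logistic model; test probabilities."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = LogisticRegression(random_state=seed)
    clf.fit(_window_mean_raw_map(train), train.y)
    probs = clf.predict_proba(_window_mean_raw_map(test))[:, 1]
    return probs, clf


def baseline_svm(
    train: WindowDataset, test: WindowDataset, seed: int = 0
) -> tuple[np.ndarray, SVC]:
    """Three-feature (channel means) RBF-SVM; test decision scores."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training set must contain both classes")
    scaler = StandardScaler().fit(_window_mean_features(train))
    clf = SVC(kernel="rbf", C=1.0, random_state=seed)
    clf.fit(scaler.transform(_window_mean_features(train)), train.y)
    scores = clf.decision_function(scaler.transform(_window_mean_features(test)))
    return scores, clf
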