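"""Feedforward DTI classifier and cross-validated ROC evaluation.

The classifier architecture: an input layer sized to the
feature vector, two ReLU hidden layers of 128 neurons, and a 2-neuron
softmax output giving the probabilities of a positive (P) and negative (N)
interaction, i.e. L_n = sigma_n(W_n L_{n-1} + b_n) per layer. Training is
mini-batch SGD on the cross-entropy loss with L2 weight decay (defaults:
learning rate 1e-4, batch 32, decay 1e-5, 30 epochs), with seeded He-uniform
initialization and seeded epoch shuffling so a repeated seed reproduces the
weights bit for bit. The gradient sums the per-sample cross-entropy over the
mini-batch (the classical SGD convention), which keeps the effective step
size of the default learning rate adequate at the thousands-of-instances
scale this package targets.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.utils.validation import check_is_fitted

from .dataset import InstanceMatrix
from .cv import FoldAssignment

logger = logging.getLogger(__name__)


@dataclass
class MLPConfig:
    """Architecture and training hyperparameters.

    ``layer_sizes`` runs input → hidden → output; (400, 128, 128, 2) is the
    standard operating point after feature selection, with the input width
    following the data everywhere else.
    """

    layer_sizes: tuple[int, ...] = (400, 128, 128, 2)
    learning_rate: float = 1e-4
    batch_size: int = 32
    weight_decay: float = 1e-5
    epochs: int = 30
    seed: int = 0
    standardize: bool = False

    def __post_init__(self):
        if len(self.layer_sizes) < 3 or self.layer_sizes[-1] != 2:
            raise ValueError("need >= 1 hidden layer and a 2-neuron output")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("rates, batch size and epochs must be positive")

    @classmethod
    def for_input(cls, n_features: int, **kwargs) -> "MLPConfig":
        return cls(layer_sizes=(n_features, 128, 128, 2), **kwargs)


class DivergenceError(RuntimeError):
    pass


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLPInteractionClassifier(ClassifierMixin, BaseEstimator):
    """Mini-batch SGD multilayer perceptron for binary DTI classification.

    Parameters mirror :class:`MLPConfig`; ``hidden_layer_sizes`` fixes the
    hidden widths while the input layer is sized from the training data.
    ``predict_proba`` returns columns ordered [N, P] following sklearn's
    ``classes_`` = [0, 1]; the decision score is the positive-class column.

    Attributes
    ----------
    weights_, biases_ : per-layer parameters (W_n, b_n)
    training_log_ : mean cross-entropy per epoch
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (128, 128),
        learning_rate: float = 1e-4,
        batch_size: int = 32,
        weight_decay: float = 1e-5,
        epochs: int = 30,
        random_state: int = 0,
        standardize: bool = False,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.random_state = random_state
        self.standardize = standardize

    # -- internals ---------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [X]
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            acts.append(np.maximum(acts[-1] @ W + b, 0.0))
        logits = acts[-1] @ self.weights_[-1] + self.biases_[-1]
        return acts, logits

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        n, d = X.shape

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(d)
            self.scale_ = np.ones(d)
        Xs = (X - self.mean_) / self.scale_

        sizes = (d, *self.hidden_layer_sizes, 2)
        rng = np.random.default_rng(self.random_state)
        self.weights_, self.biases_ = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / fan_in)
            self.weights_.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))

        Y = np.zeros((n, 2))
        Y[np.arange(n), y] = 1.0
        lr, wd = self.learning_rate, self.weight_decay

        self.training_log_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], Y[idx]
                acts, logits = self._forward(xb)
                probs = _softmax(logits)
                loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
                losses.append(loss)

                delta = probs - yb  # summed cross-entropy gradient over the batch
                for layer in range(len(self.weights_) - 1, -1, -1):
                    gW = acts[layer].T @ delta + wd * self.weights_[layer]
                    gb = delta.sum(axis=0)
                    if layer > 0:
                        delta = (delta @ self.weights_[layer].T) * (acts[layer] > 0)
                    self.weights_[layer] -= lr * gW
                    self.biases_[layer] -= lr * gb
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            self.training_log_.append(epoch_loss)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        if X.shape[1] != self.weights_[0].shape[0]:
            raise ValueError(
                f"expected {self.weights_[0].shape[0]} features, got {X.shape[1]}"
            )
        _, logits = self._forward((X - self.mean_) / self.scale_)
        probs = _softmax(logits)
        return probs[:, [0, 1]]  # columns follow classes_ = [0, 1]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class softmax probability (the P output neuron)."""
        return self.predict_proba(X)[:, 1]

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        check_is_fitted(self, "weights_")
        payload = {
            "params": self.get_params(),
            "weights": [W.tolist() for W in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "training_log": self.training_log_,
        }
        payload["params"]["hidden_layer_sizes"] = list(self.hidden_layer_sizes)
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "MLPInteractionClassifier":
        payload = json.loads(text)
        params = dict(payload["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        model.classes_ = np.array([0, 1])
        model.weights_ = [np.asarray(W) for W in payload["weights"]]
        model.biases_ = [np.asarray(b) for b in payload["biases"]]
        model.mean_ = np.asarray(payload["mean"])
        model.scale_ = np.asarray(payload["scale"])
        model.training_log_ = payload["training_log"]
        return model


def train_mlp(instances: InstanceMatrix, config: MLPConfig | None = None
              ) -> MLPInteractionClassifier:
    """Train the classifier on an instance matrix under a config."""
    if config is None:
        config = MLPConfig.for_input(instances.width)
    if config.layer_sizes[0] != instances.width:
        raise ValueError(
            f"config input width {config.layer_sizes[0]} != data width {instances.width}"
        )
    model = MLPInteractionClassifier(
        hidden_layer_sizes=tuple(config.layer_sizes[1:-1]),
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        weight_decay=config.weight_decay,
        epochs=config.epochs,
        random_state=config.seed,
        standardize=config.standardize,
    )
    return model.fit(instances.X, instances.y)


def mlp_forward(model: MLPInteractionClassifier, x: np.ndarray) -> tuple[float, float]:
    """Probability pair (P, N) for one feature vector."""
    probs = model.predict_proba(np.atleast_2d(np.asarray(x, dtype=float)))[0]
    return float(probs[1]), float(probs[0])


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve (TPR vs FPR over a threshold sweep) and trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes among the labels")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def cross_validate(
    instances: InstanceMatrix,
    folds: FoldAssignment,
    config: MLPConfig | None = None,
) -> pd.DataFrame:
    """Per-fold train/evaluate cycle scored by positive-class probability AUC.

    Folds whose evaluation half lacks a class are excluded from the summary
    (flagged in the table, warning logged). The summary mean and sd are in
    ``table.attrs["auc_mean"]`` / ``attrs["auc_sd"]``.
    """
    if config is None:
        config = MLPConfig.for_input(instances.width)
    rows = []
    for f, (train_idx, test_idx) in enumerate(folds.iter_splits(instances.meta)):
        test_y = instances.y[test_idx]
        if len(test_idx) == 0 or len(np.unique(test_y)) < 2:
            warnings.warn(f"fold {f}: single-class evaluation data, excluded")
            rows.append({"fold": f, "auc": np.nan, "n_test": len(test_idx)})
            continue
        model = train_mlp(instances.subset(train_idx), config)
        scores = model.decision_scores(instances.X[test_idx])
        rows.append({
            "fold": f,
            "auc": roc_auc(scores, test_y).auc,
            "n_test": len(test_idx),
        })
    table = pd.DataFrame(rows)
    valid = table["auc"].dropna()
    table.attrs["auc_mean"] = float(valid.mean()) if len(valid) else float("nan")
    table.attrs["auc_sd"] = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
    return table


def sweep_environment_size(
    datasets: dict[int, tuple[InstanceMatrix, FoldAssignment]],
    config: MLPConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated AUC per local-environment size N (600-dim drug+network
    inputs); the argmax N lands in ``table.attrs["best_n"]``."""
    rows = []
    for n_env in sorted(datasets):
        inst, folds = datasets[n_env]
        cfg = config if config is not None else MLPConfig.for_input(inst.width)
        if cfg.layer_sizes[0] != inst.width:
            raise ValueError(f"N={n_env}: input width {inst.width} != config"
                             f" {cfg.layer_sizes[0]}")
        table = cross_validate(inst, folds, cfg)
        rows.append({"N": n_env, "auc_mean": table.attrs["auc_mean"],
                     "auc_sd": table.attrs["auc_sd"]})
    out = pd.DataFrame(rows)
    out.attrs["best_n"] = int(out.loc[out["auc_mean"].idxmax(), "N"])
    return out
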