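"""Permutation feature importance and feature-count sweeps.

The importance of feature j is I_j = S_ori − S_perm,j: the drop in accuracy
on a held-out evaluation matrix after shuffling column j across instances
while leaving every other column and the labels untouched. Features are
ranked by descending importance and models are retrained on the top-k
features to trace classification performance and block composition against
the feature-vector length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.metrics import accuracy_score

from .dataset import BLOCKS, block_of_feature
from .mlp import MLPConfig, MLPInteractionClassifier, roc_auc, train_mlp


def _perm_rng(seed: int, j: int, repeat: int) -> np.random.Generator:
    # one generator per (seed, feature, repeat) so the naive and batched
    # paths shuffle identically
    return np.random.default_rng([seed, j, repeat])


def permutation_importance(
    model, X: np.ndarray, y: np.ndarray, j: int, seed: int = 0, repeats: int = 5,
) -> float:
    """I_j = accuracy(original) − mean accuracy over seeded shuffles of column j."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not (0 <= j < X.shape[1]):
        raise IndexError(f"feature index {j} out of range [0, {X.shape[1]})")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    s_ori = accuracy_score(y, model.predict(X))
    drops = []
    for r in range(repeats):
        perm = _perm_rng(seed, j, r).permutation(n)
        Xp = X.copy()
        Xp[:, j] = X[perm, j]
        drops.append(s_ori - accuracy_score(y, model.predict(Xp)))
    # mean of per-repeat drops: exactly 0 when the permutation is a no-op
    return float(np.mean(drops))


def all_importances(
    model: MLPInteractionClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    repeats: int = 5,
) -> np.ndarray:
    """Importances for every column, exploiting the network's layered form.

    Shuffling one input column changes the first hidden pre-activation by a
    rank-one update, so the forward pass is recomputed from the first hidden
    layer only. Produces exactly the same numbers as calling
    :func:`permutation_importance` per column with the same seed.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    Xs = (X - model.mean_) / model.scale_
    W0, b0 = model.weights_[0], model.biases_[0]
    Z0 = Xs @ W0 + b0

    def _predict_from_z0(z0):
        a = np.maximum(z0, 0.0)
        for W, b in zip(model.weights_[1:-1], model.biases_[1:-1]):
            a = np.maximum(a @ W + b, 0.0)
        logits = a @ model.weights_[-1] + model.biases_[-1]
        return (logits[:, 1] > logits[:, 0]).astype(int)

    s_ori = accuracy_score(y, _predict_from_z0(Z0))
    importances = np.empty(d)
    for j in range(d):
        col = Xs[:, j]
        drops = []
        for r in range(repeats):
            perm = _perm_rng(seed, j, r).permutation(n)
            delta = (col[perm] - col)[:, None] * W0[j][None, :]
            drops.append(s_ori - accuracy_score(y, _predict_from_z0(Z0 + delta)))
        importances[j] = np.mean(drops)
    return importances


def rank_features(importances: np.ndarray) -> pd.DataFrame:
    """Descending-importance ranking; ties break by ascending feature index."""
    importances = np.asarray(importances, dtype=float)
    if np.any(np.isnan(importances)):
        raise ValueError("importance vector contains missing scores")
    order = np.lexsort((np.arange(len(importances)), -importances))
    width = len(importances)
    blocks = BLOCKS if width == BLOCKS[-1][2] else (("all", 0, width),)
    return pd.DataFrame({
        "feature": order,
        "block": [block_of_feature(j, blocks) for j in order],
        "importance": importances[order],
    })


def sweep_feature_count(
    ranking: pd.DataFrame,
    train_X: np.ndarray,
    train_y: np.ndarray,
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    sizes,
    config: MLPConfig | None = None,
) -> pd.DataFrame:
    """Retrain on the top-k ranked features for each k; report AUC and the
    fraction of retained features contributed by each block."""
    sizes = sorted(set(int(s) for s in sizes))
    total = len(ranking)
    if not sizes:
        raise ValueError("empty size grid")
    if sizes[0] < 1 or sizes[-1] > total:
        raise ValueError(f"sizes must lie in [1, {total}]")
    block_names = [b[0] for b in (BLOCKS if train_X.shape[1] == BLOCKS[-1][2]
                                  else (("all", 0, train_X.shape[1]),))]
    rows = []
    for size in sizes:
        top = ranking.head(size)
        cols = top["feature"].to_numpy()
        cfg = config if config is not None else MLPConfig.for_input(size)
        if cfg.layer_sizes[0] != size:
            cfg = MLPConfig(layer_sizes=(size, *cfg.layer_sizes[1:-1], 2),
                            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                            weight_decay=cfg.weight_decay, epochs=cfg.epochs,
                            seed=cfg.seed, standardize=cfg.standardize)
        model = MLPInteractionClassifier(
            hidden_layer_sizes=tuple(cfg.layer_sizes[1:-1]),
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
            weight_decay=cfg.weight_decay, epochs=cfg.epochs,
            random_state=cfg.seed, standardize=cfg.standardize,
        ).fit(train_X[:, cols], train_y)
        auc_val = roc_auc(model.decision_scores(eval_X[:, cols]), eval_y).auc
        row = {"size": size, "auc": auc_val}
        counts = top["block"].value_counts()
        for name in block_names:
            row[f"frac_{name}"] = counts.get(name, 0) / size
        rows.append(row)
    return pd.DataFrame(rows)


class PermutationImportanceSelector(BaseEstimator):
    """Meta-estimator: rank features of a prefit model by permutation importance.

    ``fit(X, y)`` scores the held-out matrix (X, y); ``transform`` keeps the
    ``n_features`` most important columns.
    """

    def __init__(self, estimator=None, n_features: int = 400, repeats: int = 5,
                 random_state: int = 0):
        self.estimator = estimator
        self.n_features = n_features
        self.repeats = repeats
        self.random_state = random_state

    def fit(self, X, y):
        if self.estimator is None:
            raise ValueError("a prefit estimator is required")
        self.importances_ = all_importances(
            self.estimator, X, y, seed=self.random_state, repeats=self.repeats
        )
        self.ranking_ = rank_features(self.importances_)
        self.selected_ = self.ranking_.head(self.n_features)["feature"].to_numpy()
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.selected_]
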