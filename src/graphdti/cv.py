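"""Cross-validation fold construction for drug-target pairs.

Random-split folds deal pairs round-robin from a seeded permutation. The
cluster-based protocol groups pairs by one of three distances — FMD
(Euclidean over concatenated drug+protein features), PMD (combining 1−TC and
1−TM, range [0, √2]) or scaled PMD = PMD/(√2 − PMD) — with repeated seeded
k-medoids, selects the configuration by mean silhouette coefficient over
repetitions, and randomly merges clusters into folds so that similar pairs
never straddle a train/test boundary. Instances (expression signatures) of a
pair always inherit the pair's fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


class ClusteringError(ValueError):
    pass


def fmd(a: np.ndarray, b: np.ndarray) -> float:
    """Feature match distance: Euclidean over 600-dim drug+protein vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def pmd(tc: float, tm: float) -> float:
    """Perfect match distance sqrt((1−TC)² + (1−TM)²); 0 iff TC = TM = 1."""
    if not (0.0 <= tc <= 1.0) or not (0.0 <= tm <= 1.0):
        raise ValueError(f"similarities must lie in [0,1], got TC={tc}, TM={tm}")
    return math.hypot(1.0 - tc, 1.0 - tm)


#: values of PMD this close to the sqrt(2) pole are treated as at the pole
PMD_POLE_TOL = 1e-8


def scaled_pmd(p: float) -> float:
    """PMD/(√2 − PMD): strictly increasing, unbounded as PMD → √2.

    Values within :data:`PMD_POLE_TOL` of √2 are rejected as at the pole,
    where the denominator vanishes.
    """
    if not (0.0 <= p < SQRT2 - PMD_POLE_TOL):
        raise ValueError(f"scaled PMD requires 0 <= PMD < sqrt(2), got {p}")
    return p / (SQRT2 - p)


def pairwise_pmd_matrix(
    tc: np.ndarray, tm: np.ndarray, drug_idx: np.ndarray, prot_idx: np.ndarray,
    scaled: bool = False,
) -> np.ndarray:
    """Distance matrix over drug-target pairs from drug-TC and protein-TM matrices.

    ``drug_idx[i]`` / ``prot_idx[i]`` locate pair i's entities in the
    similarity matrices. With ``scaled=True`` applies the scaled-PMD
    transform elementwise (PMD values at the √2 pole are rejected).
    """
    dtc = np.asarray(tc)[np.ix_(drug_idx, drug_idx)]
    dtm = np.asarray(tm)[np.ix_(prot_idx, prot_idx)]
    D = np.hypot(1.0 - dtc, 1.0 - dtm)
    if scaled:
        if np.any(D >= SQRT2 - PMD_POLE_TOL):
            raise ValueError("PMD at the sqrt(2) pole; scaled PMD undefined")
        D = D / (SQRT2 - D)
    np.fill_diagonal(D, 0.0)
    return D


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ClusteringError("distance matrix must be symmetric")
    if np.any(D < 0) or np.any(np.diag(D) != 0):
        raise ClusteringError("distances must be nonnegative with zero diagonal")
    return D


class KMedoids(ClusterMixin, BaseEstimator):
    """Alternating (Voronoi-style) k-medoids on a precomputed distance matrix.

    Seeded random medoid initialization, then alternate point→nearest-medoid
    assignment and per-cluster medoid update until medoids stabilize or
    ``max_iter`` is reached. The within-cluster objective is nonincreasing
    across iterations (checked at runtime).

    Attributes
    ----------
    medoid_indices_ : ndarray of medoid row indices
    labels_ : cluster index per point
    inertia_ : final sum of distances to assigned medoids
    objective_history_ : objective after each iteration
    """

    def __init__(self, n_clusters: int = 8, max_iter: int = 300, random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        D = _check_distance_matrix(X)
        n = D.shape[0]
        k = self.n_clusters
        if not (1 <= k <= n):
            raise ClusteringError(f"need 1 <= k <= n, got k={k}, n={n}")
        rng = np.random.default_rng(self.random_state)
        medoids = np.sort(rng.choice(n, size=k, replace=False))

        history = []
        for it in range(self.max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            # keep empty clusters pinned to their medoid
            labels[medoids] = np.arange(k)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[c] = members[np.argmin(within)]
            obj = D[np.arange(n), new_medoids[np.argmin(D[:, new_medoids], axis=1)]].sum()
            if history and obj > history[-1] + 1e-9:
                raise AssertionError("k-medoids objective increased")
            history.append(float(obj))
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                medoids = new_medoids
                break
            medoids = new_medoids
        else:
            logger.info("k-medoids reached max_iter=%d without stabilizing", self.max_iter)

        self.medoid_indices_ = np.sort(medoids)
        self.labels_ = np.argmin(D[:, self.medoid_indices_], axis=1)
        self.labels_[self.medoid_indices_] = np.arange(k)
        self.inertia_ = float(
            D[np.arange(n), self.medoid_indices_[self.labels_]].sum()
        )
        self.objective_history_ = history
        self.n_iter_ = len(history)
        return self


@dataclass
class ClusteringResult:
    k: int
    medoids: np.ndarray
    assignment: np.ndarray
    objective: float
    sc_mean: float = float("nan")
    sc_se: float = float("nan")
    repetitions: int = 1


def kmedoids(distance_matrix, k: int, seed: int = 0, max_iter: int = 300) -> ClusteringResult:
    model = KMedoids(n_clusters=k, max_iter=max_iter, random_state=seed).fit(distance_matrix)
    return ClusteringResult(
        k=k, medoids=model.medoid_indices_, assignment=model.labels_,
        objective=model.inertia_,
    )


def silhouette(assignment: np.ndarray, distance_matrix: np.ndarray) -> float:
    """Mean silhouette coefficient over points; singleton clusters contribute 0."""
    D = _check_distance_matrix(distance_matrix)
    labels = np.asarray(assignment)
    if len(np.unique(labels)) < 2:
        raise ClusteringError("silhouette undefined for a single cluster")
    return float(silhouette_score(D, labels, metric="precomputed"))


def repeat_clustering(
    distance_matrix, k: int, reps: int = 50, base_seed: int = 0,
) -> tuple[float, float, ClusteringResult]:
    """Repeat seeded k-medoids; report mean silhouette, its standard error and
    the best run (highest silhouette)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scs, results = [], []
    for r in range(reps):
        res = kmedoids(distance_matrix, k, seed=base_seed + r)
        res.sc_mean = silhouette(res.assignment, distance_matrix)
        scs.append(res.sc_mean)
        results.append(res)
    scs = np.asarray(scs)
    mean = float(scs.mean())
    se = float(scs.std(ddof=1) / math.sqrt(reps)) if reps > 1 else 0.0
    best = results[int(np.argmax(scs))]
    best.sc_mean, best.sc_se, best.repetitions = mean, se, reps
    return mean, se, best


def sweep_cluster_count(
    distance_matrix, k_grid, reps: int = 50, seed: int = 0,
) -> pd.DataFrame:
    """Silhouette-vs-k sweep; the selected k is the argmax of mean silhouette."""
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty cluster-count grid")
    rows = []
    for k in k_grid:
        mean, se, _ = repeat_clustering(distance_matrix, k, reps=reps, base_seed=seed)
        rows.append({"k": k, "sc_mean": mean, "sc_se": se})
    table = pd.DataFrame(rows)
    table.attrs["selected_k"] = int(table.loc[table["sc_mean"].idxmax(), "k"])
    return table


@dataclass
class FoldAssignment:
    """Partition of drug-target pairs into cross-validation folds."""

    n_folds: int
    pair_to_fold: dict[tuple[str, str], int]
    protocol: str  # "random" | "cluster"
    seed: int

    def fold_of_rows(self, meta: pd.DataFrame) -> np.ndarray:
        """Fold index per instance row; every signature of a pair shares its fold."""
        return np.array(
            [self.pair_to_fold[(d, p)] for d, p in zip(meta["drug_id"], meta["protein_id"])]
        )

    def iter_splits(self, meta: pd.DataFrame):
        folds = self.fold_of_rows(meta)
        for f in range(self.n_folds):
            test = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            yield train, test


def random_split(pairs: list[tuple[str, str]], k: int = 10, seed: int = 0) -> FoldAssignment:
    """Seeded permutation dealt round-robin; fold sizes differ by at most 1."""
    if k <= 0:
        raise ValueError("number of folds must be positive")
    pairs = sorted(set(pairs))
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} unique pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    mapping = {pairs[idx]: i % k for i, idx in enumerate(order)}
    return FoldAssignment(n_folds=k, pair_to_fold=mapping, protocol="random", seed=seed)


def merge_clusters_to_folds(
    clustering: ClusteringResult,
    pairs: list[tuple[str, str]],
    n_folds: int = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Randomly merge clusters into folds without splitting any cluster.

    Clusters are shuffled with the seed, then placed largest-first into the
    currently smallest fold, keeping fold sizes comparable.
    """
    labels = np.asarray(clustering.assignment)
    cluster_ids = np.unique(labels)
    if len(cluster_ids) < n_folds:
        raise ClusteringError(
            f"{len(cluster_ids)} clusters cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(cluster_ids)
    sizes = {c: int((labels == c).sum()) for c in cluster_ids}
    order = sorted(shuffled, key=lambda c: -sizes[c])  # stable: ties keep shuffle order

    fold_sizes = np.zeros(n_folds, dtype=int)
    cluster_to_fold = {}
    for c in order:
        f = int(np.argmin(fold_sizes))
        cluster_to_fold[c] = f
        fold_sizes[f] += sizes[c]

    mapping = {
        pair: cluster_to_fold[labels[i]] for i, pair in enumerate(pairs)
    }
    return FoldAssignment(n_folds=n_folds, pair_to_fold=mapping, protocol="cluster",
                          seed=seed)


def cluster_split(
    distance_matrix: np.ndarray,
    pairs: list[tuple[str, str]],
    n_clusters: int,
    n_folds: int = 10,
    reps: int = 1,
    seed: int = 0,
) -> FoldAssignment:
    """End-to-end cluster-based protocol: k-medoids (best of ``reps`` seeded
    runs by silhouette) then random cluster→fold merging."""
    if reps > 1:
        _, _, best = repeat_clustering(distance_matrix, n_clusters, reps=reps,
                                       base_seed=seed)
    else:
        best = kmedoids(distance_matrix, n_clusters, seed=seed)
    return merge_clusters_to_folds(best, pairs, n_folds=n_folds, seed=seed)
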