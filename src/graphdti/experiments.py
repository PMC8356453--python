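"""Reference experiments run by the acceptance checks and the docs.

Each function regenerates its synthetic study from a seed, runs the pipeline
under the package's default study conditions, and returns plain numbers, so
results are reproducible end to end from a single integer.
"""

from __future__ import annotations

import numpy as np

from .cv import cluster_split, pairwise_pmd_matrix, random_split
from .mlp import MLPConfig, MLPInteractionClassifier, cross_validate, roc_auc
from .selection import all_importances, rank_features
from .simulate import SyntheticConfig, gen_labeled_dataset, gen_leakage_study


def classifier_sanity(seed: int, n_train: int = 1500) -> dict:
    """Train the default classifier on the high-signal preset; report the
    held-out AUC and whether a repeated seed reproduces the weights exactly."""
    inst, _ = gen_labeled_dataset(SyntheticConfig(seed=seed))
    train = inst.subset(np.arange(n_train))
    hold = inst.subset(np.arange(n_train, len(inst.X)))

    def fit():
        return MLPInteractionClassifier(random_state=seed).fit(train.X, train.y)

    model, twin = fit(), fit()
    identical = all(
        np.array_equal(a, b) for a, b in zip(model.weights_, twin.weights_)
    ) and all(np.array_equal(a, b) for a, b in zip(model.biases_, twin.biases_))
    auc = roc_auc(model.decision_scores(hold.X), hold.y).auc
    return {"auc": float(auc), "bit_identical": bool(identical)}


def leakage_experiment(seed: int, n_clusters: int = 200, n_folds: int = 10) -> dict:
    """Random-split vs cluster-based (scaled-PMD k-medoids) 10-fold CV AUC on
    the leakage preset for one seed."""
    study = gen_leakage_study(SyntheticConfig(seed=seed))
    inst = study.instances
    pairs = list(zip(inst.meta["drug_id"], inst.meta["protein_id"]))
    drug_idx = np.array([study.drug_index[d] for d, _ in pairs])
    prot_idx = np.array([study.protein_index[p] for _, p in pairs])
    D = pairwise_pmd_matrix(study.tc_matrix, study.tm_matrix, drug_idx, prot_idx,
                            scaled=True)
    config = MLPConfig.for_input(inst.width, seed=seed)
    rand = cross_validate(inst, random_split(pairs, k=n_folds, seed=seed), config)
    clus = cross_validate(
        inst, cluster_split(D, pairs, n_clusters=n_clusters, n_folds=n_folds,
                            seed=seed), config,
    )
    return {
        "random_auc": rand.attrs["auc_mean"],
        "cluster_auc": clus.attrs["auc_mean"],
        "gap": rand.attrs["auc_mean"] - clus.attrs["auc_mean"],
    }


def importance_recovery(seed: int, top_k: int = 40, repeats: int = 2,
                        n_train: int = 1400) -> float:
    """Fraction of the 20 planted informative features recovered in the
    top-``top_k`` permutation-importance ranking for one seed."""
    inst, truth = gen_labeled_dataset(SyntheticConfig(seed=seed))
    train = inst.subset(np.arange(n_train))
    hold = inst.subset(np.arange(n_train, len(inst.X)))
    model = MLPInteractionClassifier(random_state=seed).fit(train.X, train.y)
    imp = all_importances(model, hold.X, hold.y, seed=seed, repeats=repeats)
    top = set(rank_features(imp)["feature"].head(top_k))
    return len(top & set(truth.informative)) / len(truth.informative)


def noise_importance_distribution(n_seeds: int = 50, base_seed: int = 0) -> dict:
    """Permutation importance of a pure-noise feature over many seeds.

    Importance is scored on a held-out half: on training data an overfit
    model genuinely uses noise columns and their importance is biased
    upward, whereas held-out importance of an unused feature is zero in
    expectation.
    """
    from .selection import permutation_importance

    vals = []
    for s in range(n_seeds):
        rng = np.random.default_rng([base_seed, s])
        n, d = 160, 6
        y = rng.integers(0, 2, size=n)
        X = rng.standard_normal((n, d))
        X[:, 0] += 2.5 * (2 * y - 1)
        model = MLPInteractionClassifier(epochs=20, random_state=0).fit(X[:80], y[:80])
        vals.append(permutation_importance(model, X[80:], y[80:], j=d - 1,
                                           seed=base_seed + s, repeats=2))
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return {"mean": float(vals.mean()), "se": se}
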