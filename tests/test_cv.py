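import itertools
import math

import numpy as np
import pytest

from graphdti.cv import (
    SQRT2,
    ClusteringError,
    ClusteringResult,
    FoldAssignment,
    KMedoids,
    cluster_split,
    fmd,
    kmedoids,
    merge_clusters_to_folds,
    pairwise_pmd_matrix,
    pmd,
    random_split,
    repeat_clustering,
    scaled_pmd,
    silhouette,
    sweep_cluster_count,
)


def two_blob_matrix(rng, n=10, within=0.1, between=10.0):
    """Distance matrix of two tight, well-separated blobs."""
    half = n // 2
    D = np.full((n, n), float(between))
    D[:half, :half] = within
    D[half:, half:] = within
    D += rng.uniform(0, 0.01, size=(n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D, np.array([0] * half + [1] * (n - half))


def brute_force_silhouette(labels, D):
    """Oracle: the per-point (b - a) / max(a, b) formula, singletons scoring 0."""
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in own])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def exhaustive_best_medoids(D, k):
    """Oracle: minimum objective over all medoid subsets of size k."""
    n = D.shape[0]
    best, best_obj = None, np.inf
    for medoids in itertools.combinations(range(n), k):
        obj = D[:, medoids].min(axis=1).sum()
        if obj < best_obj:
            best, best_obj = medoids, obj
    return best, best_obj


class TestPairDistances:
    def test_fmd_identical_pairs_zero(self):
        v = np.arange(600.0)
        assert fmd(v, v) == 0.0

    def test_fmd_single_coordinate_difference(self):
        a = np.zeros(600)
        b = np.zeros(600)
        b[17] = 3.0
        assert fmd(a, b) == 3.0

    def test_fmd_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.standard_normal((2, 600))
            assert fmd(a, b) == pytest.approx(math.sqrt(((a - b) ** 2).sum()))

    def test_fmd_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fmd(np.zeros(600), np.zeros(300))

    @pytest.mark.parametrize("tc,tm,expected", [
        (1.0, 1.0, 0.0),
        (0.0, 0.0, SQRT2),
        (1.0, 0.0, 1.0),
        (0.0, 1.0, 1.0),
    ])
    def test_pmd_values(self, tc, tm, expected):
        assert pmd(tc, tm) == pytest.approx(expected)

    def test_pmd_requires_unit_interval_similarities(self):
        with pytest.raises(ValueError):
            pmd(1.2, 0.5)

    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (SQRT2 / 2, 1.0)])
    def test_scaled_pmd_values(self, p, expected):
        assert scaled_pmd(p) == pytest.approx(expected)

    def test_scaled_pmd_pole_rejected(self):
        with pytest.raises(ValueError):
            scaled_pmd(1.41421356237)
        with pytest.raises(ValueError):
            scaled_pmd(1.5)

    def test_scaled_pmd_strictly_increasing_on_grid(self):
        grid = np.linspace(0, SQRT2 - 1e-6, 1000)
        vals = [scaled_pmd(p) for p in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_pairwise_matrix_consistent_with_scalar_pmd(self):
        rng = np.random.default_rng(1)
        tc = rng.uniform(0, 1, (4, 4))
        tc = (tc + tc.T) / 2
        np.fill_diagonal(tc, 1.0)
        tm = rng.uniform(0, 1, (3, 3))
        tm = (tm + tm.T) / 2
        np.fill_diagonal(tm, 1.0)
        di = np.array([0, 1, 2, 3])
        pi = np.array([0, 1, 2, 0])
        D = pairwise_pmd_matrix(tc, tm, di, pi)
        for i in range(4):
            for j in range(4):
                if i != j:
                    assert D[i, j] == pytest.approx(
                        pmd(tc[di[i], di[j]], tm[pi[i], pi[j]])
                    )


class TestKMedoids:
    def test_k_equals_n_zero_objective(self):
        rng = np.random.default_rng(0)
        D, _ = two_blob_matrix(rng, n=8)
        res = kmedoids(D, k=8, seed=0)
        assert res.objective == 0.0
        assert sorted(res.medoids) == list(range(8))

    def test_two_blob_recovery_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            D, truth = two_blob_matrix(rng, n=10)
            res = kmedoids(D, k=2, seed=trial)
            # blob-pure clusters
            for blob in (truth == 0, truth == 1):
                assert len(set(res.assignment[blob])) == 1
            _, best_obj = exhaustive_best_medoids(D, 2)
            assert res.objective == pytest.approx(best_obj, rel=1e-9)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        D, _ = two_blob_matrix(rng, n=12)
        a = kmedoids(D, k=3, seed=7)
        b = kmedoids(D, k=3, seed=7)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        np.testing.assert_array_equal(a.medoids, b.medoids)

    def test_objective_nonincreasing_over_seeded_runs(self):
        rng = np.random.default_rng(2)
        for run in range(100):
            n = int(rng.integers(8, 25))
            pts = rng.standard_normal((n, 3))
            D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
            model = KMedoids(n_clusters=int(rng.integers(2, 5)),
                             random_state=run).fit(D)
            hist = model.objective_history_
            assert all(a >= b - 1e-9 for a, b in zip(hist, hist[1:]))

    def test_k_out_of_range_and_asymmetry_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ClusteringError):
            kmedoids(D, k=4)
        bad = np.array([[0, 1.0, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(ClusteringError):
            kmedoids(bad, k=2)


class TestSilhouette:
    def test_two_distant_blobs_near_one(self):
        rng = np.random.default_rng(0)
        D, truth = two_blob_matrix(rng, n=10, within=0.01, between=50)
        assert silhouette(truth, D) > 0.99

    def test_equidistant_points_score_zero(self):
        D = np.ones((6, 6)) - np.eye(6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette(labels, D) == pytest.approx(0.0)

    def test_matches_brute_force_formula_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 51))
            pts = rng.standard_normal((n, 2))
            D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
            labels = rng.integers(0, 3, size=n)
            if len(set(labels)) < 2:
                continue
            assert silhouette(labels, D) == pytest.approx(
                brute_force_silhouette(labels, D), abs=1e-10
            )

    def test_single_cluster_undefined(self):
        D = np.zeros((4, 4))
        with pytest.raises(ClusteringError):
            silhouette(np.zeros(4, dtype=int), D)


class TestRepeatClustering:
    def test_single_rep_zero_se(self):
        rng = np.random.default_rng(0)
        D, _ = two_blob_matrix(rng)
        mean, se, best = repeat_clustering(D, 2, reps=1, base_seed=0)
        assert se == 0.0
        assert best.repetitions == 1

    def test_degenerate_identical_runs_zero_se(self):
        rng = np.random.default_rng(1)
        D, _ = two_blob_matrix(rng, within=0.001, between=100)
        mean, se, _ = repeat_clustering(D, 2, reps=10, base_seed=0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_mean_close_to_single_run_on_two_blobs(self):
        rng = np.random.default_rng(2)
        D, truth = two_blob_matrix(rng)
        mean, se, best = repeat_clustering(D, 2, reps=10, base_seed=3)
        single = silhouette(kmedoids(D, 2, seed=3).assignment, D)
        assert mean == pytest.approx(single, abs=max(3 * se, 1e-9))


class TestSweepClusterCount:
    def three_blob_matrix(self, rng, per=6):
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        pts = np.vstack([c + rng.standard_normal((per, 2)) * 0.3 for c in centers])
        return np.linalg.norm(pts[:, None] - pts[None], axis=2)

    def test_grid_of_one_selects_it(self):
        rng = np.random.default_rng(0)
        D, _ = two_blob_matrix(rng)
        table = sweep_cluster_count(D, [2], reps=3, seed=0)
        assert table.attrs["selected_k"] == 2

    def test_planted_three_blob_argmax(self):
        rng = np.random.default_rng(7)
        D = self.three_blob_matrix(rng)
        table = sweep_cluster_count(D, [2, 3, 4], reps=10, seed=0)
        assert table.attrs["selected_k"] == 3

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_cluster_count(np.zeros((3, 3)), [], reps=1, seed=0)


class TestFolds:
    def pairs(self, n):
        return [(f"d{i}", f"p{i}") for i in range(n)]

    def test_random_split_even_sizes(self):
        fa = random_split(self.pairs(100), k=10, seed=0)
        sizes = np.bincount(list(fa.pair_to_fold.values()))
        assert list(sizes) == [10] * 10

    def test_random_split_near_even_sizes(self):
        fa = random_split(self.pairs(101), k=10, seed=0)
        sizes = sorted(np.bincount(list(fa.pair_to_fold.values())))
        assert sizes == [10] * 9 + [11]

    def test_random_split_seeded_determinism(self):
        a = random_split(self.pairs(50), k=5, seed=42)
        b = random_split(self.pairs(50), k=5, seed=42)
        assert a.pair_to_fold == b.pair_to_fold

    def test_random_split_bad_k(self):
        with pytest.raises(ValueError):
            random_split(self.pairs(10), k=0)

    def test_merge_singleton_clusters_one_per_fold(self):
        pairs = self.pairs(10)
        clustering = ClusteringResult(
            k=10, medoids=np.arange(10), assignment=np.arange(10), objective=0.0
        )
        fa = merge_clusters_to_folds(clustering, pairs, n_folds=10, seed=0)
        assert sorted(fa.pair_to_fold.values()) == list(range(10))

    def test_merge_balances_equal_clusters(self):
        pairs = self.pairs(200)
        clustering = ClusteringResult(
            k=40, medoids=np.arange(40), assignment=np.repeat(np.arange(40), 5),
            objective=0.0,
        )
        fa = merge_clusters_to_folds(clustering, pairs, n_folds=10, seed=1)
        sizes = np.bincount(list(fa.pair_to_fold.values()))
        assert list(sizes) == [20] * 10

    def test_merge_never_splits_a_cluster(self):
        rng = np.random.default_rng(0)
        pairs = self.pairs(60)
        assignment = rng.integers(0, 15, size=60)
        clustering = ClusteringResult(k=15, medoids=np.arange(15),
                                      assignment=assignment, objective=0.0)
        fa = merge_clusters_to_folds(clustering, pairs, n_folds=5, seed=2)
        folds = np.array([fa.pair_to_fold[p] for p in pairs])
        for c in range(15):
            assert len(set(folds[assignment == c])) <= 1
        assert set(fa.pair_to_fold) == set(pairs)

    def test_merge_requires_enough_clusters(self):
        clustering = ClusteringResult(k=3, medoids=np.arange(3),
                                      assignment=np.arange(3), objective=0.0)
        with pytest.raises(ClusteringError):
            merge_clusters_to_folds(clustering, self.pairs(3), n_folds=10)

    def test_instances_inherit_pair_fold(self):
        import pandas as pd

        fa = random_split(self.pairs(4), k=2, seed=0)
        meta = pd.DataFrame({
            "drug_id": ["d0", "d0", "d1"], "protein_id": ["p0", "p0", "p1"],
        })
        folds = fa.fold_of_rows(meta)
        assert folds[0] == folds[1]

    def test_cluster_protocol_colocates_near_duplicate_families(self):
        # families of near-identical pairs straddle random folds but stay
        # together under cluster-based splitting in nearly every seed
        rng = np.random.default_rng(0)
        n_fam, copies = 30, 4
        tc = np.full((n_fam * copies, n_fam * copies), 0.05)
        for f in range(n_fam):
            s = slice(f * copies, (f + 1) * copies)
            tc[s, s] = 0.9
        np.fill_diagonal(tc, 1.0)
        tm = tc.copy()
        pairs = [(f"d{i}", f"p{i}") for i in range(n_fam * copies)]
        idx = np.arange(n_fam * copies)
        D = pairwise_pmd_matrix(tc, tm, idx, idx, scaled=True)
        fam = np.repeat(np.arange(n_fam), copies)

        def n_split_families(fa):
            folds = np.array([fa.pair_to_fold[p] for p in pairs])
            return sum(len(set(folds[fam == f])) > 1 for f in range(n_fam))

        wins = 0
        for seed in range(20):
            rand_split_fams = n_split_families(random_split(pairs, k=10, seed=seed))
            clus = cluster_split(D, pairs, n_clusters=n_fam, n_folds=10, seed=seed)
            if n_split_families(clus) < rand_split_fams:
                wins += 1
        assert wins >= 19
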