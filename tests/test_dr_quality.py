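"""Structure metrics against brute-force oracles and limit cases."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hemadr.dr_quality import (compare_methods_ttest, coranking_matrix,
                               distance_correlation, kfold_quality_assessment,
                               manhattan_distance, neighbourhood_kept_ratio,
                               random_triplet_score, rank_structure,
                               trustworthiness)
from hemadr.reducers import (Embedding, ReducerConfig, grp_fit_transform,
                             jl_min_dimensions, reduce_matrix)

# ---------------------------------------------------------------------------
# pure-Python oracles


def brute_ranks(X, metric="manhattan"):
    """Rank r(i,j) by explicit sort with (distance, index) keys."""
    n = len(X)
    d = (lambda a, b: float(np.abs(a - b).sum())) if metric == "manhattan" \
        else (lambda a, b: float(np.linalg.norm(a - b)))
    ranks = np.zeros((n, n), dtype=int)
    for i in range(n):
        others = sorted((d(X[i], X[j]), j) for j in range(n) if j != i)
        for r, (_, j) in enumerate(others, start=1):
            ranks[i, j] = r
    return ranks


def brute_trustworthiness(high_ranks, low_ranks, k):
    """Direct rank-sum evaluation on raw ranks, bypassing the Q-matrix."""
    n = len(high_ranks)
    total = 0
    for i in range(n):
        for j in range(n):
            if j != i and low_ranks[i, j] <= k and high_ranks[i, j] > k:
                total += high_ranks[i, j] - k
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * total


def brute_triplet_score(Xh, Xl, metric="manhattan"):
    d = (lambda a, b: float(np.abs(a - b).sum())) if metric == "manhattan" \
        else (lambda a, b: float(np.linalg.norm(a - b)))
    n = len(Xh)
    agree = total = 0
    for i in range(n):
        for j, k in itertools.combinations([x for x in range(n) if x != i], 2):
            sh = np.sign(d(Xh[i], Xh[j]) - d(Xh[i], Xh[k]))
            sl = np.sign(d(Xl[i], Xl[j]) - d(Xl[i], Xl[k]))
            agree += sh == sl
            total += 1
    return agree / total


class TestManhattanDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([0, 0], [3, 4], 7.0),
        ([1, -1], [-1, 1], 4.0),
    ])
    def test_printed_examples(self, a, b, expected):
        assert manhattan_distance(a, b) == expected

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            manhattan_distance([1, 2], [1, 2, 3])


class TestRankStructure:
    def test_three_collinear_points(self):
        X = np.array([[0.0], [1.0], [10.0]])
        rs = rank_structure(X, k=1)
        assert rs.neighbours[:, 0].tolist() == [1, 0, 1]

    def test_matches_brute_force_ranks(self, rng):
        X = rng.normal(size=(40, 4))
        rs = rank_structure(X, k=5)
        assert np.array_equal(rs.ranks, brute_ranks(X))

    def test_ranks_are_permutations(self, rng):
        X = rng.normal(size=(30, 3))
        rs = rank_structure(X, k=3)
        n = len(X)
        for i in range(n):
            row = np.delete(rs.ranks[i], i)
            assert sorted(row.tolist()) == list(range(1, n))

    def test_duplicate_points_tie_toward_smaller_index(self):
        X = np.array([[0.0], [1.0], [1.0], [5.0]])
        rs = rank_structure(X, k=2)
        # from point 3: points 1 and 2 are equidistant; 1 wins rank 1
        assert rs.ranks[3, 1] < rs.ranks[3, 2]
        rs2 = rank_structure(X, k=2)
        assert np.array_equal(rs.ranks, rs2.ranks)

    @pytest.mark.parametrize("k", [0, 5])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            rank_structure(np.zeros((5, 1)) + np.arange(5)[:, None], k=k)


class TestCorankingMatrix:
    def test_identity_embedding_is_diagonal(self, rng):
        X = rng.normal(size=(20, 3))
        rs = rank_structure(X, k=3)
        Q = coranking_matrix(rs, rs)
        n = len(X)
        assert np.trace(Q.counts) == n * (n - 1)
        assert (Q.counts - np.diag(np.diag(Q.counts)) == 0).all()

    def test_total_mass_conserved(self, rng):
        Xh = rng.normal(size=(25, 4))
        Xl = rng.normal(size=(25, 2))
        Q = coranking_matrix(rank_structure(Xh, 3), rank_structure(Xl, 3))
        n = 25
        assert Q.counts.sum() == n * (n - 1)
        assert (Q.counts.sum(axis=0) == n).all()  # unique ranks per column
        assert (Q.counts.sum(axis=1) == n).all()

    def test_four_point_example_matches_pair_enumeration(self):
        high = np.array([[0.0], [1.0], [3.0], [7.0]])
        low = np.array([[0.0], [1.0], [3.0], [2.0]])
        hr, lr = brute_ranks(high), brute_ranks(low)
        Q = coranking_matrix(rank_structure(high, 1), rank_structure(low, 1))
        expected = np.zeros((3, 3), dtype=int)
        for i in range(4):
            for j in range(4):
                if i != j:
                    expected[hr[i, j] - 1, lr[i, j] - 1] += 1
        assert np.array_equal(Q.counts, expected)


class TestTrustworthiness:
    def test_identity_embedding_scores_one(self, rng):
        X = rng.normal(size=(30, 3))
        rs = rank_structure(X, k=5)
        assert trustworthiness(coranking_matrix(rs, rs), 5) == 1.0

    def test_four_point_example_matches_direct_formula(self):
        high = np.array([[0.0], [1.0], [3.0], [7.0]])
        low = np.array([[0.0], [1.0], [3.0], [2.0]])
        Q = coranking_matrix(rank_structure(high, 1), rank_structure(low, 1))
        expected = brute_trustworthiness(brute_ranks(high), brute_ranks(low), 1)
        assert trustworthiness(Q, 1) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_formula_on_random_data(self, rng):
        Xh = rng.normal(size=(40, 5))
        Xl = rng.normal(size=(40, 2))
        for k in (1, 3, 10):
            Q = coranking_matrix(rank_structure(Xh, k), rank_structure(Xl, k))
            expected = brute_trustworthiness(brute_ranks(Xh), brute_ranks(Xl), k)
            assert trustworthiness(Q, k) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.manifold import trustworthiness as skl_trust
        Xh = rng.normal(size=(60, 6))
        Xl = Xh[:, :2] + 0.3 * rng.normal(size=(60, 2))
        for k in (5, 12):
            Q = coranking_matrix(rank_structure(Xh, k, "euclidean"),
                                 rank_structure(Xl, k, "euclidean"))
            assert trustworthiness(Q, k) == pytest.approx(
                skl_trust(Xh, Xl, n_neighbors=k), abs=1e-10)

    def test_intrusion_strictly_lowers_score(self, rng):
        X = np.arange(12, dtype=float)[:, None]
        rs = rank_structure(X, k=2)
        swapped = X.copy()
        swapped[[1, 10]] = swapped[[10, 1]]  # far point intrudes locally
        rs_low = rank_structure(swapped, k=2)
        assert trustworthiness(coranking_matrix(rs, rs_low), 2) < 1.0

    def test_k_too_large_is_error(self, rng):
        X = rng.normal(size=(10, 2))
        rs = rank_structure(X, k=5)
        with pytest.raises(ValueError):
            trustworthiness(coranking_matrix(rs, rs), 5)


class TestNeighbourhoodKeptRatio:
    def test_identity_is_one_disjoint_is_zero(self, rng):
        X = rng.normal(size=(20, 2))
        rs = rank_structure(X, k=4)
        assert neighbourhood_kept_ratio(rs, rs, 4) == 1.0
        # reversing a line makes each end-point's neighbourhood disjoint
        line = np.arange(10, dtype=float)[:, None]
        lowX = np.array([[9.0], [0.0], [8.0], [1.0], [7.0], [2.0], [6.0],
                         [3.0], [5.0], [4.0]])
        high, low = rank_structure(line, 1), rank_structure(lowX, 1)
        ratio = neighbourhood_kept_ratio(high, low, 1)
        assert ratio < 0.5  # most neighbourhoods broken by the interleave

    def test_random_relabelling_matches_combinatorial_expectation(self, rng):
        n, k, reps = 200, 10, 30
        X = rng.normal(size=(n, 3))
        high = rank_structure(X, k)
        vals = []
        for _ in range(reps):
            perm = rng.permutation(n)
            low = rank_structure(X[perm], k)
            # low space = same geometry with permuted points: each high
            # neighbour survives with probability k/(n-1)
            vals.append(neighbourhood_kept_ratio(high, low, k))
        expect = k / (n - 1)
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - expect) < 3 * se + 1e-6


class TestRandomTripletScore:
    def test_identity_exhaustive_is_one(self, rng):
        X = rng.normal(size=(15, 3))
        assert random_triplet_score(X, X, exhaustive=True) == 1.0

    def test_isometry_scores_one(self, rng):
        X = rng.normal(size=(15, 3))
        assert random_triplet_score(X, -X, exhaustive=True) == 1.0
        # rotation preserves Euclidean (not Manhattan) distances
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        X2 = rng.normal(size=(15, 2))
        assert random_triplet_score(X2, X2 @ R.T, exhaustive=True,
                                    metric="euclidean") == 1.0

    def test_exhaustive_matches_pure_python_oracle(self, rng):
        Xh = rng.normal(size=(12, 3))
        Xl = rng.normal(size=(12, 2))
        assert random_triplet_score(Xh, Xl, exhaustive=True) == pytest.approx(
            brute_triplet_score(Xh, Xl), abs=1e-12)

    def test_sampled_score_tracks_exhaustive(self, rng):
        Xh = rng.normal(size=(300, 4))
        Xl = Xh[:, :2]
        exact = random_triplet_score(Xh, Xl, exhaustive=True)
        samples = [random_triplet_score(Xh, Xl, triplets_per_point=5, seed=s)
                   for s in range(20)]
        se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        assert abs(np.mean(samples) - exact) < 3 * se + 1e-4

    def test_too_few_points_is_error(self):
        with pytest.raises(ValueError):
            random_triplet_score(np.zeros((2, 1)), np.zeros((2, 1)))


class TestDistanceCorrelation:
    def test_monotone_transform_scores_one(self, rng):
        X = rng.normal(size=(30, 4))
        assert distance_correlation(X, 2 * X) == pytest.approx(1.0)

    def test_antimonotone_layout_scores_minus_one(self):
        # 1D layouts whose pairwise-distance rank order is exactly reversed
        high = np.array([[0.0], [1.0], [3.0]])  # distances 1, 3, 2
        low = np.array([[0.0], [3.0], [1.0]])  # distances 3, 1, 2
        assert distance_correlation(high, low) == pytest.approx(-1.0)

    def test_sampled_estimate_tracks_all_pairs(self, rng):
        Xh = rng.normal(size=(300, 5))
        Xl = Xh[:, :2] + 0.1 * rng.normal(size=(300, 2))
        exact = distance_correlation(Xh, Xl, n_pairs="all")
        samples = [distance_correlation(Xh, Xl, n_pairs=10_000, seed=s)
                   for s in range(15)]
        se = np.std(samples, ddof=1) / np.sqrt(len(samples))
        assert abs(np.mean(samples) - exact) < 3 * se + 1e-3

    def test_degenerate_distances_are_error(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])  # equilateral
        Y = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="undefined"):
            distance_correlation(X, Y, metric="euclidean")


class TestKFoldAssessment:
    def test_identity_embedding_all_metrics_one(self, rng):
        X = rng.normal(size=(400, 5))
        emb = reduce_matrix(X, ReducerConfig(method="identity", n_components=5))
        rep = kfold_quality_assessment(X, emb, k_neighbours=5, folds=4, seed=0)
        assert rep.fold_values.shape == (4, 4)
        assert np.allclose(rep.fold_values.to_numpy(), 1.0)

    def test_report_shape_and_finiteness(self, rng):
        X = rng.normal(size=(300, 6))
        emb = grp_fit_transform(X, 2, seed=1)
        rep = kfold_quality_assessment(X, emb, k_neighbours=5, folds=3, seed=0)
        assert rep.fold_values.shape == (3, 4)
        assert np.isfinite(rep.fold_values.to_numpy()).all()
        assert (rep.standard_errors >= 0).all()

    def test_jl_sufficient_grp_beats_two_components(self, rng):
        X = rng.normal(size=(600, 50))
        k = jl_min_dimensions(600 // 3, 0.9)
        hi = grp_fit_transform(X, min(k, 45), seed=2)
        lo = grp_fit_transform(X, 2, seed=2)
        rep_hi = kfold_quality_assessment(X, hi, k_neighbours=5, folds=3, seed=0)
        rep_lo = kfold_quality_assessment(X, lo, k_neighbours=5, folds=3, seed=0)
        assert rep_hi.means["random_triplet_score"] > \
            rep_lo.means["random_triplet_score"]

    def test_fold_too_small_for_k_is_error(self, rng):
        X = rng.normal(size=(100, 3))
        emb = reduce_matrix(X, ReducerConfig(method="identity", n_components=3))
        with pytest.raises(ValueError, match="fold"):
            kfold_quality_assessment(X, emb, k_neighbours=50, folds=10)


class TestCompareMethodsTTest:
    def _report(self, values):
        import pandas as pd
        from hemadr.dr_quality import METRIC_NAMES, QualityReport
        df = pd.DataFrame({m: values for m in METRIC_NAMES})
        return QualityReport("x", None, df)

    def test_identical_fold_vectors_give_null_result(self):
        a = self._report([0.5, 0.6, 0.7])
        t, p = compare_methods_ttest(a, a, "trustworthiness")
        assert (t, p) == (0.0, 1.0)

    def test_separated_folds_are_significant(self, rng):
        a = self._report(list(0.5 + 0.01 * rng.standard_normal(10)))
        b = self._report(list(0.9 + 0.01 * rng.standard_normal(10)))
        _, p = compare_methods_ttest(a, b, "trustworthiness")
        assert p < 0.001

    def test_matches_direct_welch_formula(self, rng):
        x = list(rng.normal(0.5, 0.05, 10))
        y = list(rng.normal(0.55, 0.08, 10))
        t, p = compare_methods_ttest(self._report(x), self._report(y),
                                     "distance_correlation")
        # Welch statistic computed from first principles
        vx, vy = np.var(x, ddof=1) / 10, np.var(y, ddof=1) / 10
        t_direct = (np.mean(x) - np.mean(y)) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / 9 + vy**2 / 9)
        p_direct = 2 * stats.t.sf(abs(t_direct), df)
        assert t == pytest.approx(t_direct, abs=1e-10)
        assert p == pytest.approx(p_direct, abs=1e-10)

    def test_single_fold_is_error(self):
        a = self._report([0.5])
        with pytest.raises(ValueError):
            compare_methods_ttest(a, a, "trustworthiness")


class TestMonotoneDegradation:
    def test_noise_added_to_identity_degrades_metrics(self, rng):
        X = rng.normal(size=(200, 4))
        sds = [0.0, 0.5, 2.0]
        means = []
        for sd in sds:
            reps = []
            for seed in range(3):
                noisy = X + sd * np.random.default_rng(seed).normal(size=X.shape)
                emb = Embedding(noisy, ReducerConfig(method="identity",
                                                     n_components=4),
                                np.arange(len(X)))
                rep = kfold_quality_assessment(X, emb, k_neighbours=5,
                                               folds=2, seed=0)
                reps.append(rep.means.to_numpy())
            means.append(np.mean(reps, axis=0))
        means = np.array(means)
        assert (np.diff(means, axis=0) <= 1e-9).all()
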