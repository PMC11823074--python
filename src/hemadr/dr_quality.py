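"""Structure-preservation metrics for dimension reductions.

The four metrics used throughout the evaluation, all rank-based and hence
insensitive to scaling:

* local: neighbourhood-kept-ratio, trustworthiness (via the co-ranking
  matrix, i.e. the Q-matrix framework);
* global: random triplet score, Spearman correlation of pairwise distances.

Conventions. Distances default to Manhattan in both spaces (the evaluation's
working metric for high-dimensional data); ranks are over all other points,
rank 1 = nearest non-self, ties broken toward the smaller index; triplet
order ties count as disagreement unless tied in both spaces.

Everything here is exact and brute-force-verifiable: distance matrices are
materialised per fold (folds of a few thousand points), which doubles as the
test oracle path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy import stats

from .reducers import Embedding, ReducerConfig

__all__ = [
    "RankStructure",
    "CorankingMatrix",
    "QualityReport",
    "METRIC_NAMES",
    "manhattan_distance",
    "rank_structure",
    "coranking_matrix",
    "trustworthiness",
    "neighbourhood_kept_ratio",
    "random_triplet_score",
    "distance_correlation",
    "kfold_quality_assessment",
    "compare_methods_ttest",
]

METRIC_NAMES = ("neighbourhood_kept_ratio", "trustworthiness",
                "random_triplet_score", "distance_correlation")

_SCIPY_METRIC = {"manhattan": "cityblock", "euclidean": "euclidean"}


def manhattan_distance(a, b) -> float:
    """Sum of absolute coordinate differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    return float(np.abs(a - b).sum())


@dataclass
class RankStructure:
    """k-NN lists and the full pairwise rank matrix of one space.

    ``ranks[i, j]`` is the rank of j among distances from i (1 = nearest
    non-self, ties toward smaller index); the diagonal is 0. ``neighbours``
    holds each point's first k ranked indices.
    """

    neighbours: np.ndarray  # (n, k) int
    ranks: np.ndarray  # (n, n) int, diagonal 0
    k: int
    metric: str

    @property
    def n(self) -> int:
        return self.ranks.shape[0]


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric not in _SCIPY_METRIC:
        raise ValueError(f"unsupported metric {metric!r}")
    return cdist(X, X, metric=_SCIPY_METRIC[metric])


def rank_structure(X: np.ndarray, k: int, metric: str = "manhattan") -> RankStructure:
    """Exact neighbour lists and full pairwise ranks under ``metric``.

    Computed from the full distance matrix with a stable argsort, which
    realises the tie-break-toward-smaller-index convention exactly; this
    single path is both the production code (fold sizes are small) and the
    quantity the pure-Python test oracle checks against.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}]")
    D = _distance_matrix(X, metric)
    np.fill_diagonal(D, np.inf)  # self excluded, sorts last
    order = np.argsort(D, axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=np.int32)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    ranks[np.arange(n), np.arange(n)] = 0
    return RankStructure(order[:, :k].copy(), ranks, k, metric)


@dataclass
class CorankingMatrix:
    """(n-1) x (n-1) counts of ordered pairs by (high rank, low rank)."""

    counts: np.ndarray

    @property
    def n(self) -> int:
        return self.counts.shape[0] + 1


def coranking_matrix(high: RankStructure, low: RankStructure) -> CorankingMatrix:
    """Joint histogram of pairwise ranks in the two spaces (the Q-matrix)."""
    n = high.n
    if low.n != n:
        raise ValueError("rank structures must describe the same points")
    off = ~np.eye(n, dtype=bool)
    a = high.ranks[off].astype(np.int64) - 1
    b = low.ranks[off].astype(np.int64) - 1
    counts = np.bincount(a * (n - 1) + b, minlength=(n - 1) ** 2)
    return CorankingMatrix(counts.reshape(n - 1, n - 1))


def trustworthiness(Q: CorankingMatrix, k: int) -> float:
    """Trustworthiness from the co-ranking matrix.

    1 - 2/(n k (2n - 3k - 1)) * sum over pairs entering the low-space
    k-neighbourhood from high-space rank r > k of (r - k). Penalises
    intrusions: points that look like neighbours in the embedding but were
    far in the original space.
    """
    n = Q.n
    if not 1 <= k < n / 2:
        raise ValueError(f"trustworthiness requires 1 <= k < n/2, got k={k}, n={n}")
    r = np.arange(1, n)
    intrusions = Q.counts[k:, :k]  # high rank > k, low rank <= k
    penalty = float((intrusions * (r[k:] - k)[:, None]).sum())
    return 1.0 - 2.0 / (n * k * (2 * n - 3 * k - 1)) * penalty


def neighbourhood_kept_ratio(high: RankStructure, low: RankStructure,
                             k: int) -> float:
    """Mean fraction of each point's high-space k-NN kept in the low space."""
    if high.n != low.n:
        raise ValueError("rank structures must describe the same points")
    if k > high.k or k > low.k:
        raise ValueError("structures were built with fewer than k neighbours")
    rows = np.arange(high.n)[:, None]
    low_rank_of_high_nn = low.ranks[rows, high.neighbours[:, :k]]
    return float((low_rank_of_high_nn <= k).mean())


def _triplet_agreement(dh_j, dh_k, dl_j, dl_k) -> np.ndarray:
    sh = np.sign(dh_j - dh_k)
    sl = np.sign(dl_j - dl_k)
    return sh == sl  # a tie (sign 0) agrees only with a tie in the other space


def random_triplet_score(X_high: np.ndarray, X_low: np.ndarray,
                         triplets_per_point: int = 5, seed: int = 0,
                         exhaustive: bool = False,
                         metric: str = "manhattan") -> float:
    """Fraction of triplets (i, j, k) whose distance order d(i,j) vs d(i,k)
    agrees between the two spaces.

    Sampled mode draws ``triplets_per_point`` random (j, k) pairs per i;
    exhaustive mode enumerates all pairs {j, k} per i (test oracle).
    """
    X_high = np.asarray(X_high, dtype=float)
    X_low = np.asarray(X_low, dtype=float)
    n = X_high.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for triplets")
    if X_low.shape[0] != n:
        raise ValueError("spaces must contain the same points")
    m = _SCIPY_METRIC[metric]
    if exhaustive:
        Dh = _distance_matrix(X_high, metric)
        Dl = _distance_matrix(X_low, metric)
        agree = total = 0
        ju, ku = np.triu_indices(n - 1, 1)
        for i in range(n):
            dh = np.delete(Dh[i], i)
            dl = np.delete(Dl[i], i)
            ok = _triplet_agreement(dh[ju], dh[ku], dl[ju], dl[ku])
            agree += int(ok.sum())
            total += ok.size
        return agree / total
    rng = np.random.default_rng(seed)
    i = np.repeat(np.arange(n), triplets_per_point)
    j = rng.integers(0, n - 1, size=i.size)
    k = rng.integers(0, n - 2, size=i.size)
    j = j + (j >= i)  # j != i
    k = k + (k >= np.minimum(i, j))
    k = k + (k >= np.maximum(i, j))  # k != i, k != j
    dh_j = np.abs(X_high[i] - X_high[j]).sum(1) if metric == "manhattan" else \
        np.linalg.norm(X_high[i] - X_high[j], axis=1)
    dh_k = np.abs(X_high[i] - X_high[k]).sum(1) if metric == "manhattan" else \
        np.linalg.norm(X_high[i] - X_high[k], axis=1)
    dl_j = np.abs(X_low[i] - X_low[j]).sum(1) if metric == "manhattan" else \
        np.linalg.norm(X_low[i] - X_low[j], axis=1)
    dl_k = np.abs(X_low[i] - X_low[k]).sum(1) if metric == "manhattan" else \
        np.linalg.norm(X_low[i] - X_low[k], axis=1)
    return float(_triplet_agreement(dh_j, dh_k, dl_j, dl_k).mean())


def distance_correlation(X_high: np.ndarray, X_low: np.ndarray,
                         n_pairs: int | str = "all", seed: int = 0,
                         metric: str = "manhattan") -> float:
    """Spearman rank correlation between high- and low-space pairwise
    distances, over all pairs or a seeded uniform pair sample."""
    X_high = np.asarray(X_high, dtype=float)
    X_low = np.asarray(X_low, dtype=float)
    n = X_high.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    m = _SCIPY_METRIC[metric]
    if n_pairs == "all":
        dh = pdist(X_high, metric=m)
        dl = pdist(X_low, metric=m)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=int(n_pairs))
        j = rng.integers(0, n - 1, size=int(n_pairs))
        j = j + (j >= i)
        if metric == "manhattan":
            dh = np.abs(X_high[i] - X_high[j]).sum(1)
            dl = np.abs(X_low[i] - X_low[j]).sum(1)
        else:
            dh = np.linalg.norm(X_high[i] - X_high[j], axis=1)
            dl = np.linalg.norm(X_low[i] - X_low[j], axis=1)
    tol_h = 1e-12 * max(1.0, float(np.max(np.abs(dh))))
    tol_l = 1e-12 * max(1.0, float(np.max(np.abs(dl))))
    if np.ptp(dh) <= tol_h or np.ptp(dl) <= tol_l:
        raise ValueError("all distances equal in one space; correlation undefined")
    rho = stats.spearmanr(dh, dl).statistic
    return float(rho)


@dataclass
class QualityReport:
    """Per-fold values of the four metrics for one reducer configuration."""

    method: str
    config: ReducerConfig | None
    fold_values: pd.DataFrame  # folds x METRIC_NAMES
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def means(self) -> pd.Series:
        return self.fold_values.mean(axis=0)

    @property
    def standard_errors(self) -> pd.Series:
        f = len(self.fold_values)
        return self.fold_values.std(axis=0, ddof=1) / np.sqrt(f)


def kfold_quality_assessment(X_high: np.ndarray, embedding: Embedding,
                             k_neighbours: int = 50, folds: int = 10,
                             seed: int = 0, metric: str = "manhattan",
                             pair_sample: int = 1_000_000) -> QualityReport:
    """All four metrics in seeded disjoint folds.

    Rows are partitioned into ``folds`` folds; each metric is computed
    within-fold (neighbour graphs never cross folds), yielding fold means
    and standard errors. Distance correlation uses all pairs for folds up to
    2,000 points and a seeded pair sample beyond that.
    """
    X_high = np.asarray(X_high, dtype=float)
    X_low = embedding.coordinates
    n = X_high.shape[0]
    if X_low.shape[0] != n:
        raise ValueError("embedding rows must align with X_high rows")
    fold_size = n // folds
    if fold_size < max(2 * k_neighbours + 2, 3):
        raise ValueError(
            f"fold size {fold_size} too small for k={k_neighbours}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    rows = []
    for f in range(folds):
        idx = np.sort(perm[f * fold_size:(f + 1) * fold_size])
        Xh, Xl = X_high[idx], X_low[idx]
        high = rank_structure(Xh, k_neighbours, metric)
        low = rank_structure(Xl, k_neighbours, metric)
        Q = coranking_matrix(high, low)
        n_pairs = "all" if len(idx) <= 2000 else pair_sample
        rows.append({
            "neighbourhood_kept_ratio": neighbourhood_kept_ratio(high, low, k_neighbours),
            "trustworthiness": trustworthiness(Q, k_neighbours),
            "random_triplet_score": random_triplet_score(
                Xh, Xl, seed=seed + f, metric=metric),
            "distance_correlation": distance_correlation(
                Xh, Xl, n_pairs=n_pairs, seed=seed + f, metric=metric),
        })
    fold_values = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return QualityReport(embedding.config.method, embedding.config, fold_values,
                         {"k_neighbours": k_neighbours, "folds": folds,
                          "seed": seed, "metric": metric})


def compare_methods_ttest(report_a: QualityReport, report_b: QualityReport,
                          metric: str) -> tuple[float, float]:
    """Welch two-sample t-test on fold values of one metric.

    Identical fold vectors return (0.0, 1.0) — the no-difference limit that
    the t statistic's 0/0 form cannot express.
    """
    a = report_a.fold_values[metric].to_numpy()
    b = report_b.fold_values[metric].to_numpy()
    if len(a) != len(b):
        raise ValueError("fold counts differ")
    if len(a) < 2:
        raise ValueError("need at least 2 folds")
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
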