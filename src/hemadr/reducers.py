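"""Dimension-reduction stages under one contract.

Native implementations of PCA (SVD with a fixed sign convention) and
Gaussian Random Projection (with the Johnson-Lindenstrauss minimum-dimension
bound), plus adapters for the neighbour-based manifold methods UMAP, TriMap
and PaCMAP. GRP serves as a negative control in the evaluation: at low
target dimension it cannot satisfy the JL distortion bound for large n, so
every structure metric should rank it below PCA there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .synth_cohort import CohortTable

__all__ = [
    "ReducerConfig",
    "Embedding",
    "DependencyError",
    "pca_fit_transform",
    "jl_min_dimensions",
    "grp_fit_transform",
    "manifold_reduce",
    "reduce_matrix",
    "subsample_for_reduction",
]

METHODS = ("pca", "grp", "umap", "trimap", "pacmap", "identity")


class DependencyError(ImportError):
    """An optional manifold/clustering backend is not installed."""


@dataclass(frozen=True)
class ReducerConfig:
    """One reducer configuration; unused hyperparameters are ignored.

    Defaults follow the evaluation's working point: 6 components, 50
    neighbours (UMAP/PaCMAP), 50 inliers / 15 outliers (TriMap), Manhattan
    distance.
    """

    method: str = "pca"
    n_components: int = 6
    n_neighbors: int = 50
    n_inliers: int = 50
    n_outliers: int = 15
    n_random: int = 5
    MN_ratio: float = 0.5
    FP_ratio: float = 2.0
    metric: str = "manhattan"
    sample_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if min(self.n_neighbors, self.n_inliers, self.n_outliers) <= 0:
            raise ValueError("neighbour/triplet counts must be positive")
        if self.metric not in ("manhattan", "euclidean"):
            raise ValueError(f"metric must be manhattan or euclidean")


@dataclass
class Embedding:
    """Reduced coordinates with full provenance."""

    coordinates: np.ndarray
    config: ReducerConfig
    row_index: np.ndarray  # source sample positions the rows correspond to
    fit_diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")
        if len(self.row_index) != len(self.coordinates):
            raise ValueError("row_index must align with coordinates")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def pca_fit_transform(X: np.ndarray, n_components: int, seed: int = 0) -> Embedding:
    """PCA projection onto the top right-singular vectors of centred X.

    Deterministic: each component's sign is fixed so that its
    largest-magnitude loading is positive. ``seed`` is accepted for
    interface uniformity only; the computation is exact.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds min(n_samples, n_features)")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    Vt = Vt[:n_components]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(n_components), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    coords = Xc @ Vt.T
    var = s**2 / max(n - 1, 1)
    evr = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    cfg = ReducerConfig(method="pca", n_components=n_components, seed=seed)
    return Embedding(coords, cfg, np.arange(n),
                     {"explained_variance_ratio": evr, "components": Vt,
                      "mean": X.mean(axis=0)})


def jl_min_dimensions(n_samples: int, eps: float) -> int:
    """Johnson-Lindenstrauss minimum embedding dimension.

    ceil(4 ln(n) / (eps^2/2 - eps^3/3)): the smallest target dimension for
    which a Gaussian random projection preserves all pairwise squared
    distances of n points within a factor (1 +/- eps), with high probability.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0.0 < eps < 1.0:
        raise ValueError("eps must lie in (0, 1)")
    denom = eps**2 / 2.0 - eps**3 / 3.0
    return int(math.ceil(4.0 * math.log(n_samples) / denom))


def grp_fit_transform(X: np.ndarray, n_components: int, seed: int = 0) -> Embedding:
    """Gaussian random projection: X @ G with iid N(0, 1/n_components) entries.

    The 1/sqrt(n_components) scaling makes projected squared Euclidean
    distances unbiased estimates of the originals.
    """
    X = np.asarray(X, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((X.shape[1], n_components)) / np.sqrt(n_components)
    # ReducerConfig validates n_components >= 2; GRP itself admits k = 1,
    # so the recorded config floors at 2 while coordinates keep the true k
    cfg = ReducerConfig(method="grp", n_components=max(2, n_components), seed=seed)
    return Embedding(X @ G, cfg, np.arange(X.shape[0]), {"projection": G})


def manifold_reduce(X: np.ndarray, config: ReducerConfig) -> Embedding:
    """Run a neighbour-based manifold reducer (UMAP/TriMap/PaCMAP) adapter.

    Hyperparameters are forwarded verbatim; initialisation is left at each
    backend's default (PCA). A missing backend raises
    :class:`DependencyError` naming the method so a pipeline can continue
    with the remaining methods.
    """
    X = np.asarray(X, dtype=float)
    method = config.method
    try:
        if method == "umap":
            import umap
            model = umap.UMAP(n_components=config.n_components,
                              n_neighbors=config.n_neighbors,
                              metric=config.metric,
                              random_state=config.seed)
        elif method == "trimap":
            import trimap
            model = trimap.TRIMAP(n_dims=config.n_components,
                                  n_inliers=config.n_inliers,
                                  n_outliers=config.n_outliers,
                                  n_random=config.n_random,
                                  distance=config.metric)
        elif method == "pacmap":
            import pacmap
            model = pacmap.PaCMAP(n_components=config.n_components,
                                  n_neighbors=config.n_neighbors,
                                  MN_ratio=config.MN_ratio,
                                  FP_ratio=config.FP_ratio,
                                  random_state=config.seed)
        else:
            raise ValueError(f"{method!r} is not a manifold method")
    except ImportError as exc:
        raise DependencyError(
            f"backend for method {method!r} is not installed") from exc
    try:
        coords = model.fit_transform(X)
    except Exception as exc:  # surface backend failures with config context
        raise RuntimeError(f"{method} backend failed for config {config}") from exc
    return Embedding(np.asarray(coords, dtype=float), config, np.arange(X.shape[0]))


def reduce_matrix(X: np.ndarray, config: ReducerConfig) -> Embedding:
    """Dispatch any ReducerConfig to the corresponding stage."""
    if config.method == "pca":
        return pca_fit_transform(X, config.n_components, config.seed)
    if config.method == "grp":
        return grp_fit_transform(X, config.n_components, config.seed)
    if config.method == "identity":
        return Embedding(np.asarray(X, dtype=float), config,
                         np.arange(np.asarray(X).shape[0]))
    return manifold_reduce(X, config)


def subsample_for_reduction(table: CohortTable | np.ndarray, sample_size: int,
                            seed: int = 0):
    """Uniform seeded subsample without replacement.

    Returns ``(subset, index)``; reusing the same seed yields the same index
    for every method so metric folds stay matched across reducers.
    """
    n = len(table)
    if sample_size > n:
        raise ValueError(f"sample_size {sample_size} exceeds table size {n}")
    rng = np.random.default_rng(seed)
    index = np.sort(rng.choice(n, size=sample_size, replace=False))
    if isinstance(table, CohortTable):
        subset = CohortTable(table.values.iloc[index].reset_index(drop=True),
                             table.meta.iloc[index].reset_index(drop=True))
    else:
        subset = np.asarray(table)[index]
    return subset, index
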