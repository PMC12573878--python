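"""Unsupervised clustering of variable embeddings with silhouette-driven
model selection.

The pipeline reduces embedding dimensionality (identity / PCA / UMAP),
clusters the reduced vectors (K-means / hierarchical agglomerative /
HDBSCAN), and scores every (reduction, clusterer) configuration in a
grid with the silhouette coefficient, selecting the maximum.  The
silhouette is computed here from its definition, in the reduced space
with the Euclidean metric, because selection must score the very
representation that was clustered.  Density clustering may leave points
unassigned (NOISE); those are excluded from silhouette values and from
allocated-cluster counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import HDBSCAN, AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA

from .embedding import EmbeddingMatrix

logger = logging.getLogger(__name__)

#: Cluster id assigned to unclustered (noise) points.
NOISE = -1

#: Sentinel silhouette for configurations with < 2 clusters.
SILHOUETTE_SENTINEL = -1.0

REDUCTION_METHODS = ("identity", "pca", "umap")
CLUSTER_ALGORITHMS = ("kmeans", "hac", "hdbscan")


@dataclass(frozen=True)
class ReductionConfig:
    """Dimensionality-reduction stage configuration.

    The default target-dimension grid used in pipeline sweeps is
    {10, 50, 100, 200, 300}; ``seed`` makes the stochastic UMAP mapping
    deterministic.
    """

    method: str = "umap"
    target_dim: int = 50
    seed: int = 0
    n_neighbors: int = 15  # umap only

    def __post_init__(self) -> None:
        if self.method not in REDUCTION_METHODS:
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.method != "identity" and self.target_dim < 1:
            raise ValueError("target_dim must be positive")


DEFAULT_DIM_GRID = (10, 50, 100, 200, 300)

#: Default HDBSCAN minimum-cluster-size sweep (13 values), overridable.
DEFAULT_MIN_CLUSTER_SIZE_GRID = tuple(range(5, 70, 5))


@dataclass(frozen=True)
class ClustererConfig:
    """Clustering stage configuration; parameters present iff the
    algorithm requires them."""

    algorithm: str
    k: int | None = None                     # kmeans
    linkage_threshold: float | None = None   # hac
    min_cluster_size: int | None = None      # hdbscan
    min_samples: int | None = None           # hdbscan
    seed: int = 0
    hac_linkage: str = "average"
    hac_metric: str = "cosine"

    def __post_init__(self) -> None:
        algo = self.algorithm
        if algo not in CLUSTER_ALGORITHMS:
            raise ValueError(f"unknown clustering algorithm {algo!r}")
        required = {
            "kmeans": ("k",),
            "hac": ("linkage_threshold",),
            "hdbscan": ("min_cluster_size", "min_samples"),
        }[algo]
        allowed = set(required)
        for name in ("k", "linkage_threshold", "min_cluster_size", "min_samples"):
            val = getattr(self, name)
            if name in allowed:
                if val is None:
                    raise ValueError(f"{algo} requires parameter {name!r}")
            elif val is not None:
                raise ValueError(f"parameter {name!r} is not used by {algo}")
        if self.k is not None and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_cluster_size is not None and self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")

    def describe(self) -> str:
        if self.algorithm == "kmeans":
            return f"kmeans(k={self.k})"
        if self.algorithm == "hac":
            return f"hac(threshold={self.linkage_threshold})"
        return f"hdbscan({self.min_cluster_size},{self.min_samples})"


@dataclass(frozen=True)
class ClusterAssignment:
    """Variable -> cluster id; ids contiguous from 0, NOISE = -1."""

    assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        ids = sorted({c for c in self.assignment.values() if c != NOISE})
        if ids and ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def cluster_ids(self) -> tuple[int, ...]:
        return tuple(sorted({c for c in self.assignment.values() if c != NOISE}))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_noise(self) -> int:
        return sum(1 for c in self.assignment.values() if c == NOISE)

    def labels_for(self, identifiers: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in identifiers], dtype=int)


def reduce_dimensions(X: np.ndarray | EmbeddingMatrix,
                      cfg: ReductionConfig) -> np.ndarray:
    """Map an n x d matrix to n x target_dim; deterministic given the seed.

    ``identity`` returns the input unchanged.  PCA requires
    ``n >= target_dim``; UMAP requires ``n >= 3`` and clamps its
    neighbourhood size to n - 1.
    """
    if isinstance(X, EmbeddingMatrix):
        X = X.vectors
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    if cfg.method == "identity":
        return X.copy()
    if cfg.target_dim >= d:
        raise ValueError(
            f"target_dim {cfg.target_dim} must be below input dimension {d} "
            f"for method {cfg.method!r}"
        )
    if cfg.method == "pca":
        if n < cfg.target_dim:
            raise ValueError(f"pca needs at least target_dim={cfg.target_dim} rows")
        return PCA(n_components=cfg.target_dim, svd_solver="full",
                   random_state=cfg.seed).fit_transform(X)
    # umap — imported lazily: numba JIT makes the import itself expensive
    import umap

    if n < 3:
        raise ValueError("umap needs at least 3 rows")
    reducer = umap.UMAP(
        n_components=cfg.target_dim,
        n_neighbors=min(cfg.n_neighbors, n - 1),
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(X), dtype=np.float64)


def _contiguous_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel to 0..K-1 by order of first appearance; -1 stays NOISE."""
    out = np.full(len(raw), NOISE, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_assignments(X: np.ndarray, identifiers: Sequence[str],
                        cfg: ClustererConfig) -> ClusterAssignment:
    """Cluster reduced vectors; every point is assigned, except that
    HDBSCAN may label points NOISE."""
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    if len(identifiers) != n:
        raise ValueError("identifiers misaligned with matrix rows")
    if cfg.algorithm == "kmeans":
        if cfg.k > n:
            raise ValueError(f"k={cfg.k} exceeds number of points n={n}")
        model = KMeans(n_clusters=cfg.k, random_state=cfg.seed, n_init=10)
        raw = model.fit_predict(X)
    elif cfg.algorithm == "hac":
        model = AgglomerativeClustering(
            n_clusters=None,
            distance_threshold=cfg.linkage_threshold,
            linkage=cfg.hac_linkage,
            metric=cfg.hac_metric,
        )
        raw = model.fit_predict(X)
    else:
        model = HDBSCAN(min_cluster_size=cfg.min_cluster_size,
                        min_samples=cfg.min_samples, copy=True)
        raw = model.fit_predict(X)
    labels = _contiguous_labels(np.asarray(raw))
    return ClusterAssignment(dict(zip(identifiers, (int(c) for c in labels))))


def silhouette_score(X: np.ndarray,
                     a: ClusterAssignment | np.ndarray,
                     identifiers: Sequence[str] | None = None) -> float:
    """Mean silhouette coefficient over non-noise points, Euclidean metric.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the point's own cluster (0 for singletons, giving s(i) = 0) and b(i)
    the smallest mean distance to another cluster.  Fewer than two
    clusters after noise removal yields the sentinel -1 with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    if isinstance(a, ClusterAssignment):
        if identifiers is None:
            raise ValueError("identifiers required with a ClusterAssignment")
        labels = a.labels_for(identifiers)
    else:
        labels = np.asarray(a, dtype=int)
    keep = labels != NOISE
    X, labels = X[keep], labels[keep]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        warnings.warn("silhouette undefined for < 2 clusters; returning sentinel",
                      RuntimeWarning, stacklevel=2)
        return SILHOUETTE_SENTINEL
    D = cdist(X, X)
    n = len(labels)
    onehot = (labels[:, None] == uniq[None, :]).astype(np.float64)
    counts = onehot.sum(axis=0)
    sums = D @ onehot                      # n x K: total distance to each cluster
    own_col = np.searchsorted(uniq, labels)
    own_count = counts[own_col]
    s = np.zeros(n)
    multi = own_count > 1
    a_i = np.zeros(n)
    a_i[multi] = sums[np.arange(n), own_col][multi] / (own_count[multi] - 1)
    mean_other = sums / counts[None, :]
    mean_other[np.arange(n), own_col] = np.inf
    b_i = mean_other.min(axis=1)
    denom = np.maximum(a_i, b_i)
    s[multi] = (b_i[multi] - a_i[multi]) / denom[multi]
    # singletons contribute s = 0
    return float(s.mean())


@dataclass(frozen=True)
class GridRow:
    reduction: ReductionConfig
    clusterer: ClustererConfig
    n_clusters: int
    silhouette: float
    valid: bool
    assignment: ClusterAssignment


@dataclass(frozen=True)
class GridResult:
    rows: tuple[GridRow, ...]
    selected: GridRow

    def __post_init__(self) -> None:
        best = max(r.silhouette for r in self.rows if r.valid)
        if self.selected.silhouette < best:
            raise ValueError("selected row is not the silhouette maximum")


def select_best_configuration(
    E: EmbeddingMatrix | np.ndarray,
    reduction_grid: Sequence[ReductionConfig],
    clusterer_grid: Sequence[ClustererConfig],
    identifiers: Sequence[str] | None = None,
) -> GridResult:
    """Evaluate every (reduction, clusterer) pair and select the maximal
    silhouette; ties broken by fewer dimensions, then fewer clusters,
    then grid order."""
    if isinstance(E, EmbeddingMatrix):
        identifiers = E.identifiers
        X0 = E.vectors
    else:
        if identifiers is None:
            raise ValueError("identifiers required with a bare matrix")
        X0 = np.asarray(E, dtype=np.float64)
    if not reduction_grid or not clusterer_grid:
        raise ValueError("grids must be non-empty")

    rows: list[GridRow] = []
    for rcfg in reduction_grid:
        Xr = reduce_dimensions(X0, rcfg)
        eff_dim = Xr.shape[1]
        for ccfg in clusterer_grid:
            try:
                assignment = cluster_assignments(Xr, identifiers, ccfg)
            except ValueError as exc:
                logger.warning("configuration %s / %s failed: %s",
                               rcfg.method, ccfg.describe(), exc)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sil = silhouette_score(Xr, assignment, identifiers)
            valid = assignment.n_clusters >= 2
            rows.append(GridRow(
                reduction=replace(rcfg, target_dim=eff_dim)
                if rcfg.method == "identity" else rcfg,
                clusterer=ccfg,
                n_clusters=assignment.n_clusters,
                silhouette=sil if valid else SILHOUETTE_SENTINEL,
                valid=valid,
                assignment=assignment,
            ))
    valid_rows = [(i, r) for i, r in enumerate(rows) if r.valid]
    if not valid_rows:
        raise RuntimeError("no valid clustering: every configuration produced "
                           "fewer than 2 clusters")
    selected = min(
        valid_rows,
        key=lambda ir: (-ir[1].silhouette, ir[1].reduction.target_dim,
                        ir[1].n_clusters, ir[0]),
    )[1]
    return GridResult(rows=tuple(rows), selected=selected)
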