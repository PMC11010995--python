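"""Normalization, dimensionality reduction and graph-based clustering.

The processing contract is the standard droplet scRNA-seq recipe:
counts-per-10k log normalization, dispersion-ranked highly variable gene
selection, PCA on the top components (default 10) and modularity community
detection on a k-nearest-neighbor graph at resolution 0.8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .io import CountMatrix

__all__ = [
    "PreprocessConfig",
    "ClusterAssignment",
    "LogNormalizer",
    "SignedPCA",
    "DepthRegressor",
    "GraphClusterer",
    "normalize_log",
    "select_hvg",
    "embed_pca",
    "project_cells",
    "cluster_graph",
    "merge_indistinct_clusters",
    "majority_annotation",
]


@dataclass
class PreprocessConfig:
    target_sum: float = 1e4
    n_hvg: int = 2000
    n_pcs: int = 10
    knn_k: int = 20
    resolution: float = 0.8
    graph: str = "snn"          # "snn" (Jaccard-weighted) or "knn"
    regress_depth: bool = True  # remove residual library-size signal before PCA
    merge_indistinct: bool = True  # merge cluster pairs with no marker genes
    seed: int = 0

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for name in ("n_hvg", "n_pcs", "knn_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ClusterAssignment:
    """Per-cell integer labels plus per-cluster majority annotation."""

    labels: np.ndarray
    majority: dict = field(default_factory=dict)  # cluster -> (type, purity)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def majority_type(self, cluster: int) -> str:
        return self.majority[cluster][0]


class LogNormalizer(TransformerMixin, BaseEstimator):
    """ln(1 + count / libsize * target_sum), preserving sparse zeros."""

    def __init__(self, target_sum: float = 1e4):
        self.target_sum = target_sum

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = sp.csr_matrix(X, dtype=float)
        lib = np.asarray(X.sum(axis=1)).ravel()
        zero = np.flatnonzero(lib == 0)
        if zero.size:
            raise ValueError(f"cells with zero library size: rows {zero[:10].tolist()}")
        out = X.multiply((self.target_sum / lib)[:, None]).tocsr()
        out.data = np.log1p(out.data)
        return out


class SignedPCA(PCA):
    """PCA with a fixed sign convention: the largest-magnitude loading of
    every component is positive, so embeddings are reproducible across runs."""

    def fit(self, X, y=None):
        super().fit(np.asarray(X, dtype=float))
        flip = np.sign(
            self.components_[np.arange(self.components_.shape[0]),
                             np.argmax(np.abs(self.components_), axis=1)]
        )
        flip[flip == 0] = 1.0
        self.components_ *= flip[:, None]
        return self


class GraphClusterer(ClusterMixin, BaseEstimator):
    """Leiden modularity clustering on a KNN or shared-nearest-neighbor graph.

    ``graph='snn'`` weights edges by the Jaccard overlap of the two cells'
    neighbor lists (edges below ``prune`` are dropped), which is markedly
    more robust against splitting large homogeneous populations than the
    unweighted KNN graph.
    """

    def __init__(self, knn_k: int = 20, resolution: float = 0.8,
                 graph: str = "snn", prune: float = 1.0 / 15, seed: int = 0):
        self.knn_k = knn_k
        self.resolution = resolution
        self.graph = graph
        self.prune = prune
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] <= self.knn_k:
            raise ValueError(f"need more than knn_k={self.knn_k} cells")
        if self.graph == "snn":
            adj = kneighbors_graph(X, n_neighbors=self.knn_k,
                                   mode="connectivity", include_self=True)
            shared = (adj @ adj.T).tocoo()
            jac = shared.data / (2 * self.knn_k - shared.data)
            keep = (jac >= self.prune) & (shared.row < shared.col)
            edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
            weights = jac[keep].tolist()
        elif self.graph == "knn":
            adj = kneighbors_graph(X, n_neighbors=self.knn_k, mode="connectivity")
            adj = adj.maximum(adj.T).tocoo()
            edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
            weights = None
        else:
            raise ValueError(f"unknown graph type {self.graph!r}")
        g = igraph.Graph(n=X.shape[0], edges=edges)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=self.resolution,
            seed=self.seed,
            n_iterations=2,
        )
        raw = np.asarray(part.membership)
        # contiguous labels ordered by cluster size (ties by first occurrence)
        order = pd.Series(raw).value_counts(sort=True).index.to_numpy()
        remap = {int(c): k for k, c in enumerate(order)}
        self.labels_ = np.array([remap[int(c)] for c in raw])
        return self


def normalize_log(counts: CountMatrix, target_sum: float = 1e4) -> CountMatrix:
    """Counts-per-``target_sum`` log normalization of a CountMatrix."""
    X = counts.X
    lib = counts.library_sizes()
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = counts.cell_ids[zero[:10]].tolist()
        raise ValueError(f"cells with zero library size: {names}")
    norm = LogNormalizer(target_sum).transform(X)
    return CountMatrix(norm, counts.cell_ids, counts.gene_ids)


def select_hvg(normalized: CountMatrix, n_hvg: int,
               force_retain=(), n_bins: int = 20) -> list:
    """Highly variable genes by binned normalized dispersion.

    Dispersion is variance/mean of the log-normalized values; genes are
    binned by mean expression and the dispersion is z-scored within each
    bin before ranking, so selection is not dominated by expression level.
    ``force_retain`` genes (e.g. gate markers) are always kept.
    """
    n_genes = normalized.n_genes
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds {n_genes} genes")
    X = normalized.X
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    df = pd.DataFrame({"mean": mean, "disp": disp})
    n_bins = max(1, min(n_bins, n_genes // 10))  # keep bins populated
    df["bin"] = pd.cut(df["mean"].rank(method="first"), bins=n_bins, labels=False)
    grp = df.groupby("bin")["disp"]
    mu, sd = grp.transform("mean"), grp.transform("std").fillna(0.0)
    df["z"] = np.where(sd > 0, (df["disp"] - mu) / sd, 0.0)
    ranked = df.sort_values(["z", "disp"], ascending=False,
                            kind="mergesort").index.to_numpy()

    chosen = list(normalized.gene_ids[ranked[:n_hvg]])
    for g in force_retain:
        if g not in chosen:
            if g not in normalized._gene_index:
                raise KeyError(f"force-retained gene {g!r} not in matrix")
            chosen.append(g)
    return chosen


class DepthRegressor(TransformerMixin, BaseEstimator):
    """Residualize each gene on (centered) log library size.

    Log normalization leaves a residual depth signature through the zero
    pattern (deeper cells detect more genes); without removal it becomes a
    dominant principal component and fragments clusters by sequencing depth.
    """

    def fit(self, X, log_libsize):
        l = np.asarray(log_libsize, dtype=float)
        self.libsize_mean_ = float(l.mean())
        C = np.column_stack([np.ones(l.size), l - self.libsize_mean_])
        self.beta_, *_ = np.linalg.lstsq(C, np.asarray(X, dtype=float), rcond=None)
        return self

    def transform(self, X, log_libsize):
        l = np.asarray(log_libsize, dtype=float)
        C = np.column_stack([np.ones(l.size), l - self.libsize_mean_])
        return np.asarray(X, dtype=float) - C @ self.beta_


def embed_pca(normalized: CountMatrix, n_pcs: int = 10, seed: int = 0,
              log_libsize: np.ndarray | None = None):
    """PCA embedding (cells x n_pcs) with the fixed sign convention.

    If ``log_libsize`` is given (log raw library sizes), depth is
    regressed out of every gene first and the fitted regressor is attached
    to the returned model as ``pca.depth_regressor_`` so held-out cells
    can be projected consistently.  Returns ``(embedding, fitted
    SignedPCA)``; if the data rank is below ``n_pcs`` the available
    components are returned with a warning.
    """
    X = np.asarray(normalized.X.todense(), dtype=float)
    depth = None
    if log_libsize is not None:
        depth = DepthRegressor().fit(X, log_libsize)
        X = depth.transform(X, log_libsize)
    rank_cap = min(X.shape)
    if n_pcs > rank_cap:
        warnings.warn(f"n_pcs={n_pcs} exceeds data rank bound {rank_cap}; truncating")
        n_pcs = rank_cap
    pca = SignedPCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    pca.fit(X)
    keep = pca.explained_variance_ > 1e-12
    if not keep.all():
        warnings.warn(
            f"data rank {int(keep.sum())} below requested {n_pcs} components")
        pca.components_ = pca.components_[keep]
        pca.explained_variance_ = pca.explained_variance_[keep]
        pca.explained_variance_ratio_ = pca.explained_variance_ratio_[keep]
        pca.n_components_ = int(keep.sum())
    pca.depth_regressor_ = depth
    return pca.transform(X), pca


def project_cells(pca: SignedPCA, normalized_dense: np.ndarray,
                  log_libsize: np.ndarray | None = None) -> np.ndarray:
    """Project held-out cells with a fitted embedding (depth-consistent)."""
    X = np.asarray(normalized_dense, dtype=float)
    if getattr(pca, "depth_regressor_", None) is not None:
        if log_libsize is None:
            raise ValueError("embedding was depth-regressed; pass log_libsize")
        X = pca.depth_regressor_.transform(X, log_libsize)
    return pca.transform(X)


def cluster_graph(embedding, knn_k: int = 20, resolution: float = 0.8,
                  seed: int = 0, graph: str = "snn") -> ClusterAssignment:
    """Leiden clustering of the embedding's (shared-)nearest-neighbor graph."""
    labels = GraphClusterer(knn_k=knn_k, resolution=resolution, graph=graph,
                            seed=seed).fit(embedding).labels_
    return ClusterAssignment(labels=labels)


def merge_indistinct_clusters(normalized: CountMatrix,
                              clusters: ClusterAssignment,
                              alpha: float = 0.05, min_pct: float = 0.1,
                              logfc_threshold: float = 0.25,
                              max_cells_per_cluster: int = 1500,
                              seed: int = 0) -> ClusterAssignment:
    """Merge cluster pairs with no significant marker genes between them.

    Graph clustering at a fixed resolution can subdivide a homogeneous
    population (typically the largest one, along residual technical
    structure).  A split is only biologically meaningful if some gene
    distinguishes the two sides, so the closest pair of cluster centroids
    is tested with the marker criteria (detection >= ``min_pct``,
    |log2FC| >= ``logfc_threshold``, Bonferroni-adjusted Wilcoxon p <
    ``alpha``) and merged when nothing passes; repeat until every
    remaining pair is distinct.  Large clusters are subsampled to
    ``max_cells_per_cluster`` cells for the test.
    """
    from .de import find_markers  # local import: de depends only on io

    labels = clusters.labels.copy()
    rng = np.random.default_rng(seed)
    X = normalized.X
    tested_distinct: set = set()
    budget = 12  # cap on pairwise DE tests per call

    def centroid(c):
        return np.asarray(X[labels == c].mean(axis=0)).ravel()

    while budget > 0:
        ids = np.unique(labels)
        if ids.size < 2:
            break
        cents = {c: centroid(c) for c in ids}
        pairs = sorted(
            ((a, b) for i, a in enumerate(ids) for b in ids[i + 1:]
             if (a, b) not in tested_distinct),
            key=lambda ab: float(np.sum((cents[ab[0]] - cents[ab[1]]) ** 2)),
        )
        merged = False
        for a, b in pairs:
            ga = np.flatnonzero(labels == a)
            gb = np.flatnonzero(labels == b)
            if ga.size < 3 or gb.size < 3:
                tested_distinct.add((a, b))
                continue
            if ga.size > max_cells_per_cluster:
                ga = rng.choice(ga, max_cells_per_cluster, replace=False)
            if gb.size > max_cells_per_cluster:
                gb = rng.choice(gb, max_cells_per_cluster, replace=False)
            budget -= 1
            table = find_markers(normalized, normalized.cell_ids[ga],
                                 normalized.cell_ids[gb], min_pct=min_pct,
                                 logfc_threshold=logfc_threshold)
            if not (table["p_val_adj"] < alpha).any():
                labels[labels == b] = a
                merged = True
                break
            tested_distinct.add((a, b))
            if budget <= 0:
                break
        if not merged:
            break

    order = pd.Series(labels).value_counts().index.to_numpy()
    remap = {int(c): k for k, c in enumerate(order)}
    return ClusterAssignment(labels=np.array([remap[int(c)] for c in labels]))


def majority_annotation(clusters: ClusterAssignment, cell_types) -> ClusterAssignment:
    """Annotate each cluster with its plurality cell type and purity.

    Ties are broken by lexicographic type name.
    """
    cell_types = np.asarray(cell_types, dtype=object)
    if len(cell_types) != len(clusters.labels):
        raise ValueError("cell_types must align with cluster labels")
    majority = {}
    for c in np.unique(clusters.labels):
        counts = pd.Series(cell_types[clusters.labels == c]).value_counts()
        top = counts[counts == counts.max()]
        name = sorted(top.index)[0]
        majority[int(c)] = (name, float(counts[name] / counts.sum()))
    return ClusterAssignment(labels=clusters.labels, majority=majority)
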