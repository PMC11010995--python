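"""Statistical separation of true hybrid cells from droplet doublets.

If gated cells were droplet doublets of an epithelial and a myeloid cell,
they should land near the epithelial and myeloid clusters in roughly the
proportion an *artificial* doublet population does (about half each when
library sizes are symmetric).  True fusion hybrids instead skew heavily
toward myeloid clusters.  This module builds that empirical null
(simulated doublets projected into the observed map), tests the observed
placement with an exact binomial test, and checks for a bimodal doublet
score distribution (a small high-score mode of residual true doublets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.mixture import GaussianMixture

from .io import CountMatrix
from .preprocess import (PreprocessConfig, cluster_graph, embed_pca,
                         majority_annotation, normalize_log, project_cells,
                         select_hvg)

__all__ = [
    "ReferenceMap",
    "NullPlacement",
    "SkewTestResult",
    "BimodalityResult",
    "fit_reference_map",
    "doublet_assignment_null",
    "test_myeloid_skew",
    "test_bimodality",
]


@dataclass
class NullPlacement:
    fraction: float          # null fraction of doublets placed in myeloid clusters
    mc_se: float             # Monte-Carlo standard error
    n_sim: int
    placements: np.ndarray = field(repr=False)  # per-doublet myeloid boolean


@dataclass
class SkewTestResult:
    n_hybrids: int
    n_myeloid_placed: int
    observed_fraction: float
    null_fraction: float
    p_value: float


@dataclass
class BimodalityResult:
    delta_bic: float         # BIC(2 components) - BIC(1 component)
    minor_weight: float      # weight of the high-score component
    decision: str            # "bimodal" | "unimodal"
    flagged: bool = False    # degenerate-variance regularization applied


@dataclass
class ReferenceMap:
    """Embedding + annotated clusters fitted on real cells, reusable for
    placing held-out count vectors (artificial doublets, gated hybrids)."""

    pca: object
    hvg_cols: np.ndarray
    centroids: np.ndarray
    cluster_lineages: list          # majority lineage per cluster
    myeloid_clusters: set
    target_sum: float
    embedding: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)

    def place(self, raw_rows: sp.spmatrix) -> np.ndarray:
        """Nearest-centroid cluster index for raw count rows."""
        raw = sp.csr_matrix(raw_rows, dtype=float)
        lib = np.asarray(raw.sum(axis=1)).ravel()
        if (lib == 0).any():
            raise ValueError("cannot place cells with zero library size")
        dn = raw.multiply((self.target_sum / lib)[:, None]).tocsr()
        dn.data = np.log1p(dn.data)
        proj = project_cells(self.pca,
                             np.asarray(dn[:, self.hvg_cols].todense()),
                             log_libsize=np.log(lib))
        return np.argmin(cdist(proj, self.centroids), axis=1)

    def myeloid_placed(self, raw_rows: sp.spmatrix) -> np.ndarray:
        return np.array([c in self.myeloid_clusters for c in self.place(raw_rows)])


def fit_reference_map(counts: CountMatrix, lineages,
                      preprocess: PreprocessConfig | None = None) -> ReferenceMap:
    """Fit normalization, HVG, depth-regressed PCA and annotated Leiden
    clusters on real cells; ``lineages`` gives each cell's lineage label
    (e.g. epithelial / myeloid / other)."""
    cfg = preprocess or PreprocessConfig()
    lineages = np.asarray(lineages, dtype=object)
    norm = normalize_log(counts, cfg.target_sum)
    hvg = select_hvg(norm, min(cfg.n_hvg, counts.n_genes))
    hvg_cols = counts.gene_indices(hvg)
    loglib = np.log(counts.library_sizes()) if cfg.regress_depth else None
    emb, pca = embed_pca(norm.subset_genes(hvg), cfg.n_pcs, seed=cfg.seed,
                         log_libsize=loglib)
    clusters = cluster_graph(emb, cfg.knn_k, cfg.resolution, cfg.seed,
                             graph=cfg.graph)
    if cfg.merge_indistinct:
        from .preprocess import merge_indistinct_clusters

        clusters = merge_indistinct_clusters(norm, clusters, seed=cfg.seed)
    clusters = majority_annotation(clusters, lineages)
    lineage_of = [clusters.majority_type(c) for c in range(clusters.n_clusters)]
    centroids = np.vstack([emb[clusters.labels == c].mean(axis=0)
                           for c in range(clusters.n_clusters)])
    return ReferenceMap(
        pca=pca, hvg_cols=hvg_cols, centroids=centroids,
        cluster_lineages=lineage_of,
        myeloid_clusters={c for c, t in enumerate(lineage_of) if t == "myeloid"},
        target_sum=cfg.target_sum, embedding=emb, labels=clusters.labels,
    )


def doublet_assignment_null(counts: CountMatrix, epithelial_ids, myeloid_ids,
                            n_sim: int = 1000,
                            preprocess: PreprocessConfig | None = None,
                            seed: int = 0,
                            reference: ReferenceMap | None = None) -> NullPlacement:
    """Fraction of artificial epithelial x myeloid doublets landing in
    myeloid clusters of the observed map.

    The map (normalization, HVG, depth-regressed PCA, Leiden clusters) is
    fitted on the real cells only; artificial doublets are summed raw
    count vectors of random parent pairs, normalized with their own
    library size, projected with the fitted loadings, and assigned to the
    nearest cluster centroid.
    """
    epithelial_ids = list(epithelial_ids)
    myeloid_ids = list(myeloid_ids)
    if not epithelial_ids or not myeloid_ids:
        raise ValueError("both parent pools must be non-empty")
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} < 100: the null fraction will be unstable")

    cell_pos = {c: i for i, c in enumerate(counts.cell_ids)}
    epi_idx = np.array([cell_pos[c] for c in epithelial_ids])
    mye_idx = np.array([cell_pos[c] for c in myeloid_ids])

    if reference is None:
        lineage = np.full(counts.n_cells, "other", dtype=object)
        lineage[epi_idx] = "epithelial"
        lineage[mye_idx] = "myeloid"
        reference = fit_reference_map(counts, lineage, preprocess)

    rng = np.random.default_rng(seed)
    a = rng.choice(epi_idx, size=n_sim)
    b = rng.choice(mye_idx, size=n_sim)
    placed = reference.myeloid_placed(counts.X[a] + counts.X[b])
    frac = float(placed.mean())
    se = float(np.sqrt(max(frac * (1 - frac), 1e-12) / n_sim))
    return NullPlacement(fraction=frac, mc_se=se, n_sim=n_sim, placements=placed)


def test_myeloid_skew(n_hybrids: int, n_myeloid_placed: int,
                      null_fraction: float) -> SkewTestResult:
    """Exact two-sided binomial test of myeloid placement.

    The p-value sums the probabilities of all outcomes no more likely than
    the observed one under Binomial(n_hybrids, null_fraction).
    """
    if not 0.0 < null_fraction < 1.0:
        raise ValueError("null_fraction must lie strictly in (0, 1)")
    if n_myeloid_placed > n_hybrids:
        raise ValueError("n_myeloid_placed cannot exceed n_hybrids")
    p = stats.binomtest(n_myeloid_placed, n_hybrids, null_fraction,
                        alternative="two-sided").pvalue
    return SkewTestResult(
        n_hybrids=n_hybrids,
        n_myeloid_placed=n_myeloid_placed,
        observed_fraction=n_myeloid_placed / n_hybrids,
        null_fraction=null_fraction,
        p_value=float(p),
    )


def test_bimodality(scores, delta_bic_cutoff: float = -10.0,
                    seed: int = 0) -> BimodalityResult:
    """Gaussian-mixture check for a second (high-score) mode.

    Fits 1- and 2-component mixtures; the distribution is called bimodal
    when the 2-component model improves BIC by more than ``-cutoff``.
    Reports the weight of the higher-mean component — the "small fraction
    of cells with high doublet scores" a residual doublet population
    would produce.  The decision is invariant to affine rescaling.
    """
    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ValueError("bimodality test needs at least 20 scores")
    flagged = False
    reg = 1e-6 * max(float(x.var()), 1e-12)
    if x.var() < 1e-12:
        flagged = True
        reg = 1e-6
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             n_init=5, reg_covar=reg, random_state=seed)
        gm.fit(x)
        fits[k] = gm
    delta = float(fits[2].bic(x) - fits[1].bic(x))
    means = fits[2].means_.ravel()
    minor_weight = float(fits[2].weights_[np.argmax(means)])
    decision = "bimodal" if delta < delta_bic_cutoff else "unimodal"
    return BimodalityResult(delta_bic=delta, minor_weight=minor_weight,
                            decision=decision, flagged=flagged)
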