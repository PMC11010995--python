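"""Marker co-expression gates calling hybrid cells, and abundance summaries.

A hybrid cell is called when it detects every epithelial marker AND every
myeloid marker at or above ``min_count`` raw counts (default: EPCAM, KRT8,
CD14, CD163 all > 0), optionally requiring its combined doublet score to be
at or below a removal threshold.  Gates operate on raw counts, so calls are
invariant under normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .doublets import DoubletScoreSet, DoubletThreshold
from .io import CountMatrix
from .preprocess import ClusterAssignment
from .simdata import MYELOID_TYPES

__all__ = [
    "GateSpec",
    "HybridCallSet",
    "HybridGate",
    "call_hybrids",
    "call_hybrids_relaxed",
    "summarize_by_group",
    "enrichment_ratio",
    "cluster_colocalization",
]


@dataclass
class GateSpec:
    epithelial_markers: tuple = ("EPCAM", "KRT8")
    myeloid_markers: tuple = ("CD14", "CD163")
    min_count: int = 1
    apply_doublet_filter: bool = False
    threshold: DoubletThreshold | None = None

    def validate(self) -> None:
        if not self.epithelial_markers or not self.myeloid_markers:
            raise ValueError("both marker lists must be non-empty")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.apply_doublet_filter and self.threshold is None:
            raise ValueError("doublet filter requested without a threshold")

    @property
    def all_markers(self) -> tuple:
        return tuple(self.epithelial_markers) + tuple(self.myeloid_markers)


@dataclass
class HybridCallSet:
    is_hybrid: np.ndarray  # per-cell boolean
    cell_ids: np.ndarray

    @property
    def hybrid_cell_ids(self) -> np.ndarray:
        return self.cell_ids[self.is_hybrid]

    @property
    def n_total(self) -> int:
        return int(self.is_hybrid.size)

    @property
    def n_hybrids(self) -> int:
        return int(self.is_hybrid.sum())

    @property
    def fraction(self) -> float:
        return self.n_hybrids / self.n_total if self.n_total else 0.0


class HybridGate(BaseEstimator):
    """Boolean AND gate over marker detection, as a predictor.

    ``predict(X)`` needs gene identity for the columns of ``X``; pass
    ``genes`` at construction when scoring bare arrays, or call the
    :func:`call_hybrids` wrapper with a :class:`CountMatrix`.
    """

    def __init__(self, gate: GateSpec = None, genes=None):
        self.gate = gate
        self.genes = genes

    def fit(self, X=None, y=None):
        return self

    def predict(self, X, scores: np.ndarray | None = None) -> np.ndarray:
        gate = self.gate or GateSpec()
        gate.validate()
        gene_index = {g: i for i, g in enumerate(self.genes)}
        missing = [g for g in gate.all_markers if g not in gene_index]
        if missing:
            raise KeyError(f"gate genes missing from matrix: {missing}")
        mask = np.ones(X.shape[0], dtype=bool)
        for g in gate.all_markers:
            col = np.asarray(X[:, gene_index[g]].todense()).ravel() \
                if hasattr(X, "todense") else np.asarray(X)[:, gene_index[g]]
            mask &= col >= gate.min_count
        if gate.apply_doublet_filter:
            if scores is None:
                raise ValueError("gate requires doublet scores for filtering")
            mask &= np.asarray(scores) <= gate.threshold.value
        return mask


def call_hybrids(counts: CountMatrix, gate: GateSpec,
                 scores: DoubletScoreSet | np.ndarray | None = None) -> HybridCallSet:
    """Apply a multi-marker gate (plus optional doublet filter) to raw counts."""
    score_vec = None
    if gate.apply_doublet_filter:
        if scores is None:
            raise ValueError("apply_doublet_filter=True requires doublet scores")
        score_vec = scores.hybrid_score if isinstance(scores, DoubletScoreSet) else scores
        if len(score_vec) != counts.n_cells:
            raise ValueError("doublet scores do not align with cells")
    mask = HybridGate(gate, genes=counts.gene_ids).predict(counts.X, scores=score_vec)
    return HybridCallSet(is_hybrid=mask, cell_ids=counts.cell_ids)


def call_hybrids_relaxed(counts: CountMatrix, epithelial_gene: str = "EPCAM",
                         myeloid_gene: str = "CD163") -> HybridCallSet:
    """Two-gene relaxed gate (one epithelial x one myeloid marker, no filter)."""
    gate = GateSpec(epithelial_markers=(epithelial_gene,),
                    myeloid_markers=(myeloid_gene,))
    return call_hybrids(counts, gate)


def summarize_by_group(calls: HybridCallSet, cells: pd.DataFrame,
                       group_key: str) -> pd.DataFrame:
    """Hybrid counts and fractions per metadata group (zero groups included)."""
    if group_key not in cells.columns:
        raise KeyError(f"unknown group key {group_key!r}")
    if len(cells) != calls.n_total:
        raise ValueError("cell table does not align with calls")
    df = pd.DataFrame({group_key: cells[group_key].to_numpy(),
                       "is_hybrid": calls.is_hybrid})
    out = df.groupby(group_key, sort=True).agg(
        n_cells=("is_hybrid", "size"), n_hybrids=("is_hybrid", "sum"))
    out["fraction"] = out["n_hybrids"] / out["n_cells"]
    return out.reset_index()


def enrichment_ratio(frac_a: float, frac_b: float) -> float:
    """Fold enrichment frac_a / frac_b (infinite, with a warning, if b = 0)."""
    if frac_b == 0:
        warnings.warn("denominator fraction is zero; enrichment is infinite")
        return float("inf")
    return frac_a / frac_b


def _lineage_of(cell_type: str) -> str:
    if cell_type in MYELOID_TYPES or cell_type == "myeloid":
        return "myeloid"
    if cell_type == "epithelial":
        return "epithelial"
    return "other"


def cluster_colocalization(calls: HybridCallSet,
                           clusters: ClusterAssignment) -> pd.DataFrame:
    """Where hybrid cells sit: fraction per majority-lineage cluster class.

    Each hybrid's cluster is mapped to the lineage of the cluster's
    majority type (myeloid / epithelial / other); fractions sum to 1.
    """
    if len(clusters.labels) != calls.n_total:
        raise ValueError("cluster labels do not align with calls")
    hybrid_clusters = clusters.labels[calls.is_hybrid]
    lineages = []
    for c in hybrid_clusters:
        if int(c) not in clusters.majority:
            warnings.warn(f"cluster {c} has no annotation; counted as 'other'")
            lineages.append("other")
        else:
            lineages.append(_lineage_of(clusters.majority_type(int(c))))
    counts = pd.Series(lineages).value_counts()
    out = pd.DataFrame({
        "lineage": ["myeloid", "epithelial", "other"],
    })
    out["n_hybrids"] = [int(counts.get(l, 0)) for l in out["lineage"]]
    total = out["n_hybrids"].sum()
    out["fraction"] = out["n_hybrids"] / total if total else 0.0
    return out
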