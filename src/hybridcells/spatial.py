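"""In-situ spatial cell-feature matrices: reading, gating, neighborhoods.

Targeted in-situ platforms yield per-cell counts over a small gene panel
plus cell centroids in micrometers.  Hybrid calling applies the same raw
count marker gate as the scRNA-seq analysis (no doublet filter: in-situ
segmentation already yields single cells), classifies the remaining cells
as epithelial / myeloid / other, and exports viewer annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .gate import GateSpec, HybridGate
from .io import CountMatrix, read_mtx_dir, write_mtx_dir

__all__ = [
    "SpatialCellTable",
    "read_spatial_dir",
    "write_spatial_dir",
    "gate_spatial",
    "export_annotations",
    "read_annotations",
    "neighborhood_composition",
]

_CENTROID_COLS = ("x_centroid", "y_centroid")
_GROUPS = ("hybrid", "epithelial", "myeloid", "other")


@dataclass
class SpatialCellTable:
    """Panel-restricted counts joined to per-cell centroids (micrometers)."""

    counts: CountMatrix
    cells: pd.DataFrame  # cell_id, x_centroid, y_centroid, total_counts, flags

    def __post_init__(self) -> None:
        if len(self.cells) != self.counts.n_cells:
            raise ValueError("cells table does not align with count matrix")
        xy = self.cells[list(_CENTROID_COLS)].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("centroid coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.counts.n_cells


def read_spatial_dir(path, max_unmatched: float = 0.01) -> SpatialCellTable:
    """Read an MTX trio plus ``cells.csv`` and join counts to centroids.

    Cells present in only one of the two sources are dropped with a report;
    a mismatch above ``max_unmatched`` of cells is an error.
    """
    path = Path(path)
    counts = read_mtx_dir(path)
    cells = pd.read_csv(path / "cells.csv")
    missing_cols = [c for c in ("cell_id",) + _CENTROID_COLS if c not in cells.columns]
    if missing_cols:
        raise ValueError(f"cells.csv lacks required columns: {missing_cols}")
    cells["cell_id"] = cells["cell_id"].astype(str)

    matrix_ids = pd.Index(counts.cell_ids.astype(str))
    shared = matrix_ids.intersection(cells["cell_id"])
    n_union = len(matrix_ids.union(cells["cell_id"]))
    unmatched = n_union - len(shared)
    if unmatched > max_unmatched * n_union:
        raise ValueError(
            f"{unmatched}/{n_union} cell ids unmatched between matrix and cells.csv")

    cells = (cells.set_index("cell_id").loc[shared]
             .rename_axis("cell_id").reset_index())
    counts = counts.subset_cells(matrix_ids.get_indexer(shared))
    if "total_counts" not in cells.columns:
        cells["total_counts"] = counts.library_sizes().astype(int)
    return SpatialCellTable(counts, cells)


def write_spatial_dir(path, table: SpatialCellTable) -> None:
    path = Path(path)
    write_mtx_dir(path, table.counts)
    table.cells.to_csv(path / "cells.csv", index=False)


def gate_spatial(table: SpatialCellTable, gate: GateSpec) -> pd.DataFrame:
    """Classify every cell as hybrid / epithelial / myeloid / other.

    ``is_hybrid`` is the full AND gate over both marker lists (no doublet
    filter); ``is_epithelial``/``is_myeloid`` require the corresponding
    marker list only and exclude hybrids, so the three flags are mutually
    exclusive.  Adds the flags and a ``group`` column to ``table.cells``
    (in place) and returns a per-group fraction summary.
    """
    gate.validate()
    X, genes = table.counts.X, table.counts.gene_ids
    epi = HybridGate(GateSpec(gate.epithelial_markers, gate.epithelial_markers,
                              gate.min_count), genes=genes).predict(X)
    mye = HybridGate(GateSpec(gate.myeloid_markers, gate.myeloid_markers,
                              gate.min_count), genes=genes).predict(X)
    hybrid = epi & mye
    table.cells["is_hybrid"] = hybrid
    table.cells["is_epithelial"] = epi & ~hybrid
    table.cells["is_myeloid"] = mye & ~hybrid
    group = np.full(table.n_cells, "other", dtype=object)
    group[table.cells["is_myeloid"]] = "myeloid"
    group[table.cells["is_epithelial"]] = "epithelial"
    group[hybrid] = "hybrid"
    table.cells["group"] = group

    n = table.n_cells
    summary = pd.DataFrame({
        "group": list(_GROUPS),
        "n_cells": [int((group == g).sum()) for g in _GROUPS],
    })
    summary["fraction"] = summary["n_cells"] / n
    return summary


def export_annotations(table: SpatialCellTable, path) -> None:
    """Viewer annotation CSV: one ``cell_id, group`` row per cell."""
    if "group" not in table.cells.columns:
        raise ValueError("run gate_spatial before exporting annotations")
    table.cells[["cell_id", "group"]].to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path)


def neighborhood_composition(table: SpatialCellTable, radius: float) -> pd.DataFrame:
    """Class composition of each hybrid cell's neighborhood.

    For every hybrid cell, the fractions of hybrid/epithelial/myeloid/other
    cells whose centroids lie within ``radius`` micrometers (self excluded).
    Hybrids with no neighbors in range get NaN fractions and are flagged.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if "group" not in table.cells.columns:
        raise ValueError("run gate_spatial before neighborhood analysis")
    xy = table.cells[list(_CENTROID_COLS)].to_numpy(dtype=float)
    group = table.cells["group"].to_numpy()
    tree = cKDTree(xy)
    rows = []
    for i in np.flatnonzero(table.cells["is_hybrid"].to_numpy()):
        nb = [j for j in tree.query_ball_point(xy[i], r=radius) if j != i]
        row = {"cell_id": table.cells["cell_id"].iloc[i], "n_neighbors": len(nb)}
        if nb:
            labels = group[nb]
            for g in _GROUPS:
                row[f"frac_{g}"] = float((labels == g).mean())
            row["isolated"] = False
        else:
            for g in _GROUPS:
                row[f"frac_{g}"] = float("nan")
            row["isolated"] = True
        rows.append(row)
    return pd.DataFrame(rows)
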