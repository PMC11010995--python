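"""Synthetic single-cell and in-situ data with known hybrid cells and doublets.

The generator plants the structures the downstream analysis must detect:

* four singlet programs (epithelial, monocyte, macrophage, other) with
  lineage marker genes strongly enriched in their owning lineage;
* rare true hybrid cells whose expected expression is a convex mixture
  ``lambda * mu_epithelial + (1 - lambda) * mu_macrophage`` plus a small set
  of hybrid-private genes up-regulated relative to both parents;
* droplet doublets formed by summing the raw count vectors of two real cells;
* a tumor/normal tissue split with different myeloid abundance, and
* a low-plex spatial panel with cell centroids in micrometers.

Counts follow a negative binomial (gamma-Poisson) law with a shared
dispersion and log-normal library sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_mtx_dir

__all__ = [
    "SimConfig",
    "make_programs",
    "simulate_cells",
    "inject_doublets",
    "simulate_spatial",
    "write_simulation",
    "MYELOID_TYPES",
]

#: cell types counted as the myeloid lineage
MYELOID_TYPES = ("monocyte", "macrophage")

#: which simulated cell types own which marker lineage
_LINEAGE_TYPES = {"epithelial": ("epithelial",), "myeloid": MYELOID_TYPES}


def _default_cells_per_type() -> dict:
    return {"epithelial": 1900, "monocyte": 400, "macrophage": 500, "other": 2200}


def _default_markers() -> dict:
    return {
        "epithelial": ["EPCAM", "KRT8", "KRT18", "KRT19"],
        "myeloid": ["CD14", "CD163", "CD68", "AIF1"],
    }


def _default_private() -> dict:
    # log2 effect sizes relative to the mixed parental background
    return {"SPP1": 2.0, "CD44": 1.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: ~5,000 cells across four
    programs, 2,000 genes, 1% true hybrids biased 90% toward tumor tissue,
    5% droplet doublets, myeloid abundance 14.8% in tumor vs 2.4% in
    normal tissue, and a log-normal library-size law around ~2,500 counts.
    The hybrid mixing weight ``lambda`` (epithelial share) defaults to
    Uniform(0.2, 0.5): hybrid transcriptomes are weighted toward the
    macrophage parent, consistent with hybrid cells being found within
    myeloid rather than epithelial clusters.
    """

    n_genes: int = 2000
    cells_per_type: dict = field(default_factory=_default_cells_per_type)
    marker_genes: dict = field(default_factory=_default_markers)
    hybrid_fraction: float = 0.01
    hybrid_tumor_share: float = 0.9
    doublet_rate: float = 0.05
    mixing_weight_range: tuple = (0.2, 0.5)
    hybrid_private_genes: dict = field(default_factory=_default_private)
    nb_dispersion: float = 0.15
    libsize_meanlog: float = math.log(2500.0)
    libsize_sdlog: float = 0.35
    tumor_myeloid_frac: float = 0.148
    normal_myeloid_frac: float = 0.024
    marker_strength: float = 20.0
    marker_leak: float = 0.002
    gamma_shape: float = 0.5
    gamma_scale: float = 2.0
    n_samples_per_tissue: int = 2
    seed: int = 0

    def validate(self) -> None:
        for name in ("hybrid_fraction", "hybrid_tumor_share", "doublet_rate",
                     "tumor_myeloid_frac", "normal_myeloid_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        lo, hi = self.mixing_weight_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("mixing_weight_range must lie strictly inside (0, 1)")
        all_markers = [g for gs in self.marker_genes.values() for g in gs]
        if len(set(all_markers)) != len(all_markers):
            raise ValueError("marker lists must be disjoint across lineages")
        if set(all_markers) & set(self.hybrid_private_genes):
            raise ValueError("hybrid private genes must not be marker genes")
        named = len(all_markers) + len(self.hybrid_private_genes)
        if self.n_genes < named:
            raise ValueError(f"n_genes={self.n_genes} < {named} named genes")
        if not 0.0 < self.marker_leak <= 0.1:
            raise ValueError("marker_leak must be in (0, 0.1] to keep >=10x enrichment")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    @property
    def cell_types(self) -> list:
        return list(self.cells_per_type)

    def gene_names(self) -> list:
        named = [g for gs in self.marker_genes.values() for g in gs]
        named += list(self.hybrid_private_genes)
        n_fill = self.n_genes - len(named)
        return named + [f"GENE{i:05d}" for i in range(1, n_fill + 1)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage
    return np.random.default_rng([config.seed, stream])


def make_programs(config: SimConfig) -> pd.DataFrame:
    """Mean-expression program per cell type (types x genes).

    Marker genes get mean ``marker_strength`` in their owning lineage and
    ``marker_strength * marker_leak`` elsewhere (guaranteeing >=10x
    enrichment); all other means are i.i.d. gamma draws.
    """
    config.validate()
    rng = _rng(config, 0)
    genes = config.gene_names()
    types = config.cell_types
    means = rng.gamma(config.gamma_shape, config.gamma_scale,
                      size=(len(types), config.n_genes))
    prog = pd.DataFrame(means, index=types, columns=genes)
    for lineage, markers in config.marker_genes.items():
        owners = [t for t in _LINEAGE_TYPES.get(lineage, ()) if t in types]
        for g in markers:
            prog[g] = config.marker_strength * config.marker_leak
            prog.loc[owners, g] = config.marker_strength
    return prog


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson sample with Var = mu + dispersion * mu^2."""
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam).astype(np.int32)


def simulate_cells(config: SimConfig, programs: pd.DataFrame):
    """Draw singlets and true hybrids; returns ``(CountMatrix, truth)``.

    The truth table has one row per matrix row with columns
    ``cell_id, true_label, tissue, sample_id, lambda, parent_a, parent_b``.
    """
    config.validate()
    rng = _rng(config, 1)
    types = config.cell_types
    prog = programs.loc[types].to_numpy(dtype=float)
    prog_norm = prog / prog.sum(axis=1, keepdims=True)
    genes = list(programs.columns)
    gene_pos = {g: j for j, g in enumerate(genes)}

    labels = np.concatenate([
        np.repeat(t, n) for t, n in config.cells_per_type.items()
    ])
    n_singlets = len(labels)
    n_hybrids = int(round(config.hybrid_fraction * n_singlets))
    if n_hybrids and not {"epithelial", "macrophage"} <= set(types):
        raise ValueError("hybrid simulation needs epithelial and macrophage programs")

    # tissue assignment: non-myeloid cells split evenly; myeloid cells are
    # allotted to tumor at the odds ratio implied by the target tissue fractions
    ot = config.tumor_myeloid_frac / max(1e-12, 1 - config.tumor_myeloid_frac)
    on = config.normal_myeloid_frac / max(1e-12, 1 - config.normal_myeloid_frac)
    myeloid_tumor_share = ot / (ot + on) if (ot + on) > 0 else 0.5
    is_mye = np.isin(labels, MYELOID_TYPES)
    tissue = np.where(
        rng.random(n_singlets) < np.where(is_mye, myeloid_tumor_share, 0.5),
        "tumor", "normal",
    ).astype(object)

    lo, hi = config.mixing_weight_range
    lam_mix = rng.uniform(lo, hi, size=n_hybrids)
    hyb_tissue = np.where(rng.random(n_hybrids) < config.hybrid_tumor_share,
                          "tumor", "normal").astype(object)

    # expected expression per cell
    type_idx = {t: i for i, t in enumerate(types)}
    rel = np.empty((n_singlets + n_hybrids, len(genes)))
    rel[:n_singlets] = prog_norm[[type_idx[t] for t in labels]]
    if n_hybrids:
        p_epi = prog_norm[type_idx["epithelial"]]
        p_mac = prog_norm[type_idx["macrophage"]]
        mix = lam_mix[:, None] * p_epi[None, :] + (1 - lam_mix[:, None]) * p_mac[None, :]
        for g, eff in config.hybrid_private_genes.items():
            mix[:, gene_pos[g]] *= 2.0 ** eff
        mix /= mix.sum(axis=1, keepdims=True)
        rel[n_singlets:] = mix

    n_total = n_singlets + n_hybrids
    libsize = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=n_total)
    counts = _nb_counts(rng, libsize[:, None] * rel, config.nb_dispersion)

    # atlas-style annotation: every cell carries a normal-type label the way
    # consumed atlas metadata does — hybrids get their dominant parental type
    hyb_annot = np.where(lam_mix >= 0.5, "epithelial", "macrophage").astype(object)
    truth = pd.DataFrame({
        "cell_id": [f"CELL{i:06d}" for i in range(n_total)],
        "true_label": np.concatenate([labels, np.repeat("hybrid", n_hybrids)]),
        "annotation": np.concatenate([labels.astype(object), hyb_annot]),
        "tissue": np.concatenate([tissue, hyb_tissue]),
        "lambda": np.concatenate([np.full(n_singlets, np.nan), lam_mix]),
        "parent_a": [None] * n_total,
        "parent_b": [None] * n_total,
    })
    truth["sample_id"] = [
        f"{'T' if t == 'tumor' else 'N'}{s}"
        for t, s in zip(truth["tissue"],
                        rng.integers(1, config.n_samples_per_tissue + 1, n_total))
    ]

    order = rng.permutation(n_total)
    truth = truth.iloc[order].reset_index(drop=True)
    matrix = CountMatrix(sp.csr_matrix(counts[order]), truth["cell_id"].to_numpy(), genes)
    return matrix, truth


def inject_doublets(counts: CountMatrix, truth: pd.DataFrame, rate: float,
                    seed: int = 0, mode: str = "uniform"):
    """Append droplet doublets whose counts are exact sums of two parents.

    ``rate`` is the number of injected doublets relative to the current
    matrix size.  ``mode='epi_myeloid'`` restricts parent pairs to
    epithelial x (monocyte | macrophage), the null used by disambiguation.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return counts, truth
    rng = np.random.default_rng([seed, 2])
    singlet = (truth["true_label"] != "doublet").to_numpy()
    n_doublets = int(round(rate * counts.n_cells))
    if mode == "uniform":
        pool = np.flatnonzero(singlet)
        if pool.size < 2:
            raise ValueError("need at least 2 singlets to form doublets")
        a = rng.choice(pool, size=n_doublets)
        b = rng.choice(pool, size=n_doublets)
        clash = a == b
        while clash.any():
            b[clash] = rng.choice(pool, size=int(clash.sum()))
            clash = a == b
    elif mode == "epi_myeloid":
        pa = np.flatnonzero(singlet & (truth["true_label"] == "epithelial").to_numpy())
        pb = np.flatnonzero(singlet & truth["true_label"].isin(MYELOID_TYPES).to_numpy())
        if pa.size == 0 or pb.size == 0:
            raise ValueError("both epithelial and myeloid parents are required")
        a = rng.choice(pa, size=n_doublets)
        b = rng.choice(pb, size=n_doublets)
    else:
        raise ValueError(f"unknown doublet mode {mode!r}")

    new_rows = counts.X[a] + counts.X[b]
    # annotation mimics what an annotation pipeline would assign a doublet:
    # the type of the parent contributing the larger library
    lib = counts.library_sizes()
    dominant = np.where(lib[a] >= lib[b], a, b)
    new_truth = pd.DataFrame({
        "cell_id": [f"DBL{i:06d}" for i in range(n_doublets)],
        "true_label": "doublet",
        "annotation": truth["annotation"].to_numpy()[dominant],
        "tissue": truth["tissue"].to_numpy()[a],
        "lambda": np.nan,
        "parent_a": truth["cell_id"].to_numpy()[a],
        "parent_b": truth["cell_id"].to_numpy()[b],
        "sample_id": truth["sample_id"].to_numpy()[a],
    })
    out = CountMatrix(
        sp.vstack([counts.X, new_rows], format="csr"),
        np.concatenate([counts.cell_ids, new_truth["cell_id"].to_numpy()]),
        counts.gene_ids,
    )
    return out, pd.concat([truth, new_truth], ignore_index=True)


def simulate_spatial(config: SimConfig, panel, field=(1000.0, 1000.0),
                     mode: str = "niche"):
    """Simulate an in-situ slide: panel-restricted counts plus centroids.

    Cells are placed uniformly (``mode='uniform'``) or around type-specific
    niche centers (``mode='niche'``); coordinates are micrometers with the
    origin at the upper-left corner of the field.
    Returns ``(SpatialCellTable, truth)``.
    """
    from .spatial import SpatialCellTable  # local import to avoid a cycle

    panel = list(panel)
    if not panel:
        raise ValueError("spatial panel must be non-empty")
    programs = make_programs(config)
    missing = [g for g in panel if g not in programs.columns]
    if missing:
        raise ValueError(f"panel genes not simulated: {missing}")
    counts, truth = simulate_cells(config, programs)

    rng = _rng(config, 3)
    w, h = field
    n = counts.n_cells
    if mode == "uniform":
        x = rng.uniform(0, w, n)
        y = rng.uniform(0, h, n)
    elif mode == "niche":
        types = sorted(truth["true_label"].unique())
        centers = {t: (rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h))
                   for t in types}
        sigma = min(w, h) / 15.0
        cx = np.array([centers[t][0] for t in truth["true_label"]])
        cy = np.array([centers[t][1] for t in truth["true_label"]])
        x = np.clip(cx + rng.normal(0, sigma, n), 0, w)
        y = np.clip(cy + rng.normal(0, sigma, n), 0, h)
    else:
        raise ValueError(f"unknown placement mode {mode!r}")

    panel_counts = counts.subset_genes(panel)
    cells = pd.DataFrame({
        "cell_id": panel_counts.cell_ids,
        "x_centroid": x,
        "y_centroid": y,
        "total_counts": panel_counts.library_sizes().astype(int),
    })
    return SpatialCellTable(panel_counts, cells), truth


def write_simulation(path, counts: CountMatrix, truth: pd.DataFrame,
                     spatial_cells: pd.DataFrame | None = None) -> None:
    """Export MTX trio plus a cell-metadata CSV (spatial adds centroids)."""
    path = Path(path)
    write_mtx_dir(path, counts)
    meta = truth[["cell_id", "sample_id", "tissue", "true_label",
                  "annotation", "lambda"]].copy()
    if spatial_cells is not None:
        meta = meta.merge(
            spatial_cells[["cell_id", "x_centroid", "y_centroid"]], on="cell_id")
    meta.to_csv(path / "cells.csv", index=False)


def default_config(**overrides) -> SimConfig:
    """The study-conditions configuration with optional field overrides."""
    return replace(SimConfig(), **overrides)
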