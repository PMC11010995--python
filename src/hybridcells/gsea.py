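"""Preranked gene-set enrichment with a gene-permutation null.

The enrichment score (ES) is the extremum of the weighted
Kolmogorov-Smirnov running sum over the metric-sorted gene list: genes in
the set increment the sum proportionally to |metric| (weight exponent 1 by
default) and genes outside decrement it uniformly.  Significance comes
from random same-size gene sets; the normalized score (NES) divides ES by
the mean |null ES| of matching sign, and adjusted p-values use
Benjamini-Hochberg across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "preranked_gsea",
    "rank_from_de",
]


@dataclass
class GeneSetCollection:
    sets: dict = field(default_factory=dict)  # name -> list of gene ids
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, genes...)."""
    path = Path(path)
    sets = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not fields[0]:
            raise ValueError(f"{path}:{lineno}: malformed GMT line")
        name, genes = fields[0], [g for g in fields[2:] if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) < len(genes):
            warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} dropped")
        sets[name] = uniq
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([name, collection.source or "na"] + list(genes))
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _es_from_positions(abs_metric: np.ndarray, positions: np.ndarray, n_genes: int,
                       weight: float = 1.0):
    """ES, extremum position and per-hit running values for sorted hit positions."""
    pos = np.sort(positions)
    k = pos.size
    w = abs_metric[pos] ** weight
    denom = w.sum()
    if denom == 0:  # all-zero metrics in the set: unweighted increments
        w = np.ones(k)
        denom = float(k)
    miss = 1.0 / (n_genes - k) if n_genes > k else 0.0
    t = np.arange(k)
    cum_hit = np.cumsum(w) / denom
    at_hit = cum_hit - (pos - t) * miss            # running sum right after each hit
    before_hit = np.concatenate(([0.0], cum_hit[:-1])) - (pos - t) * miss
    max_run = float(at_hit.max())
    min_run = float(min(before_hit.min(), 0.0))
    if abs(max_run) >= abs(min_run):
        return max_run, int(pos[int(np.argmax(at_hit))]), pos, at_hit
    return min_run, int(pos[int(np.argmin(before_hit))]), pos, at_hit


def enrichment_score(metric_sorted: np.ndarray, hit_positions,
                     weight: float = 1.0) -> float:
    """ES for a gene set given the metric in ranked (descending) order."""
    es, _, _, _ = _es_from_positions(np.abs(np.asarray(metric_sorted, dtype=float)),
                                     np.asarray(hit_positions, dtype=int),
                                     len(metric_sorted), weight)
    return es


def preranked_gsea(ranking: pd.Series, sets: GeneSetCollection,
                   n_perm: int = 1000, min_size: int = 5, max_size: int = 500,
                   seed: int = 0, weight: float = 1.0) -> pd.DataFrame:
    """Run preranked enrichment for every set in the collection.

    ``ranking`` maps gene id to the ranking metric (e.g. avg_log2FC).
    p-values use random same-size gene sets with sign-matched tails:
    ``p = (#{null ES at least as extreme, same sign} + 1) / (n_same_sign + 1)``,
    bounded below by 1/(n_perm + 1).
    """
    ranking = pd.Series(ranking)
    if ranking.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    if not np.isfinite(ranking.to_numpy(dtype=float)).all():
        raise ValueError("ranking metrics must be finite")
    order = ranking.to_frame("m").reset_index(names="gene")
    order = order.sort_values(["m", "gene"], ascending=[False, True], kind="mergesort")
    genes = order["gene"].to_numpy()
    metric = order["m"].to_numpy(dtype=float)
    absm = np.abs(metric)
    n = genes.size
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable = {}
    for name, members in sets.sets.items():
        pos = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if pos.size == 0:
            warnings.warn(f"set {name!r} has no overlap with the ranking; dropped")
            continue
        if not min_size <= pos.size <= max_size:
            continue
        usable[name] = pos

    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted({p.size for p in usable.values()}):
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm_pos = rng.choice(n, size=k, replace=False)
            null[i], _, _, _ = _es_from_positions(absm, perm_pos, n, weight)
        null_by_size[k] = null

    rows = []
    for name, pos in usable.items():
        es, ext_pos, spos, _ = _es_from_positions(absm, pos, n, weight)
        null = null_by_size[pos.size]
        if es >= 0:
            same = null[null > 0]
            p = (np.sum(same >= es) + 1) / (same.size + 1)
            nes = es / same.mean() if same.size else np.nan
            leading = genes[spos[spos <= ext_pos]]
        else:
            same = null[null < 0]
            p = (np.sum(same <= es) + 1) / (same.size + 1)
            nes = es / np.abs(same).mean() if same.size else np.nan
            leading = genes[spos[spos >= ext_pos]]
        rows.append({
            "pathway": name, "es": es, "nes": float(nes), "p_val": float(p),
            "size": int(pos.size), "leading_edge": list(leading),
        })
    columns = ["pathway", "es", "nes", "p_val", "p_adj", "size", "leading_edge"]
    if not rows:
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p_val"], method="bh")
    out = out.sort_values("p_val", kind="mergesort").reset_index(drop=True)
    return out[columns]


def rank_from_de(de: pd.DataFrame) -> pd.Series:
    """Gene ranking metric (avg_log2FC) from a DE table, ties by gene name."""
    if de["gene"].duplicated().any():
        raise ValueError("DE table contains duplicate genes")
    sub = de[["gene", "avg_log2FC"]].sort_values(
        ["avg_log2FC", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(sub["avg_log2FC"].to_numpy(), index=sub["gene"].to_numpy(),
                     name="metric")


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["leading_edge"] = out["leading_edge"].map(";".join)
    out.rename(columns={"p_val": "pval", "p_adj": "padj",
                        "leading_edge": "leadingEdge"}).to_csv(
        path, sep="\t", index=False)
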