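"""Wilcoxon differential expression with toolkit-convention metrics.

For each gene the two-sided Wilcoxon rank-sum test compares log-normalized
expression between two cell groups; reported alongside are the detection
fractions in each group (``pct.1``/``pct.2``), the log2 fold change of
pseudocounted back-transformed group means, and Bonferroni-adjusted
p-values over all genes in the matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = ["find_markers", "find_all_markers", "volcano_table"]

#: group sizes up to this use the exact rank-sum distribution when tie-free
_EXACT_MAX_N = 50

#: -log10 floor for p-values that underflow to 0
_NEG_LOG10_CAP = 323.3


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    exact = (max(a.size, b.size) <= _EXACT_MAX_N
             and np.unique(np.concatenate([a, b])).size == a.size + b.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def find_markers(normalized: CountMatrix, group_a_ids, group_b_ids,
                 min_pct: float = 0.1, logfc_threshold: float = 0.25) -> pd.DataFrame:
    """Per-gene DE table between two disjoint cell groups.

    ``avg_log2FC = log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1))``.
    Genes are pre-filtered to ``max(pct.1, pct.2) >= min_pct`` and
    ``|avg_log2FC| >= logfc_threshold``; ``p_val_adj`` is Bonferroni over
    *all* genes in the matrix.  Rows are sorted by p-value.
    """
    pos = {c: i for i, c in enumerate(normalized.cell_ids)}
    ia = np.array([pos[c] for c in group_a_ids])
    ib = np.array([pos[c] for c in group_b_ids])
    if ia.size < 3 or ib.size < 3:
        raise ValueError("both groups need at least 3 cells")
    if set(ia) & set(ib):
        raise ValueError("groups must be disjoint")

    A = np.asarray(normalized.X[ia].todense())
    B = np.asarray(normalized.X[ib].todense())
    pct1 = (A > 0).mean(axis=0)
    pct2 = (B > 0).mean(axis=0)
    lfc = np.log2((np.expm1(A).mean(axis=0) + 1.0)
                  / (np.expm1(B).mean(axis=0) + 1.0))

    keep = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    idx = np.flatnonzero(keep)
    pvals = np.array([_wilcoxon_p(A[:, j], B[:, j]) for j in idx])

    n_total = normalized.n_genes
    out = pd.DataFrame({
        "gene": normalized.gene_ids[idx],
        "p_val": pvals,
        "avg_log2FC": lfc[idx],
        "pct.1": pct1[idx],
        "pct.2": pct2[idx],
        "p_val_adj": np.minimum(1.0, pvals * n_total),
    })
    return out.sort_values(["p_val", "gene"], kind="mergesort").reset_index(drop=True)


def find_all_markers(normalized: CountMatrix, cluster_labels,
                     min_pct: float = 0.1,
                     logfc_threshold: float = 0.25) -> pd.DataFrame:
    """One-vs-rest DE per cluster; singleton/tiny clusters are skipped."""
    labels = np.asarray(cluster_labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 clusters")
    tables = []
    for c in np.unique(labels):
        in_c = normalized.cell_ids[labels == c]
        rest = normalized.cell_ids[labels != c]
        if in_c.size < 3 or rest.size < 3:
            warnings.warn(f"cluster {c} vs rest has <3 cells on a side; skipped")
            continue
        tab = find_markers(normalized, in_c, rest, min_pct, logfc_threshold)
        tab.insert(0, "cluster", c)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()


def volcano_table(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Add -log10 p and a significance flag (adjusted p below ``alpha``)."""
    out = de.copy()
    p = out["p_val"].to_numpy(dtype=float)
    capped = p <= 0
    with np.errstate(divide="ignore"):
        nl = -np.log10(p)
    nl[capped] = _NEG_LOG10_CAP
    out["neg_log10_p"] = nl
    out["p_capped"] = capped
    out["significant"] = out["p_val_adj"] < alpha
    return out
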