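# hybridcells

Detection and transcriptomic characterization of **tumor–macrophage hybrid
cells** (HCs) in droplet single-cell RNA-seq and targeted in-situ spatial
transcriptomics.

Hybrid cells — thought to arise from fusion of (or failed phagocytosis by)
monocytes/macrophages and cancer epithelial cells — co-express epithelial
markers (*EPCAM*, *KRT8*) and macrophage markers (*CD14*, *CD163*). In
droplet data they are easy to confuse with **doublets**, the technical
artifact in which two cells share one droplet and yield a summed
transcriptome. This package provides, for computational biologists working
with cell-by-gene count matrices:

- a **marker co-expression gate**: a cell is called hybrid iff raw count
  > 0 for *every* epithelial and *every* myeloid marker
  (EPCAM > 0 ∧ KRT8 > 0 ∧ CD14 > 0 ∧ CD163 > 0 by default), optionally
  requiring a combined doublet score ≤ a removal threshold
  (mean + 2·SD, or a fixed cutoff);
- **doublet scoring**: a co-expression score (*cxds*: a cell sums the
  mutual-exclusivity weights of the most exclusive gene pairs it
  co-detects), a classifier score (*bcds*: out-of-fold probability from a
  gradient-boosted classifier trained against artificial doublets), and a
  combined score. The classifier is *hybrid-aware*: its negative class is
  augmented with depth-preserving synthetic fusions so it flags the
  doublet's doubled library size and complexity rather than two-lineage
  co-expression itself — which is exactly what a fusion hybrid has;
- **doublet-vs-hybrid disambiguation**: an empirical placement null
  (artificial epithelial × myeloid doublets projected into the observed
  PCA/cluster map land ~50/50 in epithelial vs. myeloid clusters), an exact
  two-sided binomial test of the observed myeloid skew of gated cells, and
  a Gaussian-mixture ΔBIC test for a bimodal doublet-score distribution;
- the surrounding pipeline: log-CP10K normalization, highly variable
  genes, depth-regressed PCA, shared-nearest-neighbor Leiden clustering
  (resolution 0.8) with DE-guided cluster merging, Wilcoxon marker
  differential expression (`p_val`, `avg_log2FC`, `pct.1`, `pct.2`,
  Bonferroni `p_val_adj`), preranked GSEA with a gene-permutation null
  (ES/NES, BH-adjusted p), and in-situ spatial gating with viewer
  annotation export;
- a **synthetic-data generator** with ground truth: negative-binomial
  counts for epithelial/monocyte/macrophage/other programs, rare true
  hybrids with expected expression λ·μ_epithelial + (1−λ)·μ_macrophage plus
  hybrid-private genes, exact summed-count doublets, a tumor/normal split
  with different myeloid abundance, and a low-plex spatial panel with
  centroids in µm.

## Worked example

Run the full synthetic study (simulate → preprocess → doublet scores →
gate → disambiguate → DE → GSEA):

```sh
hybridcells run --out run0 --seed 0
```

which prints (one line per stage):

```text
[simulate] {"n_cells": 5302, "n_doublets_true": 252, "n_genes": 2000, "n_hybrids_true": 50}
[preprocess] {"n_clusters": 9, "n_hvg": 2000, "n_pcs": 10}
[doublets] {"n_above_threshold": 402, "threshold": 0.5436122364052666, "threshold_method": "mean_plus_2sd"}
[gate] {"myeloid_colocalization": 0.9615384615384616, "n_hybrid_calls": 52, "n_relaxed_calls": 260, "precision_vs_truth": 0.8653846153846154, "recall_vs_truth": 0.9, "tumor_normal_enrichment": 3.1858706467661695}
[disambiguate] {"bimodality": {"decision": "bimodal", "delta_bic": -136.40946545426456, "minor_weight": 0.4475330621444032}, "null_mc_se": 0.01577479001445027, "null_myeloid_fraction": 0.534, "observed_myeloid_fraction": 0.9038461538461539, "skew_p_value": 1.2384748702031214e-08}
[de] {"n_genes_tested": 1661, "n_significant": 1061}
[gsea] {"n_sets": 11, "top_nes": 1.9702173706887713, "top_p_adj": 0.015759312320916905, "top_pathway": "MYELOID_AND_HYBRID_PROGRAM"}
```

Reading the output: of 5,302 simulated cells (50 true hybrids, 252
injected doublets), the 4-marker gate with the mean+2SD doublet filter
calls 52 hybrids (precision 0.87, recall 0.90 against ground truth); 96%
of the called hybrids sit in myeloid-annotated clusters. Artificial
epithelial × myeloid doublets place in myeloid clusters at only 53% (the
null), so the observed 90% myeloid placement is wildly unlikely under a
doublet origin (exact binomial p ≈ 1.2 × 10⁻⁸). The gated cells' doublet
score is bimodal (ΔBIC = −136): a high-score minority are residual true
doublets, which the filter removes. The planted myeloid/hybrid gene set
tops the preranked enrichment (NES 1.97, adjusted p 0.016).

The same steps are available as library calls (`simulate_cells`,
`score_doublets`, `call_hybrids`, `doublet_assignment_null`,
`find_markers`, `preranked_gsea`, `gate_spatial`, ...) and as per-stage
subcommands (`hybridcells simulate|preprocess|doublets|gate|disambiguate|
de|gsea|spatial`). Estimator classes (`DoubletScorer`, `HybridGate`,
`GraphClusterer`, `LogNormalizer`, `SignedPCA`) follow scikit-learn
conventions (`fit`, fitted `*_` attributes, `get_params`).

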