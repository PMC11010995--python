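# Methods

## The problem

Tumor–macrophage hybrid cells (HCs) co-express epithelial and macrophage
lineage markers. In droplet scRNA-seq a cell that detects all of EPCAM,
KRT8, CD14 and CD163 may be (a) a true hybrid, (b) a doublet — two cells
in one droplet, producing the *sum* of two transcriptomes — or (c) a
coincidence of low-level cross-lineage expression. The package identifies
candidate hybrids with a raw-count marker gate, suppresses (b) with
doublet scoring and a removal threshold, bounds (c) through the
conjunction of four markers, and then tests the surviving calls against
the doublet hypothesis explicitly.

## Synthetic data model

The generator (`simdata`) is the ground-truth instrument for the whole
package; every benchmark in the test suite runs against it.

**Programs.** Each cell type *t* (epithelial, monocyte, macrophage,
other) has a mean-expression program over 2,000 genes. Marker genes get
mean `marker_strength` (20) in their owning lineage and
`marker_strength × marker_leak` elsewhere; non-marker means are i.i.d.
gamma(shape 0.5, scale 2) draws per type. `marker_leak` defaults to 0.002:
cross-lineage marker transcription is essentially absent in real tissue
(a macrophage transcript like *CD163* is not part of the epithelial
program), and this leak level yields a per-cell detection probability of
a foreign marker of a few percent — non-zero, as ambient/leaky counts are
in practice, but far below the within-lineage detection near 1.

**Counts.** Cell *i* of type *t* draws a library size
L_i ~ logNormal(log 2500, 0.35) and counts
x_ij ~ NB(mean = L_i · p_tj, dispersion α = 0.15) via gamma–Poisson,
where p_t is the program normalized to sum 1. Shared dispersion is the
standard scRNA-seq noise model; 2,500 counts/cell and σ_log = 0.35 are
typical droplet values.

**Hybrids.** A fraction (1%) of cells are true hybrids with program
p = λ·p_epithelial + (1−λ)·p_macrophage, hybrid-private genes (*SPP1*
×4, *CD44* ×2) multiplied in, and the result renormalized; they draw a
*single-cell* library size. λ ~ Uniform(0.2, 0.5): hybrid transcriptomes
are weighted toward the macrophage parent, consistent with hybrid cells
being observed inside myeloid rather than epithelial clusters and with
their doublet scores resembling the myeloid cluster. Hybrids are placed
in tumor tissue with probability 0.9.

**Doublets.** Injected doublets (5%) are *exact sums* of two sampled
singlets' count vectors — the generative definition of a droplet doublet.
Parent pairs are uniform by default; an epithelial×myeloid-restricted
mode exists for the disambiguation null.

**Tissue structure.** Tumor and normal tissue differ in myeloid
abundance (14.8% vs 2.4% of cells); non-myeloid cells split evenly, and
myeloid cells are allotted to tumor at the odds ratio those fractions
imply. Each cell also carries an atlas-style `annotation` column — the
label an annotation pipeline blind to hybridness would assign: singlets
get their type, hybrids their dominant parental lineage, doublets the
type of the parent with the larger library. Cluster majority annotation
consumes this column, mirroring how real analyses consume provided atlas
annotations.

**Spatial.** The in-situ simulator restricts counts to a small panel and
places cells either uniformly or in per-type Gaussian niches
(σ = field/15) on a field measured in µm, origin upper-left.

What the generator does **not** emulate: transcriptome-wide pathway
co-regulation, ambient RNA, batch effects, cell-cycle structure, or
platform-specific segmentation errors. Passing benchmarks here therefore
demonstrates correctness of the algorithms under the stated statistical
model, not performance on any particular real dataset.

## Preprocessing

Log-CP10K normalization: entry = ln(1 + count/libsize × 10⁴), sparse
zeros preserved. Highly variable genes are ranked by binned normalized
dispersion (variance/mean of the normalized values, z-scored within 20
mean-rank bins); gate markers can be force-retained.

PCA uses the top 10 components with a fixed sign convention (the
largest-magnitude loading of each component is positive). Before PCA,
each gene is residualized on centered log library size: log
normalization leaves a depth signature through the zero pattern (deeper
cells detect more genes), and without removal that signature becomes a
dominant principal direction and fragments clusters by sequencing depth —
the role the regularized-regression normalization played in the original
processing.

Clustering is Leiden modularity (RBConfiguration, resolution 0.8, two
iterations, fixed seed) on the shared-nearest-neighbor graph: k = 20
neighbors, edges weighted by the Jaccard overlap of neighbor lists and
pruned below 1/15. The SNN graph is markedly more robust than the plain
KNN graph against splitting large homogeneous populations. Because a
fixed resolution can still subdivide a homogeneous population along
residual technical structure, clusters are post-processed by **DE-guided
merging**: the closest pair of cluster centroids is tested with the
marker criteria (detection ≥ 0.1, |log2FC| ≥ 0.25, Bonferroni-adjusted
Wilcoxon p < 0.05, clusters subsampled to ≤ 1,500 cells) and merged when
no gene passes; this repeats until every remaining pair is distinct
(bounded at 12 tests per call). A split that no gene supports is not a
biological cluster distinction.

## Doublet scoring

**cxds (co-expression).** Counts are binarized to detection. On the 500
most variable detection patterns, each gene pair gets the weight
w_ij = −log P(Binom(n, p_i·p_j) ≤ o_ij) — the log-space lower-tail
probability of the observed co-detection count under independence, so
pairs co-detected far below expectation (mutually exclusive genes) score
high. A cell's score sums the weights of the 500 most exclusive pairs it
co-detects. The score depends only on the detection pattern, never on
count magnitude.

**bcds (classifier).** Artificial doublets (summed random cell pairs,
one per observed cell) are the positive class. The negative class is the
observed cells **plus depth-preserving synthetic fusions**: summed pairs
binomially downsampled to a library size drawn from the observed cells.
Without this augmentation the classifier learns "two-lineage profile ⇒
doublet" and removes precisely the true fusion hybrids the analysis is
looking for; with it, the discriminative signal shifts to what actually
distinguishes a doublet — the doubled library size and detected-gene
count, and the smoother noise profile of a summed transcriptome.
Features are log-normalized values of the 500 most variable genes plus
log library size and log detected-gene count; the model is XGBoost (150
trees, depth 4, single-threaded, seeded; logistic-regression fallback),
and every observed cell's score is an out-of-fold predicted probability
from stratified 5-fold cross-validation.

**Combined score.** The default combination refits a logistic model on
the two component scores over the same labeled training set (observed +
fusions vs artificial) and returns its out-of-fold probability: the
meta-model learns from data — with no reference to ground truth — how
much weight each component deserves, and yields a calibrated, sharply
bimodal score for which the mean + 2·SD threshold isolates the
high-scoring tail. A plain average of min–max-scaled scores
(`combine="minmax"`) and a rank-average (`combine="rank"`) are exposed;
rank normalization is deliberately *not* the default because it makes
the combined score nearly uniform on [0,1], pushing mean + 2·SD to ≈ 1
and disabling the filter.

**Threshold.** `mean_plus_2sd` computes mean + 2·SD of the combined
score (sample SD, n−1); `fixed` (default 0.5) reproduces the published
replication setting, where the two coincided.

## The hybrid gate

A cell is hybrid iff raw count ≥ `min_count` (default 1, i.e. "> 0") for
every epithelial marker AND every myeloid marker, and — when filtering —
its combined doublet score is ≤ the threshold (boundary kept: removal is
"above" the threshold). Raw-count semantics make calls invariant under
normalization; the conjunction is order-independent and monotone (adding
a marker or raising `min_count` can only shrink the call set). Per-group
summaries use each group's own denominator (tumor hybrid % = hybrids in
tumor / cells in tumor).

## Doublet-vs-hybrid disambiguation

If gated cells were epithelial×myeloid doublets, they should distribute
between epithelial and myeloid clusters roughly as artificial doublets
do. The package makes that argument exact:

1. **Reference map** — normalization, HVG, depth-regressed PCA, SNN
   Leiden clusters and majority lineages are fitted on real (singlet)
   cells only. Held-out count vectors are normalized with their own
   library size, depth-adjusted and projected with the *fitted* loadings,
   then assigned to the nearest cluster centroid (Euclidean, PC space).
2. **Empirical null** — n_sim (default 1,000) artificial epithelial ×
   myeloid doublets are summed from random parent pairs and placed; the
   null myeloid-placement fraction is reported with its Monte-Carlo
   standard error. The null is simulated rather than hard-coded at 0.5
   because library-size asymmetry between the parent pools can bias
   placement.
3. **Skew test** — the observed number of gated cells placed in myeloid
   clusters is tested against Binomial(n, null fraction) with the exact
   two-sided p-value (sum of outcome probabilities ≤ the observed
   outcome's probability).
4. **Bimodality** — 1- vs 2-component Gaussian mixtures on the gated
   cells' combined score; "bimodal" iff ΔBIC = BIC₂ − BIC₁ < −10, with
   the higher-mean component's weight reported (the residual-doublet
   mode). The GMM route, unlike a dip test, quantifies that minor-mode
   weight. The decision is affine-invariant; degenerate variance is
   regularized and flagged.

## Differential expression

Two-sided Wilcoxon rank-sum per gene on log-normalized values: exact
distribution when both groups ≤ 50 cells and the values are tie-free,
otherwise the normal approximation with tie and continuity corrections.
`avg_log2FC = log2((mean(expm1 a)+1)/(mean(expm1 b)+1))` (pseudocount
after back-transformation), `pct.1`/`pct.2` are detection fractions,
genes are pre-filtered to max(pct) ≥ 0.1 and |log2FC| ≥ 0.25, and
`p_val_adj` is Bonferroni over **all** genes in the matrix (toolkit
convention; the alternative — adjusting over tested genes only — is less
conservative and was not chosen). `volcano_table` adds −log10 p (capped
at 323.3 for underflowed p, flagged) and a `p_val_adj < 0.05` flag.

## Preranked GSEA

Genes are sorted by the metric (avg_log2FC from a DE table; ties broken
by gene name for reproducibility). ES is the extremum of the weighted
Kolmogorov–Smirnov running sum: hits increment by |metric|^w (w = 1) over
the sum of hit weights, misses decrement by 1/(N−k). The null draws
random same-size gene sets (gene permutation, the preranked convention);
p = (#{null ES at least as extreme, same sign} + 1)/(n_same_sign + 1),
bounded below by 1/(n_perm+1) and never zero; NES divides ES by the mean
|null ES| of matching sign; Benjamini–Hochberg across sets. The leading
edge is the set members at or before (after, for negative ES) the
running-sum extremum. Degenerate cases are defined: an all-gene set has
miss penalty 0 and ES 1; a set whose metrics are all zero falls back to
uniform hit increments.

## Spatial gating

In-situ tables join an MTX count trio to a `cells.csv` of centroids (µm,
origin upper-left, no coordinate flipping); id mismatches above 1% are
an error, smaller ones are dropped with a report. The hybrid gate is the
same raw-count conjunction with **no doublet filter** — in-situ
segmentation already yields single cells. `is_epithelial`/`is_myeloid`
require only their own marker list and exclude hybrids, so the four
groups (hybrid/epithelial/myeloid/other) partition all cells; the
partition is exported as a viewer annotation CSV. Neighborhood
composition uses a KD-tree within a µm radius, excluding self; isolated
cells are flagged rather than given fractions. Only the MTX trio is
read (HDF5 matrices are out of the IO surface).

## Problem sizes and tolerances

The default synthetic study is ~5,300 cells × 2,000 genes (1% hybrids,
5% doublets) — large enough for stable cluster structure and classifier
training, small enough that the full pipeline runs in about a minute on
one CPU. The placement null uses n_sim = 1,000 (MC-SE ≈ 0.016);
permutation GSEA uses 1,000 gene permutations in tests (10,000 remains
the CLI default for production runs). Oracle equivalences are asserted
at 1e−10 (cxds) and 1e−12 (Wilcoxon, ES); statistical checks use
binomial confidence bands at their stated n.

## Limitations

- Doublet/hybrid separation ultimately rests on library-size and noise
  signatures; hybrids that genuinely have doubled RNA content (e.g.
  polyploid hybrids) would be removed by any transcriptome-based filter.
- The DE-guided cluster merge assumes that a biologically real split
  shows at least one marker gene at the chosen thresholds.
- The synthetic benchmark shares its doublet-generation mechanism with
  the bcds training scheme, which flatters classifier AUROC relative to
  real data; the cxds score and the gate are unaffected.
- Replicating the published atlas counts requires the public accessions
  and their original annotations; the package ships the machinery
  (replication mode: fixed 0.5 threshold, published marker sets) but not
  the data.
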