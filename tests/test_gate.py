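import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hybridcells.doublets import DoubletThreshold
from hybridcells.gate import (GateSpec, call_hybrids, call_hybrids_relaxed,
                              cluster_colocalization, enrichment_ratio,
                              summarize_by_group)
from hybridcells.io import CountMatrix
from hybridcells.preprocess import ClusterAssignment, majority_annotation

GATE_GENES = ["EPCAM", "KRT8", "CD14", "CD163"]


def random_matrix(rng, n_cells=40, extra_genes=6):
    genes = GATE_GENES + [f"G{i}" for i in range(extra_genes)]
    X = rng.poisson(0.8, (n_cells, len(genes)))
    return CountMatrix(sp.csr_matrix(X), [f"c{i}" for i in range(n_cells)], genes)


def brute_force_gate(counts, gate, scores=None):
    """Independent oracle: explicit per-cell loop over the gate definition."""
    X = np.asarray(counts.X.todense())
    out = []
    for i in range(counts.n_cells):
        ok = True
        for g in list(gate.epithelial_markers) + list(gate.myeloid_markers):
            j = list(counts.gene_ids).index(g)
            if X[i, j] < gate.min_count:
                ok = False
        if ok and gate.apply_doublet_filter and scores[i] > gate.threshold.value:
            ok = False
        out.append(ok)
    return np.array(out)


class TestCallHybrids:
    def test_single_zero_marker_blocks_call(self):
        X = np.ones((1, 4), dtype=int)
        X[0, 2] = 0
        counts = CountMatrix(sp.csr_matrix(X), ["c0"], GATE_GENES)
        assert call_hybrids(counts, GateSpec()).n_hybrids == 0

    def test_all_markers_with_low_score_is_called(self):
        counts = CountMatrix(sp.csr_matrix(np.ones((1, 4), dtype=int)),
                             ["c0"], GATE_GENES)
        gate = GateSpec(apply_doublet_filter=True,
                        threshold=DoubletThreshold("fixed", 0.5))
        calls = call_hybrids(counts, gate, np.array([0.0]))
        assert calls.n_hybrids == 1
        # a boundary score (== threshold) is kept, score above is removed
        assert call_hybrids(counts, gate, np.array([0.5])).n_hybrids == 1
        assert call_hybrids(counts, gate, np.array([0.51])).n_hybrids == 0

    def test_missing_gene_named_in_error(self, rng):
        counts = random_matrix(rng)
        with pytest.raises(KeyError, match="NOPE"):
            call_hybrids(counts, GateSpec(epithelial_markers=("EPCAM", "NOPE")))

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(30):
            n = int(rng.integers(5, 100))
            counts = random_matrix(rng, n_cells=n)
            scores = rng.random(n)
            gate = GateSpec(min_count=int(rng.integers(1, 3)),
                            apply_doublet_filter=bool(rng.integers(2)),
                            threshold=DoubletThreshold("fixed", 0.5))
            if not gate.apply_doublet_filter:
                gate = GateSpec(min_count=gate.min_count)
            got = call_hybrids(counts, gate,
                               scores if gate.apply_doublet_filter else None)
            expected = brute_force_gate(counts, gate, scores)
            assert (got.is_hybrid == expected).all()

    def test_gate_monotonicity(self, rng):
        counts = random_matrix(rng, n_cells=200)
        base = call_hybrids(counts, GateSpec())
        wider = call_hybrids(counts, GateSpec(
            epithelial_markers=("EPCAM", "KRT8", "G0")))
        higher = call_hybrids(counts, GateSpec(min_count=2))
        assert set(wider.hybrid_cell_ids) <= set(base.hybrid_cell_ids)
        assert set(higher.hybrid_cell_ids) <= set(base.hybrid_cell_ids)

    def test_relaxed_superset_of_strict(self, rng):
        counts = random_matrix(rng, n_cells=300)
        strict = call_hybrids(counts, GateSpec())
        relaxed = call_hybrids_relaxed(counts, "EPCAM", "CD163")
        assert set(strict.hybrid_cell_ids) <= set(relaxed.hybrid_cell_ids)

    def test_empty_matrix_zero_calls(self):
        counts = CountMatrix(sp.csr_matrix((0, 4), dtype=int), [], GATE_GENES)
        assert call_hybrids_relaxed(counts, "EPCAM", "CD163").n_hybrids == 0

    def test_invariant_to_count_scaling(self, rng):
        # raw-count semantics: detection gate unchanged by scaling counts
        counts = random_matrix(rng, n_cells=100)
        scaled = CountMatrix(counts.X * 5, counts.cell_ids, counts.gene_ids)
        a = call_hybrids(counts, GateSpec())
        b = call_hybrids(scaled, GateSpec())
        assert (a.is_hybrid == b.is_hybrid).all()


class TestSummaries:
    def test_single_group_equals_overall(self, rng):
        counts = random_matrix(rng, n_cells=50)
        calls = call_hybrids(counts, GateSpec())
        cells = pd.DataFrame({"tissue": ["tumor"] * 50})
        tab = summarize_by_group(calls, cells, "tissue")
        assert len(tab) == 1
        assert tab["fraction"].iloc[0] == pytest.approx(calls.fraction)

    def test_zero_hybrid_group_included(self):
        counts = CountMatrix(sp.csr_matrix(np.ones((2, 4), dtype=int)),
                             ["a", "b"], GATE_GENES)
        counts.X[1, 0] = 0
        calls = call_hybrids(counts, GateSpec())
        cells = pd.DataFrame({"tissue": ["tumor", "normal"]})
        tab = summarize_by_group(calls, cells, "tissue").set_index("tissue")
        assert tab.loc["normal", "n_hybrids"] == 0
        assert tab.loc["normal", "fraction"] == 0.0
        with pytest.raises(KeyError, match="bogus"):
            summarize_by_group(calls, cells, "bogus")

    def test_planted_tissue_fractions_recovered(self):
        """Tumor/normal hybrid fractions land within the binomial 95% CI of
        the planted per-tissue rates."""
        from hybridcells.simdata import SimConfig, make_programs, simulate_cells

        cfg = SimConfig(seed=3, hybrid_fraction=0.0125, hybrid_tumor_share=0.8,
                        doublet_rate=0.0)
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        calls = call_hybrids(counts, GateSpec())
        tab = summarize_by_group(calls, truth, "tissue").set_index("tissue")
        n_hyb = (truth["true_label"] == "hybrid").sum()
        for tissue, share in [("tumor", 0.8), ("normal", 0.2)]:
            n = tab.loc[tissue, "n_cells"]
            p = n_hyb * share / n
            half = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(tab.loc[tissue, "fraction"] - p) < half + 2 / n

    def test_enrichment_ratio(self):
        assert enrichment_ratio(0.21, 0.05) == pytest.approx(4.2)
        assert enrichment_ratio(0.3, 0.3) == 1.0
        assert (enrichment_ratio(0.2, 0.4) * enrichment_ratio(0.4, 0.2)
                == pytest.approx(1.0))
        with pytest.warns(UserWarning, match="infinite"):
            assert enrichment_ratio(0.1, 0.0) == np.inf


class TestColocalization:
    def test_all_in_one_myeloid_cluster(self, rng):
        counts = random_matrix(rng, n_cells=10)
        calls = call_hybrids(counts, GateSpec(epithelial_markers=("EPCAM",),
                                              myeloid_markers=("CD14",),
                                              min_count=1))
        labels = np.zeros(10, dtype=int)
        clusters = ClusterAssignment(labels=labels,
                                     majority={0: ("macrophage", 0.9)})
        tab = cluster_colocalization(calls, clusters).set_index("lineage")
        if calls.n_hybrids:
            assert tab.loc["myeloid", "fraction"] == 1.0
        assert tab["fraction"].sum() in (0.0, pytest.approx(1.0))

    def test_fractions_partition(self, rng):
        counts = random_matrix(rng, n_cells=60)
        calls = call_hybrids(counts, GateSpec(epithelial_markers=("EPCAM",),
                                              myeloid_markers=("CD14",)))
        labels = rng.integers(0, 3, 60)
        clusters = ClusterAssignment(labels=labels, majority={
            0: ("epithelial", 1.0), 1: ("macrophage", 1.0), 2: ("other", 1.0)})
        tab = cluster_colocalization(calls, clusters)
        if calls.n_hybrids:
            assert tab["fraction"].sum() == pytest.approx(1.0)

    def test_macrophage_weighted_hybrids_land_in_myeloid_clusters(
            self, study_data, study_config):
        """Hybrids mixed toward the macrophage program co-cluster with
        myeloid cells (the annotated-cluster placement the analysis relies
        on)."""
        import numpy as np

        from hybridcells.preprocess import (cluster_graph, embed_pca,
                                            merge_indistinct_clusters,
                                            normalize_log, select_hvg)

        counts, truth = study_data
        norm = normalize_log(counts)
        emb, _ = embed_pca(norm.subset_genes(select_hvg(norm, 2000)), 10,
                           log_libsize=np.log(counts.library_sizes()))
        assign = cluster_graph(emb, 20, 0.8, study_config.seed)
        assign = merge_indistinct_clusters(norm, assign, seed=study_config.seed)
        assign = majority_annotation(assign, truth["annotation"])
        calls = call_hybrids(counts, GateSpec())
        tab = cluster_colocalization(calls, assign).set_index("lineage")
        assert tab.loc["myeloid", "fraction"] > 0.5
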