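import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridcells.simdata import (SimConfig, inject_doublets, make_programs,
                                 simulate_cells, simulate_spatial)

GATE_MARKERS = ("EPCAM", "KRT8", "CD14", "CD163")
ALL_MARKERS = ("EPCAM", "KRT8", "KRT18", "KRT19", "CD14", "CD163", "CD68", "AIF1")


def small_config(**kw):
    defaults = dict(
        n_genes=200,
        cells_per_type={"epithelial": 120, "monocyte": 40,
                        "macrophage": 60, "other": 80},
        seed=11,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestMakePrograms:
    def test_marker_fold_enrichment(self):
        prog = make_programs(small_config())
        for g, owners in [("EPCAM", ["epithelial"]),
                          ("CD163", ["monocyte", "macrophage"])]:
            own = prog.loc[owners, g].min()
            others = prog.loc[[t for t in prog.index if t not in owners], g].max()
            assert own >= 10 * others

    def test_determinism(self):
        cfg = small_config()
        a, b = make_programs(cfg), make_programs(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_overlapping_markers_rejected(self):
        cfg = small_config(marker_genes={"epithelial": ["EPCAM", "CD14"],
                                         "myeloid": ["CD14", "CD163"]})
        with pytest.raises(ValueError, match="disjoint"):
            make_programs(cfg)

    def test_gamma_moments(self):
        # non-marker means are gamma(k, theta): empirical mean within 3 SE of k*theta
        cfg = small_config(n_genes=10_000, gamma_shape=0.5, gamma_scale=2.0)
        prog = make_programs(cfg)
        named = set(ALL_MARKERS) | set(cfg.hybrid_private_genes)
        bg = prog.loc["other", [g for g in prog.columns if g not in named]]
        k, theta = cfg.gamma_shape, cfg.gamma_scale
        se = theta * np.sqrt(k / len(bg))
        assert abs(bg.mean() - k * theta) < 3 * se


class TestSimulateCells:
    def test_no_hybrids_no_doublets_when_disabled(self):
        cfg = small_config(hybrid_fraction=0.0, doublet_rate=0.0)
        _, truth = simulate_cells(cfg, make_programs(cfg))
        assert not truth["true_label"].isin(["hybrid", "doublet"]).any()

    def test_determinism(self):
        cfg = small_config()
        prog = make_programs(cfg)
        c1, t1 = simulate_cells(cfg, prog)
        c2, t2 = simulate_cells(cfg, prog)
        assert (c1.X != c2.X).nnz == 0
        pd.testing.assert_frame_equal(t1, t2)

    def test_type_mean_matches_nb_expectation(self):
        # empirical per-gene mean of one type ~ E[libsize] * relative program
        cfg = small_config(cells_per_type={"other": 2000}, hybrid_fraction=0.0)
        prog = make_programs(cfg)
        counts, truth = simulate_cells(cfg, prog)
        rel = prog.loc["other"] / prog.loc["other"].sum()
        elib = np.exp(cfg.libsize_meanlog + cfg.libsize_sdlog ** 2 / 2)
        expected = elib * rel.to_numpy()
        X = np.asarray(counts.X.todense(), dtype=float)
        emp_mean = X.mean(axis=0)
        emp_se = X.std(axis=0, ddof=1) / np.sqrt(X.shape[0])
        top = np.argsort(-expected)[:25]  # well-expressed genes: stable SE
        z = (emp_mean[top] - expected[top]) / emp_se[top]
        assert np.all(np.abs(z) < 4.5)

    def test_hybrids_express_all_markers(self):
        cfg = small_config(hybrid_fraction=0.1)
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        hyb = counts.subset_cells((truth["true_label"] == "hybrid").to_numpy())
        marker_counts = np.asarray(
            hyb.X[:, hyb.gene_indices(ALL_MARKERS)].sum(axis=0)).ravel()
        assert (marker_counts > 0).all()

    def test_marker_separability(self):
        # rank-sum test between owning and other lineages: p < 1e-6 at 500/type
        cfg = SimConfig(n_genes=300,
                        cells_per_type={"epithelial": 500, "macrophage": 500},
                        hybrid_fraction=0.0, seed=5)
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        epi = (truth["true_label"] == "epithelial").to_numpy()
        for g, owner in [("EPCAM", epi), ("CD163", ~epi)]:
            col = counts.gene_column(g)
            p = stats.mannwhitneyu(col[owner], col[~owner],
                                   alternative="greater").pvalue
            assert p < 1e-6

    def test_hybrid_marker_monotone_in_lambda(self):
        # expected epithelial-marker expression rises with the mixing weight
        cfg = small_config()
        prog = make_programs(cfg)
        rel = prog.div(prog.sum(axis=1), axis=0)
        vals = []
        for lam in np.linspace(0.1, 0.9, 9):
            mix = lam * rel.loc["epithelial"] + (1 - lam) * rel.loc["macrophage"]
            for g, eff in cfg.hybrid_private_genes.items():
                mix[g] *= 2.0 ** eff
            mix /= mix.sum()
            vals.append(mix["EPCAM"] + mix["KRT8"])
        assert np.all(np.diff(vals) > 0)


class TestInjectDoublets:
    def test_rate_zero_is_identity(self):
        cfg = small_config()
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        c2, t2 = inject_doublets(counts, truth, 0.0)
        assert c2 is counts and t2 is truth

    def test_library_size_additivity(self):
        cfg = small_config()
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        c2, t2 = inject_doublets(counts, truth, 0.1, seed=3)
        libs = dict(zip(c2.cell_ids, c2.library_sizes()))
        dbl = t2[t2["true_label"] == "doublet"]
        assert len(dbl) > 0
        for _, row in dbl.iterrows():
            assert libs[row["cell_id"]] == libs[row["parent_a"]] + libs[row["parent_b"]]

    def test_epi_myeloid_gate_probability_matches_enumeration(self):
        # brute-force over the parent pools: P(doublet detects all 4 gate markers)
        cfg = small_config(cells_per_type={"epithelial": 150, "macrophage": 150},
                          hybrid_fraction=0.0)
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        c2, t2 = inject_doublets(counts, truth, 0.5, seed=3, mode="epi_myeloid")
        gidx = counts.gene_indices(GATE_MARKERS)
        det = np.asarray((counts.X[:, gidx] > 0).todense())
        epi = (truth["true_label"] == "epithelial").to_numpy()
        mye = truth["true_label"].isin(["monocyte", "macrophage"]).to_numpy()
        A, B = det[epi], det[mye]
        # enumerate all parent pairs via the 16 detection patterns per pool
        pow2 = 2 ** np.arange(4)
        ca = np.bincount(A @ pow2, minlength=16)
        cb = np.bincount(B @ pow2, minlength=16)
        hits = sum(ca[i] * cb[j] for i in range(16) for j in range(16)
                   if (i | j) == 15)
        p_expected = hits / (ca.sum() * cb.sum())

        dbl_mask = (t2["true_label"] == "doublet").to_numpy()
        dbl_det = np.asarray((c2.X[dbl_mask][:, gidx] > 0).todense())
        frac = dbl_det.all(axis=1).mean()
        n = int(dbl_mask.sum())
        se = np.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(frac - p_expected) < 4 * se + 1e-9

    def test_too_few_singlets(self):
        cfg = small_config(cells_per_type={"epithelial": 1}, hybrid_fraction=0.0)
        counts, truth = simulate_cells(cfg, make_programs(cfg))
        with pytest.raises(ValueError, match="singlets"):
            inject_doublets(counts, truth, 0.5, seed=0)


class TestSimulateSpatial:
    def test_centroids_in_bounds_and_panel_restriction(self):
        cfg = small_config()
        table, truth = simulate_spatial(cfg, panel=list(GATE_MARKERS),
                                        field=(400.0, 300.0))
        assert list(table.counts.gene_ids) == list(GATE_MARKERS)
        assert table.cells["x_centroid"].between(0, 400).all()
        assert table.cells["y_centroid"].between(0, 300).all()

    def test_full_panel_matches_scrna_counts(self):
        cfg = small_config()
        prog = make_programs(cfg)
        counts, _ = simulate_cells(cfg, prog)
        table, _ = simulate_spatial(cfg, panel=list(prog.columns))
        assert (table.counts.X != counts.X).nnz == 0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_spatial(small_config(), panel=[])

    def test_niche_mode_concentrates_types(self):
        cfg = small_config()
        table, truth = simulate_spatial(cfg, panel=["EPCAM"], mode="niche")
        xy = table.cells[["x_centroid", "y_centroid"]].to_numpy()
        lab = truth.set_index("cell_id").loc[
            table.cells["cell_id"], "true_label"].to_numpy()
        epi = xy[lab == "epithelial"]
        other = xy[lab == "other"]
        from scipy.spatial.distance import cdist

        d_epi = cdist(epi, epi)
        np.fill_diagonal(d_epi, np.inf)
        within = d_epi.min(axis=1).mean()
        across = cdist(epi, other).min(axis=1).mean()
        assert within < across
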