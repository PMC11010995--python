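"""End-to-end pipeline: simulate -> preprocess -> doublets -> gate ->
disambiguate -> DE -> GSEA, with flat-file stage outputs and a JSON report.

Every stage writes plain CSV/TSV/MTX/JSON files into the run directory so
individual stages can be re-run and inspected; the report aggregates
per-stage summaries and is stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de as de_mod
from . import disambiguate as dis_mod
from . import gsea as gsea_mod
from .doublets import derive_threshold, score_doublets
from .gate import (GateSpec, call_hybrids, call_hybrids_relaxed,
                   cluster_colocalization, enrichment_ratio, summarize_by_group)
from .preprocess import (PreprocessConfig, cluster_graph, embed_pca,
                         majority_annotation, normalize_log, select_hvg)
from .simdata import (MYELOID_TYPES, SimConfig, inject_doublets, make_programs,
                      simulate_cells, write_simulation)

__all__ = ["PipelineConfig", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

_ALL_STAGES = ("simulate", "preprocess", "doublets", "gate",
               "disambiguate", "de", "gsea")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    gate: GateSpec = field(default_factory=GateSpec)
    threshold_mode: str = "mean_plus_2sd"   # or "fixed"
    fixed_threshold: float = 0.5
    n_sim_null: int = 1000
    n_perm: int = 1000
    gmt_path: str | None = None
    min_set_size: int = 3
    stages: tuple = _ALL_STAGES
    seed: int = 0
    replication_mode: bool = False

    def __post_init__(self) -> None:
        # one global seed drives every stochastic stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.preprocess = dataclasses.replace(self.preprocess, seed=self.seed)
        if self.replication_mode:
            self.threshold_mode = "fixed"

    def config_hash(self) -> str:
        blob = json.dumps(_asdict_jsonable(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _asdict_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _asdict_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the configured stages; returns the machine-readable report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in config.stages:
        if stage not in _ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            summary = _STAGE_FUNCS[stage](config, state, outdir)
        except Exception as err:  # halt with stage name and cause
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        report["stages"][stage] = summary
    (outdir / "report.json").write_text(
        json.dumps(_asdict_jsonable(report), sort_keys=True, indent=1) + "\n")
    return report


def _stage_simulate(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    programs = make_programs(cfg.sim)
    counts, truth = simulate_cells(cfg.sim, programs)
    counts, truth = inject_doublets(counts, truth, cfg.sim.doublet_rate,
                                    seed=cfg.seed)
    write_simulation(outdir / "matrix", counts, truth)
    st.update(counts=counts, truth=truth)
    lab = truth["true_label"]
    return {"n_cells": int(counts.n_cells), "n_genes": int(counts.n_genes),
            "n_hybrids_true": int((lab == "hybrid").sum()),
            "n_doublets_true": int((lab == "doublet").sum())}


def _stage_preprocess(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    counts = st["counts"]
    norm = normalize_log(counts, cfg.preprocess.target_sum)
    hvg = select_hvg(norm, min(cfg.preprocess.n_hvg, counts.n_genes),
                     force_retain=cfg.gate.all_markers)
    loglib = (np.log(counts.library_sizes())
              if cfg.preprocess.regress_depth else None)
    emb, pca = embed_pca(norm.subset_genes(hvg), cfg.preprocess.n_pcs,
                         seed=cfg.seed, log_libsize=loglib)
    clusters = cluster_graph(emb, cfg.preprocess.knn_k,
                             cfg.preprocess.resolution, cfg.seed,
                             graph=cfg.preprocess.graph)
    if cfg.preprocess.merge_indistinct:
        from .preprocess import merge_indistinct_clusters

        clusters = merge_indistinct_clusters(norm, clusters, seed=cfg.seed)
    clusters = majority_annotation(clusters, st["truth"]["annotation"])
    st.update(norm=norm, embedding=emb, pca=pca, clusters=clusters, hvg=hvg)
    pd.DataFrame({"cell_id": counts.cell_ids, "cluster": clusters.labels}).to_csv(
        outdir / "clusters.csv", index=False)
    return {"n_hvg": len(hvg), "n_clusters": clusters.n_clusters,
            "n_pcs": int(emb.shape[1])}


def _stage_doublets(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    scores = score_doublets(st["counts"], seed=cfg.seed)
    if cfg.threshold_mode == "fixed":
        thr = derive_threshold(scores.hybrid_score, "fixed", cfg.fixed_threshold)
    else:
        thr = derive_threshold(scores.hybrid_score, cfg.threshold_mode)
    st.update(scores=scores, threshold=thr)
    pd.DataFrame({
        "cell_id": st["counts"].cell_ids, "cxds": scores.cxds,
        "bcds": scores.bcds, "hybrid_score": scores.hybrid_score,
    }).to_csv(outdir / "doublet_scores.csv", index=False)
    n_removed = int((scores.hybrid_score > thr.value).sum())
    return {"threshold": float(thr.value), "threshold_method": thr.method,
            "n_above_threshold": n_removed}


def _stage_gate(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    counts, truth = st["counts"], st["truth"]
    gate = dataclasses.replace(cfg.gate, apply_doublet_filter=True,
                               threshold=st["threshold"])
    calls = call_hybrids(counts, gate, st["scores"])
    relaxed = call_hybrids_relaxed(counts, cfg.gate.epithelial_markers[0],
                                   cfg.gate.myeloid_markers[-1])
    by_tissue = summarize_by_group(calls, truth, "tissue")
    frac = dict(zip(by_tissue["tissue"], by_tissue["fraction"]))
    ratio = (enrichment_ratio(frac["tumor"], frac["normal"])
             if {"tumor", "normal"} <= set(frac) and frac.get("normal", 0) > 0
             else None)
    coloc = cluster_colocalization(calls, st["clusters"])
    st.update(calls=calls, gate_used=gate)
    pd.DataFrame({"cell_id": counts.cell_ids,
                  "is_hybrid": calls.is_hybrid}).to_csv(
        outdir / "hybrid_calls.csv", index=False)
    by_tissue.to_csv(outdir / "hybrid_by_tissue.csv", index=False)

    truth_hybrid = (truth["true_label"] == "hybrid").to_numpy()
    tp = int((calls.is_hybrid & truth_hybrid).sum())
    precision = tp / calls.n_hybrids if calls.n_hybrids else float("nan")
    recall = tp / truth_hybrid.sum() if truth_hybrid.sum() else float("nan")
    myeloid_frac = float(
        coloc.loc[coloc["lineage"] == "myeloid", "fraction"].iloc[0])
    return {"n_hybrid_calls": calls.n_hybrids,
            "n_relaxed_calls": relaxed.n_hybrids,
            "tumor_normal_enrichment": None if ratio is None else float(ratio),
            "myeloid_colocalization": myeloid_frac,
            "precision_vs_truth": float(precision),
            "recall_vs_truth": float(recall)}


def _stage_disambiguate(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    counts, truth = st["counts"], st["truth"]
    lab = truth["true_label"]
    singlet_mask = ~lab.isin(["doublet", "hybrid"]).to_numpy()
    singlets = counts.subset_cells(singlet_mask)
    lineage = np.where(lab[singlet_mask].isin(MYELOID_TYPES), "myeloid",
                       np.where(lab[singlet_mask] == "epithelial",
                                "epithelial", "other")).astype(object)
    reference = dis_mod.fit_reference_map(singlets, lineage, cfg.preprocess)
    epi = singlets.cell_ids[lineage == "epithelial"]
    mye = singlets.cell_ids[lineage == "myeloid"]
    null = dis_mod.doublet_assignment_null(
        singlets, list(epi), list(mye), n_sim=cfg.n_sim_null,
        preprocess=cfg.preprocess, seed=cfg.seed, reference=reference)

    calls = st["calls"]
    if calls.n_hybrids:
        hybrid_rows = counts.X[calls.is_hybrid]
        k = int(reference.myeloid_placed(hybrid_rows).sum())
        skew = dis_mod.test_myeloid_skew(calls.n_hybrids, k, null.fraction)
    else:
        skew = None

    gate_no_filter = dataclasses.replace(st["gate_used"],
                                         apply_doublet_filter=False,
                                         threshold=None)
    gated_all = call_hybrids(counts, gate_no_filter)
    bimod = dis_mod.test_bimodality(
        st["scores"].hybrid_score[gated_all.is_hybrid], seed=cfg.seed) \
        if gated_all.n_hybrids >= 20 else None

    summary = {
        "null_myeloid_fraction": null.fraction, "null_mc_se": null.mc_se,
        "observed_myeloid_fraction": None if skew is None else skew.observed_fraction,
        "skew_p_value": None if skew is None else skew.p_value,
        "bimodality": None if bimod is None else {
            "delta_bic": bimod.delta_bic, "minor_weight": bimod.minor_weight,
            "decision": bimod.decision},
    }
    (outdir / "disambiguation.json").write_text(
        json.dumps(_asdict_jsonable(summary), sort_keys=True, indent=1) + "\n")
    st["skew"] = skew
    return summary


def _stage_de(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    norm, truth, calls = st["norm"], st["truth"], st["calls"]
    hyb_ids = calls.hybrid_cell_ids
    epi_ids = norm.cell_ids[(truth["true_label"] == "epithelial").to_numpy()
                            & ~calls.is_hybrid]
    if len(hyb_ids) < 3:
        return {"skipped": "fewer than 3 hybrid calls"}
    table = de_mod.volcano_table(de_mod.find_markers(norm, hyb_ids, epi_ids))
    table.to_csv(outdir / "de_hybrid_vs_epithelial.tsv", sep="\t", index=False)
    st["de"] = table
    return {"n_genes_tested": int(len(table)),
            "n_significant": int(table["significant"].sum())}


def _stage_gsea(cfg: PipelineConfig, st: dict, outdir: Path) -> dict:
    if "de" not in st:
        return {"skipped": "no DE table"}
    if cfg.gmt_path:
        collection = gsea_mod.read_gmt(cfg.gmt_path)
    else:
        collection = _synthetic_collection(cfg, st)
    ranking = gsea_mod.rank_from_de(st["de"])
    table = gsea_mod.preranked_gsea(ranking, collection, n_perm=cfg.n_perm,
                                    min_size=cfg.min_set_size, seed=cfg.seed)
    gsea_mod.write_enrichment_tsv(table, outdir / "gsea.tsv")
    top = table.iloc[0] if len(table) else None
    return {"n_sets": int(len(table)),
            "top_pathway": None if top is None else str(top["pathway"]),
            "top_nes": None if top is None else float(top["nes"]),
            "top_p_adj": None if top is None else float(top["p_adj"])}


def _synthetic_collection(cfg: PipelineConfig, st: dict) -> "gsea_mod.GeneSetCollection":
    # planted myeloid/hybrid-program set plus random background sets
    rng = np.random.default_rng([cfg.seed, 9])
    genes = list(st["de"]["gene"])
    sets = {"MYELOID_AND_HYBRID_PROGRAM": list(cfg.sim.marker_genes["myeloid"])
            + list(cfg.sim.hybrid_private_genes)}
    for i in range(10):
        size = min(20, max(cfg.min_set_size, len(genes) // 4))
        sets[f"RANDOM_SET_{i:02d}"] = list(rng.choice(genes, size=size,
                                                      replace=False))
    return gsea_mod.GeneSetCollection(sets=sets, source="synthetic")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "doublets": _stage_doublets,
    "gate": _stage_gate,
    "disambiguate": _stage_disambiguate,
    "de": _stage_de,
    "gsea": _stage_gsea,
}
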