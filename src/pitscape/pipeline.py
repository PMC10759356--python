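"""End-to-end orchestration with one config, derived per-stage seeds and a
reproducible manifest.

A single global seed deterministically derives per-stage seeds by hashing the
stage name, so any stage re-run in isolation reproduces its in-pipeline
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    AGGRESSIVE,
    NON_AGGRESSIVE,
    harmonize_bulk,
    harmonize_sc,
    predict_aggressiveness,
    select_classifier_genes,
    train_classifier,
)
from .datatypes import GeneSet, annotations_to_frame
from .io import write_annotations, write_bulk, write_counts
from .mapping import compute_centroids, centroids_frame, harmonize_genes, map_cells
from .markers import find_markers
from .pseudobulk import (
    build_pseudobulk,
    cluster_dendrogram,
    cosine_similarity_matrix,
    pc_embed,
    profiles_matrix,
    to_newick,
)
from .qc import QCThresholds, apply_qc, default_covariates, lognormalize, regress_scale, select_hvgs
from .signatures import module_score, quadrant_classify
from .simulate import (
    AGGRESSIVE_LABEL,
    generate_bulk_cohort,
    generate_reference_atlas,
    generate_sc_dataset,
)

log = logging.getLogger("pitscape")

STAGES = ("simulate", "qc", "normalize", "markers", "signatures", "map",
          "pseudobulk", "classify")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed = CRC32(stage name) XOR global seed, folded below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (global_seed & 0xFFFFFFFF)) % (2**31)


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    outdir: str = "pitscape_run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)
    map: dict = field(default_factory=dict)
    pseudobulk: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages on a generated dataset and write a manifest.

    Stage order: simulate -> qc -> normalize (+HVG/scale) -> markers ->
    signatures / map / pseudobulk -> classify. Every output is a text file
    under ``cfg.outdir``; the manifest records seeds, parameters and artifact
    paths. Re-running with the same config reproduces identical outputs.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: derive_seed(cfg.seed, s) for s in STAGES},
        "artifacts": {},
    }
    art = manifest["artifacts"]

    # --- simulate ---------------------------------------------------------
    sim_kw = dict(cfg.simulate)
    counts, annotations, truth = generate_sc_dataset(
        seed=derive_seed(cfg.seed, "simulate"), **sim_kw
    )
    write_counts(counts, out / "counts.mtx")
    write_annotations(annotations, out / "annotations.tsv")
    truth.to_json(out / "truth.json")
    art["counts"] = "counts.mtx"
    art["annotations"] = "annotations.tsv"
    art["truth"] = "truth.json"
    ann = annotations_to_frame(annotations)

    # --- qc + normalize ---------------------------------------------------
    thresholds = QCThresholds(**cfg.qc) if cfg.qc else QCThresholds()
    filtered, report = apply_qc(counts, mito_genes=set(truth.mito_genes),
                                thresholds=thresholds)
    (out / "qc_report.json").write_text(json.dumps(report, indent=1))
    art["qc_report"] = "qc_report.json"
    nm = lognormalize(filtered)
    ann = ann.loc[nm.cell_ids]

    n_hvg = min(1000, nm.n_genes)
    hvgs = select_hvgs(nm, filtered, n=n_hvg)
    (out / "hvgs.txt").write_text("\n".join(hvgs) + "\n")
    art["hvgs"] = "hvgs.txt"
    scaled = regress_scale(
        nm.subset_genes(hvgs),
        default_covariates(filtered, set(truth.mito_genes)),
    )

    # --- markers ----------------------------------------------------------
    clusters = ann["cluster"]
    marker_kw = dict(cfg.markers)
    marker_table = find_markers(nm, clusters, **marker_kw)
    marker_table.to_csv(out / "markers.tsv", sep="\t", index=False)
    art["markers"] = "markers.tsv"

    # --- signatures -------------------------------------------------------
    sig_seed = derive_seed(cfg.seed, "signatures")
    prolif = GeneSet("proliferation_program",
                     [g for g in truth.proliferation_genes if g in nm.gene_ids])
    scores = module_score(nm, prolif, seed=sig_seed, **cfg.signatures)
    ga, gb = truth.hormone_genes
    sig_out = pd.DataFrame({"proliferation_score": scores})
    if ga in nm.gene_ids and gb in nm.gene_ids:
        quad = quadrant_classify(nm, ga, gb, groups=ann["group"])
        sig_out["quadrant"] = quad.category
        quad.group_proportions.to_csv(out / "quadrant_proportions.tsv", sep="\t")
        art["quadrant_proportions"] = "quadrant_proportions.tsv"
    sig_out.to_csv(out / "signatures.tsv", sep="\t")
    art["signatures"] = "signatures.tsv"

    # --- reference mapping ------------------------------------------------
    map_seed = derive_seed(cfg.seed, "map")
    centroids = compute_centroids(nm, clusters)
    map_kw = dict(cfg.map)
    atlas_counts, atlas_ann = generate_reference_atlas(
        {c.cluster: c.mean_expression for c in centroids},
        nm.gene_ids, seed=map_seed, **map_kw,
    )
    atlas_nm = lognormalize(atlas_counts)
    q, r, shared = harmonize_genes(atlas_nm, nm)
    ref_centroids = compute_centroids(r, clusters.reindex(r.cell_ids))
    mapping = map_cells(q, ref_centroids)
    atlas_clusters = annotations_to_frame(atlas_ann)["cluster"]
    mapping["true_cluster"] = atlas_clusters.reindex(mapping.index).to_numpy()
    mapping.to_csv(out / "mapping.tsv", sep="\t", index=False)
    art["mapping"] = "mapping.tsv"

    # --- pseudobulk + dendrogram -----------------------------------------
    profiles = build_pseudobulk(nm, ann["sample_id"])
    X, ids = profiles_matrix(profiles)
    n_pcs = min(int(cfg.pseudobulk.get("n_pcs", 20)), len(ids) - 1)
    coords = pc_embed(X, n_pcs=n_pcs)
    sim = cosine_similarity_matrix(coords, ids)
    sim.to_frame().to_csv(out / "pseudobulk_similarity.tsv", sep="\t")
    art["pseudobulk_similarity"] = "pseudobulk_similarity.tsv"
    dend = cluster_dendrogram(scaled, clusters,
                              n_pcs=min(20, len(hvgs) - 1, nm.n_cells - 1))
    (out / "dendrogram.nwk").write_text(to_newick(dend) + "\n")
    art["dendrogram"] = "dendrogram.nwk"

    # --- classifier transfer ---------------------------------------------
    cls_seed = derive_seed(cfg.seed, "classify")
    cls_kw = dict(cfg.classify)
    n_trees = int(cls_kw.pop("n_trees", 500))
    aggr_labels = pd.Series(
        [AGGRESSIVE_LABEL if c in truth.aggressive_cells else clusters[c]
         for c in nm.cell_ids], index=nm.cell_ids,
    )
    mix_centroids = {c.cluster: c.mean_expression
                     for c in compute_centroids(nm, aggr_labels)}
    bulk = generate_bulk_cohort(truth, mix_centroids, nm.gene_ids,
                                seed=cls_seed, **cls_kw)
    write_bulk(bulk, out / "bulk_cohort.csv")
    art["bulk_cohort"] = "bulk_cohort.csv"

    aggr_markers = find_markers(
        nm,
        pd.Series(np.where(aggr_labels == AGGRESSIVE_LABEL, AGGRESSIVE_LABEL, "rest"),
                  index=nm.cell_ids),
    )
    genes = select_classifier_genes(aggr_markers, bulk.gene_ids,
                                    cluster=AGGRESSIVE_LABEL)
    (out / "selection_log.json").write_text(json.dumps(genes.selection_log, indent=1))
    art["selection_log"] = "selection_log.json"

    sc_feat = harmonize_sc(nm, genes)
    bulk_feat = harmonize_bulk(bulk, genes)
    cell_labels = pd.Series(
        [AGGRESSIVE if c in truth.aggressive_cells else NON_AGGRESSIVE
         for c in nm.cell_ids], index=nm.cell_ids,
    )
    # keep per-tree strata no larger than the available cells at demo scale
    n_pos = min(1500, int((cell_labels == AGGRESSIVE).sum()) * 10)
    model = train_classifier(sc_feat, cell_labels, n_trees=n_trees,
                             n_pos=n_pos, seed=cls_seed)
    preds = predict_aggressiveness(model, bulk_feat)
    preds["true_label"] = [bulk.labels[bulk.sample_ids.index(s)]
                           for s in preds["sample_id"]]
    preds.to_csv(out / "predictions.tsv", sep="\t", index=False)
    art["predictions"] = "predictions.tsv"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline complete; %d artifacts in %s", len(art), out)
    return manifest
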