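"""Cross-dataset cell assignment by centroid correlation.

Each reference cluster is represented by its centroid (mean log-normalized
expression); every query cell is assigned to the centroid with the highest
Pearson correlation over the shared gene space, after explicit gene-space
harmonization (case-normalized symbols or a user ortholog table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import NormalizedMatrix

log = logging.getLogger("pitscape")

UNASSIGNED = "unassigned"


@dataclass
class CentroidProfile:
    """Mean log-normalized expression of one reference cluster."""

    cluster: str
    mean_expression: np.ndarray
    n_cells: int
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.mean_expression = np.asarray(self.mean_expression, dtype=float)
        if self.n_cells < 1:
            raise ValueError("centroid must summarize at least one cell")
        if self.mean_expression.shape != (len(self.gene_ids),):
            raise ValueError("centroid length does not match gene ids")


def harmonize_genes(
    query: NormalizedMatrix,
    reference: NormalizedMatrix,
    ortholog_map: dict[str, str] | None = None,
) -> tuple[NormalizedMatrix, NormalizedMatrix, list[str]]:
    """Restrict both matrices to shared genes, in the query's gene order.

    Without an ortholog table, genes match when their uppercased symbols are
    identical (mouse Gh1 <-> human GH1). With ``ortholog_map`` (reference
    gene id -> query gene id, one-to-one), only mapped pairs are shared.
    """
    if ortholog_map is not None:
        targets = list(ortholog_map.values())
        if len(set(targets)) != len(targets):
            raise ValueError("ortholog_map must be one-to-one")
        ref_to_query = dict(ortholog_map)
    else:
        ref_to_query = {g: g.upper() for g in reference.gene_ids}
        if len(set(ref_to_query.values())) != len(ref_to_query):
            raise ValueError("uppercased reference symbols collide; supply ortholog_map")

    query_upper = {(g.upper() if ortholog_map is None else g): g for g in query.gene_ids}
    pairs: dict[str, str] = {}
    for ref_gene in reference.gene_ids:
        target = ref_to_query.get(ref_gene)
        if target is None:
            continue
        qg = query_upper.get(target)
        if qg is not None:
            pairs[qg] = ref_gene
    shared = [g for g in query.gene_ids if g in pairs]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} shared genes; at least 50 required")
    q = query.subset_genes(shared)
    r = reference.subset_genes([pairs[g] for g in shared])
    # present the reference in the query's namespace
    r = NormalizedMatrix(r.values, shared, list(r.cell_ids), r.scale_factor, r.log_base)
    log.info("harmonize_genes: %d shared genes", len(shared))
    return q, r, shared


def compute_centroids(nm: NormalizedMatrix, clusters) -> list[CentroidProfile]:
    """Per-cluster mean of log-normalized expression."""
    labels = pd.Series(clusters).reindex(nm.cell_ids) if not isinstance(clusters, pd.Series) \
        else clusters.reindex(nm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    if (labels.astype(str) == "").any():
        raise ValueError("empty cluster label")
    out = []
    for lab in sorted(labels.unique()):
        mask = (labels == lab).to_numpy()
        out.append(
            CentroidProfile(
                str(lab), nm.values[:, mask].mean(axis=1), int(mask.sum()),
                list(nm.gene_ids),
            )
        )
    return out


def centroids_frame(centroids: list[CentroidProfile]) -> pd.DataFrame:
    """Centroids as a genes x clusters DataFrame (shared gene order required)."""
    genes = centroids[0].gene_ids
    for c in centroids:
        if c.gene_ids != genes:
            raise ValueError("centroids have inconsistent gene spaces")
    return pd.DataFrame(
        {c.cluster: c.mean_expression for c in centroids}, index=genes
    )


def map_cells(
    query: NormalizedMatrix,
    centroids: list[CentroidProfile],
    min_r: float = -1.0,
) -> pd.DataFrame:
    """Assign each query cell to the best-correlated centroid.

    Returns a DataFrame with one correlation column per centroid plus
    best_cluster / best_r. Ties are broken by cluster label order (labels are
    processed sorted). Zero-variance cells or centroids give r = 0 (logged).
    Cells with best_r < ``min_r`` are labeled "unassigned".
    """
    cf = centroids_frame(centroids)
    if list(cf.index) != list(query.gene_ids):
        raise ValueError("query genes do not match centroid gene order; run harmonize_genes")
    labels = sorted(cf.columns)
    C = cf[labels].to_numpy()

    X = query.values  # genes x cells
    Xc = X - X.mean(axis=0, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=0)
    cn = np.linalg.norm(Cc, axis=0)
    zero_cells = xn == 0
    zero_cent = cn == 0
    if zero_cells.any():
        log.info("map_cells: %d zero-variance cells, r set to 0", int(zero_cells.sum()))
    if zero_cent.any():
        log.info("map_cells: zero-variance centroids %s, r set to 0",
                 [labels[i] for i in np.flatnonzero(zero_cent)])
    xn[zero_cells] = 1.0
    cn[zero_cent] = 1.0
    R = (Xc.T @ Cc) / np.outer(xn, cn)
    R[zero_cells, :] = 0.0
    R[:, zero_cent] = 0.0

    best_idx = R.argmax(axis=1)
    best_r = R[np.arange(R.shape[0]), best_idx]
    best = np.array([labels[i] for i in best_idx], dtype=object)
    best[best_r < min_r] = UNASSIGNED
    out = pd.DataFrame(R, index=query.cell_ids, columns=[f"r_{l}" for l in labels])
    out.insert(0, "cell_id", query.cell_ids)
    out["best_cluster"] = best
    out["best_r"] = best_r
    return out
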