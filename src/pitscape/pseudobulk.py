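"""Pseudo-bulk profiles, PC-space cosine similarity and the TF dendrogram.

A pseudo-bulk sample is the gene-wise sum of log-normalized expression over
all cells of one sample. Sample-level structure is read off the pairwise
cosine similarity of pseudo-bulk profiles embedded into the leading principal
components; cluster regulatory similarity is summarized by a hierarchical
dendrogram over cluster centroids in TF-expression PC space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage, to_tree
from scipy.spatial.distance import pdist

from .datatypes import NormalizedMatrix, ScaledMatrix

log = logging.getLogger("pitscape")


@dataclass
class PseudobulkProfile:
    sample_id: str
    summed_expression: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.summed_expression = np.asarray(self.summed_expression, dtype=float)
        if self.n_cells < 1:
            raise ValueError("pseudo-bulk profile must cover at least one cell")
        if (self.summed_expression < 0).any():
            raise ValueError("summed log-normalized expression must be non-negative")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class DendrogramResult:
    leaf_labels: list[str]
    merges: np.ndarray  # scipy linkage matrix, (n-1) x 4
    linkage: str

    def __post_init__(self) -> None:
        if self.merges.shape != (len(self.leaf_labels) - 1, 4):
            raise ValueError("merge history must have n-1 rows for n leaves")


def build_pseudobulk(nm: NormalizedMatrix, sample_of_cell) -> list[PseudobulkProfile]:
    """Sum log-normalized expression over all cells of each sample."""
    labels = pd.Series(sample_of_cell).reindex(nm.cell_ids) if not isinstance(sample_of_cell, pd.Series) \
        else sample_of_cell.reindex(nm.cell_ids)
    if labels.isna().any():
        raise ValueError("sample labels missing for some cells")
    out = []
    for s in sorted(labels.unique()):
        mask = (labels == s).to_numpy()
        out.append(PseudobulkProfile(str(s), nm.values[:, mask].sum(axis=1), int(mask.sum())))
    return out


def profiles_matrix(profiles: list[PseudobulkProfile]) -> tuple[np.ndarray, list[str]]:
    """Stack pseudo-bulk profiles into an observations x genes matrix."""
    return np.vstack([p.summed_expression for p in profiles]), [p.sample_id for p in profiles]


def pc_embed(X: np.ndarray, n_pcs: int = 20, scale: bool = True) -> np.ndarray:
    """Project observations x features onto the top principal components.

    Features are centered (and scaled to unit variance when ``scale``;
    constant features dropped with a log message) and the data projected onto
    the leading ``n_pcs`` right singular directions. The sign of each
    component is fixed so its largest-magnitude loading is positive, making
    the embedding deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    Y = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = Y.std(axis=0, ddof=1)
        keep = sd > 1e-12
        if not keep.all():
            log.info("pc_embed: dropped %d constant features", int((~keep).sum()))
        Y = Y[:, keep] / sd[keep]
    if n_pcs > min(X.shape[0] - 1, Y.shape[1]):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(observations-1, features)="
            f"{min(X.shape[0] - 1, Y.shape[1])}"
        )
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    for j in range(n_pcs):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U[:, :n_pcs] * S[:n_pcs]


def cosine_similarity_matrix(coords: np.ndarray, ids: list[str]) -> SimilarityMatrix:
    """Pairwise cosine similarity; pairs involving an all-zero row get 0."""
    coords = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    zero = norms == 0
    if zero.any():
        log.info("cosine_similarity: %d zero rows, their similarities set to 0",
                 int(zero.sum()))
    safe = np.where(zero, 1.0, norms)
    S = (coords @ coords.T) / np.outer(safe, safe)
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(ids), S)


def cluster_dendrogram(
    sm: ScaledMatrix,
    clusters,
    n_pcs: int = 20,
    linkage: str = "complete",
    tf_genes: list[str] | None = None,
) -> DendrogramResult:
    """Hierarchical dendrogram over cluster centroids in PC space.

    The scaled matrix (optionally restricted to a transcription-factor gene
    list) is embedded by PCA over cells, cluster means are taken in PC space
    and merged agglomeratively under the chosen linkage on Euclidean
    distances. ``n_pcs`` is capped at the available rank with a log message.
    """
    if linkage not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    values, gene_ids = sm.values, list(sm.gene_ids)
    if tf_genes is not None:
        present = [g for g in tf_genes if g in set(gene_ids)]
        if not present:
            raise ValueError("no TF gene present in the matrix")
        pos = pd.Index(gene_ids).get_indexer(present)
        values = values[pos]
        gene_ids = present
    labels = pd.Series(clusters).reindex(sm.cell_ids) if not isinstance(clusters, pd.Series) \
        else clusters.reindex(sm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("at least 2 clusters required for a dendrogram")

    k = min(n_pcs, values.shape[1] - 1, values.shape[0])
    if k < n_pcs:
        log.info("cluster_dendrogram: n_pcs capped at %d", k)
    coords = pc_embed(values.T, n_pcs=k, scale=False)  # already scaled input
    cent = np.vstack([
        coords[(labels == lab).to_numpy()].mean(axis=0) for lab in uniq
    ])
    if linkage == "ward":
        Z = scipy_linkage(cent, method="ward")
    else:
        Z = scipy_linkage(pdist(cent), method=linkage)
    return DendrogramResult([str(u) for u in uniq], Z, linkage)


def to_newick(d: DendrogramResult) -> str:
    """Serialize the merge history as a Newick string with branch lengths."""
    tree = to_tree(d.merges)

    def fmt(node) -> str:
        if node.is_leaf():
            return d.leaf_labels[node.id]
        left, right = node.get_left(), node.get_right()
        bl_l = max(node.dist - left.dist, 0.0)
        bl_r = max(node.dist - right.dist, 0.0)
        return f"({fmt(left)}:{bl_l:.6g},{fmt(right)}:{bl_r:.6g})"

    return fmt(tree) + ";"
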