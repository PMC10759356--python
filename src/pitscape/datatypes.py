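"""Core in-memory containers for the pipeline.

All single-cell matrices are genes x cells; bulk cohorts are samples x genes
(the direction in which the classifier is transferred). Conversions between
the two orientations are always explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ScaledMatrix",
    "CellAnnotation",
    "GeneSet",
    "BulkCohort",
    "annotations_to_frame",
    "frame_to_annotations",
]


def _check_ids(ids: list[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells.

    Entries must be non-negative integers; gene and cell identifiers are
    unique and ordered exactly as on disk.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        if self.counts.size == 0:
            self.counts = self.counts.astype(np.int64)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                bad = np.argwhere(self.counts != np.round(self.counts))
                g, c = bad[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"cell {self.cell_ids[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells.

    value(g, c) = log(count(g, c) / total(c) * scale_factor + 1), natural log.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale_factor: float = 10_000.0
    log_base: str = "natural"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        if (self.values < 0).any():
            raise ValueError("log-normalized values must be non-negative")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.log_base != "natural":
            raise ValueError("only natural-log normalization is supported")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match identifier lists")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, genes: list[str]) -> "NormalizedMatrix":
        idx = pd.Index(self.gene_ids)
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        pos = idx.get_indexer(genes)
        return NormalizedMatrix(
            self.values[pos], list(genes), list(self.cell_ids),
            self.scale_factor, self.log_base,
        )


@dataclass
class ScaledMatrix:
    """Covariate-regressed, per-gene standardized expression (genes x cells)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    regressed_covariates: list[str] = field(default_factory=list)
    clip: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match identifier lists")


@dataclass
class CellAnnotation:
    """Per-cell metadata: source sample, normal/tumor group, cluster label."""

    cell_id: str
    sample_id: str
    group: str
    cluster: str

    def __post_init__(self) -> None:
        if self.group not in ("normal", "tumor"):
            raise ValueError(f"group must be 'normal' or 'tumor', got {self.group!r}")
        if not self.cluster:
            raise ValueError(f"empty cluster label for cell {self.cell_id!r}")


def annotations_to_frame(annotations: list[CellAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [a.cell_id for a in annotations],
            "sample_id": [a.sample_id for a in annotations],
            "group": [a.group for a in annotations],
            "cluster": [a.cluster for a in annotations],
        }
    ).set_index("cell_id", drop=False)


def frame_to_annotations(df: pd.DataFrame) -> list[CellAnnotation]:
    return [
        CellAnnotation(str(r.cell_id), str(r.sample_id), str(r.group), str(r.cluster))
        for r in df.itertuples(index=False)
    ]


@dataclass
class GeneSet:
    """A named gene list, e.g. a proliferation program or an M1/M2 signature."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        self.genes = _check_ids(self.genes, f"gene (set {self.name!r})")


@dataclass
class BulkCohort:
    """Bulk expression, samples x genes; missing entries are NaN, never zero."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must align with sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
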