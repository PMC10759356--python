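"""Readers and writers for the standard on-disk formats.

Matrix Market counts follow the 10x convention: genes as rows, 1-based
coordinates, companion ``features.tsv`` / ``barcodes.tsv`` next to the
``.mtx``; gzipped variants are accepted. Loaders never reorder, deduplicate
or coerce silently — any mutation is an error naming the offending entry.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import BulkCohort, CellAnnotation, CountMatrix, GeneSet, frame_to_annotations

log = logging.getLogger("pitscape")

DEFAULT_NA_TOKENS = ("NA", "NaN", "")


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_companion(mtx_path: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        for suffix in ("", ".gz"):
            p = mtx_path.parent / (name + suffix)
            if p.exists():
                return p
    raise FileNotFoundError(
        f"no companion file among {names} next to {mtx_path}"
    )


def _read_id_column(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def load_counts(path: str | Path, format: str | None = None) -> CountMatrix:
    """Load a raw count matrix from Matrix Market (+TSV companions) or dense TSV.

    ``format`` is inferred from the file name when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "mtx" if ".mtx" in path.name else "tsv"
    if format == "mtx":
        genes = _read_id_column(_find_companion(path, ("features.tsv", "genes.tsv")))
        cells = _read_id_column(_find_companion(path, ("barcodes.tsv",)))
        mat = scipy.io.mmread(_open_maybe_gz(path))
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        return CountMatrix(counts, genes, cells)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns])
    raise ValueError(f"unknown count format {format!r}")


def write_counts(m: CountMatrix, path: str | Path, format: str | None = None) -> None:
    """Write counts; ``load_counts`` on the result reproduces ``m`` exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format is None:
        format = "mtx" if ".mtx" in path.name else "tsv"
    if format == "mtx":
        sparse = scipy.sparse.coo_matrix(m.counts)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        with open(path.parent / "features.tsv", "w") as fh:
            fh.writelines(f"{g}\n" for g in m.gene_ids)
        with open(path.parent / "barcodes.tsv", "w") as fh:
            fh.writelines(f"{c}\n" for c in m.cell_ids)
    elif format == "tsv":
        m.to_frame().to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown count format {format!r}")


def load_bulk(
    path: str | Path,
    na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS,
    samples_as_rows: bool = True,
) -> BulkCohort:
    """Load a bulk cohort CSV (sample rows x gene columns by default).

    Missing-value tokens are mapped to NaN; any other non-numeric field is an
    error reported with its row/column coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if not samples_as_rows:
        raw = raw.T
    values = np.empty(raw.shape, dtype=float)
    tokens = set(na_tokens)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            s = cell.strip()
            if s in tokens:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(s)
            except ValueError:
                raise ValueError(
                    f"unparseable value {cell!r} at sample {raw.index[i]!r}, "
                    f"gene {col!r} in {path}"
                ) from None
    return BulkCohort(values, [str(s) for s in raw.index], [str(g) for g in raw.columns])


def write_bulk(b: BulkCohort, path: str | Path, na_token: str = "NA") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    b.to_frame().to_csv(path, na_rep=na_token)


def load_annotations(path: str | Path) -> list[CellAnnotation]:
    """Load a per-cell annotation TSV with columns cell_id, sample_id, group, cluster."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "sample_id", "group", "cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return frame_to_annotations(df[["cell_id", "sample_id", "group", "cluster"]])


def write_annotations(annotations: list[CellAnnotation], path: str | Path) -> None:
    from .datatypes import annotations_to_frame

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def load_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Load a gene set from a one-gene-per-line text file."""
    path = Path(path)
    genes = [line.strip() for line in _open_maybe_gz(path) if line.strip()]
    return GeneSet(name or path.stem, genes)


def load_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Load gene sets from a GMT file (name, description, genes... per line)."""
    sets = []
    with _open_maybe_gz(Path(path)) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets
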