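"""Cell/gene quality control, log normalization, HVG selection and scaling.

The normalization is the standard library-size "TPM-like" transform: counts
are divided by the cell total, multiplied by a scale factor (default 10,000)
and natural-log transformed after adding a pseudo-count of 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import CountMatrix, NormalizedMatrix, ScaledMatrix

log = logging.getLogger("pitscape")


@dataclass
class QCThresholds:
    """Cell and gene filter cutoffs.

    No universal numeric cutoffs exist for droplet scRNA-seq QC, so these
    defaults are package choices and every field is configurable. For
    cross-species reference data the conventional filters are
    ``genes_min=200`` and ``mito_max=0.5``.
    """

    umi_min: int = 500
    umi_max: int = 60_000
    genes_min: int = 200
    genes_max: int = 8_000
    mito_max: float = 0.2
    dissoc_max: float = 0.05
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.umi_min > self.umi_max or self.genes_min > self.genes_max:
            raise ValueError("min thresholds must not exceed max thresholds")
        for frac, name in [(self.mito_max, "mito_max"), (self.dissoc_max, "dissoc_max")]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def apply_qc(
    m: CountMatrix,
    mito_genes: set[str] | None = None,
    dissoc_genes: set[str] | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[CountMatrix, dict]:
    """Remove low-quality cells, then genes detected in too few cells.

    Four cell filters: UMI total out of range, detected-gene count out of
    range, mitochondrial fraction too high, dissociation-signature fraction
    too high. Cells are filtered first, genes second. Returns the filtered
    matrix and a report of per-filter removal counts.
    """
    mito_genes = mito_genes or set()
    dissoc_genes = dissoc_genes or set()
    t = thresholds or QCThresholds()
    for s, name in [(mito_genes, "mito"), (dissoc_genes, "dissociation")]:
        unknown = s - set(m.gene_ids)
        if unknown:
            raise ValueError(f"{name} gene ids not in matrix: {sorted(unknown)[:5]}")

    counts = m.counts
    totals = counts.sum(axis=0)
    n_detected = (counts > 0).sum(axis=0)
    mito_mask = np.isin(m.gene_ids, list(mito_genes))
    dissoc_mask = np.isin(m.gene_ids, list(dissoc_genes))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, counts[mito_mask].sum(axis=0) / totals, 0.0)
        dissoc_frac = np.where(totals > 0, counts[dissoc_mask].sum(axis=0) / totals, 0.0)

    fail_umi = (totals < t.umi_min) | (totals > t.umi_max)
    fail_genes = (n_detected < t.genes_min) | (n_detected > t.genes_max)
    fail_mito = mito_frac > t.mito_max
    fail_dissoc = dissoc_frac > t.dissoc_max
    keep_cells = ~(fail_umi | fail_genes | fail_mito | fail_dissoc)

    report = {
        "n_cells_in": m.n_cells,
        "n_genes_in": m.n_genes,
        "cells_failing_umi": int(fail_umi.sum()),
        "cells_failing_gene_count": int(fail_genes.sum()),
        "cells_failing_mito": int(fail_mito.sum()),
        "cells_failing_dissociation": int(fail_dissoc.sum()),
        "cells_removed": int((~keep_cells).sum()),
    }
    if not keep_cells.any():
        raise ValueError(f"all cells removed by QC; report: {report}")

    sub = counts[:, keep_cells]
    detected = (sub > 0).sum(axis=1)
    keep_genes = detected >= t.min_cells_per_gene
    report["genes_removed"] = int((~keep_genes).sum())
    report["n_cells_out"] = int(keep_cells.sum())
    report["n_genes_out"] = int(keep_genes.sum())

    out = CountMatrix(
        sub[keep_genes],
        [g for g, k in zip(m.gene_ids, keep_genes) if k],
        [c for c, k in zip(m.cell_ids, keep_cells) if k],
    )
    log.info("QC: %d/%d cells, %d/%d genes retained",
             out.n_cells, m.n_cells, out.n_genes, m.n_genes)
    return out, report


def lognormalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """value(g, c) = ln(count(g, c) / total(c) * scale_factor + 1)."""
    totals = m.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {m.cell_ids[zero[0]]!r} has zero total count")
    values = np.log1p(m.counts / totals * scale_factor)
    return NormalizedMatrix(values, list(m.gene_ids), list(m.cell_ids), scale_factor)


def select_hvgs(
    nm: NormalizedMatrix,
    raw: CountMatrix,
    n: int = 2000,
    span: float = 0.3,
) -> list[str]:
    """Rank genes by variance standardized against a mean-variance trend.

    A vst-style score computed on raw counts: per gene, counts are
    standardized by the trend-predicted standard deviation (local regression
    of log10 variance on log10 mean, span ``span``), clipped at sqrt(n_cells),
    and the variance of the clipped values is the score. The top ``n`` gene
    ids are returned, ties broken by gene id.
    """
    if raw.gene_ids != nm.gene_ids or raw.cell_ids != nm.cell_ids:
        raise ValueError("raw and normalized matrices must share genes and cells")
    if raw.n_genes < 10:
        raise ValueError("at least 10 genes required to fit the mean-variance trend")
    if n > raw.n_genes:
        raise ValueError("n exceeds the number of genes")

    x = raw.counts.astype(float)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    score = np.zeros(raw.n_genes)
    usable = (mean > 0) & (var > 0)
    if usable.sum() >= 10:
        lx = np.log10(mean[usable])
        ly = np.log10(var[usable])
        fit = lowess(ly, lx, frac=span, xvals=lx)
        sd_pred = np.sqrt(10.0 ** fit)
        clip = np.sqrt(raw.n_cells)
        z = (x[usable] - mean[usable, None]) / sd_pred[:, None]
        np.clip(z, -clip, clip, out=z)
        score[usable] = z.var(axis=1, ddof=1)

    order = sorted(range(raw.n_genes), key=lambda i: (-score[i], raw.gene_ids[i]))
    return [raw.gene_ids[i] for i in order[:n]]


def default_covariates(raw: CountMatrix, mito_genes: set[str] | None = None) -> pd.DataFrame:
    """Per-cell total UMI count and mitochondrial fraction, for regress_scale."""
    mito_genes = mito_genes or {g for g in raw.gene_ids if g.upper().startswith("MT-")}
    totals = raw.counts.sum(axis=0).astype(float)
    mito_mask = np.isin(raw.gene_ids, list(mito_genes))
    mito_frac = np.where(totals > 0, raw.counts[mito_mask].sum(axis=0) / totals, 0.0)
    return pd.DataFrame(
        {"total_umis": totals, "mito_fraction": mito_frac}, index=raw.cell_ids
    )


def regress_scale(
    nm: NormalizedMatrix,
    covariates: pd.DataFrame,
    clip: float | None = None,
) -> ScaledMatrix:
    """OLS-residualize each gene on the covariates, then standardize.

    Per gene: residuals of log-normalized expression on the covariates (with
    intercept), centered and scaled to unit variance (n-1 denominator).
    Constant genes yield an all-zero row (logged, not an error). Optional
    symmetric clipping at ``clip``.
    """
    missing = [c for c in nm.cell_ids if c not in covariates.index]
    if missing:
        raise ValueError(f"covariates missing for cells: {missing[:5]}")
    X = np.column_stack(
        [np.ones(nm.n_cells), covariates.loc[nm.cell_ids].to_numpy(dtype=float)]
    )
    beta, *_ = np.linalg.lstsq(X, nm.values.T, rcond=None)
    resid = nm.values - (X @ beta).T
    mu = resid.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] <= 1e-12
    if constant.any():
        log.info("regress_scale: %d constant genes set to zero", int(constant.sum()))
    sd[constant] = 1.0
    values = (resid - mu) / sd
    values[constant] = 0.0
    if clip is not None:
        np.clip(values, -clip, clip, out=values)
    return ScaledMatrix(
        values, list(nm.gene_ids), list(nm.cell_ids),
        regressed_covariates=list(covariates.columns), clip=clip,
    )
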