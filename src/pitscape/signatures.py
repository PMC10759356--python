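"""Gene-set scoring: mean-expression signatures, binned-control module scores,
cell-cycle phase assignment, ternary state scores and the hormone
co-expression quadrant analysis.

The module score follows the classic binned-control recipe: genes are binned
by mean expression, each set gene draws control genes from its own bin, and
the score is the set mean minus the pooled control mean — so a random gene
set scores ~0 regardless of expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneSet, NormalizedMatrix

log = logging.getLogger("pitscape")

QUADRANT_CATEGORIES = ["neither", "A_only", "B_only", "both_low", "both_high", "both_mixed"]


def _present_genes(nm: NormalizedMatrix, gs: GeneSet) -> list[str]:
    idx = set(nm.gene_ids)
    present = [g for g in gs.genes if g in idx]
    dropped = len(gs.genes) - len(present)
    if dropped:
        log.info("gene set %r: %d/%d genes absent, dropped", gs.name, dropped, len(gs.genes))
    if not present:
        raise ValueError(f"no gene of set {gs.name!r} is present in the matrix")
    return present


def mean_signature(nm: NormalizedMatrix, gs: GeneSet) -> pd.Series:
    """Per-cell mean of log-normalized expression over the set's present genes."""
    present = _present_genes(nm, gs)
    pos = pd.Index(nm.gene_ids).get_indexer(present)
    return pd.Series(nm.values[pos].mean(axis=0), index=nm.cell_ids, name=gs.name)


def _expression_bins(nm: NormalizedMatrix, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index per gene, binned on mean expression.

    Ties in mean expression are broken by gene id so binning is deterministic.
    """
    means = nm.values.mean(axis=1)
    order = sorted(range(nm.n_genes), key=lambda i: (means[i], nm.gene_ids[i]))
    bins = np.empty(nm.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        bins[chunk] = b
    return bins


def module_score(
    nm: NormalizedMatrix,
    gs: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    For each set gene, ``n_ctrl`` control genes are drawn with replacement
    (seeded) from the gene's expression bin; the score is the mean expression
    of the set genes minus the mean over all pooled control draws.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    present = _present_genes(nm, gs)
    gene_index = pd.Index(nm.gene_ids)
    set_pos = gene_index.get_indexer(present)
    set_mask = np.zeros(nm.n_genes, dtype=bool)
    set_mask[set_pos] = True

    bins = _expression_bins(nm, n_bins)
    rng = np.random.default_rng(seed)
    control_rows: list[np.ndarray] = []
    for g in set_pos:
        b = bins[g]
        pool = np.flatnonzero((bins == b) & ~set_mask)
        if pool.size == 0:
            # bin degenerate (only set genes): borrow the nearest bin with
            # non-set genes
            for delta in range(1, n_bins):
                for nb in (b - delta, b + delta):
                    if 0 <= nb < n_bins:
                        pool = np.flatnonzero((bins == nb) & ~set_mask)
                        if pool.size:
                            break
                if pool.size:
                    break
            log.info("module_score %r: bin %d degenerate, borrowed controls", gs.name, b)
            if pool.size == 0:
                raise ValueError("no control genes available outside the set")
        control_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    controls = np.concatenate(control_rows)
    score = nm.values[set_pos].mean(axis=0) - nm.values[controls].mean(axis=0)
    return pd.Series(score, index=nm.cell_ids, name=gs.name)


def cell_cycle_phase(
    nm: NormalizedMatrix,
    s_set: GeneSet,
    g2m_set: GeneSet,
    seed: int = 0,
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> pd.DataFrame:
    """S/G2M module scores and discrete phase per cell.

    Phase is G1 when both scores are <= 0, otherwise the phase of the larger
    score.
    """
    s_score = module_score(nm, s_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    g2m_score = module_score(nm, g2m_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + 1)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score.to_numpy() > g2m_score.to_numpy(), "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase}, index=nm.cell_ids
    )


def ternary_scores(
    sig_e: pd.Series, sig_m: pd.Series, sig_s: pd.Series
) -> pd.DataFrame:
    """Normalize three non-negative mean-expression signatures onto the simplex.

    Returns per-cell (e, m, s) summing to 1; all-zero cells map to
    (1/3, 1/3, 1/3) with a logged count.
    """
    df = pd.DataFrame({"e": sig_e, "m": sig_m, "s": sig_s})
    if df.isna().any().any():
        raise ValueError("signatures cover different cells")
    if (df.to_numpy() < 0).any():
        raise ValueError(
            "ternary scores require non-negative mean-expression signatures"
        )
    total = df.sum(axis=1)
    zero = total == 0
    if zero.any():
        log.info("ternary_scores: %d cells with all-zero signatures set to (1/3,1/3,1/3)",
                 int(zero.sum()))
    out = df.div(total.where(~zero, 1.0), axis=0)
    out[zero] = 1.0 / 3.0
    # make the row sum exactly 1.0 in floating point: s is the complement of
    # the rounded e+m (clamped at 0, absorbing the ulp into m if needed)
    e = out["e"].to_numpy()
    m = out["m"].to_numpy()
    s = 1.0 - (e + m)
    neg = s < 0
    s[neg] = 0.0
    m[neg] = 1.0 - e[neg]
    return pd.DataFrame({"e": e, "m": m, "s": s}, index=df.index)


@dataclass
class QuadrantSummary:
    """Per-cell hormone co-expression categories and per-group proportions."""

    category: pd.Series
    group_proportions: pd.DataFrame
    double_expressing_split: pd.DataFrame
    high_min: dict[str, float]

    def __post_init__(self) -> None:
        rowsums = self.group_proportions.sum(axis=1)
        if not np.allclose(rowsums, 1.0):
            raise ValueError("group proportions must sum to 1")


def quadrant_classify(
    nm: NormalizedMatrix,
    gene_a: str,
    gene_b: str,
    groups,
    expr_min: float = 0.0,
    high_min: float | dict[str, float] | None = None,
) -> QuadrantSummary:
    """Categorize cells by joint expression of a hormone gene pair.

    A gene is "expressed" in a cell when value > ``expr_min`` and "high" when
    value >= ``high_min``. When ``high_min`` is None it defaults, per gene,
    to the upper-quartile value among expressing cells (scale-free default).
    Categories: neither, A_only, B_only and — for double-expressing cells —
    both_low, both_high, both_mixed. ``group_proportions`` are over all cells
    of each group; ``double_expressing_split`` is the low-low vs high-high
    fraction among double-expressing cells.
    """
    for g in (gene_a, gene_b):
        if g not in nm.gene_ids:
            raise KeyError(f"gene {g!r} not present in the matrix")
    idx = pd.Index(nm.gene_ids)
    va = nm.values[idx.get_loc(gene_a)]
    vb = nm.values[idx.get_loc(gene_b)]

    def _cutoff(v: np.ndarray, gene: str) -> float:
        if isinstance(high_min, dict):
            return float(high_min[gene])
        if high_min is not None:
            return float(high_min)
        expressed = v[v > expr_min]
        if expressed.size == 0:
            return np.inf
        return float(np.quantile(expressed, 0.75))

    cut_a, cut_b = _cutoff(va, gene_a), _cutoff(vb, gene_b)
    for cut in (cut_a, cut_b):
        if cut <= expr_min:
            raise ValueError("high_min must exceed expr_min")

    a_expr, b_expr = va > expr_min, vb > expr_min
    a_high, b_high = va >= cut_a, vb >= cut_b
    category = np.full(nm.n_cells, "neither", dtype=object)
    category[a_expr & ~b_expr] = "A_only"
    category[~a_expr & b_expr] = "B_only"
    both = a_expr & b_expr
    category[both & a_high & b_high] = "both_high"
    category[both & ~a_high & ~b_high] = "both_low"
    category[both & (a_high ^ b_high)] = "both_mixed"
    category = pd.Series(category, index=nm.cell_ids, name="category")

    groups = pd.Series(groups).reindex(nm.cell_ids) if not isinstance(groups, pd.Series) \
        else groups.reindex(nm.cell_ids)
    if groups.isna().any():
        raise ValueError("group labels missing for some cells")

    tab = pd.crosstab(groups, category)
    for cat in QUADRANT_CATEGORIES:
        if cat not in tab.columns:
            tab[cat] = 0
    tab = tab[QUADRANT_CATEGORIES]
    proportions = tab.div(tab.sum(axis=1), axis=0)

    both_series = category[both]
    both_groups = groups[both]
    split = pd.crosstab(both_groups, both_series)
    for cat in ("both_low", "both_high", "both_mixed"):
        if cat not in split.columns:
            split[cat] = 0
    split = split[["both_low", "both_high", "both_mixed"]]
    split = split.div(split.sum(axis=1), axis=0)

    return QuadrantSummary(
        category=category,
        group_proportions=proportions,
        double_expressing_split=split,
        high_min={gene_a: cut_a, gene_b: cut_b},
    )
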