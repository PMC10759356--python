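"""Cluster marker detection: Wilcoxon rank-sum tests, multiple-testing
adjustment, log fold changes and threshold filtering.

For small problems (n*m <= 200) the rank-sum p-value is exact: the full null
distribution of the rank sum over all C(N, n) group assignments is computed
by dynamic programming over (doubled) midranks, which handles ties without
enumeration. Larger problems use the normal approximation with tie and
continuity corrections.
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .datatypes import NormalizedMatrix

log = logging.getLogger("pitscape")

EXACT_NM_MAX = 200

MARKER_COLUMNS = ["cluster", "gene", "log_fc", "p_value", "adj_p", "pct_in", "pct_out"]


def _exact_ranksum_p(ranks: np.ndarray, n: int) -> float:
    """Two-sided exact p for the rank sum of a size-n group.

    ``ranks`` are pooled midranks with the first ``n`` belonging to group A.
    Doubling midranks makes them integers; a DP over (#chosen, doubled sum)
    counts, for every achievable rank sum, the number of subsets attaining
    it. p = P(|W - E| >= |w_obs - E|) under uniform subset choice; the null
    is symmetric about E = n(N+1)/2.
    """
    N = ranks.size
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    w_obs = int(r2[:n].sum())
    total = int(r2.sum())
    # table[c] is a vector over doubled-sum values 0..total
    table = np.zeros((n + 1, total + 1))
    table[0, 0] = 1.0
    for r in r2:
        for c in range(n, 0, -1):
            table[c, r:] += table[c - 1, : total + 1 - r]
    dist = table[n]
    sums = np.arange(total + 1)
    e2 = n * (total / N)  # doubled expectation: n * (N+1) when no ties... general: n*mean
    dev = abs(w_obs - e2)
    p = dist[np.abs(sums - e2) >= dev - 1e-9].sum() / comb(N, n)
    return float(min(1.0, p))


def _asymptotic_ranksum_p(ranks: np.ndarray, n: int) -> float:
    """Normal approximation with tie correction and continuity correction."""
    N = ranks.size
    m = N - n
    w = ranks[:n].sum()
    e = n * (N + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    from scipy.stats import norm

    z = (abs(w - e) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_test(x, y, alternative: str = "two_sided") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when n*m <= 200 (ties handled via midranks),
    normal approximation with tie and continuity corrections otherwise.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = rankdata(pooled)
    if x.size * y.size <= EXACT_NM_MAX:
        return _exact_ranksum_p(ranks, x.size)
    return _asymptotic_ranksum_p(ranks, x.size)


def bh_adjust(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up (or Bonferroni) adjusted p-values, input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def log_fold_change(
    nm: NormalizedMatrix,
    in_cells,
    out_cells,
    pseudo: float = 1.0,
    base: float = 2.0,
) -> pd.Series:
    """Per-gene log fold change between two disjoint cell groups.

    log2((mean of de-logged in-group expression + pseudo)
         / (mean of de-logged out-group expression + pseudo)).
    """
    in_idx = _cell_indices(nm, in_cells)
    out_idx = _cell_indices(nm, out_cells)
    if in_idx.size == 0 or out_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    if set(in_idx) & set(out_idx):
        raise ValueError("cell groups must be disjoint")
    m_in = np.expm1(nm.values[:, in_idx]).mean(axis=1)
    m_out = np.expm1(nm.values[:, out_idx]).mean(axis=1)
    lfc = (np.log(m_in + pseudo) - np.log(m_out + pseudo)) / np.log(base)
    return pd.Series(lfc, index=nm.gene_ids, name="log_fc")


def _cell_indices(nm: NormalizedMatrix, cells) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        if cells.size != nm.n_cells:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(cells)
    if np.issubdtype(cells.dtype, np.integer):
        return cells
    idx = pd.Index(nm.cell_ids).get_indexer(cells)
    if (idx < 0).any():
        missing = [c for c, i in zip(cells, idx) if i < 0]
        raise KeyError(f"cells not present: {missing[:5]}")
    return idx


def _vector_ranksum_p(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Per-row two-sided rank-sum p-values for in-vs-out cell groups."""
    n_in = int(in_mask.sum())
    n_out = values.shape[1] - n_in
    if n_in * n_out > EXACT_NM_MAX:
        res = mannwhitneyu(
            values[:, in_mask], values[:, ~in_mask],
            alternative="two-sided", method="asymptotic", use_continuity=True,
            axis=1,
        )
        p = np.asarray(res.pvalue, dtype=float)
        # constant rows have undefined z; define p = 1
        constant = np.all(values == values[:, :1], axis=1)
        p[constant] = 1.0
        return np.minimum(p, 1.0)
    return np.array(
        [wilcoxon_test(row[in_mask], row[~in_mask]) for row in values]
    )


def find_markers(
    nm: NormalizedMatrix,
    clusters,
    mode: str = "one_vs_rest",
    min_cells: int = 3,
    min_pct: float = 0.1,
    min_abs_log_fc: float = 0.1,
    adjust_method: str = "bh",
    prefilter: bool = True,
) -> pd.DataFrame:
    """One-vs-rest marker test for every cluster.

    ``clusters`` maps cell id to cluster label (mapping or pandas Series).
    Genes pass the detection prefilter when expressed in at least ``min_pct``
    of either group and |log_fc| >= ``min_abs_log_fc`` (set ``prefilter=False``
    to test every gene). Adjusted p-values are computed over the full table
    of tested (cluster, gene) rows.
    """
    if mode != "one_vs_rest":
        raise ValueError("only one_vs_rest mode is supported")
    labels = pd.Series(clusters).reindex(nm.cell_ids) if not isinstance(clusters, pd.Series) \
        else clusters.reindex(nm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    uniq = sorted(labels.unique())
    sizes = labels.value_counts()
    usable = [u for u in uniq if sizes[u] >= min_cells]
    for u in uniq:
        if u not in usable:
            log.warning("cluster %r has fewer than %d cells; skipped", u, min_cells)
    if len(usable) < 2:
        raise ValueError("at least 2 clusters with enough cells are required")

    detected = nm.values > 0
    rows: list[dict] = []
    for lab in usable:
        in_mask = (labels == lab).to_numpy()
        pct_in = detected[:, in_mask].mean(axis=1)
        pct_out = detected[:, ~in_mask].mean(axis=1)
        lfc = log_fold_change(nm, in_mask, ~in_mask).to_numpy()
        if prefilter:
            tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (
                np.abs(lfc) >= min_abs_log_fc
            )
        else:
            tested = np.ones(nm.n_genes, dtype=bool)
        idx = np.flatnonzero(tested)
        if idx.size == 0:
            continue
        p = _vector_ranksum_p(nm.values[idx], in_mask)
        for g, pv in zip(idx, p):
            rows.append(
                {
                    "cluster": lab,
                    "gene": nm.gene_ids[g],
                    "log_fc": lfc[g],
                    "p_value": pv,
                    "pct_in": pct_in[g],
                    "pct_out": pct_out[g],
                }
            )
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy(), method=adjust_method)
    return table[MARKER_COLUMNS].reset_index(drop=True)


def filter_markers(
    table: pd.DataFrame,
    min_log_fc: float = 0.25,
    max_adj_p: float = 0.01,
    positive_only: bool = True,
) -> pd.DataFrame:
    """Keep rows with log_fc > min_log_fc and adj_p < max_adj_p (strict)."""
    keep = (table["log_fc"] > min_log_fc) & (table["adj_p"] < max_adj_p)
    if positive_only:
        keep &= table["log_fc"] > 0
    return table[keep].reset_index(drop=True)
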