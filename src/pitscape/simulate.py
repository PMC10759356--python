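"""Synthetic scRNA-seq, bulk-cohort and reference-atlas generators with ground truth.

The single-cell generator draws negative-binomial counts from cluster-specific
mean programs: a log-normal baseline profile, planted differentially expressed
genes per cluster (log2 mean shift), log-normal library sizes, a mitochondrial
gene block, a hormone gene pair with per-cluster high/low regimes (to exercise
the co-expression quadrant analysis), and a small cross-sample "aggressive"
subpopulation whose proliferation-program genes are up-shifted — the structure
needed to train and validate the carcinoma-vs-adenoma transfer classifier.

Bulk cohorts are convex mixtures of cluster centroids (in log-normalized
space) with gene-wise log-normal noise and masked missing entries; carcinoma-
like samples receive an elevated weight on the aggressive centroid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datatypes import BulkCohort, CellAnnotation, CountMatrix

log = logging.getLogger("pitscape")

#: cluster label given to aggressive cells when building centroid mixtures
AGGRESSIVE_LABEL = "aggressive"

BULK_LABELS = ("carcinoma_like", "invasive_like", "noninvasive_like")

_HORMONE_REGIMES = ("both_high", "A_only", "B_only", "both_low", "neither")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for parameter-recovery tests."""

    cluster_of_cell: dict[str, str]
    sample_of_cell: dict[str, str]
    aggressive_cells: set[str]
    de_genes: dict[str, list[tuple[str, float]]]
    hormone_genes: tuple[str, str]
    hormone_regimes: dict[str, str]
    proliferation_genes: list[str]
    mito_genes: list[str]
    seed: int
    group_of_sample: dict[str, str] = field(default_factory=dict)
    mixing_weights: dict[str, dict[str, float]] | None = None
    bulk_labels: dict[str, str] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cluster_of_cell": self.cluster_of_cell,
            "sample_of_cell": self.sample_of_cell,
            "aggressive_cells": sorted(self.aggressive_cells),
            "de_genes": {k: [[g, e] for g, e in v] for k, v in self.de_genes.items()},
            "hormone_genes": list(self.hormone_genes),
            "hormone_regimes": self.hormone_regimes,
            "proliferation_genes": self.proliferation_genes,
            "mito_genes": self.mito_genes,
            "seed": self.seed,
            "group_of_sample": self.group_of_sample,
            "mixing_weights": self.mixing_weights,
            "bulk_labels": self.bulk_labels,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=1))


def _default_clusters(k: int = 5) -> list[tuple[str, float]]:
    return [(f"C{i}", 1.0 / k) for i in range(k)]


def generate_sc_dataset(
    n_genes: int = 2000,
    n_cells: int = 3000,
    clusters: Sequence[tuple[str, float]] | None = None,
    de_fraction: float = 0.05,
    de_effect: float = 2.0,
    dispersion: float = 2.0,
    libsize_sigma: float = 0.35,
    mito_fraction: float = 0.05,
    aggressive_fraction: float = 0.02,
    proliferation_set_size: int = 25,
    seed: int = 0,
    n_samples: int = 4,
    lineage_bias: float = 0.0,
    mean_library_size: float = 5000.0,
    aggressive_effect: float = 2.0,
    tumor_sample_fraction: float = 0.5,
) -> tuple[CountMatrix, list[CellAnnotation], SyntheticTruth]:
    """Draw a clustered negative-binomial scRNA-seq dataset with known truth.

    Parameters
    ----------
    clusters
        ``(label, proportion)`` pairs; proportions must sum to 1. Default:
        five equal clusters C0..C4.
    de_fraction, de_effect
        Fraction of genes planted as up-regulated markers per cluster
        (disjoint across clusters) and their log2 mean shift.
    dispersion
        Negative-binomial size parameter (variance = mu + mu^2/dispersion).
    libsize_sigma
        Log-normal sigma of per-cell library-size factors.
    aggressive_fraction, proliferation_set_size, aggressive_effect
        A fraction of cells in every sample carries a proliferation program
        of ``proliferation_set_size`` genes up-shifted by ``aggressive_effect``
        (log2), emulating a rare cross-sample aggressive subpopulation.
    lineage_bias
        0 mixes clusters uniformly across samples; 1 makes each sample draw
        only from its designated dominant cluster (round-robin). Intermediate
        values interpolate the per-sample cluster distribution.
    """
    if clusters is None:
        clusters = _default_clusters()
    labels = [c[0] for c in clusters]
    props = np.array([c[1] for c in clusters], dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("cluster proportions must sum to 1")
    for frac, name in [
        (de_fraction, "de_fraction"),
        (mito_fraction, "mito_fraction"),
        (aggressive_fraction, "aggressive_fraction"),
        (lineage_bias, "lineage_bias"),
    ]:
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if n_cells < len(clusters):
        raise ValueError("need at least one cell per cluster")

    rng = np.random.default_rng(seed)

    n_mito = int(round(mito_fraction * n_genes))
    gene_ids = [f"MT-G{i:04d}" for i in range(n_mito)]
    gene_ids += [f"G{i:04d}" for i in range(n_mito, n_genes)]
    mito_genes = gene_ids[:n_mito]

    # baseline relative expression profile
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # hormone pair: two dedicated non-mitochondrial genes
    horm_a, horm_b = n_mito, n_mito + 1
    hormone_genes = (gene_ids[horm_a], gene_ids[horm_b])
    base[[horm_a, horm_b]] = np.quantile(base, 0.8)

    eligible = list(range(n_mito + 2, n_genes))
    n_de = int(round(de_fraction * n_genes))
    if de_fraction > 0 and n_de < 1:
        raise ValueError("infeasible configuration: de_fraction * n_genes < 1")
    needed = n_de * len(labels) + proliferation_set_size
    if needed > len(eligible):
        raise ValueError(
            f"infeasible configuration: need {needed} distinct program genes "
            f"but only {len(eligible)} are eligible"
        )
    program_pool = rng.permutation(eligible)
    de_idx = {
        lab: program_pool[i * n_de : (i + 1) * n_de].tolist()
        for i, lab in enumerate(labels)
    }
    prolif_idx = program_pool[
        len(labels) * n_de : len(labels) * n_de + proliferation_set_size
    ].tolist()

    # per-cluster mean multipliers
    mult = np.ones((len(labels), n_genes))
    for i, lab in enumerate(labels):
        mult[i, de_idx[lab]] = 2.0 ** de_effect
    regimes = {
        lab: _HORMONE_REGIMES[i % len(_HORMONE_REGIMES)] for i, lab in enumerate(labels)
    }
    high, low, off = 8.0, 1.0, 0.05
    for i, lab in enumerate(labels):
        reg = regimes[lab]
        a = high if reg in ("both_high", "A_only") else (off if reg == "neither" else low)
        b = high if reg in ("both_high", "B_only") else (off if reg == "neither" else low)
        mult[i, horm_a] = a
        mult[i, horm_b] = b

    # assign cells to samples, clusters, aggressive status
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    n_tumor = int(round(tumor_sample_fraction * n_samples))
    group_of_sample = {
        s: ("tumor" if j >= n_samples - n_tumor else "normal")
        for j, s in enumerate(sample_ids)
    }
    per_sample = np.full(n_samples, n_cells // n_samples)
    per_sample[: n_cells % n_samples] += 1

    cell_ids: list[str] = []
    cluster_of_cell: dict[str, str] = {}
    sample_of_cell: dict[str, str] = {}
    aggressive: set[str] = set()
    cluster_idx = np.empty(n_cells, dtype=int)
    aggr_flag = np.zeros(n_cells, dtype=bool)
    pos = 0
    for j, (s, n_s) in enumerate(zip(sample_ids, per_sample)):
        dom = np.zeros(len(labels))
        dom[j % len(labels)] = 1.0
        p = (1.0 - lineage_bias) * props + lineage_bias * dom
        ks = rng.choice(len(labels), size=n_s, p=p)
        n_aggr = int(round(aggressive_fraction * n_s))
        aggr_local = rng.choice(n_s, size=n_aggr, replace=False) if n_aggr else []
        for t in range(n_s):
            cid = f"{s}_cell{t:05d}"
            cell_ids.append(cid)
            cluster_of_cell[cid] = labels[ks[t]]
            sample_of_cell[cid] = s
        cluster_idx[pos : pos + n_s] = ks
        for t in aggr_local:
            aggressive.add(cell_ids[pos + t])
            aggr_flag[pos + t] = True
        pos += n_s

    lib = mean_library_size * rng.lognormal(0.0, libsize_sigma, size=n_cells)

    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    aggr_mult = np.ones(n_genes)
    aggr_mult[prolif_idx] = 2.0 ** aggressive_effect
    for i in range(len(labels)):
        for is_aggr in (False, True):
            sel = (cluster_idx == i) & (aggr_flag == is_aggr)
            if not sel.any():
                continue
            prof = base * mult[i] * (aggr_mult if is_aggr else 1.0)
            prof = prof / prof.sum()
            mu = np.outer(prof, lib[sel])
            p = dispersion / (dispersion + mu)
            counts[:, sel] = rng.negative_binomial(dispersion, p)

    annotations = [
        CellAnnotation(
            cid,
            sample_of_cell[cid],
            group_of_sample[sample_of_cell[cid]],
            cluster_of_cell[cid],
        )
        for cid in cell_ids
    ]
    truth = SyntheticTruth(
        cluster_of_cell=cluster_of_cell,
        sample_of_cell=sample_of_cell,
        aggressive_cells=aggressive,
        de_genes={
            lab: [(gene_ids[g], de_effect) for g in de_idx[lab]] for lab in labels
        },
        hormone_genes=hormone_genes,
        hormone_regimes=regimes,
        proliferation_genes=[gene_ids[g] for g in prolif_idx],
        mito_genes=mito_genes,
        seed=seed,
        group_of_sample=group_of_sample,
    )
    return CountMatrix(counts, gene_ids, cell_ids), annotations, truth


def generate_bulk_cohort(
    truth: SyntheticTruth,
    centroids: Mapping[str, np.ndarray],
    gene_ids: Sequence[str],
    n_samples: int = 13,
    n_carcinoma: int = 3,
    n_invasive: int = 5,
    carcinoma_aggressive_weight: float = 0.4,
    base_aggressive_weight: float = 0.05,
    noise_sigma: float = 0.2,
    na_rate: float = 0.05,
    gene_detect_fraction: float = 1.0,
    seed: int = 0,
) -> BulkCohort:
    """Mix cluster centroids into a noisy bulk cohort with missing entries.

    ``centroids`` maps cluster labels (including :data:`AGGRESSIVE_LABEL`) to
    mean log-normalized expression vectors over ``gene_ids``. Carcinoma-like
    samples receive ``carcinoma_aggressive_weight`` on the aggressive centroid,
    all other samples ``base_aggressive_weight``; the remaining mass is spread
    over the other clusters by a Dirichlet draw. Gene-wise multiplicative
    log-normal noise is applied and ``na_rate`` of entries are masked NaN.
    ``gene_detect_fraction`` < 1 drops a random gene subset from the cohort,
    emulating genes not measured on the bulk platform.
    """
    if not 0.0 <= na_rate < 1.0:
        raise ValueError("na_rate must be in [0, 1); na_rate = 1 leaves nothing to classify")
    if AGGRESSIVE_LABEL not in centroids:
        raise ValueError(f"centroids must include the {AGGRESSIVE_LABEL!r} profile")
    missing = [c for c in set(truth.cluster_of_cell.values()) if c not in centroids]
    if missing:
        raise ValueError(f"centroids missing for clusters: {sorted(missing)}")
    if n_carcinoma + n_invasive > n_samples:
        raise ValueError("n_carcinoma + n_invasive exceeds n_samples")

    rng = np.random.default_rng(seed)
    other = sorted(k for k in centroids if k != AGGRESSIVE_LABEL)
    C = np.column_stack([np.asarray(centroids[k], dtype=float) for k in other])
    aggr = np.asarray(centroids[AGGRESSIVE_LABEL], dtype=float)
    if C.shape[0] != len(gene_ids):
        raise ValueError("centroid length does not match gene_ids")

    labels = (
        [BULK_LABELS[0]] * n_carcinoma
        + [BULK_LABELS[1]] * n_invasive
        + [BULK_LABELS[2]] * (n_samples - n_carcinoma - n_invasive)
    )
    order = rng.permutation(n_samples)
    labels = [labels[i] for i in order]
    sample_ids = [f"B{j + 1:02d}" for j in range(n_samples)]

    values = np.empty((n_samples, len(gene_ids)))
    weights: dict[str, dict[str, float]] = {}
    for j, (sid, lab) in enumerate(zip(sample_ids, labels)):
        w_a = carcinoma_aggressive_weight if lab == "carcinoma_like" else base_aggressive_weight
        w_rest = (1.0 - w_a) * rng.dirichlet(np.ones(len(other)))
        values[j] = w_a * aggr + C @ w_rest
        weights[sid] = {AGGRESSIVE_LABEL: w_a, **dict(zip(other, w_rest))}
    values *= rng.lognormal(0.0, noise_sigma, size=values.shape)
    if na_rate > 0:
        mask = rng.random(values.shape) < na_rate
        values[mask] = np.nan

    gene_ids = list(gene_ids)
    if not 0.0 < gene_detect_fraction <= 1.0:
        raise ValueError("gene_detect_fraction must be in (0, 1]")
    if gene_detect_fraction < 1.0:
        n_detect = int(np.ceil(gene_detect_fraction * len(gene_ids)))
        keep = np.sort(rng.choice(len(gene_ids), size=n_detect, replace=False))
        values = values[:, keep]
        gene_ids = [gene_ids[i] for i in keep]

    truth.mixing_weights = weights
    truth.bulk_labels = dict(zip(sample_ids, labels))
    return BulkCohort(values, sample_ids, gene_ids, labels=labels)


def generate_reference_atlas(
    centroids: Mapping[str, np.ndarray],
    gene_ids: Sequence[str],
    gene_keep_fraction: float = 0.8,
    scale_sigma: float = 0.3,
    cells_per_cluster: int = 100,
    seed: int = 0,
    count_sampling: bool = True,
    mean_library_size: float = 5000.0,
    libsize_sigma: float = 0.2,
) -> tuple[CountMatrix, list[CellAnnotation]]:
    """Build a perturbed "foreign species" atlas around given centroids.

    A ``gene_keep_fraction`` subset of genes is retained, each retained gene
    receives a log-normal scale distortion (sigma ``scale_sigma``), and
    ``cells_per_cluster`` cells are sampled around each centroid (Poisson
    counts; deterministic expected counts when ``count_sampling`` is off —
    the exactly noiseless limit). Gene symbols are re-cased mouse-style
    (capitalized) to exercise case-normalized symbol harmonization.
    """
    if not 0.0 < gene_keep_fraction <= 1.0:
        raise ValueError("gene_keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    n_keep = int(np.ceil(gene_keep_fraction * n_genes))
    if n_keep < 50:
        raise ValueError(
            f"gene_keep_fraction leaves only {n_keep} genes; at least 50 required"
        )
    keep = np.sort(rng.choice(n_genes, size=n_keep, replace=False))
    kept_ids = [str(gene_ids[i]).capitalize() for i in keep]
    scale = rng.lognormal(0.0, scale_sigma, size=n_keep) if scale_sigma > 0 else np.ones(n_keep)

    clusters = sorted(centroids)
    blocks, cell_ids, annotations = [], [], []
    for lab in clusters:
        prof = np.expm1(np.asarray(centroids[lab], dtype=float))[keep] * scale
        total = prof.sum()
        if total <= 0:
            raise ValueError(f"centroid {lab!r} has no expression on kept genes")
        prof = prof / total
        if count_sampling:
            lib = mean_library_size * rng.lognormal(0.0, libsize_sigma, cells_per_cluster)
            mu = np.outer(prof, lib)
            blocks.append(rng.poisson(mu))
        else:
            col = np.rint(prof * mean_library_size).astype(np.int64)
            blocks.append(np.repeat(col[:, None], cells_per_cluster, axis=1))
        for t in range(cells_per_cluster):
            cid = f"REF_{lab}_{t:04d}"
            cell_ids.append(cid)
            annotations.append(CellAnnotation(cid, "REF", "normal", lab))
    counts = np.concatenate(blocks, axis=1)
    return CountMatrix(counts, kept_ids, cell_ids), annotations


def plant_quadrant_matrix(
    n_cells: int,
    fractions: Mapping[str, float],
    low_value: float = 0.5,
    high_value: float = 3.0,
    seed: int = 0,
    gene_a: str = "HORM-A",
    gene_b: str = "HORM-B",
):
    """Build a two-gene expression matrix with planted co-expression categories.

    ``fractions`` maps category names (neither, A_only, B_only, both_low,
    both_high, both_mixed) to fractions summing to 1; cells are allocated to
    categories in exact counts (largest-remainder rounding) and shuffled, so
    the planted fractions are deterministic up to 1/n_cells. Expression is
    ``low_value`` for expressed-but-low and ``high_value`` for high (cutoffs
    0 and the midpoint make the planting exact). Returns
    (NormalizedMatrix, per-cell category list).
    """
    from .datatypes import NormalizedMatrix

    cats = ["neither", "A_only", "B_only", "both_low", "both_high", "both_mixed"]
    p = np.array([fractions.get(c, 0.0) for c in cats], dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("category fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.floor(p * n_cells).astype(int)
    remainder = p * n_cells - counts
    for i in np.argsort(-remainder)[: n_cells - counts.sum()]:
        counts[i] += 1
    draw = rng.permutation(np.repeat(np.arange(len(cats)), counts))
    va = np.zeros(n_cells)
    vb = np.zeros(n_cells)
    lo, hi = low_value, high_value
    for i, k in enumerate(draw):
        c = cats[k]
        if c == "A_only":
            va[i] = lo
        elif c == "B_only":
            vb[i] = lo
        elif c == "both_low":
            va[i], vb[i] = lo, lo
        elif c == "both_high":
            va[i], vb[i] = hi, hi
        elif c == "both_mixed":
            va[i], vb[i] = hi, lo
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    nm = NormalizedMatrix(np.vstack([va, vb]), [gene_a, gene_b], cell_ids)
    return nm, [cats[k] for k in draw]
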