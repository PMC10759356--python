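"""Single-cell -> bulk aggressiveness classifier.

The transfer chain: select marker genes of the aggressive tumor-cell cluster
(log2FC > 0.75, adjusted P < 0.05, then keep only genes detected in the bulk
cohort); harmonize both modalities onto one scale (bulk: KNN imputation of
missing values, quantile normalization across samples, per-gene z-scores;
single cell: per-gene z-scores of log-normalized expression); train a
class-balanced ensemble of decision trees on the labeled cells (stratified
bootstrap of n_pos aggressive vs n_neg non-aggressive cells per tree,
sqrt(p) features per split); report each bulk sample's probability of being
aggressive as the fraction of trees voting for the aggressive class.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.impute import KNNImputer
from sklearn.tree import DecisionTreeClassifier

from .datatypes import BulkCohort, NormalizedMatrix
from .markers import filter_markers

log = logging.getLogger("pitscape")

AGGRESSIVE = "aggressive"
NON_AGGRESSIVE = "non_aggressive"


@dataclass
class ClassifierGeneSet:
    """Selected feature genes plus counts at each selection stage."""

    genes: list[str]
    selection_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("classifier gene set is empty")
        # canonical lexicographic order so every downstream feature matrix is
        # independent of the marker table's row order
        self.genes = sorted(self.genes)


def select_classifier_genes(
    table: pd.DataFrame,
    bulk_genes,
    min_log_fc: float = 0.75,
    max_adj_p: float = 0.05,
    cluster: str | None = None,
) -> ClassifierGeneSet:
    """Marker-gene selection chain for the aggressive cluster.

    Stages: tested genes -> pass the log-fold-change / adjusted-P filter
    (positive only) -> detected in the bulk cohort. Stage counts are recorded
    in ``selection_log``; emptying at any stage is an error naming the stage.
    """
    t = table
    if cluster is not None:
        t = t[t["cluster"] == cluster]
    elif t["cluster"].nunique() > 1:
        raise ValueError("marker table has several clusters; pass cluster=")
    n_tested = len(t)
    if n_tested == 0:
        raise ValueError("selection emptied at stage 'tested': no marker rows")
    passed = filter_markers(t, min_log_fc=min_log_fc, max_adj_p=max_adj_p,
                            positive_only=True)
    if passed.empty:
        raise ValueError("selection emptied at stage 'fold-change/adjusted-P filter'")
    bulk_set = set(bulk_genes)
    final = [g for g in passed["gene"] if g in bulk_set]
    if not final:
        raise ValueError("selection emptied at stage 'bulk detection'")
    sel_log = {
        "tested": n_tested,
        "passed_filter": len(passed),
        "detected_in_bulk": len(final),
        "min_log_fc": min_log_fc,
        "max_adj_p": max_adj_p,
    }
    log.info("classifier genes: %d tested -> %d filtered -> %d in bulk",
             n_tested, len(passed), len(final))
    return ClassifierGeneSet(final, sel_log)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a genes x samples matrix.

    Every column's sorted values are replaced by the rank-wise mean of sorted
    values over all columns; tied ranks receive the mean of the corresponding
    reference quantiles (average-rank interpolation).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return out


def knn_impute(values: np.ndarray, k: int = 10) -> np.ndarray:
    """Impute NaNs in a genes x samples matrix from the k nearest genes.

    Distances between gene rows use the samples observed in both rows; each
    missing entry becomes the average of the neighbors' values in that
    sample (the classic gene-wise nearest-neighbor imputation).
    """
    values = np.asarray(values, dtype=float)
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"gene row {int(np.flatnonzero(all_missing)[0])} is missing in all samples"
        )
    if not np.isnan(values).any():
        return values.copy()
    k = min(k, values.shape[0] - 1)
    return KNNImputer(n_neighbors=k, weights="uniform").fit_transform(values)


def harmonize_bulk(
    b: BulkCohort,
    genes: ClassifierGeneSet,
    k_impute: int = 10,
) -> pd.DataFrame:
    """Impute, quantile-normalize and z-score the bulk cohort on the selected genes.

    Imputation and quantile normalization operate on the full cohort — the
    sample-wide distributions are what quantile normalization aligns, and
    restricting it to the handful of selected genes would cancel exactly the
    coordinated elevation the classifier looks for. The selected-gene
    submatrix is then z-scored per gene (n-1 denominator). No missing values
    remain; constant genes become zero columns (logged).
    """
    idx = pd.Index(b.gene_ids)
    missing = [g for g in genes.genes if g not in idx]
    if missing:
        raise KeyError(f"selected genes absent from bulk cohort: {missing[:5]}")
    X = b.values.T  # genes x samples, full cohort
    observed = (~np.isnan(X)).sum(axis=1)
    if (observed < 2).any():
        g = b.gene_ids[int(np.argmax(observed < 2))]
        raise ValueError(f"gene {g!r} observed in fewer than 2 samples")
    X = knn_impute(X, k=k_impute)
    X = quantile_normalize(X)
    pos = idx.get_indexer(genes.genes)
    Z = _zscore_columns(X[pos].T, genes.genes)  # samples x genes
    return pd.DataFrame(Z, index=b.sample_ids, columns=genes.genes)


def harmonize_sc(nm: NormalizedMatrix, genes: ClassifierGeneSet) -> pd.DataFrame:
    """Per-gene z-scores of log-normalized expression, cells x genes."""
    sub = nm.subset_genes(genes.genes)
    Z = _zscore_columns(sub.values.T, genes.genes)
    return pd.DataFrame(Z, index=nm.cell_ids, columns=genes.genes)


def _zscore_columns(X: np.ndarray, names) -> np.ndarray:
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    constant = sd[0] <= 1e-12
    if constant.any():
        log.info("z-scoring: %d constant genes set to zero: %s",
                 int(constant.sum()),
                 [n for n, c in zip(names, constant) if c][:5])
    sd[0, constant] = 1.0
    Z = (X - mu) / sd
    Z[:, constant] = 0.0
    return Z


@dataclass
class EnsembleModel:
    """Class-balanced ensemble of decision trees over a fixed gene order."""

    trees: list
    feature_names: list[str]
    n_trees: int
    n_pos: int
    n_neg: int
    seed: int
    classes: tuple[str, str] = (AGGRESSIVE, NON_AGGRESSIVE)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, EnsembleModel):
            raise TypeError("file does not contain an EnsembleModel")
        return model


def train_classifier(
    features: pd.DataFrame,
    labels,
    n_trees: int = 4000,
    n_pos: int = 1500,
    n_neg: int = 500,
    seed: int = 0,
) -> EnsembleModel:
    """Train the stratified-bootstrap tree ensemble on labeled cells.

    ``features`` is cells x genes (z-scores); ``labels`` holds "aggressive" /
    "non_aggressive" per cell. Each tree sees a bootstrap of ``n_pos``
    aggressive and ``n_neg`` non-aggressive cells drawn with replacement
    (the class-balancing that compensates the rarity of aggressive cells)
    and uses sqrt(p) candidate features per split. Feature columns are
    canonicalized to lexicographic order before training, so the fitted model
    and its predictions do not depend on the input column order.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    features = features[sorted(features.columns)]
    y = pd.Series(labels).reindex(features.index) if not isinstance(labels, pd.Series) \
        else labels.reindex(features.index)
    if y.isna().any():
        raise ValueError("labels missing for some cells")
    bad = set(y.unique()) - {AGGRESSIVE, NON_AGGRESSIVE}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    pos_idx = np.flatnonzero((y == AGGRESSIVE).to_numpy())
    neg_idx = np.flatnonzero((y == NON_AGGRESSIVE).to_numpy())
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both classes must be present in the training cells")

    X = features.to_numpy(dtype=float)
    y_arr = y.to_numpy()
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        boot = np.concatenate([
            rng.choice(pos_idx, size=n_pos, replace=True),
            rng.choice(neg_idx, size=n_neg, replace=True),
        ])
        tree = DecisionTreeClassifier(
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y_arr[boot])
        trees.append(tree)
    return EnsembleModel(
        trees, list(features.columns), n_trees=n_trees, n_pos=n_pos, n_neg=n_neg,
        seed=seed,
    )


def predict_aggressiveness(model: EnsembleModel, bulk_features: pd.DataFrame) -> pd.DataFrame:
    """Score bulk samples: p_aggressive = fraction of trees voting aggressive.

    The bulk feature columns must match the model's gene order exactly —
    a mismatch is an error, never a silent reordering. Ranks are assigned by
    descending p_aggressive, ties broken by sample id.
    """
    if list(bulk_features.columns) != model.feature_names:
        raise ValueError(
            "bulk feature genes/order do not match the model; refusing to reorder"
        )
    X = bulk_features.to_numpy(dtype=float)
    votes = np.zeros(X.shape[0])
    for tree in model.trees:
        votes += tree.predict(X) == AGGRESSIVE
    p = votes / len(model.trees)
    out = pd.DataFrame(
        {
            "sample_id": list(bulk_features.index),
            "p_aggressive": p,
            "p_non_aggressive": 1.0 - p,
        }
    )
    order = out.sort_values(["p_aggressive", "sample_id"],
                            ascending=[False, True]).index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks.sort_index().to_numpy()
    return out.set_index("sample_id", drop=False)
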