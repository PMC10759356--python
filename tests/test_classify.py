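"""Classifier transfer chain: gene selection, bulk harmonization, the
balanced tree ensemble and its predictions."""

import numpy as np
import pandas as pd
import pytest

from pitscape.classify import (
    AGGRESSIVE,
    NON_AGGRESSIVE,
    ClassifierGeneSet,
    EnsembleModel,
    harmonize_bulk,
    harmonize_sc,
    knn_impute,
    predict_aggressiveness,
    quantile_normalize,
    select_classifier_genes,
    train_classifier,
)
from pitscape.datatypes import BulkCohort

from conftest import make_normalized


def _toy_marker_table():
    return pd.DataFrame({
        "cluster": "T00",
        "gene": [f"gene{i}" for i in range(1, 6)],
        "log_fc": [1.0, 0.8, 0.7, 0.9, 2.0],
        "p_value": [0.01, 0.04, 0.01, 0.2, 0.001],
        "adj_p": [0.01, 0.04, 0.01, 0.2, 0.001],
        "pct_in": 0.9, "pct_out": 0.1,
    })


class TestGeneSelection:
    def test_stage_counts_five_three_two(self):
        bulk_genes = ["gene1", "gene2", "gene3", "gene4"]  # all but gene5
        gs = select_classifier_genes(_toy_marker_table(), bulk_genes)
        assert gs.selection_log["tested"] == 5
        assert gs.selection_log["passed_filter"] == 3
        assert gs.selection_log["detected_in_bulk"] == 2
        assert gs.genes == ["gene1", "gene2"]

    def test_full_bulk_makes_stage_three_a_noop(self):
        t = _toy_marker_table()
        gs = select_classifier_genes(t, list(t.gene))
        assert gs.selection_log["passed_filter"] == gs.selection_log["detected_in_bulk"]

    def test_thresholds_recorded_and_empty_stage_named(self):
        gs = select_classifier_genes(_toy_marker_table(), list(_toy_marker_table().gene))
        assert gs.selection_log["min_log_fc"] == 0.75
        assert gs.selection_log["max_adj_p"] == 0.05
        with pytest.raises(ValueError, match="bulk detection"):
            select_classifier_genes(_toy_marker_table(), ["unrelated"])
        with pytest.raises(ValueError, match="filter"):
            select_classifier_genes(_toy_marker_table(), ["gene1"], min_log_fc=5.0)


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        X = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(X)
        assert np.allclose(out[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_columns_share_sorted_multiset(self, rng):
        X = rng.random((40, 7))
        out = quantile_normalize(X)
        ref = np.sort(out[:, 0])
        for j in range(1, 7):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_ties_get_mean_reference_quantile(self):
        X = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(X)
        ref = np.sort(X, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[0, 0] == out[1, 0]


class TestKNNImpute:
    def test_constant_matrix_imputes_constant(self):
        X = np.full((5, 4), 3.0)
        X[2, 1] = np.nan
        assert knn_impute(X, k=2)[2, 1] == pytest.approx(3.0)

    def test_rank_one_with_duplicate_rows_recovered_exactly(self, rng):
        # gene loadings repeated in blocks larger than k: nearest neighbors
        # are exact duplicates, so neighbor-mean imputation is exact
        loadings = np.repeat(rng.random(5) + 0.5, 6)  # 30 genes, blocks of 6
        v = rng.random(8) + 0.5
        X = np.outer(loadings, v)
        masked = X.copy()
        mask = rng.random(X.shape) < 0.05
        masked[mask] = np.nan
        out = knn_impute(masked, k=3)
        assert np.abs(out[mask] - X[mask]).max() < 1e-6

    def test_fully_missing_gene_rejected(self):
        X = np.array([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="missing in all samples"):
            knn_impute(X)


class TestHarmonize:
    def test_sc_zscore_closed_form_and_constant_column(self):
        nm = make_normalized([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        gs = ClassifierGeneSet(["g0", "g1"], {})
        z = harmonize_sc(nm, gs)
        assert np.allclose(z["g0"], [-1.0, 0.0, 1.0])
        assert np.allclose(z["g1"], 0.0)

    def test_bulk_chain_contract(self, rng):
        values = rng.lognormal(0, 0.5, size=(10, 30))
        values[rng.random(values.shape) < 0.05] = np.nan
        b = BulkCohort(values, [f"s{i}" for i in range(10)],
                       [f"g{j}" for j in range(30)])
        gs = ClassifierGeneSet([f"g{j}" for j in range(8)], {})
        z = harmonize_bulk(b, gs)
        assert z.shape == (10, 8)
        assert not z.isna().any().any()
        assert np.abs(z.mean(axis=0)).max() < 1e-8
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-8

    def test_missing_selected_gene_rejected(self, rng):
        b = BulkCohort(rng.random((4, 3)), list("abcd"), ["g0", "g1", "g2"])
        with pytest.raises(KeyError, match="gX"):
            harmonize_bulk(b, ClassifierGeneSet(["g0", "gX"], {}))


def _separable_features(n=400, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = np.where(X[:, 0] > 0, AGGRESSIVE, NON_AGGRESSIVE)
    X[:, 0] += np.where(X[:, 0] > 0, 2.0, -2.0)  # widen the margin
    feats = pd.DataFrame(X, columns=["f0", "f1", "f2"],
                         index=[f"cell{i}" for i in range(n)])
    return feats, pd.Series(y, index=feats.index)


class TestEnsemble:
    def test_separable_single_feature_problem_learned(self):
        feats, labels = _separable_features()
        one = feats[["f0"]]
        model = train_classifier(one, labels, n_trees=50, n_pos=100, n_neg=100,
                                 seed=1)
        preds = predict_aggressiveness(model, one)
        p = preds["p_aggressive"].to_numpy()
        assert p[(labels == AGGRESSIVE).to_numpy()].min() > 0.95
        assert p[(labels == NON_AGGRESSIVE).to_numpy()].max() < 0.05

    def test_deterministic_under_seed(self):
        feats, labels = _separable_features()
        a = train_classifier(feats, labels, n_trees=20, n_pos=50, n_neg=50, seed=7)
        b = train_classifier(feats, labels, n_trees=20, n_pos=50, n_neg=50, seed=7)
        pd.testing.assert_frame_equal(
            predict_aggressiveness(a, feats), predict_aggressiveness(b, feats)
        )

    def test_shuffled_labels_give_chance_auc(self):
        from sklearn.metrics import roc_auc_score

        feats, labels = _separable_features(n=300, seed=2)
        rng = np.random.default_rng(3)
        aucs = []
        for s in range(5):
            shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                                 index=labels.index)
            half = 150
            model = train_classifier(feats.iloc[:half], shuffled.iloc[:half],
                                     n_trees=60, n_pos=60, n_neg=60, seed=s)
            p = predict_aggressiveness(model, feats.iloc[half:])["p_aggressive"]
            aucs.append(roc_auc_score((shuffled.iloc[half:] == AGGRESSIVE), p))
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_gene_column_permutation_invariance(self):
        """Training canonicalizes the feature order, so a consistent column
        permutation of the training and prediction matrices changes nothing."""
        feats, labels = _separable_features()
        model = train_classifier(feats, labels, n_trees=30, n_pos=50, n_neg=50,
                                 seed=4)
        model_p = train_classifier(feats[["f2", "f0", "f1"]], labels, n_trees=30,
                                   n_pos=50, n_neg=50, seed=4)
        assert model_p.feature_names == model.feature_names
        a = predict_aggressiveness(model, feats[model.feature_names])
        b = predict_aggressiveness(model_p, feats[model_p.feature_names])
        assert np.allclose(a["p_aggressive"], b["p_aggressive"])

    def test_gene_order_mismatch_rejected(self):
        feats, labels = _separable_features()
        model = train_classifier(feats, labels, n_trees=5, n_pos=20, n_neg=20,
                                 seed=5)
        with pytest.raises(ValueError, match="refusing to reorder"):
            predict_aggressiveness(model, feats[["f1", "f0", "f2"]])

    def test_single_class_rejected(self):
        feats, labels = _separable_features()
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(feats, pd.Series(AGGRESSIVE, index=feats.index),
                             n_trees=2)

    def test_probabilities_sum_to_one_and_model_round_trips(self, tmp_path):
        feats, labels = _separable_features(n=100, seed=6)
        model = train_classifier(feats, labels, n_trees=10, n_pos=20, n_neg=20,
                                 seed=6)
        model.save(tmp_path / "model.pkl")
        back = EnsembleModel.load(tmp_path / "model.pkl")
        preds = predict_aggressiveness(back, feats)
        assert np.allclose(preds["p_aggressive"] + preds["p_non_aggressive"], 1.0)
        assert sorted(preds["rank"]) == list(range(1, 101))
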