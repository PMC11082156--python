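import numpy as np
import pytest

from sctemporal.annotate import (
    ClassifierSpec,
    predict,
    stepwise_merge,
    train_classifier,
    unsupervised_t0_labels,
)
from sctemporal.io import CellMetadata, ExpressionMatrix, TimepointDataset, ValidationError
from sctemporal.metrics import accuracy, adjusted_rand_index
from sctemporal.preprocess import apply_training_features, prepare_training_features


@pytest.fixture(scope="module")
def trained(separable_pair):
    t0, _ = separable_pair
    x0, fs, stats = prepare_training_features(t0.matrix, n_hvg=60)
    spec = ClassifierSpec(seed=0, max_epochs=100)
    clf = train_classifier(x0, t0.labels, spec)
    return t0, x0, fs, stats, clf


class TestTraining:
    def test_separable_classes_reach_high_validation_accuracy(self, trained):
        t0, x0, _, _, clf = trained
        result = predict(clf, x0)
        assert accuracy(t0.labels, result.predicted_label) >= 0.99

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(rng.poisson(2, (20, 10)), [f"g{i}" for i in range(20)],
                             [f"c{i}" for i in range(10)], normalized=False)
        from sctemporal.preprocess import min_max_normalize
        with pytest.raises(ValidationError, match="2 distinct classes"):
            train_classifier(min_max_normalize(m), ["A"] * 10)

    def test_singleton_class_rejected(self, trained):
        _, x0, _, _, _ = trained
        labels = ["A"] * (x0.n_cells - 1) + ["B"]
        with pytest.raises(ValidationError, match="single cell"):
            train_classifier(x0, labels, ClassifierSpec(seed=0))

    def test_same_seed_is_deterministic(self, separable_pair):
        t0, t1 = separable_pair
        x0, fs, stats = prepare_training_features(t0.matrix, n_hvg=60)
        x1 = apply_training_features(t1.matrix, fs, stats)
        spec = ClassifierSpec(seed=7, max_epochs=15, patience=3)
        labels_a = predict(train_classifier(x0, t0.labels, spec), x1).predicted_label
        labels_b = predict(train_classifier(x0, t0.labels,
                                            ClassifierSpec(seed=7, max_epochs=15, patience=3)),
                           x1).predicted_label
        assert labels_a == labels_b

    def test_early_stopping_restores_best_weights(self, trained):
        *_, clf = trained
        val = clf.history["val_loss"]
        assert min(val) == val[clf.best_epoch]
        # the restored model's loss is the best seen, not the last
        assert val[clf.best_epoch] <= val[-1] + 1e-12


class TestPredict:
    def test_probability_rows_sum_to_one(self, trained):
        _, x0, _, _, clf = trained
        res = predict(clf, x0)
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert res.probabilities.min() >= 0

    def test_training_cells_are_memorized(self, trained):
        t0, x0, _, _, clf = trained
        res = predict(clf, x0)
        assert accuracy(t0.labels, res.predicted_label) >= 0.99

    def test_zero_vector_cell_yields_valid_probabilities(self, trained):
        _, x0, _, _, clf = trained
        zeros = ExpressionMatrix(np.zeros((x0.n_genes, 1)), x0.gene_ids, ["z"],
                                 normalized=True)
        res = predict(clf, zeros)
        assert np.isfinite(res.probabilities).all()
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_prediction_invariant_to_cell_order(self, trained, separable_pair):
        _, t1 = separable_pair
        _, x0, fs, stats, clf = trained
        x1 = apply_training_features(t1.matrix, fs, stats)
        res = predict(clf, x1)
        perm = np.random.default_rng(1).permutation(x1.n_cells)
        x1_perm = ExpressionMatrix(x1.values[:, perm], x1.gene_ids,
                                   [x1.cell_ids[i] for i in perm], normalized=True)
        res_perm = predict(clf, x1_perm)
        assert [res.predicted_label[i] for i in perm] == res_perm.predicted_label

    def test_feature_mismatch_rejected(self, trained):
        _, x0, _, _, clf = trained
        bad = ExpressionMatrix(np.zeros((3, 2)), ["a", "b", "c"], ["c1", "c2"],
                               normalized=True)
        with pytest.raises(ValidationError, match="features"):
            predict(clf, bad)

    def test_cross_timepoint_transfer(self, trained, separable_pair):
        _, t1 = separable_pair
        _, _, fs, stats, clf = trained
        x1 = apply_training_features(t1.matrix, fs, stats)
        res = predict(clf, x1)
        assert accuracy(t1.labels, res.predicted_label) >= 0.95


class TestUnsupervisedFallback:
    def test_recovers_separated_populations(self, separable_pair):
        t0, _ = separable_pair
        x0, _, _ = prepare_training_features(t0.matrix, n_hvg=60)
        labels = unsupervised_t0_labels(x0, seed=0)
        assert adjusted_rand_index(t0.labels, labels) >= 0.95
        assert all(l.startswith("cluster_") for l in labels)

    def test_deterministic_under_seed(self, separable_pair):
        t0, _ = separable_pair
        x0, _, _ = prepare_training_features(t0.matrix, n_hvg=60)
        assert unsupervised_t0_labels(x0, seed=3) == unsupervised_t0_labels(x0, seed=3)

    def test_too_few_cells_rejected(self):
        m = ExpressionMatrix(np.random.default_rng(0).random((30, 5)),
                             [f"g{i}" for i in range(30)],
                             [f"c{i}" for i in range(5)], normalized=True)
        with pytest.raises(ValidationError):
            unsupervised_t0_labels(m, n_neighbors=15, embed_dim=3, seed=0)


class TestStepwiseMerge:
    def _mini(self, tp, genes, n, label):
        rng = np.random.default_rng(hash(tp) % 2**31)
        ids = [f"{tp}_{i}" for i in range(n)]
        return TimepointDataset(
            ExpressionMatrix(rng.poisson(2, (len(genes), n)), genes, ids),
            CellMetadata(ids, timepoint=[tp] * n, labels=[label] * n),
        )

    def test_concatenates_cells(self):
        a = self._mini("t0", ["g1", "g2"], 100, "A")
        b = self._mini("t1", ["g1", "g2"], 80, "B")
        merged = stepwise_merge(a, b)
        assert merged.n_cells == 180
        assert merged.labels == ["A"] * 100 + ["B"] * 80

    def test_merges_on_gene_intersection(self):
        a = self._mini("t0", ["g1", "g2"], 10, "A")
        b = self._mini("t1", ["g2", "g3"], 10, "B")
        merged = stepwise_merge(a, b)
        assert merged.matrix.gene_ids == ["g2"]

    def test_empty_intersection_rejected(self):
        a = self._mini("t0", ["g1"], 10, "A")
        b = self._mini("t1", ["g9"], 10, "B")
        with pytest.raises(ValidationError, match="overlap"):
            stepwise_merge(a, b)

    def test_overlapping_barcodes_are_disambiguated(self):
        a = self._mini("t0", ["g1"], 10, "A")
        b = self._mini("t0", ["g1"], 10, "B")  # same ids as a
        merged = stepwise_merge(a, b)
        assert len(set(merged.matrix.cell_ids)) == 20

    def test_unlabeled_input_rejected(self):
        a = self._mini("t0", ["g1"], 10, "A")
        b = self._mini("t1", ["g1"], 10, "B")
        b.meta.labels = None
        with pytest.raises(ValidationError, match="labeled"):
            stepwise_merge(a, b)
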