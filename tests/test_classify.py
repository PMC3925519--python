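"""Linear classifier: training geometry, metrics arithmetic, serialization."""

import numpy as np
import pytest

from ictal.classify import (
    ConfusionMatrix,
    LinearModel,
    confusion,
    metrics_from_confusion,
    predict,
    train,
)


def gaussian_clouds(rng, centers, n_per=50, spread=1.0):
    X, y = [], []
    for k, c in enumerate(centers):
        X.append(rng.normal(size=(n_per, len(c))) * spread + np.asarray(c))
        y += [k] * n_per
    return np.vstack(X), np.asarray(y)


class TestTraining:
    def test_separated_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(42)
        X, y = gaussian_clouds(rng, [(0, 0), (10, 10)], spread=1.0)
        model = train(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_duplicated_points_give_perpendicular_bisector(self):
        # degenerate scatter triggers the ridge fallback; the boundary is then
        # the perpendicular bisector of the two class points
        X = np.array([[0.0, 0.0], [0.0, 0.0], [4.0, 0.0], [4.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="ridge"):
            model = train(X, y)
        assert model.predict(np.array([1.9, 5.0])) == 0
        assert model.predict(np.array([2.1, -5.0])) == 1

    def test_three_class_predictions_stay_in_label_set(self):
        rng = np.random.default_rng(0)
        X, y = gaussian_clouds(rng, [(0, 0), (8, 0), (0, 8)])
        model = train(X, y)
        preds = model.predict(rng.normal(size=(200, 2)) * 10)
        assert set(preds.tolist()) <= {0, 1, 2}

    def test_requires_two_classes_and_two_samples(self):
        with pytest.raises(ValueError, match="2 classes"):
            train(np.ones((4, 2)), [0, 0, 0, 0])
        with pytest.raises(ValueError, match="fewer than 2"):
            train(np.eye(3), [0, 0, 1])

    def test_rejects_nonfinite_features(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train(X, [0, 0, 1, 1])

    def test_lsq_trainer_separates_clouds(self):
        rng = np.random.default_rng(7)
        X, y = gaussian_clouds(rng, [(0, 0), (10, 10)])
        model = train(X, y, trainer="lsq")
        assert model.trainer == "lsq"
        assert np.mean(model.predict(X) == y) == 1.0

    def test_unknown_trainer_rejected(self):
        with pytest.raises(ValueError, match="trainer"):
            train(np.eye(4), [0, 0, 1, 1], trainer="svm")

    def test_agrees_with_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X, y = gaussian_clouds(rng, [(0, 0, 0), (3, 0, 1), (0, 3, -1)], spread=1.5)
        probe = rng.normal(size=(500, 3)) * 3
        ours = train(X, y).predict(probe)
        theirs = LinearDiscriminantAnalysis().fit(X, y).predict(probe)
        # identical rule up to floating-point boundary ties
        assert np.mean(ours == theirs) >= 0.99


class TestPrediction:
    def test_centroid_maps_to_its_class(self):
        rng = np.random.default_rng(11)
        centers = [(0, 0), (12, 0), (0, 12)]
        X, y = gaussian_clouds(rng, centers)
        model = train(X, y)
        for k, c in enumerate(centers):
            assert model.predict(np.asarray(c, dtype=float)) == k

    def test_zero_weights_tie_breaks_to_first_label(self):
        model = LinearModel(
            class_labels=(0, 1, 2),
            weights=np.zeros((3, 3)),
            feature_names=("a", "b"),
        )
        assert model.predict(np.array([1.0, -1.0])) == 0

    def test_batch_equals_elementwise(self):
        rng = np.random.default_rng(2)
        X, y = gaussian_clouds(rng, [(0, 0), (5, 5)])
        model = train(X, y)
        probes = rng.normal(size=(30, 2)) * 5
        batch = model.predict(probes)
        single = [predict(model, p) for p in probes]
        assert batch.tolist() == single

    def test_dimension_mismatch_names_lengths(self):
        model = LinearModel(
            class_labels=(0, 1), weights=np.zeros((2, 4)), feature_names=("a", "b", "c")
        )
        with pytest.raises(ValueError, match="expected 3.*received 2"):
            model.predict(np.ones(2))

    def test_score_shift_invariance(self):
        rng = np.random.default_rng(9)
        X, y = gaussian_clouds(rng, [(0, 0), (4, 4)])
        model = train(X, y)
        shifted = LinearModel(
            class_labels=model.class_labels,
            weights=model.weights + np.array([0.0, 0.0, 13.5]),
            feature_names=model.feature_names,
        )
        probes = rng.normal(size=(50, 2)) * 4
        assert model.predict(probes).tolist() == shifted.predict(probes).tolist()


class TestConfusion:
    def test_perfect_classifier_is_diagonal(self):
        rng = np.random.default_rng(5)
        X, y = gaussian_clouds(rng, [(0, 0), (10, 10)], n_per=20)
        cm = confusion(train(X, y), X, y)
        assert np.all(cm.counts == np.diag([20, 20]))

    def test_constant_classifier_single_column(self):
        model = LinearModel(
            class_labels=(0, 1), weights=np.array([[0.0, 1.0], [0.0, 0.0]]),
            feature_names=("x0",),
        )
        cm = confusion(model, np.zeros((6, 1)), [0, 0, 0, 1, 1, 1])
        assert cm.counts[:, 0].sum() == 6
        assert cm.counts[:, 1].sum() == 0

    def test_row_sums_are_class_counts(self):
        rng = np.random.default_rng(6)
        X, y = gaussian_clouds(rng, [(0, 0), (2, 2), (4, 0)], n_per=17)
        cm = confusion(train(X, y), X, y)
        assert cm.counts.sum(axis=1).tolist() == [17, 17, 17]

    def test_unknown_test_label_rejected(self):
        rng = np.random.default_rng(8)
        X, y = gaussian_clouds(rng, [(0, 0), (9, 9)])
        with pytest.raises(ValueError, match="unseen"):
            confusion(train(X, y), X[:3], [0, 1, 5])


class TestMetrics:
    def test_identity_confusion_all_hundred(self):
        cm = ConfusionMatrix(labels=(0, 1, 2), counts=np.diag([5, 5, 5]))
        m = metrics_from_confusion(cm, negative_class=0)
        assert m["accuracy"] == 100.0
        assert m["specificity"] == 100.0
        assert all(v == 100.0 for v in m["sensitivity"].values())

    def test_zero_diagonal_zero_accuracy(self):
        cm = ConfusionMatrix(labels=(0, 1), counts=np.array([[0, 4], [4, 0]]))
        assert metrics_from_confusion(cm, 0)["accuracy"] == 0.0

    def test_empty_row_rejected(self):
        cm = ConfusionMatrix(labels=(0, 1), counts=np.array([[3, 1], [0, 0]]))
        with pytest.raises(ValueError, match="empty"):
            metrics_from_confusion(cm, 0)

    def test_unknown_negative_class_rejected(self):
        cm = ConfusionMatrix(labels=(0, 1), counts=np.eye(2, dtype=int))
        with pytest.raises(ValueError, match="negative class"):
            metrics_from_confusion(cm, 9)


class TestSerialization:
    def test_json_round_trip_bit_identical_predictions(self):
        rng = np.random.default_rng(13)
        X, y = gaussian_clouds(rng, [(0, 0, 0), (3, 3, 3), (6, 0, 3)])
        model = train(X, y, standardize=True)
        clone = LinearModel.from_json(model.to_json())
        probes = rng.normal(size=(100, 3)) * 6
        np.testing.assert_array_equal(model.scores(probes), clone.scores(probes))
        assert model.predict(probes).tolist() == clone.predict(probes).tolist()

    def test_rejects_foreign_json(self):
        with pytest.raises(ValueError, match="not a recognised"):
            LinearModel.from_json('{"hello": 1}')
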