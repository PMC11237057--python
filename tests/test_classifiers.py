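import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from mtqsar.classifiers import (
    DiscriminantModel,
    ForestConfig,
    ForestModel,
    fit_lda,
    fit_rf,
    lda_predict,
    rf_predict,
)
from mtqsar.feature_selection import wilks_lambda


class TestFitLDA:
    def test_symmetric_classes_boundary_at_zero(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(-1, 0.3, 300), rng.normal(1, 0.3, 300)].reshape(-1, 1)
        y = np.r_[np.zeros(300, int), np.ones(300, int)]
        model = fit_lda(X, y)
        # the raw-scale boundary is where score == 0: x* = -b_raw / w_raw
        boundary = -model.raw_intercept / model.raw_coefficients[0]
        assert boundary == pytest.approx(0.0, abs=0.05)

    def test_separable_data_perfect_training_accuracy(self, two_class_data):
        X, y = two_class_data(n=200, p=4, n_informative=2, effect=8.0, seed=1)
        model = fit_lda(X, y)
        _, labels = lda_predict(model, X)
        assert (labels == np.where(y == 1, "active", "inactive")).all()
        assert model.training_confusion["fp"] == model.training_confusion["fn"] == 0

    def test_rescaling_raw_column_changes_nothing(self, two_class_data):
        X, y = two_class_data(n=150, p=3, seed=2)
        model_a = fit_lda(X, y)
        X_scaled = X.assign(f0=X["f0"] * 10.0)
        model_b = fit_lda(X_scaled, y)
        scores_a, labels_a = lda_predict(model_a, X)
        scores_b, labels_b = lda_predict(model_b, X_scaled)
        np.testing.assert_allclose(scores_a, scores_b, rtol=1e-9)
        assert (labels_a == labels_b).all()
        assert model_a.wilks_lambda_train == pytest.approx(model_b.wilks_lambda_train)

    def test_zero_variance_column_rejected_by_name(self, two_class_data):
        X, y = two_class_data(n=50, p=3)
        X = X.assign(flat=1.0)
        with pytest.raises(ValueError, match="flat"):
            fit_lda(X, y)

    def test_collinear_columns_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = rng.integers(0, 2, size=100)
        with pytest.raises(ValueError):
            fit_lda(X, y)

    def test_lambda_consistent_with_feature_selection_module(self, two_class_data):
        X, y = two_class_data(n=120, p=4, seed=4)
        model = fit_lda(X, y, subset=["f0", "f2"])
        assert model.wilks_lambda_train == pytest.approx(
            wilks_lambda(X, y, ["f0", "f2"]), rel=1e-10
        )

    def test_agrees_with_reference_lda_on_labels(self, two_class_data):
        # independent oracle: sklearn's LDA with equal priors ranks/labels the same
        X, y = two_class_data(n=300, p=5, n_informative=3, effect=1.5, seed=5)
        model = fit_lda(X, y)
        _, labels = lda_predict(model, X)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        ref_labels = np.where(ref.predict(X) == 1, "active", "inactive")
        assert (labels == ref_labels).mean() > 0.99


class TestLDAPredict:
    def test_zero_z_vector_scores_at_intercept(self, two_class_data):
        X, y = two_class_data(n=100, p=3, seed=6)
        model = fit_lda(X, y)
        x_mean = pd.DataFrame([model.feature_means], columns=model.descriptor_names)
        scores, labels = lda_predict(model, x_mean)
        assert scores[0] == pytest.approx(model.intercept)
        assert labels[0] == ("active" if model.intercept > model.threshold else "inactive")

    def test_hand_computed_dot_product(self):
        model = DiscriminantModel(
            descriptor_names=["a", "b"],
            coefficients=np.array([2.0, -1.0]),
            intercept=0.5,
            feature_means=np.array([1.0, 2.0]),
            feature_sds=np.array([2.0, 4.0]),
            wilks_lambda_train=0.5,
        )
        X = pd.DataFrame({"a": [1.0, 3.0, 5.0], "b": [2.0, 6.0, -2.0]})
        # z = ((x-mean)/sd); score = 2*z_a - 1*z_b + 0.5, by hand:
        expected = np.array([0.5, 1.5, 5.5])
        scores, labels = lda_predict(model, X)
        np.testing.assert_allclose(scores, expected, rtol=1e-12)
        assert list(labels) == ["active", "active", "active"]

    def test_score_is_affine_in_z_space(self, two_class_data):
        X, y = two_class_data(n=80, p=3, seed=7)
        model = fit_lda(X, y)
        x1, x2 = X.iloc[[0]].to_numpy(), X.iloc[[1]].to_numpy()
        for alpha in (0.0, 0.25, 0.7, 1.0):
            mix = pd.DataFrame(alpha * x1 + (1 - alpha) * x2, columns=X.columns)
            s_mix = model.scores(mix)[0]
            s1, s2 = model.scores(X.iloc[[0]])[0], model.scores(X.iloc[[1]])[0]
            assert s_mix == pytest.approx(alpha * s1 + (1 - alpha) * s2, rel=1e-9)

    def test_missing_descriptor_rejected(self, two_class_data):
        X, y = two_class_data(n=60, p=3)
        model = fit_lda(X, y)
        with pytest.raises(KeyError, match="f2"):
            lda_predict(model, X[["f0", "f1"]])

    def test_json_round_trip(self, two_class_data, tmp_path):
        X, y = two_class_data(n=60, p=3)
        model = fit_lda(X, y)
        model.to_json(tmp_path / "m.json")
        back = DiscriminantModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(model.scores(X), back.scores(X), rtol=1e-12)


class TestRandomForest:
    def test_single_deep_tree_memorizes_distinct_rows(self, two_class_data):
        X, y = two_class_data(n=80, p=4, effect=0.5, seed=8)
        model = fit_rf(X, y, ForestConfig(n_trees=1, bootstrap=False, seed=0))
        _, labels = rf_predict(model, X)
        assert (labels == np.where(y == 1, "active", "inactive")).all()

    def test_separable_data_high_test_accuracy(self, two_class_data):
        X, y = two_class_data(n=400, p=6, n_informative=3, effect=2.0, seed=9)
        model = fit_rf(X.iloc[:300], y[:300], ForestConfig(n_trees=100, seed=1))
        _, labels = rf_predict(model, X.iloc[300:])
        acc = (labels == np.where(y[300:] == 1, "active", "inactive")).mean()
        assert acc >= 0.9

    def test_deterministic_given_seed(self, two_class_data):
        X, y = two_class_data(n=100, p=4)
        a = fit_rf(X, y, ForestConfig(n_trees=20, seed=5))
        b = fit_rf(X, y, ForestConfig(n_trees=20, seed=5))
        fa, la = rf_predict(a, X)
        fb, lb = rf_predict(b, X)
        np.testing.assert_array_equal(fa, fb)
        np.testing.assert_array_equal(la, lb)

    def test_vote_fraction_equals_per_tree_tally(self, two_class_data):
        X, y = two_class_data(n=120, p=4, effect=1.0, seed=10)
        model = fit_rf(X, y, ForestConfig(n_trees=5, seed=2))
        fractions, _ = rf_predict(model, X)
        M = X.to_numpy()
        tally = np.mean(
            [tree.predict(M) == 1 for tree in model.estimator.estimators_], axis=0
        )
        np.testing.assert_allclose(fractions, tally, rtol=1e-12)

    def test_tied_vote_predicts_inactive(self):
        # two stub trees that always disagree -> fraction exactly 0.5
        from sklearn.tree import DecisionTreeClassifier

        X0 = np.array([[0.0], [1.0]])
        t_active = DecisionTreeClassifier().fit(X0, [1, 1])
        t_inactive = DecisionTreeClassifier().fit(X0, [0, 0])

        class Stub:
            estimators_ = [t_active, t_inactive]

        model = ForestModel(estimator=Stub(), descriptor_names=["x"])
        fractions, labels = rf_predict(model, pd.DataFrame({"x": [0.3, 0.9]}))
        np.testing.assert_allclose(fractions, 0.5)
        assert list(labels) == ["inactive", "inactive"]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError):
            fit_rf(X, np.ones(20, int))
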