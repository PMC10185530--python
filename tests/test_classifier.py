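"""Feature assembly, selection loss, GBM training and hyperparameter search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esp.classifier import (BaselineClassifier, FeatureRecipe, PairClassifier,
                            SelectionLoss, assemble_features,
                            check_folds_disjoint, classify, load_model,
                            predict_scores, random_search_cv, save_model,
                            selection_loss)
from esp.data_io import PairRecord


def random_vectors(ids, dim, seed=0):
    rng = np.random.default_rng(seed)
    return {i: rng.normal(0, 1, dim) for i in ids}


class TestAssembleFeatures:
    def test_dimensions_enzyme_first(self):
        pairs = [PairRecord("E1", "M1", 1), PairRecord("E1", "M2", 0,
                                                       evidence="sampled")]
        evecs = random_vectors(["E1"], 1280)
        mvecs = random_vectors(["M1", "M2"], 100, seed=1)
        X, y, recipe = assemble_features(pairs, evecs, mvecs)
        assert X.shape == (2, 1380)
        assert recipe.total_dim == 1380
        assert np.array_equal(X[0, :1280], evecs["E1"])  # enzyme part first
        assert np.array_equal(y, [1, 0])
        X2, _, recipe2 = assemble_features(pairs, evecs,
                                           random_vectors(["M1", "M2"], 1024))
        assert X2.shape == (2, 2304) and recipe2.molecule_dim == 1024

    def test_missing_id_raises(self):
        with pytest.raises(KeyError, match="EX"):
            assemble_features([PairRecord("EX", "M1", 1)],
                              random_vectors(["E1"], 8),
                              random_vectors(["M1"], 8))

    def test_recipe_mismatch_rejected(self):
        a = FeatureRecipe(enzyme_dim=100, molecule_dim=1024)
        b = FeatureRecipe(enzyme_dim=1024, molecule_dim=100)  # swapped order
        with pytest.raises(ValueError, match="recipe"):
            a.check(b)


class TestSelectionLoss:
    def test_closed_form_values(self):
        assert selection_loss(0, 0) == 0.0
        assert selection_loss(1, 1) == pytest.approx(3.0)
        assert selection_loss(0.5, 0.5) == pytest.approx(
            2 * 0.25 + 0.5 ** 1.3)  # = 0.90613...

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            selection_loss(1.2, 0)
        with pytest.raises(ValueError):
            selection_loss(0, -0.1)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 0.2), st.floats(0, 0.2))
    def test_monotone_in_each_rate(self, fnr, fpr, dn, dp):
        base = selection_loss(fnr, fpr)
        assert selection_loss(min(fnr + dn, 1), fpr) >= base
        assert selection_loss(fnr, min(fpr + dp, 1)) >= base
        assert base >= 0
        if base == 0:
            # the powers underflow for tiny inputs; both rates must still
            # be numerically negligible
            assert fnr < 1e-150 and fpr < 1e-200

    def test_custom_parameters(self):
        loss = SelectionLoss(fn_coefficient=1, fn_exponent=1, fp_exponent=1)
        assert loss(0.25, 0.5) == pytest.approx(0.75)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    n = 400
    X = rng.normal(0, 1, (n, 8))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    return X, y


class TestPairClassifier:
    def test_capacity_on_separable_data(self, separable):
        X, y = separable
        model = PairClassifier(seed=0, n_estimators=100).fit(X, y)
        preds = model.predict(X)
        assert (preds == y).mean() > 0.99
        scores = predict_scores(model, X)
        assert scores.min() >= 0 and scores.max() <= 1

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single-class"):
            PairClassifier().fit(np.zeros((5, 2)), np.zeros(5))

    def test_negative_weight_raises_tpr(self):
        """Down-weighting negatives shifts decisions toward the positive
        class on imbalanced, noisy data."""
        rng = np.random.default_rng(1)
        tprs = {}
        for w in (1.0, 0.3):
            vals = []
            for seed in range(3):
                X = rng.normal(0, 1, (600, 6))
                margin = X[:, 0] + rng.normal(0, 1.2, 600)
                y = (margin > 0.8).astype(int)  # ~20% positives, noisy
                if y.sum() < 5:
                    continue
                m = PairClassifier(seed=seed, negative_weight=w,
                                   n_estimators=80).fit(X, y)
                preds = m.predict(X)
                vals.append(((preds == 1) & (y == 1)).sum() / max(y.sum(), 1))
            tprs[w] = np.mean(vals)
        assert tprs[0.3] > tprs[1.0]

    def test_classify_threshold_conventions(self):
        scores = np.array([0.0, 0.499, 0.5, 0.9])
        assert classify(scores).tolist() == [0, 0, 1, 1]  # 0.5 is positive
        assert classify(scores, 0).tolist() == [1, 1, 1, 1]

    def test_serialization_roundtrip(self, separable, tmp_path):
        X, y = separable
        model = PairClassifier(seed=0, n_estimators=50).fit(
            X, y, FeatureRecipe(4, 4))
        before = predict_scores(model, X)
        save_model(tmp_path / "m.pkl", model)
        loaded = load_model(tmp_path / "m.pkl")
        assert np.array_equal(before, predict_scores(loaded, X))
        with pytest.raises(ValueError, match="feature length"):
            loaded.predict_proba(X[:, :5])


class TestBaselines:
    def test_logistic_separable(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]] * 10)
        y = (X[:, 0] > 0.5).astype(int)
        m = BaselineClassifier("logistic").fit(X, y)
        assert (m.predict(X) == y).all()

    def test_random_forest_scores_unit_interval(self, separable):
        X, y = separable
        m = BaselineClassifier("random_forest", n_estimators=30, seed=0).fit(X, y)
        s = predict_scores(m, X)
        assert s.min() >= 0 and s.max() <= 1

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            BaselineClassifier("svm").fit(np.zeros((4, 2)), [0, 1, 0, 1])


class TestRandomSearchCV:
    def _folded(self, n_enzymes=20, pairs_per=10, seed=0):
        rng = np.random.default_rng(seed)
        enzyme_ids, rows, labels = [], [], []
        enzyme_effect = rng.normal(0, 1, n_enzymes)
        for e in range(n_enzymes):
            for _ in range(pairs_per):
                x = rng.normal(0, 1, 6)
                x[5] = enzyme_effect[e]
                rows.append(x)
                labels.append(int(x[0] + 0.5 * enzyme_effect[e] > 0))
            enzyme_ids += [f"E{e}"] * pairs_per
        folds = np.array([int(e[1:]) % 5 + 1 for e in enzyme_ids])
        return np.array(rows), np.array(labels), enzyme_ids, folds

    def test_two_point_space_selects_the_good_config(self):
        X, y, enzyme_ids, folds = self._folded()
        space = {"max_depth": ("choice", [6]),
                 "n_estimators": ("choice", [100, 1]),
                 "learning_rate": ("choice", [0.2, 0.001])}
        best, log = random_search_cv(X, y, enzyme_ids, folds, space,
                                     n_trials=8, seed=0)
        assert best["n_estimators"] == 100 and best["learning_rate"] == 0.2
        assert log["mean_loss"].min() == pytest.approx(
            log.loc[log["mean_loss"].idxmin(), "mean_loss"])

    def test_argmin_property_and_determinism(self):
        X, y, enzyme_ids, folds = self._folded()
        best1, log1 = random_search_cv(X, y, enzyme_ids, folds, n_trials=4,
                                       seed=7)
        best2, log2 = random_search_cv(X, y, enzyme_ids, folds, n_trials=4,
                                       seed=7)
        assert best1 == best2
        assert log1["mean_loss"].tolist() == log2["mean_loss"].tolist()
        best_loss = min(log1["mean_loss"])
        assert all(best_loss <= v for v in log1["mean_loss"])

    def test_leaky_folds_rejected(self):
        X, y, enzyme_ids, folds = self._folded()
        folds = folds.copy()
        folds[0] = folds[0] % 5 + 1  # first row of E0 moved to another fold
        with pytest.raises(ValueError, match="leakage"):
            random_search_cv(X, y, enzyme_ids, folds, n_trials=1, seed=0)
        check_folds_disjoint(["a", "a", "b"], [1, 1, 2])  # clean passes

    def test_shuffled_labels_give_chance_auc(self):
        from esp.evaluation import roc_auc

        X, y, enzyme_ids, folds = self._folded(seed=3)
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        aucs = []
        for f in np.unique(folds):
            m = PairClassifier(seed=0, n_estimators=60).fit(
                X[folds != f], y_shuf[folds != f])
            aucs.append(roc_auc(predict_scores(m, X[folds == f]),
                                y_shuf[folds == f]))
        assert 0.4 < np.mean(aucs) < 0.6

    def test_gbm_beats_baselines_on_benchmark(self, bench_model):
        """Selection loss of the boosted model does not exceed the linear
        and forest baselines on the planted benchmark test set."""
        from esp.evaluation import confusion

        X_parts = bench_model
        train, test = X_parts["train_pairs"], X_parts["test_pairs"]
        evecs, fpd = X_parts["enzyme_vectors"], X_parts["mol_vectors"]
        X_tr, y_tr, _ = assemble_features(train, evecs, fpd)
        X_te, y_te, _ = assemble_features(test, evecs, fpd)
        loss = SelectionLoss()

        def loss_of(model):
            c = confusion(predict_scores(model, X_te), y_te)
            return loss(c.fnr, c.fpr)

        gbm_loss = loss_of(X_parts["model"])
        logistic = BaselineClassifier("logistic", seed=0).fit(X_tr, y_tr)
        forest = BaselineClassifier("random_forest", n_estimators=100,
                                    seed=0).fit(X_tr, y_tr)
        assert gbm_loss <= loss_of(logistic)
        assert gbm_loss <= loss_of(forest)
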