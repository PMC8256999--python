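"""CART/forest correctness: Gini arithmetic, splits, growth, votes, importance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polarforest as pf
from polarforest.forest import best_split
from polarforest.training import split_Xy


class TestGini:
    def test_pure_node_is_zero(self):
        assert pf.gini([10, 0, 0, 0]) == 0.0

    def test_uniform_four_class_mix(self):
        assert pf.gini([5, 5, 5, 5]) == pytest.approx(0.75)

    def test_two_class_worked_example(self):
        # 1 - (30/51)^2 - (21/51)^2
        assert pf.gini([30, 21]) == pytest.approx(0.4844, abs=5e-5)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            pf.gini([0, 0])
        with pytest.raises(ValueError):
            pf.gini([3, -1])

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=8).filter(lambda c: sum(c) > 0))
    @settings(deadline=None, max_examples=200)
    def test_bounds_and_permutation_invariance(self, counts):
        g = pf.gini(counts)
        k = len(counts)
        assert 0.0 <= g <= 1.0 - 1.0 / k + 1e-12
        assert g == pytest.approx(pf.gini(sorted(counts)))


class TestImpurityDecrease:
    def test_perfect_separation_recovers_full_impurity(self):
        parent = [8, 8]
        assert pf.impurity_decrease(parent, [8, 0], [0, 8], weight=0.5) == pytest.approx(
            0.5 * pf.gini(parent)
        )

    def test_children_with_parent_mix_give_zero(self):
        assert pf.impurity_decrease([6, 6], [3, 3], [3, 3]) == pytest.approx(0.0)

    def test_worked_example_6_6_into_4_2_2_4(self):
        assert pf.impurity_decrease([6, 6], [4, 2], [2, 4], weight=1.0) == pytest.approx(
            0.0556, abs=5e-5
        )

    def test_inconsistent_children_rejected(self):
        with pytest.raises(ValueError):
            pf.impurity_decrease([6, 6], [4, 2], [3, 4])


def _brute_force_best(X, y):
    """Independent oracle: enumerate every feature and midpoint directly."""
    labels = sorted(set(y), key=str)
    counts = lambda rows: [sum(1 for r in rows if y[r] == c) for c in labels]
    n = len(y)
    best = None
    for f in range(X.shape[1]):
        for t in sorted(set((a + b) / 2 for a, b in zip(sorted(X[:, f])[:-1], sorted(X[:, f])[1:]))):
            left = [i for i in range(n) if X[i, f] <= t]
            right = [i for i in range(n) if X[i, f] > t]
            if not left or not right:
                continue
            dec = (
                pf.gini(counts(range(n)))
                - len(left) / n * pf.gini(counts(left))
                - len(right) / n * pf.gini(counts(right))
            )
            if best is None or dec > best[0] + 1e-12:
                best = (dec, f, t)
    return best


class TestBestSplit:
    def test_textbook_two_class_threshold(self):
        rule = best_split(np.array([[1.0], [2.0], [3.0], [4.0]]), ["A", "A", "B", "B"])
        assert rule.feature == 0
        assert rule.threshold == pytest.approx(2.5)
        assert rule.decrease == pytest.approx(0.5)

    def test_constant_features_give_none(self):
        assert best_split(np.ones((6, 3)), ["A", "B", "A", "B", "A", "B"]) is None

    def test_pure_node_gives_none(self):
        assert best_split(np.arange(8.0).reshape(4, 2), ["A"] * 4) is None

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(25, 3)).round(1)  # rounding forces ties
            y = rng.choice(["A", "B", "C"], size=25)
            rule = best_split(X, y)
            expected = _brute_force_best(X, y)
            if expected is None or expected[0] <= 1e-12:
                assert rule is None
            else:
                assert rule.decrease == pytest.approx(expected[0])


class TestTreeGrowth:
    def test_linearly_separable_toy_needs_one_split(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["A", "A", "B", "B"])
        tree = pf.grow_tree(X, y)
        assert tree.get_depth() == 1
        assert np.mean(tree.predict(X) == y) == 1.0

    def test_max_depth_zero_predicts_global_majority(self):
        X = np.arange(10.0).reshape(-1, 1)
        y = np.array(["A"] * 6 + ["B"] * 4)
        tree = pf.grow_tree(X, y, max_depth=0)
        assert tree.tree_.n_nodes == 1
        assert set(tree.predict(X)) == {"A"}

    def test_pure_data_gives_single_leaf(self):
        tree = pf.grow_tree(np.arange(6.0).reshape(-1, 1), ["A"] * 6)
        assert tree.tree_.n_nodes == 1

    def test_child_counts_and_weights_conserved(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        tree = pf.grow_tree(X, y, max_depth=6).tree_
        k = tree.counts.shape[1]
        for j in range(tree.n_nodes):
            g = pf.gini(tree.counts[j])
            assert 0.0 <= g <= 1.0 - 1.0 / k + 1e-12
            if tree.feature[j] >= 0:
                np.testing.assert_allclose(
                    tree.counts[tree.left[j]] + tree.counts[tree.right[j]], tree.counts[j]
                )

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            pf.grow_tree(np.empty((0, 2)), [])


class TestForest:
    def test_degenerate_forest_equals_single_tree(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        forest = pf.fit_forest(X, y, n_trees=1, max_depth=5,
                               features_per_split=None, bootstrap=False, seed=0)
        tree = pf.grow_tree(X, y, max_depth=5)
        np.testing.assert_array_equal(forest.predict(X), tree.predict(X))
        np.testing.assert_allclose(forest.feature_importances_, tree.feature_importances_)

    def test_seed_reproducibility(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        Xt, _ = split_Xy(small_dataset[1])
        a = pf.fit_forest(X, y, n_trees=20, max_depth=8, seed=42)
        b = pf.fit_forest(X, y, n_trees=20, max_depth=8, seed=42)
        np.testing.assert_array_equal(a.predict(Xt), b.predict(Xt))
        np.testing.assert_allclose(a.feature_importances_, b.feature_importances_)

    def test_vote_fractions_are_probability_vectors(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        Xt, _ = split_Xy(small_dataset[1])
        model = pf.fit_forest(X, y, n_trees=15, max_depth=8, seed=1)
        proba = model.predict_proba(Xt)
        assert proba.shape == (len(Xt), 4)
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        # fractions are multiples of 1/T (one vote per tree)
        np.testing.assert_allclose(proba * 15, np.round(proba * 15), atol=1e-9)

    def test_unanimous_votes_give_fraction_one(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        y = np.array(["A", "A", "B", "B"])
        model = pf.fit_forest(X, y, n_trees=9, max_depth=3, features_per_split=None,
                              bootstrap=False, seed=0)
        proba = model.predict_proba(np.array([[0.0]]))
        np.testing.assert_allclose(proba, [[1.0, 0.0]])

    def test_plurality_tie_breaks_to_fixed_class_order(self):
        # unsplittable node with a 1-1 class tie: BCC wins over melanoma
        X = np.zeros((2, 1))
        y = np.array(["melanoma", "BCC"])
        model = pf.fit_forest(X, y, n_trees=4, max_depth=3, bootstrap=False, seed=0)
        assert model.predict(np.zeros((1, 1)))[0] == "BCC"

    def test_feature_count_mismatch_rejected(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        model = pf.fit_forest(X, y, n_trees=2, max_depth=2, seed=0)
        with pytest.raises(ValueError, match="features"):
            model.predict(X[:, :10])

    @pytest.mark.parametrize("bad", [{"n_trees": 0}, {"max_depth": -1}])
    def test_invalid_hyperparameters_rejected(self, small_dataset, bad):
        X, y = split_Xy(small_dataset[0])
        with pytest.raises(ValueError):
            pf.fit_forest(X, y, **bad)

    def test_missing_values_rejected(self):
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError, match="missing"):
            pf.fit_forest(X, ["A", "B"], n_trees=1)


class TestImportance:
    def test_only_varying_feature_takes_all_importance(self, rng):
        X = np.ones((40, 5))
        X[:, 2] = rng.normal(size=40)
        y = np.where(X[:, 2] > 0, "A", "B")
        model = pf.fit_forest(X, y, n_trees=10, max_depth=4, seed=0)
        np.testing.assert_allclose(model.feature_importances_, np.eye(5)[2], atol=1e-12)

    def test_depth_one_tree_is_one_hot(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.where(X[:, 3] > 0, "A", "B")
        tree = pf.grow_tree(X, y, max_depth=1)
        assert tree.tree_.feature[0] == 3
        np.testing.assert_allclose(tree.feature_importances_, np.eye(6)[3])

    def test_importance_sums_to_one(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        model = pf.fit_forest(X, y, n_trees=25, max_depth=10, seed=3)
        assert (model.feature_importances_ >= 0).all()
        assert model.feature_importances_.sum() == pytest.approx(1.0)

    def test_stump_forest_has_zero_importance(self):
        model = pf.fit_forest(np.zeros((4, 2)), ["A"] * 4, n_trees=3, seed=0)
        np.testing.assert_allclose(model.feature_importances_, 0.0)

    def test_invariant_to_consistent_positive_feature_scaling(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        a = pf.fit_forest(X, y, n_trees=10, max_depth=8, seed=7)
        b = pf.fit_forest(X * 1000.0, y, n_trees=10, max_depth=8, seed=7)
        np.testing.assert_allclose(a.feature_importances_, b.feature_importances_)


class TestPersistence:
    def test_json_round_trip_preserves_predictions_and_importance(self, small_dataset):
        X, y = split_Xy(small_dataset[0])
        Xt, _ = split_Xy(small_dataset[1])
        model = pf.fit_forest(X, y, n_trees=12, max_depth=8, seed=9)
        restored = pf.forest_from_json(pf.forest_to_json(model))
        np.testing.assert_array_equal(model.predict(Xt), restored.predict(Xt))
        np.testing.assert_allclose(model.predict_proba(Xt), restored.predict_proba(Xt))
        np.testing.assert_allclose(
            model.feature_importances_, restored.feature_importances_
        )


class TestSklearnOracle:
    """The reference library is the independent cross-check, never the engine."""

    @pytest.mark.parametrize("depth", [2, 4, 8, None])
    def test_single_tree_training_accuracy_matches_reference(self, small_dataset, depth):
        from sklearn.tree import DecisionTreeClassifier

        X, y = split_Xy(small_dataset[0])
        ours = pf.grow_tree(X, y, max_depth=depth)
        ref = DecisionTreeClassifier(max_depth=depth, random_state=0).fit(X, y)
        assert np.mean(ours.predict(X) == y) == np.mean(ref.predict(X) == y)

    def test_sklearn_grid_search_composes_with_estimator(self, small_dataset):
        from sklearn.model_selection import GridSearchCV

        X, y = split_Xy(small_dataset[0])
        gs = GridSearchCV(
            pf.GiniRandomForestClassifier(n_estimators=10, random_state=0),
            {"max_depth": [1, 6]},
            cv=3,
        ).fit(X, y)
        assert gs.best_params_["max_depth"] == 6
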