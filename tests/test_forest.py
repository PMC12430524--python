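"""Random forest, variant aggregation, LOVO evaluation, subset comparison."""

import numpy as np
import pytest

import angleforest as af
from angleforest.forest import (lovo_evaluate, predict_unknowns,
                                predict_variant, subset_comparison,
                                train_forest)
from angleforest.selection import fit_tree, iterative_selection


def test_training_accuracy_on_separable_classes(small_known, small_forest):
    frames = small_forest.predict_matrix(small_known)
    assert np.mean(frames == small_known.y) > 0.99


def test_single_tree_no_bootstrap_equals_fit_tree(small_known):
    feats = ["phi455", "psi460"]
    forest = train_forest(small_known, feats, n_trees=1, seed=0,
                          bootstrap=False, max_depth=2)
    tree = fit_tree(small_known, features=feats, max_depth=2)
    X = small_known.X(feats)
    assert np.array_equal(forest.predict_frames(X),
                          tree.predict(X, feats))


def test_fixed_seed_is_deterministic(small_known):
    feats = ["phi455", "psi460"]
    a = train_forest(small_known, feats, n_trees=10, seed=42)
    b = train_forest(small_known, feats, n_trees=10, seed=42)
    X = small_known.X(feats)
    assert np.array_equal(a.predict_frames(X), b.predict_frames(X))


def test_empty_feature_list_rejected(small_known):
    with pytest.raises(ValueError):
        train_forest(small_known, [], n_trees=5, seed=0)


class TestPredictVariant:
    def test_counting_and_fraction(self, small_forest):
        class Stub:
            features = small_forest.features
            def predict_frames(self, X):
                return np.array([1] * 1600 + [0] * 1400)
        pred = predict_variant(Stub(), np.zeros((3000, 2)))
        assert pred.label == "R"
        assert pred.vote_fraction == pytest.approx(1600 / 3000)

    def test_exact_tie_goes_sensitive_and_is_flagged(self, small_forest):
        class Stub:
            features = small_forest.features
            def predict_frames(self, X):
                return np.array([0, 1, 0, 1])
        pred = predict_variant(Stub(), np.zeros((4, 2)))
        assert pred.label == "S" and pred.tie

    def test_zero_frames_rejected(self, small_forest):
        with pytest.raises(ValueError):
            predict_variant(small_forest, np.zeros((0, 2)))


class TestLovo:
    def test_planted_signal_gives_perfect_variant_accuracy(self, small_known):
        res = lovo_evaluate(small_known, ["phi455", "psi460"],
                            n_trees=25, seed=1)
        assert res.accuracy == 1.0
        table = res.to_table()
        assert set(table.columns) >= {"variant", "status", "prediction"}
        assert len(table) == 12

    def test_accuracy_invariant_to_frame_order(self, small_known, rng):
        perm = rng.permutation(small_known.n_rows)
        shuffled = small_known.subset_rows(perm)
        a = lovo_evaluate(small_known, ["phi455", "psi460"], n_trees=10, seed=7)
        b = lovo_evaluate(shuffled, ["phi455", "psi460"], n_trees=10, seed=7)
        assert a.accuracy == b.accuracy

    def test_single_variant_class_rejected(self, small_known):
        keep = ["V600E", "V600M", "G469A"]  # 2 sensitive, 1 resistant
        sub = small_known.select_variants(keep)
        with pytest.raises(ValueError, match="at least 2"):
            lovo_evaluate(sub, ["phi455", "psi460"], n_trees=5, seed=0)

    def test_permutation_null_collapses_accuracy(self, small_known):
        planted = lovo_evaluate(small_known, ["phi455", "psi460"],
                                n_trees=10, seed=3).accuracy
        null = af.permutation_null(small_known, ["phi455", "psi460"],
                                   n_permutations=3, n_trees=10, seed=3)
        assert planted == 1.0
        assert np.mean(null) < 0.8


class TestSubsetsAndUnknowns:
    def test_subset_comparison_layout(self, small_known):
        sel = iterative_selection(small_known, n_rounds=2)
        table = subset_comparison(small_known, sel,
                                  [(1, 2), (1,), (2,), (1,)],  # dup request
                                  n_trees=10, seed=5)
        assert list(table.columns) == ["features", "rounds", "accuracy_pct"]
        assert len(table) == 3  # deduplicated
        row1 = table[table["rounds"] == "1"].iloc[0]
        assert row1["accuracy_pct"] == 100.0

    def test_signal_bearing_rounds_dominate(self, small_known):
        sel = iterative_selection(small_known, n_rounds=2)
        table = subset_comparison(small_known, sel, [(1,), (2,)],
                                  n_trees=10, seed=5)
        acc = dict(zip(table["rounds"], table["accuracy_pct"]))
        assert acc["1"] > acc["2"]

    def test_unknown_variants_get_one_call_each(self, small_known,
                                                small_unknown):
        preds = predict_unknowns(small_known, ["phi455", "psi460"],
                                 small_unknown, n_trees=25, seed=2)
        assert len(preds) == 4
        by_name = {p.variant: p.label for p in preds}
        # VUS were planted on the side of their published calls
        assert by_name["L505H"] == "S"
        assert by_name["L597R"] == "R"
        assert by_name["V600E+L505H"] == "R"
        assert by_name["V600E+L514V"] == "S"

    def test_no_unknowns_is_empty_not_error(self, small_known):
        empty = small_known.subset_rows(np.zeros(small_known.n_rows, bool))
        assert predict_unknowns(small_known, ["phi455"], empty,
                                n_trees=2, seed=0) == []


def test_forest_agrees_with_sklearn_on_planted_data(small_known):
    """Independent cross-check: scikit-learn's forest reaches the same
    variant calls on the same selected features."""
    from sklearn.ensemble import RandomForestClassifier

    feats = ["phi455", "psi460"]
    X, y = small_known.X(feats), small_known.y
    skl = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
    ours = train_forest(small_known, feats, n_trees=50, seed=0)
    agreement = np.mean(skl.predict(X) == ours.predict_frames(X))
    assert agreement > 0.99
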