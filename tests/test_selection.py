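"""Gini trees: impurity, exhaustive splits vs. brute force, iterative rounds."""

import numpy as np
import pytest

import angleforest as af
from angleforest.selection import (best_split, fit_tree, gini_impurity,
                                   iterative_selection)


def brute_force_best_split(values, labels, min_leaf=1):
    """Independent enumeration: evaluate every midpoint of consecutive
    distinct sorted values by masking, keep the smallest weighted Gini
    (ties -> smaller threshold)."""
    v = np.asarray(values, float)
    y = np.asarray(labels)
    distinct = np.unique(v)
    best = None
    n = len(v)
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = 0.5 * (lo + hi)
        left = v <= thr
        n_left, n_right = int(left.sum()), int((~left).sum())
        if n_left < min_leaf or n_right < min_leaf:
            continue
        def g(mask, m):
            c1 = int(np.sum(y[mask] == 1))
            c0 = m - c1
            return 1.0 - ((c0 / m) ** 2 + (c1 / m) ** 2)
        weighted = (n_left * g(left, n_left) + n_right * g(~left, n_right)) / n
        if best is None or weighted < best[1]:
            best = (thr, weighted)
    return best


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini_impurity((7, 0)) == 0.0

    def test_balanced_node_is_half(self):
        assert gini_impurity((1, 1)) == 0.5

    def test_three_one_split(self):
        assert gini_impurity((3, 1)) == pytest.approx(0.375)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))
        with pytest.raises(ValueError):
            gini_impurity((-1, 2))


class TestBestSplit:
    def test_perfectly_separable(self):
        thr, imp = best_split([1, 2, 3, 4], [0, 0, 1, 1])
        assert thr == 2.5 and imp == 0.0

    def test_constant_column_gives_no_split(self):
        assert best_split([3.0, 3.0, 3.0], [0, 1, 0]) is None

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            n = rng.integers(2, 40)
            # draw from few distinct values so exact ties actually occur
            v = rng.choice(np.linspace(-2, 2, 7), size=n)
            y = rng.integers(0, 2, n)
            ml = int(rng.integers(1, 4))
            ours = best_split(v, y, min_leaf=ml)
            oracle = brute_force_best_split(v, y, min_leaf=ml)
            if oracle is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours[0] == oracle[0]      # identical threshold (ties!)
                assert ours[1] == oracle[1]

    def test_split_never_increases_impurity(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 60))
            v = rng.normal(size=n)
            y = rng.integers(0, 2, n)
            res = best_split(v, y)
            if res is None:
                continue
            parent = gini_impurity((int(np.sum(y == 0)), int(np.sum(y == 1))))
            assert res[1] <= parent + 1e-12


class TestFitTree:
    def test_separable_single_angle_gives_depth_one_pure_tree(self):
        X = np.array([[-30.0], [-31.0], [-29.0], [30.0], [31.0], [29.0],
                      [-28.0], [28.0], [-32.0], [32.0]])
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1])
        tree = fit_tree((X, y, ["phi450"]), max_depth=2, min_leaf=1)
        assert tree.depth() == 1
        assert tree.split_features() == ["phi450"]
        assert np.array_equal(tree.predict(X, ["phi450"]), y)

    def test_duplicated_columns_tie_broken_by_name_order(self, rng):
        col = rng.normal(size=40)
        y = (col > 0).astype(int)
        X = np.column_stack([col, col, col])
        # psi449 < phi450 < psi450 in canonical order (resid, phi<psi)
        tree = fit_tree((X, y, ["psi450", "phi450", "psi449"]),
                        max_depth=1, min_leaf=1)
        assert tree.root.feature == "psi449"

    def test_single_class_matrix_gives_single_leaf(self):
        X = np.arange(10.0)[:, None]
        y = np.zeros(10, dtype=int)
        tree = fit_tree((X, y, ["phi450"]))
        assert tree.root.is_leaf and tree.root.prediction == 0

    def test_child_counts_sum_to_parent(self, small_known):
        tree = fit_tree(small_known, max_depth=2)
        def walk(node):
            if node.is_leaf:
                return
            assert node.left.counts[0] + node.right.counts[0] == node.counts[0]
            assert node.left.counts[1] + node.right.counts[1] == node.counts[1]
            walk(node.left)
            walk(node.right)
        walk(tree.root)

    def test_min_leaf_respected(self, small_known):
        tree = fit_tree(small_known, max_depth=6, min_leaf=25)
        def walk(node):
            if node.is_leaf:
                assert sum(node.counts) >= 25
            else:
                walk(node.left)
                walk(node.right)
        walk(tree.root)


class TestIterativeSelection:
    def test_round_one_recovers_planted_angles(self, small_known):
        sel = iterative_selection(small_known, n_rounds=2)
        assert set(sel.rounds[0].selected) == {"phi455", "psi460"}
        # later rounds work with strictly less signal
        assert sel.rounds[1].gini_after > sel.rounds[0].gini_after

    def test_rounds_are_disjoint_and_recorded(self, small_known):
        sel = iterative_selection(small_known, n_rounds=3)
        sets = [set(r.selected) for r in sel.rounds]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]
        assert sel.features_of_rounds([1]) == sel.rounds[0].selected

    def test_pool_exhaustion_stops_early_with_warning(self, small_known):
        with pytest.warns(UserWarning):
            sel = iterative_selection(small_known, n_rounds=4,
                                      features=["phi455", "psi460"])
        assert len(sel.rounds) < 4

    def test_json_serialization_round_trip(self, small_known, tmp_path):
        import json
        sel = iterative_selection(small_known, n_rounds=2)
        path = tmp_path / "sel.json"
        sel.to_json(path)
        data = json.loads(path.read_text())
        assert [r["selected"] for r in data["rounds"]] == sel.selected_by_round

    def test_high_concentration_recovers_only_planted_angles(self):
        """With very tight per-angle distributions every early round
        selects planted angles only, and together they recover the full
        planted set, for every seed tried.  (At high concentration one
        planted angle can separate the classes perfectly, so a single
        round may legitimately stop after one angle.)"""
        for seed in (1, 2, 3):
            spec = af.make_planted_study(
                "dabrafenib", planted=["phi455", "psi460"], offset=60.0,
                seed=seed, n_residues=30, residue_offset=448,
                frames_per_trajectory=60, retain_last=20,
                concentration=200.0, variant_jitter_sd=2.0)
            known, _ = af.build_data_matrix(
                af.generate_study(spec), spec.label_table("dabrafenib"),
                "dabrafenib")
            sel = iterative_selection(known, n_rounds=2)
            assert set(sel.rounds[0].selected) <= {"phi455", "psi460"}
            union = set(sel.features_of_rounds([1, 2]))
            assert {"phi455", "psi460"} <= union
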