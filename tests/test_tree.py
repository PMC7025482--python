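"""CART: impurity, split search, surrogates, growth, pruning, prediction."""

import numpy as np
import pandas as pd
import pytest

import survgain as sg
from survgain.tree import (
    FeatureSchema,
    GrowthParams,
    Split,
    _prune_sequence,
    best_split,
    find_surrogates,
)
from tests.oracles import exhaustive_best_gain


def _params(**kw):
    base = dict(min_split=2, min_bucket=1, max_depth=30, cp_grow=0.0)
    base.update(kw)
    return GrowthParams(**base)


def _split_on(frame, y, **kw):
    schema = FeatureSchema.from_frame(frame)
    return best_split(schema.encode(frame), np.asarray(y, int), schema, _params(**kw))


class TestGini:
    def test_values(self):
        assert sg.gini((5, 5)) == pytest.approx(0.5)
        assert sg.gini((8, 0)) == pytest.approx(0.0)
        assert sg.gini((2, 6)) == pytest.approx(0.375)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            sg.gini((0, 0))


class TestBestSplit:
    def test_perfect_separation(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        split = _split_on(frame, [0, 0, 1, 1])
        assert split.variable == "x"
        assert split.threshold == pytest.approx(2.5)
        assert split.gain == pytest.approx(0.5)

    def test_pure_node_returns_none(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert _split_on(frame, [1, 1, 1]) is None

    def test_threshold_between_observed_values(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 5.0, 5.0, 9.0]})
        split = _split_on(frame, [0, 0, 1, 1, 1])
        assert split.threshold == pytest.approx(3.0)

    def test_categorical_subset_split(self):
        frame = pd.DataFrame({"g": ["a", "a", "b", "b", "c", "c"]})
        split = _split_on(frame, [1, 1, 0, 0, 1, 1])
        assert split.kind == "categorical"
        assert split.subset == ("b",)
        assert split.gain == pytest.approx(2 / 9 * 2)

    def test_tie_broken_by_schema_order(self):
        y = [0, 0, 1, 1]
        frame = pd.DataFrame({"b": [0.0, 0.0, 1.0, 1.0], "a": [0.0, 0.0, 1.0, 1.0]})
        assert _split_on(frame, y).variable == "b"  # column order, not name

    def test_missing_values_penalize_gain(self):
        # same separating power, but one variable is half missing
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        frame = pd.DataFrame({
            "full": [1, 1, 1, 1, 9, 9, 9, 9.0],
            "holey": [1, 1, np.nan, np.nan, np.nan, np.nan, 9, 9.0],
        })
        split = _split_on(frame, y)
        assert split.variable == "full"
        holey = _split_on(frame[["holey"]], y)
        assert holey.gain == pytest.approx(split.gain * 0.5)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            frame = pd.DataFrame({
                "x1": rng.normal(size=n).round(1),
                "x2": rng.integers(0, 3, n).astype(float),
                "g": rng.choice(["a", "b", "c"], n),
            })
            frame.loc[rng.random(n) < 0.15, "x1"] = np.nan
            y = rng.integers(0, 2, n)
            split = _split_on(frame, y)
            oracle = exhaustive_best_gain(frame, y, min_bucket=1)
            got = split.gain if split is not None else 0.0
            assert got == pytest.approx(oracle, abs=1e-9)


class TestSurrogates:
    def _setup(self, frame, y, var="x"):
        schema = FeatureSchema.from_frame(frame)
        X = schema.encode(frame)
        split = best_split(X, np.asarray(y, int), schema, _params())
        j = schema.names.index(split.variable)
        observed = ~np.isnan(X[:, j])
        go_left = X[:, j] <= split.threshold
        return find_surrogates(X, schema, split, go_left, observed)

    def test_duplicate_variable_is_perfect_first_surrogate(self):
        x = np.arange(12, dtype=float)
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": x, "copy": x, "noise": rng.permutation(x)})
        surrogates = self._setup(frame, [0] * 6 + [1] * 6)
        assert surrogates[0][0].variable == "copy"
        assert surrogates[0][1] == pytest.approx(1.0)

    def test_anticorrelated_variable_usable_via_reversed_orientation(self):
        x = np.arange(12, dtype=float)
        frame = pd.DataFrame({"x": x, "neg": -x})
        surrogates = self._setup(frame, [0] * 6 + [1] * 6)
        (surr, agreement), = surrogates
        assert surr.variable == "neg" and surr.direction == "gt"
        assert agreement == pytest.approx(1.0)

    def test_no_other_variables_gives_empty_list(self):
        frame = pd.DataFrame({"x": np.arange(12, dtype=float)})
        assert self._setup(frame, [0] * 6 + [1] * 6) == []

    def test_independent_variable_rarely_qualifies(self):
        # agreement of an unrelated variable hovers at the majority baseline
        rng = np.random.default_rng(1)
        excluded = 0
        reps = 40
        for _ in range(reps):
            n = 500
            frame = pd.DataFrame({"x": rng.normal(size=n),
                                  "junk": rng.normal(size=n)})
            y = (frame["x"] > 0).astype(int)
            surrogates = self._setup(frame, y)
            excluded += not any(s.variable == "junk" for s, _ in surrogates)
        assert excluded / reps >= 0.95


class TestGrow:
    def test_noise_free_threshold_gives_depth_one_tree(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"x1": rng.normal(size=100), "x2": rng.normal(size=100)})
        y = (frame["x1"] <= 0).astype(int)
        tree = sg.grow_tree(frame, y, _params(min_split=5, min_bucket=2))
        assert tree.split_variables() == ["x1"]
        leaves = tree.leaves()
        assert len(leaves) == 2
        assert all(leaf.probability_response in (0.0, 1.0) for leaf in leaves)

    def test_max_depth_zero_gives_prevalence_stump(self):
        frame = pd.DataFrame({"x": [1, 2, 3, 4.0]})
        tree = sg.grow_tree(frame, [0, 1, 1, 1], _params(max_depth=0))
        assert tree.root.is_leaf
        assert tree.root.probability_response == pytest.approx(0.75)

    def test_single_class_input_gives_root_only(self):
        frame = pd.DataFrame({"x": [1, 2, 3, 4.0]})
        tree = sg.grow_tree(frame, [1, 1, 1, 1], _params())
        assert tree.root.is_leaf

    def test_child_counts_sum_to_parent(self, small_cohort):
        f = small_cohort.frame[small_cohort.frame.treated == 1].reset_index()
        y = (f["os_months"] > f["os_months"].median()).astype(int)
        tree = sg.grow_tree(f[sg.COVARIATES], y)
        for node in tree.internal_nodes():
            left, right = node.children
            assert left.n_train + right.n_train == node.n_train
            assert sum(node.class_counts) == node.n_train

    def test_leaf_counts_partition_root(self, small_cohort):
        f = small_cohort.frame[small_cohort.frame.treated == 1].reset_index()
        y = (f["os_months"] > f["os_months"].median()).astype(int)
        tree = sg.grow_tree(f[sg.COVARIATES], y)
        totals = np.sum([leaf.class_counts for leaf in tree.leaves()], axis=0)
        assert tuple(totals) == tree.root.class_counts

    def test_planted_two_level_structure_recovered(self):
        """y = (age>=50 AND chemo) with 10% label noise: the first split is
        on age in nearly all seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 2000
            frame = pd.DataFrame({
                "age": rng.uniform(30, 70, n).round(),
                "chemo": rng.binomial(1, 0.6, n).astype(float),
                "noise1": rng.normal(size=n),
            })
            y = ((frame.age >= 50) & (frame.chemo == 1)).astype(int)
            flip = rng.random(n) < 0.10
            y = (y ^ flip).astype(int)
            tree = sg.grow_tree(frame, y, GrowthParams())
            sv = tree.split_variables()
            hits += bool(sv) and sv[0] == "age"
        assert hits / n_seeds >= 0.8


class TestPruning:
    def _labeled_frame(self, seed=3, n=400, signal=True):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n),
                              "g": rng.choice(["a", "b"], n)})
        if signal:
            y = ((frame.x1 > 0) ^ (rng.random(n) < 0.15)).astype(int)
        else:
            y = rng.integers(0, 2, n)
        return frame, y

    def test_sequence_ends_at_root_only(self):
        frame, y = self._labeled_frame()
        tree = sg.grow_tree(frame, y)
        assert tree.cp_table[0]["n_leaves"] == len(tree.leaves())
        assert tree.cp_table[-1]["n_leaves"] == 1  # cp -> infinity limit

    def test_cp_table_monotone(self):
        frame, y = self._labeled_frame()
        tree = sg.grow_tree(frame, y)
        cps = [r["cp"] for r in tree.cp_table]
        leaves = [r["n_leaves"] for r in tree.cp_table]
        assert cps == sorted(cps)
        assert leaves == sorted(leaves, reverse=True)

    def test_subtrees_are_nested(self):
        frame, y = self._labeled_frame(seed=4, n=600)
        tree = sg.grow_tree(frame, y)
        seq = _prune_sequence(tree.root)
        for (_, a), (_, b) in zip(seq, seq[1:]):
            assert a <= b  # collapsed sets only ever grow

    def test_cv_pruning_keeps_signal_split(self):
        frame, y = self._labeled_frame(seed=5, n=600, signal=True)
        tree = sg.grow_tree(frame, y)
        pruned = sg.prune_cv(tree, frame, y, n_folds=10, seed=0)
        assert "x1" in pruned.split_variables()
        assert pruned.selected_cp is not None
        assert all(r["cv_error"] is not None for r in pruned.cp_table)

    def test_reproducible_given_seed(self):
        frame, y = self._labeled_frame(seed=6, n=500)
        tree1 = sg.prune_cv(sg.grow_tree(frame, y), frame, y, n_folds=10, seed=9)
        tree2 = sg.prune_cv(sg.grow_tree(frame, y), frame, y, n_folds=10, seed=9)
        assert tree1.to_dict() == tree2.to_dict()

    def test_one_se_rule_not_larger_than_min_rule(self):
        frame, y = self._labeled_frame(seed=7, n=500)
        grown = sg.grow_tree(frame, y)
        t_min = sg.prune_cv(grown, frame, y, seed=1, rule="min")
        t_1se = sg.prune_cv(grown, frame, y, seed=1, rule="1se")
        assert len(t_1se.leaves()) <= len(t_min.leaves())


class TestPredict:
    def _grown(self):
        frame = pd.DataFrame({
            "age": [30, 35, 40, 45, 60, 65, 70, 75.0],
            "chemo": [0, 0, 1, 1, 1, 1, 1, 1.0],
        })
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        return sg.grow_tree(frame, y, _params()), frame, np.asarray(y)

    def test_pure_leaf_identity(self):
        tree, frame, y = self._grown()
        scores = sg.predict_proba(tree, frame)
        np.testing.assert_allclose(scores, y)

    def test_all_missing_follows_majority_path(self):
        tree, frame, _ = self._grown()
        blank = pd.DataFrame({"age": [np.nan], "chemo": [np.nan]})
        expected = tree.root
        while not expected.is_leaf:
            # no surrogate can fire either; majority direction all the way
            idx = 0 if expected.majority_direction == "left" else 1
            expected = expected.children[idx]
        assert sg.predict_proba(tree, blank)[0] == expected.probability_response

    def test_complete_data_matches_path_following_oracle(self):
        rng = np.random.default_rng(8)
        frame = pd.DataFrame({"x1": rng.normal(size=300), "x2": rng.normal(size=300),
                              "g": rng.choice(["a", "b", "c"], 300)})
        y = ((frame.x1 + (frame.g == "a")) > 0.5).astype(int)
        tree = sg.grow_tree(frame, y, GrowthParams(min_split=10, min_bucket=3))

        def oracle(row):
            nd = tree.root
            while not nd.is_leaf:
                sp = nd.primary_split
                v = row[sp.variable]
                if sp.kind == "numeric":
                    left = (v <= sp.threshold) if sp.direction == "le" else (v > sp.threshold)
                else:
                    left = v in sp.subset
                nd = nd.children[0] if left else nd.children[1]
            return nd.probability_response

        scores = sg.predict_proba(tree, frame)
        expected = frame.apply(oracle, axis=1).to_numpy()
        np.testing.assert_allclose(scores, expected)

    def test_unknown_level_routes_by_majority_with_warning(self):
        frame = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5, "x": range(10)})
        y = [0] * 5 + [1] * 5
        tree = sg.grow_tree(frame, np.asarray(y), _params())
        new = pd.DataFrame({"g": ["zzz"], "x": [0]})
        with pytest.warns(UserWarning, match="zzz"):
            score = sg.predict_proba(tree, new)[0]
        assert 0.0 <= score <= 1.0


def test_render_and_json_round_trip_structure(tmp_path):
    frame = pd.DataFrame({"age": [30, 40, 60, 70.0], "chemo": [0, 1, 0, 1.0]})
    tree = sg.grow_tree(frame, [0, 0, 1, 1], _params())
    text = sg.render_text(tree)
    assert "age" in text and "p(response)" in text
    path = tmp_path / "tree.json"
    tree.to_json(path)
    import json
    payload = json.loads(path.read_text())
    assert payload["root"]["n_train"] == 4
    assert payload["root"]["primary_split"]["variable"] == "age"
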