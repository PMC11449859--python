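import numpy as np
import pytest

from pepxai import (
    AttributionTable,
    Condition,
    FeatureMeta,
    PredictionSet,
    SurrogateConfig,
    extract_rules,
    fit_surrogate,
    predict_surrogate,
    render_condition,
    render_rule,
    split_train_test,
)
from pepxai.errors import SchemaError
from pepxai.surrogate import Rule


def make_table(counts, kinds=None):
    counts = np.asarray(counts, dtype=int)
    kinds = kinds or ["increasing"] * counts.shape[1]
    meta = []
    seen = {}
    for kind in kinds:
        j = seen.get(kind, 0)
        meta.append(FeatureMeta(kind=kind, cluster=j, centroid=(10.0, 2.0, 0.5)))
        seen[kind] = j + 1
    return AttributionTable(
        counts=counts, feature_meta=meta, instance_ids=[f"i{r}" for r in range(len(counts))]
    )


class TestSplit:
    def test_ten_instances_balanced_classes(self):
        table = make_table(np.zeros((10, 2), dtype=int))
        preds = PredictionSet(labels=[0] * 5 + [1] * 5)
        train, test = split_train_test(table, preds, SurrogateConfig(seed=0))
        assert len(train) == 7 and len(test) == 3
        train_classes = {preds.labels[i] for i in train}
        assert train_classes == {0, 1}

    def test_half_split_of_four(self):
        table = make_table(np.zeros((4, 1), dtype=int))
        preds = PredictionSet(labels=[0, 0, 1, 1])
        train, test = split_train_test(
            table, preds, SurrogateConfig(train_fraction=0.5, seed=3)
        )
        assert len(train) == 2 and len(test) == 2

    def test_same_seed_same_partition(self):
        table = make_table(np.zeros((20, 1), dtype=int))
        preds = PredictionSet(labels=[0, 1] * 10)
        cfg = SurrogateConfig(seed=7)
        a = split_train_test(table, preds, cfg)
        b = split_train_test(table, preds, cfg)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_singleton_class_falls_back_with_warning(self):
        table = make_table(np.zeros((6, 1), dtype=int))
        preds = PredictionSet(labels=[0, 0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="unstratified"):
            train, test = split_train_test(table, preds, SurrogateConfig(seed=0))
        assert len(train) + len(test) == 6


class TestFitSurrogate:
    def test_constant_labels_give_depth_zero_tree(self):
        table = make_table([[0], [1], [2], [3]])
        tree = fit_surrogate(table.counts, ["A"] * 4, table.feature_meta, SurrogateConfig())
        assert tree.depth == 0 and tree.n_nodes == 1
        assert tree.predict(table) == ["A"] * 4

    def test_separable_count_rule_recovered_with_one_split(self):
        # black box: inc_c0 count >= 1 => class B; second column is noise
        rng = np.random.default_rng(0)
        inc = np.array([0, 0, 0, 0, 1, 1, 2, 1, 1, 2] * 3)
        noise = rng.integers(0, 5, size=inc.size)
        table = make_table(np.column_stack([inc, noise]))
        labels = ["B" if c >= 1 else "A" for c in inc]
        tree = fit_surrogate(
            table.counts, labels, table.feature_meta, SurrogateConfig(seed=0)
        )
        assert tree.depth == 1 and tree.n_nodes == 3
        rules = extract_rules(tree)
        (cond,) = rules.rules[0].conditions
        assert (cond.kind, cond.cluster) == ("increasing", 0)
        assert 0.0 < cond.threshold < 1.0
        assert tree.predict(table) == labels  # training agreement 1.0

    def test_huge_alpha_prunes_to_root(self):
        table = make_table([[0, 3], [1, 1], [2, 0], [3, 2]])
        labels = ["A", "B", "A", "B"]
        tree = fit_surrogate(
            table.counts, labels, table.feature_meta, SurrogateConfig(ccp_alpha=1e6)
        )
        assert tree.depth == 0

    def test_pruning_path_is_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 4, size=(60, 3))
        labels = [(r[0] + r[1] + rng.integers(0, 2)) % 2 for r in X]
        table = make_table(X)
        node_counts = []
        for alpha in [0.0, 0.01, 0.05, 0.1, 0.5]:
            tree = fit_surrogate(
                table.counts, labels, table.feature_meta, SurrogateConfig(ccp_alpha=alpha)
            )
            node_counts.append(tree.n_nodes)
        assert node_counts == sorted(node_counts, reverse=True)


class TestPredict:
    def test_depth_zero_tree_is_constant(self):
        table = make_table([[5], [0]])
        tree = fit_surrogate(table.counts, ["X", "X"], table.feature_meta, SurrogateConfig())
        assert predict_surrogate(tree, make_table([[9], [1], [0]])).labels == ["X"] * 3

    def test_one_split_tree_matches_manual_descent(self):
        train = make_table([[0], [0], [2], [2]])
        tree = fit_surrogate(
            train.counts, ["lo", "lo", "hi", "hi"], train.feature_meta, SurrogateConfig()
        )
        # single split at threshold in (0, 2); <= goes left to "lo"
        test = make_table([[0], [1], [2]])
        got = predict_surrogate(tree, test).labels
        thr = tree.estimator.tree_.threshold[0]
        want = ["lo" if c <= thr else "hi" for c in [0, 1, 2]]
        assert got == want

    def test_zero_impurity_tree_reproduces_training_labels(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(30, 2))
        labels = [f"{r[0]}-{r[1]}" for r in X]  # fully determined by features
        table = make_table(X)
        tree = fit_surrogate(
            table.counts, labels, table.feature_meta, SurrogateConfig(ccp_alpha=0.0)
        )
        assert tree.predict(table) == labels

    def test_missing_feature_column_raises(self):
        train = make_table([[0, 1], [2, 0]])
        tree = fit_surrogate(train.counts, ["a", "b"], train.feature_meta, SurrogateConfig())
        narrow = make_table([[1]], kinds=["local_max"])
        with pytest.raises(SchemaError):
            tree.predict(narrow)


class TestRules:
    def test_depth_zero_yields_single_unconditional_rule(self):
        table = make_table([[0], [1]])
        tree = fit_surrogate(table.counts, ["A", "A"], table.feature_meta, SurrogateConfig())
        rules = extract_rules(tree)
        assert len(rules.rules) == 1
        assert rules.rules[0].conditions == []
        assert rules.rules[0].predicted_class == "A"

    def test_one_split_yields_two_single_condition_rules(self):
        table = make_table([[0], [0], [3], [3]])
        tree = fit_surrogate(
            table.counts, ["A", "A", "B", "B"], table.feature_meta, SurrogateConfig()
        )
        rules = extract_rules(tree)
        assert [len(r.conditions) for r in rules.rules] == [1, 1]
        assert rules.rules[0].conditions[0].relation == "≤"
        assert rules.rules[1].conditions[0].relation == ">"

    def test_three_leaf_tree_paths_match_manual_enumeration(self):
        # labels: A iff c0<=0; else B iff c1<=0; else C
        counts = np.array([[0, 0], [0, 5], [2, 0], [2, 3], [3, 0], [3, 4]])
        labels = ["A", "A", "B", "C", "B", "C"]
        table = make_table(counts)
        tree = fit_surrogate(
            table.counts, labels, table.feature_meta, SurrogateConfig(ccp_alpha=0.0)
        )
        rules = extract_rules(tree)
        assert len(rules.rules) == 3
        assert sorted(len(r.conditions) for r in rules.rules) == [1, 2, 2]
        assert sorted(r.predicted_class for r in rules.rules) == ["A", "B", "C"]

    def test_rules_are_exhaustive_and_mutually_exclusive(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 4, size=(40, 3))
        labels = [int(r[0] > 1) + int(r[2] > 2) for r in X]
        table = make_table(X)
        tree = fit_surrogate(
            table.counts, labels, table.feature_meta, SurrogateConfig(ccp_alpha=0.0)
        )
        rules = extract_rules(tree)
        probe = make_table(rng.integers(0, 6, size=(50, 3)))
        names = probe.column_names
        for row in probe.counts:
            assert len(rules.matching_rules(dict(zip(names, row)))) == 1
        assert rules.predict(probe) == tree.predict(probe)


class TestRendering:
    def test_increasing_run_condition_narrative(self):
        cond = Condition("increasing", 0, (70.0, 1.0, 0.79), "≤", 12.5)
        assert (
            render_condition(cond)
            == "increases from time 70 to 71 with average value 0.79 ≤ 12.5"
        )

    def test_decreasing_run_condition_narrative_with_article(self):
        cond = Condition("decreasing", 1, (23.0, 6.0, -0.07), "≤", 3.5)
        assert (
            render_condition(cond, article=True)
            == "decreases from time 23 to 29 with an average value -0.07 ≤ 3.5"
        )

    def test_extremum_condition_narrative(self):
        cond = Condition("local_max", 2, (10.0, 1.5), ">", 0.5)
        assert render_condition(cond) == "local maximum at time 10 with value 1.50 > 0.5"

    def test_technical_style(self):
        cond = Condition("local_min", 3, (4.0, -2.0), "≤", 1.5)
        assert render_condition(cond, style="technical") == "count(local_min_c3) ≤ 1.5"

    def test_full_rule_rendering(self):
        rule = Rule(
            conditions=[
                Condition("increasing", 0, (70.0, 1.0, 0.79), ">", 12.5),
            ],
            predicted_class="Normal Heartbeat",
        )
        assert (
            render_rule(rule)
            == "increases from time 70 to 71 with average value 0.79 > 12.5 ⇒ Normal Heartbeat"
        )
        empty = Rule(conditions=[], predicted_class="A")
        assert render_rule(empty) == "always ⇒ A"
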