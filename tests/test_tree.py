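"""Gini CART construction, cross-validation consensus, and 2x2 metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wmlpatterns.features import FEATURE_NAMES
from wmlpatterns.tree import (
    ConsensusTree,
    UnstableConsensusError,
    _modal_value,
    assign_pattern,
    assign_patterns,
    best_split,
    build_tree,
    candidate_thresholds,
    classification_metrics,
    consensus_tree,
    gini_impurity,
    stratified_folds,
)

from .oracles import brute_force_best_split, brute_force_tree, random_feature_frame, trees_equal


class TestGiniImpurity:
    def test_pure_node_is_zero(self):
        assert gini_impurity((10, 0)) == 0.0

    def test_balanced_binary_node_is_half(self):
        assert gini_impurity((5, 5)) == 0.5

    def test_cohort_scale_event_split(self):
        # 315 non-events vs 111 events out of 426
        assert gini_impurity((315, 111)) == pytest.approx(
            1 - (111 / 426) ** 2 - (315 / 426) ** 2
        )
        assert gini_impurity((315, 111)) == pytest.approx(0.3853, abs=5e-5)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=5))
    def test_bounds(self, counts):
        if sum(counts) == 0:
            return
        g = gini_impurity(counts)
        assert 0.0 <= g < 1.0
        k = len(counts)
        assert g <= 1 - 1 / k + 1e-12


class TestCandidateThresholds:
    def test_midpoints_of_distinct_values(self):
        assert candidate_thresholds([1, 2, 3]) == [1.5, 2.5]

    def test_duplicates_collapse(self):
        assert candidate_thresholds([1, 1, 2]) == [1.5]

    def test_identical_values_yield_empty(self):
        assert candidate_thresholds([4.2, 4.2, 4.2]) == []

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            candidate_thresholds([1.0])

    def test_matches_dense_grid_search(self, rng):
        """The midpoint candidate set loses nothing against a dense grid."""
        v = rng.uniform(0, 10, size=20)
        y = (v + rng.normal(0, 2, size=20) > 5).astype(int)
        X = pd.DataFrame({name: v if name == "total_wml" else np.zeros(20) for name in FEATURE_NAMES})
        s = best_split(X, y)

        def weighted(thr):
            left = v < thr
            nl, nr = left.sum(), (~left).sum()
            if nl == 0 or nr == 0:
                return np.inf
            return (
                nl * gini_impurity(((y[left] == 0).sum(), y[left].sum()))
                + nr * gini_impurity(((y[~left] == 0).sum(), y[~left].sum()))
            ) / 20

        grid_best = min(weighted(t) for t in np.linspace(v.min(), v.max(), 10_000))
        assert s.impurity == pytest.approx(grid_best, abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=2, max_size=30))
    def test_thresholds_strictly_between_observations(self, values):
        u = sorted(set(values))
        for thr in candidate_thresholds(values):
            below = max(x for x in u if x < thr)
            above = min(x for x in u if x > thr)
            assert below < thr < above


class TestBestSplit:
    def test_perfect_separation_reaches_zero_impurity(self, rng):
        v = np.concatenate([rng.uniform(0, 1, 10), rng.uniform(2, 3, 10)])
        y = np.array([0] * 10 + [1] * 10)
        X = random_feature_frame(rng, 20)
        X["total_wml"] = v
        s = best_split(X, y)
        assert s.feature == "total_wml"
        assert 1 < s.threshold < 2
        assert s.impurity == pytest.approx(0.0, abs=1e-15)

    def test_single_class_node_has_no_split(self, rng):
        X = random_feature_frame(rng, 10)
        assert best_split(X, np.zeros(10, dtype=int)) is None

    def test_matches_brute_force_on_random_instances(self, rng):
        for trial in range(60):
            n = int(rng.integers(4, 26))
            tying = int(rng.integers(2, 8)) if trial % 2 else None
            X = random_feature_frame(rng, n, n_distinct=tying)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            min_child = int(rng.integers(1, 4))
            ours = best_split(X, y, min_child=min_child)
            ref = brute_force_best_split(X, y, min_child=min_child)
            if ref is None:
                assert ours is None
            else:
                assert ours is not None
                assert ours.feature == ref[1]
                assert ours.threshold == pytest.approx(ref[2], abs=0)
                assert ours.impurity == pytest.approx(ref[0], abs=0)

    def test_shuffled_labels_never_beat_separable_labels(self, rng):
        v = np.sort(rng.uniform(0, 10, 30))
        y = (v > 5).astype(int)
        X = random_feature_frame(rng, 30)
        X["total_wml"] = v
        base = best_split(X, y).impurity
        for _ in range(100):
            perm = rng.permutation(y)
            if perm.min() == perm.max():
                continue
            assert best_split(X, perm).impurity >= base - 1e-12

    def test_accepted_split_never_increases_impurity(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            X = random_feature_frame(rng, n)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = best_split(X, y)
            parent = gini_impurity(((y == 0).sum(), y.sum()))
            assert s.impurity <= parent + 1e-12


class TestBuildTree:
    def test_six_mixed_subjects_stay_one_leaf(self, rng):
        X = random_feature_frame(rng, 6)
        y = np.array([0, 1, 0, 1, 0, 1])
        t = build_tree(X, y, min_leaf=6)
        assert t.is_leaf and t.counts == (3, 3)

    def test_pure_input_is_single_leaf(self, rng):
        X = random_feature_frame(rng, 50)
        t = build_tree(X, np.ones(50, dtype=int), min_leaf=6)
        assert t.is_leaf

    def test_every_leaf_has_min_leaf_observations(self, rng):
        X = random_feature_frame(rng, 120)
        y = rng.integers(0, 2, 120)
        t = build_tree(X, y, min_leaf=6)

        def walk(node):
            if node.is_leaf:
                assert node.n >= 6
            else:
                walk(node.left)
                walk(node.right)

        walk(t)

    def test_recovers_planted_two_level_structure(self, rng):
        # events iff total >= 2.8 and temporal share >= 20: a depth-2 truth
        # whose root split (30% of subjects, 2/3 of them events) is strictly
        # better than the share split (67% of subjects, 30% events)
        n = 80
        X = random_feature_frame(rng, n)
        X["total_wml"] = rng.uniform(0, 4, n)
        X["temporal_wmlr"] = rng.uniform(0, 60, n)
        y = ((X.total_wml >= 2.8) & (X.temporal_wmlr >= 20)).astype(int).to_numpy()
        t = build_tree(X, y, min_leaf=6)
        assert t.feature == "total_wml"
        assert not t.right.is_leaf and t.right.feature == "temporal_wmlr"
        assert t.depth() == 2

    def test_matches_recursive_brute_force_oracle(self, rng):
        for trial in range(25):
            n = int(rng.integers(12, 26))
            tying = int(rng.integers(3, 9)) if trial % 2 else None
            X = random_feature_frame(rng, n, n_distinct=tying)
            y = rng.integers(0, 2, size=n)
            min_leaf = int(rng.integers(2, 7))
            if y.sum() in (0, n) or n < min_leaf:
                continue
            assert trees_equal(
                build_tree(X, y, min_leaf=min_leaf), brute_force_tree(X, y, min_leaf=min_leaf)
            )

    def test_subject_order_does_not_change_the_tree(self, rng):
        X = random_feature_frame(rng, 80)
        y = (X.total_wml + rng.normal(0, 2, 80) > 5).astype(int).to_numpy()
        t1 = build_tree(X, y, min_leaf=6)
        perm = rng.permutation(80)
        t2 = build_tree(X.iloc[perm].reset_index(drop=True), y[perm], min_leaf=6)
        assert trees_equal(t1, t2)

    def test_split_thresholds_fall_between_observed_values(self, rng):
        X = random_feature_frame(rng, 100, n_distinct=12)
        y = rng.integers(0, 2, 100)

        def walk(node, frame):
            if node.is_leaf:
                return
            v = frame[node.feature].to_numpy()
            assert v[v < node.threshold].size and v[v > node.threshold].size
            assert node.threshold not in set(v)
            mask = frame[node.feature] < node.threshold
            walk(node.left, frame[mask])
            walk(node.right, frame[~mask])

        walk(build_tree(X, y, min_leaf=6), X)

    def test_agrees_with_sklearn_root_split(self, rng):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        X = random_feature_frame(rng, 200)
        y = ((X.total_wml > 6) | (rng.random(200) < 0.15)).astype(int).to_numpy()
        ours = build_tree(X, y, min_leaf=6)
        clf = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=6, random_state=0
        ).fit(X.to_numpy(), y)
        assert ours.feature == list(X.columns)[clf.tree_.feature[0]]
        # sklearn casts features to float32 internally, so thresholds agree
        # only to single precision
        assert ours.threshold == pytest.approx(clf.tree_.threshold[0], rel=1e-6)


class TestStratifiedFolds:
    def test_partition_and_stratification(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_folds(y, 10, seed=3)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(100))
        for f in folds:
            assert y[f].sum() == 2  # 20 events spread evenly over 10 folds

    def test_seed_determinism(self):
        y = np.arange(100) % 2
        a = stratified_folds(y, 10, seed=5)
        b = stratified_folds(y, 10, seed=5)
        assert all((x == z).all() for x, z in zip(a, b))


class TestModalValue:
    def test_repeated_value_wins(self):
        assert _modal_value([1.6, 1.6001, 1.6002, 2.5]) == pytest.approx(1.6, abs=1e-3)

    def test_all_distinct_falls_back_to_median(self):
        assert _modal_value([1.0, 2.0, 9.0]) == 2.0


class TestConsensus:
    def test_homogeneous_folds_reproduce_the_common_tree(self, rng):
        # a huge planted margin: every fold tree splits identically
        n = 200
        X = random_feature_frame(rng, n)
        X["total_wml"] = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(3, 4, 100)])
        y = (X.total_wml > 2).astype(int).to_numpy()
        c = consensus_tree(X, y, k=10, min_leaf=6, seed=0)
        assert c.root_feature == "total_wml"
        assert c.root_votes == {"total_wml": 10}
        assert 1 < c.root_threshold < 3

    def test_unstable_when_labels_are_noise(self, rng):
        X = random_feature_frame(rng, 120)
        found_unstable = False
        for seed in range(8):
            y = np.random.default_rng(seed).integers(0, 2, 120)
            c = consensus_tree(X, y, k=10, min_leaf=6, seed=seed)
            if not c.stable:
                found_unstable = True
                with pytest.raises(UnstableConsensusError):
                    assign_patterns(X, c)
                break
        assert found_unstable

    def test_requires_enough_subjects(self, rng):
        X = random_feature_frame(rng, 30)
        with pytest.raises(ValueError, match="min_leaf"):
            consensus_tree(X, np.arange(30) % 2, k=10, min_leaf=6, seed=0)

    def test_serialization_round_trip(self, rng, tmp_path):
        n = 200
        X = random_feature_frame(rng, n)
        X["total_wml"] = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(3, 4, 100)])
        X["temporal_wmlr"] = rng.uniform(0, 5, n)
        y = ((X.total_wml > 2) & (X.temporal_wmlr > 2.5)).astype(int).to_numpy()
        c = consensus_tree(X, y, k=10, min_leaf=6, seed=1)
        c.save(tmp_path / "c.json")
        back = ConsensusTree.load(tmp_path / "c.json")
        assert back.root_feature == c.root_feature
        assert back.root_threshold == c.root_threshold
        assert back.second_feature == c.second_feature
        assert back.second_threshold == c.second_threshold
        assert len(back.fold_trees) == 10
        assert trees_equal(back.fold_trees[0], c.fold_trees[0])


class TestAssignPattern:
    consensus = ConsensusTree(
        k=10,
        root_feature="total_wml",
        root_threshold=1.587,
        second_feature="temporal_wmlr",
        second_threshold=0.65,
    )

    @pytest.mark.parametrize(
        "total,tshare,expected",
        [
            (0.45, 2.0, 1),  # low lesion load
            (5.4, 0.3, 2),  # high load, spared temporal region
            (5.9, 1.5, 3),  # high load with temporal involvement
            (1.587, 0.65, 3),  # >= goes right at both boundaries
            (1.587, 0.6499, 2),
            (1.5869, 99.0, 1),
        ],
    )
    def test_routing(self, total, tshare, expected):
        f = {"total_wml": total, "temporal_wmlr": tshare}
        assert assign_pattern(f, self.consensus) == expected

    def test_vectorized_matches_scalar(self, rng):
        X = random_feature_frame(rng, 50)
        X["total_wml"] = rng.uniform(0, 4, 50)
        X["temporal_wmlr"] = rng.uniform(0, 2, 50)
        vec = assign_patterns(X, self.consensus)
        for i in range(50):
            assert vec.iloc[i] == assign_pattern(X.iloc[i].to_dict(), self.consensus)

    def test_unstable_consensus_raises(self):
        c = ConsensusTree(k=10, root_feature=None, root_threshold=None,
                          second_feature=None, second_threshold=None)
        with pytest.raises(UnstableConsensusError):
            assign_pattern({"total_wml": 1.0}, c)


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 0, 1, 1])
        m = classification_metrics(y.astype(bool), y)
        assert (m["sensitivity"], m["specificity"], m["ppv"], m["npv"]) == (100, 100, 100, 100)

    def test_reconstructed_cohort_table(self):
        # 2x2 consistent with the published margins (111 events / 315 others)
        # and rounded sensitivity 29% / specificity 88%
        pred = np.array([1] * 32 + [0] * 79 + [1] * 38 + [0] * 277, dtype=bool)
        truth = np.array([1] * 111 + [0] * 315)
        m = classification_metrics(pred, truth)
        assert (m["tp"], m["fn"], m["fp"], m["tn"]) == (32, 79, 38, 277)
        assert m["sensitivity"] == pytest.approx(28.8, abs=0.05)
        assert m["specificity"] == pytest.approx(87.9, abs=0.05)
        assert m["ppv"] == pytest.approx(45.7, abs=0.05)
        assert m["npv"] == pytest.approx(77.8, abs=0.05)

    def test_predicting_nobody_at_risk(self):
        truth = np.array([1] * 10 + [0] * 90)
        m = classification_metrics(np.zeros(100, dtype=bool), truth)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 100.0
        assert m["ppv"] is None  # zero predicted positives: undefined, not 0
        assert m["npv"] == pytest.approx(90.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(np.zeros(5, dtype=bool), np.ones(5, dtype=int))
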