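"""Hoeffding-tree learning, splitting, routing, and pointer bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalcds.errors import SchemaError, ValidationError
from vitalcds.vfdt import (
    HoeffdingTreeClassifier,
    LeafNode,
    VFDTConfig,
    best_splits,
    hoeffding_bound,
)

from oracles import batch_info_gain_argmax, batch_best_threshold, walk_tree


class TestHoeffdingBound:
    def test_delta_one_gives_zero(self):
        assert hoeffding_bound(1.0, 1.0, 10) == 0.0

    @pytest.mark.parametrize("R", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("delta", [1e-7, 1e-3, 0.05])
    @pytest.mark.parametrize("n", [1, 10, 1000, 10**6])
    def test_closed_form_grid(self, R, delta, n):
        expected = math.sqrt(R * R * math.log(1.0 / delta) / (2.0 * n))
        assert hoeffding_bound(R, delta, n) == pytest.approx(expected, abs=1e-12)

    def test_high_precision_spot_value(self):
        # sqrt(ln 20 / 2000), evaluated independently
        assert hoeffding_bound(1.0, 0.05, 1000) == pytest.approx(
            math.sqrt(math.log(20.0) / 2000.0), abs=1e-15
        )

    def test_monotone_decreasing_in_n_and_delta(self):
        assert hoeffding_bound(1.0, 0.05, 100) > hoeffding_bound(1.0, 0.05, 10000)
        assert hoeffding_bound(1.0, 0.01, 500) > hoeffding_bound(1.0, 0.2, 500)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            hoeffding_bound(1.0, 0.05, 0)
        with pytest.raises(ValidationError):
            hoeffding_bound(1.0, 0.0, 5)
        with pytest.raises(ValidationError):
            hoeffding_bound(-1.0, 0.05, 5)


def _filled_leaf(X, y, n_attrs):
    leaf = LeafNode("C1", n_attrs)
    for row, lab in zip(X, y):
        leaf.observe(row, lab)
    return leaf


class TestBestSplits:
    def test_single_class_leaf_yields_no_split(self):
        leaf = _filled_leaf([[1.0, 2.0]] * 5, ["a"] * 5, 2)
        first, second = best_splits(leaf)
        assert first.gain == 0.0 and first.attribute == -1

    def test_perfectly_separated_attribute_wins_with_prior_entropy_gain(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 3)) * 0.1
        y = ["a"] * 200 + ["b"] * 200
        X[200:, 1] += 10.0  # attribute 1 separates the classes completely
        leaf = _filled_leaf(X, y, 3)
        first, _ = best_splits(leaf)
        assert first.attribute == 1
        # balanced binary prior -> entropy 1 bit, achieved by a clean cut
        assert first.gain == pytest.approx(1.0, abs=1e-3)
        g_oracle, _ = batch_best_threshold(X, np.asarray(y, dtype=object), 1)
        assert g_oracle == pytest.approx(1.0, abs=1e-12)
        # any threshold inside the margin separates cleanly; require that
        assert X[:200, 1].max() < first.threshold < X[200:, 1].min()

    def test_identical_attributes_tie(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=600)
        X = np.stack([vals, vals], axis=1)  # both attributes identical
        y = np.where(rng.random(600) < 0.5, "a", "b")  # labels independent
        leaf = _filled_leaf(X, y, 2)
        first, second = best_splits(leaf)
        assert abs(first.gain - second.gain) < 0.02

    def test_gains_bounded_by_prior_entropy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4))
        y = rng.choice(["a", "b", "c"], size=300)
        leaf = _filled_leaf(X, y, 4)
        prior = -sum(
            (c / 300) * math.log2(c / 300)
            for c in [np.sum(y == k) for k in "abc"]
        )
        first, second = best_splits(leaf)
        assert 0.0 <= second.gain <= first.gain <= prior + 1e-9


class TestLearnAndClassify:
    def test_first_example_makes_single_leaf_model(self):
        tree = HoeffdingTreeClassifier()
        leaf_id = tree.learn_one([1.0, 2.0], "flu")
        assert leaf_id == "C1"
        assert tree.n_leaves == 1
        lid, label, post = tree.classify_one([9.0, 9.0])
        assert (lid, label) == ("C1", "flu")
        assert post["flu"] == pytest.approx(1.0)

    def test_adder_attaches_pointer_to_result_leaf(self):
        tree = HoeffdingTreeClassifier()
        leaf_id = tree.learn_one([1.0, 2.0], "flu", pointer=1)
        assert tree.find_leaf(leaf_id).pointer_list == [1]

    def test_dimension_mismatch_raises(self):
        tree = HoeffdingTreeClassifier()
        tree.learn_one([1.0, 2.0], "flu")
        with pytest.raises(SchemaError):
            tree.learn_one([1.0], "flu")
        with pytest.raises(SchemaError):
            tree.classify_one([1.0, 2.0, 3.0])

    def test_new_class_registered_on_the_fly(self):
        tree = HoeffdingTreeClassifier()
        tree.learn_one([0.0], "a")
        tree.learn_one([1.0], "b")
        assert tree.classes_ == ["a", "b"]

    def test_root_split_matches_batch_gain_oracle(self, two_gaussian_stream):
        """On a separable stationary stream the first split lands on the
        attribute a batch info-gain scan of the same data picks."""
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier()
        tree.partial_fit(X, y)
        assert tree.n_leaves >= 2
        root = tree.root_
        oracle_attr, _ = batch_info_gain_argmax(X, y)
        assert root.attribute == oracle_attr == 1

    def test_root_split_matches_sklearn_stump(self, two_gaussian_stream):
        sklearn = pytest.importorskip("sklearn.tree")
        X, y = two_gaussian_stream
        stump = sklearn.DecisionTreeClassifier(
            max_depth=1, criterion="entropy", random_state=0
        ).fit(X, y.astype(str))
        tree = HoeffdingTreeClassifier()
        tree.partial_fit(X, y)
        assert tree.root_.attribute == stump.tree_.feature[0]

    def test_classify_agrees_with_naive_traversal_oracle(self, two_gaussian_stream):
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier()
        tree.partial_fit(X[:3000], y[:3000])
        for row in X[3000:3100]:
            leaf = walk_tree(tree.root_, row)
            lid, label, _ = tree.classify_one(row)
            assert lid == leaf.leaf_id
            assert label == leaf.majority_class()

    def test_anytime_property(self, two_gaussian_stream):
        """The model answers queries validly after any training prefix."""
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier()
        probe = X[-5:]
        for i in range(200):
            tree.learn_one(X[i], y[i])
            lid, label, post = tree.classify_one(probe[i % 5])
            assert label in tree.classes_
            assert post and abs(sum(post.values()) - 1.0) < 1e-9


class TestSplitDynamics:
    def test_split_soundness_on_instrumented_trace(self, two_gaussian_stream):
        """Every split happens only at an attempt point satisfying
        G1 - G2 > eps or eps < tau."""
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier()
        events = []
        original = tree._split_leaf

        def spy(leaf, cand):
            first, second = best_splits(leaf)
            n_classes = max(2, len(tree._class_set))
            eps = hoeffding_bound(math.log2(n_classes), tree.delta, leaf.total)
            events.append((first.gain, second.gain, eps))
            return original(leaf, cand)

        tree._split_leaf = spy
        tree.partial_fit(X, y)
        assert events, "expected at least one split on separable data"
        for g1, g2, eps in events:
            assert g1 - g2 > eps or eps < tree.tau

    def test_pointer_conservation_through_splits(self):
        """Union of leaf pointer lists == pointers ever trained; no leaf
        holds a pointer twice; each pointer is in exactly one leaf."""
        rng = np.random.default_rng(3)
        tree = HoeffdingTreeClassifier(tau=0.5, grace_period=50)
        means = {"a": (0.0, 0.0), "b": (6.0, 0.0), "c": (0.0, 6.0)}
        for p in range(1, 601):
            lab = ("a", "b", "c")[rng.integers(3)]
            x = np.asarray(means[lab]) + rng.standard_normal(2)
            tree.learn_one(x, lab, pointer=p)
        assert tree.n_leaves >= 3
        ptrs = tree.all_pointers()
        assert len(ptrs) == 600
        assert set(ptrs) == set(range(1, 601))

    def test_pointers_rerouted_to_children_by_stored_features(self):
        rng = np.random.default_rng(4)
        tree = HoeffdingTreeClassifier(tau=0.5, grace_period=100)
        xs, labs = [], []
        for p in range(1, 401):
            lab = "a" if p % 2 else "b"
            x = [rng.normal(0.0 if lab == "a" else 8.0), rng.normal()]
            tree.learn_one(x, lab, pointer=p)
            xs.append(x)
            labs.append(lab)
        assert tree.n_leaves >= 2
        for leaf in tree.iter_leaves():
            for ptr in leaf.pointer_list:
                # the pointer's stored features route exactly to this leaf
                assert walk_tree(tree.root_, leaf.pointer_features[ptr]) is leaf

    def test_max_depth_bounds_growth(self, two_gaussian_stream):
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier(max_depth=0)
        tree.partial_fit(X, y)
        assert tree.n_leaves == 1


class TestSerialization:
    def test_roundtrip_preserves_classifications_and_pointers(self, two_gaussian_stream):
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier()
        tree.partial_fit(X[:4000], y[:4000],
                         pointers=list(range(1, 4001)))
        clone = HoeffdingTreeClassifier.from_json(tree.to_json())
        probe = X[4000:4200]
        assert list(tree.predict(probe)) == list(clone.predict(probe))
        assert tree.all_pointers() == clone.all_pointers()
        assert [l.leaf_id for l in tree.iter_leaves()] == [
            l.leaf_id for l in clone.iter_leaves()
        ]

    def test_unfitted_roundtrip_keeps_params(self):
        tree = HoeffdingTreeClassifier(delta=1e-3, tau=0.1, grace_period=50)
        clone = HoeffdingTreeClassifier.from_json(tree.to_json())
        assert clone.get_params() == tree.get_params()


class TestSklearnSurface:
    def test_get_set_params_roundtrip(self):
        tree = HoeffdingTreeClassifier()
        params = tree.get_params()
        tree.set_params(**{**params, "tau": 0.25})
        assert tree.get_params()["tau"] == 0.25

    def test_predict_proba_rows_sum_to_one(self, two_gaussian_stream):
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier().fit(X[:1000], y[:1000])
        proba = tree.predict_proba(X[1000:1050])
        assert proba.shape == (50, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_score_high_on_separable_data(self, two_gaussian_stream):
        X, y = two_gaussian_stream
        tree = HoeffdingTreeClassifier().fit(X, y)
        assert tree.score(X[-500:], y[-500:]) > 0.9


@given(
    labels=st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=80),
    seed=st.integers(0, 2**20),
)
@settings(max_examples=40, deadline=None)
def test_class_counts_always_sum_to_samples_seen(labels, seed):
    rng = np.random.default_rng(seed)
    tree = HoeffdingTreeClassifier(grace_period=10, tau=0.5)
    for i, lab in enumerate(labels):
        tree.learn_one(rng.normal(size=3), lab, pointer=i + 1)
    total = sum(sum(l.class_counts.values()) for l in tree.iter_leaves())
    # splits reset child statistics, so totals never exceed the stream length
    assert total <= len(labels)
    assert set(tree.all_pointers()) == set(range(1, len(labels) + 1))
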