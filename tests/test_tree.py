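import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermfish.tree import TreeNode, best_split, fit_tree, gini_impurity, predict


def brute_force_best_split(values, labels, min_leaf=1):
    """Exhaustive oracle: try every midpoint threshold explicitly.

    Single-class input is a no-split signal by contract.
    """
    values = np.asarray(values, float)
    if len(set(labels)) < 2:
        return None
    order = np.argsort(values, kind="stable")
    v = values[order]
    labs = np.asarray(labels)[order]
    best = None
    for i in range(len(v) - 1):
        if v[i] == v[i + 1]:
            continue
        if i + 1 < min_leaf or len(v) - i - 1 < min_leaf:
            continue
        thr = (v[i] + v[i + 1]) / 2
        left, right = labs[: i + 1], labs[i + 1 :]
        gl = gini_impurity((left == "low").sum(), (left == "high").sum())
        gr = gini_impurity((right == "low").sum(), (right == "high").sum())
        wg = (len(left) * gl + len(right) * gr) / len(v)
        if best is None or wg < best[1] - 1e-12:
            best = (thr, wg)
    return best


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "n_low,n_high,expected",
        [(0, 10, 0.0), (5, 5, 0.5), (150, 100, 0.48)],
    )
    def test_values(self, n_low, n_high, expected):
        assert gini_impurity(n_low, n_high) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity(0, 0)


class TestBestSplit:
    def test_perfect_separation(self):
        thr, wg = best_split(
            [1, 2, 3, 10, 11, 12], ["low"] * 3 + ["high"] * 3
        )
        assert thr == pytest.approx(6.5)
        assert wg == pytest.approx(0.0)

    def test_all_equal_values_no_split(self):
        assert best_split([2, 2, 2, 2], ["low", "low", "high", "high"]) is None

    def test_single_class_no_split(self):
        assert best_split([1, 2, 3], ["low", "low", "low"]) is None

    def test_matches_brute_force_on_1000_random_instances(self):
        """Vectorized split search == exhaustive search, n <= 50."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(2, 51)
            values = np.round(rng.uniform(0, 1, n), rng.integers(1, 4))
            labels = np.where(rng.uniform(size=n) < 0.5, "low", "high")
            expected = brute_force_best_split(values, labels)
            got = best_split(values, labels)
            if expected is None:
                assert got is None
            else:
                assert got[0] == pytest.approx(expected[0])
                assert got[1] == pytest.approx(expected[1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_split_never_increases_impurity(self, data):
        n = data.draw(st.integers(2, 30))
        values = data.draw(
            st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.sampled_from(["low", "high"]), min_size=n, max_size=n)
        )
        parent = gini_impurity(labels.count("low"), labels.count("high"))
        res = best_split(values, labels)
        if res is not None:
            assert res[1] <= parent + 1e-12


class TestFitTree:
    def test_single_class_gives_leaf(self):
        X = pd.DataFrame({"itd": [0.1, 0.2, 0.3], "cta": [0.2, 0.3, 0.4]})
        tree = fit_tree(X, ["high"] * 3, min_leaf=1)
        assert tree.is_leaf and tree.prediction == "high"
        assert tree.gini == 0.0

    def test_children_counts_sum_to_parent(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"itd": rng.uniform(0, 1, 60), "cta": rng.uniform(0, 1, 60)})
        labels = np.where(X["cta"] + rng.normal(0, 0.1, 60) > 0.5, "low", "high")
        tree = fit_tree(X, labels)

        def check(node):
            if node.is_leaf:
                return
            assert node.left.n_low + node.right.n_low == node.n_low
            assert node.left.n_high + node.right.n_high == node.n_high
            check(node.left)
            check(node.right)

        check(tree)

    def test_predict_routes_to_majority_leaf(self):
        X = pd.DataFrame(
            {"itd": [0.1, 0.2, 0.8, 0.9], "cta": [0.1, 0.15, 0.6, 0.7]}
        )
        tree = fit_tree(X, ["high", "high", "low", "low"], min_leaf=1)
        assert predict(tree, {"itd": 0.1, "cta": 0.1}) == "high"
        assert predict(tree, {"itd": 0.9, "cta": 0.9}) == "low"

    def test_max_depth_respected(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"itd": rng.uniform(0, 1, 100), "cta": rng.uniform(0, 1, 100)})
        labels = np.where(rng.uniform(size=100) < 0.5, "low", "high")
        tree = fit_tree(X, labels, max_depth=2, min_leaf=1)

        def depth(node):
            if node.is_leaf:
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        assert depth(tree) <= 2

    def test_json_round_trip_structure(self):
        X = pd.DataFrame({"itd": [0.1, 0.9], "cta": [0.1, 0.9]})
        tree = fit_tree(X, ["high", "low"], min_leaf=1)
        d = tree.to_dict()
        assert d["n_low"] == 1 and d["n_high"] == 1

    def test_root_matches_sklearn_cart(self):
        """Cross-check root (feature, threshold) against sklearn's CART."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(77)
        n = 120
        X = pd.DataFrame(
            {
                "itd": np.r_[rng.beta(2.7, 4.2, n // 2), rng.beta(2.4, 6.1, n // 2)],
                "cta": np.r_[rng.beta(8.7, 15.9, n // 2), rng.beta(9.8, 38.2, n // 2)],
            }
        )
        labels = np.array(["low"] * (n // 2) + ["high"] * (n // 2))
        ours = fit_tree(X, labels, max_depth=2, min_leaf=5)
        ref = sklearn_tree.DecisionTreeClassifier(
            criterion="gini", max_depth=2, min_samples_leaf=5, random_state=0
        ).fit(X.to_numpy(), labels)
        assert ours.feature == X.columns[ref.tree_.feature[0]]
        assert ours.threshold == pytest.approx(ref.tree_.threshold[0], abs=1e-6)
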