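"""Binary CART-style decision tree on (ITD, CTA) with Gini-impurity splits.

Written from scratch so every step of the classifier that separates low-
from high-score sperm is inspectable: node impurity is
``1 - p_low**2 - p_high**2``, candidate thresholds are midpoints between
consecutive distinct sorted feature values, and the greedy split minimizes
the size-weighted mean child impurity.  Ties are broken toward the
smallest threshold and, across features, toward the first feature in
column order.  Leaves predict the majority class (tie -> low).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOW = "low"
HIGH = "high"


def gini_impurity(n_low: int, n_high: int) -> float:
    """Gini impurity of a node: 1 minus the sum of squared class
    probabilities.  0 for a pure node, 0.5 at a 50/50 mix."""
    total = n_low + n_high
    if total < 1:
        raise ValueError("node must contain at least one sample")
    p_low = n_low / total
    p_high = n_high / total
    return 1.0 - p_low**2 - p_high**2


def best_split(values, labels, min_leaf: int = 1):
    """Exhaustively optimal single-feature split.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; each side must keep ``min_leaf`` samples.  Returns
    ``(threshold, weighted_gini)`` minimizing the size-weighted child
    impurity (ties -> smallest threshold), or ``None`` when no valid split
    exists (single class, all values equal, or too few samples).
    """
    values = np.asarray(values, dtype=float)
    is_low = np.asarray([lab == LOW for lab in labels])
    n = values.size
    if n < 2 or is_low.all() or (~is_low).all():
        return None

    order = np.argsort(values, kind="stable")
    v = values[order]
    low = is_low[order].astype(int)

    cum_low = np.cumsum(low)
    total_low = cum_low[-1]
    total_high = n - total_low

    # split after position i (left = v[:i+1]); valid where value changes
    i = np.arange(n - 1)
    valid = v[i] < v[i + 1]
    valid &= (i + 1 >= min_leaf) & (n - i - 1 >= min_leaf)
    if not valid.any():
        return None
    i = i[valid]

    n_left = i + 1
    n_right = n - n_left
    low_left = cum_low[i]
    high_left = n_left - low_left
    low_right = total_low - low_left
    high_right = total_high - high_left

    gini_left = 1 - (low_left / n_left) ** 2 - (high_left / n_left) ** 2
    gini_right = 1 - (low_right / n_right) ** 2 - (high_right / n_right) ** 2
    weighted = (n_left * gini_left + n_right * gini_right) / n

    # smallest threshold among numerically tied optima (1e-12 tolerance)
    best = np.flatnonzero(weighted <= weighted.min() + 1e-12)[0]
    thr = (v[i[best]] + v[i[best] + 1]) / 2
    return float(thr), float(weighted[best])


@dataclass
class TreeNode:
    n_low: int
    n_high: int
    gini: float
    feature: str | None = None       # None for leaves
    threshold: float | None = None
    left: "TreeNode | None" = None   # samples with feature <= threshold
    right: "TreeNode | None" = None
    prediction: str | None = None    # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"n_low": self.n_low, "n_high": self.n_high, "gini": self.gini}
        if self.is_leaf:
            d["prediction"] = self.prediction
        else:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def format_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        head = f"{pad}[n_low={self.n_low} n_high={self.n_high} gini={self.gini:.3f}]"
        if self.is_leaf:
            return f"{head} -> {self.prediction}\n"
        out = f"{head} split on {self.feature} <= {self.threshold:.4f}\n"
        return out + self.left.format_text(indent + 1) + self.right.format_text(indent + 1)


def _majority(n_low: int, n_high: int) -> str:
    return LOW if n_low >= n_high else HIGH   # tie -> low


def fit_tree(
    features: pd.DataFrame,
    labels,
    max_depth: int = 2,
    min_leaf: int = 5,
) -> TreeNode:
    """Greedy recursive partitioning with Gini impurity.

    ``features`` is a numeric table (expected columns: itd, cta); growth
    stops at ``max_depth``, node purity, ``min_leaf``, or when no split
    strictly decreases the weighted impurity.  No pruning.
    """
    labels = np.asarray([str(lab) for lab in labels])
    if len(features) != len(labels) or len(labels) == 0:
        raise ValueError("features and labels must be non-empty and aligned")
    bad = set(labels) - {LOW, HIGH}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        labs = labels[idx]
        n_low = int((labs == LOW).sum())
        n_high = len(labs) - n_low
        node = TreeNode(n_low=n_low, n_high=n_high, gini=gini_impurity(n_low, n_high))
        if depth >= max_depth or node.gini == 0.0 or len(idx) < 2 * min_leaf:
            node.prediction = _majority(n_low, n_high)
            return node

        choice = None
        for feat in features.columns:
            split = best_split(features[feat].to_numpy()[idx], labs, min_leaf=min_leaf)
            if split is None:
                continue
            thr, wg = split
            if choice is None or wg < choice[2] - 1e-15:
                choice = (feat, thr, wg)
        if choice is None or choice[2] >= node.gini - 1e-12:
            node.prediction = _majority(n_low, n_high)
            return node

        feat, thr, _ = choice
        go_left = features[feat].to_numpy()[idx] <= thr
        node.feature = feat
        node.threshold = thr
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return build(np.arange(len(labels)), 0)


def predict(tree: TreeNode, row) -> str:
    """Route one observation (mapping feature -> value) to its leaf class."""
    node = tree
    while not node.is_leaf:
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.prediction
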