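"""Independent brute-force reference implementations used only by tests.

Deliberately written in the most naive style possible (python loops over
every feature and every candidate cut) so they share no code path with the
package's vectorized tree construction.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from wmlpatterns.tree import MIN_GAIN, TreeNode, gini_impurity


def brute_force_best_split(X: pd.DataFrame, y, min_child: int = 1):
    """Scan every (feature, midpoint-between-distinct-values) pair and return
    the minimizer of the weighted child Gini impurity, with the same
    deterministic tie rules (column order, then smaller threshold)."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2 or y.min() == y.max():
        return None
    best = None  # (impurity, feature, threshold, n_left, n_right)
    for feature in X.columns:
        v = X[feature].to_numpy(dtype=float)
        distinct = sorted(set(v))
        for a, b in zip(distinct, distinct[1:]):
            thr = (a + b) / 2.0
            if not (a < thr < b):
                continue
            left = v < thr
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_child or nr < min_child:
                continue
            el = int(y[left].sum())
            er = int(y[~left].sum())
            gl = 1.0 - ((nl - el) / nl) ** 2 - (el / nl) ** 2
            gr = 1.0 - ((nr - er) / nr) ** 2 - (er / nr) ** 2
            w = (nl * gl + nr * gr) / n
            if best is None or w < best[0]:
                best = (w, feature, thr, nl, nr)
    return best


def brute_force_tree(X: pd.DataFrame, y, min_leaf: int = 6) -> TreeNode:
    """Recursive CART oracle mirroring the documented stopping rules."""
    y = np.asarray(y, dtype=int)
    counts = (int((y == 0).sum()), int((y == 1).sum()))
    node = TreeNode(counts=counts)
    if counts[0] == 0 or counts[1] == 0 or len(y) < 2 * min_leaf:
        return node
    s = brute_force_best_split(X, y, min_child=min_leaf)
    if s is None:
        return node
    w, feature, thr, _, _ = s
    if not w < gini_impurity(counts) - MIN_GAIN:
        return node
    mask = X[feature].to_numpy(dtype=float) < thr
    node.feature = feature
    node.threshold = thr
    node.left = brute_force_tree(X[mask], y[mask], min_leaf)
    node.right = brute_force_tree(X[~mask], y[~mask], min_leaf)
    return node


def trees_equal(a: TreeNode, b: TreeNode, tol: float = 1e-12) -> bool:
    if a.counts != b.counts:
        return False
    if a.is_leaf != b.is_leaf:
        return False
    if a.is_leaf:
        return True
    if a.feature != b.feature or abs(a.threshold - b.threshold) > tol:
        return False
    return trees_equal(a.left, b.left, tol) and trees_equal(a.right, b.right, tol)


def brute_force_risk_set(records, t: float) -> set[str]:
    """Subjects at risk at event age t: entry < t <= exit."""
    return {r.subject_id for r in records if r.entry_age < t <= r.exit_age}


def random_feature_frame(rng, n: int, n_distinct: Optional[int] = None) -> pd.DataFrame:
    """Random descriptor tables, with optional heavy value-tying to exercise
    the distinct-value handling of the split search."""
    from wmlpatterns.features import FEATURE_NAMES

    cols = {}
    for name in FEATURE_NAMES:
        if n_distinct:
            pool = rng.uniform(0, 10, size=n_distinct)
            cols[name] = rng.choice(pool, size=n)
        else:
            cols[name] = rng.uniform(0, 10, size=n)
    return pd.DataFrame(cols)
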