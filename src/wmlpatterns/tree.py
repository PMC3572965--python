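"""Exhaustive Gini decision trees and the cross-validation consensus procedure.

This is the discovery engine of the package.  A binary CART is grown over the
five lesion descriptors (total WML volume and the four relative regional
volumes) against the outcome "developed MCI/dementia during follow-up":

* at every node, **all** descriptors are tested with **all** candidate
  thresholds — the midpoints between successive distinct observed values —
  and the pair minimizing the weighted Gini impurity of the children is kept;
* growth stops when a node is pure, when no admissible split leaves at least
  ``min_leaf`` observations in each child (default 6), or when no split
  strictly reduces impurity.

A single tree on a few hundred subjects is unstable, so the retained model is
a *consensus*: k trees are grown by k-fold cross-validation (each on k-1
folds, folds stratified by outcome), and at the root — and again at the
second level inside the root's ">=" branch — the descriptor used by a strict
majority of the fold trees is retained, with its threshold set to the modal
value across those trees.  The consensus is truncated at depth 2, which
yields three lesion patterns:

* pattern 1 — total WML volume below the root threshold (low lesion load);
* pattern 2 — high load, relative temporal volume below the second threshold;
* pattern 3 — high load with temporal WMLr at or above it (the at-risk group).

The ">=" convention applies at both boundaries: a value equal to a threshold
goes right.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, WmlFeatures

__all__ = [
    "ConsensusTree",
    "Split",
    "TreeNode",
    "UnstableConsensusError",
    "assign_pattern",
    "assign_patterns",
    "best_split",
    "build_tree",
    "candidate_thresholds",
    "classification_metrics",
    "consensus_tree",
    "gini_impurity",
    "stratified_folds",
]

#: Minimum strict impurity improvement for a split to be accepted.
MIN_GAIN = 1e-12

#: Decimals kept when pooling fold thresholds into a mode.
MODE_DECIMALS = 3


class UnstableConsensusError(RuntimeError):
    """No strict-majority descriptor emerged from the fold trees."""


# ---------------------------------------------------------------------------
# Impurity and candidate thresholds
# ---------------------------------------------------------------------------


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_i^2) of a node's class frequency distribution.

    0 for a pure node; 0.5 for a balanced binary node.  Raises on all-zero
    counts (an empty node has no defined impurity).
    """
    counts = [float(c) for c in class_counts]
    if any(c < 0 for c in counts):
        raise ValueError(f"negative class count in {class_counts!r}")
    n = sum(counts)
    if n == 0:
        raise ValueError("gini_impurity undefined for all-zero class counts")
    imp = 1.0
    for c in counts:
        imp -= (c / n) ** 2
    return imp


def candidate_thresholds(values: Sequence[float]) -> list[float]:
    """All admissible cut points for one feature: midpoints between successive
    distinct sorted values.

    Midpoints that do not fall strictly between their two neighbours (possible
    for adjacent floats) are dropped, so every returned threshold separates at
    least one observation from another.  All-identical values yield an empty
    list.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("candidate_thresholds requires at least 2 values")
    u = np.unique(arr)
    mid = (u[:-1] + u[1:]) / 2.0
    ok = (mid > u[:-1]) & (mid < u[1:])
    return [float(m) for m in mid[ok]]


# ---------------------------------------------------------------------------
# Single-tree construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Split:
    feature: str
    threshold: float
    impurity: float  # weighted child impurity
    n_left: int
    n_right: int


@dataclass
class TreeNode:
    """A CART node.  Internal nodes route ``feature < threshold`` left and
    ``feature >= threshold`` right; every node carries its training class
    counts ``(healthy, event)`` and majority class."""

    counts: tuple[int, int]
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return self.counts[0] + self.counts[1]

    @property
    def majority(self) -> str:
        return "event" if self.counts[1] > self.counts[0] else "healthy"

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        d = {"counts": list(self.counts)}
        if not self.is_leaf:
            d |= {
                "feature": self.feature,
                "threshold": self.threshold,
                "left": self.left.to_dict(),
                "right": self.right.to_dict(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(counts=tuple(d["counts"]))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        names = [c for c in features.columns if c in FEATURE_NAMES] or list(features.columns)
        return features[names].to_numpy(dtype=float), list(names)
    arr = np.asarray(features, dtype=float)
    if arr.ndim != 2:
        raise ValueError("features must be a 2-D array or DataFrame")
    if arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} descriptor columns")
    return arr, list(FEATURE_NAMES)


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == object:
        y = np.asarray([1 if v in (1, True, "event") else 0 for v in y])
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/healthy, 1/event)")
    return y


def best_split(features, labels, *, min_child: int = 1) -> Optional[Split]:
    """Exhaustive search for the (descriptor, threshold) pair minimizing the
    weighted Gini impurity of the two children.

    Candidate thresholds per descriptor are the midpoints between successive
    distinct observed values; only splits leaving >= ``min_child``
    observations on each side are admissible.  Ties are broken by descriptor
    priority (column order, i.e. total volume first) and then by the smaller
    threshold, making the result deterministic and independent of row order.
    Returns None when the node is single-class or no admissible candidate
    exists.
    """
    X, names = _as_matrix(features)
    y = _as_labels(labels)
    n = y.size
    if n != X.shape[0]:
        raise ValueError("features/labels length mismatch")
    if n < 2 or y.min() == y.max():
        return None

    best: Optional[Split] = None
    for j, name in enumerate(names):
        order = np.argsort(X[:, j], kind="mergesort")
        v = X[order, j]
        e = np.cumsum(y[order])  # events in the left block after each position
        total_e = int(e[-1])
        cut = np.nonzero(np.diff(v) > 0)[0]  # left block = positions 0..i
        if cut.size == 0:
            continue
        thr = (v[cut] + v[cut + 1]) / 2.0
        ok = (thr > v[cut]) & (thr < v[cut + 1])
        cut, thr = cut[ok], thr[ok]
        nl = cut + 1
        nr = n - nl
        admissible = (nl >= min_child) & (nr >= min_child)
        if not admissible.any():
            continue
        cut, thr, nl, nr = cut[admissible], thr[admissible], nl[admissible], nr[admissible]
        el = e[cut]
        hl = nl - el
        er = total_e - el
        hr = nr - er
        gl = 1.0 - (hl / nl) ** 2 - (el / nl) ** 2
        gr = 1.0 - (hr / nr) ** 2 - (er / nr) ** 2
        w = (nl * gl + nr * gr) / n
        i = int(np.argmin(w))  # first minimum -> smallest threshold within the feature
        if best is None or w[i] < best.impurity:
            best = Split(
                feature=name,
                threshold=float(thr[i]),
                impurity=float(w[i]),
                n_left=int(nl[i]),
                n_right=int(nr[i]),
            )
    return best


def build_tree(features, labels, *, min_leaf: int = 6) -> TreeNode:
    """Grow a full CART by recursive exhaustive Gini splitting.

    A node becomes a leaf when it is pure, when fewer than ``2 * min_leaf``
    observations remain, when no admissible split keeps >= ``min_leaf``
    observations per child, or when the best split does not strictly reduce
    the weighted impurity.
    """
    X, names = _as_matrix(features)
    y = _as_labels(labels)
    if y.size < min_leaf:
        raise ValueError(f"need at least min_leaf={min_leaf} observations, got {y.size}")
    Xdf = pd.DataFrame(X, columns=names)

    def grow(idx: np.ndarray) -> TreeNode:
        ysub = y[idx]
        counts = (int((ysub == 0).sum()), int((ysub == 1).sum()))
        node = TreeNode(counts=counts)
        if counts[0] == 0 or counts[1] == 0 or idx.size < 2 * min_leaf:
            return node
        s = best_split(Xdf.iloc[idx], ysub, min_child=min_leaf)
        if s is None:
            return node
        parent = gini_impurity(counts)
        if not s.impurity < parent - MIN_GAIN:
            return node
        j = names.index(s.feature)
        go_left = X[idx, j] < s.threshold
        node.feature = s.feature
        node.threshold = s.threshold
        node.left = grow(idx[go_left])
        node.right = grow(idx[~go_left])
        return node

    return grow(np.arange(y.size))


# ---------------------------------------------------------------------------
# Cross-validation consensus
# ---------------------------------------------------------------------------


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition into k folds, stratified by label so that every
    fold carries its share of the (minority) events."""
    y = _as_labels(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def _modal_value(values: Iterable[float]) -> float:
    """Mode of the thresholds after rounding to 3 decimals; if multimodal,
    the median of the modal set (a continuous feature rarely repeats exactly)."""
    rounded = [round(float(v), MODE_DECIMALS) for v in values]
    cnt = Counter(rounded)
    top = max(cnt.values())
    modal = sorted(v for v, c in cnt.items() if c == top)
    return float(median(modal))


@dataclass
class ConsensusTree:
    """The stabilized depth-2 tree: a root split and a second split inside the
    root's ">=" branch, distilled from the k fold trees by majority descriptor
    and modal threshold.  ``fold_trees`` keeps the full per-fold trees for
    audit; anything below depth 2 is reported but not used."""

    k: int
    root_feature: Optional[str]
    root_threshold: Optional[float]
    second_feature: Optional[str]
    second_threshold: Optional[float]
    root_votes: dict[str, int] = field(default_factory=dict)
    second_votes: dict[str, int] = field(default_factory=dict)
    fold_trees: list[TreeNode] = field(default_factory=list)

    @property
    def stable(self) -> bool:
        return self.root_feature is not None and self.second_feature is not None

    def pattern_definitions(self) -> dict[int, str]:
        if not self.stable:
            return {}
        return {
            1: f"{self.root_feature} < {self.root_threshold:g}",
            2: f"{self.root_feature} >= {self.root_threshold:g} and "
            f"{self.second_feature} < {self.second_threshold:g}",
            3: f"{self.root_feature} >= {self.root_threshold:g} and "
            f"{self.second_feature} >= {self.second_threshold:g}",
        }

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "root_feature": self.root_feature,
            "root_threshold": self.root_threshold,
            "second_feature": self.second_feature,
            "second_threshold": self.second_threshold,
            "root_votes": self.root_votes,
            "second_votes": self.second_votes,
            "pattern_definitions": {str(p): d for p, d in self.pattern_definitions().items()},
            "fold_trees": [t.to_dict() for t in self.fold_trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusTree":
        return cls(
            k=d["k"],
            root_feature=d["root_feature"],
            root_threshold=d["root_threshold"],
            second_feature=d["second_feature"],
            second_threshold=d["second_threshold"],
            root_votes={k: int(v) for k, v in d.get("root_votes", {}).items()},
            second_votes={k: int(v) for k, v in d.get("second_votes", {}).items()},
            fold_trees=[TreeNode.from_dict(t) for t in d.get("fold_trees", [])],
        )

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")
        return path

    @classmethod
    def load(cls, path: Path | str) -> "ConsensusTree":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def consensus_tree(features, labels, *, k: int = 10, min_leaf: int = 6, seed: int = 0) -> ConsensusTree:
    """Build k fold trees by k-fold cross-validation and distill the consensus.

    Each fold tree is grown on the other k-1 folds.  The consensus root is the
    descriptor used at the root by a strict majority of the k fold trees, with
    threshold equal to the modal value among those trees; the consensus second
    split applies the same rule to the ">="-branch child of the root, over the
    fold trees that agree with the consensus root.  When no strict majority
    exists at a position the corresponding consensus slot is None and the
    result is flagged unstable rather than silently picking a descriptor.
    """
    X, names = _as_matrix(features)
    y = _as_labels(labels)
    n = y.size
    if n < k * min_leaf:
        raise ValueError(f"need n >= k*min_leaf = {k * min_leaf}, got {n}")
    folds = stratified_folds(y, k, seed)
    Xdf = pd.DataFrame(X, columns=names)

    trees: list[TreeNode] = []
    for i in range(k):
        train = np.array(sorted(set(range(n)) - set(folds[i].tolist())), dtype=int)
        trees.append(build_tree(Xdf.iloc[train], y[train], min_leaf=min_leaf))

    root_votes = Counter(t.feature for t in trees if not t.is_leaf)
    root_feature = root_threshold = None
    if root_votes:
        feat, votes = root_votes.most_common(1)[0]
        if votes > k / 2:
            root_feature = feat
            root_threshold = _modal_value(t.threshold for t in trees if t.feature == feat)

    second_feature = second_threshold = None
    second_votes: Counter = Counter()
    if root_feature is not None:
        right_children = [
            t.right for t in trees if t.feature == root_feature and not t.right.is_leaf
        ]
        second_votes = Counter(c.feature for c in right_children)
        if right_children:
            feat, votes = second_votes.most_common(1)[0]
            if votes > len(right_children) / 2:
                second_feature = feat
                second_threshold = _modal_value(
                    c.threshold for c in right_children if c.feature == feat
                )

    return ConsensusTree(
        k=k,
        root_feature=root_feature,
        root_threshold=root_threshold,
        second_feature=second_feature,
        second_threshold=second_threshold,
        root_votes=dict(root_votes),
        second_votes=dict(second_votes),
        fold_trees=trees,
    )


# ---------------------------------------------------------------------------
# Pattern assignment and 2x2 metrics
# ---------------------------------------------------------------------------


def assign_pattern(f: WmlFeatures | dict, consensus: ConsensusTree) -> int:
    """Route one subject's descriptors through the depth-2 consensus tree.

    Pattern 1: below the root threshold.  Otherwise pattern 2 or 3 by the
    second split, with ">=" going to pattern 3 at both boundaries.
    """
    if not consensus.stable:
        raise UnstableConsensusError("consensus tree is unstable; patterns are undefined")
    get = f.get if isinstance(f, dict) else lambda name: getattr(f, name)
    if get(consensus.root_feature) < consensus.root_threshold:
        return 1
    if get(consensus.second_feature) < consensus.second_threshold:
        return 2
    return 3


def assign_patterns(features: pd.DataFrame, consensus: ConsensusTree) -> pd.Series:
    """Vectorized :func:`assign_pattern` over a descriptor table."""
    if not consensus.stable:
        raise UnstableConsensusError("consensus tree is unstable; patterns are undefined")
    root = features[consensus.root_feature].to_numpy(dtype=float)
    second = features[consensus.second_feature].to_numpy(dtype=float)
    out = np.where(
        root < consensus.root_threshold, 1, np.where(second < consensus.second_threshold, 2, 3)
    )
    return pd.Series(out, index=features.index, name="pattern")


def classification_metrics(predicted_at_risk, event_labels) -> dict:
    """Sensitivity/specificity/PPV/NPV (in %) of the binary "pattern 3" flag
    against observed progression, from the standard 2x2 table.

    Undefined quantities (zero denominator) are reported as None, never 0.
    """
    p = np.asarray(predicted_at_risk).astype(bool)
    e = _as_labels(event_labels).astype(bool)
    if p.shape != e.shape:
        raise ValueError("prediction/label length mismatch")
    if not e.any() or e.all():
        raise ValueError("need at least one event and one non-event")
    tp = int((p & e).sum())
    fn = int((~p & e).sum())
    fp = int((p & ~e).sum())
    tn = int((~p & ~e).sum())

    def pct(num: int, den: int) -> Optional[float]:
        return None if den == 0 else 100.0 * num / den

    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "sensitivity": pct(tp, tp + fn),
        "specificity": pct(tn, tn + fp),
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }
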