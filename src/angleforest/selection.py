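"""Iterative decision-tree feature selection.

A small CART-style tree (Gini criterion, exhaustive threshold scan) is fit
on the frame-level matrix; the distinct angles it splits on form that
round's selected features; those angles are removed from the pool and the
procedure repeats.  Depth-2 trees contribute at most three angles per
round, matching the two-angles-per-tree cardinality of the original
analysis.

Determinism contracts: the threshold scan evaluates the midpoints of
consecutive distinct sorted values and breaks impurity ties by the smaller
threshold; feature ties are broken by lower residue number, phi before psi.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ensembles import canonical_feature_order
from .matrix import DihedralMatrix

__all__ = [
    "gini_impurity",
    "best_split",
    "fit_tree",
    "iterative_selection",
    "TreeNode",
    "DecisionTree",
    "SelectionRound",
    "SelectionResult",
]


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node's class counts.

    0 for a pure node; 0.5 is the two-class maximum.
    """
    counts = np.asarray(class_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("class_counts must be a nonempty 1-D sequence")
    if (counts < 0).any():
        raise ValueError("class counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero class counts: impurity undefined")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def best_split(values, labels, min_leaf: int = 1):
    """Exhaustive best binary split of one feature column.

    Scans the midpoints of consecutive distinct sorted values and returns
    ``(threshold, weighted_child_impurity)`` minimizing the sample-weighted
    mean child Gini (rows with value <= threshold go left).  Ties are
    broken by the smaller threshold.  Returns None when no admissible split
    exists (constant column, or min_leaf cannot be honored).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    n = v.size
    if n != y.size:
        raise ValueError("values and labels must have equal length")
    if n < 2:
        return None
    order = np.argsort(v, kind="stable")
    vs = v[order]
    ys = (y[order] == 1).astype(np.int64)

    cum1 = np.cumsum(ys)
    total1 = int(cum1[-1])
    # candidate boundaries after position i (1..n-1), only between distinct values
    i = np.arange(1, n)
    valid = vs[1:] > vs[:-1]
    if min_leaf > 1:
        valid &= (i >= min_leaf) & (n - i >= min_leaf)
    if not valid.any():
        return None
    i = i[valid]
    n_left = i.astype(float)
    n_right = n - n_left
    left1 = cum1[i - 1].astype(float)
    left0 = n_left - left1
    right1 = total1 - left1
    right0 = n_right - right1
    gini_left = 1.0 - ((left0 / n_left) ** 2 + (left1 / n_left) ** 2)
    gini_right = 1.0 - ((right0 / n_right) ** 2 + (right1 / n_right) ** 2)
    weighted = (n_left * gini_left + n_right * gini_right) / n
    best = int(np.argmin(weighted))  # first minimum -> smallest threshold
    thr = 0.5 * (vs[i[best] - 1] + vs[i[best]])
    return float(thr), float(weighted[best])


def _best_split_matrix(X, y, min_leaf: int = 1):
    """Fused exhaustive split scan over every column of a node's submatrix.

    Same arithmetic and tie-break semantics as :func:`best_split` applied
    column by column (first feature, then smallest threshold), in a single
    vectorized sweep.  Returns ``(col, threshold, weighted_impurity)`` or
    None.
    """
    n, k = X.shape
    if n < 2:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    vs = np.take_along_axis(X, order, axis=0)
    ys = (y[order] == 1).astype(np.int64)
    cum1 = np.cumsum(ys, axis=0)
    total1 = cum1[-1].astype(float)

    i = np.arange(1, n, dtype=float)[:, None]
    valid = vs[1:] > vs[:-1]
    if min_leaf > 1:
        ii = np.arange(1, n)[:, None]
        valid &= (ii >= min_leaf) & (n - ii >= min_leaf)
    if not valid.any():
        return None
    n_left = i
    n_right = n - n_left
    left1 = cum1[:-1].astype(float)
    left0 = n_left - left1
    right1 = total1[None, :] - left1
    right0 = n_right - right1
    gini_left = 1.0 - ((left0 / n_left) ** 2 + (left1 / n_left) ** 2)
    gini_right = 1.0 - ((right0 / n_right) ** 2 + (right1 / n_right) ** 2)
    weighted = (n_left * gini_left + n_right * gini_right) / n
    weighted = np.where(valid, weighted, np.inf)
    per_feature = weighted.min(axis=0)
    j = int(np.argmin(per_feature))       # first feature at impurity ties
    if not np.isfinite(per_feature[j]):
        return None
    r = int(np.argmin(weighted[:, j]))    # first row -> smallest threshold
    thr = 0.5 * (vs[r, j] + vs[r + 1, j])
    return j, float(thr), float(weighted[r, j])


@dataclass
class TreeNode:
    """Internal node (feature/threshold set) or leaf (feature is None)."""

    counts: tuple            # (n_sensitive, n_resistant) at this node
    gini: float
    prediction: int          # majority class; tie -> 0 (sensitive)
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {"counts": list(self.counts), "gini": self.gini,
             "prediction": self.prediction}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class DecisionTree:
    """A fitted classification tree over named angle features."""

    root: TreeNode
    features: list[str]          # the allowed feature pool it was fit on

    def predict(self, X: np.ndarray, feature_names: list[str]) -> np.ndarray:
        """Predicted class (0/1) per row of X (columns = feature_names)."""
        idx = {f: j for j, f in enumerate(feature_names)}
        out = np.empty(X.shape[0], dtype=int)

        def descend(node, rows):
            if rows.size == 0:
                return
            if node.is_leaf:
                out[rows] = node.prediction
                return
            go_left = X[rows, idx[node.feature]] <= node.threshold
            descend(node.left, rows[go_left])
            descend(node.right, rows[~go_left])

        descend(self.root, np.arange(X.shape[0]))
        return out

    def split_features(self) -> list[str]:
        """Distinct features used at internal nodes, in canonical order."""
        found = set()

        def walk(node):
            if node is None or node.is_leaf:
                return
            found.add(node.feature)
            walk(node.left)
            walk(node.right)

        walk(self.root)
        return canonical_feature_order(found)

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def dump(self) -> str:
        """Human-readable text rendering of the tree."""
        lines = []

        def walk(node, indent):
            pad = "  " * indent
            tag = f"counts(S,R)={node.counts} gini={node.gini:.4f}"
            if node.is_leaf:
                lines.append(f"{pad}leaf -> {'R' if node.prediction else 'S'} "
                             f"[{tag}]")
            else:
                lines.append(f"{pad}{node.feature} <= {node.threshold:.3f} "
                             f"[{tag}]")
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)


def _node_counts(y):
    return (int(np.sum(y == 0)), int(np.sum(y == 1)))


def fit_tree(matrix, features=None, max_depth: int = 2,
             min_leaf: int = 5) -> DecisionTree:
    """Fit a Gini decision tree on the frame-level matrix.

    At each node, every allowed feature is scanned exhaustively and the
    (feature, threshold) pair with minimal weighted child impurity wins;
    only strictly impurity-reducing splits honoring ``min_leaf`` are
    accepted.  A single-class matrix yields a degenerate one-leaf tree.

    ``matrix`` may be a DihedralMatrix or a tuple ``(X, y, feature_names)``.
    """
    if isinstance(matrix, DihedralMatrix):
        pool = matrix.feature_names if features is None else list(features)
        pool = canonical_feature_order(pool)
        X = matrix.X(pool)
        y = matrix.y
    else:
        X, y, names = matrix
        pool = list(names) if features is None else list(features)
        try:
            pool = canonical_feature_order(pool)
        except ValueError:
            pool = list(pool)  # non phi/psi names: keep caller's order
        cols = {f: j for j, f in enumerate(names)}
        X = np.asarray(X, dtype=float)[:, [cols[f] for f in pool]]
        y = np.asarray(y, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a tree on an empty matrix")

    def build(rows, depth):
        yr = y[rows]
        counts = _node_counts(yr)
        g = gini_impurity(counts)
        pred = 1 if counts[1] > counts[0] else 0
        node = TreeNode(counts=counts, gini=g, prediction=pred)
        if depth == max_depth or g == 0.0 or rows.size < 2 * min_leaf:
            return node
        best = _best_split_matrix(X[rows], yr, min_leaf=min_leaf)
        if best is None or best[2] >= g:
            return node
        j, thr, _imp = best
        node.feature = pool[j]
        node.threshold = thr
        go_left = X[rows, j] <= thr
        node.left = build(rows[go_left], depth + 1)
        node.right = build(rows[~go_left], depth + 1)
        return node

    root = build(np.arange(X.shape[0]), 0)
    return DecisionTree(root=root, features=pool)


@dataclass
class SelectionRound:
    index: int                      # 1-based round number
    tree: DecisionTree
    selected: list[str]
    gini_before: float              # root impurity
    gini_after: float               # weighted leaf impurity of the tree

    def to_dict(self):
        return {"round": self.index, "selected": self.selected,
                "gini_before": self.gini_before,
                "gini_after": self.gini_after,
                "tree": self.tree.root.to_dict()}


@dataclass
class SelectionResult:
    """Ordered rounds of iterative tree-based feature selection."""

    rounds: list[SelectionRound] = field(default_factory=list)

    @property
    def selected_by_round(self) -> list[list[str]]:
        return [r.selected for r in self.rounds]

    def features_of_rounds(self, indices) -> list[str]:
        """Union of the named (1-based) rounds' selections, canonical order."""
        chosen = set()
        for i in indices:
            if not 1 <= i <= len(self.rounds):
                raise IndexError(f"no selection round {i}")
            chosen.update(self.rounds[i - 1].selected)
        return canonical_feature_order(chosen)

    @property
    def all_selected(self) -> list[str]:
        return self.features_of_rounds(range(1, len(self.rounds) + 1))

    def to_json(self, path=None) -> str:
        payload = json.dumps({"rounds": [r.to_dict() for r in self.rounds]},
                             indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _weighted_leaf_gini(node, total):
    if node.is_leaf:
        return node.gini * sum(node.counts) / total
    return _weighted_leaf_gini(node.left, total) + \
        _weighted_leaf_gini(node.right, total)


def iterative_selection(matrix: DihedralMatrix, n_rounds: int = 3,
                        max_depth: int = 2, min_leaf: int = 5,
                        features=None) -> SelectionResult:
    """Fit a tree, harvest its split angles, remove them, repeat.

    Round r fits on the full pool minus everything selected in earlier
    rounds, so the per-round feature sets are pairwise disjoint.  Stops
    early (with a warning) if the pool is exhausted or a round selects
    nothing.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be at least 1")
    pool = canonical_feature_order(
        matrix.feature_names if features is None else features)
    result = SelectionResult()
    excluded: set[str] = set()
    n = matrix.n_rows
    for r in range(1, n_rounds + 1):
        remaining = [f for f in pool if f not in excluded]
        if not remaining:
            warnings.warn(f"feature pool exhausted after {r - 1} rounds")
            break
        tree = fit_tree(matrix, features=remaining,
                        max_depth=max_depth, min_leaf=min_leaf)
        selected = tree.split_features()
        if not selected:
            warnings.warn(f"round {r} produced no splits; stopping")
            break
        result.rounds.append(SelectionRound(
            index=r, tree=tree, selected=selected,
            gini_before=tree.root.gini,
            gini_after=_weighted_leaf_gini(tree.root, n)))
        excluded.update(selected)
    sets = [set(r.selected) for r in result.rounds]
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            assert not (sets[a] & sets[b]), "rounds selected overlapping features"
    return result
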