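"""Entropy-based C4.5-style decision tree for binary lateralization.

Greedy top-down induction over binary numeric splits: candidate
thresholds sit at midpoints between consecutive distinct sorted feature
values, the split maximizing the gain ratio (information gain divided
by split information) is chosen, and the grown tree is pruned with the
classic pessimistic error estimate (one-sided binomial upper confidence
limit, default confidence 0.25).  The comparison convention is
"value <= threshold follows the first branch", matching the usual
printed-rule style ``AI[region] <= t: class``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import beta
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import PetasymError

_LN2 = np.log(2.0)


@dataclass
class TreeNode:
    """Internal node (feature/threshold/children) or leaf (leaf_class)."""

    feature: str | None = None
    threshold: float | None = None
    le: "TreeNode | None" = None   # branch for value <= threshold
    gt: "TreeNode | None" = None   # branch for value > threshold
    leaf_class: str | None = None
    n: int = 0
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class is not None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.le.leaves() + self.gt.leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.le.depth(), self.gt.depth())


def _entropy_bits(counts: np.ndarray) -> np.ndarray:
    """Entropy (bits) of rows of a counts array, vectorized."""
    counts = np.atleast_2d(counts).astype(np.float64)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        h = (xlogy(n, n) - xlogy(counts, counts).sum(axis=1)) / (n * _LN2)
    return np.where(n > 0, h, 0.0)


def best_split(X: np.ndarray, y: np.ndarray, min_leaf: int = 2,
               threshold_style: str = "midpoint"):
    """Gain-ratio-optimal binary split, or None.

    ``X``: (n, p) float matrix; ``y``: integer class codes (0/1).
    Ties in gain ratio are resolved toward the lower feature index and,
    within a feature, the lower threshold.  ``threshold_style`` selects
    the midpoint between neighbouring distinct values (default) or the
    lower observed value, C4.5-style.

    Returns ``(feature_index, threshold, gain_ratio, gain)``.
    """
    n = len(y)
    total = np.bincount(y, minlength=2).astype(np.float64)
    h_parent = float(_entropy_bits(total)[0])
    best: tuple[float, int, float, float] | None = None  # (gr, j, thr, gain)
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        ys = y[order]
        nl = np.arange(1, n)                     # left sizes
        left1 = np.cumsum(ys)[:-1].astype(np.float64)
        left = np.stack([nl - left1, left1], axis=1)
        right = total - left
        distinct = xs[1:] != xs[:-1]
        valid = distinct & (nl >= min_leaf) & ((n - nl) >= min_leaf)
        if not valid.any():
            continue
        info = (nl * _entropy_bits(left) + (n - nl) * _entropy_bits(right)) / n
        gain = h_parent - info
        split_info = _entropy_bits(np.stack([nl, n - nl], axis=1).astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            gr = np.where((split_info > 0) & valid & (gain > 1e-12),
                          gain / split_info, -np.inf)
        i = int(np.argmax(gr))
        if not np.isfinite(gr[i]):
            continue
        if threshold_style == "midpoint":
            thr = float((xs[i] + xs[i + 1]) / 2.0)
        elif threshold_style == "lower":
            thr = float(xs[i])
        else:
            raise ValueError(f"unknown threshold_style {threshold_style!r}")
        if best is None or gr[i] > best[0] + 1e-12:
            best = (float(gr[i]), j, thr, float(gain[i]))
    if best is None:
        return None
    gr_val, j, thr, gain_val = best
    return j, thr, gr_val, gain_val


def _pessimistic_errors(n: int, e: int, cf: float) -> float:
    """C4.5 pessimistic error count: n times the one-sided binomial
    upper confidence limit on the error rate at confidence ``cf``."""
    if n == 0:
        return 0.0
    if e >= n:
        return float(n)
    return float(n * beta.ppf(1.0 - cf, e + 1, n - e))


class C45TreeClassifier(ClassifierMixin, BaseEstimator):
    """C4.5-style entropy decision tree (binary classes, numeric features).

    Parameters
    ----------
    min_leaf : int, default 2
        Minimum training instances per leaf.
    pruning_confidence : float, default 0.25
        Confidence for the pessimistic error estimate; lower prunes
        harder.  ``None`` disables pruning.
    threshold_style : {"midpoint", "lower"}
        Where the numeric threshold is placed between neighbouring
        distinct values.

    Attributes (after fit)
    ----------------------
    tree_ : TreeNode — root of the induced tree.
    classes_ : ndarray of the two class labels, sorted.
    feature_names_in_ : ndarray of column names.
    """

    def __init__(self, min_leaf: int = 2, pruning_confidence: float | None = 0.25,
                 threshold_style: str = "midpoint"):
        self.min_leaf = min_leaf
        self.pruning_confidence = pruning_confidence
        self.threshold_style = threshold_style

    # -- fitting -------------------------------------------------------

    def fit(self, X, y):
        X, y, feature_names = _check_table(X, y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        if len(self.classes_) > 2:
            raise PetasymError("only binary classification is supported")
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = X.shape[1]
        if len(self.classes_) == 1:
            # degenerate single-class table: a lone leaf, by design
            self.tree_ = self._leaf(codes)
            return self
        self.tree_ = self._grow(X, codes)
        if self.pruning_confidence is not None:
            self._prune(self.tree_)
        return self

    def _leaf(self, codes: np.ndarray) -> TreeNode:
        counts = np.bincount(codes, minlength=len(self.classes_))
        # majority; exact tie broken toward the later class (Right)
        winner = int(np.flatnonzero(counts == counts.max())[-1])
        return TreeNode(leaf_class=str(self.classes_[winner]), n=len(codes),
                        class_counts={str(c): int(k) for c, k in zip(self.classes_, counts)})

    def _grow(self, X: np.ndarray, codes: np.ndarray) -> TreeNode:
        if len(np.unique(codes)) == 1 or len(codes) < 2 * self.min_leaf:
            return self._leaf(codes)
        found = best_split(X, codes, self.min_leaf, self.threshold_style)
        if found is None:
            return self._leaf(codes)
        j, thr, _, _ = found
        mask = X[:, j] <= thr
        node = TreeNode(feature=str(self.feature_names_in_[j]), threshold=thr,
                        n=len(codes),
                        class_counts={str(c): int(k) for c, k in zip(
                            self.classes_, np.bincount(codes, minlength=len(self.classes_)))})
        node.le = self._grow(X[mask], codes[mask])
        node.gt = self._grow(X[~mask], codes[~mask])
        return node

    def _prune(self, node: TreeNode) -> float:
        """Bottom-up subtree replacement; returns pessimistic errors."""
        cf = self.pruning_confidence
        if node.is_leaf:
            e = node.n - node.class_counts.get(node.leaf_class, 0)
            return _pessimistic_errors(node.n, e, cf)
        subtree_err = self._prune(node.le) + self._prune(node.gt)
        counts = node.class_counts
        as_leaf_e = node.n - max(counts.values())
        as_leaf_err = _pessimistic_errors(node.n, as_leaf_e, cf)
        if as_leaf_err <= subtree_err + 1e-9:
            majority = max(sorted(counts), key=lambda c: (counts[c], c))
            node.leaf_class = majority
            node.feature = node.threshold = node.le = node.gt = None
            return as_leaf_err
        return subtree_err

    # -- prediction ----------------------------------------------------

    def predict(self, X):
        X = _check_features(X, self.feature_names_in_)
        name_to_col = {n: i for i, n in enumerate(self.feature_names_in_)}
        out = []
        for row in X:
            node = self.tree_
            while not node.is_leaf:
                node = node.le if row[name_to_col[node.feature]] <= node.threshold else node.gt
            out.append(node.leaf_class)
        return np.asarray(out, dtype=object)

    @classmethod
    def from_tree(cls, tree: TreeNode, classes=("Left", "Right"),
                  feature_names=None) -> "C45TreeClassifier":
        """Wrap an externally specified rule tree as a fitted classifier."""
        clf = cls()
        clf.tree_ = tree
        clf.classes_ = np.asarray(classes, dtype=object)
        used = sorted({n.feature for n in _walk(tree) if n.feature is not None})
        clf.feature_names_in_ = np.asarray(
            used if feature_names is None else list(feature_names), dtype=object)
        clf.n_features_in_ = len(clf.feature_names_in_)
        return clf


def _walk(node: TreeNode):
    yield node
    if not node.is_leaf:
        yield from _walk(node.le)
        yield from _walk(node.gt)


# -- shared input plumbing ---------------------------------------------


def _check_table(X, y):
    """Validate a training table; returns float matrix, labels, names."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        values = X.to_numpy(dtype=np.float64)
    else:
        values = np.asarray(X, dtype=np.float64)
        if values.ndim != 2:
            raise PetasymError("X must be a 2D table")
        names = [f"x{i}" for i in range(values.shape[1])]
    if values.shape[0] == 0:
        raise PetasymError("empty training table")
    if not np.all(np.isfinite(values)):
        raise PetasymError("features contain missing or non-finite values")
    y = np.asarray(pd.Series(y).astype(str), dtype=object)
    if len(y) != values.shape[0]:
        raise PetasymError("X and y lengths differ")
    return values, y, names


def _check_features(X, feature_names):
    """Validate a prediction table against the model's feature set."""
    if isinstance(X, pd.Series):
        X = X.to_frame().T
    if isinstance(X, dict):
        X = pd.DataFrame([X])
    if isinstance(X, pd.DataFrame):
        missing = [n for n in feature_names if n not in X.columns]
        if missing:
            raise PetasymError(f"missing features: {missing}")
        values = X[list(feature_names)].to_numpy(dtype=np.float64)
    else:
        values = np.asarray(X, dtype=np.float64)
        if values.ndim == 1:
            values = values[None, :]
        if values.shape[1] != len(feature_names):
            raise PetasymError(
                f"expected {len(feature_names)} features, got {values.shape[1]}")
    if not np.all(np.isfinite(values)):
        raise PetasymError("features contain missing or non-finite values")
    return values
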