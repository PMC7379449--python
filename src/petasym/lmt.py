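"""Logistic model tree (LMT) for binary lateralization.

The leaf models are additive logistic regressions fitted by two-class
LogitBoost with *simple* base learners: each boosting iteration fits a
weighted least-squares regression on every single feature and keeps the
one with the smallest weighted SSE.  Because every base learner is
linear in one feature, the boosted model collapses to a single linear
score, reported as antisymmetric per-class scores

    score(Right) = b0 + sum_j b_j * AI_j,    score(Left) = -score(Right)

with the class of the larger score predicted (ties go to Right).  The
number of boosting iterations is chosen by seeded internal
cross-validation.  A node is considered for splitting (C4.5-style gain
ratio) only when it holds at least ``min_split`` instances and its
logistic model still misclassifies training rows; the split is kept
only if it strictly lowers the internal-CV error, which keeps cohorts
of a few dozen subjects at a single root model — the regime in which
LMT is equivalent to a boosted simple logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import PetasymError
from .tree import _check_features, _check_table, best_split

_Z_MAX = 3.0      # working-response clamp (standard LogitBoost guard)
_W_MIN = 1e-10    # weight floor to keep WLS well-posed


@dataclass
class LinearScoreModel:
    """Antisymmetric two-class linear score over AI features.

    ``intercept`` and ``coef`` parameterize the score of ``classes[1]``
    (Right); the score of ``classes[0]`` is its exact negative.
    """

    intercept: float
    coef: dict[str, float]
    classes: tuple[str, str] = ("Left", "Right")

    def score(self, x: dict[str, float] | "np.ndarray", feature_names=None) -> float:
        """Linear score of ``classes[1]`` for one feature row."""
        if isinstance(x, dict):
            return self.intercept + sum(w * x[f] for f, w in self.coef.items())
        names = list(feature_names)
        return self.intercept + sum(w * x[names.index(f)] for f, w in self.coef.items())

    def class_scores(self, x, feature_names=None) -> dict[str, float]:
        s = self.score(x, feature_names)
        return {self.classes[0]: -s, self.classes[1]: s}


@dataclass
class LMTNode:
    """Split node of a logistic model tree; leaves hold linear models."""

    model: LinearScoreModel | None = None
    feature: str | None = None
    threshold: float | None = None
    le: "LMTNode | None" = None
    gt: "LMTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> list["LMTNode"]:
        if self.is_leaf:
            return [self]
        return self.le.leaves() + self.gt.leaves()


def _boost(X: np.ndarray, y: np.ndarray, n_iter: int,
           F0: np.ndarray | None = None,
           X_eval: np.ndarray | None = None, y_eval: np.ndarray | None = None):
    """Two-class LogitBoost with one-feature WLS base learners.

    ``y`` in {0, 1}; the boosted score F targets class 1 through
    p = expit(2F).  Returns (intercept, coef_vector) of the collapsed
    linear score and, when an eval set is given, the held-out error
    count after each iteration.
    """
    n, p = X.shape
    F = np.zeros(n) if F0 is None else F0.astype(np.float64).copy()
    b0, bvec = 0.0, np.zeros(p)
    errs = []
    F_eval = None
    if X_eval is not None:
        F_eval = np.zeros(len(X_eval))
    for _ in range(n_iter):
        prob = expit(2.0 * F)
        w = np.clip(prob * (1.0 - prob), _W_MIN, None)
        z = np.clip((y - prob) / w, -_Z_MAX, _Z_MAX)
        sw = w.sum()
        xmean = (w[:, None] * X).sum(axis=0) / sw
        zmean = (w * z).sum() / sw
        Xc = X - xmean
        zc = z - zmean
        sxz = (w[:, None] * Xc * zc[:, None]).sum(axis=0)
        sxx = (w[:, None] * Xc * Xc).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(sxx > 1e-12, sxz / sxx, 0.0)
        sse = (w[:, None] * (zc[:, None] - Xc * slope) ** 2).sum(axis=0)
        j = int(np.argmin(sse))
        a = zmean - slope[j] * xmean[j]
        F += 0.5 * (a + slope[j] * X[:, j])
        b0 += 0.5 * a
        bvec[j] += 0.5 * slope[j]
        if F_eval is not None:
            F_eval += 0.5 * (a + slope[j] * X_eval[:, j])
            errs.append(int(np.sum((F_eval >= 0).astype(int) != y_eval)))
    return b0, bvec, errs


class LogisticModelTreeClassifier(ClassifierMixin, BaseEstimator):
    """Logistic model tree / boosted simple logistic classifier.

    Parameters
    ----------
    max_boost_iter : int, default 200
        Upper bound on LogitBoost iterations per node.
    inner_cv : int, default 5
        Folds of the seeded internal CV that picks the iteration count
        (and arbitrates split pruning).  Folds are plain shuffled
        partitions, which makes label-swapped training exactly
        antisymmetric.
    min_split : int, default 15
        Minimum node size at which a split is even considered.
    max_depth : int, default 3
        Hard cap on split nesting.
    random_state : int, default 0
        Seed for the internal CV partitions.

    Attributes (after fit)
    ----------------------
    model_ : LinearScoreModel | LMTNode — root-only linear score, or a
        tree with linear-score leaves when splitting survived pruning.
    n_boost_iter_ : int — iterations chosen at the root.
    classes_, feature_names_in_, n_features_in_.
    """

    def __init__(self, max_boost_iter: int = 200, inner_cv: int = 5,
                 min_split: int = 15, max_depth: int = 3, random_state: int = 0):
        self.max_boost_iter = max_boost_iter
        self.inner_cv = inner_cv
        self.min_split = min_split
        self.max_depth = max_depth
        self.random_state = random_state

    # -- fitting -------------------------------------------------------

    def fit(self, X, y):
        X, y, names = _check_table(X, y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        if len(self.classes_) == 1:
            raise PetasymError("training table holds a single class")
        if len(self.classes_) > 2:
            raise PetasymError("only binary classification is supported")
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        node, best_iter, _ = self._fit_node(X, codes, depth=0)
        self.model_ = node.model if node.is_leaf else node
        self.tree_ = node
        self.n_boost_iter_ = best_iter
        return self

    def _cv_folds(self, n: int) -> list[np.ndarray]:
        rng = np.random.default_rng(self.random_state)
        k = min(self.inner_cv, n)
        return np.array_split(rng.permutation(n), k)

    def _select_iterations(self, X, codes) -> tuple[int, int]:
        """(best iteration count, its summed CV error) via internal CV."""
        folds = self._cv_folds(len(codes))
        total = np.zeros(self.max_boost_iter, dtype=int)
        for test_idx in folds:
            if len(test_idx) == 0:
                continue
            mask = np.ones(len(codes), dtype=bool)
            mask[test_idx] = False
            _, _, errs = _boost(X[mask], codes[mask], self.max_boost_iter,
                                X_eval=X[test_idx], y_eval=codes[test_idx])
            total += np.asarray(errs)
        best = int(np.argmin(total)) + 1  # ties -> fewest iterations
        return best, int(total[best - 1])

    def _fit_node(self, X, codes, depth, F0=None):
        """Fit one node; returns (LMTNode, iterations, cv error or None)."""
        best_iter, cv_err = self._select_iterations(X, codes)
        b0, bvec, _ = _boost(X, codes, best_iter, F0=F0)
        model = self._to_model(b0, bvec)
        node = LMTNode(model=model)
        F = b0 + X @ bvec
        train_err = int(np.sum((F >= 0).astype(int) != codes))
        can_split = (depth < self.max_depth and len(codes) >= self.min_split
                     and train_err > 0 and len(np.unique(codes)) == 2)
        if not can_split:
            return node, best_iter, cv_err
        found = best_split(X, codes, min_leaf=2)
        if found is None:
            return node, best_iter, cv_err
        j, thr, _, _ = found
        split_cv_err = self._split_cv_error(X, codes, best_iter, j, thr)
        if split_cv_err >= cv_err:
            return node, best_iter, cv_err  # pruned: the leaf model wins
        mask = X[:, j] <= thr
        child_le, _, _ = self._fit_node(X[mask], codes[mask], depth + 1,
                                        F0=b0 + X[mask] @ bvec)
        child_gt, _, _ = self._fit_node(X[~mask], codes[~mask], depth + 1,
                                        F0=b0 + X[~mask] @ bvec)
        split_node = LMTNode(feature=str(self.feature_names_in_[j]), threshold=thr,
                             le=child_le, gt=child_gt)
        return split_node, best_iter, split_cv_err

    def _split_cv_error(self, X, codes, n_iter, j, thr) -> int:
        """CV error of root-model + one split + warm-started child models,
        with iteration counts frozen to keep the comparison cheap."""
        child_iter = min(n_iter, 30)
        total = 0
        for test_idx in self._cv_folds(len(codes)):
            if len(test_idx) == 0:
                continue
            mask = np.ones(len(codes), dtype=bool)
            mask[test_idx] = False
            Xtr, ytr = X[mask], codes[mask]
            b0, bvec, _ = _boost(Xtr, ytr, n_iter)
            side_tr = Xtr[:, j] <= thr
            params = {}
            for branch, sel in (("le", side_tr), ("gt", ~side_tr)):
                if sel.sum() == 0 or len(np.unique(ytr[sel])) < 2:
                    params[branch] = (b0, bvec)
                    continue
                c0, cvec, _ = _boost(Xtr[sel], ytr[sel], child_iter,
                                     F0=b0 + Xtr[sel] @ bvec)
                params[branch] = (b0 + c0, bvec + cvec)
            Xte, yte = X[test_idx], codes[test_idx]
            side_te = Xte[:, j] <= thr
            for branch, sel in (("le", side_te), ("gt", ~side_te)):
                if sel.sum() == 0:
                    continue
                p0, pvec = params[branch]
                F = p0 + Xte[sel] @ pvec
                total += int(np.sum((F >= 0).astype(int) != yte[sel]))
        return total

    def _to_model(self, b0: float, bvec: np.ndarray) -> LinearScoreModel:
        coef = {str(self.feature_names_in_[i]): float(b)
                for i, b in enumerate(bvec) if b != 0.0}
        return LinearScoreModel(float(b0), coef,
                                classes=tuple(str(c) for c in self.classes_))

    # -- prediction ------------------------------------------------------

    def _leaf_for(self, row: np.ndarray, name_to_col) -> LinearScoreModel:
        node = self.tree_
        while not node.is_leaf:
            node = node.le if row[name_to_col[node.feature]] <= node.threshold else node.gt
        return node.model

    def decision_function(self, X):
        """Linear score of ``classes_[1]`` per row (>= 0 predicts it)."""
        X = _check_features(X, self.feature_names_in_)
        name_to_col = {n: i for i, n in enumerate(self.feature_names_in_)}
        out = np.empty(len(X))
        for i, row in enumerate(X):
            model = self._leaf_for(row, name_to_col)
            out[i] = model.intercept + sum(
                w * row[name_to_col[f]] for f, w in model.coef.items())
        return out

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= 0, self.classes_[1], self.classes_[0]).astype(object)

    def predict_proba(self, X):
        p1 = expit(2.0 * self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    @classmethod
    def from_linear_model(cls, model: LinearScoreModel) -> "LogisticModelTreeClassifier":
        """Wrap an externally specified linear rule as a fitted classifier."""
        clf = cls()
        clf.classes_ = np.asarray(model.classes, dtype=object)
        clf.feature_names_in_ = np.asarray(sorted(model.coef), dtype=object)
        clf.n_features_in_ = len(clf.feature_names_in_)
        clf.model_ = model
        clf.tree_ = LMTNode(model=model)
        clf.n_boost_iter_ = 0
        return clf
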