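"""Splits, k-fold cross-validation, lateralization ratios, Cohen's kappa.

Cohen's kappa is chance-corrected agreement between two categorical
label assignments: kappa = (po - pe) / (1 - pe) with observed agreement
po and chance agreement pe from the marginal products.  Significance is
tested against the null of chance agreement with the standard null
standard error

    SE0 = sqrt(pe + pe^2 - sum_i p_i+ p_+i (p_i+ + p_+i)) / ((1 - pe) sqrt(n))

and z = kappa / SE0 referred to a standard normal (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import clone

from .errors import PetasymError
from .features import split_xy
from .lmt import LogisticModelTreeClassifier
from .tree import C45TreeClassifier


# -- split plans ---------------------------------------------------------


@dataclass
class SplitPlan:
    """Train/test assignment or fold membership for a cohort."""

    assignment: pd.Series  # index: position or subject_id; values: "train"/"test" or fold int
    seed: int
    kind: str  # "holdout" | "folds"

    @property
    def train_idx(self) -> np.ndarray:
        return np.asarray(self.assignment.index[self.assignment == "train"])

    @property
    def test_idx(self) -> np.ndarray:
        return np.asarray(self.assignment.index[self.assignment == "test"])

    @property
    def folds(self) -> list[np.ndarray]:
        ks = sorted(set(self.assignment))
        return [np.asarray(self.assignment.index[self.assignment == k]) for k in ks]


def make_split(labels, train_fraction: float, seed: int = 0) -> SplitPlan:
    """Randomized holdout split honoring ``train_fraction`` to rounding."""
    labels = pd.Series(labels).reset_index(drop=True)
    if not 0.0 < train_fraction < 1.0:
        raise PetasymError("train_fraction must lie strictly in (0, 1)")
    if labels.nunique() < 1 or len(labels) < 2:
        raise PetasymError("need at least two labeled subjects")
    n = len(labels)
    n_train = round(n * train_fraction)
    perm = np.random.default_rng(seed).permutation(n)
    assign = pd.Series("test", index=range(n))
    assign.iloc[perm[:n_train]] = "train"
    return SplitPlan(assign, seed, "holdout")


def make_folds(labels, k: int, seed: int = 0, balance: bool = True) -> SplitPlan:
    """k nonoverlapping folds with sizes differing by at most one.

    With ``balance`` the assignment is a shuffled within-class
    round-robin (fold pointer carried across classes), which keeps the
    class ratio per fold as even as integer arithmetic allows.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    n = len(labels)
    if k < 2:
        raise PetasymError("k must be >= 2")
    if k > n:
        raise PetasymError("k cannot exceed the number of subjects")
    rng = np.random.default_rng(seed)
    assign = pd.Series(-1, index=range(n), dtype=int)
    pointer = rng.integers(k)  # random starting fold
    if balance:
        groups = [labels.index[labels == c].to_numpy() for c in sorted(labels.unique())]
    else:
        groups = [np.arange(n)]
    for idx in groups:
        for i in rng.permutation(idx):
            assign.iloc[int(i)] = pointer % k
            pointer += 1
    plan = SplitPlan(assign, seed, "folds")
    _assert_partition(plan, n)
    return plan


def _assert_partition(plan: SplitPlan, n: int) -> None:
    folds = plan.folds
    all_idx = np.concatenate(folds)
    if len(all_idx) != n or len(np.unique(all_idx)) != n:
        raise PetasymError("folds do not partition the cohort")
    sizes = [len(f) for f in folds]
    if max(sizes) - min(sizes) > 1:
        raise PetasymError("fold sizes differ by more than one")


# -- ratios and kappa ----------------------------------------------------


@dataclass
class Ratio:
    correct: int
    total: int

    @property
    def ratio(self) -> float:
        return self.correct / self.total

    def __str__(self) -> str:  # Table-style "16/18, 89%"
        return f"{self.correct}/{self.total}, {round(100 * self.ratio):.0f}%"

    def __iter__(self):
        yield from (self.correct, self.total, self.ratio)


def correct_ratio(predicted, truth) -> Ratio:
    """Exact correct/total counts; any non-matching token (including a
    "No lateralization" call) counts as incorrect."""
    predicted = pd.Series(predicted).reset_index(drop=True)
    truth = pd.Series(truth).reset_index(drop=True)
    if len(predicted) != len(truth):
        raise PetasymError("prediction and truth vectors differ in length")
    return Ratio(int((predicted == truth).sum()), len(truth))


@dataclass
class KappaResult:
    po: float
    pe: float
    kappa: float
    se0: float
    z: float
    p_value: float
    table: pd.DataFrame = field(repr=False, default=None)


def cohens_kappa(predicted, truth) -> KappaResult:
    """Cohen's kappa with the null-SE z statistic and two-sided p.

    Symmetric in its arguments.  Raises on degenerate marginals
    (pe = 1, e.g. both raters constant), where kappa is undefined.
    """
    a = pd.Series(predicted).reset_index(drop=True)
    b = pd.Series(truth).reset_index(drop=True)
    if len(a) != len(b):
        raise PetasymError("label vectors differ in length")
    n = len(a)
    if n == 0:
        raise PetasymError("empty label vectors")
    cats = sorted(set(a) | set(b))
    table = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    p = table.to_numpy(dtype=float) / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        raise PetasymError("degenerate marginals: kappa undefined (pe = 1)")
    kappa = (po - pe) / (1.0 - pe)
    se0 = float(np.sqrt(pe + pe ** 2 - np.sum(row * col * (row + col)))
                / ((1.0 - pe) * np.sqrt(n)))
    z = kappa / se0
    p_value = 2.0 * float(norm.sf(abs(z)))
    return KappaResult(po, pe, kappa, se0, z, p_value, table)


# -- cross-validation ----------------------------------------------------


def make_classifier(algo: str, params: dict | None = None):
    params = dict(params or {})
    if algo == "c45":
        return C45TreeClassifier(**params)
    if algo == "lmt":
        return LogisticModelTreeClassifier(**params)
    raise PetasymError(f"unknown algorithm {algo!r}; expected 'c45' or 'lmt'")


@dataclass
class CrossValResult:
    folds: list[np.ndarray]
    models: list
    per_run: list[Ratio]
    predictions: pd.Series  # per-subject out-of-fold prediction

    @property
    def run_ratios(self) -> list[float]:
        return [r.ratio for r in self.per_run]

    @property
    def mean_ratio(self) -> float:
        """Pooled correct lateralization ratio: total correct / cohort size."""
        return sum(r.correct for r in self.per_run) / sum(r.total for r in self.per_run)

    @property
    def mean_run_ratio(self) -> float:
        """Average of the per-run ratios (the run-averaging convention)."""
        return float(np.mean(self.run_ratios))


def cross_validate(table: pd.DataFrame, k: int = 5, algo="lmt",
                   params: dict | None = None, seed: int = 0) -> CrossValResult:
    """Stratified k-fold CV of a lateralization classifier.

    ``algo`` is "c45", "lmt", or an estimator instance to clone.  Each
    run trains on k-1 folds and predicts the held-out fold; per-run
    correct/total counts and the pooled mean ratio are returned.
    """
    X, y = split_xy(table)
    plan = make_folds(y, k, seed=seed, balance=True)
    base = algo if not isinstance(algo, str) else make_classifier(algo, params)
    models, per_run = [], []
    preds = pd.Series(index=range(len(y)), dtype=object)
    for fold in plan.folds:
        test_mask = np.zeros(len(y), dtype=bool)
        test_mask[np.asarray(fold, dtype=int)] = True
        clf = clone(base)
        clf.fit(X[~test_mask], y[~test_mask])
        yhat = clf.predict(X[test_mask])
        preds.iloc[np.flatnonzero(test_mask)] = yhat
        models.append(clf)
        per_run.append(correct_ratio(yhat, y[test_mask].to_numpy()))
    assert preds.notna().all()
    return CrossValResult(plan.folds, models, per_run, preds)
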