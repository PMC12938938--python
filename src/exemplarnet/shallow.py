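"""Shallow classification of the selected deep features.

Three classifiers with fixed, deliberately simple settings:

* kNN — k = 1, L1 (city-block) distance, unweighted voting. Implemented
  directly so that ties (equal distances, equal votes) resolve
  deterministically to the lowest training index.
* SVM — cubic polynomial kernel (x . z + 1)**3, box constraint C = 1,
  one-vs-one multiclass coding (scikit-learn SVC).
* LDA — Gaussian linear discriminant with shared covariance, no shrinkage
  (gamma = 0), empirical class priors; the SVD solver tolerates singular
  pooled covariance (pseudo-inverse behaviour).

Evaluation is either train -> test (fit on all training rows, predict the held
out split) or stratified 10-fold cross-validation, where every sample is
predicted exactly once by a model not trained on its fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError, InputError


@dataclass
class ClassifierSpec:
    """Settings for one of the three shallow classifiers."""

    kind: str = "knn"                 # knn | svm | lda
    knn_k: int = 1
    svm_c: float = 1.0
    svm_degree: int = 3
    svm_coef0: float = 1.0
    svm_gamma: float = 1.0
    lda_shrinkage: float = 0.0        # gamma = 0: no shrinkage

    def validate(self) -> None:
        if self.kind not in ("knn", "svm", "lda"):
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1:
            raise ConfigurationError("knn_k must be >= 1")
        if self.svm_c <= 0:
            raise ConfigurationError("svm box constraint C must be > 0")


@dataclass
class FoldPlan:
    """Stratified fold assignment: ``assignments[i]`` is the fold of sample i."""

    assignments: np.ndarray
    n_folds: int
    seed: int
    stratified: bool = True


@dataclass
class PredictionSet:
    """Aligned true/predicted labels from one classifier + evaluation mode."""

    y_true: np.ndarray
    y_pred: np.ndarray
    source: str = ""
    fold_accuracies: np.ndarray | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean(np.asarray(self.y_true) == np.asarray(self.y_pred)))


def _check_dims(train_X, test_X) -> None:
    if train_X.ndim != 2 or test_X.ndim != 2 or train_X.shape[1] != test_X.shape[1]:
        raise InputError(
            f"feature dimensions differ: train {train_X.shape}, test {test_X.shape}")


def knn_predict(train_X: np.ndarray, train_y, test_X: np.ndarray,
                spec: ClassifierSpec | None = None, test_y=None) -> PredictionSet:
    """k-nearest-neighbour prediction under the L1 metric.

    k = 1 returns the label of the nearest training row; larger k uses an
    unweighted majority vote. All ties (equal distance at k = 1, tied votes for
    k > 1) resolve to the neighbour appearing first in (distance, training
    index) order.
    """
    spec = spec or ClassifierSpec(kind="knn")
    spec.validate()
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise DataError("empty training set")
    _check_dims(train_X, test_X)
    D = cdist(test_X, train_X, metric="cityblock")
    if spec.knn_k == 1:
        pred = train_y[np.argmin(D, axis=1)]      # argmin: lowest index on ties
    else:
        k = min(spec.knn_k, train_X.shape[0])
        pred = np.empty(test_X.shape[0], dtype=train_y.dtype)
        for r in range(test_X.shape[0]):
            order = np.lexsort((np.arange(train_X.shape[0]), D[r]))[:k]
            labs = train_y[order]
            uniq, counts = np.unique(labs, return_counts=True)
            winners = set(uniq[counts == counts.max()])
            pred[r] = next(l for l in labs if l in winners)
    y_true = np.asarray(test_y) if test_y is not None else np.full(len(pred), None)
    return PredictionSet(y_true=y_true, y_pred=pred, source="knn/train->test")


def svm_train_predict(train_X: np.ndarray, train_y, test_X: np.ndarray,
                      spec: ClassifierSpec | None = None, test_y=None) -> PredictionSet:
    """One-vs-one SVMs with the cubic polynomial kernel (x . z + 1)**3, C = 1."""
    spec = spec or ClassifierSpec(kind="svm")
    spec.validate()
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    _check_dims(train_X, test_X)
    if np.unique(train_y).size < 2:
        raise DataError("SVM requires at least 2 classes in the training labels")
    clf = SVC(C=spec.svm_c, kernel="poly", degree=spec.svm_degree,
              gamma=spec.svm_gamma, coef0=spec.svm_coef0,
              decision_function_shape="ovo")
    clf.fit(train_X, train_y)
    pred = clf.predict(test_X)
    y_true = np.asarray(test_y) if test_y is not None else np.full(len(pred), None)
    return PredictionSet(y_true=y_true, y_pred=pred, source="svm/train->test")


def lda_train_predict(train_X: np.ndarray, train_y, test_X: np.ndarray,
                      spec: ClassifierSpec | None = None, test_y=None) -> PredictionSet:
    """Linear discriminant with shared covariance, empirical priors, gamma = 0.

    The SVD solver projects out zero-variance directions, so exactly collinear
    or duplicated feature columns fall back to pseudo-inverse behaviour instead
    of failing on a singular pooled covariance.
    """
    spec = spec or ClassifierSpec(kind="lda")
    spec.validate()
    train_X = np.asarray(train_X, dtype=np.float64)
    test_X = np.asarray(test_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    _check_dims(train_X, test_X)
    if np.unique(train_y).size < 2:
        raise DataError("LDA requires at least 2 classes in the training labels")
    clf = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*collinear.*")
        clf.fit(train_X, train_y)
        pred = clf.predict(test_X)
    y_true = np.asarray(test_y) if test_y is not None else np.full(len(pred), None)
    return PredictionSet(y_true=y_true, y_pred=pred, source="lda/train->test")


_CLASSIFIERS = {"knn": knn_predict, "svm": svm_train_predict, "lda": lda_train_predict}


def stratified_folds(y, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded stratified partition into ``n_folds``; per-class counts across
    folds differ by at most one.

    If some class has fewer samples than ``n_folds``, the fold count is reduced
    to that class size (best effort) with a warning.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    if n_folds > n:
        raise ConfigurationError(f"n_folds={n_folds} exceeds sample count {n}")
    _, counts = np.unique(y, return_counts=True)
    effective = n_folds
    if counts.min() < n_folds:
        effective = max(2, int(counts.min()))
        warnings.warn(
            f"smallest class has {counts.min()} samples < {n_folds} folds; "
            f"using {effective} folds")
    skf = StratifiedKFold(n_splits=effective, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y)):
        assignments[test_idx] = f
    return FoldPlan(assignments=assignments, n_folds=effective, seed=seed)


def cross_validate(X: np.ndarray, y, spec: ClassifierSpec,
                   plan: FoldPlan) -> PredictionSet:
    """Out-of-fold predictions: each sample predicted exactly once by a model
    that never saw its fold. Fold accuracies ride along on the result."""
    X = np.asarray(X)
    y = np.asarray(y)
    if plan.assignments.shape[0] != y.shape[0]:
        raise ConfigurationError("fold plan does not cover the label vector")
    spec.validate()
    predict = _CLASSIFIERS[spec.kind]
    y_pred = np.empty_like(y)
    fold_acc = []
    for f in np.unique(plan.assignments):
        test = plan.assignments == f
        train = ~test
        try:
            ps = predict(X[train], y[train], X[test], spec, test_y=y[test])
        except Exception as e:
            raise type(e)(f"fold {f}: {e}") from e
        y_pred[test] = ps.y_pred
        fold_acc.append(ps.accuracy)
    return PredictionSet(y_true=y.copy(), y_pred=y_pred,
                         source=f"{spec.kind}/cv{plan.n_folds}",
                         fold_accuracies=np.array(fold_acc))
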