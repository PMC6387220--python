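"""Classifier benchmark under stratified k-fold cross-validation.

The roster mirrors a standard WEKA-style comparison: Gaussian naive
Bayes, k-nearest neighbours (k = 1 or 7), a single-hidden-layer
multilayer perceptron, a pruned decision tree, a 100-tree random forest,
and SVMs with linear / cubic-polynomial / RBF kernels.  Performance is
summarised as the accuracy rate

    R = 100 * (TP + TN) / P

(which in the multiclass reading is 100 * trace(confusion) / total),
plus prevalence-weighted one-vs-rest sensitivity, specificity and area
under the ROC curve (WAUC).

Min-max normalisation to [0, 1], fitted on training folds only, is on by
default for the distance/margin/gradient models (knn, svm, mlp) and off
for trees and naive Bayes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datasets import Dataset

FAMILIES = ("naive_bayes", "knn", "mlp", "decision_tree", "random_forest", "svm")

#: Families that get train-fold min-max normalisation by default.
_NORMALIZED_FAMILIES = ("knn", "svm", "mlp")


# ---------------------------------------------------------------------------
# nearest-neighbour classifier with deterministic tie-breaking


def knn_predict(train_X: np.ndarray, train_y: Sequence, query: np.ndarray,
                k: int = 1, classes: Optional[Sequence] = None):
    """Majority-vote k-NN label for one query point.

    Euclidean distance; a vote tie is broken by the nearest neighbour
    among the tied classes, and a residual tie by canonical (sorted or
    supplied) class order.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= train_X.shape[0]:
        raise ValueError(f"k={k} outside [1, {train_X.shape[0]}]")
    order = list(classes) if classes is not None else sorted(set(train_y.tolist()))
    q = np.asarray(query, dtype=float).ravel()
    d = np.sqrt(np.sum((train_X - q) ** 2, axis=1))
    nn = np.argsort(d, kind="stable")[:k]
    votes = {}
    for idx in nn:
        votes[train_y[idx]] = votes.get(train_y[idx], 0) + 1
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    # nearest neighbour among the tied classes; exact distance ties fall
    # through to canonical class order
    best_dist = {c: min(d[idx] for idx in nn if train_y[idx] == c) for c in tied}
    min_dist = min(best_dist.values())
    closest = [c for c in tied if best_dist[c] == min_dist]
    return min(closest, key=order.index)


class KNNClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-compatible wrapper around :func:`knn_predict`.

    Exists so the benchmark's nearest-neighbour results follow the exact
    tie-breaking rule above; predict_proba returns vote fractions.
    """

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X, y):
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y)
        self.classes_ = np.array(sorted(set(self.y_.tolist())))
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([
            knn_predict(self.X_, self.y_, row, k=self.k,
                        classes=self.classes_.tolist())
            for row in X
        ])

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        proba = np.zeros((X.shape[0], self.classes_.size))
        class_pos = {c: i for i, c in enumerate(self.classes_.tolist())}
        for i, row in enumerate(X):
            d = np.sqrt(np.sum((self.X_ - row) ** 2, axis=1))
            nn = np.argsort(d, kind="stable")[: self.k]
            for idx in nn:
                proba[i, class_pos[self.y_[idx]]] += 1.0 / self.k
        return proba


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """One benchmark entry: classifier family plus its parameters.

    ``normalize=None`` means the family default (on for knn/svm/mlp).
    Parameter defaults re-express common WEKA-style settings explicitly:
    pruned tree with min leaf 2; 100-tree forest with sqrt(d) features per
    split; one hidden layer of (features+classes)/2 units trained 500
    epochs at learning rate 0.3, momentum 0.2; SVM C = 1, cubic
    polynomial, RBF gamma = 1/d; Gaussian class-conditional naive Bayes.
    """

    family: str
    params: dict = field(default_factory=dict)
    normalize: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.family == "knn" and self.params.get("k", 1) < 1:
            raise ValueError("knn k must be >= 1")
        if self.family == "svm" and self.params.get("kernel", "rbf") not in (
                "linear", "poly3", "rbf"):
            raise ValueError("svm kernel must be linear, poly3 or rbf")

    @property
    def normalized(self) -> bool:
        if self.normalize is not None:
            return self.normalize
        return self.family in _NORMALIZED_FAMILIES

    def describe(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.family}({inner})" if inner else self.family


def default_roster() -> List[ModelSpec]:
    """The full benchmark roster."""
    return [
        ModelSpec("naive_bayes"),
        ModelSpec("knn", {"k": 1}),
        ModelSpec("knn", {"k": 7}),
        ModelSpec("mlp"),
        ModelSpec("decision_tree"),
        ModelSpec("random_forest"),
        ModelSpec("svm", {"kernel": "linear"}),
        ModelSpec("svm", {"kernel": "poly3"}),
        ModelSpec("svm", {"kernel": "rbf"}),
    ]


def make_estimator(spec: ModelSpec, n_features: int, n_classes: int, seed: int = 0):
    """Instantiate the sklearn (or in-package knn) estimator for a spec."""
    fam = spec.family
    if fam == "naive_bayes":
        est = GaussianNB()
    elif fam == "knn":
        est = KNNClassifier(k=spec.params.get("k", 1))
    elif fam == "mlp":
        hidden = max((n_features + n_classes) // 2, 2)
        est = MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=500,
                            solver="sgd", learning_rate_init=0.3, momentum=0.2,
                            random_state=seed)
    elif fam == "decision_tree":
        est = DecisionTreeClassifier(min_samples_leaf=2, random_state=seed)
    elif fam == "random_forest":
        est = RandomForestClassifier(n_estimators=100, max_features="sqrt",
                                     random_state=seed)
    else:
        kernel = spec.params.get("kernel", "rbf")
        kw = dict(C=1.0, random_state=seed)
        if kernel == "linear":
            est = SVC(kernel="linear", **kw)
        elif kernel == "poly3":
            est = SVC(kernel="poly", degree=3, gamma="scale", **kw)
        else:
            est = SVC(kernel="rbf", gamma=1.0 / n_features, **kw)
    if spec.normalized:
        return Pipeline([("minmax", MinMaxScaler()), ("clf", est)])
    return est


# ---------------------------------------------------------------------------
# metrics


def accuracy(confusion: np.ndarray) -> float:
    """Accuracy rate in percent from a confusion matrix.

    For the binary 2x2 case this is exactly 100*(TP+TN)/P; the multiclass
    reading generalises to 100 * trace / total.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
        raise ValueError("confusion must be a non-empty square matrix")
    if np.any(c < 0):
        raise ValueError("confusion entries must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(c)) / float(total)


def per_class_metrics(confusion: np.ndarray, classes: Sequence,
                      y_true: Optional[np.ndarray] = None,
                      scores: Optional[np.ndarray] = None):
    """Prevalence-weighted one-vs-rest sensitivity, specificity and WAUC.

    ``scores`` holds per-class membership scores aligned with ``y_true``
    and the class order; when absent, the ROC is built from the hard 0/1
    assignments implied by the confusion matrix, in which case each
    class's AUC reduces to (sensitivity + specificity) / 2.
    """
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    sens = np.zeros(len(classes))
    spec = np.zeros(len(classes))
    weights = c.sum(axis=1) / n
    for i, cls in enumerate(classes):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn == 0:
            raise ValueError(f"class {cls!r} absent from the test folds")
        sens[i] = tp / (tp + fn)
        spec[i] = tn / (tn + fp) if (tn + fp) > 0 else 0.0
    sensitivity = float(np.dot(weights, sens))
    specificity = float(np.dot(weights, spec))
    if scores is not None and y_true is not None:
        aucs = np.array([
            roc_auc_score((np.asarray(y_true) == cls).astype(int), scores[:, i])
            for i, cls in enumerate(classes)
        ])
        wauc = float(np.dot(weights, aucs))
    else:
        wauc = float(np.dot(weights, (sens + spec) / 2.0))
    return sensitivity, specificity, wauc


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one model spec."""

    spec: ModelSpec
    fold_confusions: List[np.ndarray]
    fold_accuracies: List[float]
    accuracy_pct: float
    sensitivity: float
    specificity: float
    wauc: float
    classes: tuple
    seed: int
    k_folds: int

    @property
    def confusion(self) -> np.ndarray:
        return np.sum(self.fold_confusions, axis=0)

    def summary(self) -> str:
        return (
            f"{self.spec.describe():<28} acc {self.accuracy_pct:6.2f}%  "
            f"wauc {self.wauc:.3f}  sens {self.sensitivity:.3f}  "
            f"spec {self.specificity:.3f}  ({self.k_folds}-fold, seed {self.seed})"
        )


def _membership_scores(est, X, classes):
    """Per-class score matrix in the given class order."""
    fitted_classes = list(est.classes_) if hasattr(est, "classes_") else None
    if isinstance(est, Pipeline):
        fitted_classes = list(est[-1].classes_)
    if hasattr(est, "predict_proba"):
        raw = est.predict_proba(X)
    elif hasattr(est, "decision_function"):
        raw = est.decision_function(X)
        if raw.ndim == 1:  # binary margin -> two columns
            raw = np.column_stack([-raw, raw])
    else:
        pred = est.predict(X)
        raw = np.array([[1.0 if p == c else 0.0 for c in fitted_classes]
                        for p in pred])
    cols = [fitted_classes.index(c) for c in classes]
    return np.asarray(raw, dtype=float)[:, cols]


def crossval(dataset: Dataset, spec: ModelSpec, k_folds: int = 10,
             seed: int = 0) -> CVResult:
    """Stratified k-fold cross-validation of one model on one dataset.

    Folds come from a seeded shuffle; every instance is tested exactly
    once; normalisation (when the spec uses it) is fitted on training
    folds only.
    """
    X, y = dataset.X, dataset.y
    classes = dataset.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c, cnt in counts.items():
        if cnt < k_folds:
            raise ValueError(f"class {c!r} has {cnt} instances < {k_folds} folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_confusions: List[np.ndarray] = []
    fold_accs: List[float] = []
    all_true: List = []
    all_scores: List[np.ndarray] = []
    pos = {c: i for i, c in enumerate(classes)}
    for train_idx, test_idx in skf.split(X, y):
        est = make_estimator(spec, X.shape[1], len(classes), seed=seed)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y[test_idx], pred):
            cm[pos[t], pos[p]] += 1
        fold_confusions.append(cm)
        fold_accs.append(accuracy(cm))
        all_true.extend(y[test_idx])
        all_scores.append(_membership_scores(est, X[test_idx], classes))
    total = np.sum(fold_confusions, axis=0)
    scores = np.vstack(all_scores)
    sens, specf, wauc = per_class_metrics(total, classes,
                                          y_true=np.array(all_true), scores=scores)
    return CVResult(spec=spec, fold_confusions=fold_confusions,
                    fold_accuracies=fold_accs, accuracy_pct=accuracy(total),
                    sensitivity=sens, specificity=specf, wauc=wauc,
                    classes=tuple(classes), seed=seed, k_folds=k_folds)


def resubstitution_accuracy(dataset: Dataset, spec: ModelSpec, seed: int = 0) -> float:
    """Training-set accuracy (fit and evaluate on all instances), percent."""
    X, y = dataset.X, dataset.y
    classes = dataset.classes
    est = make_estimator(spec, X.shape[1], len(classes), seed=seed)
    est.fit(X, y)
    pred = est.predict(X)
    return 100.0 * float(np.mean(pred == y))
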