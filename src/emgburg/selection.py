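"""Dimensionality reduction: sequential wrappers, CFS and PCA.

Four procedures:

* ``plus_l_take_away_r`` — start from all features (l = d, r = 0) and
  repeatedly remove the feature whose removal least hurts a wrapper
  evaluator; a removal that would drop the score below the initial
  reference minus a tolerance is undone and the search stops.
* ``forward_selection`` — start from a (possibly seeded) small set and
  greedily add the best-improving feature; additions that do not improve
  are rejected and the search stops.
* ``cfs_subset_eval`` — correlation-based subset selection: best-first
  search maximising the merit  k r_cf / sqrt(k + k (k-1) r_ff), which
  rewards feature-class correlation and penalises inter-feature
  correlation.
* ``pca_transform`` — principal components retaining a requested fraction
  of total variance.

The default wrapper evaluator is 1-nearest-neighbour accuracy under
seeded stratified 10-fold cross-validation, the reference classifier of
the benchmark.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .bench import ModelSpec, crossval
from .datasets import Dataset

Evaluator = Callable[[Dataset], float]


@dataclass(frozen=True)
class SelectionConfig:
    """Sequential-selection settings; tolerance is the allowed score drop."""

    tolerance: float = 0.0
    evaluator_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selection procedure.

    ``trace`` records one row per accepted step: the l/r counters, the
    feature moved, and the evaluator score after the step.
    """

    selected: List[str]
    trace: pd.DataFrame
    evaluator_spec: str

    def trace_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)


def make_cv_evaluator(spec: Optional[ModelSpec] = None, k_folds: int = 10,
                      seed: int = 0) -> Evaluator:
    """Wrapper criterion: CV accuracy (fraction) of a classifier.

    Folds are clamped to the smallest class count so the evaluator stays
    defined on small datasets.
    """
    spec = spec or ModelSpec("knn", {"k": 1})

    def evaluate(dataset: Dataset) -> float:
        counts = [int(np.sum(dataset.y == c)) for c in dataset.classes]
        folds = max(2, min(k_folds, min(counts)))
        return crossval(dataset, spec, k_folds=folds, seed=seed).accuracy_pct / 100.0

    evaluate.description = f"{spec.describe()} / {k_folds}-fold CV (seed {seed})"
    return evaluate


def plus_l_take_away_r(dataset: Dataset, evaluator: Optional[Evaluator] = None,
                       cfg: SelectionConfig = SelectionConfig()) -> SelectionResult:
    """Backward sequential elimination with a reinstatement rule.

    Never returns a feature set whose evaluator score falls below the
    initial (all-features) score minus ``cfg.tolerance``.  Score ties
    between candidate removals are broken towards the feature later in
    canonical column order, keeping the procedure deterministic.
    """
    evaluator = evaluator or make_cv_evaluator(k_folds=cfg.evaluator_folds,
                                               seed=cfg.seed)
    all_features = list(dataset.feature_names)
    remaining = list(all_features)
    reference = evaluator(dataset)
    rows = [{"l": len(remaining), "r": 0, "feature": "", "action": "start",
             "score": reference}]
    while len(remaining) > 1:
        best_feature = None
        best_score = -np.inf
        for f in remaining:  # later canonical position wins ties
            trial = [g for g in remaining if g != f]
            score = evaluator(dataset.select(trial))
            if score >= best_score:
                best_score, best_feature = score, f
        if best_score < reference - cfg.tolerance:
            break  # best removal already hurts: reinstate and stop
        remaining.remove(best_feature)
        rows.append({"l": len(remaining), "r": len(all_features) - len(remaining),
                     "feature": best_feature, "action": "removed",
                     "score": best_score})
    return SelectionResult(selected=remaining, trace=pd.DataFrame(rows),
                           evaluator_spec=getattr(evaluator, "description", "custom"))


def forward_selection(dataset: Dataset, evaluator: Optional[Evaluator] = None,
                      seed_features: Sequence[str] = (),
                      cfg: SelectionConfig = SelectionConfig(),
                      candidate_pool: Optional[Sequence[str]] = None) -> SelectionResult:
    """Greedy forward wrapper selection from a seeded feature set.

    ``candidate_pool`` restricts which features may be added (the seeds
    are always kept).  Ties between candidate additions are broken
    towards the earlier feature in canonical column order.
    """
    evaluator = evaluator or make_cv_evaluator(k_folds=cfg.evaluator_folds,
                                               seed=cfg.seed)
    missing = [f for f in seed_features if f not in dataset.feature_names]
    if missing:
        raise KeyError(f"seed features not in dataset: {missing}")
    selected = list(seed_features)
    pool = [f for f in (candidate_pool or dataset.feature_names)
            if f not in selected]
    current = evaluator(dataset.select(selected)) if selected else -np.inf
    rows = [{"l": len(selected), "r": 0, "feature": ",".join(selected) or "",
             "action": "seed", "score": current if selected else np.nan}]
    while pool:
        best_feature = None
        best_score = -np.inf
        for f in pool:  # earlier canonical position wins ties
            score = evaluator(dataset.select(selected + [f]))
            if score > best_score:
                best_score, best_feature = score, f
        if best_score <= current:
            break  # no candidate improves: reject the addition and stop
        selected.append(best_feature)
        pool.remove(best_feature)
        current = best_score
        rows.append({"l": len(selected), "r": 0, "feature": best_feature,
                     "action": "added", "score": best_score})
    return SelectionResult(selected=selected, trace=pd.DataFrame(rows),
                           evaluator_spec=getattr(evaluator, "description", "custom"))


# ---------------------------------------------------------------------------
# correlation-based subset selection


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _class_correlations(X: np.ndarray, y: np.ndarray, classes: Sequence) -> np.ndarray:
    """Per-feature class correlation: prevalence-weighted mean |Pearson r|
    against one-vs-rest class indicators."""
    out = np.zeros(X.shape[1])
    for c in classes:
        ind = (y == c).astype(float)
        w = ind.mean()
        for j in range(X.shape[1]):
            out[j] += w * abs(_safe_pearson(X[:, j], ind))
    return out


def cfs_merit(dataset: Dataset, subset: Sequence[str],
              _cache: Optional[dict] = None) -> float:
    """CFS merit of a feature subset: k r_cf / sqrt(k + k (k-1) r_ff)."""
    k = len(subset)
    if k == 0:
        return 0.0
    cols = [dataset.feature_names.index(f) for f in subset]
    X = dataset.X
    y = dataset.y
    if _cache is not None and "rcf" in _cache:
        rcf_all = _cache["rcf"]
    else:
        rcf_all = _class_correlations(X, y, dataset.classes)
        if _cache is not None:
            _cache["rcf"] = rcf_all
    r_cf = float(np.mean(rcf_all[cols]))
    if k == 1:
        return r_cf
    r_ff_vals = []
    for i in range(k):
        for j in range(i + 1, k):
            r_ff_vals.append(abs(_safe_pearson(X[:, cols[i]], X[:, cols[j]])))
    r_ff = float(np.mean(r_ff_vals))
    return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def cfs_subset_eval(dataset: Dataset, max_stale: int = 20) -> SelectionResult:
    """Best-first forward search over subsets scored by the CFS merit.

    The search stops after ``max_stale`` consecutive expansions without a
    new best merit.
    """
    if dataset.n_features < 1:
        raise ValueError("need at least one feature")
    names = dataset.feature_names
    cache: dict = {}
    best_subset: frozenset = frozenset()
    best_merit = 0.0
    visited = {frozenset()}
    counter = 0  # heap tie-breaker keeps ordering deterministic
    heap = [(-0.0, counter, frozenset())]
    stale = 0
    rows = []
    while heap and stale <= max_stale:
        _, _, subset = heapq.heappop(heap)
        improved = False
        for f in names:
            if f in subset:
                continue
            child = subset | {f}
            if child in visited:
                continue
            visited.add(child)
            merit = cfs_merit(dataset, sorted(child, key=names.index), cache)
            counter += 1
            heapq.heappush(heap, (-merit, counter, child))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
                rows.append({"l": len(child), "r": 0,
                             "feature": ",".join(sorted(child, key=names.index)),
                             "action": "best", "score": merit})
        stale = 0 if improved else stale + 1
    selected = sorted(best_subset, key=names.index)
    return SelectionResult(selected=selected, trace=pd.DataFrame(rows),
                           evaluator_spec="CFS merit / best-first")


def pca_transform(dataset: Dataset, variance_retained: float = 0.95,
                  standardize: bool = True) -> Dataset:
    """Project onto principal components retaining the requested variance.

    Features are standardised to unit variance first by default (the
    blocks mix amplitude units with counts); components are ordered by
    decreasing explained variance and named PC1, PC2, ...
    """
    if len(dataset) < 2:
        raise ValueError("PCA needs at least 2 instances")
    if not (0 < variance_retained <= 1.0):
        raise ValueError("variance_retained must lie in (0, 1]")
    X = dataset.X
    if standardize:
        X = StandardScaler().fit_transform(X)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if variance_retained == 1.0:
        pca = PCA(n_components=max_rank)
    else:
        pca = PCA(n_components=variance_retained, svd_solver="full")
    Z = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(Z.shape[1])]
    return Dataset(features=pd.DataFrame(Z, columns=cols),
                   labels=dataset.labels.reset_index(drop=True),
                   subjects=dataset.subjects.reset_index(drop=True),
                   trials=dataset.trials.reset_index(drop=True),
                   variant="PC")
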