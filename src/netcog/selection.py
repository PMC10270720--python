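"""Feature selection: univariate filters, L1 sparsity, and a sequential
forward floating selection (SFFS) wrapper.

All selection is computed on training data only; the benchmark engine is
responsible for calling it inside the cross-validation loop.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin, f_classif, mutual_info_classif
from sklearn.model_selection import StratifiedKFold, KFold, cross_val_score
from sklearn.svm import LinearSVC

FS_METHODS = (
    "none",
    "anova_f_top10",
    "mutual_info_top10",
    "l1_linear_svm",
    "hybrid_anova50_sffs10",
    "corr_top10",
    "embedded",
)

__all__ = ["FS_METHODS", "select_features", "sffs", "SequentialFloatingSelector"]


def _top_fraction(scores: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the top ``fraction`` of features by score (ceil count,
    ties broken toward the lowest index via stable sort)."""
    scores = np.nan_to_num(np.asarray(scores, dtype=float), nan=-np.inf)
    k = max(1, math.ceil(fraction * len(scores)))
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


def _corr_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(r)


def sffs(
    scorer: Callable[[tuple[int, ...]], float],
    n_candidates: int | Sequence[int],
    k: int,
    floating: bool = True,
) -> list[int]:
    """Sequential forward floating selection over feature indices.

    Greedy forward additions; after each addition, conditional backward
    exclusions are attempted while they improve on the best score recorded
    for the smaller subset size.  ``scorer`` maps a sorted tuple of indices
    to a scalar (higher is better); ties break toward the lowest index.
    Deterministic given a deterministic scorer.
    """
    candidates = (
        list(range(n_candidates)) if isinstance(n_candidates, int) else list(n_candidates)
    )
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidates")
    cache: dict[tuple[int, ...], float] = {}

    def score(subset: Sequence[int]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = float(scorer(key))
        return cache[key]

    selected: list[int] = []
    best_at_size: dict[int, float] = {}
    while len(selected) < k:
        # forward step
        best_f, best_s = None, -np.inf
        for f in candidates:
            if f in selected:
                continue
            s = score(selected + [f])
            if s > best_s or (s == best_s and (best_f is None or f < best_f)):
                best_f, best_s = f, s
        selected.append(best_f)
        size = len(selected)
        best_at_size[size] = max(best_at_size.get(size, -np.inf), best_s)
        # floating backward steps
        if floating:
            improved = True
            while improved and len(selected) > 2:
                improved = False
                best_r, best_rs = None, -np.inf
                for f in selected[:-1]:  # never remove the one just added
                    trial = [g for g in selected if g != f]
                    s = score(trial)
                    if s > best_rs or (s == best_rs and (best_r is None or f < best_r)):
                        best_r, best_rs = f, s
                target = best_at_size.get(len(selected) - 1, -np.inf)
                if best_r is not None and best_rs > target:
                    selected.remove(best_r)
                    best_at_size[len(selected)] = best_rs
                    improved = True
    return selected


def cv_subset_scorer(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    scoring: str,
    n_splits: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> Callable[[tuple[int, ...]], float]:
    """Internal-CV scorer for SFFS: mean CV score of the estimator on a
    feature subset of the training data."""
    cv = (
        StratifiedKFold(n_splits, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits, shuffle=True, random_state=seed)
    )

    def scorer(subset: tuple[int, ...]) -> float:
        return float(
            np.mean(
                cross_val_score(
                    clone(estimator), X[:, list(subset)], y, cv=cv, scoring=scoring
                )
            )
        )

    return scorer


def select_features(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    task: str = "classification",
    estimator=None,
    seed: int = 0,
) -> np.ndarray:
    """Training-fold feature selection; returns sorted selected indices.

    anova_f_top10 / mutual_info_top10 (classification) and corr_top10
    (regression) keep the top ceil(10%) by score; l1_linear_svm keeps the
    nonzero-coefficient features of an L1-penalized linear SVM;
    hybrid_anova50_sffs10 keeps the top 50% by ANOVA F then runs SFFS down
    to exactly 10 features with the wrapped estimator; embedded and none
    pass everything through.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    if method in ("none", "embedded"):
        return np.arange(d)
    if method == "corr_top10":
        if task != "regression":
            raise ValueError("corr_top10 is a regression-only filter")
        return _top_fraction(_corr_scores(X, y.astype(float)), 0.10)
    if task != "classification":
        raise ValueError(f"{method} is a classification-only method")
    if method == "anova_f_top10":
        F, _ = f_classif(X, y)
        return _top_fraction(F, 0.10)
    if method == "mutual_info_top10":
        mi = mutual_info_classif(X, y, random_state=seed)
        return _top_fraction(mi, 0.10)
    if method == "l1_linear_svm":
        svm = LinearSVC(penalty="l1", dual=False, max_iter=5000, random_state=seed)
        svm.fit(X, y)
        coef = np.abs(svm.coef_).max(axis=0)
        idx = np.where(coef > 1e-10)[0]
        if idx.size == 0:  # degenerate: keep the strongest single feature
            idx = np.array([int(np.argmax(coef))])
        return idx
    if method == "hybrid_anova50_sffs10":
        F, _ = f_classif(X, y)
        pool = _top_fraction(F, 0.50)
        k = min(10, pool.size)
        if estimator is None:
            raise ValueError("hybrid selection needs a wrapped estimator")
        scorer = cv_subset_scorer(
            estimator, X, y, scoring="balanced_accuracy", seed=seed
        )
        chosen = sffs(lambda s: scorer(s), list(pool), k)
        return np.sort(np.asarray(chosen))
    raise ValueError(f"unknown feature-selection method {method!r}")


class SequentialFloatingSelector(SelectorMixin, BaseEstimator):
    """sklearn-compatible SFFS selector.

    Wraps :func:`sffs` with an internal-CV scorer of ``estimator`` on the
    training data; exposes get_support()/transform like any sklearn
    selector.
    """

    def __init__(
        self,
        estimator=None,
        k: int = 10,
        scoring: str = "balanced_accuracy",
        cv: int = 5,
        floating: bool = True,
        seed: int = 0,
    ):
        self.estimator = estimator
        self.k = k
        self.scoring = scoring
        self.cv = cv
        self.floating = floating
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        stratified = self.scoring != "r2"
        scorer = cv_subset_scorer(
            self.estimator, X, y, self.scoring, self.cv, self.seed, stratified
        )
        chosen = sffs(scorer, X.shape[1], self.k, floating=self.floating)
        self.n_features_in_ = X.shape[1]
        self.selected_ = np.sort(np.asarray(chosen))
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
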