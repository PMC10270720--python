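"""Leakage-safe ML benchmarking engine.

Repeated (nested) cross-validation over a configuration grid: algorithm x
feature selection x hyperparameter optimization x deconfounding mode x
feature set x sample, with a dummy reference model fitted on every
training fold and a >80% fold-win rule flagging robust outperformance.

Every fitted transform — unit-variance scaler, confound regression,
feature selection, grid search — is a function of the outer-training fold
only.  An intentionally leaky mode (selection on the full data before CV)
exists solely to demonstrate the inflation it causes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from sklearn.model_selection import (
    RepeatedKFold,
    RepeatedStratifiedKFold,
    cross_val_score,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

from .deconfound import DECONFOUND_MODES, deconfound
from .selection import FS_METHODS, select_features

CLASSIFIERS = (
    "svm_linear",
    "svm_rbf",
    "svm_poly",
    "knn",
    "decision_tree",
    "naive_bayes",
    "lda",
)
REGRESSORS = ("svr", "kernel_ridge_rvr_substitute", "ridge", "lasso", "elastic_net")

__all__ = [
    "PipelineConfig",
    "CVScheme",
    "CVResult",
    "enumerate_configs",
    "default_classification_space",
    "default_regression_space",
    "make_estimator",
    "hyperparameter_grid",
    "grid_search",
    "classification_metrics",
    "regression_metrics",
    "dummy_baseline",
    "evaluate",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One fully specified benchmarking pipeline."""

    task: str = "classification"
    algorithm: str = "svm_linear"
    fs_method: str = "none"
    hpo: bool = False
    deconfound: str = "nr"
    feature_set: str = "strength_plus_network"
    sample: str = "full"
    target: str = "PC1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        valid_alg = CLASSIFIERS if self.task == "classification" else REGRESSORS
        if self.algorithm not in valid_alg:
            raise ValueError(f"{self.algorithm!r} invalid for {self.task}")
        if self.fs_method not in FS_METHODS:
            raise ValueError(f"unknown fs_method {self.fs_method!r}")
        if self.deconfound not in DECONFOUND_MODES:
            raise ValueError(f"unknown deconfound mode {self.deconfound!r}")
        if self.task == "classification":
            if self.fs_method == "corr_top10":
                raise ValueError("corr_top10 is regression-only")
            if self.deconfound in ("nr_cr", "cr_cr"):
                raise ValueError("classification deconfounding is nr or cr")
            if self.fs_method == "embedded":
                raise ValueError("embedded selection is regression-only")
        else:
            if self.fs_method in (
                "anova_f_top10",
                "mutual_info_top10",
                "l1_linear_svm",
                "hybrid_anova50_sffs10",
            ):
                raise ValueError(f"{self.fs_method} is classification-only")
            if self.deconfound == "cr":
                raise ValueError("regression deconfounding is nr, nr_cr or cr_cr")
            if self.fs_method == "embedded" and self.algorithm not in (
                "lasso",
                "elastic_net",
            ):
                raise ValueError("embedded selection needs lasso/elastic_net")


@dataclass(frozen=True)
class CVScheme:
    """Repeated (nested) CV layout: 10 folds x 5 repeats by default."""

    outer_folds: int = 10
    outer_repeats: int = 5
    inner_folds: int = 10
    inner_repeats: int = 5
    stratified: bool = True
    seed: int = 0


def enumerate_configs(space: dict) -> list[PipelineConfig]:
    """Deterministic Cartesian product of the declared axes minus invalid
    combinations (validated by PipelineConfig)."""
    axes = {
        "task": space.get("task", ["classification"]),
        "algorithm": space["algorithm"],
        "fs_method": space.get("fs_method", ["none"]),
        "hpo": space.get("hpo", [False]),
        "deconfound": space.get("deconfound", ["nr"]),
        "feature_set": space.get("feature_set", ["strength_plus_network"]),
        "sample": space.get("sample", ["full"]),
        "target": space.get("target", ["PC1"]),
    }
    configs = []
    for combo in itertools.product(*axes.values()):
        kw = dict(zip(axes.keys(), combo))
        try:
            configs.append(PipelineConfig(**kw))
        except ValueError:
            continue
    if not configs:
        raise ValueError("configuration space is empty")
    return configs


def default_classification_space() -> dict:
    return {
        "task": ["classification"],
        "algorithm": list(CLASSIFIERS),
        "fs_method": [
            "none",
            "anova_f_top10",
            "mutual_info_top10",
            "l1_linear_svm",
            "hybrid_anova50_sffs10",
        ],
        "hpo": [False, True],
        "deconfound": ["nr", "cr"],
    }


def default_regression_space() -> dict:
    return {
        "task": ["regression"],
        "algorithm": list(REGRESSORS),
        "fs_method": ["none", "corr_top10", "embedded"],
        "hpo": [False, True],
        "deconfound": ["nr", "nr_cr", "cr_cr"],
    }


def make_estimator(algorithm: str, seed: int = 0, **params):
    """Instantiate a named algorithm with library defaults plus overrides.

    ``kernel_ridge_rvr_substitute`` stands in for relevance vector
    regression: an RBF kernel ridge — same kernel-regression family,
    without the sparse Bayesian evidence maximization.
    """
    factories = {
        "svm_linear": lambda: SVC(kernel="linear", random_state=seed),
        "svm_rbf": lambda: SVC(kernel="rbf", random_state=seed),
        "svm_poly": lambda: SVC(kernel="poly", random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "naive_bayes": lambda: GaussianNB(),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "svr": lambda: SVR(),
        "kernel_ridge_rvr_substitute": lambda: KernelRidge(kernel="rbf"),
        "ridge": lambda: Ridge(),
        "lasso": lambda: Lasso(),
        "elastic_net": lambda: ElasticNet(),
    }
    if algorithm not in factories:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    est = factories[algorithm]()
    if params:
        est.set_params(**params)
    return est


def hyperparameter_grid(algorithm: str) -> list[dict]:
    """The declared tuning grid per algorithm, ordered so that stronger
    regularization (smaller C, larger penalty) comes first — the grid-search
    tie-break preference."""
    C = np.logspace(-4, 1, 10)
    ridge_lam = np.logspace(-3, 5, 10)[::-1]
    sparse_lam = np.logspace(-1, 2, 10)[::-1]
    alpha_mix = np.linspace(0.0, 1.0, 10)
    grids: dict[str, list[dict]] = {
        "svm_linear": [{"C": c} for c in C],
        "svm_rbf": [{"C": c} for c in C],
        "svm_poly": [{"C": c} for c in C],
        "knn": [{"n_neighbors": k} for k in range(1, 26, 2)],
        "decision_tree": [
            {"max_depth": d, "criterion": c}
            for d in (4, 6, 8, 10, 20, 40, None)
            for c in ("gini", "entropy")
        ],
        "naive_bayes": [],
        "lda": [],
        "svr": [{"C": c, "kernel": k} for c in C for k in ("linear", "rbf", "poly")],
        "ridge": [{"alpha": lam} for lam in ridge_lam],
        "lasso": [{"alpha": lam} for lam in sparse_lam],
        "elastic_net": [
            {"alpha": lam, "l1_ratio": a} for lam in sparse_lam for a in alpha_mix
        ],
        "kernel_ridge_rvr_substitute": [],
    }
    return grids[algorithm]


def grid_search(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    scheme: CVScheme,
    task: str,
    seed: int = 0,
) -> dict:
    """Exhaustive inner-loop grid search.

    Scores every grid point by mean inner repeated-CV balanced accuracy
    (classification) or R^2 (regression); the first-encountered maximum
    wins, and the grids are ordered so ties resolve toward stronger
    regularization / smaller complexity.
    """
    grid = hyperparameter_grid(algorithm)
    if not grid:
        return {}
    if task == "classification":
        cv = RepeatedStratifiedKFold(
            n_splits=scheme.inner_folds,
            n_repeats=scheme.inner_repeats,
            random_state=seed,
        )
        scoring = "balanced_accuracy"
    else:
        cv = RepeatedKFold(
            n_splits=scheme.inner_folds,
            n_repeats=scheme.inner_repeats,
            random_state=seed,
        )
        scoring = "r2"
    best_params, best_score = {}, -np.inf
    for params in grid:
        est = make_estimator(algorithm, seed=seed, **params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(est, X, y, cv=cv, scoring=scoring, error_score=-np.inf)
        mean = float(np.mean(scores))
        if mean > best_score:
            best_params, best_score = params, mean
    return best_params


def classification_metrics(truth, predicted) -> dict:
    """Sensitivity, specificity and balanced accuracy for binary labels
    (positive class = the lexicographically larger label)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    classes = np.unique(truth)
    if classes.size != 2:
        return {"bac": np.nan, "sensitivity": np.nan, "specificity": np.nan,
                "flag": "missing class in truth"}
    neg, pos = classes
    tp = np.sum((truth == pos) & (predicted == pos))
    fn = np.sum((truth == pos) & (predicted != pos))
    tn = np.sum((truth == neg) & (predicted == neg))
    fp = np.sum((truth == neg) & (predicted != neg))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {"bac": (sens + spec) / 2.0, "sensitivity": sens, "specificity": spec}


def regression_metrics(truth, predicted) -> dict:
    """MAE and test-fold R^2 (1 - SSres/SStot; can be negative)."""
    truth = np.asarray(truth, float)
    predicted = np.asarray(predicted, float)
    if truth.size < 2:
        raise ValueError("need at least 2 observations")
    mae = float(np.mean(np.abs(truth - predicted)))
    sstot = float(np.sum((truth - truth.mean()) ** 2))
    if sstot == 0:
        return {"mae": mae, "r2": np.nan, "flag": "zero-variance truth"}
    r2 = 1.0 - float(np.sum((truth - predicted) ** 2)) / sstot
    return {"mae": mae, "r2": r2}


def dummy_baseline(task: str):
    """Reference model: majority train class / train-mean predictor."""
    if task == "classification":
        return DummyClassifier(strategy="most_frequent")
    return DummyRegressor(strategy="mean")


@dataclass
class CVResult:
    """Per-fold and aggregate benchmark outcome for one config."""

    config: PipelineConfig
    folds: pd.DataFrame  # one row per outer fold, model + dummy metrics
    aggregate: dict
    dummy_win_fraction: float
    robust: bool
    selected_features: list = field(default_factory=list)
    chosen_params: list = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = None
        if "n_folds" in self.aggregate:
            expected = self.aggregate["n_folds"]
        if expected is not None and len(self.folds) != expected:
            raise ValueError("fold count inconsistent with aggregate")


def _scale_train_test(X_train: np.ndarray, X_test: np.ndarray):
    """Unit-variance scaling with statistics from the training block only;
    constant training features map to zero in both blocks."""
    scaler = StandardScaler()
    Xt = scaler.fit_transform(X_train)
    Xs = scaler.transform(X_test)
    zero_var = np.isclose(np.asarray(X_train).std(axis=0), 0.0)
    if zero_var.any():
        Xt[:, zero_var] = 0.0
        Xs[:, zero_var] = 0.0
    return Xt, Xs, scaler


def evaluate(
    config: PipelineConfig,
    X,
    y,
    confounds=None,
    scheme: CVScheme | None = None,
    leaky_selection: bool = False,
) -> CVResult:
    """Run one config through repeated (nested) cross-validation.

    Per outer fold: unit-variance scaling -> deconfounding -> feature
    selection -> (inner-loop grid search if hpo) -> fit/predict -> metrics,
    plus a dummy baseline fit on the same training fold.  The fold-level
    model-vs-dummy comparison uses BAC (classification) or R^2
    (regression) with strict inequality; the robust flag requires wins in
    more than 80% of folds.

    ``leaky_selection=True`` deliberately performs feature selection on
    the full data before CV — only for demonstrating leakage inflation.
    """
    scheme = scheme or CVScheme(seed=config.seed)
    X = np.asarray(X, dtype=float)
    y_arr = np.asarray(y)
    C = None if confounds is None else np.asarray(confounds, dtype=float)
    if config.deconfound != "nr" and C is None:
        raise ValueError("deconfounding requested but no confounds given")
    task = config.task
    if task == "classification":
        classes, y_codes = np.unique(y_arr, return_inverse=True)
        if classes.size != 2:
            raise ValueError("classification expects exactly 2 classes")
        y_work: np.ndarray = y_codes
        splitter = RepeatedStratifiedKFold(
            n_splits=scheme.outer_folds,
            n_repeats=scheme.outer_repeats,
            random_state=scheme.seed,
        )
        key = "bac"
    else:
        y_work = y_arr.astype(float)
        splitter = RepeatedKFold(
            n_splits=scheme.outer_folds,
            n_repeats=scheme.outer_repeats,
            random_state=scheme.seed,
        )
        key = "r2"

    global_sel = None
    if leaky_selection:
        global_sel = select_features(
            config.fs_method, X, y_work, task=task, seed=config.seed,
            estimator=make_estimator(config.algorithm, seed=config.seed),
        )

    rows, selected_all, params_all = [], [], []
    for fold_id, (tr, te) in enumerate(splitter.split(X, y_work)):
        X_tr, X_te, _ = _scale_train_test(X[tr], X[te])
        y_tr, y_te = y_work[tr], y_work[te]
        if config.deconfound != "nr":
            X_tr, y_tr, X_te, y_te = deconfound(
                X_tr, y_tr, X_te, y_te, C[tr], C[te], mode=config.deconfound
            )
        if global_sel is not None:
            sel = global_sel
        else:
            sel = select_features(
                config.fs_method, X_tr, y_tr, task=task, seed=config.seed,
                estimator=make_estimator(config.algorithm, seed=config.seed),
            )
        X_tr_s, X_te_s = X_tr[:, sel], X_te[:, sel]
        params = (
            grid_search(config.algorithm, X_tr_s, y_tr, scheme, task, seed=config.seed)
            if config.hpo
            else {}
        )
        est = make_estimator(config.algorithm, seed=config.seed, **params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X_tr_s, y_tr)
            pred = est.predict(X_te_s)
            dummy = dummy_baseline(task).fit(X_tr_s, y_tr)
            dummy_pred = dummy.predict(X_te_s)
        if task == "classification":
            m = classification_metrics(y_te, pred)
            dm = classification_metrics(y_te, dummy_pred)
        else:
            m = regression_metrics(y_te, pred)
            dm = regression_metrics(y_te, dummy_pred)
        row = {"fold": fold_id, **m}
        row.update({f"dummy_{k}": v for k, v in dm.items() if k != "flag"})
        rows.append(row)
        selected_all.append(np.asarray(sel))
        params_all.append(params)

    folds = pd.DataFrame(rows)
    wins = (folds[key] > folds[f"dummy_{key}"]).to_numpy()
    win_fraction = float(np.mean(wins))
    metric_cols = [c for c in folds.columns if c != "fold"]
    aggregate = {
        "n_folds": len(folds),
        **{f"mean_{c}": float(folds[c].mean()) for c in metric_cols},
        **{f"sd_{c}": float(folds[c].std(ddof=1)) for c in metric_cols},
    }
    return CVResult(
        config=config,
        folds=folds,
        aggregate=aggregate,
        dummy_win_fraction=win_fraction,
        robust=win_fraction > 0.8,
        selected_features=selected_all,
        chosen_params=params_all,
    )
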