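"""Train-fitted confound regression.

Residualizes features and/or targets on covariates (age, sex, education,
with intercept) using ordinary least squares fit on the training fold only
and applied to both training and test data — the leakage-safe construction
for nr / cr / nr-cr / cr-cr deconfounding modes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

DECONFOUND_MODES = ("nr", "cr", "nr_cr", "cr_cr")

__all__ = ["DECONFOUND_MODES", "ConfoundRegressor", "deconfound"]


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """OLS residualizer: X -> X - C @ B, with B estimated at fit time.

    ``fit(X, confounds=C)`` solves the least-squares problem per column of
    X on [1, C]; ``transform(X, confounds=C)`` subtracts the fitted
    predictions.  Works for a feature matrix or a 1-D target.
    """

    def fit(self, X, y=None, confounds=None):
        if confounds is None:
            raise ValueError("confounds are required")
        C = self._design(confounds)
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("rank-deficient confound matrix")
        X = np.asarray(X, dtype=float)
        flat = X.ndim == 1
        self.coef_, *_ = np.linalg.lstsq(C, X.reshape(len(X), -1), rcond=None)
        self.flat_ = flat
        return self

    def transform(self, X, confounds=None):
        if confounds is None:
            raise ValueError("confounds are required")
        C = self._design(confounds)
        X = np.asarray(X, dtype=float)
        resid = X.reshape(len(X), -1) - C @ self.coef_
        return resid.ravel() if self.flat_ else resid

    def fit_transform(self, X, y=None, confounds=None):
        return self.fit(X, confounds=confounds).transform(X, confounds=confounds)

    @staticmethod
    def _design(confounds) -> np.ndarray:
        C = np.asarray(confounds, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        return np.column_stack([np.ones(len(C)), C])


def deconfound(
    X_train,
    y_train,
    X_test,
    y_test,
    confounds_train,
    confounds_test,
    mode: str = "nr",
):
    """Apply a deconfounding mode with train-only fitting.

    nr: identity; cr: features residualized; nr_cr: target residualized;
    cr_cr: both.  Returns (X_train, y_train, X_test, y_test).
    """
    if mode not in DECONFOUND_MODES:
        raise ValueError(f"unknown deconfounding mode {mode!r}")
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if mode in ("cr", "cr_cr"):
        reg = ConfoundRegressor().fit(X_train, confounds=confounds_train)
        X_train = reg.transform(X_train, confounds=confounds_train)
        X_test = reg.transform(X_test, confounds=confounds_test)
    if mode in ("nr_cr", "cr_cr"):
        reg = ConfoundRegressor().fit(y_train.astype(float), confounds=confounds_train)
        y_train = reg.transform(y_train.astype(float), confounds=confounds_train)
        y_test = reg.transform(y_test.astype(float), confounds=confounds_test)
    return X_train, y_train, X_test, y_test
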