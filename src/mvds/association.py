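"""Univariate logistic regression of a binary outcome on the mVDS score.

The analysis mirrors the clinical tables: a single predictor entered
directly (no selection), maximum likelihood via iteratively reweighted
least squares (IRLS), Wald standard errors from the inverse observed
information, the odds ratio per score point with its 95% Wald interval
``exp(beta ± 1.96·se)``, and a two-sided normal p-value.

IRLS uses step-halving so the deviance is non-increasing across iterations;
complete separation is detected up front (for a univariate predictor it is
exactly a class-splitting threshold) and returned as a flagged,
non-converged fit rather than silently penalised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "LogisticFit",
    "SeparationWarning",
    "fit_univariate_logistic",
    "UnivariateLogisticRegression",
]

_Z95 = 1.96
_TOL = 1e-8
_MAX_ITER = 100


class SeparationWarning(UserWarning):
    """The outcome is completely separated by the predictor; the MLE diverges."""


@dataclass(frozen=True)
class LogisticFit:
    """One row of a univariate logistic-regression table."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    converged: bool
    intercept: float
    deviance: float
    n_iter: int


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # -2 loglik via log1p(exp(..)) for numerical safety
    return float(2.0 * np.sum(np.logaddexp(0.0, eta) - y * eta))


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation of a scalar predictor: classes split strictly."""
    x1, x0 = x[y == 1], x[y == 0]
    return bool(x1.max() < x0.min() or x0.max() < x1.min())


def fit_univariate_logistic(x, y) -> LogisticFit:
    """ML fit of ``logit P(y=1) = a + b·x``.

    Requires ``n >= 10`` and both classes present. Convergence when the max
    parameter change is below 1e-8, up to 100 IRLS iterations; on complete
    separation a :class:`SeparationWarning` is issued and the returned fit
    has ``converged=False``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"x and y lengths differ: {x.shape} vs {y.shape}")
    n = x.size
    if n < 10:
        raise ValueError(f"need n >= 10 observations, got {n}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("degenerate outcome: y contains a single class")

    separated = _is_separated(x, y)

    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    eta = X @ beta
    dev = _deviance(y, eta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            new_beta = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            break
        step = new_beta - beta
        # step-halving keeps the deviance non-increasing
        new_dev = _deviance(y, X @ new_beta)
        halvings = 0
        while new_dev > dev + 1e-10 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_dev = _deviance(y, X @ new_beta)
            halvings += 1
        if new_dev > dev + 1e-10:
            raise RuntimeError("IRLS deviance increased; fit aborted")
        delta = float(np.max(np.abs(new_beta - beta)))
        beta, dev = new_beta, new_dev
        eta = X @ beta
        if delta < _TOL:
            converged = True
            break

    if separated:
        warnings.warn(
            "complete separation: |beta| diverges and the Wald output is unreliable",
            SeparationWarning,
            stacklevel=2,
        )
        converged = False

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X.T * w) @ X
    cov = np.linalg.pinv(info)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    z_stat = b / se if se > 0 else np.inf
    with np.errstate(over="ignore"):  # separated fits overflow to inf honestly
        or_, ci_low, ci_high = (
            float(np.exp(b)),
            float(np.exp(b - _Z95 * se)),
            float(np.exp(b + _Z95 * se)),
        )
    return LogisticFit(
        beta=b,
        se=se,
        or_=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(2.0 * norm.sf(abs(z_stat))),
        n=n,
        converged=converged,
        intercept=float(beta[0]),
        deviance=dev,
        n_iter=it,
    )


class UnivariateLogisticRegression(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`fit_univariate_logistic`.

    ``X`` is a single column (or 1-D array) of scores; ``y`` is binary.
    Fitted attributes expose the report row: ``beta_``, ``se_``, ``or_``,
    ``ci_``, ``p_``, ``intercept_``, ``converged_``, plus ``fit_result_``.
    """

    def __init__(self):
        pass

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("univariate model: X must have exactly one column")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D or a single column")
        return X

    def fit(self, X, y) -> "UnivariateLogisticRegression":
        x = self._validate(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("degenerate outcome: y must contain exactly two classes")
        y01 = (y == self.classes_[1]).astype(float)
        res = fit_univariate_logistic(x, y01)
        self.fit_result_ = res
        self.beta_ = res.beta
        self.se_ = res.se
        self.or_ = res.or_
        self.ci_ = (res.ci_low, res.ci_high)
        self.p_ = res.p
        self.intercept_ = res.intercept
        self.converged_ = res.converged
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        x = self._validate(X)
        p1 = expit(self.intercept_ + self.beta_ * x)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]
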