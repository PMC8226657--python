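"""Inter-rater reliability of total scores.

Implements ICC(2,1) — two-way random-effects ANOVA, absolute agreement,
single rater — together with Cronbach's alpha on the same subjects × raters
matrix. The two answer different questions: ICC(2,1) penalises systematic
between-rater shifts (absolute agreement), alpha does not (consistency), so
``rater2 = rater1 + c`` gives alpha = 1 but ICC < 1.

With the usual two-way mean squares (rows = subjects, columns = raters)::

    ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    alpha    = k/(k-1) * (1 - sum_j var(col_j) / var(row sums))

Optional confidence limits for ICC(2,1) follow the F-distribution /
Satterthwaite construction of McGraw & Wong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator

__all__ = ["ICCResult", "icc_2_1", "cronbach_alpha", "InterRaterReliability"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) with its ANOVA mean squares, Cronbach's alpha, and shape."""

    icc: float
    alpha: float
    ms_subjects: float
    ms_raters: float
    ms_error: float
    n_subjects: int
    k_raters: int
    degenerate: bool = False
    ci_low: float | None = None
    ci_high: float | None = None


def _as_matrix(values) -> np.ndarray:
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"ratings must be a 2-D subjects x raters matrix, got shape {m.shape}")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings matrix contains missing or non-finite cells")
    return m


def _mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def cronbach_alpha(values) -> float:
    """Cronbach's alpha over columns (raters as 'items')."""
    m = _as_matrix(values)
    k = m.shape[1]
    var_total = float(np.var(m.sum(axis=1), ddof=1))
    if var_total <= _DEGENERATE_TOL:
        return 1.0
    var_cols = float(np.sum(np.var(m, axis=0, ddof=1)))
    return k / (k - 1) * (1.0 - var_cols / var_total)


def icc_2_1(values, confidence: float | None = None) -> ICCResult:
    """ICC(2,1) and Cronbach's alpha of a subjects × raters score matrix.

    ``confidence`` (e.g. 0.95) adds F-based confidence limits. A matrix with
    zero total variance (all cells equal) is perfect agreement by
    convention: icc = alpha = 1 with ``degenerate=True``.
    """
    m = _as_matrix(values)
    n, k = m.shape
    ms_r, ms_c, ms_e = _mean_squares(m)

    if np.ptp(m) <= _DEGENERATE_TOL:
        return ICCResult(1.0, 1.0, ms_r, ms_c, ms_e, n, k, degenerate=True)

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) <= _DEGENERATE_TOL:
        # identical rows with rater shifts only: no subject variance to agree on
        return ICCResult(0.0, cronbach_alpha(m), ms_r, ms_c, ms_e, n, k, degenerate=True)
    icc = (ms_r - ms_e) / denom

    ci_low = ci_high = None
    if confidence is not None:
        ci_low, ci_high = _icc_2_1_ci(icc, ms_r, ms_c, ms_e, n, k, confidence)
    return ICCResult(
        icc=float(icc),
        alpha=float(cronbach_alpha(m)),
        ms_subjects=ms_r,
        ms_raters=ms_c,
        ms_error=ms_e,
        n_subjects=n,
        k_raters=k,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def _icc_2_1_ci(
    icc: float, ms_r: float, ms_c: float, ms_e: float, n: int, k: int, confidence: float
) -> tuple[float, float]:
    """McGraw & Wong F/Satterthwaite interval for ICC(2,1)."""
    alpha2 = (1.0 - confidence) / 2.0
    if 1.0 - icc < 1e-12:  # error-free agreement: interval collapses
        return 1.0, 1.0
    a = (k * icc) / (n * (1.0 - icc))
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
    v_num = (a * ms_c + b * ms_e) ** 2
    v_den = (a * ms_c) ** 2 / (k - 1.0) + (b * ms_e) ** 2 / ((n - 1.0) * (k - 1.0))
    v = v_num / v_den
    f1 = f_dist.ppf(1.0 - alpha2, n - 1.0, v)
    f2 = f_dist.ppf(1.0 - alpha2, v, n - 1.0)
    lo = n * (ms_r - f1 * ms_e) / (f1 * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
    hi = n * (f2 * ms_r - ms_e) / (k * ms_c + (k * n - k - n) * ms_e + n * f2 * ms_r)
    return float(lo), float(hi)


class InterRaterReliability(BaseEstimator):
    """Estimator wrapper: ``fit(X)`` on a subjects × raters score matrix.

    Fitted attributes: ``icc_``, ``alpha_``, ``result_`` (full
    :class:`ICCResult`), and ``ci_`` when ``confidence`` is set.
    """

    def __init__(self, confidence: float | None = 0.95):
        self.confidence = confidence

    def fit(self, X, y=None) -> "InterRaterReliability":
        res = icc_2_1(X, confidence=self.confidence)
        self.result_ = res
        self.icc_ = res.icc
        self.alpha_ = res.alpha
        self.ci_ = (res.ci_low, res.ci_high) if self.confidence is not None else None
        self.n_features_in_ = res.k_raters
        return self
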