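"""ROC analysis with Youden-index and full-specificity cutoff selection.

The clinical question is directional: a *low* mVDS total argues for oral
feeding, a *high* one for non-oral feeding, so a test-positive call is
``score <= c`` (direction ``"low"``) or ``score >= c`` (direction
``"high"``), inclusive at the cutoff. Candidate cutoffs are midpoints
between consecutive distinct observed scores plus a sentinel below the
minimum and above the maximum — hence half-point cutoffs like 36.5.

AUC is the Mann–Whitney concordance probability (ties count 1/2), which
equals the trapezoidal area under the empirical curve; its variance, 95%
interval and the test against AUC = 0.5 use DeLong's placement-value
method. The Youden-optimal cutoff maximises sensitivity + specificity − 1,
ties broken deterministically toward the larger cutoff (the one admitting
more patients to oral feeding). Each result also carries the two
100%-specificity rules: the highest ``<= c`` cutoff that captures no
high-class patient and the lowest ``>= c`` cutoff that captures no
low-class patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ROCPoint",
    "ROCResult",
    "SubgroupROC",
    "roc_curve",
    "subgroup_roc",
    "YoudenCutoffSelector",
]

logger = logging.getLogger(__name__)

_Z95 = 1.96


@dataclass(frozen=True)
class ROCPoint:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ROCResult:
    direction: str  # "low": score <= c is test-positive; "high": score >= c
    points: tuple[ROCPoint, ...]
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float
    auc_p: float
    optimal: ROCPoint
    full_spec_low: ROCPoint  # best 100%-specific "score <= c" rule for the low class
    full_spec_high: ROCPoint  # best 100%-specific "score >= c" rule for the high class
    n_positive: int
    n_negative: int
    degenerate: bool = False


def _midrank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def _delong_auc(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC (higher value ⇒ positive orientation) and its DeLong variance."""
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def roc_curve(scores, labels, direction: str = "low") -> ROCResult:
    """Full ROC sweep of ``scores`` against binary ``labels`` (1 = positive).

    ``direction`` fixes the test-positive inequality: ``"low"`` flags
    ``score <= cutoff`` (e.g. oral feeding on a severity scale), ``"high"``
    flags ``score >= cutoff``. Both classes must be present; identical
    scores for everyone yield a flagged AUC of 0.5.
    """
    if direction not in ("low", "high"):
        raise ValueError(f"direction must be 'low' or 'high', got {direction!r}")
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and labels lengths differ")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    cutoffs = _candidate_cutoffs(s)
    if direction == "low":
        sens = np.array([(pos <= c).mean() for c in cutoffs])
        spec = np.array([(neg > c).mean() for c in cutoffs])
    else:
        sens = np.array([(pos >= c).mean() for c in cutoffs])
        spec = np.array([(neg < c).mean() for c in cutoffs])
    points = tuple(
        ROCPoint(float(c), float(se), float(sp)) for c, se, sp in zip(cutoffs, sens, spec)
    )

    degenerate = np.unique(s).size == 1
    # orient so that a larger transformed value argues for the positive class
    sign = -1.0 if direction == "low" else 1.0
    auc, var = _delong_auc(sign * pos, sign * neg)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2.0 * norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    ci_low = max(0.0, auc - _Z95 * se)
    ci_high = min(1.0, auc + _Z95 * se)

    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # ties -> larger cutoff

    # 100%-specificity rules; the low class is whichever class low scores flag
    low_scores, high_scores = (pos, neg) if direction == "low" else (neg, pos)
    low_ok = np.array([(high_scores <= c).sum() == 0 for c in cutoffs])
    c_low = cutoffs[np.flatnonzero(low_ok)[-1]]
    full_spec_low = ROCPoint(float(c_low), float((low_scores <= c_low).mean()), 1.0)
    high_ok = np.array([(low_scores >= c).sum() == 0 for c in cutoffs])
    c_high = cutoffs[np.flatnonzero(high_ok)[0]]
    full_spec_high = ROCPoint(float(c_high), float((high_scores >= c_high).mean()), 1.0)

    return ROCResult(
        direction=direction,
        points=points,
        auc=auc,
        auc_se=se,
        auc_ci_low=float(ci_low),
        auc_ci_high=float(ci_high),
        auc_p=p,
        optimal=points[best],
        full_spec_low=full_spec_low,
        full_spec_high=full_spec_high,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        degenerate=bool(degenerate),
    )


@dataclass(frozen=True)
class SubgroupROC:
    """Per-group ROC runs in both feeding directions, with skipped groups."""

    oral: Mapping[str, ROCResult]  # direction "low", positive = low class
    nonoral: Mapping[str, ROCResult]  # direction "high", positive = high class
    skipped: Mapping[str, str] = field(default_factory=dict)


def subgroup_roc(
    scores,
    labels,
    groups,
    group_names: Sequence[str] | None = None,
) -> SubgroupROC:
    """ROC per subgroup and overall ("all"), in both directions.

    ``labels`` = 1 for the low-score (oral-feeding) class. Groups with a
    single outcome class (or no members) are reported as skipped, not fatal.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    g = np.asarray(groups).ravel()
    if not (s.shape == y.shape == g.shape):
        raise ValueError("scores, labels and groups must have equal length")
    names = list(group_names) if group_names is not None else sorted(set(g))
    oral: dict[str, ROCResult] = {}
    nonoral: dict[str, ROCResult] = {}
    skipped: dict[str, str] = {}
    for name in ["all", *names]:
        mask = np.ones_like(y, dtype=bool) if name == "all" else g == name
        ys, ss = y[mask], s[mask]
        if ys.size == 0:
            skipped[name] = "empty subgroup"
        elif ys.min() == ys.max():
            skipped[name] = "single outcome class"
        else:
            oral[name] = roc_curve(ss, ys, direction="low")
            nonoral[name] = roc_curve(ss, 1 - ys, direction="high")
        if name in skipped:
            logger.info("ROC subgroup %r skipped: %s", name, skipped[name])
    return SubgroupROC(oral=oral, nonoral=nonoral, skipped=skipped)


class YoudenCutoffSelector(ClassifierMixin, BaseEstimator):
    """Threshold classifier fitted by maximising the Youden index.

    ``X`` is a single score column; ``y`` binary with 1 = the class the
    chosen ``direction`` flags. Fitted attributes: ``cutoff_``, ``auc_``,
    ``auc_ci_``, ``sensitivity_``, ``specificity_``, ``roc_result_``.
    """

    def __init__(self, direction: str = "low"):
        self.direction = direction

    def _scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single score column")
            X = X[:, 0]
        return X.ravel()

    def fit(self, X, y) -> "YoudenCutoffSelector":
        s = self._scores(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("y must contain exactly two classes")
        res = roc_curve(s, (y == self.classes_[1]).astype(int), direction=self.direction)
        self.roc_result_ = res
        self.cutoff_ = res.optimal.cutoff
        self.auc_ = res.auc
        self.auc_ci_ = (res.auc_ci_low, res.auc_ci_high)
        self.sensitivity_ = res.optimal.sensitivity
        self.specificity_ = res.optimal.specificity
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        s = self._scores(X)
        positive = s <= self.cutoff_ if self.direction == "low" else s >= self.cutoff_
        return self.classes_[positive.astype(int)]
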