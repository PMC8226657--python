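"""ROC analysis: pair-counting, exhaustive-cutoff and DeLong oracles,
direction duality, invariances, subgroup handling."""

from fractions import Fraction

import numpy as np
import pytest

from mvds.roc import YoudenCutoffSelector, roc_curve, subgroup_roc


def auc_pair_count_oracle(scores, y, direction):
    """Concordant-pair count (+1/2 for ties) over all positive/negative pairs."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            better = p < q if direction == "low" else p > q
            total += 1.0 if better else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def candidate_cutoffs_oracle(scores):
    u = sorted(set(scores))
    mids = [(a + b) / 2 for a, b in zip(u, u[1:])]
    return [u[0] - 1.0] + mids + [u[-1] + 1.0]


def youden_exhaustive_oracle(scores, y, direction):
    """Exhaustive search over all candidate cutoffs with exact rational
    arithmetic; ties broken toward the larger cutoff."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    best_c, best_j = None, None
    for c in candidate_cutoffs_oracle(scores):
        if direction == "low":
            sens = Fraction(sum(s <= c for s in pos), len(pos))
            spec = Fraction(sum(s > c for s in neg), len(neg))
        else:
            sens = Fraction(sum(s >= c for s in pos), len(pos))
            spec = Fraction(sum(s < c for s in neg), len(neg))
        j = sens + spec - 1
        if best_j is None or j > best_j or (j == best_j and c > best_c):
            best_c, best_j = c, j
    return best_c, float(best_j)


def full_spec_oracle(scores, y, which):
    """Definitional enumeration of the 100%-specificity cutoffs (labels: 1 is
    the low-score class)."""
    low = [s for s, l in zip(scores, y) if l == 1]
    high = [s for s, l in zip(scores, y) if l == 0]
    cand = candidate_cutoffs_oracle(scores)
    if which == "low":
        ok = [c for c in cand if not any(s <= c for s in high)]
        return max(ok)
    ok = [c for c in cand if not any(s >= c for s in low)]
    return min(ok)


def delong_variance_oracle(pos, neg):
    """Naive O(m·n) placement-value DeLong variance (higher ⇒ positive)."""
    m, n = len(pos), len(neg)
    v10 = np.array(
        [np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for q in neg]) for p in pos]
    )
    v01 = np.array(
        [np.mean([1.0 if p > q else 0.5 if p == q else 0.0 for p in pos]) for q in neg]
    )
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.mean(v10)), s10 / m + s01 / n


def _random_instance(rng, max_n=30):
    while True:
        n = int(rng.integers(6, max_n + 1))
        scores = rng.choice(np.arange(0, 100.5, 0.5), size=n)
        y = (rng.random(n) < 0.5).astype(int)
        if 0 < y.sum() < n:
            return scores, y


class TestOracleEquivalence:
    def test_auc_and_cutoffs_match_oracles_on_random_instances(self, rng):
        """On 150 random small instances: AUC equals pair counting to 1e-12,
        the Youden cutoff equals exhaustive search, and the full-specificity
        cutoffs equal definitional enumeration."""
        for _ in range(150):
            scores, y = _random_instance(rng)
            direction = "low" if rng.random() < 0.5 else "high"
            res = roc_curve(scores, y, direction=direction)
            assert res.auc == pytest.approx(
                auc_pair_count_oracle(scores, y, direction), abs=1e-12
            )
            c, j = youden_exhaustive_oracle(scores, y, direction)
            assert res.optimal.cutoff == c
            assert res.optimal.youden_j == pytest.approx(j, abs=1e-12)
            y_low = y if direction == "low" else 1 - y
            assert res.full_spec_low.cutoff == full_spec_oracle(scores, y_low, "low")
            assert res.full_spec_high.cutoff == full_spec_oracle(scores, y_low, "high")

    def test_delong_variance_matches_naive_oracle(self, rng):
        for _ in range(50):
            scores, y = _random_instance(rng)
            res = roc_curve(scores, y, direction="low")
            auc, var = delong_variance_oracle(
                [-s for s, l in zip(scores, y) if l == 1],
                [-s for s, l in zip(scores, y) if l == 0],
            )
            assert res.auc == pytest.approx(auc, abs=1e-12)
            assert res.auc_se**2 == pytest.approx(var, abs=1e-12)

    def test_auc_equals_trapezoidal_area(self, rng):
        """Mann–Whitney AUC equals the trapezoidal area under the curve."""
        for _ in range(20):
            scores, y = _random_instance(rng)
            res = roc_curve(scores, y, direction="low")
            fpr = np.array([1 - p.specificity for p in res.points])
            tpr = np.array([p.sensitivity for p in res.points])
            order = np.argsort(fpr)
            assert np.trapezoid(tpr[order], fpr[order]) == pytest.approx(
                res.auc, abs=1e-12
            )


class TestEdgeCases:
    def test_perfect_separation(self):
        scores = np.array([10.0, 12, 15, 40, 44, 50])
        y = np.array([1, 1, 1, 0, 0, 0])
        res = roc_curve(scores, y, direction="low")
        assert res.auc == 1.0
        assert res.optimal.youden_j == pytest.approx(1.0)
        assert res.optimal.sensitivity == 1.0
        assert res.optimal.specificity == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(99)
        scores = rng.normal(40, 15, 2000)
        y = (rng.random(2000) < 0.4).astype(int)
        res = roc_curve(scores, y, direction="low")
        assert abs(res.auc - 0.5) < 3 * res.auc_se

    def test_all_identical_scores_degenerate(self):
        res = roc_curve(np.full(12, 30.0), np.array([0, 1] * 6), direction="low")
        assert res.auc == 0.5
        assert res.degenerate

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve(np.arange(6.0), np.ones(6, dtype=int))


class TestInvariances:
    def test_direction_duality(self, rng):
        """Flipping labels and direction exchanges sensitivity with
        specificity at every cutoff and preserves the AUC exactly."""
        scores, y = _random_instance(rng)
        a = roc_curve(scores, y, direction="low")
        b = roc_curve(scores, 1 - y, direction="high")
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        pts_a = {p.cutoff: p for p in a.points}
        for p in b.points:
            q = pts_a[p.cutoff]
            assert p.sensitivity == pytest.approx(q.specificity, abs=1e-12)
            assert p.specificity == pytest.approx(q.sensitivity, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores, y = _random_instance(rng)
        base = roc_curve(scores, y, direction="low")
        for f in (lambda s: 3.0 * s + 7.0, lambda s: np.expm1(s / 30.0)):
            res = roc_curve(f(scores), y, direction="low")
            assert res.auc == pytest.approx(base.auc, abs=1e-12)
            assert res.optimal.sensitivity == base.optimal.sensitivity
            assert res.optimal.specificity == base.optimal.specificity


class TestSubgroups:
    def test_identical_subgroups_give_identical_aucs(self):
        scores = np.array([10.0, 20, 30, 40, 50, 60] * 2)
        y = np.array([1, 1, 1, 0, 0, 0] * 2)
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = subgroup_roc(scores, y, g, ["a", "b"])
        assert res.oral["a"].auc == res.oral["b"].auc == res.oral["all"].auc

    def test_single_class_subgroup_skipped_not_fatal(self):
        scores = np.array([10.0, 20, 30, 40, 50, 60, 15, 25])
        y = np.array([1, 1, 1, 0, 0, 0, 1, 1])
        g = np.array(["a"] * 6 + ["b"] * 2)
        res = subgroup_roc(scores, y, g, ["a", "b"])
        assert "b" in res.skipped
        assert {"all", "a"} <= set(res.oral)
        assert "b" not in res.oral

    def test_nonoral_direction_reported_per_group(self):
        scores = np.array([10.0, 20, 30, 40, 50, 60])
        y = np.array([1, 1, 1, 0, 0, 0])
        res = subgroup_roc(scores, y, np.array(["a"] * 6), ["a"])
        assert res.nonoral["all"].direction == "high"
        assert res.nonoral["all"].auc == res.oral["all"].auc


class TestSelectorEstimator:
    def test_predict_applies_inclusive_inequality(self):
        scores = np.array([[10.0], [20], [30], [40], [50], [60]])
        y = np.array(["oral"] * 3 + ["non_oral"] * 3)
        # classes_ sorted: ['non_oral', 'oral']; positive class is classes_[1]
        sel = YoudenCutoffSelector(direction="low").fit(scores, y)
        assert sel.auc_ == 1.0
        pred = sel.predict(np.array([[sel.cutoff_], [sel.cutoff_ + 0.1]]))
        assert pred[0] == "oral" and pred[1] == "non_oral"

    def test_matches_roc_curve(self, rng):
        scores, y = _random_instance(rng)
        sel = YoudenCutoffSelector(direction="low").fit(scores.reshape(-1, 1), y)
        ref = roc_curve(scores, y, direction="low")
        assert sel.cutoff_ == ref.optimal.cutoff
        assert sel.auc_ == ref.auc
        assert (sel.sensitivity_, sel.specificity_) == (
            ref.optimal.sensitivity,
            ref.optimal.specificity,
        )
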