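"""Evaluation statistics for the aggressiveness classifier.

Confusion metrics with Wilson 95% CIs at a strict score cutoff,
Mann-Whitney U for per-feature group comparison, DeLong's test for paired
AUC comparison, and the Pearson chi-squared test for comparing performance
between centers. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .exceptions import DegenerateDataError


@dataclass
class Proportion:
    """A proportion with numerator, denominator, and 95% Wilson CI."""

    value: float
    count: int
    nobs: int
    ci_lo: float
    ci_hi: float

    @classmethod
    def from_counts(cls, count: int, nobs: int) -> "Proportion":
        lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
        # the Wilson bounds are exactly 0/1 at the degenerate counts;
        # snap away numerical round-off so the estimate stays inside its CI
        lo = 0.0 if count == 0 else float(np.clip(lo, 0.0, 1.0))
        hi = 1.0 if count == nobs else float(np.clip(hi, 0.0, 1.0))
        return cls(value=count / nobs, count=count, nobs=nobs, ci_lo=lo, ci_hi=hi)

    def as_percent(self) -> str:
        return f"{100 * self.value:.1f}% [{self.count}/{self.nobs}] ({100 * self.ci_lo:.1f}-{100 * self.ci_hi:.1f})"


@dataclass
class ConfusionReport:
    """2x2 confusion counts plus the derived proportions with CIs.

    PPV/NPV are ``None`` when no positive/negative call was made
    (undefined, not zero)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Proportion
    specificity: Proportion
    accuracy: Proportion
    ppv: Proportion | None
    npv: Proportion | None

    def to_dict(self) -> dict:
        def prop(p):
            if p is None:
                return None
            return {
                "value": p.value,
                "count": p.count,
                "nobs": p.nobs,
                "ci_95": [p.ci_lo, p.ci_hi],
            }

        return {
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "accuracy": prop(self.accuracy),
            "ppv": prop(self.ppv),
            "npv": prop(self.npv),
        }


def confusion_metrics(scores, labels, cutoff: float) -> ConfusionReport:
    """Confusion counts and Wilson-CI proportions at a strict cutoff
    (positive iff score > cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("confusion metrics require both classes")
    pred = scores > cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return ConfusionReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=Proportion.from_counts(tp, tp + fn),
        specificity=Proportion.from_counts(tn, tn + fp),
        accuracy=Proportion.from_counts(tp + tn, tp + tn + fp + fn),
        ppv=Proportion.from_counts(tp, tp + fp) if tp + fp > 0 else None,
        npv=Proportion.from_counts(tn, tn + fn) if tn + fn > 0 else None,
    )


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples have n <= 8 and the pooled data is
    tie-free; tie-corrected normal approximation (no continuity
    correction) otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and no_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# --------------------------------------------------------------------------
# DeLong's test for paired AUCs

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n, dtype=float)
    out[order] = t
    return out


def _delong_covariance(preds: np.ndarray, labels: np.ndarray):
    """AUCs and DeLong covariance matrix for k paired score vectors.

    ``preds`` has shape (k, n); labels are binary over the same cases.
    """
    pos = labels == 1
    m = int(pos.sum())
    n_neg = int((~pos).sum())
    if m == 0 or n_neg == 0:
        raise DegenerateDataError("DeLong requires both classes")
    k = preds.shape[0]
    ordered = np.concatenate([preds[:, pos], preds[:, ~pos]], axis=1)
    tx = np.empty((k, m))
    ty = np.empty((k, n_neg))
    tz = np.empty((k, m + n_neg))
    for r in range(k):
        tx[r] = _midrank(ordered[r, :m])
        ty[r] = _midrank(ordered[r, m:])
        tz[r] = _midrank(ordered[r])
    aucs = tz[:, :m].sum(axis=1) / (m * n_neg) - (m + 1.0) / (2.0 * n_neg)
    v01 = (tz[:, :m] - tx) / n_neg
    v10 = 1.0 - (tz[:, m:] - ty) / m
    sx = np.cov(v01)
    sy = np.cov(v10)
    cov = sx / m + sy / n_neg
    return aucs, np.atleast_2d(cov)


def delong_auc(scores, labels) -> float:
    """Mann-Whitney (midrank) AUC estimate, the statistic DeLong's test
    is built on."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    aucs, _ = _delong_covariance(scores[None, :], labels)
    return float(aucs[0])


def delong_test(scores1, scores2, labels) -> tuple[float, float, float]:
    """DeLong's two-sided z-test comparing the AUCs of two paired score
    vectors over the same cases. Returns (auc1, auc2, p). A degenerate
    zero-variance difference yields p = 1."""
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if s1.shape != s2.shape or s1.shape[0] != labels.shape[0]:
        raise ValueError("scores1, scores2, labels must be paired over the same cases")
    aucs, cov = _delong_covariance(np.vstack([s1, s2]), labels)
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var <= 1e-15:
        p = 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), min(p, 1.0)


def chi_squared_2x2(counts, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table, without continuity
    correction by default (``yates=True`` switches it on). A zero row or
    column marginal is an error."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("degenerate table: zero marginal")
    stat, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return float(stat), float(p)
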