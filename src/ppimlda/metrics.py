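"""Classifier evaluation: confusion metrics, ROC/AUC, significance tests.

Patients are the positive class throughout: sensitivity is the correct-
classification rate among patients, specificity among controls.  The
binomial test of accuracy against chance is an exact one-sided upper-tail
sum (the directional hypothesis is detection above chance); the AUC is the
exact rank statistic P(z_patient > z_control) + 0.5 P(tie).  Alongside, a
chi-square test of the 2x2 confusion table is reported as a separately named
output — the two tests answer different questions and neither is folded into
the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
from scipy import stats

from .mlda import CVResult


@dataclass
class MetricsReport:
    """Headline evaluation metrics for one cross-validated classifier."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    p_binomial: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    p_chi2_confusion: float | None = None
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(result: CVResult) -> MetricsReport:
    """Counts and proportions from per-subject LOOCV predictions."""
    y, yhat = result.true_labels, result.predictions
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    return MetricsReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        accuracy=(tp + tn) / (tp + fn + tn + fp),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        metadata={"positive_class": "patient", "threshold": 0.0},
    )


def roc_curve_auc(
    decision_values: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float, list[str]]:
    """ROC points and exact rank-based AUC.

    The curve is traced by sweeping the rule ``z > tau`` over the sorted
    unique decision values (descending), prepended with (0, 0); the AUC is
    computed independently of the curve as the exact pair statistic
    ``P(z_patient > z_control) + 0.5 * P(tie)``.
    """
    z = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    warnings: list[str] = []
    pos, neg = z[y == 1], z[y == 0]

    points = [(0.0, 0.0)]
    for tau in np.unique(z)[::-1]:
        points.append((float((neg > tau).mean()), float((pos > tau).mean())))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    # dedupe while preserving order
    deduped = [points[0]]
    for pt in points[1:]:
        if pt != deduped[-1]:
            deduped.append(pt)

    if np.unique(z).size == 1:
        warnings.append("constant decision values: AUC defaults to 0.5")
        return deduped, 0.5, warnings
    diff = pos[:, None] - neg[None, :]
    auc = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))
    return deduped, auc, warnings


def auc_trapezoidal(roc_points: list[tuple[float, float]]) -> float:
    """AUC by trapezoidal integration of an ROC polyline (cross-check route)."""
    pts = np.asarray(roc_points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def binomial_vs_chance(k_correct: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided binomial tail P(K >= k | n, p0).

    Computed as a big-integer rational sum, so the result is exact to float
    rounding for any n encountered here.
    """
    if not 0 <= k_correct <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k_correct}, n={n}")
    p = Fraction(p0).limit_denominator(10**12)
    total = sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k_correct, n + 1)
    )
    return float(total)


def correlate_decisions(
    result: CVResult, scores: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of decision values with a per-subject covariate
    (e.g. observer-rated symptom severity); missing scores are dropped
    pairwise.  Returns (r, two-sided p, n_used)."""
    z = result.decision_values
    s = np.asarray(scores, dtype=float)
    if s.shape != z.shape:
        raise ValueError("scores must align with decision values")
    ok = ~np.isnan(s) & ~np.isnan(z)
    z, s = z[ok], s[ok]
    if len(z) < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if np.ptp(z) == 0 or np.ptp(s) == 0:
        raise ValueError("zero variance in decision values or scores")
    r, p = stats.pearsonr(z, s)
    return float(r), float(p), int(len(z))


def ranksum_by_group(
    values: np.ndarray, group_flags: np.ndarray
) -> dict[str, float]:
    """Mann-Whitney comparison of a quantity between two subgroups
    (e.g. decision values of medicated vs. medication-free patients).

    ``W`` is the U statistic of the first subgroup (flag true): rank sum minus
    n1(n1+1)/2, midranks for ties.  The p value is exact by enumeration for
    small tie-free samples (n1+n2 <= 12), otherwise a normal approximation
    with tie and continuity corrections.  The raw rank sum is also reported
    since software conventions for "W" differ.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_flags, dtype=bool)
    if v.shape != g.shape:
        raise ValueError("values and group_flags must align")
    x1, x2 = v[g], v[~g]
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("both subgroups must be non-empty")
    n1, n2 = len(x1), len(x2)
    has_ties = len(np.unique(v)) < len(v)
    method = "exact" if (n1 + n2 <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x1, x2, alternative="two-sided", method=method, use_continuity=True
    )
    ranks = stats.rankdata(v)
    rank_sum = float(ranks[g].sum())
    return {
        "W": float(res.statistic),
        "rank_sum": rank_sum,
        "p": float(res.pvalue),
        "n1": n1,
        "n2": n2,
        "method": method,
    }


def evaluate_cv(
    result: CVResult,
    symptom_scores: np.ndarray | None = None,
    subgroup_flags: np.ndarray | None = None,
) -> MetricsReport:
    """Full evaluation bundle from a LOOCV result.

    Optional covariates add the decision-value/severity correlation and the
    subgroup rank-sum comparison (restricted to patients when the flags carry
    NaN/False for controls is up to the caller) to the report metadata.
    """
    report = confusion_metrics(result)
    roc, auc, warns = roc_curve_auc(result.decision_values, result.true_labels)
    report.roc_points = roc
    report.auc = auc
    report.warnings.extend(warns)
    n = len(result.true_labels)
    k = int(report.tp + report.tn)
    report.p_binomial = binomial_vs_chance(k, n)
    table = np.array([[report.tp, report.fn], [report.fp, report.tn]])
    if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
        _, p_chi2, _, _ = stats.chi2_contingency(table, correction=False)
        report.p_chi2_confusion = float(p_chi2)
    report.metadata.update(
        {
            "binomial_test": "one-sided upper tail vs p0=0.5",
            "auc_definition": "P(z_patient > z_control) + 0.5 P(tie)",
            "n_subjects": n,
            "k_correct": k,
        }
    )
    if symptom_scores is not None:
        r, p, n_used = correlate_decisions(result, symptom_scores)
        report.metadata["symptom_correlation"] = {"r": r, "p": p, "n": n_used}
    if subgroup_flags is not None:
        report.metadata["subgroup_ranksum"] = ranksum_by_group(
            result.decision_values, subgroup_flags
        )
    return report


def binomial_null_band(n: int, coverage: float = 0.95, p0: float = 0.5) -> tuple[int, int]:
    """Central acceptance band [k_lo, k_hi] for Binomial(n, p0) correct counts."""
    alpha = (1.0 - coverage) / 2.0
    k_lo = int(stats.binom.ppf(alpha, n, p0))
    k_hi = int(stats.binom.ppf(1.0 - alpha, n, p0))
    return k_lo, k_hi
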