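"""ROC analysis and diagnostic-test comparison.

AUC standard errors and paired AUC comparisons follow Hanley and McNeil:
the AUC variance uses the exponential-approximation moments
``Q1 = A / (2 - A)`` and ``Q2 = 2 A^2 / (1 + A)``; the paired comparison
``z = (A1 - A2) / sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2)`` draws the
AUC-correlation ``r`` from a lookup table indexed by the average
class-conditional rank correlation of the two scores and the average AUC.
The table shipped here was generated once by bivariate-binormal Monte Carlo
(the same construction underlying the published table) and is bilinearly
interpolated.

Sensitivity/specificity confidence intervals are exact Clopper-Pearson
(substituted, and labelled as such, for the originally cited interval
method).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import beta, norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

# --- Correlated-AUC r-table (Monte-Carlo derived; see module docstring). ---
# Rows: average class-conditional rank correlation of the two scores.
# Columns: average of the two AUCs.  The zero-correlation row is set to its
# exact value (independent scores give independent AUC estimates).
_HM_ROWS = np.array(
    [0.0, 0.0946, 0.1892, 0.2856, 0.3807, 0.4782, 0.5768, 0.6772, 0.7804, 0.8862]
)
_HM_COLS = np.array([0.5, 0.6, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.975])
_HM_R = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0955, 0.1043, 0.0845, 0.0923, 0.0944, 0.0901, 0.0742, 0.0278, 0.0569],
        [0.2018, 0.1565, 0.1991, 0.1811, 0.1730, 0.1679, 0.1643, 0.1454, 0.0922],
        [0.2948, 0.3104, 0.2701, 0.2623, 0.2493, 0.2558, 0.2314, 0.1940, 0.1885],
        [0.3925, 0.3742, 0.3588, 0.3815, 0.3347, 0.3614, 0.2825, 0.2690, 0.2725],
        [0.4918, 0.4836, 0.4744, 0.4737, 0.4516, 0.4430, 0.4108, 0.3605, 0.3445],
        [0.5623, 0.5878, 0.5599, 0.5859, 0.5391, 0.5457, 0.5199, 0.4554, 0.4199],
        [0.6771, 0.6813, 0.6643, 0.6685, 0.6551, 0.6387, 0.6244, 0.5906, 0.5422],
        [0.7875, 0.7698, 0.7757, 0.7694, 0.7734, 0.7433, 0.7355, 0.7226, 0.6752],
        [0.8902, 0.8860, 0.8874, 0.8772, 0.8779, 0.8693, 0.8665, 0.8501, 0.8193],
    ]
)
_HM_INTERP = RegularGridInterpolator(
    (_HM_ROWS, _HM_COLS), _HM_R, bounds_error=False, fill_value=None
)


def hm_auc_correlation(r_avg: float, auc_avg: float) -> float:
    """Intermediate correlation for the paired AUC comparison."""
    r_avg = float(np.clip(r_avg, _HM_ROWS[0], _HM_ROWS[-1]))
    auc_avg = float(np.clip(auc_avg, _HM_COLS[0], _HM_COLS[-1]))
    return float(np.clip(_HM_INTERP((r_avg, auc_avg)), 0.0, 1.0))


@dataclass
class ROCResult:
    """An ROC curve with its area and Hanley-McNeil standard error."""

    thresholds: np.ndarray  # ascending score thresholds
    sensitivity: np.ndarray  # P(score >= threshold | positive)
    specificity: np.ndarray  # P(score < threshold | negative)
    auc: float
    auc_se: float
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def roc(
    scores: Sequence[float],
    labels: Sequence,
    positive_label="glaucoma",
) -> ROCResult:
    """ROC curve for a score oriented so that higher means more diseased.

    Ties between positive and negative scores receive half credit, so the
    trapezoidal area equals the Mann-Whitney concordance statistic
    ``P(score_pos > score_neg) + 0.5 P(tie)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    # Reorder ascending in threshold; drop the sentinel +inf threshold point.
    keep = np.isfinite(thr)
    thr, tpr, fpr = thr[keep][::-1], tpr[keep][::-1], fpr[keep][::-1]
    auc = _mann_whitney_auc(scores[y == 1], scores[y == 0])
    result = ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_se=0.0,
        n_pos=n_pos,
        n_neg=n_neg,
        scores=scores,
        labels=y,
    )
    result.auc_se = auc_se(result)
    return result


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def auc_se(roc_result: ROCResult) -> float:
    """Hanley-McNeil standard error of the AUC."""
    a = roc_result.auc
    n_pos, n_neg = roc_result.n_pos, roc_result.n_neg
    if a in (0.0, 1.0):
        import warnings

        warnings.warn("degenerate AUC: standard error is 0", stacklevel=2)
        return 0.0
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(math.sqrt(max(var, 0.0)))


def compare_auc(
    roc_a: ROCResult,
    roc_b: ROCResult,
    paired: bool = True,
) -> tuple[float, float]:
    """Compare two AUCs: returns ``(z, two-sided p)``.

    In paired mode both ROC results must come from the same eyes in the same
    order; the correlation term is looked up from the packaged table using
    the average class-conditional Spearman correlation of the two scores.
    Unpaired mode sets the correlation to zero (plain two-SE z-test).
    """
    a1, a2 = roc_a.auc, roc_b.auc
    se1, se2 = roc_a.auc_se, roc_b.auc_se
    r = 0.0
    if paired:
        if (
            roc_a.scores is None
            or roc_b.scores is None
            or len(roc_a.scores) != len(roc_b.scores)
            or not np.array_equal(roc_a.labels, roc_b.labels)
        ):
            raise ValueError("paired comparison requires aligned subject sets")
        rs = []
        for cls in (1, 0):
            m = roc_a.labels == cls
            rs.append(_spearman(roc_a.scores[m], roc_b.scores[m]))
        r = hm_auc_correlation(float(np.mean(rs)), 0.5 * (a1 + a2))
    denom = se1 * se1 + se2 * se2 - 2.0 * r * se1 * se2
    if denom <= 0:
        return (0.0, 1.0) if a1 == a2 else (math.copysign(math.inf, a1 - a2), 0.0)
    z = (a1 - a2) / math.sqrt(denom)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(p, 1.0)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


@dataclass
class BinaryTestPerformance:
    """Counts and proportions for a categorical test, with exact CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ci_method: str = "clopper-pearson"


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def binary_performance(
    predicted: Sequence[bool],
    labels: Sequence,
    positive_label="glaucoma",
    ci_level: float = 0.95,
) -> BinaryTestPerformance:
    """Sensitivity and specificity of a categorical test against labels."""
    pred = np.asarray(predicted, dtype=bool)
    y = np.asarray([l == positive_label for l in labels])
    if pred.shape != y.shape:
        raise ValueError("predicted and labels must align")
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return BinaryTestPerformance(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=_clopper_pearson(tp, tp + fn, ci_level),
        specificity_ci=_clopper_pearson(tn, tn + fp, ci_level),
    )


def optimal_point(roc_result: ROCResult) -> float:
    """Threshold closest to 100% sensitivity and 100% specificity.

    Euclidean distance in (sensitivity, specificity) space; exact ties go to
    the lower threshold.
    """
    d2 = (1.0 - roc_result.sensitivity) ** 2 + (1.0 - roc_result.specificity) ** 2
    best = np.min(d2)
    idx = np.nonzero(d2 == best)[0]
    return float(roc_result.thresholds[idx[0]])  # thresholds ascending


def concordance_table(
    outcomes: Mapping[str, Sequence[bool]],
    mask: Optional[Sequence[bool]] = None,
) -> dict[tuple[bool, ...], int]:
    """Counts of eyes per combination of test positivity.

    ``outcomes`` maps test name to an aligned boolean vector; the returned
    dict maps each observed positivity pattern (ordered as the mapping's
    keys) to its count.  ``mask`` restricts to a subset (e.g. an MD stratum).
    Counts sum to the number of (masked) eyes.
    """
    names = list(outcomes)
    arrays = [np.asarray(outcomes[n], dtype=bool) for n in names]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("test outcome vectors must be aligned")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != n:
            raise ValueError("mask must align with outcomes")
    table: dict[tuple[bool, ...], int] = {}
    for i in range(n):
        if not mask[i]:
            continue
        key = tuple(bool(a[i]) for a in arrays)
        table[key] = table.get(key, 0) + 1
    return table
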