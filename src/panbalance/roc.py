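"""Iterative ROC calibration of the imbalance diagnosis.

Crop yield (the response) is continuous, so the usual clinical ROC recipe is
extended in two ways:

* the *response delimiter* (yield cut-off) is scanned: for each candidate
  the Mahalanobis-distance predictor is calibrated and the cut-off with the
  largest step AUC wins, subject to a minimum reference (TN) size;
* the reference population that defines the distance is itself an output of
  the classification, so it is re-estimated iteratively: high-yielders seed
  the reference, a Youden-optimal critical distance is chosen on the ROC
  curve, the true negatives under that delimiter become the new reference,
  and the loop stops when two successive iterations classify every specimen
  identically.

Quadrants: condition-positive = yield below the cut-off; test-positive =
distance above the critical value.  TN (balanced high-yielders) is the
reference quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distance import ReferenceNorms, fit_norms, mahalanobis
from .transforms import BalanceSet

LABELS = ("TN", "TP", "FN", "FP")


@dataclass(frozen=True)
class ROCCurve:
    """Operating points of the distance predictor over a threshold sweep."""

    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        se = np.asarray(self.sensitivity, dtype=float)
        sp = np.asarray(self.specificity, dtype=float)
        if not (t.size == se.size == sp.size):
            raise ValueError("thresholds, sensitivity, specificity must align")
        if np.any(np.diff(se) > 1e-12) or np.any(np.diff(sp) < -1e-12):
            raise ValueError(
                "sensitivity must be non-increasing and specificity non-decreasing in the threshold"
            )
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "sensitivity", se)
        object.__setattr__(self, "specificity", sp)

    def __len__(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class CalibrationResult:
    """Converged calibration: delimiters, norms, quadrants and accuracy metrics."""

    yield_cutoff: float
    critical_distance: float
    auc_step: float
    auc_binormal: float | None
    auc_binormal_ci: tuple[float, float] | None
    norms: ReferenceNorms
    labels: np.ndarray = field(repr=False)
    distances: np.ndarray = field(repr=False)
    curve: ROCCurve = field(repr=False, default=None)
    metrics: dict = field(default_factory=dict)
    iterations: int = 0
    converged: bool = True


def classify(distances, yields, critical_distance: float, yield_cutoff: float) -> np.ndarray:
    """Quadrant labels TN/TP/FN/FP for each specimen.

    TN: d <= critical and yield >= cutoff;  TP: d > critical and yield < cutoff;
    FP: d > critical and yield >= cutoff;   FN: d <= critical and yield < cutoff.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(yields, dtype=float)
    if d.size == 0:
        raise ValueError("empty input")
    if d.shape != y.shape:
        raise ValueError("distances and yields must have equal length")
    test_pos = d > critical_distance
    cond_pos = y < yield_cutoff
    out = np.empty(d.shape, dtype="<U2")
    out[test_pos & cond_pos] = "TP"
    out[test_pos & ~cond_pos] = "FP"
    out[~test_pos & cond_pos] = "FN"
    out[~test_pos & ~cond_pos] = "TN"
    return out


def roc_curve(distances, low_yield_mask) -> ROCCurve:
    """Sweep thresholds over the unique distances (plus +/- infinity).

    sensitivity(t) = share of low-yielders with distance > t;
    specificity(t) = share of high-yielders with distance <= t.
    """
    d = np.asarray(distances, dtype=float)
    pos = np.asarray(low_yield_mask, dtype=bool)
    if pos.all() or not pos.any():
        raise ValueError("both yield classes must be present")
    thresholds = np.concatenate(([-np.inf], np.unique(d), [np.inf]))
    sens = np.array([(d[pos] > t).mean() for t in thresholds])
    spec = np.array([(d[~pos] <= t).mean() for t in thresholds])
    return ROCCurve(thresholds, sens, spec)


def youden_optimal(curve: ROCCurve) -> tuple[float, float]:
    """Threshold maximising Youden's J = sensitivity + specificity - 1.

    Ties break toward the smallest threshold (most exclusive reference).
    """
    j = curve.sensitivity + curve.specificity - 1.0
    i = int(np.argmax(j))  # argmax returns the first (smallest-threshold) maximum
    return float(curve.thresholds[i]), float(j[i])


def auc_step(curve: ROCCurve) -> float:
    """Area under the ROC step curve by summing rectangles.

    Operating points are traversed in threshold order (false-positive rate
    rising from 0 to 1); each rectangle takes the sensitivity at its
    larger-FPR edge, so tied predictor values count as concordant.
    """
    x = (1.0 - curve.specificity)[::-1]  # descending threshold: FPR rises
    y = curve.sensitivity[::-1]
    area = float(np.sum(np.diff(x) * y[1:]))
    return min(max(area, 0.0), 1.0)


def auc_binormal(curve: ROCCurve) -> tuple[float, float, float]:
    """Binormal AUC with a 95% CI.

    Fits probit(sensitivity) = a + b * probit(1 - specificity) by ordinary
    least squares over the interior operating points (both rates strictly
    inside (0, 1)), then AUC = Phi(a / sqrt(1 + b^2)).  The CI propagates
    the OLS covariance of (a, b) through the delta method.
    """
    sens = curve.sensitivity
    fpr = 1.0 - curve.specificity
    interior = (sens > 0) & (sens < 1) & (fpr > 0) & (fpr < 1)
    if interior.sum() < 3:
        raise ValueError("need at least 3 interior operating points for the binormal fit")
    zs = stats.norm.ppf(sens[interior])
    zf = stats.norm.ppf(fpr[interior])
    X = np.column_stack([np.ones(zf.size), zf])
    beta, res, *_ = np.linalg.lstsq(X, zs, rcond=None)
    a, b = beta
    dof = zf.size - 2
    resid = zs - X @ beta
    s2 = float(resid @ resid) / max(dof, 1)
    cov_ab = s2 * np.linalg.inv(X.T @ X)
    scale = math.sqrt(1.0 + b * b)
    m = a / scale
    grad = np.array([1.0 / scale, -a * b / scale**3])
    se_m = math.sqrt(max(float(grad @ cov_ab @ grad), 0.0))
    z975 = stats.norm.ppf(0.975)
    auc = float(stats.norm.cdf(m))
    lo = float(stats.norm.cdf(m - z975 * se_m))
    hi = float(stats.norm.cdf(m + z975 * se_m))
    return auc, lo, hi


def confusion_metrics(labels) -> dict:
    """Sensitivity, specificity, PPV, NPV and accuracy from quadrant labels.

    Undefined ratios (empty denominator) are returned as NaN, never 0.
    """
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("empty input")
    tp = int((lab == "TP").sum())
    tn = int((lab == "TN").sum())
    fp = int((lab == "FP").sum())
    fn = int((lab == "FN").sum())

    def ratio(num, den):
        return num / den if den else float("nan")

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / lab.size,
    }


def class_sum_of_squares(yields, test_positive_mask) -> float:
    """Between-group sum of squares of yields under a predictor split."""
    y = np.asarray(yields, dtype=float)
    m = np.asarray(test_positive_mask, dtype=bool)
    if m.all() or not m.any():
        raise ValueError("both groups must be non-empty")
    grand = y.mean()
    return float(
        m.sum() * (y[m].mean() - grand) ** 2 + (~m).sum() * (y[~m].mean() - grand) ** 2
    )


def iterate_reference(
    balances,
    yields,
    yield_cutoff: float,
    outlier_alpha: float = 0.01,
    max_iter: int = 50,
):
    """Iteratively re-estimate the TN reference for a fixed yield cut-off.

    Iteration 0 seeds the reference with every high-yielder; each pass fits
    reference norms, computes all distances, picks the Youden-optimal
    critical distance on the ROC curve and re-labels the quadrants; the new
    reference is the TN quadrant.  Stops when two successive passes label
    identically; a 2-cycle returns the iterate with the larger step AUC
    (converged = False), as does hitting ``max_iter``.

    Returns ``(norms, labels, curve, iterations, converged)`` where norms
    carry the calibrated critical distance and yield cut-off.
    """
    names = balances.balance_names if isinstance(balances, BalanceSet) else None
    z = balances.values if isinstance(balances, BalanceSet) else np.atleast_2d(
        np.asarray(balances, dtype=float)
    )
    y = np.asarray(yields, dtype=float)
    low = y < yield_cutoff
    if low.all() or not low.any():
        raise ValueError("both yield classes must be non-empty at this cut-off")

    ref_mask = ~low
    history: list[tuple[np.ndarray, ...]] = []  # (labels, norms, curve, critical)
    prev_labels = None
    for it in range(1, max_iter + 1):
        if ref_mask.sum() < 2:
            raise ValueError(
                f"reference collapsed to {ref_mask.sum()} specimens at iteration {it} "
                f"(cut-off {yield_cutoff:g})"
            )
        norms = fit_norms(z[ref_mask], outlier_alpha=outlier_alpha, balance_names=names)
        d = mahalanobis(z, norms)
        curve = roc_curve(d, low)
        critical, _ = youden_optimal(curve)
        labels = classify(d, y, critical, yield_cutoff)
        norms = norms.with_calibration(critical, yield_cutoff)
        history.append((labels, norms, curve, d))
        if prev_labels is not None and np.array_equal(labels, prev_labels):
            return norms, labels, curve, d, it, True
        if len(history) >= 3 and np.array_equal(labels, history[-3][0]):
            # 2-cycle: keep whichever iterate of the cycle has the larger AUC
            cand = [history[-1], history[-2]]
            best = max(cand, key=lambda h: auc_step(h[2]))
            return best[1], best[0], best[2], best[3], it, False
        prev_labels = labels
        ref_mask = labels == "TN"
    last = history[-1]
    return last[1], last[0], last[2], last[3], max_iter, False


def calibrate(
    balances,
    yields,
    candidate_cutoffs=None,
    min_tn: int = 20,
    outlier_alpha: float = 0.01,
    max_iter: int = 50,
) -> CalibrationResult:
    """Scan candidate yield cut-offs and return the calibration with maximal step AUC.

    Candidates default to the midpoints between consecutive unique yields.
    A candidate is discarded if the iteration fails to converge, raises, or
    leaves fewer than ``min_tn`` specimens in the TN quadrant.  Ties on the
    AUC break toward the larger cut-off.
    """
    y = np.asarray(yields, dtype=float)
    if min_tn > y.size:
        raise ValueError(f"min_tn={min_tn} exceeds sample size {y.size}")
    if candidate_cutoffs is None:
        uniq = np.unique(y)
        if uniq.size < 2:
            raise ValueError("need at least 2 distinct yields to form candidate cut-offs")
        candidate_cutoffs = (uniq[:-1] + uniq[1:]) / 2.0
    candidate_cutoffs = np.asarray(candidate_cutoffs, dtype=float)
    if candidate_cutoffs.size < 2:
        raise ValueError("need at least 2 candidate cut-offs")

    best: CalibrationResult | None = None
    for cutoff in np.sort(candidate_cutoffs):
        low = y < cutoff
        if low.all() or not low.any():
            continue
        try:
            norms, labels, curve, d, iters, conv = iterate_reference(
                balances, y, cutoff, outlier_alpha=outlier_alpha, max_iter=max_iter
            )
        except ValueError:
            continue
        if not conv or int((labels == "TN").sum()) < min_tn:
            continue
        a = auc_step(curve)
        if best is not None and a < best.auc_step:
            continue
        try:
            ab, lo, hi = auc_binormal(curve)
            bin_auc, bin_ci = ab, (lo, hi)
        except ValueError:
            bin_auc, bin_ci = None, None
        cand = CalibrationResult(
            yield_cutoff=float(cutoff),
            critical_distance=float(norms.critical_distance),
            auc_step=a,
            auc_binormal=bin_auc,
            auc_binormal_ci=bin_ci,
            norms=norms,
            labels=labels,
            distances=d,
            curve=curve,
            metrics=confusion_metrics(labels),
            iterations=iters,
            converged=conv,
        )
        # >= keeps the larger cut-off on ties (candidates scanned ascending)
        if best is None or a >= best.auc_step:
            best = cand
    if best is None:
        raise ValueError(
            f"no candidate cut-off converged with at least {min_tn} TN specimens"
        )
    return best
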