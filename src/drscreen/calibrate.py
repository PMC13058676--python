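"""ROC analysis, Youden-index operating points and per-stage threshold calibration.

The calibration question: given a cohort with gold-standard ordinal stages
and a continuous severity score per patient, where should the stage
boundaries sit for THIS population?  For each ordinal boundary k the truth is
binarised cumulatively (positive iff gold stage >= k), an empirical ROC curve
is built over candidate thresholds, and the threshold maximising the Youden
index J = sensitivity + specificity - 1 becomes cutpoint t_k.  The three
cutpoints assemble into a population-specific ThresholdSet.

Binarisation rule everywhere: a score is called positive iff score > t.
Candidate thresholds are the midpoints between consecutive distinct observed
scores, plus one sentinel below the minimum and one above the maximum, so
the ">" rule is unambiguous at every data point and the candidate grid
realises every achievable confusion table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, ScreeningStatus, screening_status, worse_eye_score, worse_eye_stage
from .errors import CrossingThresholdsError, DegenerateLabelsError, MissingStageError
from .thresholds import ThresholdSet

__all__ = [
    "RocCurve",
    "YoudenResult",
    "roc_curve",
    "auc",
    "youden_threshold",
    "derive_stage_thresholds",
    "referral_sweep",
    "cohort_scores_and_stages",
]


@dataclass
class RocCurve:
    """Empirical ROC over an exhaustive candidate-threshold grid.

    ``thresholds`` ascend; positives are called by score > threshold, so
    sensitivity is non-increasing and specificity non-decreasing along the
    grid, with sens=1 at the low sentinel and spec=1 at the high sentinel.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class YoudenResult:
    """Optimal operating point for one stage boundary."""

    boundary: int
    threshold: float
    j: float
    sensitivity: float
    specificity: float


def _validate_binary(scores: np.ndarray, labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("need at least one positive and one negative")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct scores plus below/above sentinels."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Exhaustive empirical ROC curve (positive iff score > threshold)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _validate_binary(s, y)
    cand = candidate_thresholds(s)
    pos = np.sort(s[y])
    neg = np.sort(s[~y])
    # count(score > t) via sorted search; exact, O(n log n)
    sens = 1.0 - np.searchsorted(pos, cand, side="right") / pos.size
    spec = np.searchsorted(neg, cand, side="right") / neg.size
    return RocCurve(thresholds=cand, sensitivity=sens, specificity=spec)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical ROC.

    Equals the Mann–Whitney pair statistic P(score_pos > score_neg) +
    ½·P(tie) because the candidate grid realises every step of the curve.
    """
    fpr = 1.0 - curve.specificity
    # thresholds ascend => fpr descends; integrate left-to-right
    return float(np.trapezoid(curve.sensitivity[::-1], fpr[::-1]))


def youden_threshold(
    scores: Sequence[float], labels: Sequence[bool], boundary: int = 1
) -> YoudenResult:
    """Candidate threshold maximising J; ties go to the smallest threshold.

    The smallest-threshold tie-break maximises sensitivity at equal J, the
    conservative choice for a screening application.
    """
    curve = roc_curve(scores, labels)
    j = curve.sensitivity + curve.specificity - 1.0
    idx = int(np.argmax(j))  # first maximum = smallest threshold
    return YoudenResult(
        boundary=boundary,
        threshold=float(curve.thresholds[idx]),
        j=float(j[idx]),
        sensitivity=float(curve.sensitivity[idx]),
        specificity=float(curve.specificity[idx]),
    )


def cohort_scores_and_stages(
    cohort: Sequence[PatientRecord], unit: str = "patient"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (score, gold stage) pairs for calibration.

    ``unit="patient"`` uses worse-eye score vs worse-eye gold stage over
    regression-graded patients (the unit of every reported metric);
    ``unit="eye"`` uses each scored-and-graded eye.  Quality-flagged eyes
    are included either way: flagged images still carry usable scores.
    """
    scores: list[float] = []
    stages: list[int] = []
    if unit == "patient":
        for p in cohort:
            if screening_status(p, "regression") is not ScreeningStatus.GRADED:
                continue
            scores.append(worse_eye_score(p))
            stages.append(int(worse_eye_stage(p)))
    elif unit == "eye":
        for p in cohort:
            for e in p.eyes:
                if e.score is not None and e.gold_stage is not None:
                    scores.append(e.score)
                    stages.append(int(e.gold_stage.collapsed()))
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return np.asarray(scores, dtype=float), np.asarray(stages, dtype=int)


def derive_stage_thresholds(
    cohort: Sequence[PatientRecord] | tuple[np.ndarray, np.ndarray],
    boundaries: Sequence[int] = (1, 2, 3),
    unit: str = "patient",
) -> tuple[ThresholdSet, list[YoudenResult]]:
    """Per-stage Youden calibration: one cumulative binarisation per boundary.

    For boundary k the positive class is gold stage >= k, so the optimal
    cutpoints inherit the printed interval structure (no DR up to t1, mild
    up to t2, ...).  Non-monotone optima are reported as an error, never
    silently reordered.
    """
    if isinstance(cohort, tuple):
        scores, stages = cohort
    else:
        scores, stages = cohort_scores_and_stages(cohort, unit=unit)
    results = []
    for k in boundaries:
        labels = stages >= k
        if labels.all() or not labels.any():
            raise MissingStageError(
                f"boundary {k}: no patients on one side (stages present: "
                f"{sorted(set(stages.tolist()))})"
            )
        results.append(youden_threshold(scores, labels, boundary=k))
    cut = [r.threshold for r in results]
    if any(a >= b for a, b in zip(cut, cut[1:])):
        raise CrossingThresholdsError(f"crossing thresholds: {cut}")
    return ThresholdSet(tuple(cut)), results


def referral_sweep(
    cohort: Sequence[PatientRecord], cutoff_grid: Sequence[float]
) -> pd.DataFrame:
    """Referred and missed-case fractions across score-based cutoffs.

    Computed among regression-graded patients: for each cutoff, the fraction
    referred (worse-eye score > cutoff), and the fraction of gold-moderate
    and gold-severe patients NOT referred (the cases a screening programme
    would miss at that operating point).
    """
    grid = np.asarray(list(cutoff_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    if np.any((grid < 0.0) | (grid > 5.0)):
        raise ValueError("cutoffs outside [0, 5]")
    scores, stages = cohort_scores_and_stages(cohort, unit="patient")
    if scores.size == 0:
        raise MissingStageError("no graded patients to sweep")
    rows = []
    for c in grid:
        referred = scores > c
        mod = stages == 2
        sev = stages == 3
        rows.append(
            {
                "cutoff": c,
                "referred_fraction": float(referred.mean()),
                "missed_moderate_fraction": float((~referred[mod]).mean())
                if mod.any()
                else float("nan"),
                "missed_severe_fraction": float((~referred[sev]).mean())
                if sev.any()
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
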