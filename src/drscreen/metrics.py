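"""Screening performance metrics with and without unscreenable patients.

Controlled-study sensitivities condition on patients the algorithm could
grade.  In a real screening programme the patients with no image, an
incomplete image set or a quality rejection still exist — and an algorithm
that cannot grade them has, operationally, not detected their disease.  The
dual-denominator framework therefore reports every metric twice:

* ``_d`` (diagnosable): denominator = graded patients only;
* ``_a`` (all): denominator = every examined patient, with non-graded
  positives counted as undetected and non-graded negatives as not-cleared.

The exact identity ``sens_a * P = sens_d * P_d`` (P = all positives, P_d =
graded positives) links the two and lets published aggregate proportions be
inverted back into patient counts (:func:`reconstruct_from_aggregates`),
reproducing a publication's referral arithmetic from its printed table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away, round_half_away_int
from .cohort import (
    DRStage,
    PatientRecord,
    ScreeningStatus,
    patient_classifier_stage,
    screening_status,
    worse_eye_score,
    worse_eye_stage,
)
from .errors import InconsistentAggregatesError, UndefinedMetricError
from .thresholds import ReferralPolicy, ThresholdSet, patient_stage

__all__ = [
    "ConfusionMatrix",
    "DualMetrics",
    "ScreeningOutcome",
    "confusion_matrix",
    "dual_metrics",
    "screening_outcome",
    "reconstruct_from_aggregates",
    "quality_accuracy_curve",
    "linear_fit_r2",
    "screening_report",
]

Predictor = ThresholdSet | str  # a ThresholdSet, or "classifier"


def _kind(predictor: Predictor) -> str:
    return "classifier" if predictor == "classifier" else "regression"


def _predicted_stage(patient: PatientRecord, predictor: Predictor) -> DRStage | None:
    if predictor == "classifier":
        return patient_classifier_stage(patient)
    return patient_stage(patient, predictor)


def _graded(cohort: Sequence[PatientRecord], predictor: Predictor):
    kind = _kind(predictor)
    return [
        p
        for p in cohort
        if p.exam_done and screening_status(p, kind) is ScreeningStatus.GRADED
    ]


def _is_referred(patient: PatientRecord, predictor: Predictor, policy: ReferralPolicy | None) -> bool:
    """Referral call for a GRADED patient."""
    if policy is not None and policy.mode == "score_based":
        return worse_eye_score(patient) > policy.cutoff
    pred = _predicted_stage(patient, predictor)
    return pred is not None and pred.collapsed() >= DRStage.MODERATE


@dataclass
class ConfusionMatrix:
    """Gold (rows, 0–3) vs predicted (columns, 0–3 or 0–4) stage counts."""

    counts: np.ndarray
    pred_stages: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(range(4), name="gold_stage"),
            columns=pd.Index(self.pred_stages, name="predicted_stage"),
        )

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def missed_more_than_mild(self) -> int:
        """Gold moderate-or-worse predicted as no/mild DR."""
        return int(self.counts[2:, :2].sum())

    @property
    def undergraded(self) -> int:
        """Entries strictly below the (collapsed) diagonal."""
        total = 0
        for g in range(4):
            for j, ps in enumerate(self.pred_stages):
                if min(ps, 3) < g:
                    total += int(self.counts[g, j])
        return total


def confusion_matrix(
    cohort: Sequence[PatientRecord], predictor: Predictor
) -> ConfusionMatrix:
    """Stage agreement between gold standard and predictor, graded patients only.

    Regression predictors with a 4-cutpoint ThresholdSet (or classifier
    outputs reaching proliferative) yield a 5-column matrix; the gold axis
    is always the 4 clinical classes.
    """
    if predictor == "classifier":
        n_pred = 5
    else:
        n_pred = predictor.n_stages
    counts = np.zeros((4, n_pred), dtype=int)
    for p in _graded(cohort, predictor):
        pred = _predicted_stage(p, predictor)
        if pred is None:
            continue
        counts[int(worse_eye_stage(p)), int(pred)] += 1
    return ConfusionMatrix(counts=counts, pred_stages=tuple(range(n_pred)))


@dataclass
class DualMetrics:
    """Sensitivity/specificity with diagnosable and all-patient denominators."""

    sens_d: float
    sens_a: float
    spec_d: float
    spec_a: float
    tp: int
    pos_graded: int
    pos_all: int
    tn: int
    neg_graded: int
    neg_all: int


def dual_metrics(
    cohort: Sequence[PatientRecord],
    predictor: Predictor,
    positive: str = "more_than_mild",
    policy: ReferralPolicy | None = None,
    severe_by_referral: bool = False,
) -> DualMetrics:
    """Dual-denominator sensitivity and specificity.

    ``positive="more_than_mild"``: positives are gold stage >= moderate and a
    true positive is a referred positive.  ``positive="severe"``: positives
    are gold severe; detection means predicted severe-or-worse (exact-stage
    convention) unless ``severe_by_referral`` asks for the referral call
    instead.  Specificity always concerns gold no/mild patients, a negative
    call being "not referred".  Non-graded patients count against both
    all-patient metrics.
    """
    if positive not in ("more_than_mild", "severe"):
        raise ValueError(f"unknown positive class {positive!r}")
    kind = _kind(predictor)
    examined = [p for p in cohort if p.exam_done]

    def is_pos(p: PatientRecord) -> bool:
        g = worse_eye_stage(p)
        return g >= DRStage.SEVERE if positive == "severe" else g >= DRStage.MODERATE

    def detected(p: PatientRecord) -> bool:
        if positive == "severe" and not severe_by_referral:
            pred = _predicted_stage(p, predictor)
            return pred is not None and pred.collapsed() >= DRStage.SEVERE
        return _is_referred(p, predictor, policy)

    tp = tn = pos_graded = neg_graded = pos_all = neg_all = 0
    for p in examined:
        pos = is_pos(p)
        graded = screening_status(p, kind) is ScreeningStatus.GRADED
        if pos:
            pos_all += 1
            if graded:
                pos_graded += 1
                if detected(p):
                    tp += 1
        else:
            neg_all += 1
            if graded:
                neg_graded += 1
                if not _is_referred(p, predictor, policy):
                    tn += 1
    if pos_graded == 0 or neg_graded == 0 or pos_all == 0 or neg_all == 0:
        raise UndefinedMetricError("a sensitivity/specificity denominator is zero")
    return DualMetrics(
        sens_d=tp / pos_graded,
        sens_a=tp / pos_all,
        spec_d=tn / neg_graded,
        spec_a=tn / neg_all,
        tp=tp,
        pos_graded=pos_graded,
        pos_all=pos_all,
        tn=tn,
        neg_graded=neg_graded,
        neg_all=neg_all,
    )


@dataclass
class ScreeningOutcome:
    """Referral burden and missed cases under the screening scenario."""

    referred_count: int
    total: int
    missed_moderate: int
    missed_severe: int

    @property
    def pct_change_exams(self) -> float:
        """Exam-load change vs referring everyone: −100·(1 − referred/total)."""
        return -100.0 * (1.0 - self.referred_count / self.total)


def screening_outcome(
    cohort: Sequence[PatientRecord],
    policy: ReferralPolicy,
    thresholds: ThresholdSet,
    predictor: Predictor | None = None,
) -> ScreeningOutcome:
    """Hypothetical screening scenario: follow up every patient with no
    image, an incomplete set, a quality rejection, or a referable result.

    Missed cases are gold moderate/severe GRADED patients the policy does
    not refer (non-graded patients are referred by construction, hence never
    missed).
    """
    pred: Predictor = thresholds if predictor is None else predictor
    kind = _kind(pred)
    examined = [p for p in cohort if p.exam_done]
    referred = missed_mod = missed_sev = 0
    for p in examined:
        if screening_status(p, kind) is not ScreeningStatus.GRADED:
            referred += 1
            continue
        if _is_referred(p, pred, policy):
            referred += 1
        else:
            g = worse_eye_stage(p)
            if g == DRStage.MODERATE:
                missed_mod += 1
            elif g >= DRStage.SEVERE:
                missed_sev += 1
    return ScreeningOutcome(
        referred_count=referred,
        total=len(examined),
        missed_moderate=missed_mod,
        missed_severe=missed_sev,
    )


def reconstruct_from_aggregates(
    sens_d: float,
    sens_a: float,
    spec_d: float,
    spec_a: float,
    n_positive: int,
    n_negative: int,
    total: int,
) -> dict[str, float]:
    """Invert published dual-denominator proportions into patient counts.

    Given the four printed sensitivities/specificities of one screening mode
    plus the gold-standard class totals, recover TP, graded positives,
    TN, graded negatives, the number of patients without a result, and the
    referral burden of the screening scenario.  Counts round half away from
    zero, matching how published tables round.
    """
    if not (0.0 < sens_d <= 1.0 and 0.0 <= sens_a <= sens_d):
        raise InconsistentAggregatesError("sensitivities out of order or range")
    if not (0.0 < spec_d <= 1.0 and 0.0 <= spec_a <= spec_d):
        raise InconsistentAggregatesError("specificities out of order or range")
    if n_positive + n_negative != total:
        raise InconsistentAggregatesError("class totals do not sum to the cohort size")
    tp = round_half_away_int(sens_a * n_positive)
    pos_graded = round_half_away_int(tp / sens_d)
    tn = round_half_away_int(spec_a * n_negative)
    neg_graded = round_half_away_int(tn / spec_d)
    no_result = total - pos_graded - neg_graded
    if no_result < 0:
        raise InconsistentAggregatesError(
            f"graded counts ({pos_graded}+{neg_graded}) exceed the cohort total {total}"
        )
    fp = neg_graded - tn
    referred = no_result + tp + fp
    return {
        "tp": tp,
        "pos_graded": pos_graded,
        "tn": tn,
        "neg_graded": neg_graded,
        "no_result": no_result,
        "fp": fp,
        "referred": referred,
        "pct_change_exams": -100.0 * (1.0 - referred / total),
    }


def quality_accuracy_curve(
    cohort: Sequence[PatientRecord],
    quality_bins: Sequence[float],
    thresholds: ThresholdSet,
) -> pd.DataFrame:
    """Exact-stage accuracy per image-quality bin (regression-graded patients).

    Patient quality is the mean of the eye quality scores; accuracy is the
    fraction of patients whose mapped worse-eye stage equals the gold stage.
    Empty bins are reported with n=0 and NaN accuracy, not dropped.
    """
    edges = np.asarray(list(quality_bins), dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("quality bins need >= 2 strictly increasing edges")
    quals, correct = [], []
    for p in _graded(cohort, thresholds):
        qs = [e.quality for e in p.eyes if e.quality is not None]
        if not qs:
            continue
        quals.append(float(np.mean(qs)))
        pred = patient_stage(p, thresholds)
        correct.append(int(pred.collapsed() == worse_eye_stage(p)))
    quals_arr = np.asarray(quals)
    correct_arr = np.asarray(correct)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        inbin = (quals_arr >= lo) & (quals_arr < hi)
        n = int(inbin.sum())
        rows.append(
            {
                "quality_lo": lo,
                "quality_hi": hi,
                "n": n,
                "accuracy": float(correct_arr[inbin].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def linear_fit_r2(x: Sequence[float], y: Sequence[float]) -> dict[str, object]:
    """OLS of a quality score on an ordinal 1–5 rating: slope, R², fitted means.

    Used to compare an algorithm's 0–100 image-quality score with a human
    grader's 1 (best) to 5 (uninterpretable) rating.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(xa).size < 2:
        raise ValueError("constant x: regression undefined")
    fit = stats.linregress(xa, ya)
    fitted = {r: fit.intercept + fit.slope * r for r in range(1, 6)}
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "fitted_means": fitted,
    }


def screening_report(
    cohort: Sequence[PatientRecord],
    youden_thresholds: ThresholdSet,
    manufacturer_thresholds: ThresholdSet | None = None,
    greifswald_cutoff: float = 0.1,
    include_classifier: bool = True,
) -> pd.DataFrame:
    """Publication-style comparison grid: one row per screening mode.

    Modes: the classifier column (if classifier outputs are present), the
    regression algorithm with manufacturer stage bins, with Youden-adjusted
    bins, and with the score-based Greifswald referral cutoff (stage labels
    staying on the Youden bins).
    """
    from .thresholds import MANUFACTURER_THRESHOLDS

    if manufacturer_thresholds is None:
        manufacturer_thresholds = MANUFACTURER_THRESHOLDS
    stage_policy = ReferralPolicy(mode="stage_based")
    modes: list[tuple[str, Predictor, ReferralPolicy]] = []
    if include_classifier and any(
        patient_classifier_stage(p) is not None for p in cohort
    ):
        modes.append(("classifier", "classifier", stage_policy))
    modes += [
        ("manufacturer", manufacturer_thresholds, stage_policy),
        ("youden", youden_thresholds, stage_policy),
        (
            "greifswald",
            youden_thresholds,
            ReferralPolicy(mode="score_based", cutoff=greifswald_cutoff),
        ),
    ]
    rows = []
    for name, predictor, policy in modes:
        dm = dual_metrics(cohort, predictor, policy=policy)
        sev = dual_metrics(cohort, predictor, positive="severe", policy=policy)
        thr = predictor if isinstance(predictor, ThresholdSet) else youden_thresholds
        out = screening_outcome(cohort, policy, thr, predictor=predictor)
        rows.append(
            {
                "mode": name,
                "patients_diagnosable": dm.pos_graded + dm.neg_graded,
                "patients_total": dm.pos_all + dm.neg_all,
                "sens_d_more_than_mild_pct": round_half_away(100 * dm.sens_d, 2),
                "sens_d_severe_pct": round_half_away(100 * sev.sens_d, 2),
                "spec_d_pct": round_half_away(100 * dm.spec_d, 2),
                "sens_a_more_than_mild_pct": round_half_away(100 * dm.sens_a, 2),
                "sens_a_severe_pct": round_half_away(100 * sev.sens_a, 2),
                "spec_a_pct": round_half_away(100 * dm.spec_a, 2),
                "referred": out.referred_count,
                "pct_change_exams": round_half_away(out.pct_change_exams, 2),
                "moderate_missed": out.missed_moderate,
                "severe_missed": out.missed_severe,
            }
        )
    return pd.DataFrame(rows)
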