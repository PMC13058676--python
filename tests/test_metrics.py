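"""Confusion matrices, dual-denominator metrics, screening arithmetic."""

import numpy as np
import pytest

from drscreen import (
    DRStage,
    EyeAssessment,
    PatientRecord,
    ReferralPolicy,
    ThresholdSet,
    confusion_matrix,
    dual_metrics,
    generate_cohort,
    linear_fit_r2,
    quality_accuracy_curve,
    reconstruct_from_aggregates,
    screening_outcome,
    screening_report,
)
from drscreen import GeneratorConfig
from drscreen.errors import InconsistentAggregatesError, UndefinedMetricError

YOUDEN = ThresholdSet((0.07, 1.02, 1.67))
STAGE_POLICY = ReferralPolicy(mode="stage_based")


def make_patient(pid, gold, score=None, quality=60.0):
    """One-eye patient; score None means no image at all."""
    available = score is not None
    return PatientRecord(
        patient_id=pid,
        eyes=[
            EyeAssessment(
                laterality="left",
                gold_stage=DRStage(gold),
                score=score,
                quality=quality if available else None,
                image_available=available,
                in_complete_set=available,
            )
        ],
    )


# scores landing in the middle of each Youden interval, per stage
STAGE_SCORE = {0: 0.03, 1: 0.5, 2: 1.3, 3: 2.5}


def perfect_cohort(stage_counts=(4, 3, 2, 1)):
    cohort = []
    i = 0
    for stage, n in enumerate(stage_counts):
        for _ in range(n):
            cohort.append(make_patient(f"P{i}", stage, STAGE_SCORE[stage]))
            i += 1
    return cohort


def test_perfect_predictor_confusion_is_diagonal():
    cm = confusion_matrix(perfect_cohort(), YOUDEN)
    assert np.all(cm.counts == np.diag([4, 3, 2, 1]))
    assert cm.missed_more_than_mild == 0
    assert cm.undergraded == 0


def test_all_predicted_no_dr_misses_every_moderate():
    cohort = [make_patient(f"P{i}", 2, 0.01) for i in range(10)]
    cohort.append(make_patient("N", 0, 0.01))
    cm = confusion_matrix(cohort, YOUDEN)
    assert cm.missed_more_than_mild == 10
    assert cm.undergraded == 10


def test_confusion_marginals_match_hand_tally(study_cohort):
    cm = confusion_matrix(study_cohort, YOUDEN)
    from drscreen import ScreeningStatus, screening_status, worse_eye_stage

    graded = [
        p for p in study_cohort
        if screening_status(p, "regression") is ScreeningStatus.GRADED
    ]
    tally = np.zeros(4, dtype=int)
    for p in graded:
        tally[int(worse_eye_stage(p))] += 1
    np.testing.assert_array_equal(cm.counts.sum(axis=1), tally)
    assert cm.n == len(graded)


def test_full_coverage_makes_both_denominators_agree():
    dm = dual_metrics(perfect_cohort(), YOUDEN, policy=STAGE_POLICY)
    assert dm.sens_a == dm.sens_d == 1.0
    assert dm.spec_a == dm.spec_d == 1.0


def test_half_the_positives_unscreened():
    cohort = perfect_cohort(stage_counts=(5, 0, 4, 0))
    for p in cohort[5:7]:  # two of four moderate patients lose their image
        p.eyes[0] = EyeAssessment(laterality="left", gold_stage=DRStage.MODERATE)
    dm = dual_metrics(cohort, YOUDEN, policy=STAGE_POLICY)
    assert dm.sens_d == 1.0
    assert dm.sens_a == pytest.approx(0.5)


def test_dual_metric_identity_on_synthetic_cohort(study_cohort):
    """sens_a · P == sens_d · P_d exactly, and same for specificity."""
    for predictor in (YOUDEN, "classifier"):
        dm = dual_metrics(study_cohort, predictor, policy=STAGE_POLICY)
        assert dm.sens_a * dm.pos_all == pytest.approx(
            dm.sens_d * dm.pos_graded, abs=1e-9
        )
        assert dm.spec_a * dm.neg_all == pytest.approx(
            dm.spec_d * dm.neg_graded, abs=1e-9
        )


def test_zero_denominator_signalled():
    with pytest.raises(UndefinedMetricError):
        dual_metrics(perfect_cohort(stage_counts=(3, 0, 0, 0)), YOUDEN,
                     policy=STAGE_POLICY)


def test_screening_outcome_hand_count():
    cohort = [
        make_patient("A", 0),            # no image -> referred
        make_patient("B", 1, 0.5),       # mild, stage-based -> not referred
        make_patient("C", 3, 2.5),       # severe -> referred
        make_patient("D", 0, 0.03),      # no DR -> not referred
    ]
    out = screening_outcome(cohort, STAGE_POLICY, YOUDEN)
    assert out.referred_count == 2
    assert out.pct_change_exams == pytest.approx(-50.0)
    assert out.missed_moderate == out.missed_severe == 0


def test_everyone_no_image_means_no_exam_reduction():
    cohort = [make_patient(f"P{i}", 0) for i in range(5)]
    out = screening_outcome(cohort, STAGE_POLICY, YOUDEN)
    assert out.referred_count == 5
    assert out.pct_change_exams == pytest.approx(0.0)


def test_perfect_stage_predictor_refers_exactly_the_positives():
    cohort = perfect_cohort(stage_counts=(6, 3, 2, 2))
    out = screening_outcome(cohort, STAGE_POLICY, YOUDEN)
    assert out.referred_count == 4
    assert out.missed_moderate == out.missed_severe == 0


def test_reconstruct_full_coverage_has_no_result_zero():
    r = reconstruct_from_aggregates(0.9, 0.9, 0.8, 0.8, 100, 400, 500)
    assert r["no_result"] == 0


def test_reconstruct_rejects_inconsistent_aggregates():
    with pytest.raises(InconsistentAggregatesError):
        reconstruct_from_aggregates(0.5, 0.9, 0.8, 0.8, 100, 400, 500)
    with pytest.raises(InconsistentAggregatesError):
        reconstruct_from_aggregates(0.9, 0.9, 0.8, 0.8, 100, 400, 600)


def test_reconstruct_is_left_inverse_of_metrics(study_cohort):
    """Feeding a cohort's own aggregates back recovers its referral count."""
    policy = ReferralPolicy(mode="score_based", cutoff=0.1)
    dm = dual_metrics(study_cohort, YOUDEN, policy=policy)
    out = screening_outcome(study_cohort, policy, YOUDEN)
    exact = reconstruct_from_aggregates(
        dm.sens_d, dm.sens_a, dm.spec_d, dm.spec_a,
        dm.pos_all, dm.neg_all, dm.pos_all + dm.neg_all,
    )
    assert exact["referred"] == out.referred_count
    assert exact["no_result"] == out.total - dm.pos_graded - dm.neg_graded
    rounded = reconstruct_from_aggregates(
        round(dm.sens_d, 4), round(dm.sens_a, 4),
        round(dm.spec_d, 4), round(dm.spec_a, 4),
        dm.pos_all, dm.neg_all, dm.pos_all + dm.neg_all,
    )
    assert abs(rounded["referred"] - out.referred_count) <= 1


def test_missed_more_than_mild_matches_sens_d_complement(study_cohort):
    """(1 − sens_d)·P_d equals the confusion matrix's missed count."""
    dm = dual_metrics(study_cohort, YOUDEN, policy=STAGE_POLICY)
    cm = confusion_matrix(study_cohort, YOUDEN)
    assert cm.missed_more_than_mild == round((1 - dm.sens_d) * dm.pos_graded)


def test_quality_accuracy_hand_count():
    cohort = [
        make_patient("A", 0, 0.03, quality=20.0),   # correct, low bin
        make_patient("B", 2, 0.03, quality=25.0),   # wrong, low bin
        make_patient("C", 0, 0.03, quality=30.0),   # correct, low bin
        make_patient("D", 1, 0.5, quality=70.0),    # correct, high bin
        make_patient("E", 3, 2.0, quality=75.0),    # correct, high bin
        make_patient("F", 0, 0.01, quality=80.0),   # correct, high bin
    ]
    curve = quality_accuracy_curve(cohort, [0.0, 50.0, 100.0], YOUDEN)
    assert curve["accuracy"].tolist() == pytest.approx([2 / 3, 1.0])
    assert curve["n"].tolist() == [3, 3]


def test_quality_accuracy_reports_empty_bins():
    cohort = [make_patient("A", 0, 0.03, quality=90.0)]
    curve = quality_accuracy_curve(cohort, [0.0, 50.0, 100.0], YOUDEN)
    assert curve["n"].tolist() == [0, 1]
    assert np.isnan(curve["accuracy"].iloc[0])


def test_accuracy_improves_with_quality_by_construction():
    """Quality-dependent stage noise produces a rising accuracy trend."""
    rng = np.random.default_rng(3)
    cohort = []
    for i in range(600):
        gold = int(rng.integers(0, 4))
        quality = float(rng.uniform(10, 95))
        p_wrong = 0.7 * (1 - quality / 100.0)
        stage = gold if rng.random() > p_wrong else int(rng.integers(0, 4))
        cohort.append(make_patient(f"P{i}", gold, STAGE_SCORE[stage], quality=quality))
    curve = quality_accuracy_curve(cohort, [0, 25, 50, 75, 100], YOUDEN)
    acc = curve["accuracy"].to_numpy()
    from scipy.stats import spearmanr

    rho, _ = spearmanr(np.arange(acc.size), acc)
    assert rho > 0


def test_linear_fit_exact_line_and_noise():
    exact = linear_fit_r2([1, 2, 3, 4, 5], [70, 60, 50, 40, 30])
    assert exact["slope"] == pytest.approx(-10.0)
    assert exact["r_squared"] == pytest.approx(1.0)
    assert exact["fitted_means"][1] == pytest.approx(70.0)
    rng = np.random.default_rng(4)
    x = rng.integers(1, 6, 500)
    noise = linear_fit_r2(x, rng.normal(50, 10, 500))
    assert noise["r_squared"] < 0.05
    y2 = 2 * np.arange(10, dtype=float)
    assert linear_fit_r2(np.arange(10, dtype=float), y2)["r_squared"] == pytest.approx(1.0)


def test_linear_fit_rejects_degenerate_input():
    with pytest.raises(ValueError):
        linear_fit_r2([1, 1, 1], [2, 3, 4])
    with pytest.raises(ValueError):
        linear_fit_r2([1, 2], [2, 3])


def test_report_greifswald_refers_at_least_manufacturer(study_cohort):
    """Cutoff 0.1 sits far below the manufacturer's moderate boundary (2.0)."""
    ts, _ = __import__("drscreen").derive_stage_thresholds(study_cohort)
    report = screening_report(study_cohort, ts).set_index("mode")
    assert (
        report.loc["greifswald", "referred"] >= report.loc["manufacturer", "referred"]
    )
    assert set(report.index) == {"classifier", "manufacturer", "youden", "greifswald"}
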