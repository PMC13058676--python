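"""ROC, AUC and Youden calibration against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drscreen import (
    GeneratorConfig,
    auc,
    derive_stage_thresholds,
    generate_cohort,
    referral_sweep,
    roc_curve,
    youden_threshold,
)
from drscreen.calibrate import cohort_scores_and_stages
from drscreen.errors import DegenerateLabelsError, MissingStageError

from conftest import brute_force_auc, brute_force_best_j, brute_force_roc


def test_separable_case_perfect_operating_point():
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = [False, False, True, True]
    res = youden_threshold(scores, labels)
    assert res.j == pytest.approx(1.0)
    assert 0.2 < res.threshold < 0.8
    assert auc(roc_curve(scores, labels)) == pytest.approx(1.0)


def test_anti_separated_pair_has_zero_best_j():
    # positive below negative: under score > t, no threshold beats J = 0
    res = youden_threshold([0.1, 0.9], [True, False])
    assert res.j == pytest.approx(0.0)


def test_known_small_example():
    # positives {2, 3}, negatives {1, 2}: best J = 0.5 (threshold between 2 and 3
    # gives sens 1/2, spec 1; threshold between 1 and 2 gives sens 1, spec 1/2)
    res = youden_threshold([2.0, 3.0, 1.0, 2.0], [True, True, False, False])
    assert res.j == pytest.approx(0.5)


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(0)
    scores = rng.random(50)
    labels = rng.random(50) < 0.4
    curve = roc_curve(scores, labels)
    assert curve.sensitivity[0] == 1.0 and curve.specificity[-1] == 1.0
    assert np.all(np.diff(curve.sensitivity) <= 1e-12)
    assert np.all(np.diff(curve.specificity) >= -1e-12)


def test_degenerate_labels_rejected():
    with pytest.raises(DegenerateLabelsError):
        roc_curve([0.1, 0.2], [True, True])
    with pytest.raises(DegenerateLabelsError):
        youden_threshold([0.1, 0.2], [False, False])


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_roc_matches_brute_force_counting(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.random(20), 2)  # rounding forces ties
    labels = rng.random(20) < 0.5
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    curve = roc_curve(scores, labels)
    for t, sens, spec in zip(curve.thresholds, curve.sensitivity, curve.specificity):
        bs, bp = brute_force_roc(scores, labels, t)
        assert sens == pytest.approx(bs, abs=1e-12)
        assert spec == pytest.approx(bp, abs=1e-12)


@given(
    st.lists(st.integers(min_value=0, max_value=100), min_size=4, max_size=200),
    st.randoms(use_true_random=False),
)
def test_auc_and_youden_match_oracles(raw, rnd):
    """Exhaustive-enumeration and pair-counting oracles agree exactly."""
    scores = np.array(raw, dtype=float) / 20.0
    labels = np.array([rnd.random() < 0.5 for _ in raw])
    if labels.all() or not labels.any():
        labels[0] = not labels[0]
    assert auc(roc_curve(scores, labels)) == pytest.approx(
        brute_force_auc(scores, labels), abs=1e-12
    )
    assert youden_threshold(scores, labels).j == pytest.approx(
        brute_force_best_j(scores, labels), abs=1e-12
    )


def test_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    scores = np.round(rng.random(300), 2)
    labels = rng.random(300) < 0.3
    assert auc(roc_curve(scores, labels)) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12
    )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(8)
    scores = rng.random(100) * 5
    labels = rng.random(100) < 0.4
    a1 = auc(roc_curve(scores, labels))
    a2 = auc(roc_curve(np.expm1(scores) / 60.0, labels))
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_disjoint_stage_intervals_recover_boundaries():
    """Scores separated by stage put every cutpoint between the intervals."""
    rng = np.random.default_rng(9)
    stages = np.repeat([0, 1, 2, 3], 30)
    lows = np.array([0.0, 1.0, 2.0, 3.0])[stages]
    scores = lows + 0.8 * rng.random(stages.size)
    ts, results = derive_stage_thresholds((scores, stages))
    for k, cut in enumerate(ts.cutpoints, start=1):
        assert (k - 1) * 1.0 + 0.8 <= cut <= k * 1.0
    assert all(r.j == pytest.approx(1.0) for r in results)


def test_missing_stage_signalled():
    scores = np.array([0.1, 0.2, 0.9, 1.0])
    stages = np.array([0, 0, 1, 1])  # no moderate/severe patients
    with pytest.raises(MissingStageError):
        derive_stage_thresholds((scores, stages))
    # restricting to the boundaries the cohort supports succeeds
    ts, _ = derive_stage_thresholds((scores, stages), boundaries=(1,))
    assert len(ts.cutpoints) == 1 and 0.2 < ts.cutpoints[0] < 0.9


def test_default_cohort_yields_increasing_cutpoints(study_cohort):
    ts, _ = derive_stage_thresholds(study_cohort)
    assert ts.cutpoints[0] < ts.cutpoints[1] < ts.cutpoints[2]


def test_eye_level_unit_switch(study_cohort):
    scores_p, stages_p = cohort_scores_and_stages(study_cohort, unit="patient")
    scores_e, stages_e = cohort_scores_and_stages(study_cohort, unit="eye")
    assert scores_e.size > scores_p.size  # two eyes for most patients


def test_sweep_extremes_and_monotonicity(study_cohort):
    grid = np.linspace(0.0, 5.0, 26)
    sweep = referral_sweep(study_cohort, grid)
    scores, stages = cohort_scores_and_stages(study_cohort)
    below = sweep.iloc[0]  # cutoff 0: everyone with score > 0 referred
    assert below["referred_fraction"] == pytest.approx((scores > 0).mean())
    top = sweep.iloc[-1]  # cutoff 5: nobody referred, every case missed
    assert top["referred_fraction"] == 0.0
    assert top["missed_severe_fraction"] == 1.0
    assert np.all(np.diff(sweep["referred_fraction"]) <= 1e-12)
    assert np.all(np.diff(sweep["missed_moderate_fraction"]) >= -1e-12)
    assert np.all(np.diff(sweep["missed_severe_fraction"]) >= -1e-12)


def test_sweep_rejects_bad_grid(study_cohort):
    with pytest.raises(ValueError):
        referral_sweep(study_cohort, [])
    with pytest.raises(ValueError):
        referral_sweep(study_cohort, [6.0])
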