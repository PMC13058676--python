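"""Mapping continuous severity scores to ordinal stages, and referral policies.

A :class:`ThresholdSet` carries strictly increasing cutpoints ``t1 < t2 < ...``
on the 0–5 score axis with left-open/right-closed interval semantics: stage 0
iff ``s <= t1``, stage k iff ``t_k < s <= t_{k+1}``, top stage iff
``s > t_last``.  Three cutpoints yield the 4-stage clinical scale
(no/mild/moderate/severe); four cutpoints add proliferative, as the
manufacturer's default 1/2/3/4 grid does.

Referral is decided per patient on the worse-eye severity:

* ``stage_based`` — refer iff the mapped patient stage is more than mild
  (moderate or worse), the conventional international criterion;
* ``score_based`` — refer iff the worse-eye score exceeds a cutoff chosen
  for the local population (the "Greifswald modification" uses 0.1, below
  the mild/moderate boundary, trading specificity for sensitivity).

In the hypothetical screening scenario, every patient without a usable
algorithm result (no image, incomplete set, quality-rejected) is referred
for an in-person exam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    DRStage,
    PatientRecord,
    ScreeningStatus,
    screening_status,
    worse_eye_score,
)
from .errors import ConfigError, NoScoreError

__all__ = [
    "ThresholdSet",
    "ReferralPolicy",
    "MANUFACTURER_THRESHOLDS",
    "GREIFSWALD_CUTOFF",
    "score_to_stage",
    "patient_stage",
    "refer",
]

#: Score-based referral cutoff of the Greifswald modification.
GREIFSWALD_CUTOFF = 0.1


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered cutpoints mapping a continuous score to ordinal stages."""

    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        object.__setattr__(self, "cutpoints", cp)
        if not 1 <= len(cp) <= 4:
            raise ConfigError("threshold set needs 1-4 cutpoints")
        if any(not 0.0 <= c <= 5.0 for c in cp):
            raise ConfigError(f"cutpoints {cp} outside [0, 5]")
        if any(a >= b for a, b in zip(cp, cp[1:])):
            raise ConfigError(f"cutpoints {cp} not strictly increasing")

    @property
    def n_stages(self) -> int:
        return len(self.cutpoints) + 1

    def stage_of(self, score: float) -> DRStage:
        return score_to_stage(score, self)

    def stages_of(self, scores: np.ndarray) -> np.ndarray:
        """Vectorised stage mapping (integer codes)."""
        s = np.asarray(scores, dtype=float)
        if np.any((s < 0.0) | (s > 5.0)):
            raise ValueError("scores outside [0, 5]")
        # first index where cutpoint >= s: upper bounds are stage-inclusive
        return np.searchsorted(np.asarray(self.cutpoints), s, side="left")


#: Manufacturer default grid: 0–1 no, 1–2 mild, 2–3 moderate, 3–4 severe,
#: 4–5 proliferative.
MANUFACTURER_THRESHOLDS = ThresholdSet((1.0, 2.0, 3.0, 4.0))


def score_to_stage(score: float, thresholds: ThresholdSet) -> DRStage:
    """Map one score to its stage (left-open/right-closed intervals)."""
    if not 0.0 <= score <= 5.0:
        raise ValueError(f"score {score} outside [0, 5]")
    return DRStage(int(thresholds.stages_of(np.array([score]))[0]))


def patient_stage(patient: PatientRecord, thresholds: ThresholdSet) -> DRStage:
    """Stage of the patient's worse-eye (maximum) score."""
    return score_to_stage(worse_eye_score(patient), thresholds)


@dataclass(frozen=True)
class ReferralPolicy:
    """How a graded patient's algorithm output triggers referral."""

    mode: str = "stage_based"  # "stage_based" | "score_based"
    cutoff: float = GREIFSWALD_CUTOFF

    def __post_init__(self) -> None:
        if self.mode not in ("stage_based", "score_based"):
            raise ConfigError(f"unknown referral mode {self.mode!r}")
        if not 0.0 <= self.cutoff <= 5.0:
            raise ConfigError(f"cutoff {self.cutoff} outside [0, 5]")


def refer(
    patient: PatientRecord,
    policy: ReferralPolicy,
    thresholds: ThresholdSet,
    scenario: str = "screening",
    algorithm_kind: str = "regression",
) -> str:
    """Referral decision: ``"refer"``, ``"no_refer"`` or ``"no_result"``.

    ``scenario="screening"`` refers every patient without a usable result;
    ``scenario="diagnosable_only"`` returns ``"no_result"`` for them instead
    (the controlled-study view that ignores unscreenable patients).
    """
    if scenario not in ("screening", "diagnosable_only"):
        raise ValueError(f"unknown scenario {scenario!r}")
    status = screening_status(patient, algorithm_kind)
    if status is not ScreeningStatus.GRADED:
        return "refer" if scenario == "screening" else "no_result"
    if policy.mode == "score_based":
        return "refer" if worse_eye_score(patient) > policy.cutoff else "no_refer"
    try:
        stage = patient_stage(patient, thresholds)
    except NoScoreError:
        return "refer" if scenario == "screening" else "no_result"
    return "refer" if stage.collapsed() >= DRStage.MODERATE else "no_refer"
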