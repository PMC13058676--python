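"""Core data model for screened patients, eyes and gradability accounting.

A screening cohort is a list of :class:`PatientRecord`, each holding one or
two :class:`EyeAssessment` objects.  Every patient carries a gold-standard
grade from dilated fundoscopy; algorithm outputs attach per eye.  Two
algorithm families are modelled:

* ``classifier`` — needs a complete image set per patient and may reject a
  patient outright for image quality (no output at all);
* ``regression`` — scores every available image on a continuous 0–5 severity
  scale plus a 0–100 quality score, flagging (but still scoring) low-quality
  images.

The four mutually exclusive per-patient screening statuses
(:class:`ScreeningStatus`) and their tallies (:class:`CohortAccounting`)
formalise the "how many patients actually got a result" bookkeeping that a
real-world screening evaluation needs before any sensitivity can be quoted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import pandas as pd

from ._util import round_half_away
from .errors import EmptyCohortError, NoScoreError, UngradedPatientError

__all__ = [
    "DRStage",
    "NOT_ANALYSABLE",
    "EyeAssessment",
    "PatientRecord",
    "ScreeningStatus",
    "CohortAccounting",
    "worse_eye_stage",
    "worse_eye_score",
    "screening_status",
    "patient_classifier_stage",
    "cohort_accounting",
    "cohort_to_frame",
    "frame_to_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "DEFAULT_QUALITY_FLAG_CUTOFF",
]

#: Regression-algorithm images with quality below this are flagged as
#: recommended-for-rejection (they still carry a usable severity score).
DEFAULT_QUALITY_FLAG_CUTOFF = 25.0

#: Sentinel classifier output: image quality too poor, no stage produced.
NOT_ANALYSABLE = "not_analysable"


class DRStage(enum.IntEnum):
    """Ordinal diabetic retinopathy severity.

    Gold-standard patient grades use only 0–3 (severe subsumes
    proliferative); algorithm stage outputs may use the full 0–4 range and
    must be collapsed with :meth:`collapsed` before comparison with truth.
    """

    NO_DR = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    PROLIFERATIVE = 4

    def collapsed(self) -> "DRStage":
        """Map proliferative onto severe (4 → 3) for 4-class comparisons."""
        return DRStage(min(int(self), 3))


ClassifierOutput = Union[DRStage, str, None]  # DRStage | NOT_ANALYSABLE | None


class ScreeningStatus(enum.Enum):
    """Per-patient, per-algorithm outcome of the screening attempt."""

    NO_IMAGE = "no_image"
    INCOMPLETE_SET = "incomplete_set"
    REJECTED_QUALITY = "rejected_quality"
    GRADED = "graded"


@dataclass
class EyeAssessment:
    """One eye's gold grade, algorithm outputs and image availability.

    ``score`` and ``quality`` are present iff ``image_available``.
    ``in_complete_set`` records whether the patient's full image set (as a
    classifier-type algorithm requires) was acquired.
    """

    laterality: str  # "left" | "right"
    gold_stage: DRStage | None = None
    score: float | None = None
    quality: float | None = None
    image_available: bool = False
    in_complete_set: bool = False
    classifier_stage: ClassifierOutput = None

    def __post_init__(self) -> None:
        if self.image_available:
            if self.score is None or self.quality is None:
                raise ValueError("available image must carry score and quality")
            if not 0.0 <= self.score <= 5.0:
                raise ValueError(f"score {self.score} outside [0, 5]")
            if not 0.0 <= self.quality <= 100.0:
                raise ValueError(f"quality {self.quality} outside [0, 100]")
        elif self.score is not None or self.quality is not None:
            raise ValueError("score/quality present without an image")

    def quality_flagged(self, cutoff: float = DEFAULT_QUALITY_FLAG_CUTOFF) -> bool:
        """True if the image was scored but recommended for rejection."""
        return self.quality is not None and self.quality < cutoff


@dataclass
class PatientRecord:
    """A screened patient: one or two eyes plus the exam flag."""

    patient_id: str
    eyes: list[EyeAssessment] = field(default_factory=list)
    exam_done: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.eyes) <= 2:
            raise ValueError("a patient has one or two eye records")

    @property
    def gold_patient_stage(self) -> DRStage:
        return worse_eye_stage(self)


def worse_eye_stage(patient: PatientRecord) -> DRStage:
    """Gold patient stage: the most severe grade across the graded eyes."""
    stages = [e.gold_stage for e in patient.eyes if e.gold_stage is not None]
    if not stages:
        raise UngradedPatientError(f"patient {patient.patient_id} has no graded eye")
    return DRStage(max(int(s.collapsed()) for s in stages))


def worse_eye_score(patient: PatientRecord) -> float:
    """Worse-eye continuous severity score (max over scored eyes).

    Quality-flagged eyes participate: a flagged image still carries a usable
    score.
    """
    scores = [e.score for e in patient.eyes if e.score is not None]
    if not scores:
        raise NoScoreError(f"patient {patient.patient_id} has no scored eye")
    return max(scores)


def patient_classifier_stage(patient: PatientRecord) -> DRStage | None:
    """Patient-level classifier output: the worse of the per-eye stages."""
    stages = [
        e.classifier_stage
        for e in patient.eyes
        if isinstance(e.classifier_stage, DRStage)
    ]
    if not stages:
        return None
    return DRStage(max(int(s) for s in stages))


def screening_status(patient: PatientRecord, algorithm_kind: str) -> ScreeningStatus:
    """Resolve the patient's screening outcome for one algorithm family.

    classifier: NO_IMAGE → INCOMPLETE_SET → REJECTED_QUALITY → GRADED, in
    that precedence; a classifier needs both eyes with complete image sets.
    regression: NO_IMAGE or GRADED only (flagged eyes stay GRADED).
    """
    if algorithm_kind not in ("classifier", "regression"):
        raise ValueError(f"unknown algorithm kind {algorithm_kind!r}")
    imaged = [e for e in patient.eyes if e.image_available]
    if not imaged:
        return ScreeningStatus.NO_IMAGE
    if algorithm_kind == "regression":
        return ScreeningStatus.GRADED
    if len(imaged) < 2 or any(not e.in_complete_set for e in imaged):
        return ScreeningStatus.INCOMPLETE_SET
    if any(e.classifier_stage == NOT_ANALYSABLE for e in imaged):
        return ScreeningStatus.REJECTED_QUALITY
    return ScreeningStatus.GRADED


@dataclass
class CohortAccounting:
    """Counts and percentages of patients per screening status.

    The denominator is the number of patients who underwent the
    gold-standard exam.  ``incomplete_pct_of_imaged`` additionally reports
    the incomplete-set share among patients with at least one image, because
    published figures sometimes quote that share against the imaged
    denominator rather than the full exam denominator.
    """

    counts: dict[ScreeningStatus, int]
    denominator: int

    @property
    def proportions(self) -> dict[ScreeningStatus, float]:
        """Percentages over the exam denominator, rounded to 1 dp."""
        return {
            s: round_half_away(100.0 * self.counts.get(s, 0) / self.denominator, 1)
            for s in ScreeningStatus
        }

    @property
    def incomplete_pct_of_imaged(self) -> float:
        imaged = self.denominator - self.counts.get(ScreeningStatus.NO_IMAGE, 0)
        if imaged == 0:
            return float("nan")
        return round_half_away(
            100.0 * self.counts.get(ScreeningStatus.INCOMPLETE_SET, 0) / imaged, 1
        )

    @property
    def lacking_prerequisites_pct(self) -> float:
        """No-image plus incomplete-set share: patients a classifier never sees."""
        n = self.counts.get(ScreeningStatus.NO_IMAGE, 0) + self.counts.get(
            ScreeningStatus.INCOMPLETE_SET, 0
        )
        return round_half_away(100.0 * n / self.denominator, 1)

    @classmethod
    def from_counts(
        cls,
        no_image: int = 0,
        incomplete_set: int = 0,
        rejected_quality: int = 0,
        graded: int = 0,
    ) -> "CohortAccounting":
        counts = {
            ScreeningStatus.NO_IMAGE: no_image,
            ScreeningStatus.INCOMPLETE_SET: incomplete_set,
            ScreeningStatus.REJECTED_QUALITY: rejected_quality,
            ScreeningStatus.GRADED: graded,
        }
        denom = sum(counts.values())
        if denom == 0:
            raise EmptyCohortError("no patients in accounting")
        return cls(counts=counts, denominator=denom)


def cohort_accounting(
    cohort: Sequence[PatientRecord], algorithm_kind: str
) -> CohortAccounting:
    """Tally screening statuses over the patients with a completed exam."""
    examined = [p for p in cohort if p.exam_done]
    if not examined:
        raise EmptyCohortError("empty input: no examined patients")
    counts = {s: 0 for s in ScreeningStatus}
    for p in examined:
        counts[screening_status(p, algorithm_kind)] += 1
    return CohortAccounting(counts=counts, denominator=len(examined))


# ---------------------------------------------------------------------------
# Tabular interchange: one CSV row per eye.

_COLUMNS = [
    "patient_id",
    "laterality",
    "gold_stage",
    "score",
    "quality",
    "image_available",
    "in_complete_set",
    "classifier_stage",
]


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for e in p.eyes:
            if isinstance(e.classifier_stage, DRStage):
                cls_out: object = int(e.classifier_stage)
            elif e.classifier_stage == NOT_ANALYSABLE:
                cls_out = NOT_ANALYSABLE
            else:
                cls_out = ""
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "laterality": e.laterality,
                    "gold_stage": "" if e.gold_stage is None else int(e.gold_stage),
                    "score": "" if e.score is None else e.score,
                    "quality": "" if e.quality is None else e.quality,
                    "image_available": int(e.image_available),
                    "in_complete_set": int(e.in_complete_set),
                    "classifier_stage": cls_out,
                }
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    cohort: list[PatientRecord] = []
    for pid, group in frame.groupby("patient_id", sort=False):
        eyes = []
        for _, row in group.iterrows():
            gold = row["gold_stage"]
            gold_stage = None
            if gold != "" and pd.notna(gold):
                # severe subsumes proliferative in the gold standard
                gold_stage = DRStage(int(gold)).collapsed()
            cls_raw = row["classifier_stage"]
            cls_out: ClassifierOutput = None
            if cls_raw == NOT_ANALYSABLE:
                cls_out = NOT_ANALYSABLE
            elif cls_raw != "" and pd.notna(cls_raw):
                cls_out = DRStage(int(float(cls_raw)))
            score = row["score"]
            quality = row["quality"]
            eyes.append(
                EyeAssessment(
                    laterality=str(row["laterality"]),
                    gold_stage=gold_stage,
                    score=None if score == "" or pd.isna(score) else float(score),
                    quality=None if quality == "" or pd.isna(quality) else float(quality),
                    image_available=bool(int(row["image_available"])),
                    in_complete_set=bool(int(row["in_complete_set"])),
                    classifier_stage=cls_out,
                )
            )
        cohort.append(PatientRecord(patient_id=str(pid), eyes=eyes))
    return cohort


def write_cohort_csv(cohort: Iterable[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, keep_default_na=True)
    return frame_to_cohort(frame)
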