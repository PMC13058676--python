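"""Seeded synthetic screening cohorts with the structure real screening data has.

The generator emulates a non-mydriatic DR screening population: ordinal
gold-standard stage per patient (worse eye), a correlated fellow eye,
stage-conditional continuous severity scores concentrated near zero for
healthy eyes, per-patient latent imaging difficulty driving the 0–100
quality scores of both eyes, and the real-world loss channels — patients
with no acquirable image, incomplete image sets (including single-eye
patients), and classifier quality rejections linked to image quality
through a logistic model.

Default parameters target the composition of a 1716-patient specialist-
centre cohort: stage mix 61.0/20.8/10.4/7.8%, 5.7% no-image, 2.1%
incomplete sets, ≈25.5% classifier rejections, ≈7% of patients with a
quality-flagged eye, and ≈67.6% of eye scores in [0, 0.1].

Randomness: one integer seed feeds five named substreams (stages, scores,
quality, missingness, classifier), each drawing fixed-size arrays, so
toggling one process never shifts the draws of another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import DRStage, EyeAssessment, NOT_ANALYSABLE, PatientRecord
from .errors import ConfigError

__all__ = [
    "ScoreComponent",
    "GeneratorConfig",
    "generate_cohort",
    "eye_stage_distribution",
    "expected_score_histogram",
    "expected_quality_flag_rate",
    "config_hash",
]

_STREAMS = {"stages": 0, "scores": 1, "quality": 2, "missingness": 3, "classifier": 4}

#: Scaled-Beta mixture components per gold stage: (weight, alpha, beta) with
#: score = 5 · Beta(alpha, beta).  Each stage mixes a "subclinical" component
#: hugging zero (Beta(1, 220): 98.8% of its mass below score 0.1) with a
#: stage-typical component; the subclinical weights fall with severity and
#: are tuned so the closed-form mass of eye scores in [0, 0.1] is ≈0.676.
_DEFAULT_SCORE_MODEL: dict[int, tuple[tuple[float, float, float], ...]] = {
    0: ((0.945, 1.0, 220.0), (0.055, 1.5, 10.0)),
    1: ((0.355, 1.0, 220.0), (0.645, 2.2, 12.0)),
    2: ((0.05, 1.0, 220.0), (0.95, 6.0, 16.0)),
    3: ((0.02, 1.0, 220.0), (0.98, 5.0, 6.0)),
}

#: Row-stochastic confusion kernel for the classifier-type algorithm:
#: P(predicted stage j | gold stage g), predictions 0–4.
_DEFAULT_CONFUSION_KERNEL: tuple[tuple[float, ...], ...] = (
    (0.84, 0.11, 0.04, 0.01, 0.00),
    (0.16, 0.60, 0.18, 0.05, 0.01),
    (0.03, 0.07, 0.62, 0.23, 0.05),
    (0.01, 0.03, 0.09, 0.57, 0.30),
)


@dataclass(frozen=True)
class ScoreComponent:
    weight: float
    alpha: float
    beta: float


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort.

    ``stage_probs`` is the gold patient-stage (worse eye) distribution;
    ``contralateral_downgrade`` the probability that the fellow eye is one
    stage lower.  ``quality_mean``/``quality_sd`` parameterise the per-eye
    truncated normal on [0, 100]; ``difficulty_coef`` scales the shared
    per-patient standard-normal imaging-difficulty latent that correlates
    the two eyes' qualities.  ``reject_intercept``/``reject_slope`` define
    P(classifier rejects | mean quality q) = expit(intercept + slope·q),
    calibrated at the defaults to an overall rejection share of ≈25.5%.
    """

    n_patients: int = 1716
    stage_probs: tuple[float, float, float, float] = (
        1046 / 1716,
        357 / 1716,
        179 / 1716,
        134 / 1716,
    )
    contralateral_downgrade: float = 0.3
    score_model: dict[int, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: {k: v for k, v in _DEFAULT_SCORE_MODEL.items()}
    )
    quality_mean: float = 55.0
    quality_sd: float = 12.0
    difficulty_coef: float = 12.0
    p_no_image: float = 0.057
    p_incomplete_set: float = 0.021
    p_single_eye_given_incomplete: float = 0.7
    reject_intercept: float = 3.18
    reject_slope: float = -0.08
    confusion_kernel: tuple[tuple[float, ...], ...] = _DEFAULT_CONFUSION_KERNEL
    quality_flag_cutoff: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        sp = np.asarray(self.stage_probs, dtype=float)
        if sp.size != 4 or np.any(sp < 0) or abs(sp.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"stage_probs must be a 4-vector summing to 1 (got {self.stage_probs})"
            )
        for name in ("contralateral_downgrade", "p_no_image", "p_incomplete_set",
                     "p_single_eye_given_incomplete"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.p_no_image >= 1.0:
            raise ConfigError("p_no_image must be < 1")
        for stage, comps in self.score_model.items():
            if stage not in (0, 1, 2, 3):
                raise ConfigError(f"score model stage {stage} not in 0-3")
            w = sum(c[0] for c in comps)
            if abs(w - 1.0) > 1e-9:
                raise ConfigError(f"stage {stage} component weights sum to {w}, not 1")
            if any(c[1] <= 0 or c[2] <= 0 for c in comps):
                raise ConfigError("Beta shape parameters must be positive")
        kern = np.asarray(self.confusion_kernel, dtype=float)
        if kern.shape != (4, 5) or np.any(kern < 0) or np.any(
            np.abs(kern.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ConfigError("confusion kernel must be 4x5 row-stochastic")
        if self.quality_sd <= 0:
            raise ConfigError("quality_sd must be positive")
        if not 0.0 <= self.quality_flag_cutoff <= 100.0:
            raise ConfigError("quality_flag_cutoff outside [0, 100]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_model"] = {
            str(k): [list(c) for c in v] for k, v in self.score_model.items()
        }
        d["confusion_kernel"] = [list(r) for r in self.confusion_kernel]
        d["stage_probs"] = list(self.stage_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "stage_probs" in d:
            d["stage_probs"] = tuple(float(x) for x in d["stage_probs"])
        if "score_model" in d:
            d["score_model"] = {
                int(k): tuple(tuple(float(x) for x in c) for c in v)
                for k, v in d["score_model"].items()
            }
        if "confusion_kernel" in d:
            d["confusion_kernel"] = tuple(
                tuple(float(x) for x in r) for r in d["confusion_kernel"]
            )
        return cls(**d)


def config_hash(config: GeneratorConfig) -> str:
    """Stable hash of the full parameterisation, for provenance sidecars."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    return {name: np.random.default_rng([seed, i]) for name, i in _STREAMS.items()}


def eye_stage_distribution(config: GeneratorConfig) -> np.ndarray:
    """Closed-form eye-level stage frequencies implied by the patient model.

    One eye carries the patient (worse-eye) stage; the fellow eye is one
    stage lower with probability ``contralateral_downgrade`` (floored at 0).
    """
    p = np.asarray(config.stage_probs, dtype=float)
    d = config.contralateral_downgrade
    fellow = np.zeros(4)
    fellow[0] = p[0] + d * p[1]
    for k in (1, 2):
        fellow[k] = (1 - d) * p[k] + d * p[k + 1]
    fellow[3] = (1 - d) * p[3]
    return (p + fellow) / 2.0


def expected_score_histogram(
    config: GeneratorConfig, bin_edges: Sequence[float]
) -> np.ndarray:
    """Closed-form expected fraction of eye scores per bin (mixture CDF differences).

    Missingness is independent of the score process, so the conditional
    distribution of observed eye scores is the stage mixture itself.
    """
    edges = np.asarray(list(bin_edges), dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigError("bin edges must be >= 2 and strictly increasing")
    if edges[0] < 0.0 or edges[-1] > 5.0:
        raise ConfigError("bin edges outside [0, 5]")
    w_eye = eye_stage_distribution(config)
    cdf = np.zeros_like(edges)
    for stage, comps in config.score_model.items():
        for weight, a, b in comps:
            cdf += w_eye[stage] * weight * stats.beta.cdf(edges / 5.0, a, b)
    return np.diff(cdf)


def expected_quality_flag_rate(config: GeneratorConfig, n_nodes: int = 80) -> float:
    """Marginal P(eye quality < cutoff), by Gauss–Hermite quadrature over the
    latent difficulty, with the per-eye truncated normal tail in closed form."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    # difficulty d ~ N(0,1); eye quality | d ~ TruncNorm(mean - coef*d, sd) on [0,100]
    loc = config.quality_mean - config.difficulty_coef * nodes
    a = (0.0 - loc) / config.quality_sd
    b = (100.0 - loc) / config.quality_sd
    tail = stats.truncnorm.cdf(
        config.quality_flag_cutoff, a, b, loc=loc, scale=config.quality_sd
    )
    return float(np.sum(weights * tail) / np.sqrt(2.0 * np.pi))


def _draw_scores(
    stages_flat: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    scores = np.zeros(stages_flat.size)
    for stage, comps in config.score_model.items():
        mask = stages_flat == stage
        n = int(mask.sum())
        if n == 0:
            continue
        w = np.array([c[0] for c in comps])
        pick = rng.choice(len(comps), size=n, p=w)
        vals = np.empty(n)
        for j, (_, a, b) in enumerate(comps):
            cnt = int((pick == j).sum())
            vals[pick == j] = 5.0 * rng.beta(a, b, size=cnt)
        scores[mask] = vals
    return np.clip(scores, 0.0, 5.0)


def generate_cohort(
    config: GeneratorConfig | None = None,
    n_patients: int | None = None,
    seed: int | None = None,
) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort of :class:`PatientRecord`.

    Scores are drawn conditional on each eye's gold stage before any
    missingness is applied; a no-image patient's scores are then erased, so
    toggling missingness never changes the score draws of other patients.
    """
    config = GeneratorConfig() if config is None else config
    config.validate()
    n = config.n_patients if n_patients is None else int(n_patients)
    if n <= 0:
        raise ConfigError("n_patients must be positive")
    seed = config.seed if seed is None else int(seed)
    rngs = _rngs(seed)

    # --- stages (worse eye per patient, downgraded fellow eye) ------------
    rs = rngs["stages"]
    worse = rs.choice(4, size=n, p=np.asarray(config.stage_probs))
    downgrade = rs.random(n) < config.contralateral_downgrade
    fellow = np.where(downgrade, np.maximum(worse - 1, 0), worse)
    worse_is_right = rs.random(n) < 0.5
    eye_stages = np.empty((n, 2), dtype=int)  # col 0 = left, col 1 = right
    eye_stages[:, 0] = np.where(worse_is_right, fellow, worse)
    eye_stages[:, 1] = np.where(worse_is_right, worse, fellow)

    # --- scores -----------------------------------------------------------
    scores = _draw_scores(eye_stages.ravel(), config, rngs["scores"]).reshape(n, 2)

    # --- quality ----------------------------------------------------------
    rq = rngs["quality"]
    difficulty = rq.standard_normal(n)
    loc = config.quality_mean - config.difficulty_coef * difficulty
    a = (0.0 - loc) / config.quality_sd
    b = (100.0 - loc) / config.quality_sd
    u = rq.random((n, 2))
    # inverse-CDF sampling keeps the draw count fixed per patient
    qual = stats.truncnorm.ppf(
        u, a[:, None], b[:, None], loc=loc[:, None], scale=config.quality_sd
    )

    # --- missingness ------------------------------------------------------
    rm = rngs["missingness"]
    no_image = rm.random(n) < config.p_no_image
    p_inc_cond = (
        config.p_incomplete_set / (1.0 - config.p_no_image)
        if config.p_no_image < 1.0
        else 0.0
    )
    incomplete = (~no_image) & (rm.random(n) < p_inc_cond)
    single_eye = incomplete & (
        rm.random(n) < config.p_single_eye_given_incomplete
    )
    missing_eye = rm.integers(0, 2, size=n)

    # --- classifier: quality-linked rejection, then confusion kernel ------
    rc = rngs["classifier"]
    mean_qual = qual.mean(axis=1)
    p_reject = expit(config.reject_intercept + config.reject_slope * mean_qual)
    rejected = (~no_image) & (~incomplete) & (rc.random(n) < p_reject)
    kern = np.asarray(config.confusion_kernel)
    cum = np.cumsum(kern, axis=1)
    u_cls = rc.random(n)
    predicted = (u_cls[:, None] > cum[worse]).sum(axis=1)

    cohort: list[PatientRecord] = []
    width = len(str(n))
    for i in range(n):
        eyes = []
        for j, side in enumerate(("left", "right")):
            available = not no_image[i] and not (single_eye[i] and missing_eye[i] == j)
            if rejected[i]:
                cls_out: object = NOT_ANALYSABLE
            elif available and not no_image[i] and not incomplete[i]:
                cls_out = DRStage(int(predicted[i]))
            else:
                cls_out = None
            eyes.append(
                EyeAssessment(
                    laterality=side,
                    gold_stage=DRStage(int(eye_stages[i, j])),
                    score=float(scores[i, j]) if available else None,
                    quality=float(qual[i, j]) if available else None,
                    image_available=available,
                    in_complete_set=available and not incomplete[i],
                    classifier_stage=cls_out if available else None,
                )
            )
        cohort.append(PatientRecord(patient_id=f"P{i:0{width}d}", eyes=eyes))
    return cohort
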