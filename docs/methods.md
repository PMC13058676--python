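# Methods

## Data model

A cohort is a list of patients, each with one or two eye assessments. The
gold standard is a dilated-fundoscopy ETDRS-style grade per eye; the
patient-level grade is the worse (maximum) eye. Gold patient grades use
four classes (no / mild / moderate / severe DR, severe subsuming
proliferative); algorithm stage outputs may use five and are collapsed
(proliferative → severe) before any comparison with truth.

Two algorithm families attach outputs to eyes:

* **classifier** — requires both eyes, each with a complete image set; may
  reject a patient for image quality, producing no stage at all. Its
  patient-level statuses are NO_IMAGE, INCOMPLETE_SET, REJECTED_QUALITY or
  GRADED, mutually exclusive and exhaustive.
* **regression** — produces a continuous severity score in [0, 5] and a
  quality score in [0, 100] for every available image; images with quality
  below 25 are *flagged* as recommended-for-rejection but still scored, so
  the only loss channel is NO_IMAGE. Flagged eyes participate in the
  worse-eye maximum and in calibration: the design position is that a
  flagged score is a usable score.

The classifier output is conceptually patient-level; it is stored on each
imaged eye so the one-row-per-eye CSV schema is uniform, and patient-level
readers take the worse of the per-eye values.

## Dual-denominator metrics

Positives are gold more-than-mild (stage ≥ moderate) unless the severe
variant is requested. For each screening mode:

* `sens_d = TP / graded positives`, `spec_d = TN / graded negatives` — the
  controlled-study view;
* `sens_a = TP / all positives`, `spec_a = TN / all negatives` — the
  real-world view, in which every non-graded patient counts against both
  metrics (an unscreened positive is undetected; an unscreened negative is
  not cleared).

The unrounded identity `sens_a · P = sens_d · P_d` holds by construction.
`reconstruct_from_aggregates` inverts four printed proportions plus the
class totals into TP, graded counts, patients without a result, and the
screening-scenario referral burden `no_result + TP + FP`, rounding counts
half-away-from-zero as clinical tables do. Exam-load change is reported as
`−100·(1 − referred/total)` exactly; two published cells we compared
against appear to truncate rather than round at the second decimal, so
consumers should expect ≤ 0.08 pp discrepancies at that precision.

Severe-DR sensitivity uses exact-stage detection (predicted severe-or-worse
among gold severe) by default, with a referral-based variant behind a flag.
Specificity always concerns gold no/mild patients, a negative call being
"not referred".

## Stage mapping and referral policies

A `ThresholdSet` holds 1–4 strictly increasing cutpoints on [0, 5] with
left-open/right-closed intervals: stage 0 iff s ≤ t1, stage k iff
t_k < s ≤ t_{k+1}. A score exactly at a printed upper bound therefore
belongs to the lower stage, which is how published interval notation like
"(>0.07–1.02)" reads literally. Referral is always decided on the
patient's worse-eye severity:

* `stage_based` — refer iff the mapped stage is moderate or worse;
* `score_based` — refer iff worse-eye score > cutoff. The Greifswald
  modification is `score_based` with cutoff 0.1 for the referral decision
  while confusion matrices keep the Youden-calibrated stage labels.

In the hypothetical screening scenario, all patients with status NO_IMAGE,
INCOMPLETE_SET or REJECTED_QUALITY are referred; in the diagnosable-only
scenario they yield "no result" instead.

## ROC, AUC and Youden calibration

Scores are binarised by "positive iff score > t". Candidate thresholds are
the midpoints between consecutive distinct observed scores plus sentinels
below the minimum and above the maximum — this realises every achievable
operating point and leaves no ambiguity at data values. Sensitivity and
specificity are exact counts (sorted-array search, O(n log n)). AUC is the
trapezoid over the empirical curve, which equals the Mann–Whitney statistic
P(score_pos > score_neg) + ½·P(tie); no smoothing or binormal fit is
applied. The Youden optimum takes the first (smallest) threshold at
maximal J, preferring sensitivity on ties — the conservative choice for
screening.

Per-stage calibration binarises the ordinal truth cumulatively (positive
iff gold ≥ k) for k = 1, 2, 3, one Youden optimum per boundary. Crossing
cutpoints raise an error rather than being silently reordered; a cohort
missing a stage raises unless the requested boundaries are restricted.
Calibration operates on patient-level worse-eye scores by default (every
reported metric is patient-level); an eye-level switch exists because
score-distribution figures are usually eye-level.

## Synthetic cohort generator

The generator emulates the composition of a 1716-patient non-mydriatic
screening population at a specialist diabetes centre. Defaults:

| parameter | default | meaning |
|---|---|---|
| `stage_probs` | 1046/357/179/134 ÷ 1716 | worse-eye gold stage distribution |
| `contralateral_downgrade` | 0.3 | P(fellow eye one stage lower) |
| `score_model` | per-stage scaled-Beta mixtures | stage-conditional eye scores |
| `quality_mean`, `quality_sd` | 55, 12 | per-eye truncated normal on [0, 100] |
| `difficulty_coef` | 12 | weight of the shared per-patient latent N(0,1) |
| `p_no_image` | 0.057 | patients with no acquirable image |
| `p_incomplete_set` | 0.021 | marginal share with an incomplete set |
| `p_single_eye_given_incomplete` | 0.7 | incomplete sets that are single-eye |
| `reject_intercept`, `reject_slope` | 3.18, −0.08 | logistic quality→rejection link |
| `quality_flag_cutoff` | 25 | regression flag boundary |

Each stage mixes a "subclinical" component hugging zero (Beta(1, 220)
scaled to [0, 5]; 98.8% of its mass below 0.1) with a stage-typical
component; weights were set once, via the closed-form expected histogram,
so that the expected eye-score mass in [0, 0.1] is 0.676 — the hallmark of
a screening population dominated by healthy eyes. The quality model
(eye sd 12, shared-latent coefficient 12) yields a ≈3.8% per-eye flag rate,
≈7% of patients with a flagged eye and ≈0.8% with both eyes flagged; the
rejection intercept was calibrated once by Monte Carlo so the expected
classifier rejection share is ≈25.5% of all patients. `p_incomplete_set`
is the *marginal* share and is drawn conditionally
(p/(1 − p_no_image)) among imaged patients.

Randomness: one integer seed feeds five named substreams (stages, scores,
quality, missingness, classifier), each drawing fixed-size arrays, so
switching one process off never perturbs another — verified by a
ceteris-paribus test. Identical (config, seed) produces byte-identical
cohort CSVs.

Closed-form companions exist for the main distributional targets: the
eye-level stage distribution, the expected score histogram (mixture CDF
differences), and the quality-flag rate (Gauss–Hermite quadrature over the
latent difficulty of the truncated-normal tail).

### What the generator does not model

Eye scores are independent given the eye stages, so the worse-eye maximum
of two low-score draws is rarer than in real data where fellow eyes are
strongly correlated; patient-level missed-moderate rates are consequently
optimistic. Image quality affects rejection but not the score's accuracy;
no demographics, no macular oedema channel, no camera effects, no
inter-grader variability. Passing tests therefore demonstrate the
pipeline's arithmetic and statistical behaviour, not clinical performance
on real images.

## Numerical choices and problem sizes

Counts round half-away-from-zero to the printed precision (1–2 dp).
Percent-style outputs are exact floats before formatting. The Youden
argmax is an M-estimator with cube-root asymptotics; the parameter-recovery
test compares cutpoints derived from n = 8000 cohorts (three seeds) with
the model's closed-form optima at tolerance 5·n^(−1/3). Convergence checks
use 50 000 eyes with 3/√n tolerances; the acceptance script calibrates on
20 000 patients, sizes at which every run completes in seconds.

## Known limitations

* Published data-dependent quantities (the study's AUC, its specific
  cutpoints 0.07/1.02/1.67) are not reproducible without the raw data;
  they are covered by oracle-equivalence and parameter-recovery properties
  instead.
* The inter-eye stage/score correlation model is a free parameter, not an
  inferred quantity.
* No confidence intervals for AUC or thresholds, and no cross-validation:
  the calibration is designed to be run once during initial validation on
  a representative sample.
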