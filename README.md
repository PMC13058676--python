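# drscreen

Population-specific calibration and real-world evaluation of AI-based
diabetic retinopathy (DR) screening.

## The problem

Screening algorithms for DR come in two families. Classifier-type systems
(IDx-DR-like) emit a discrete stage — no / mild / moderate / severe DR — but
demand a complete image set per patient and reject poor-quality images
outright. Regression-type systems (RetCAD-like) emit a continuous severity
score in [0, 5] plus a 0–100 image-quality score for anything imaged, and
merely flag low-quality images while still scoring them.

Controlled validation studies quote sensitivity among *diagnosable* patients.
In routine non-mydriatic screening, a substantial fraction of patients have
no acquirable image, an incomplete image set, or a quality rejection — and
for them the algorithm has, operationally, detected nothing. This package
implements both halves of the response to that gap:

1. **Dual-denominator evaluation.** Every sensitivity/specificity is
   reported twice: over graded patients (`sens_d`, `spec_d`) and over all
   examined patients (`sens_a`, `spec_a`), with non-graded positives counted
   as undetected. The exact identity `sens_a · P = sens_d · P_d`
   (P = all positives, P_d = graded positives) links the two and makes
   published aggregate tables invertible back into patient counts
   (`reconstruct_from_aggregates`).

2. **Youden-index stage calibration.** A continuous score lets the referral
   operating point be tuned to the local population. For each ordinal stage
   boundary k the truth is binarised cumulatively (gold stage ≥ k), an
   empirical ROC is built over worse-eye scores (positive iff score > t,
   candidate thresholds at midpoints of distinct observed scores), and the
   threshold maximising the Youden index J = sensitivity + specificity − 1
   becomes cutpoint t_k. A score-based referral rule with a deliberately low
   cutoff (worse-eye score > 0.1, the "Greifswald modification") maximises
   sensitivity for moderate/severe DR while stage labels stay on the
   Youden-calibrated bins.

A seeded synthetic-cohort generator reproduces the statistical structure of
a 1716-patient specialist-centre screening population (stage mix, no-image
and incomplete-set rates, quality-linked classifier rejections, near-zero
score mass for healthy eyes), so the entire pipeline is testable without
any patient data.

## Worked example

Inverting a published screening table's aggregate proportions into referral
counts (`examples/01_reconstruct_published_screening.py`):

```text
mode                             referred no result exam change
ophthalmologist on image              656       499     -61.77%
classifier (IDx-DR-type)              900       571     -47.55%
regression, manufacturer bins         369        98     -78.50%
regression, Youden-adjusted           564        98     -67.13%
regression, Greifswald cutoff         766        98     -55.36%
```

Each row takes only that mode's four printed proportions plus the class
totals (313 more-than-mild, 1403 no/mild of 1716 patients) and recovers the
number of patients an ophthalmologist must still examine under the
screening scenario (refer everyone with no usable result or a referable
finding), the patients left without a result, and the change in exam load
relative to examining everyone in person.

Calibrating thresholds on a synthetic cohort
(`examples/03_calibrate_thresholds.py`):

```text
Youden-calibrated stage intervals (score axis 0-5):
  no DR     (0.00, 0.16]
  mild      (0.16, 0.94]
  moderate  (0.94, 1.47]
  severe    (1.47, 5.00]

AUC for detecting more-than-mild DR: 0.9710
```

The cutpoints land far below the manufacturer's generic 1/2/3/4 grid
because most healthy eyes in this population score near 0 — exactly the
situation where population-specific calibration pays off.

The other examples cover gradability accounting
(`02_simulate_and_account.py`) and the four-policy comparison grid with
dual-denominator metrics (`04_compare_referral_policies.py`).

## Command line

A thin CLI wraps the library:

```bash
drscreen simulate  --n 1716 --seed 1 --out cohort.csv
drscreen calibrate --cohort cohort.csv --out-dir calib/
drscreen evaluate  --cohort cohort.csv --thresholds calib/thresholds.yaml
drscreen reconstruct --sens-d 0.7041 --sens-a 0.6006 --spec-d 0.9386 \
    --spec-a 0.9038 --positives 313 --negatives 1403 --total 1716
```

Exit codes: 0 success, 2 validation error, 3 inconsistent aggregates.
Every simulate run writes a provenance sidecar (config hash, seed, version)
sufficient to regenerate the cohort bit-identically.

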