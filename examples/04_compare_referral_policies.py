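"""Compare referral policies on one cohort, the real-world way.

Four screening modes run on the same synthetic cohort: the classifier
column, and the regression score under manufacturer bins, Youden-adjusted
bins, and the score-based Greifswald cutoff (refer iff worse-eye score >
0.1, stage labels staying on the Youden bins).  Every metric appears with
both denominators, and the screening scenario refers all patients without
a usable result.
"""

from drscreen import GeneratorConfig, derive_stage_thresholds, generate_cohort, screening_report

cohort = generate_cohort(GeneratorConfig(seed=42))
youden, _ = derive_stage_thresholds(cohort)
report = screening_report(cohort, youden, greifswald_cutoff=0.1)

print(f"Youden cutpoints: {[round(c, 3) for c in youden.cutpoints]}\n")
print(report.to_string(index=False))

# Read sens_d vs sens_a per row: the gap is the price of unscreenable
# patients.  'referred' is the ophthalmologist workload under the screening
# scenario; 'severe_missed' counts gold-severe graded patients the policy
# failed to refer.  Lowering the Greifswald cutoff buys sensitivity at the
# cost of specificity and referral volume.
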