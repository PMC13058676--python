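"""Generate a synthetic screening cohort and account for gradability.

The generator's defaults emulate a 1716-patient non-mydriatic screening
population: stage mix, no-image rate, incomplete image sets, and
quality-linked classifier rejections.  The accounting shows why a
classifier-type algorithm (needs a complete image set, may reject) grades
far fewer patients than a regression-type one (scores anything imaged).
"""

from drscreen import (
    GeneratorConfig,
    ScreeningStatus,
    cohort_accounting,
    generate_cohort,
)

cohort = generate_cohort(GeneratorConfig(seed=42))
print(f"patients examined: {len(cohort)}\n")

for kind in ("classifier", "regression"):
    acc = cohort_accounting(cohort, kind)
    print(f"{kind} algorithm:")
    for status in ScreeningStatus:
        print(
            f"  {status.value:16s} {acc.counts[status]:5d}"
            f"  ({acc.proportions[status]:.1f}%)"
        )
    print()

# Statuses are mutually exclusive and sum to the exam denominator.  Only
# GRADED patients contribute to diagnosable-denominator metrics; the rest
# must be referred in a real screening programme, which is what separates
# real-world from controlled-study performance.
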