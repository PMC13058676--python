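"""Invert published screening aggregates into referral counts.

A screening study reports sensitivity/specificity twice per mode — among
diagnosable patients (``_d``) and among all patients (``_a``) — plus the
gold-standard class totals.  Those proportions fully determine the referral
burden of the hypothetical screening scenario (follow up everyone with no
result or a referable finding), so the printed numbers can be turned back
into patient counts.
"""

from drscreen import reconstruct_from_aggregates

# (sens_d, sens_a, spec_d, spec_a) for more-than-mild DR per screening mode,
# with 313 gold more-than-mild and 1403 gold no/mild patients of 1716.
MODES = {
    "ophthalmologist on image": (0.7823, 0.4824, 0.9941, 0.7256),
    "classifier (IDx-DR-type)": (0.9016, 0.5272, 0.8295, 0.5688),
    "regression, manufacturer bins": (0.7041, 0.6006, 0.9386, 0.9038),
    "regression, Youden-adjusted": (0.8689, 0.7414, 0.8267, 0.7962),
    "regression, Greifswald cutoff": (0.9363, 0.7987, 0.6906, 0.665),
}

print(f"{'mode':32s} {'referred':>8s} {'no result':>9s} {'exam change':>11s}")
for name, props in MODES.items():
    r = reconstruct_from_aggregates(*props, 313, 1403, 1716)
    print(
        f"{name:32s} {r['referred']:8.0f} {r['no_result']:9.0f} "
        f"{r['pct_change_exams']:10.2f}%"
    )

# 'referred' counts patients an ophthalmologist must still see; the exam
# change is relative to examining all 1716 patients in person.  The
# score-based Greifswald cutoff trades ~200 extra referrals against the
# manufacturer bins for a much lower chance of missing moderate/severe DR.
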