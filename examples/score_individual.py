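"""Score one respondent's raw EAR indices against the published norms.

A 63-year-old woman identified 48 of 60 emotions correctly (ER) and
classified 45 of 60 expressions' authenticity correctly (EA).  The report
shows her demographically adjusted scores and the Equivalent Score (0 =
abnormal, 1 = borderline, 2 = low-end normal, 3-4 = normal) each adjusted
score maps to.
"""

from earnorms import score_individual

report = score_individual(er_raw=48, ea_raw=45, age=63, sex="F")
print(report.to_text())
print()
print(
    "The age correction is positive past ~42.6 years (it compensates the "
    "age-related decline),\nso her adjusted scores exceed the raw ones "
    "before the ES thresholds are applied."
)
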