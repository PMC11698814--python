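"""Run the whole norming pipeline on a synthetic cohort.

1. simulate a normative-size cohort (n = 522);
2. select the demographic adjustment model (candidate transforms of age
   and education plus sex; p < .05 retention) - on calibrated data this
   retains age**2 and sex, the published structure;
3. adjust every raw score;
4. compute the outer/inner tolerance limits (distribution-free bounds on
   the population 5th centile, 95% confidence);
5. partition the adjusted scores into the five Equivalent Score bands.

The resulting thresholds are this cohort's own norms - they parallel the
published table but are derived entirely from simulated data.
"""

import numpy as np

from earnorms import (
    adjust_score,
    compute_tls,
    default_config,
    es_bands,
    generate_cohort,
    select_model,
)
from earnorms.limits import norm_table

cohort = generate_cohort(default_config(), n=522, seed=2024)

for index in ("ER", "EA"):
    model = select_model(cohort, index)
    adjusted = np.array(
        [
            adjust_score(row[f"{index.lower()}_raw"], row["age"], row["sex"],
                         model, education=row["education"])
            for _, row in cohort.iterrows()
        ]
    )
    tls = compute_tls(adjusted)
    bands = es_bands(adjusted, tls)
    table = norm_table(index, tls, bands)
    print(f"{index}: retained {model.retained_predictors}, "
          f"beta_age2 = {model.beta_age2:.5f}, "
          f"sex offset = {model.sex_offset:+.3f}")
    print(f"    oTL = {tls.oTL:.2f} (rank {tls.outer_rank}), "
          f"iTL = {tls.iTL:.2f} (rank {tls.inner_rank})")
    t = bands.thresholds
    print(f"    ES0 <= {t[0]:.2f} < ES1 <= {t[1]:.2f} < ES2 <= {t[2]:.2f}"
          f" < ES3 <= {t[3]:.2f} < ES4")
print("\nES 0 marks the 'abnormal' range: with 95% confidence no more than "
      "5% of the healthy\npopulation falls at or below the oTL.")
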