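"""A-priori sample size for the norming regressions.

How many participants does a norming study need so that a multiple
regression with three predictors (transformed age, education, sex)
detects a small effect (Cohen's f**2 = 0.05) with 90% power at
alpha = .05?  Solved through the noncentral F distribution with
lambda = f2 * N.
"""

from earnorms import required_n_f2

spec = required_n_f2(u=3, f2=0.05, alpha=0.05, power=0.90)
print(f"numerator df u = {spec.u}, effect size f2 = {spec.f2}")
print(f"smallest denominator df v = {spec.v}")
print(f"required N = u + v + 1 = {spec.n_required} "
      f"(achieved power {spec.achieved_power:.4f})")

alt = required_n_f2(u=3, f2=0.05, alpha=0.05, power=0.90,
                    lambda_convention="error")
print(f"under the lambda = f2*v convention instead: N = {alt.n_required}")
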