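# Methods

This note records the models behind `earnorms`, the assumptions they make,
the numerical conventions, and the design choices taken where the
published material left the design open.

## Test model and scoring

The EAR manifest is a fixed combinatorial structure: 60 items, 10 per
basic emotion, each emotion split 5 authentic / 5 posed. `build_manifest`
seeds only the presentation order and synthetic clip durations
(log-normal around per-emotion means: fear 1.69 s, sadness 7.91 s, the
remaining emotions ≈ 2.2 s so the overall mean is ≈ 3 s). Durations are
descriptive metadata; scoring never reads them. Scoring is exact
counting; protocols that do not cover all 60 items exactly once are
rejected rather than prorated, because the norms assume the 0–60 scale.

## Synthetic normative cohorts

### Demographics

Participants are drawn from the published age-band × education-band × sex
stratification grid, with uniform integer ages and educations inside each
band (the within-band distributions are unreported; uniformity is an
assumption, and it widens the education SD relative to the published
value — 5.3 vs 3.1 years — because the open-ended top band 17–24 is
broad). The printed grid totals 520 participants (216 M / 304 F) against
a reported 216/306; the cells are used as sampling weights as printed.
The resulting mean age is 39.7 vs the published 39.97.

### Raw scores

Each index has a Gaussian latent linear model,

`latent = β₀ + β_a·(age² − E[age²]) + β_e·(edu − E[edu]) + β_s·(sex − E[sex]) + ε`,

with sex coded ±½ (so β_s is the M−F gap), discretised by rounding and
clipped to [0, 60]. Age enters through age² — the same transform the
published adjustment uses — so the generator and the norming stage share
one functional form and parameter recovery is well-posed. Education gets
a real (small) effect even though the published adjustment retains only
age and sex: its marginal correlation with the scores is mostly
age-mediated (age and education correlate −0.24 in the stratification
grid), which is exactly the situation the selection rule must handle.
The shape choice (truncated Gaussian) is a decision; only normality-check
summaries of the real distribution are published.

`calibrate` solves β_a, β_e and the residual SD in closed form from the
target mean, SD and age/education correlations, using *exact* demographic
moments obtained by enumerating the strata cells. β_s is pinned at −2×
the published sex offset (offsets are corrections *added* to men, so men
score lower in the generating model). Because rounding and the ceiling at
60 shrink the observed mean, SD and correlations relative to the latent
(≈ 4% of latent mass sits above 60 for ER), the closed-form solution is
then refined by a damped fixed-point loop against simulated cohorts
(5 iterations at n = 300 000, plus a final intercept-only pass at
n = 600 000), all under a fixed internal seed so the default
configuration is reproducible. Infeasible targets (implied residual
variance ≤ 0) raise a calibration error naming the offending index.

Default calibrated moments at n = 20 000 (seed 11): mean ER 51.10,
r(age, ER) −0.497, r(edu, ER) 0.143, mean fear subscore 6.53 — all within
the tolerances the test suite asserts (±0.15, ±0.03, ±0.03, ±0.1).

### Item level

Given a participant's ER total, the specific correct items are chosen by
weighted sampling *without* replacement (Efraimidis–Spirakis keys) with
per-emotion odds weights, so harder emotions (fear, anger) absorb the
errors while each participant's responses still sum exactly to the stored
total — rescoring generated responses reproduces the stored indices
identically. The six odds weights are calibrated by stochastic
approximation against the published per-emotion means. The published
means sum to 51.14 while the published ER mean is 51.17; the ≈ 0.005
per-emotion residual this forces is far inside the asserted tolerance.
Incorrect answers on fear items are labelled "surprise" with probability
0.6 (the classic fear→surprise confusion; the reverse confusion is not
modelled), other errors are uniform. EA correctness is allocated
uniformly across items.

### Covariates

MoCA exists only for ages ≥ 50 (as administered). It is Gaussian in the
two latent abilities standardised *within that subset* (the published
correlations are computed there), rounded and clipped to [0, 30]; the
ceiling at 30 is heavy (the latent mean must sit above the observed
27.95), so the mean/SD/loadings are refined against simulation like the
score models. IRI has four subscales (0–28 each, total = their sum by
construction): Fantasy loads on the shared ability component, Perspective
Taking on the EA-specific component (so ER–PT correlation stays near
zero while EA–PT is real, matching the reported qualitative pattern),
Empathic Concern and Personal Distress are noise. About 7% of IRI records
are missing completely at random, mirroring the published 485/522
coverage and exercising pairwise-complete correlation handling.

### What the generator does not emulate

Real response distributions are left-skewed counts, not rounded
Gaussians; real item responses have participant-specific emotion
profiles beyond one ability dimension; MoCA's true distribution is
skewed with domain structure; education is recorded in discrete
credential jumps. Passing tests show the *pipeline* behaves correctly
under the published moment structure — they do not validate the
generator as a model of real respondents.

## Demographic adjustment

`select_model` fixes the candidate pool to {age, age², log(age)} ×
{education, log(education)} × {sex}. Within each collinear family
(pairwise r > 0.97 over ages 17–88) the best-fitting single transform is
chosen by simple-regression R²; the multiple regression on the chosen
transforms is fitted once, predictors with p < .05 are retained, and the
model is refitted on the retained set — a single pass, no stepwise
iteration. log(age) is used rather than a shifted log, which would be
undefined at the minimum normative age of 17. Returned coefficients are
on the correction scale (negated fit coefficients) centred at the cohort
means, so the adjustment is exactly ±sex-offset at age √c.

Two conventions deserve loud documentation:

* **Sign.** Corrections are *positive at older ages*: adjusted = raw +
  b(age² − c) ± s. The published footnote equation carries the opposite
  sign, but the printed grids — 26 independently checkable numbers per
  index, consistent with performance *declining* with age — carry this
  one, and the grids win.
* **Display rounding.** The grids are reproduced cell-for-cell by
  two-stage decimal rounding: the age term to 3 decimals (ties away from
  zero), then the sum with the sex offset to 2. Single-stage rounding of
  the full-precision sum misses three male ER cells by 0.01. Internal
  arithmetic (`adjust_score`, ES classification) always uses full
  precision; rounding is display-only. The published EA male row contains
  two typesetting slips (a dropped 0.00 cell and a sign flip on 0.85);
  the equation-generated values are treated as canonical.

Parameter recovery on bounded scores has a subtlety the tests respect:
OLS on the clipped 0–60 scores estimates the slope of the *observed*
process, which the ceiling attenuates by a factor ≈ P(latent in range)
≈ 0.96 relative to the latent slope. Recovery is therefore judged
against the generator's observable-scale coefficients (large-sample OLS
of the observed process), not the latent ones, which no estimator of the
observed data could match.

## Tolerance limits and Equivalent Scores

Ranks come from exact binomial tail sums (scipy's regularised incomplete
beta; the test oracle recomputes them by explicit summation): the outer
rank is the largest r with CDF(r−1; n, p) ≤ 1 − confidence, the inner
rank the smallest r with CDF(r−1) ≥ confidence. No normal approximation
is used; the minimum feasible n at p = .05, confidence .95 is 59
(0.95⁵⁹ ≈ 0.0485). By construction the outer rank sits ≈ 1.645 binomial
SEs below n·p — that offset is what purchases the one-sided 95%
confidence — so outer_rank/n → p from below at rate 1/√n.

The published material pins ES 0 (≤ oTL) and ES 4 (> median) but not how
ES 1–3 partition the interval between. Default here: the ranks strictly
between the outer rank and the median rank are split into three
near-equal bins (remainders to the lower bins) and the cut points are the
sample values at the bin edges — distribution-free and reproducible. A
z-score-based partition (equal standard-score spacing between oTL and
median) is available behind `method="z"`. Neither is asserted to
reproduce the published inner thresholds, which require the original raw
data. The median is the lower middle order statistic for even n, so
"above the median" is exact; boundary values always resolve to the lower
band. Tied cut points (possible in heavily discrete samples) collapse a
band and emit a warning instead of silently shifting thresholds.

## Published norms resource

The shipped JSON resource carries the published adjustment constants and
ES thresholds with a SHA-256 checksum over the canonical payload; loading
verifies it, so an edited file cannot pass as the published version. The
printed two-decimal band edges are encoded as half-open intervals with
inclusive upper bounds (ES1 = (42.35, 46.09], etc.); adjusted scores are
classified at full precision. Age validity is pinned to the normative
17–88; ages above 65 get a standing caution (sparsely represented in the
norming sample), ages outside the range get the ES withheld.

## Power analysis

`required_n_f2` finds the smallest denominator df v such that the
level-α F test with df (u, v) and noncentrality λ = f²·(u+v+1) = f²·N
reaches the target power, and reports N = u + v + 1; the λ = f²·v
convention is available behind a flag. For u = 3, f² = .05, α = .05,
power = .90 this gives v = 284, N = 288 (continuous solve v* = 283.37,
N* = 287.37); a commonly quoted figure for these inputs, 286, equals
u + v* with the "+1" dropped. The implementation keeps the textbook
definition and reports 288.

## Problem sizes and tolerances

The test suite works at the sizes the checks need and nothing more: exact
checks (grids, ranks vs oracle over n = 59…1000, power) are instant;
calibration-moment checks use one n = 20 000 cohort (correlation
tolerances ±0.03 correspond to ≈ 4 SEs there); parameter recovery uses 20
cohorts of n = 522 against an n = 500 000 observable-scale reference;
the oTL coverage check uses 200 replicates of n = 522 against an
n = 200 000 reference population. Calibration itself (cached) simulates a
few cohorts of n = 300 000–600 000 and takes a few seconds.
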