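"""Demographic adjustment: published grids, the correction equation and
data-driven model selection."""

import math

import numpy as np
import pytest

from earnorms import (
    PUBLISHED_EA,
    PUBLISHED_ER,
    adjust_score,
    correction_grid,
    generate_cohort,
    sample_demographics,
    select_model,
)
from earnorms.adjustment import (
    AdjustmentModel,
    AgeOutOfRangeError,
    GRID_AGES,
    model_from_json,
    model_to_json,
)

# Published correction grids (ages 25..85 step 5).  The EA male row is the
# equation-generated one: the printed source carries two typesetting
# slips there (a dropped 0.00 cell and a sign flip on 0.85), and the
# equation-consistent values are canonical.
ER_GRID_M = [-1.56, -1.01, -0.36, 0.40, 1.25, 2.20, 3.25,
             4.40, 5.65, 7.00, 8.45, 10.00, 11.65]
ER_GRID_F = [-3.19, -2.64, -1.99, -1.24, -0.39, 0.56, 1.61,
             2.76, 4.01, 5.36, 6.81, 8.36, 10.01]
EA_GRID_M = [-1.95, -1.40, -0.75, 0.00, 0.85, 1.80, 2.85,
             4.00, 5.25, 6.60, 8.05, 9.60, 11.25]
EA_GRID_F = [-2.79, -2.24, -1.59, -0.84, 0.01, 0.96, 2.01,
             3.16, 4.41, 5.76, 7.21, 8.76, 10.41]


@pytest.mark.parametrize(
    "model,row_m,row_f",
    [(PUBLISHED_ER, ER_GRID_M, ER_GRID_F), (PUBLISHED_EA, EA_GRID_M, EA_GRID_F)],
    ids=["ER", "EA"],
)
def test_published_grids_reproduced(model, row_m, row_f):
    """Every grid cell matches the published correction tables to two
    decimals under the display-rounding convention."""
    grid = correction_grid(model, GRID_AGES)
    assert grid.loc["M"].tolist() == row_m
    assert grid.loc["F"].tolist() == row_f


@pytest.mark.parametrize("model", [PUBLISHED_ER, PUBLISHED_EA], ids=["ER", "EA"])
def test_grid_antisymmetry(model):
    """M and F cells differ by twice the sex offset (up to display
    rounding)."""
    grid = correction_grid(model, GRID_AGES)
    diff = grid.loc["M"] - grid.loc["F"]
    assert np.all(np.abs(diff - 2 * model.sex_offset) <= 0.0100001)


def test_centering_identity():
    """At age sqrt(c) the age term vanishes and the adjustment is exactly
    the sex offset."""
    age = math.sqrt(PUBLISHED_ER.centering_c)
    assert adjust_score(42, age, "M", PUBLISHED_ER) == pytest.approx(42.818)
    assert adjust_score(42, age, "F", PUBLISHED_ER) == pytest.approx(41.182)


def test_adjustment_examples():
    # 25-year-old man, ER: the correction is negative (young respondents
    # give up points relative to the centring age)
    assert adjust_score(0, 25, "M", PUBLISHED_ER) == pytest.approx(-1.5545, abs=1e-4)
    # 85-year-old man, EA: raw 50 gains the full old-age compensation
    assert adjust_score(50, 85, "M", PUBLISHED_EA) == pytest.approx(61.25, abs=0.005)


def test_adjustment_monotone_in_age():
    ages = np.arange(43, 89)
    adj = [adjust_score(50, a, "F", PUBLISHED_ER) for a in ages]
    assert np.all(np.diff(adj) > 0)


def test_age_outside_validity_range():
    with pytest.raises(AgeOutOfRangeError, match="validity range"):
        adjust_score(50, 16, "F", PUBLISHED_ER)
    with pytest.raises(AgeOutOfRangeError):
        adjust_score(50, 89, "M", PUBLISHED_EA)


def test_select_model_recovers_structure(calibrated_config):
    """On a large calibrated cohort the selection retains exactly age**2
    and sex, and the slope lands within 10% of the generating value."""
    cohort = generate_cohort(calibrated_config, n=5000, seed=42)
    model = select_model(cohort, "ER")
    assert set(model.retained_predictors) == {"age2", "sex"}
    generating = -calibrated_config.er.beta_age2
    assert model.beta_age2 == pytest.approx(generating, rel=0.10)
    assert model.centering_c == pytest.approx((cohort["age"] ** 2).mean())


def test_select_model_null_cohort(calibrated_config, rng):
    """With no demographic effects nothing is retained and the adjustment
    is the identity."""
    demo = sample_demographics(calibrated_config, n=2000, seed=6)
    demo["er_raw"] = np.round(rng.normal(50, 5, len(demo))).clip(0, 60)
    model = select_model(demo, "ER")
    assert model.retained_predictors == ()
    assert model.beta_age2 == 0.0
    assert model.sex_offset == 0.0
    assert adjust_score(44, 30, "F", model,
                        education=10) == pytest.approx(44.0)


def test_select_model_refit_recovers_sex_offset(calibrated_config):
    """Refitting on a cohort generated from the published-constant pattern
    recovers the sex offset within +/-0.1."""
    cohort = generate_cohort(calibrated_config, n=20_000, seed=8)
    model = select_model(cohort, "ER")
    assert "sex" in model.retained_predictors
    assert abs(model.sex_offset - 0.818) <= 0.1


def test_collinear_age_transforms_pruned(calibrated_config):
    """Offering age, age**2 and log(age) together retains at most one of
    them (the best-fitting single age transform)."""
    cohort = generate_cohort(calibrated_config, n=3000, seed=14)
    model = select_model(
        cohort, "ER",
        candidates=["age", "age2", "log_age", "education", "log_education",
                    "sex"],
    )
    n_age_terms = sum(
        p in ("age", "age2", "log_age") for p in model.retained_predictors
    )
    assert n_age_terms <= 1


def test_small_or_incomplete_cohorts_rejected(calibrated_config):
    cohort = generate_cohort(calibrated_config, n=20, seed=1)
    with pytest.raises(ValueError, match=">= 30"):
        select_model(cohort, "ER")
    cohort2 = generate_cohort(calibrated_config, n=50, seed=1)
    cohort2.loc[cohort2.index[0], "er_raw"] = np.nan
    with pytest.raises(ValueError, match="missing raw scores"):
        select_model(cohort2, "ER")


def test_model_json_roundtrip(tmp_path):
    model = AdjustmentModel(
        index_name="ER", beta_age2=0.002, centering_c=1811.257,
        sex_offset=0.818, extra_terms={"education": (-0.05, 15.1)},
    )
    path = tmp_path / "model.json"
    model_to_json(model, path)
    loaded = model_from_json(path)
    assert loaded == model
    assert adjust_score(50, 60, "M", loaded, education=13) == pytest.approx(
        adjust_score(50, 60, "M", model, education=13)
    )
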