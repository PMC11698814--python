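"""Synthetic-cohort generator: demographics, score model, calibration and
item-level round trips."""

import numpy as np
import pandas as pd
import pytest

from earnorms import (
    EMOTIONS,
    calibrate,
    generate_cohort,
    sample_demographics,
    sample_item_level,
    sample_scores,
    score_responses,
    simulate_emotion_subscores,
)
from earnorms.cohort import (
    CalibrationError,
    ConfigurationError,
    GeneratorConfig,
    IndexTargets,
    PAPER_TARGETS,
    CalibrationTargets,
    ScoreModel,
    config_from_yaml,
    config_to_yaml,
    demographic_moments,
)


def test_sex_split_matches_stratification(calibrated_config):
    """The marginal M/F proportion approaches the published 216/306 split
    as the cohort grows."""
    demo = sample_demographics(calibrated_config, n=20_000, seed=7)
    prop_m = (demo["sex"] == "M").mean()
    assert abs(prop_m - 216 / 522) <= 0.03


def test_empty_cohort(calibrated_config):
    demo = sample_demographics(calibrated_config, n=0)
    assert len(demo) == 0
    scored = sample_scores(demo, calibrated_config)
    assert len(scored) == 0


def test_mean_age_matches_descriptives(calibrated_config):
    """Monte-Carlo check of the strata weights against the published mean
    age of 39.97 years."""
    demo = sample_demographics(calibrated_config, n=50_000, seed=1)
    assert abs(demo["age"].mean() - 39.97) <= 0.5
    assert demo["age"].between(17, 88).all()
    assert demo["education"].between(5, 24).all()


def test_empty_strata_rejected():
    with pytest.raises(ConfigurationError, match="empty strata"):
        GeneratorConfig(strata=pd.DataFrame(columns=["weight"]))


def test_degenerate_generator_is_constant(calibrated_config):
    """Zero effects and vanishing noise collapse every score to the
    rounded intercept."""
    config = GeneratorConfig(
        strata=calibrated_config.strata,
        er=ScoreModel(47.0, 0.0, 0.0, 0.0, 1e-9),
        ea=ScoreModel(44.2, 0.0, 0.0, 0.0, 1e-9),
    )
    df = sample_scores(sample_demographics(config, n=200, seed=3), config)
    assert (df["er_raw"] == 47).all()
    assert (df["ea_raw"] == 44).all()


def test_scores_are_bounded_integers(cohort_20k):
    for col in ("er_raw", "ea_raw"):
        assert cohort_20k[col].between(0, 60).all()
        assert pd.api.types.is_integer_dtype(cohort_20k[col])
    # published score ranges (31-60 ER, 33-60 EA) are plausible: almost no
    # simulated mass below them
    assert (cohort_20k["er_raw"] < 31).mean() <= 0.01
    assert (cohort_20k["ea_raw"] < 33).mean() <= 0.01


def test_moca_present_iff_age_50(cohort_20k):
    has_moca = cohort_20k["moca"].notna()
    assert (has_moca == (cohort_20k["age"] >= 50)).all()
    sub = cohort_20k.loc[has_moca, "moca"]
    assert sub.between(0, 30).all()


def test_iri_total_equals_subscale_sum(cohort_20k):
    sub = cohort_20k.dropna(subset=["iri_total"])
    assert len(sub) > 0
    total = sub[["iri_pt", "iri_f", "iri_ec", "iri_pd"]].sum(axis=1)
    assert (total == sub["iri_total"]).all()
    assert sub["iri_total"].between(0, 112).all()


def test_age_effect_monotone_in_beta(calibrated_config):
    """Tripling the age-squared coefficient strengthens the age-score
    correlation monotonically."""
    base = calibrated_config.er
    rs = []
    for scale in (1.0, 2.0, 3.0):
        config = GeneratorConfig(
            strata=calibrated_config.strata,
            er=ScoreModel(base.intercept, base.beta_age2 * scale,
                          base.beta_edu, base.beta_sex, base.sigma_resid),
            ea=calibrated_config.ea,
        )
        df = sample_scores(
            sample_demographics(config, n=20_000, seed=5), config, seed=5
        )
        rs.append(np.corrcoef(df["age"], df["er_raw"])[0, 1])
    assert rs[0] > rs[1] > rs[2]  # correlations grow more negative


def test_calibrate_null_targets():
    """Zero correlations and SD 5 solve to zero slopes and sigma close
    to 5 (closed form, before simulation refinement)."""
    targets = CalibrationTargets(
        er=IndexTargets(mean=50, sd=5, r_age=0, r_edu=0, sex_offset=0),
        ea=IndexTargets(mean=50, sd=5, r_age=0, r_edu=0, sex_offset=0),
        emotion_means=PAPER_TARGETS.emotion_means,
        moca_mean=28, moca_sd=2, moca_r_er=0.1, moca_r_ea=0.1,
        iri_mean=66, iri_sd=13, iri_r_er=0.1, iri_r_ea=0.1,
    )
    config = calibrate(targets, refine=False)
    assert config.er.beta_age2 == pytest.approx(0.0, abs=1e-12)
    assert config.er.beta_edu == pytest.approx(0.0, abs=1e-12)
    assert config.er.sigma_resid == pytest.approx(5.0, abs=0.05)


def test_calibrate_infeasible_targets():
    """Correlations stronger than the requested SD allows are refused."""
    targets = CalibrationTargets(
        er=IndexTargets(mean=50, sd=1.0, r_age=-0.98, r_edu=0.6,
                        sex_offset=0.818),
        ea=PAPER_TARGETS.ea,
        emotion_means=PAPER_TARGETS.emotion_means,
        moca_mean=28, moca_sd=2, moca_r_er=0.4, moca_r_ea=0.4,
        iri_mean=66, iri_sd=13, iri_r_er=0.2, iri_r_ea=0.2,
    )
    with pytest.raises(CalibrationError, match="residual variance"):
        calibrate(targets, refine=False)


def test_truncation_warning():
    """A generating mean near the ceiling trips the calibration warning."""
    config = GeneratorConfig(
        er=ScoreModel(60.0, 0.0, 0.0, 0.0, 5.0),
        ea=ScoreModel(50.0, 0.0, 0.0, 0.0, 5.0),
    )
    demo = sample_demographics(config, n=2000, seed=1)
    with pytest.warns(UserWarning, match="truncates"):
        sample_scores(demo, config)


def test_item_level_round_trip(calibrated_config, manifest):
    """Scoring the generated trial responses reproduces the stored raw
    indices exactly, with fear errors biased toward surprise."""
    cohort = generate_cohort(calibrated_config, n=40, seed=9)
    fear_errors = []
    for i, row in cohort.iterrows():
        responses = sample_item_level(
            row, manifest, calibrated_config, seed=100 + i
        )
        scores = score_responses(responses, manifest)
        assert scores.er_index == row["er_raw"]
        assert scores.ea_index == row["ea_raw"]
        by_id = {s.stimulus_id: s for s in manifest}
        for r in responses:
            stim = by_id[r.stimulus_id]
            if stim.emotion == "fear" and r.chosen_emotion != "fear":
                fear_errors.append(r.chosen_emotion)
    if len(fear_errors) >= 20:
        surprise_share = fear_errors.count("surprise") / len(fear_errors)
        assert surprise_share > 1 / 5  # elevated above the uniform rate


def test_emotion_subscores_sum_to_er(cohort_20k, calibrated_config):
    sub = simulate_emotion_subscores(cohort_20k, calibrated_config, seed=11)
    assert list(sub.columns) == list(EMOTIONS)
    assert (sub.to_numpy().sum(axis=1) == cohort_20k["er_raw"].to_numpy()).all()
    assert (sub.to_numpy() >= 0).all() and (sub.to_numpy() <= 10).all()


def test_generation_deterministic(calibrated_config):
    a = generate_cohort(calibrated_config, n=300, seed=21)
    b = generate_cohort(calibrated_config, n=300, seed=21)
    pd.testing.assert_frame_equal(a, b)


def test_config_yaml_roundtrip(calibrated_config, tmp_path):
    path = tmp_path / "config.yaml"
    config_to_yaml(calibrated_config, path)
    loaded = config_from_yaml(path)
    assert loaded.er == calibrated_config.er
    assert loaded.ea == calibrated_config.ea
    assert loaded.emotion_logodds == calibrated_config.emotion_logodds
    a = generate_cohort(calibrated_config, n=100, seed=4)
    b = generate_cohort(loaded, n=100, seed=4)
    pd.testing.assert_frame_equal(a, b)


def test_demographic_moments_match_simulation(calibrated_config):
    """The exact enumeration the calibration relies on agrees with a large
    simulated cohort."""
    mom = demographic_moments(calibrated_config.strata)
    demo = sample_demographics(calibrated_config, n=100_000, seed=13)
    assert mom["mean_age"] == pytest.approx(demo["age"].mean(), abs=0.15)
    assert mom["mean_age2"] == pytest.approx((demo["age"] ** 2).mean(), rel=0.01)
    assert mom["mean_edu"] == pytest.approx(demo["education"].mean(), abs=0.06)
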