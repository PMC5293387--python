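"""Synthetic-cohort generator: marginals, determinism, noise calibration."""

import numpy as np
import pandas as pd
import pytest

from renovol import geometry
from renovol.regression import PUBLISHED_AGE_MODEL, PUBLISHED_PRAIV_MODEL, fit_univariate
from renovol.simulate import (
    TABLE_COVARIATES,
    CohortConfig,
    ConfigError,
    CovariateSpec,
    NoiseCalibration,
    calibrate_noise,
    correlated_raiv_praiv_cohort,
    generate_cohort,
    generate_outcomes,
    sample_covariates,
    truncated_normal,
)


def test_same_seed_gives_identical_cohort():
    config = CohortConfig(n=63, seed=7)
    pd.testing.assert_frame_equal(generate_cohort(config), generate_cohort(config))


def test_different_seeds_differ():
    a = generate_cohort(CohortConfig(n=63, seed=1))
    b = generate_cohort(CohortConfig(n=63, seed=2))
    assert not a["praiv"].equals(b["praiv"])


def test_all_covariates_respect_truncation_bounds():
    table = sample_covariates(CohortConfig(n=2000, seed=3))
    for name, spec in TABLE_COVARIATES.items():
        col = table[name]
        assert col.min() >= spec.low and col.max() <= spec.high, name


def test_truncated_normal_hits_target_mean(rng):
    # asymmetric bounds: naive parent location would bias the mean upward
    spec = TABLE_COVARIATES["praiv"]
    draws = truncated_normal(spec, 200_000, rng)
    assert draws.mean() == pytest.approx(4.4, abs=0.05)


def test_sampled_age_marginal_matches_reported_summary():
    table = sample_covariates(CohortConfig(n=10_000, seed=11))
    assert table["age"].mean() == pytest.approx(57.4, abs=1.0)
    assert table["age"].between(25, 83).all()


def test_near_degenerate_truncation_still_samples(rng):
    spec = CovariateSpec(mean=5.0, low=5.0 - 1e-6, high=5.0 + 1e-6)
    draws = truncated_normal(spec, 50, rng)
    assert len(draws) == 50
    assert np.allclose(draws, 5.0, atol=1e-5)


def test_nephrometry_scores_are_integers():
    table = sample_covariates(CohortConfig(n=500, seed=5))
    assert (table["renal_score"] == table["renal_score"].round()).all()
    assert (table["padua_score"] == table["padua_score"].round()).all()


def test_generated_cindex_spans_observed_range():
    table = sample_covariates(CohortConfig(n=5000, seed=13))
    assert table["cindex"].min() < 1.2
    assert table["cindex"].max() > 5.5
    assert table["cindex"].between(0.8, 6.7).all()


@pytest.mark.parametrize(
    "slope, r2, var, expected",
    [
        (1.0, 0.5, 1.0, 1.0),
        (2.0, 0.5, 1.0, 2.0),
        (1.0, 0.999999, 1.0, pytest.approx(0.001, abs=1e-3)),
    ],
)
def test_calibrate_noise_closed_form(slope, r2, var, expected):
    assert calibrate_noise(slope, r2, var) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize("bad_r2", [0.0, 1.0, -0.2, 1.5])
def test_calibrate_noise_rejects_bad_r2(bad_r2):
    with pytest.raises(ConfigError):
        calibrate_noise(1.0, bad_r2, 1.0)


def test_calibrated_noise_reproduces_target_r2_at_large_n():
    cohort = generate_cohort(CohortConfig(n=5000, seed=17))
    res = fit_univariate(cohort, "pct_reduction", "praiv")
    assert res.rsquared == pytest.approx(PUBLISHED_PRAIV_MODEL.r_squared, abs=0.02)


def test_noiseless_outcomes_lie_on_published_lines():
    table = pd.DataFrame({"praiv": [4.4], "age": [57.4], "preop_egfr": [80.0]})
    praiv_out = generate_outcomes(table, PUBLISHED_PRAIV_MODEL, 0.0, rng=0)
    assert praiv_out.loc[0, "pct_reduction"] == pytest.approx(1.512 + 2.752 * 4.4, abs=1e-12)
    assert praiv_out.loc[0, "nadir_egfr"] == pytest.approx(
        80.0 * (1 - praiv_out.loc[0, "pct_reduction"] / 100.0)
    )
    age_out = generate_outcomes(table, PUBLISHED_AGE_MODEL, 0.0, rng=0)
    assert age_out.loc[0, "pct_reduction"] == pytest.approx(-4.958 + 0.324 * 57.4, abs=1e-12)


@pytest.mark.parametrize(
    "model_name, model",
    [("praiv", PUBLISHED_PRAIV_MODEL), ("age", PUBLISHED_AGE_MODEL)],
)
def test_refits_recover_generating_parameters_at_nominal_coverage(model_name, model):
    """Across seeded replicates the refitted slope and intercept fall within
    2 standard errors of the generating values at close to the nominal
    2-sigma rate (a single replicate can legitimately miss)."""
    n_reps = 50
    slope_ok = intercept_ok = 0
    for rep in range(n_reps):
        cohort = generate_cohort(
            CohortConfig(n=5000, seed=1000 + rep, outcome_model=model_name)
        )
        res = fit_univariate(cohort, "pct_reduction", model.covariate)
        slope_ok += abs(res.params[model.covariate] - model.slope) <= 2 * res.bse[model.covariate]
        intercept_ok += abs(res.intercept - model.intercept) <= 2 * res.bse["const"]
    assert slope_ok >= 0.9 * n_reps
    assert intercept_ok >= 0.9 * n_reps


def test_geometric_mode_praiv_recomputable_from_geometry():
    table = sample_covariates(CohortConfig(n=40, seed=19, praiv_mode="geometric"))
    for _, row in table.iterrows():
        tumor = geometry.TumorGeometry.from_diameter(
            row["tumor_diameter_cm"], row["invasion_depth_cm"]
        )
        kidney = geometry.KidneyGeometry(
            row["kidney_length_cm"], row["kidney_width_cm"], row["kidney_height_cm"]
        )
        spec = geometry.ResectionSpec(row["margin_cm"])
        assert geometry.praiv(tumor, kidney, spec) == row["praiv"]
        assert geometry.raiv(tumor, spec) == row["raiv"]


def test_joint_model_targets_cohort_mean_outcome():
    cohort = generate_cohort(CohortConfig(n=20_000, seed=23, outcome_model="joint"))
    assert cohort["pct_reduction"].mean() == pytest.approx(13.7, abs=1.0)


def test_correlated_raiv_praiv_cohort_structure():
    cohort = correlated_raiv_praiv_cohort(n=2000, rho=0.7, seed=31)
    corr = np.corrcoef(cohort["raiv"], cohort["praiv"])[0, 1]
    assert corr == pytest.approx(0.7, abs=0.1)
    assert cohort["raiv"].between(1.8, 45.1).all()
    assert cohort["praiv"].between(1, 16).all()


@pytest.mark.parametrize(
    "builder",
    [
        lambda: CohortConfig(n=2),
        lambda: CohortConfig(outcome_model="nope"),
        lambda: CohortConfig(praiv_mode="nope"),
        lambda: CovariateSpec(mean=20.0, low=0.0, high=10.0),
        lambda: CovariateSpec(mean=5.0, low=10.0, high=0.0),
        lambda: correlated_raiv_praiv_cohort(rho=1.5),
    ],
)
def test_config_errors(builder):
    with pytest.raises(ConfigError):
        builder()
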