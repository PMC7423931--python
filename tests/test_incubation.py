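"""Incubation analyses: detection limits, mixed model, nutrient regressions."""

import numpy as np
import pandas as pd
import pytest

from snowflux import (
    fit_nutrient_regression, fit_respiration_lmm, interaction_effect_table,
    simulate_incubation, simulate_nutrients, substitute_detection_limits,
)
from snowflux.incubation import NH4_DETECTION_FLOOR, RESPIRATION_DETECTION_FLOOR


def test_detection_limit_substitution_rules():
    resp = pd.DataFrame({
        "jar_id": ["a", "b"], "respiration": [0.004, 3.0],
        "below_detection": [True, False],
    })
    out = substitute_detection_limits(resp, "respiration")
    assert out.loc[0, "respiration"] == RESPIRATION_DETECTION_FLOOR == 0.01
    assert out.loc[1, "respiration"] == 3.0

    nutr = pd.DataFrame({
        "jar_id": ["a", "b"], "analyte": ["NH4_N", "NO3_N"],
        "concentration": [0.2, 0.2], "below_detection": [True, True],
    })
    out = substitute_detection_limits(nutr, "nh4")
    assert out.loc[0, "concentration"] == NH4_DETECTION_FLOOR == 0.5
    assert out.loc[1, "concentration"] == 0.2  # only NH4 rows substituted

    # idempotent, never decreases a substituted value
    again = substitute_detection_limits(out, "nh4")
    pd.testing.assert_frame_equal(out, again)
    assert (again["concentration"] >= nutr["concentration"] - 1e-15).all()

    unflagged = resp.assign(below_detection=False)
    pd.testing.assert_frame_equal(
        substitute_detection_limits(unflagged, "respiration"), unflagged)


def linear_records(beta, dates=(10, 30, 50, 70, 90), temps=(-10, -6, -2),
                   cs=(0.0, 0.2, 0.4, 2.0), n_jars=2, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    day_mean = np.mean(dates)
    jar = 0
    for t in temps:
        for c in cs:
            for _ in range(n_jars):
                jar += 1
                for d in dates:
                    dc = d - day_mean
                    mu = (beta[0] + beta[1] * t + beta[2] * c + beta[3] * t * c
                          + beta[4] * dc + beta[5] * t * dc)
                    rows.append({"jar_id": f"j{jar}", "temperature_c": t,
                                 "c_addition": c, "julian_date": d,
                                 "respiration": float(np.exp(mu + rng.normal(0, sigma))),
                                 "below_detection": False})
    return pd.DataFrame(rows)


def test_lmm_noiseless_recovery():
    beta = (2.0, 0.1, 0.5, 0.03, -0.02, -0.002)
    res = fit_respiration_lmm(linear_records(beta), subset="below_zero")
    est = res.coefficients["estimate"]
    for name, true in zip(["intercept", "temperature_c", "c_addition",
                           "temperature_c:c_addition", "date_c",
                           "temperature_c:date_c"], beta):
        assert est[name] == pytest.approx(true, abs=1e-6)
    assert res.r2_pred_obs == pytest.approx(1.0, abs=1e-8)
    assert res.obs_on_pred_slope == pytest.approx(1.0, abs=1e-6)
    assert res.three_way_test["excluded"] is True


def test_lmm_subset_contract(truth):
    records, _ = simulate_incubation(truth, seed=4)
    res = fit_respiration_lmm(records, subset="below_zero")
    assert res.subset == "below_zero"
    assert res.n_jars == 3 * 4 * 4
    res_all = fit_respiration_lmm(records, subset="all")
    assert res_all.n_jars == 5 * 4 * 4
    with pytest.raises(ValueError):
        fit_respiration_lmm(records, subset="warm")


def test_lmm_recovers_mechanistic_signs(incubation_records):
    """The depletion mechanism yields a positive C-addition effect and a
    negative date x temperature interaction (faster decline when warm)."""
    records, _ = incubation_records
    res = fit_respiration_lmm(records, subset="below_zero")
    coef = res.coefficients
    assert coef.loc["c_addition", "estimate"] > 0
    assert coef.loc["c_addition", "p"] < 0.01
    assert coef.loc["temperature_c:date_c", "estimate"] < 0
    assert coef.loc["temperature_c:date_c", "p"] < 0.01
    assert res.random_intercept_var >= 0
    assert res.residual_var > 0


def test_nutrient_regression_exact_and_df(truth):
    # exact recovery at zero noise
    import dataclasses
    nuts = {k: dataclasses.replace(v, sigma=0.0) for k, v in truth.nutrients.items()}
    t0 = dataclasses.replace(truth, nutrients=nuts)
    records = simulate_nutrients(t0, seed=8)
    res = fit_nutrient_regression(records, "NO3_N")
    nt = truth.nutrients["NO3_N"]
    assert res.coefficients.loc["temperature_c", "estimate"] == pytest.approx(nt.beta_temp, abs=1e-8)
    assert res.coefficients.loc["temperature_c:c_addition", "estimate"] == \
        pytest.approx(nt.beta_interaction, abs=1e-8)
    # 48-jar sub-zero design: F df = (3, 44)
    assert res.f_df == (3, 44)
    assert res.n == 48

    res_nh4 = fit_nutrient_regression(simulate_nutrients(truth, seed=8), "NH4_N")
    assert res_nh4.log_scale
    with pytest.raises(ValueError):
        fit_nutrient_regression(records, "DOC")


def test_po4_null_behaviour(truth):
    """PO4-P is generated at a floor with pure noise: temperature and
    interaction t-tests are each non-significant in >= 90% of replicates."""
    n_sig_temp = n_sig_int = 0
    n_sim = 200
    for i in range(n_sim):
        rec = simulate_nutrients(truth, seed=40_000 + i)
        res = fit_nutrient_regression(rec, "PO4_P")
        n_sig_temp += res.coefficients.loc["temperature_c", "p"] < 0.05
        n_sig_int += res.coefficients.loc["temperature_c:c_addition", "p"] < 0.05
    assert n_sig_temp / n_sim <= 0.10
    assert n_sig_int / n_sim <= 0.10


def test_interaction_effect_table_closed_form(truth):
    import dataclasses
    nuts = {k: dataclasses.replace(v, sigma=0.0) for k, v in truth.nutrients.items()}
    t0 = dataclasses.replace(truth, nutrients=nuts)
    res = fit_nutrient_regression(simulate_nutrients(t0, seed=8), "NO3_N")
    grid = interaction_effect_table(res)
    nt = truth.nutrients["NO3_N"]
    for row in grid.itertuples():
        expected = (nt.alpha + nt.beta_temp * row.temperature_c
                    + nt.beta_c * row.c_addition
                    + nt.beta_interaction * row.temperature_c * row.c_addition)
        assert row.prediction == pytest.approx(expected, abs=1e-8)
        assert row.lower_se <= row.prediction <= row.upper_se
    # beta3 < 0: NO3 declines with C fastest at the warmest temperature
    warm = grid[grid.temperature_c == -2.0].sort_values("c_addition")
    assert np.all(np.diff(warm["prediction"]) < 0)


def test_interaction_effect_table_lmm_backtransform():
    beta = (2.0, 0.1, 0.5, 0.03, -0.02, -0.002)
    res = fit_respiration_lmm(linear_records(beta), subset="below_zero")
    grid = interaction_effect_table(res)
    for row in grid.itertuples():
        mu = (beta[0] + beta[1] * row.temperature_c + beta[2] * row.c_addition
              + beta[3] * row.temperature_c * row.c_addition)
        assert row.prediction == pytest.approx(np.exp(mu), rel=1e-5)
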