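"""Ground-truth generator: determinism, mechanism invariants, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from snowflux import (
    compute_fluxes, fit_ancova, fit_q10_by_group, load_truth,
    simulate_field_season, simulate_glucose_experiment, simulate_incubation,
    simulate_lmm_scenario, simulate_nutrients, temperature_scaler,
    expected_respiration,
)
from snowflux.synthetic import invert_diffusive_gradient
from snowflux.snowpack_flux import DiffusionConstants, SnowpackSummary, \
    GradientMeasurement, diffusive_flux


def test_temperature_scaler_examples():
    assert temperature_scaler(0.0, 2.0, 0.3) == pytest.approx(1.0)
    assert temperature_scaler(-10.0, 2.0, 0.3) == pytest.approx(0.5 * np.exp(-3.0))
    # continuity at 0 and strict monotonicity
    assert temperature_scaler(-1e-9, 2.5, 0.12) == pytest.approx(1.0, rel=1e-6)
    temps = np.linspace(-15, 10, 101)
    g = temperature_scaler(temps, 2.5, 0.12)
    assert np.all(np.diff(g) > 0)
    with pytest.raises(ValueError):
        temperature_scaler(0.0, 0.9, 0.3)


def test_generators_are_pure_functions_of_seed(truth):
    for gen in (lambda s: simulate_incubation(truth, seed=s)[0],
                lambda s: simulate_nutrients(truth, seed=s),
                lambda s: simulate_glucose_experiment(truth, seed=s)[0],
                lambda s: simulate_field_season(truth, seed=s)[0],
                lambda s: simulate_lmm_scenario(truth, seed=s)):
        a, b, c = gen(123), gen(123), gen(124)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


def test_depletion_flat_baseline_limit(truth):
    inc = dataclasses.replace(truth.incubation, k_l_per_day=0.0)
    r0 = expected_respiration(inc, -6.0, 0.0, 0.0)
    r90 = expected_respiration(inc, -6.0, 2.0, 90.0)
    g = temperature_scaler(-6.0, inc.q10, inc.lambda_per_degc)
    assert r0 == pytest.approx(inc.baseline_rate_ug_per_g_day * g)
    assert r90 == pytest.approx(r0)


@pytest.mark.parametrize("temp", [-10.0, -6.0, -2.0])
@pytest.mark.parametrize("addition", [0.0, 2.0])
def test_mass_balance_of_labile_pool(truth, temp, addition):
    """Discretized cumulative labile respiration at t = 5/(k_l g) matches the
    analytic integral (C_l0 + a)(1 - e^-5) within 1%."""
    inc = truth.incubation
    g = temperature_scaler(temp, inc.q10, inc.lambda_per_degc)
    k_eff = inc.k_l_per_day * g
    horizon = 5.0 / k_eff
    t = np.linspace(0, horizon, 20_000)
    labile_rate = expected_respiration(inc, temp, addition, t) \
        - inc.baseline_rate_ug_per_g_day * g
    cum_mg = np.trapezoid(labile_rate, t) / 1000.0
    expected = (inc.c_l0_mg_per_g + addition) * (1 - np.exp(-5.0))
    assert cum_mg == pytest.approx(expected, rel=0.01)


def test_diffusion_inversion_identity():
    const = DiffusionConstants()
    summ = SnowpackSummary(280.0, 0.712, 0.893, 267.0)
    delta = invert_diffusive_gradient(0.6, 0.55, summ.porosity, summ.tortuosity,
                                      summ.mean_temperature_k, const)
    meas = GradientMeasurement("t", "s", 400.0, 400.0 + delta, 0.55, -4.0)
    est = diffusive_flux(meas, summ, const)
    assert est.flux_umol_m2_s == pytest.approx(0.6, rel=1e-10)


def test_field_round_trip_zero_noise(truth):
    fb = dataclasses.replace(truth.field_block, sigma_ln=0.0)
    snow = dataclasses.replace(truth.snow, sigma_ppm=0.0)
    t0 = dataclasses.replace(truth, field_block=fb, snow=snow)
    grads, pits, true_fluxes = simulate_field_season(t0, seed=55)
    fluxes = compute_fluxes(pits, grads)
    merged = fluxes.merge(true_fluxes[["unit_id", "true_flux_umol_m2_s"]],
                          on="unit_id")
    np.testing.assert_allclose(merged["flux_umol_m2_s"],
                               merged["true_flux_umol_m2_s"], rtol=1e-10)
    fits = fit_q10_by_group(fluxes, "year")
    for year, fit in fits.items():
        yt = truth.field_block.years[str(year)]
        assert fit.a_hat == pytest.approx(yt.a, rel=1e-6)
        assert fit.b_hat == pytest.approx(yt.b, rel=1e-6)


def test_field_recovery_with_noise(truth):
    """sigma_ppm = 0, sigma_ln = 0.2, n = 48 per year, fixed seed:
    cold-year (widest temperature span) parameters recovered within 10%."""
    snow = dataclasses.replace(truth.snow, sigma_ppm=0.0)
    t0 = dataclasses.replace(truth, snow=snow)
    grads, pits, _ = simulate_field_season(t0, seed=20190301)
    fluxes = compute_fluxes(pits, grads)
    fits = fit_q10_by_group(fluxes, "year")
    yt = truth.field_block.years["2017"]
    fit = fits[2017]
    assert fit.n == 48
    assert abs(fit.a_hat - yt.a) / yt.a < 0.10
    assert abs(fit.b_hat - yt.b) / yt.b < 0.10


def test_glucose_generator_null_and_exact(truth):
    fb = dataclasses.replace(truth.field_block, glucose_effect=2.0,
                             glucose_sigma_ln=0.0)
    t0 = dataclasses.replace(truth, field_block=fb)
    records, info = simulate_glucose_experiment(t0, seed=3)
    res = fit_ancova(records)
    assert res.effect_ratio == pytest.approx(2.0, rel=1e-8)

    # effect = 1: treatment coefficient centered on zero across replicates
    fb_null = dataclasses.replace(truth.field_block, glucose_effect=1.0)
    t_null = dataclasses.replace(truth, field_block=fb_null)
    betas = [fit_ancova(simulate_glucose_experiment(t_null, seed=600 + i)[0])
             .coefficients.loc["treatment", "estimate"] for i in range(60)]
    assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas))


def test_glucose_effect_recovery_interval(truth):
    records, info = simulate_glucose_experiment(truth, seed=20190301)
    res = fit_ancova(records)
    assert 1.6 <= res.effect_ratio <= 3.1
    assert res.treatment_p < 0.01


def test_nutrient_sign_pattern_power(truth):
    """Interaction signs (NO3 < 0, NH4 < 0, TFPA > 0) detected at p < 0.05
    in >= 80% of replicates of the 48-jar design."""
    from snowflux import fit_nutrient_regression
    hits = {"NO3_N": 0, "NH4_N": 0, "TFPA": 0}
    signs = {"NO3_N": -1, "NH4_N": -1, "TFPA": 1}
    n_sim = 100
    for i in range(n_sim):
        rec = simulate_nutrients(truth, seed=70_000 + i)
        for analyte, sign in signs.items():
            res = fit_nutrient_regression(rec, analyte)
            row = res.coefficients.loc["temperature_c:c_addition"]
            hits[analyte] += (np.sign(row["estimate"]) == sign) and row["p"] < 0.05
    for analyte, sign in signs.items():
        assert hits[analyte] / n_sim >= 0.80, analyte
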