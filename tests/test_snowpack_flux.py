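"""Snowpack diffusion kernel: porosity, tortuosity, flux law, barrier QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snowflux import (
    DiffusionConstants, GradientMeasurement, InvalidMeasurementError,
    SnowLayer, SnowPitProfile, SnowpackSummary, barrier_check, compute_fluxes,
    diffusive_flux, porosity, summarize_pit, tortuosity,
)

CONST = DiffusionConstants()


def oracle_flux(theta, tau, temp_k, delta_c, z, c=CONST):
    # independent one-line transcription of the printed diffusion law
    return theta * tau * c.d_co2 * c.molar_density_stp * (temp_k / c.t0_k) ** c.temp_exponent * delta_c / z


@pytest.mark.parametrize("density,expected", [(973.0, 0.0), (0.0, 1.0), (291.9, 0.70)])
def test_porosity_examples(density, expected):
    assert porosity(density) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("theta,expected", [(1.0, 1.0), (0.512, 0.8), (0.0, 0.0)])
def test_tortuosity_examples(theta, expected):
    assert tortuosity(theta) == pytest.approx(expected, abs=1e-12)


def test_porosity_rejects_unphysical_density():
    with pytest.raises(InvalidMeasurementError, match="pit7"):
        porosity(1200.0, pit_id="pit7")
    with pytest.raises(InvalidMeasurementError):
        porosity(-1.0)


def test_summarize_pit_means_and_units():
    layers = (SnowLayer(0, 280.0, -6.0), SnowLayer(10, 300.0, -4.0))
    summ = summarize_pit(SnowPitProfile("p1", "hydric", layers))
    assert summ.mean_density == pytest.approx(290.0)
    assert summ.mean_temperature_k == pytest.approx(268.15)

    single = summarize_pit(SnowPitProfile("p2", "hydric", (SnowLayer(0, 291.9, -5.0),)))
    assert single.porosity == pytest.approx(0.70)
    assert single.tortuosity == pytest.approx(0.887904, abs=5e-7)


def test_pit_invariants():
    with pytest.raises(InvalidMeasurementError):
        SnowPitProfile("p", "s", ())
    with pytest.raises(InvalidMeasurementError, match="contiguous"):
        SnowPitProfile("p", "s", (SnowLayer(0, 300, -5), SnowLayer(30, 300, -5)))
    with pytest.raises(InvalidMeasurementError):
        SnowLayer(0, 1000.0, -5.0)


def test_flux_hand_example():
    """Frozen hand evaluation of the diffusion law."""
    summ = SnowpackSummary(291.9, 0.70, 0.887904, 268.15)
    meas = GradientMeasurement("t1", "hydric", 400.0, 1400.0, 0.5, -4.0)
    est = diffusive_flux(meas, summ)
    assert est.flux_umol_m2_s == pytest.approx(0.7545, abs=2e-4)
    assert est.delta_c_ppm == 1000.0
    assert not est.negative_gradient


def test_flux_zero_gradient_and_depth_scaling():
    summ = SnowpackSummary(290.0, 0.7, 0.888, 268.15)
    flat = GradientMeasurement("t", "s", 405.0, 405.0, 0.5, -4.0)
    assert diffusive_flux(flat, summ).flux_umol_m2_s == 0.0
    m1 = GradientMeasurement("t", "s", 400.0, 900.0, 0.5, -4.0)
    m2 = GradientMeasurement("t", "s", 400.0, 900.0, 1.0, -4.0)
    f1 = diffusive_flux(m1, summ).flux_umol_m2_s
    f2 = diffusive_flux(m2, summ).flux_umol_m2_s
    assert f1 == pytest.approx(2 * f2, rel=1e-12)


def test_negative_gradient_flagged_not_truncated():
    summ = SnowpackSummary(290.0, 0.7, 0.888, 268.15)
    meas = GradientMeasurement("t", "s", 500.0, 400.0, 0.5, -4.0)
    est = diffusive_flux(meas, summ)
    assert est.flux_umol_m2_s < 0
    assert est.negative_gradient


@settings(max_examples=200, derandomize=True)
@given(
    density=st.floats(10.0, 960.0),
    temp_c=st.floats(-40.0, -0.1),
    delta_c=st.floats(-500.0, 5000.0),
    z=st.floats(0.05, 2.0),
)
def test_flux_matches_oracle_property(density, temp_c, delta_c, z):
    """The kernel equals an independent transcription of the formula."""
    theta = porosity(density)
    tau = tortuosity(theta)
    summ = SnowpackSummary(density, theta, tau, temp_c + 273.15)
    meas = GradientMeasurement("t", "s", 400.0, 400.0 + max(delta_c, -400.0), z, -4.0)
    est = diffusive_flux(meas, summ)
    expected = oracle_flux(theta, tau, temp_c + 273.15, meas.co2_subnivean_ppm - 400.0, z)
    assert est.flux_umol_m2_s == pytest.approx(expected, rel=1e-12, abs=1e-15)


def test_flux_monotone_in_porosity():
    fluxes = []
    for density in (500.0, 400.0, 300.0, 200.0):
        theta = porosity(density)
        summ = SnowpackSummary(density, theta, tortuosity(theta), 268.15)
        meas = GradientMeasurement("t", "s", 400.0, 1400.0, 0.5, -4.0)
        fluxes.append(diffusive_flux(meas, summ).flux_umol_m2_s)
    assert np.all(np.diff(fluxes) > 0)


def test_barrier_check():
    depths = np.arange(0, 60, 10.0)
    linear = [(d, 400 + 10 * d) for d in depths]
    res = barrier_check(linear)
    assert res.status == "pass" and res.r_squared == pytest.approx(1.0)

    # step discontinuity (ice lens): constructed so OLS R^2 is well below 0.9
    step = [(d, 400.0 if d < 30 else 1400.0) for d in depths]
    res = barrier_check(step)
    assert res.status == "fail" and res.r_squared < 0.9

    assert barrier_check([(0, 400), (50, 900)]).status == "insufficient data"


def test_compute_fluxes_round_trip_means(tmp_path):
    import pandas as pd
    pits = pd.DataFrame([
        {"pit_id": "p1", "site": "hydric", "date": "d", "top_depth_cm": 0.0,
         "density_g_per_l": 291.9, "temperature_c": -5.0},
        {"pit_id": "p1", "site": "hydric", "date": "d", "top_depth_cm": 10.0,
         "density_g_per_l": 291.9, "temperature_c": -5.0},
    ])
    grads = pd.DataFrame([
        {"unit_id": "t1", "site": "hydric", "date": "d", "year": 2019,
         "treatment": "control", "phase": "survey", "co2_surface_ppm": 400.0,
         "co2_subnivean_ppm": 1400.0, "snow_depth_m": 0.5,
         "soil_temperature_c": -4.0},
        # replicate probe insertion for the same tree: averaged first
        {"unit_id": "t1", "site": "hydric", "date": "d", "year": 2019,
         "treatment": "control", "phase": "survey", "co2_surface_ppm": 400.0,
         "co2_subnivean_ppm": 1400.0, "snow_depth_m": 0.5,
         "soil_temperature_c": -4.0},
    ])
    out = compute_fluxes(pits, grads)
    assert len(out) == 1
    assert out.loc[0, "flux_umol_m2_s"] == pytest.approx(0.75448, abs=1e-4)
    assert out.loc[0, "qc_flag"] == "ok"
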