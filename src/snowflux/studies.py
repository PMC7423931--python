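"""Reproducible validation studies of the analysis chain.

Each study generates its own inputs from the synthetic ground-truth
generator (or from random draws of the flux-law inputs), runs the package's
estimators and measures recovery, coverage or design properties.  They are
the package's built-in evidence that the estimators do what they claim, and
are driven both by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .incubation import fit_nutrient_regression, fit_respiration_lmm
from .q10 import fit_q10, mc_interval, predict_flux
from .snowpack_flux import (DiffusionConstants, GradientMeasurement,
                            SnowpackSummary, diffusive_flux, porosity,
                            tortuosity)
from .synthetic import (SyntheticTruth, simulate_glucose_experiment,
                        simulate_lmm_scenario, simulate_nutrients)
from .treatment import fit_ancova

#: canonical Q10 recovery scenario: truth, balanced temperature design, noise
Q10_TRUTH = (0.5, 3.0)
Q10_TEMPS = np.repeat([-8.0, -6.0, -4.0, -2.0], 12)
Q10_SIGMA_LN = 0.2


def flux_oracle_max_rel_err(n: int = 1000, seed: int = 0) -> float:
    """Worst relative disagreement between the flux kernel and a direct
    one-line evaluation of the diffusion law over random valid inputs."""
    rng = np.random.default_rng(seed)
    c = DiffusionConstants()
    worst = 0.0
    for _ in range(n):
        density = rng.uniform(50.0, 950.0)
        theta = porosity(density, c)
        tau = tortuosity(theta)
        temp_k = rng.uniform(233.15, 273.15)
        delta_c = rng.uniform(1.0, 5000.0)
        z = rng.uniform(0.05, 2.0)
        summ = SnowpackSummary(density, theta, tau, temp_k)
        meas = GradientMeasurement("u", "s", 400.0, 400.0 + delta_c, z, -4.0)
        got = diffusive_flux(meas, summ, c).flux_umol_m2_s
        want = (theta * tau * c.d_co2 * c.molar_density_stp
                * (temp_k / c.t0_k) ** c.temp_exponent * delta_c / z)
        worst = max(worst, abs(got - want) / abs(want))
    return worst


def q10_recovery(seed: int = 20190301) -> dict:
    """Fixed-seed single-dataset recovery of (A, B) under lognormal noise."""
    rng = np.random.default_rng(seed)
    a, b = Q10_TRUTH
    flux = a * b ** ((Q10_TEMPS + 5) / 10.0) * np.exp(
        rng.normal(0.0, Q10_SIGMA_LN, Q10_TEMPS.size) - Q10_SIGMA_LN ** 2 / 2)
    fit = fit_q10(zip(Q10_TEMPS, flux))
    return {"a_hat": fit.a_hat, "b_hat": fit.b_hat,
            "a_rel_err": abs(fit.a_hat - a) / a,
            "b_rel_err": abs(fit.b_hat - b) / b, "n": int(Q10_TEMPS.size)}


def q10_coverage(n_replicates: int = 500, n_draws: int = 2000,
                 temperature_c: float = -3.0, alpha: float = 0.05,
                 seed: int = 20190301) -> dict:
    """Monte Carlo interval coverage of the true prediction over replicates."""
    rng_master = np.random.default_rng(seed)
    a, b = Q10_TRUTH
    true_pred = a * b ** ((temperature_c + 5) / 10.0)
    covered = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            rng = np.random.default_rng(rng_master.integers(2 ** 31))
            flux = a * b ** ((Q10_TEMPS + 5) / 10.0) * np.exp(
                rng.normal(0.0, Q10_SIGMA_LN, Q10_TEMPS.size)
                - Q10_SIGMA_LN ** 2 / 2)
            fit = fit_q10(zip(Q10_TEMPS, flux))
            iv = mc_interval(fit, temperature_c, alpha, n_draws,
                             seed=int(rng.integers(2 ** 31)))
            covered += iv.lower <= true_pred <= iv.upper
    return {"coverage": covered / n_replicates, "n": n_replicates,
            "nominal": 1 - alpha}


def ancova_design_df(truth: SyntheticTruth, seed: int = 20190301) -> dict:
    """Treatment-test df structure of the paired-plot design.

    Simulates the 3 sites x 5 pairs x 2 treatments experiment with one plot
    unusable (a failed pre-treatment measurement, as in the reported field
    campaign, whose printed F tests imply 29 analysed plots) and reads the
    final-model treatment F df.
    """
    records, _ = simulate_glucose_experiment(truth, seed=seed)
    usable = records.iloc[1:]
    res = fit_ancova(usable)
    return {"df1": res.treatment_df[0], "df2": res.treatment_df[1],
            "n": res.n, "treatment_f": res.treatment_f,
            "effect_ratio": res.effect_ratio}


def nutrient_design_df(truth: SyntheticTruth, analyte: str = "NO3_N",
                       seed: int = 20190301) -> dict:
    """Regression F df on the 48-jar sub-zero nutrient design."""
    records = simulate_nutrients(truth, seed=seed)
    res = fit_nutrient_regression(records, analyte)
    return {"df1": res.f_df[0], "df2": res.f_df[1], "n": res.n,
            "r_squared": res.r_squared}


def lmm_recovery(truth: SyntheticTruth, n_replicates: int = 200,
                 seed: int = 20190301) -> dict:
    """Mixed-model fixed-coefficient recovery at the known-β default scenario.

    Returns per-coefficient mean relative bias over replicates and the
    fraction of replicates with the expected sign pattern (positive
    C-addition effect, negative date x temperature interaction).
    """
    true_beta = truth.lmm_scenario.coefficients()
    rng_master = np.random.default_rng(seed)
    estimates = []
    sign_hits = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            records = simulate_lmm_scenario(
                truth, seed=int(rng_master.integers(2 ** 31)))
            res = fit_respiration_lmm(records, subset="below_zero")
            est = res.coefficients["estimate"].reindex(true_beta.index)
            estimates.append(est.to_numpy())
            sign_hits += (est["c_addition"] > 0
                          and est["temperature_c:date_c"] < 0)
    est_arr = np.array(estimates)
    mean_bias = est_arr.mean(axis=0) - true_beta.to_numpy()
    rel_bias = np.abs(mean_bias) / np.abs(true_beta.to_numpy())
    return {
        "terms": list(true_beta.index),
        "true": true_beta.to_numpy().tolist(),
        "mean_estimate": est_arr.mean(axis=0).tolist(),
        "relative_bias": rel_bias.tolist(),
        "max_relative_bias": float(rel_bias.max()),
        "sign_pattern_rate": sign_hits / n_replicates,
        "n_replicates": n_replicates,
    }
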