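"""Synthetic study generator with known ground truth.

Generates every input table the analysis pipeline consumes — snow-pit
profiles, two-point [CO2] gradients, paired glucose plots, incubation
respiration time series and endpoint nutrient concentrations — from a single
ground-truth parameter set, so that every estimator in the package can be
tested for parameter recovery without any external data.

The incubation generator embodies a labile-carbon substrate-depletion
mechanism: respiration is the sum of a first-order decaying labile pool and
a constant recalcitrant baseline, both scaled by a temperature function that
combines a Q10 factor with an extra sub-zero attenuation,

    g(T) = q**(T/10)                 for T >= 0
    g(T) = q**(T/10) * exp(lam * T)  for T < 0   (continuous at 0)

    R(t) = 1000 * k_l * g(T) * (C_l0 + a) * exp(-k_l * g(T) * t)
           + baseline * g(T)

with pools in mg C/g dry soil, rates in 1/day, respiration in µg C/g/day and
``a`` the added labile C.  Warm jars respire faster and deplete sooner —
exactly the decline-especially-at-warm-temperatures pattern the analysis
modules are built to detect.  Every generator is a pure function of
(truth, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .snowpack_flux import DiffusionConstants

#: default measurement schedule: dense early, weekly, then biweekly (days)
DEFAULT_DATES = (2, 5, 9, 12, 16, 19, 23, 26, 30, 37, 44, 51, 58, 65, 72, 79, 86, 90)
DEFAULT_SITES = ("hydric", "mesic", "xeric")


@dataclass(frozen=True)
class YearTruth:
    a: float
    b: float
    soil_temp_range: tuple[float, float]


@dataclass(frozen=True)
class FieldTruth:
    years: dict[str, YearTruth]
    sigma_ln: float = 0.2
    glucose_effect: float = 2.225
    glucose_sigma_ln: float = 0.25
    pre_flux_median: dict[str, float] = field(default_factory=dict)
    pre_flux_sigma_ln: float = 0.4


@dataclass(frozen=True)
class SnowTruth:
    ambient_co2_ppm: float = 405.0
    sigma_ppm: float = 10.0
    density_mean: dict[str, float] = field(default_factory=dict)
    density_sd: float = 25.0
    temp_mean_c: float = -6.0
    temp_sd_c: float = 1.5
    depth_mean_m: float = 0.6
    depth_sd_m: float = 0.1
    n_pits_per_site: int = 3


@dataclass(frozen=True)
class IncubationTruth:
    c_l0_mg_per_g: float = 0.8
    k_l_per_day: float = 0.03
    baseline_rate_ug_per_g_day: float = 2.0
    q10: float = 2.5
    lambda_per_degc: float = 0.12
    sigma_jar: float = 0.2
    sigma_resid: float = 0.3

    def __post_init__(self) -> None:
        if self.q10 <= 1:
            raise ValueError("q10 must be > 1")
        if self.lambda_per_degc <= 0:
            raise ValueError("lambda_per_degc must be > 0")
        for name in ("c_l0_mg_per_g", "k_l_per_day", "baseline_rate_ug_per_g_day",
                     "sigma_jar", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class NutrientTruth:
    alpha: float
    beta_temp: float
    beta_c: float
    beta_interaction: float
    sigma: float
    log_scale: bool = False


@dataclass(frozen=True)
class LmmScenario:
    """Known-coefficient linear log-respiration scenario for recovery studies."""

    intercept: float = 2.5
    temperature_c: float = 0.12
    c_addition: float = 0.5
    temperature_c_x_c_addition: float = 0.04
    date_c: float = -0.02
    temperature_c_x_date_c: float = -0.002
    sigma_jar: float = 0.2
    sigma_resid: float = 0.3

    def coefficients(self) -> "pd.Series":
        return pd.Series({
            "intercept": self.intercept, "temperature_c": self.temperature_c,
            "c_addition": self.c_addition,
            "temperature_c:c_addition": self.temperature_c_x_c_addition,
            "date_c": self.date_c,
            "temperature_c:date_c": self.temperature_c_x_date_c,
        })


@dataclass(frozen=True)
class SyntheticTruth:
    """Complete ground-truth parameter set carried with every synthetic dataset."""

    field_block: FieldTruth
    snow: SnowTruth
    incubation: IncubationTruth
    nutrients: dict[str, NutrientTruth]
    lmm_scenario: LmmScenario = LmmScenario()
    seed: int = 20190301

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        years = {
            str(y): YearTruth(v["a"], v["b"], tuple(v["soil_temp_range"]))
            for y, v in d["field"]["years"].items()
        }
        fb = {k: v for k, v in d["field"].items() if k != "years"}
        return cls(
            field_block=FieldTruth(years=years, **fb),
            snow=SnowTruth(**d["snow"]),
            incubation=IncubationTruth(**d["incubation"]),
            nutrients={k: NutrientTruth(**v) for k, v in d["nutrients"].items()},
            lmm_scenario=LmmScenario(**d.get("lmm_scenario", {})),
            seed=int(d.get("seed", 20190301)),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field"] = d.pop("field_block")
        return d


def load_truth(path: str | Path | None = None) -> SyntheticTruth:
    """Load a truth configuration; defaults to the packaged parameter set."""
    if path is None:
        text = resources.files("snowflux").joinpath("data/default_truth.yaml").read_text()
    else:
        text = Path(path).read_text()
    return SyntheticTruth.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Incubation mechanism

def temperature_scaler(temperature_c, q: float, lam: float):
    """Unitless temperature scaling g(T) of respiration kinetics.

    Above 0 °C this is the plain Q10 factor referenced to 0 °C; below 0 °C an
    additional exponential attenuation represents the rapid loss of liquid
    water and solute transport in frozen soil.  Continuous and strictly
    increasing in T.
    """
    if q <= 1:
        raise ValueError("q must be > 1")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    t = np.asarray(temperature_c, dtype=float)
    g = q ** (t / 10.0) * np.exp(lam * np.minimum(t, 0.0))
    return g if g.ndim else float(g)


def expected_respiration(truth: IncubationTruth, temperature_c, c_addition,
                         t_days):
    """Noise-free expected respiration (µg C/g dry soil/day) of the mechanism."""
    g = temperature_scaler(temperature_c, truth.q10, truth.lambda_per_degc)
    k_eff = truth.k_l_per_day * g
    labile = 1000.0 * k_eff * (truth.c_l0_mg_per_g + np.asarray(c_addition, float))
    return labile * np.exp(-k_eff * np.asarray(t_days, float)) \
        + truth.baseline_rate_ug_per_g_day * g


def simulate_incubation(truth: SyntheticTruth,
                        temperatures: Sequence[float] = (-10, -6, -2, 2, 6),
                        c_additions: Sequence[float] = (0.0, 0.2, 0.4, 2.0),
                        n_jars: int = 4,
                        dates: Sequence[int] = DEFAULT_DATES,
                        seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the jar incubation: records plus per-record expected truth.

    Observed respiration is exp(ln R + jar intercept + residual) with the
    jar intercept drawn once per jar; observations below the 0.01 µg C/g/day
    detection floor are flagged.
    """
    if not len(temperatures) or not len(c_additions) or n_jars < 1:
        raise ValueError("design must be non-empty")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    inc = truth.incubation
    rows = []
    jar_no = 0
    for temp in temperatures:
        for c in c_additions:
            for _ in range(n_jars):
                jar_no += 1
                jar_id = f"jar{jar_no:03d}"
                u = rng.normal(0.0, inc.sigma_jar)
                for day in dates:
                    mu = expected_respiration(inc, temp, c, day)
                    obs = float(np.exp(np.log(mu) + u + rng.normal(0.0, inc.sigma_resid)))
                    rows.append({
                        "jar_id": jar_id, "temperature_c": float(temp),
                        "c_addition": float(c), "julian_date": int(day),
                        "respiration": obs,
                        "below_detection": obs < 0.01,
                        "true_respiration": float(mu),
                        "true_jar_intercept": float(u),
                    })
    full = pd.DataFrame(rows)
    records = full.drop(columns=["true_respiration", "true_jar_intercept"])
    return records, full


def linearized_lmm_truth(truth: SyntheticTruth,
                         temperatures: Sequence[float] = (-10, -6, -2),
                         c_additions: Sequence[float] = (0.0, 0.2, 0.4, 2.0),
                         dates: Sequence[int] = DEFAULT_DATES) -> pd.Series:
    """True fixed coefficients of the log-respiration mixed model.

    The depletion mechanism is nonlinear in (T, C, t); the estimand of the
    linear mixed model is therefore the least-squares projection of the
    noise-free log expected respiration onto the fitted design (julian date
    centered at the design mean).  Returned in the model's term order.
    """
    grid = [(t, c, d) for t in temperatures for c in c_additions for d in dates]
    temp = np.array([g[0] for g in grid], float)
    c = np.array([g[1] for g in grid], float)
    day = np.array([g[2] for g in grid], float)
    day_c = day - day.mean()
    y = np.log(expected_respiration(truth.incubation, temp, c, day))
    X = np.column_stack([np.ones_like(temp), temp, c, temp * c, day_c, temp * day_c])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta, index=["intercept", "temperature_c", "c_addition",
                                  "temperature_c:c_addition", "date_c",
                                  "temperature_c:date_c"])


def simulate_lmm_scenario(truth: SyntheticTruth,
                          temperatures: Sequence[float] = (-10, -6, -2),
                          c_additions: Sequence[float] = (0.0, 0.2, 0.4, 2.0),
                          n_jars: int = 4,
                          dates: Sequence[int] = DEFAULT_DATES,
                          seed: int | None = None) -> pd.DataFrame:
    """Generate respiration records directly from the known-β linear model.

    Unlike :func:`simulate_incubation`, which draws from the nonlinear
    depletion mechanism, this scenario generates log respiration exactly from
    the linear fixed-effect formula the mixed model fits (julian date
    centered at the design mean), plus the jar intercept and residual noise —
    so the mixed-model estimator is exactly unbiased for the configured
    coefficients and recovery can be measured against a known truth.
    """
    sc = truth.lmm_scenario
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    day_mean = float(np.mean(dates))
    rows = []
    jar_no = 0
    for temp in temperatures:
        for c in c_additions:
            for _ in range(n_jars):
                jar_no += 1
                u = rng.normal(0.0, sc.sigma_jar)
                for day in dates:
                    dc = day - day_mean
                    mu = (sc.intercept + sc.temperature_c * temp
                          + sc.c_addition * c
                          + sc.temperature_c_x_c_addition * temp * c
                          + sc.date_c * dc
                          + sc.temperature_c_x_date_c * temp * dc)
                    obs = float(np.exp(mu + u + rng.normal(0.0, sc.sigma_resid)))
                    rows.append({"jar_id": f"jar{jar_no:03d}",
                                 "temperature_c": float(temp),
                                 "c_addition": float(c),
                                 "julian_date": int(day), "respiration": obs,
                                 "below_detection": obs < 0.01})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Field generators

def invert_diffusive_gradient(flux: float, snow_depth_m: float, theta: float,
                              tau: float, temp_k: float,
                              constants: DiffusionConstants = DiffusionConstants()
                              ) -> float:
    """Subnivean-minus-surface [CO2] difference (ppm) producing a given flux."""
    denom = (theta * tau * constants.d_co2 * constants.molar_density_stp
             * (temp_k / constants.t0_k) ** constants.temp_exponent)
    return flux * snow_depth_m / denom


def _draw_pits(truth: SyntheticTruth, site: str, date: str, rng,
               n_layers: int) -> list[dict]:
    snow = truth.snow
    rows = []
    for p in range(snow.n_pits_per_site):
        for i in range(n_layers):
            dens = float(np.clip(rng.normal(snow.density_mean[site], snow.density_sd),
                                 60.0, 900.0))
            temp = float(np.minimum(rng.normal(snow.temp_mean_c, snow.temp_sd_c), -0.1))
            rows.append({"pit_id": f"{site}_{date}_p{p + 1}", "site": site,
                         "date": date, "top_depth_cm": 10.0 * i,
                         "density_g_per_l": dens, "temperature_c": temp})
    return rows


def simulate_field_season(truth: SyntheticTruth, n_trees_per_site: int = 16,
                          sites: Sequence[str] = DEFAULT_SITES,
                          years: Sequence[str] | None = None,
                          seed: int | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate late-March gradient surveys: gradients, pits and true fluxes.

    True fluxes follow each year's Q10 truth with mean-one lognormal noise;
    subnivean [CO2] is obtained by inverting the diffusion law through the
    site-mean pit summary (so the analysis round trip is exact at zero
    noise), then additive Gaussian ppm noise is applied to both readings.
    """
    from .snowpack_flux import summarize_pits_table  # local: avoids cycle at import

    if n_trees_per_site < 1:
        raise ValueError("need n >= 1 trees per site")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    fb, snow = truth.field_block, truth.snow
    if years is None:
        years = sorted(fb.years)
    grad_rows, pit_rows, true_rows = [], [], []
    for year in years:
        yt = fb.years[str(year)]
        date = f"{year}-03-25"
        n_layers = max(int(round(snow.depth_mean_m / 0.10)), 1)
        for site in sites:
            pit_rows.extend(_draw_pits(truth, site, date, rng, n_layers))
    pits = pd.DataFrame(pit_rows)
    summaries = summarize_pits_table(pits).set_index(["site", "date"])
    for year in years:
        yt = fb.years[str(year)]
        date = f"{year}-03-25"
        lo, hi = yt.soil_temp_range
        for site in sites:
            summ = summaries.loc[(site, date)]
            for i in range(n_trees_per_site):
                unit_id = f"{site}_{year}_t{i + 1:02d}"
                treatment = "control" if i < n_trees_per_site // 2 else "snowfence"
                soil_t = float(rng.uniform(lo, hi))
                noise = np.exp(rng.normal(0.0, fb.sigma_ln) - fb.sigma_ln ** 2 / 2.0)
                true_flux = yt.a * yt.b ** ((soil_t + 5.0) / 10.0) * noise
                depth = float(np.clip(rng.normal(snow.depth_mean_m, snow.depth_sd_m),
                                      0.2, 1.5))
                delta_c = invert_diffusive_gradient(
                    true_flux, depth, summ["theta"], summ["tau"],
                    summ["mean_temperature_k"])
                surface = snow.ambient_co2_ppm + rng.normal(0.0, snow.sigma_ppm)
                subniv = snow.ambient_co2_ppm + delta_c + rng.normal(0.0, snow.sigma_ppm)
                grad_rows.append({
                    "unit_id": unit_id, "site": site, "date": date,
                    "year": int(year), "treatment": treatment, "phase": "survey",
                    "co2_surface_ppm": surface, "co2_subnivean_ppm": max(subniv, 0.0),
                    "snow_depth_m": depth, "soil_temperature_c": soil_t,
                })
                true_rows.append({"unit_id": unit_id, "year": int(year),
                                  "site": site, "true_flux_umol_m2_s": true_flux,
                                  "soil_temperature_c": soil_t})
    return pd.DataFrame(grad_rows), pits, pd.DataFrame(true_rows)


def simulate_glucose_experiment(truth: SyntheticTruth, n_pairs_per_site: int = 5,
                                sites: Sequence[str] = DEFAULT_SITES,
                                seed: int | None = None
                                ) -> tuple[pd.DataFrame, dict]:
    """Simulate the paired-plot glucose addition: records plus effect truth.

    Pre-treatment fluxes are lognormal around site medians; post-treatment
    control fluxes are pre times lognormal noise and glucose fluxes carry the
    additional multiplicative treatment effect.
    """
    if n_pairs_per_site < 2:
        raise ValueError("need >= 2 pairs per site")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    fb, snow = truth.field_block, truth.snow
    rows = []
    for site in sites:
        med = fb.pre_flux_median.get(site, 0.35)
        for pair in range(n_pairs_per_site):
            pre_pair = med * np.exp(rng.normal(0.0, fb.pre_flux_sigma_ln))
            depth = float(np.clip(rng.normal(snow.depth_mean_m, snow.depth_sd_m),
                                  0.2, 1.5))
            for treatment in ("control", "glucose"):
                pre = pre_pair * np.exp(rng.normal(0.0, 0.1))
                mult = fb.glucose_effect if treatment == "glucose" else 1.0
                post = pre * mult * np.exp(rng.normal(0.0, fb.glucose_sigma_ln))
                rows.append({
                    "plot_id": f"{site}_pair{pair + 1}_{treatment}", "site": site,
                    "treatment": treatment, "flux_pre": pre, "flux_post": post,
                    "snow_depth_pre_m": depth,
                })
    return pd.DataFrame(rows), {"glucose_effect": fb.glucose_effect,
                                "sigma_ln": fb.glucose_sigma_ln}


def simulate_nutrients(truth: SyntheticTruth,
                       temperatures: Sequence[float] = (-10, -6, -2),
                       c_additions: Sequence[float] = (0.0, 0.2, 0.4, 2.0),
                       n_jars: int = 4,
                       seed: int | None = None) -> pd.DataFrame:
    """Simulate endpoint nutrient concentrations for each analyte.

    Linear in temperature, C addition and their interaction with the
    configured coefficient signs; log-scale analytes (NH4-N) are generated on
    the log scale.  Values below the NH4 assay floor are flagged.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for analyte, nt in truth.nutrients.items():
        jar_no = 0
        for temp in temperatures:
            for c in c_additions:
                for _ in range(n_jars):
                    jar_no += 1
                    mu = (nt.alpha + nt.beta_temp * temp + nt.beta_c * c
                          + nt.beta_interaction * temp * c)
                    val = mu + rng.normal(0.0, nt.sigma)
                    if nt.log_scale:
                        val = float(np.exp(val))
                    val = max(float(val), 0.01)
                    below = analyte == "NH4_N" and val < 0.5
                    rows.append({"jar_id": f"{analyte}_jar{jar_no:03d}",
                                 "temperature_c": float(temp),
                                 "c_addition": float(c), "analyte": analyte,
                                 "concentration": val,
                                 "below_detection": below})
    return pd.DataFrame(rows)
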