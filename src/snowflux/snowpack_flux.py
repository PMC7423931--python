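"""Diffusion-gradient estimation of CO2 efflux through a seasonal snowpack.

The gradient method treats the snowpack as a porous diffusive medium: CO2
produced by soil microbial respiration accumulates in the subnivean space and
diffuses to the atmosphere down the concentration gradient.  Efflux is

    J_c = theta * tau * D * (P0 / (R * T0)) * (T / T0)**0.81 * dC / z

with snowpack porosity ``theta`` (from mean snow density relative to ice),
tortuosity ``tau = theta**(1/3)``, the diffusion coefficient of CO2 in air
``D``, the molar density of an ideal gas at STP, the snowpack temperature
``T`` (K), the subnivean-minus-surface mixing ratio difference ``dC``
(µmol/mol) and snow depth ``z`` (m).  The result is in µmol·m⁻²·s⁻¹.

Snowpack physical properties come from excavated pit profiles measured in
contiguous 10-cm density/temperature intervals; a two-point [CO2] gradient
(snow surface and ground surface) provides ``dC`` and ``z`` per tree or plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class InvalidMeasurementError(ValueError):
    """A field measurement violates a physical constraint."""


@dataclass(frozen=True)
class DiffusionConstants:
    """Physical constants of the snowpack diffusion law.

    Attributes
    ----------
    d_co2 : float
        Diffusion coefficient of CO2 in air, m²/s.
    molar_density_stp : float
        Molar density of an ideal gas at standard temperature and
        pressure (P0/(R·T0)), mol/m³.
    ice_density : float
        Density of pure ice, g/L (numerically identical to kg/m³).
    temp_exponent : float
        Exponent of the (T/T0) temperature correction of diffusivity.
    t0_k : float
        Reference (standard) temperature, K.
    """

    d_co2: float = 0.1381e-4
    molar_density_stp: float = 44.613
    ice_density: float = 973.0
    temp_exponent: float = 0.81
    t0_k: float = 273.15

    def __post_init__(self) -> None:
        for name in ("d_co2", "molar_density_stp", "ice_density", "temp_exponent", "t0_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"DiffusionConstants.{name} must be strictly positive")


@dataclass(frozen=True)
class SnowLayer:
    """One 10-cm pit interval: depth below the snow surface, density, temperature."""

    top_depth_cm: float
    density: float  # g/L == kg/m³
    temperature_c: float

    def __post_init__(self) -> None:
        if not 0 < self.density <= 973.0:
            raise InvalidMeasurementError(
                f"snow density {self.density} g/L outside (0, 973]"
            )
        if self.top_depth_cm < 0:
            raise InvalidMeasurementError("layer top depth must be >= 0")


@dataclass(frozen=True)
class SnowPitProfile:
    """Ordered layers of one excavated snow pit, surface downward."""

    pit_id: str
    site: str
    layers: tuple[SnowLayer, ...]
    interval_cm: float = 10.0

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise InvalidMeasurementError(f"pit {self.pit_id}: no layers")
        tops = [lay.top_depth_cm for lay in self.layers]
        expected = [i * self.interval_cm for i in range(len(self.layers))]
        if not np.allclose(tops, expected):
            raise InvalidMeasurementError(
                f"pit {self.pit_id}: layers not contiguous {self.interval_cm} cm "
                f"intervals from the surface (got tops {tops})"
            )


@dataclass(frozen=True)
class SnowpackSummary:
    """Pit-aggregated physical quantities entering the flux formula."""

    mean_density: float
    porosity: float
    tortuosity: float
    mean_temperature_k: float


@dataclass(frozen=True)
class GradientMeasurement:
    """One tree/plot two-point [CO2] gradient observation."""

    unit_id: str
    site: str
    co2_surface_ppm: float
    co2_subnivean_ppm: float
    snow_depth_m: float
    soil_temperature_c: float
    treatment: str = "control"
    phase: str = "survey"
    year: int = 0

    def __post_init__(self) -> None:
        if self.snow_depth_m <= 0:
            raise InvalidMeasurementError(
                f"unit {self.unit_id}: snow depth must be > 0 m"
            )
        if self.co2_surface_ppm < 0 or self.co2_subnivean_ppm < 0:
            raise InvalidMeasurementError(
                f"unit {self.unit_id}: [CO2] must be >= 0"
            )


@dataclass(frozen=True)
class FluxEstimate:
    """Computed efflux with the snowpack quantities that produced it."""

    unit_id: str
    flux_umol_m2_s: float
    summary_used: SnowpackSummary
    delta_c_ppm: float
    negative_gradient: bool = False


@dataclass(frozen=True)
class BarrierCheck:
    """QC result of the within-snowpack [CO2] profile linearity test."""

    status: str  # "pass" | "fail" | "insufficient data"
    r_squared: float | None
    threshold: float
    n_points: int


def porosity(mean_density: float, constants: DiffusionConstants = DiffusionConstants(),
             pit_id: str = "<pit>") -> float:
    """Snowpack porosity theta = 1 - rho / rho_ice, from mean density in g/L."""
    if mean_density < 0 or mean_density > constants.ice_density:
        raise InvalidMeasurementError(
            f"pit {pit_id}: mean density {mean_density} g/L outside "
            f"[0, {constants.ice_density}]"
        )
    return 1.0 - mean_density / constants.ice_density


def tortuosity(theta: float) -> float:
    """Snowpack tortuosity tau = theta**(1/3); monotone in porosity."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"porosity {theta} outside [0, 1]")
    return theta ** (1.0 / 3.0)


def summarize_pit(profile: SnowPitProfile,
                  constants: DiffusionConstants = DiffusionConstants(),
                  weighting: str = "unweighted") -> SnowpackSummary:
    """Aggregate a pit profile to the quantities the flux formula needs.

    ``weighting`` selects the layer aggregation: "unweighted" (default)
    averages the 10-cm interval values directly; "depth" weights layers by
    their thickness (identical for the standard uniform-interval profiles,
    provided for profiles with a short bottom layer).
    """
    dens = np.array([lay.density for lay in profile.layers], dtype=float)
    temps = np.array([lay.temperature_c for lay in profile.layers], dtype=float)
    if weighting == "unweighted":
        w = np.ones_like(dens)
    elif weighting == "depth":
        w = np.full_like(dens, profile.interval_cm)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    mean_density = float(dens @ w)
    mean_temp_k = float(temps @ w) + 273.15
    if mean_temp_k > 273.15:
        warnings.warn(
            f"pit {profile.pit_id}: mean snowpack temperature above 0 degC",
            stacklevel=2,
        )
    theta = porosity(mean_density, constants, pit_id=profile.pit_id)
    return SnowpackSummary(
        mean_density=mean_density,
        porosity=theta,
        tortuosity=tortuosity(theta),
        mean_temperature_k=mean_temp_k,
    )


def diffusive_flux(meas: GradientMeasurement, summary: SnowpackSummary,
                   constants: DiffusionConstants = DiffusionConstants()) -> FluxEstimate:
    """Evaluate the snowpack diffusion law for one gradient measurement.

    Returns the efflux in µmol·m⁻²·s⁻¹.  A negative subnivean-minus-surface
    gradient yields a negative flux, flagged rather than truncated.
    """
    if meas.snow_depth_m <= 0:
        raise InvalidMeasurementError(f"unit {meas.unit_id}: snow depth must be > 0")
    delta_c = meas.co2_subnivean_ppm - meas.co2_surface_ppm
    flux = (
        summary.porosity
        * summary.tortuosity
        * constants.d_co2
        * constants.molar_density_stp
        * (summary.mean_temperature_k / constants.t0_k) ** constants.temp_exponent
        * delta_c
        / meas.snow_depth_m
    )
    return FluxEstimate(
        unit_id=meas.unit_id,
        flux_umol_m2_s=float(flux),
        summary_used=summary,
        delta_c_ppm=float(delta_c),
        negative_gradient=delta_c < 0,
    )


def barrier_check(profile_co2: Sequence[tuple[float, float]],
                  r2_threshold: float = 0.90) -> BarrierCheck:
    """Linearity QC of a within-snowpack [CO2]-vs-depth profile.

    A structurally homogeneous snowpack in diffusive steady state shows a
    linear [CO2] profile; an ice lens or wind crust acting as a diffusion
    barrier breaks the linearity and would bias the two-point estimate high.
    Fits [CO2] on depth by OLS and compares R² against the threshold.  The
    flag is advisory; no data are dropped here.
    """
    pts = list(profile_co2)
    if len(pts) < 3:
        return BarrierCheck("insufficient data", None, r2_threshold, len(pts))
    depth = np.array([p[0] for p in pts], dtype=float)
    ppm = np.array([p[1] for p in pts], dtype=float)
    res = stats.linregress(depth, ppm)
    r2 = float(res.rvalue ** 2)
    status = "pass" if r2 >= r2_threshold else "fail"
    return BarrierCheck(status, r2, r2_threshold, len(pts))


# ---------------------------------------------------------------------------
# Tabular pipeline layer

def summarize_pits_table(pits: pd.DataFrame,
                         constants: DiffusionConstants = DiffusionConstants(),
                         weighting: str = "unweighted") -> pd.DataFrame:
    """Per-(site, date) mean snowpack summary from a long-format pit table.

    Each pit is summarized individually, then pit summaries are averaged per
    site and date: every gradient measurement at a site uses the mean of its
    representative pits.
    """
    rows = []
    for (pit_id, site, date), grp in pits.groupby(["pit_id", "site", "date"], sort=True):
        grp = grp.sort_values("top_depth_cm")
        layers = tuple(
            SnowLayer(r.top_depth_cm, r.density_g_per_l, r.temperature_c)
            for r in grp.itertuples()
        )
        summ = summarize_pit(SnowPitProfile(str(pit_id), str(site), layers),
                             constants, weighting)
        rows.append({
            "site": site, "date": date,
            "mean_density": summ.mean_density,
            "mean_temperature_k": summ.mean_temperature_k,
        })
    per_pit = pd.DataFrame(rows)
    agg = per_pit.groupby(["site", "date"], as_index=False).mean(numeric_only=True)
    agg["theta"] = [porosity(d, constants) for d in agg["mean_density"]]
    agg["tau"] = [tortuosity(t) for t in agg["theta"]]
    return agg


def compute_fluxes(pits: pd.DataFrame, gradients: pd.DataFrame,
                   constants: DiffusionConstants = DiffusionConstants(),
                   weighting: str = "unweighted") -> pd.DataFrame:
    """End-to-end gradient-method fluxes for tables of pits and measurements.

    Replicate gradient rows (same unit_id and date) are averaged before the
    kernel is applied.  Returns one row per unit_id × date with the flux and
    the snowpack quantities used.
    """
    summaries = summarize_pits_table(pits, constants, weighting)
    keep = ["unit_id", "site", "date", "year", "treatment", "phase",
            "soil_temperature_c"]
    keep = [c for c in keep if c in gradients.columns]
    grouped = gradients.groupby(["unit_id", "date"], as_index=False).agg(
        {**{c: "first" for c in keep if c not in ("unit_id", "date")},
         "co2_surface_ppm": "mean", "co2_subnivean_ppm": "mean",
         "snow_depth_m": "mean"}
    )
    merged = grouped.merge(summaries, on=["site", "date"], how="left", validate="m:1")
    missing = merged["mean_density"].isna()
    if missing.any():
        bad = merged.loc[missing, ["site", "date"]].drop_duplicates()
        raise InvalidMeasurementError(
            f"no snow pit summary for site/date combinations:\n{bad.to_string(index=False)}"
        )
    out_rows = []
    for r in merged.itertuples():
        meas = GradientMeasurement(
            unit_id=str(r.unit_id), site=str(r.site),
            co2_surface_ppm=r.co2_surface_ppm,
            co2_subnivean_ppm=r.co2_subnivean_ppm,
            snow_depth_m=r.snow_depth_m,
            soil_temperature_c=r.soil_temperature_c,
        )
        summ = SnowpackSummary(r.mean_density, r.theta, r.tau, r.mean_temperature_k)
        est = diffusive_flux(meas, summ, constants)
        row = {c: getattr(r, c) for c in keep}
        row["date"] = r.date
        row.update(
            flux_umol_m2_s=est.flux_umol_m2_s,
            delta_c_ppm=est.delta_c_ppm,
            theta=summ.porosity, tau=summ.tortuosity,
            mean_temp_k=summ.mean_temperature_k,
            qc_flag="negative_gradient" if est.negative_gradient else "ok",
        )
        out_rows.append(row)
    return pd.DataFrame(out_rows)
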