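"""Q10 temperature-response fitting with Monte Carlo prediction intervals.

The exponential Q10 model relates soil respiration to soil temperature:

    flux = A * B**((T + 5) / 10)

where ``A`` is the flux at the −5 °C anchor temperature and ``B`` is the Q10
factor, the multiplicative increase in flux per 10 °C of warming.  Fits are
made per winter by nonlinear least squares; year-to-year contrasts are drawn
at a common reference temperature with Monte Carlo confidence intervals
obtained by resampling the fitted parameter vector from its asymptotic
bivariate normal distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

_ANCHOR_C = -5.0  # temperature at which the model intercept A is defined


@dataclass(frozen=True)
class Q10Fit:
    """Fitted Q10 temperature-response model."""

    a_hat: float
    b_hat: float
    covariance: np.ndarray  # 2x2, order (A, B)
    n: int
    rss: float
    converged: bool
    n_excluded_nonpositive: int = 0


@dataclass(frozen=True)
class PredictionInterval:
    temperature_c: float
    point: float
    lower: float
    upper: float
    alpha: float
    n_draws: int
    seed: int


def _model(a: float, b: float, temp_c: np.ndarray) -> np.ndarray:
    return a * b ** ((temp_c - _ANCHOR_C) / 10.0)


def fit_q10(pairs: Iterable[tuple[float, float]],
            init: tuple[float, float] | None = None,
            cov_type: str = "hc3") -> Q10Fit:
    """Fit flux = A·B**((T+5)/10) to (soil temperature °C, flux) pairs.

    Non-positive fluxes (possible under the diffusion method when the
    gradient inverts) cannot be described by the exponential model and are
    excluded with a logged count.  Optimization runs on log-parameters so the
    positivity constraints A, B > 0 hold by construction; the reported
    covariance is for (A, B) from the Jacobian at the optimum.

    ``cov_type`` selects the parameter covariance: "hc3" (default), a
    leverage-corrected sandwich estimator that stays valid under the
    multiplicative (variance proportional to the mean) measurement error
    typical of field fluxes, or "iid" for the classical
    homoscedastic-residual covariance.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (temperature_c, flux) tuples")
    temp, flux = arr[:, 0], arr[:, 1]
    keep = flux > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("fit_q10: excluded %d non-positive flux value(s)", n_excluded)
    temp, flux = temp[keep], flux[keep]
    if len(flux) < 3:
        raise ValueError("need at least 3 positive-flux observations")
    if len(np.unique(temp)) < 2:
        raise ValueError("need at least 2 distinct temperatures")

    a0, b0 = init if init is not None else (float(np.median(flux)), 2.0)
    x0 = np.log([max(a0, 1e-12), max(b0, 1e-12)])

    def resid(logp: np.ndarray) -> np.ndarray:
        a, b = np.exp(logp)
        return _model(a, b, temp) - flux

    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    a_hat, b_hat = np.exp(sol.x)
    r = _model(a_hat, b_hat, temp) - flux
    rss = float(r @ r)
    n = len(flux)

    # Jacobian in (A, B) space for the asymptotic covariance
    expo = (temp - _ANCHOR_C) / 10.0
    jac = np.column_stack([b_hat ** expo, a_hat * expo * b_hat ** (expo - 1.0)])
    dof = max(n - 2, 1)
    try:
        jtj_inv = np.linalg.inv(jac.T @ jac)
        if cov_type == "iid":
            cov = (rss / dof) * jtj_inv
        elif cov_type == "hc3":
            lev = np.sum((jac @ jtj_inv) * jac, axis=1)
            w = r ** 2 / np.clip(1.0 - lev, 1e-8, None) ** 2
            cov = jtj_inv @ (jac.T @ (jac * w[:, None])) @ jtj_inv
        else:
            raise ValueError(f"unknown cov_type {cov_type!r}")
        converged = bool(sol.success)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        converged = False
    if converged and not np.all(np.isfinite(cov)):
        converged = False
    return Q10Fit(float(a_hat), float(b_hat), cov, n, rss, converged, n_excluded)


def predict_flux(fit: Q10Fit, temperature_c: float) -> float:
    """Point prediction A·B**((T+5)/10) at a given soil temperature."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    return float(_model(fit.a_hat, fit.b_hat, np.asarray(temperature_c, dtype=float)))


def mc_interval(fit: Q10Fit, temperature_c: float, alpha: float = 0.05,
                n_draws: int = 10_000, seed: int | None = None) -> PredictionInterval:
    """Monte Carlo confidence interval for the model prediction.

    Draws (A, B) vectors from the asymptotic bivariate normal at the optimum,
    evaluates the prediction for each draw and returns the central
    (alpha/2, 1 − alpha/2) percentile interval.  Deterministic for a fixed
    seed.  A covariance that is not positive semi-definite (degenerate fits)
    falls back to its diagonal with a warning.
    """
    if not fit.converged:
        raise ValueError("cannot build an interval from a non-converged fit")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    if seed is None:
        raise ValueError("seed is required for a reproducible interval")
    cov = np.array(fit.covariance, dtype=float)
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eig.min() < -1e-12 * max(eig.max(), 1.0):
        warnings.warn("parameter covariance not PSD; falling back to its diagonal")
        cov = np.diag(np.diag(cov))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal([fit.a_hat, fit.b_hat], cov, size=n_draws,
                                    method="eigh")
    a, b = draws[:, 0], draws[:, 1]
    valid = b > 0
    if not valid.all():
        warnings.warn(
            f"mc_interval: discarded {int((~valid).sum())} draw(s) with B <= 0"
        )
    preds = _model(a[valid], b[valid], np.asarray(temperature_c, dtype=float))
    lo, hi = np.percentile(preds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    point = predict_flux(fit, temperature_c)
    return PredictionInterval(float(temperature_c), point, float(lo), float(hi),
                              alpha, n_draws, seed)


def compare_years(fits: Mapping[object, Q10Fit], temperature_c: float,
                  alpha: float = 0.05, n_draws: int = 10_000,
                  seed: int | None = None) -> pd.DataFrame:
    """Per-year predictions at a common temperature with interval-overlap flags.

    Returns one row per pair of years with both intervals and a
    ``distinct`` flag set when the intervals do not overlap — a conservative
    screen for a year-to-year difference at the reference temperature.
    """
    if len(fits) < 2:
        raise ValueError("need at least two per-year fits to compare")
    if seed is None:
        raise ValueError("seed is required")
    intervals: dict[object, PredictionInterval] = {}
    for i, (year, fit) in enumerate(sorted(fits.items(), key=lambda kv: str(kv[0]))):
        intervals[year] = mc_interval(fit, temperature_c, alpha, n_draws,
                                      seed=seed + i)
    years = list(intervals)
    rows = []
    for i, y1 in enumerate(years):
        for y2 in years[i + 1:]:
            i1, i2 = intervals[y1], intervals[y2]
            distinct = i1.upper < i2.lower or i2.upper < i1.lower
            higher = None
            if distinct:
                higher = y1 if i1.point > i2.point else y2
            rows.append({
                "year_a": y1, "point_a": i1.point, "lower_a": i1.lower, "upper_a": i1.upper,
                "year_b": y2, "point_b": i2.point, "lower_b": i2.lower, "upper_b": i2.upper,
                "distinct": distinct, "higher": higher,
            })
    return pd.DataFrame(rows)


def fit_q10_by_group(fluxes: pd.DataFrame, group_by: str = "year",
                     temp_col: str = "soil_temperature_c",
                     flux_col: str = "flux_umol_m2_s") -> dict[object, Q10Fit]:
    """Convenience: one fit_q10 per level of a grouping column."""
    return {
        key: fit_q10(zip(grp[temp_col], grp[flux_col]))
        for key, grp in fluxes.groupby(group_by)
    }
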