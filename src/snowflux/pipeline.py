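"""End-to-end pipeline: flux -> Q10 -> ANCOVA -> incubation, from one config."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import read_table, write_table
from .snowpack_flux import DiffusionConstants, compute_fluxes
from .q10 import fit_q10_by_group, compare_years, mc_interval
from .treatment import fit_ancova, group_means
from .incubation import fit_respiration_lmm, fit_nutrient_regression, ANALYTES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, constants and seeds for a full pipeline run.

    Every stochastic stage (the Monte Carlo intervals) requires an explicit
    seed; a config without one is refused before execution starts.
    """

    pits_csv: str | None = None
    gradients_csv: str | None = None
    paired_plots_csv: str | None = None
    incubation_respiration_csv: str | None = None
    incubation_nutrients_csv: str | None = None
    out_dir: str = "snowflux_out"
    t0_k: float = 273.15
    barrier_r2: float = 0.90
    predict_at_c: float = -3.0
    alpha: float = 0.05
    mc_draws: int = 10_000
    mc_seed: int | None = None
    incubation_subset: str = "below_zero"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _validate(config: PipelineConfig) -> None:
    wants_q10 = config.gradients_csv is not None
    if wants_q10 and config.mc_seed is None:
        raise ValueError(
            "config refused: the Monte Carlo interval stage requires an "
            "explicit mc_seed")
    for name in ("pits_csv", "gradients_csv", "paired_plots_csv",
                 "incubation_respiration_csv", "incubation_nutrients_csv"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"config {name}: {p} does not exist")
    if config.gradients_csv is not None and config.pits_csv is None:
        raise ValueError("gradient fluxes need a snow-pit table (pits_csv)")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages, writing a JSON report plus CSV outputs.

    Any stage failure aborts with the stage name; outputs of completed
    stages are preserved on disk.
    """
    _validate(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    constants = DiffusionConstants(t0_k=config.t0_k)
    report: dict = {"software_version": __version__,
                    "config_hash": config.config_hash(),
                    "stages": {}}
    stage = "flux"
    try:
        if config.gradients_csv is not None:
            pits = read_table(config.pits_csv, "snow_pits")
            grads = read_table(config.gradients_csv, "gradients")
            fluxes = compute_fluxes(pits, grads, constants)
            write_table(fluxes, out_dir / "fluxes.csv")
            n_neg = int((fluxes["qc_flag"] == "negative_gradient").sum())
            if n_neg:
                logger.info("flux stage: %d negative-gradient flux(es) flagged", n_neg)
            report["stages"]["flux"] = {
                "n": len(fluxes), "negative_gradients": n_neg,
                "mean_flux": float(fluxes["flux_umol_m2_s"].mean()),
                "out": str(out_dir / "fluxes.csv"),
            }

            stage = "q10"
            fits = fit_q10_by_group(fluxes, "year")
            q10_rows = []
            for year, fit in sorted(fits.items()):
                iv = mc_interval(fit, config.predict_at_c, config.alpha,
                                 config.mc_draws, seed=config.mc_seed)
                if fit.n_excluded_nonpositive:
                    logger.info("q10 %s: excluded %d non-positive flux(es)",
                                year, fit.n_excluded_nonpositive)
                q10_rows.append({
                    "year": year, "a_hat": fit.a_hat, "b_hat": fit.b_hat,
                    "n": fit.n, "converged": fit.converged,
                    "predict_at_c": config.predict_at_c, "point": iv.point,
                    "lower": iv.lower, "upper": iv.upper, "seed": config.mc_seed,
                })
            q10_table = pd.DataFrame(q10_rows)
            write_table(q10_table, out_dir / "q10_fits.csv")
            section = {"fits": q10_rows, "mc_seed": config.mc_seed}
            if len(fits) >= 2:
                comp = compare_years(fits, config.predict_at_c, config.alpha,
                                     config.mc_draws, seed=config.mc_seed)
                section["comparisons"] = comp.to_dict("records")
            report["stages"]["q10"] = section

        stage = "ancova"
        if config.paired_plots_csv is not None:
            plots = read_table(config.paired_plots_csv, "paired_plots")
            res = fit_ancova(plots)
            means = group_means(plots)
            report["stages"]["ancova"] = {
                "n": res.n,
                "treatment_f": res.treatment_f, "treatment_df": res.treatment_df,
                "treatment_p": res.treatment_p,
                "effect_ratio": res.effect_ratio,
                "screening": res.screening_log,
                "coefficients": res.coefficients.to_dict("index"),
                "group_means": means.to_dict("records"),
            }

        stage = "incubation"
        if config.incubation_respiration_csv is not None:
            resp = read_table(config.incubation_respiration_csv,
                              "incubation_respiration")
            lmm = fit_respiration_lmm(resp, config.incubation_subset)
            report["stages"]["incubation"] = {
                "subset": lmm.subset, "n_obs": lmm.n_obs, "n_jars": lmm.n_jars,
                "coefficients": lmm.coefficients.to_dict("index"),
                "random_intercept_var": lmm.random_intercept_var,
                "residual_var": lmm.residual_var,
                "r2_pred_obs": lmm.r2_pred_obs,
                "obs_on_pred_slope": lmm.obs_on_pred_slope,
                "obs_on_pred_intercept": lmm.obs_on_pred_intercept,
                "three_way_test": lmm.three_way_test,
                "fallback_fixed_effects_only": lmm.fallback_fixed_effects_only,
            }
        if config.incubation_nutrients_csv is not None:
            nutr = read_table(config.incubation_nutrients_csv,
                              "incubation_nutrients")
            nut_section = {}
            for analyte in sorted(nutr["analyte"].unique()):
                r = fit_nutrient_regression(nutr, analyte)
                nut_section[analyte] = {
                    "r_squared": r.r_squared, "f": r.f_statistic, "df": r.f_df,
                    "p": r.f_pvalue, "log_scale": r.log_scale,
                    "coefficients": r.coefficients.to_dict("index"),
                }
            report["stages"]["nutrients"] = nut_section
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
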