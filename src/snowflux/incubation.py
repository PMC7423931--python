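"""Laboratory incubation analyses: respiration mixed model and nutrient regressions.

Organic-soil microcosms incubated for 90 days across sub-zero to above-zero
temperatures, crossed with labile-C (cellobiose) additions, test whether
respiration is substrate-limited.  Log respiration is modelled with a linear
mixed-effects model (random intercept per jar for the repeated measures):

    ln(R)_ij = α + β_T·T_ij + β_C·C_ij + β_d·date_ij
               + β_TC·(T×C)_ij + β_Td·(T×date)_ij + u_i + ε_ij

Endpoint nutrient availability (NO3-N, NH4-N, total free primary amines,
PO4-P) is modelled per analyte by multiple regression on temperature, C
addition and their interaction; NH4-N is fitted on the natural-log scale.
Below-detection observations are substituted with fixed floor values before
modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

RESPIRATION_DETECTION_FLOOR = 0.01  # µg C / g dry soil / day
NH4_DETECTION_FLOOR = 0.5  # µg N / g dry soil

DESIGN_TEMPERATURES = (-10.0, -6.0, -2.0, 2.0, 6.0)
BELOW_ZERO_TEMPERATURES = (-10.0, -6.0, -2.0)
DESIGN_C_ADDITIONS = (0.0, 0.2, 0.4, 2.0)  # mg C / g dry soil
ANALYTES = ("NO3_N", "NH4_N", "TFPA", "PO4_P")

_FIXED_TERMS = ("intercept", "temperature_c", "c_addition", "date_c",
                "temperature_c:c_addition", "temperature_c:date_c")
_BETWEEN_TERMS = {"intercept", "temperature_c", "c_addition",
                  "temperature_c:c_addition"}


@dataclass(frozen=True)
class LmmResult:
    """Random-intercept mixed-model fit of log respiration."""

    coefficients: pd.DataFrame  # estimate, std_error, t, df, p per fixed term
    random_intercept_var: float
    residual_var: float
    r2_pred_obs: float          # back-transformed predicted vs observed
    obs_on_pred_slope: float
    obs_on_pred_intercept: float
    subset: str
    n_obs: int
    n_jars: int
    date_center: float          # julian-date centering constant
    three_way_test: dict
    converged: bool
    fallback_fixed_effects_only: bool = False


@dataclass(frozen=True)
class NutrientRegressionResult:
    analyte: str
    coefficients: pd.DataFrame
    r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    f_pvalue: float
    log_scale: bool
    n: int
    _results: object = field(repr=False, compare=False, default=None)


def substitute_detection_limits(records: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Replace below-detection observations with the assay floor.

    ``kind='respiration'`` sets flagged respiration to 0.01 µg C/g/day;
    ``kind='nh4'`` sets flagged NH4-N concentrations to 0.5 µg N/g dry soil.
    Idempotent; never decreases a retained value below its floor; the number
    of substitutions is logged.
    """
    out = records.copy()
    if "below_detection" not in out.columns:
        return out
    mask = out["below_detection"].astype(bool)
    if kind == "respiration":
        col, floor = "respiration", RESPIRATION_DETECTION_FLOOR
    elif kind == "nh4":
        col, floor = "concentration", NH4_DETECTION_FLOOR
        if "analyte" in out.columns:
            mask = mask & (out["analyte"] == "NH4_N")
    else:
        raise ValueError(f"unknown detection-limit kind {kind!r}")
    n = int(mask.sum())
    if n:
        logger.info("substituted %d below-detection %s value(s) with %s", n, kind, floor)
    out.loc[mask, col] = floor
    return out


def _containment_df(n_obs: int, n_jars: int) -> dict[str, int]:
    """Approximate containment denominator df per fixed term.

    Terms constant within a jar (temperature, C addition and their
    interaction) are tested against between-jar variation; terms varying
    within jars (date and its interaction) against within-jar variation.
    """
    n_between = len(_BETWEEN_TERMS) - 1  # excluding intercept
    n_within = len(_FIXED_TERMS) - len(_BETWEEN_TERMS)
    df_between = max(n_jars - n_between - 1, 1)
    df_within = max(n_obs - n_jars - n_within, 1)
    return {t: (df_between if t in _BETWEEN_TERMS else df_within)
            for t in _FIXED_TERMS}


def fit_respiration_lmm(records: pd.DataFrame, subset: str = "below_zero") -> LmmResult:
    """Fit the log-respiration mixed model with a per-jar random intercept.

    ``subset`` selects "all" incubation temperatures or "below_zero"
    (temperatures < 0 °C, matching field-relevant winter soil conditions).
    Julian date is centered at the subset mean.  The three-way
    temperature×C×date interaction is fitted (ML) and its Wald test logged,
    then excluded from the reported model, which is estimated by REML.
    A singular random-effects structure falls back to a fixed-effects-only
    OLS fit, clearly flagged.
    """
    df = substitute_detection_limits(records, "respiration")
    if subset == "below_zero":
        df = df[df["temperature_c"] < 0].copy()
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'below_zero'")
    if df.empty:
        raise ValueError("no observations in the requested subset")
    counts = df.groupby("jar_id").size()
    if (counts < 2).any():
        raise ValueError("every jar needs >= 2 observations for the random intercept")
    if (df["respiration"] <= 0).any():
        raise ValueError("non-positive respiration after substitution")

    date_center = float(df["julian_date"].mean())
    df = df.assign(ln_resp=np.log(df["respiration"]),
                   date_c=df["julian_date"] - date_center)

    formula = "ln_resp ~ temperature_c * c_addition + temperature_c * date_c"
    three_formula = formula + " + temperature_c:c_addition:date_c"

    # three-way interaction screened on the ML fit (fixed-effects comparison)
    three_way: dict = {"term": "temperature_c:c_addition:date_c"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            m3 = smf.mixedlm(three_formula, df, groups=df["jar_id"]).fit(reml=False)
            est = float(m3.fe_params["temperature_c:c_addition:date_c"])
            se = float(m3.bse_fe["temperature_c:c_addition:date_c"])
            t3 = est / se
            dfw = max(len(df) - df["jar_id"].nunique() - 3, 1)
            three_way.update(estimate=est, t=t3, df=dfw,
                             p=float(2 * stats.t.sf(abs(t3), dfw)), excluded=True)
        except Exception as exc:  # pragma: no cover - degenerate designs
            three_way.update(error=str(exc), excluded=True)

    fallback = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["jar_id"])
        try:
            res = model.fit(reml=True)
            if not res.converged:
                res = model.fit(reml=True, method="lbfgs")
            converged = bool(res.converged)
        except Exception:
            converged = False
            res = None
    if res is None or not np.all(np.isfinite(res.bse_fe)):
        fallback = True

    if not fallback:
        fe = res.fe_params
        bse = res.bse_fe
        re_var = float(res.cov_re.iloc[0, 0])
        resid_var = float(res.scale)
        fitted = np.asarray(res.fittedvalues)  # includes the random intercepts
    else:
        logger.warning("singular random-effects structure; fixed-effects-only fallback")
        ols = smf.ols(formula, df).fit()
        fe, bse = ols.params, ols.bse
        re_var, resid_var = 0.0, float(ols.mse_resid)
        fitted = np.asarray(ols.fittedvalues)
        converged = True

    names = {"Intercept": "intercept"}
    terms = [names.get(t, t) for t in fe.index]
    dfs = _containment_df(len(df), df["jar_id"].nunique())
    tvals = np.asarray(fe) / np.asarray(bse)
    term_df = np.array([dfs.get(t, len(df) - len(terms)) for t in terms])
    pvals = 2 * stats.t.sf(np.abs(tvals), term_df)
    coef = pd.DataFrame({"estimate": np.asarray(fe), "std_error": np.asarray(bse),
                         "t": tvals, "df": term_df, "p": pvals}, index=terms)

    obs = np.exp(df["ln_resp"].to_numpy())
    pred = np.exp(fitted)
    r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
    slope, intercept = np.polyfit(pred, obs, 1)

    return LmmResult(
        coefficients=coef, random_intercept_var=re_var, residual_var=resid_var,
        r2_pred_obs=r2, obs_on_pred_slope=float(slope),
        obs_on_pred_intercept=float(intercept), subset=subset,
        n_obs=len(df), n_jars=df["jar_id"].nunique(), date_center=date_center,
        three_way_test=three_way, converged=converged,
        fallback_fixed_effects_only=fallback,
    )


def fit_nutrient_regression(records: pd.DataFrame, analyte: str,
                            log_scale: bool | None = None) -> NutrientRegressionResult:
    """Endpoint nutrient availability ~ temperature * C addition.

    NH4-N is fitted on the natural-log scale (after detection-limit
    substitution); other analytes on the raw scale unless ``log_scale``
    overrides.  Temperature and C addition enter as continuous covariates.
    """
    if analyte not in set(records.get("analyte", pd.Series(dtype=object))):
        raise ValueError(f"analyte {analyte!r} not present in records")
    df = records[records["analyte"] == analyte].copy()
    if analyte == "NH4_N":
        df = substitute_detection_limits(df, "nh4")
    cells = df[["temperature_c", "c_addition"]].drop_duplicates()
    if len(cells) < 3:
        raise ValueError("need >= 3 distinct (temperature, C addition) cells")
    if log_scale is None:
        log_scale = analyte == "NH4_N"
    if log_scale:
        if (df["concentration"] <= 0).any():
            raise ValueError("non-positive concentrations under a log-scale fit")
        df["y"] = np.log(df["concentration"])
    else:
        df["y"] = df["concentration"]
    res = smf.ols("y ~ temperature_c * c_addition", df).fit()
    names = {"Intercept": "intercept"}
    coef = pd.DataFrame({"estimate": res.params, "std_error": res.bse,
                         "t": res.tvalues, "p": res.pvalues})
    coef.index = [names.get(i, i) for i in coef.index]
    return NutrientRegressionResult(
        analyte=analyte, coefficients=coef, r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue), log_scale=bool(log_scale), n=int(res.nobs),
        _results=res,
    )


def _design_row(term_names: list[str], temp: float, c: float, date_c: float = 0.0
                ) -> np.ndarray:
    vals = {"Intercept": 1.0, "intercept": 1.0, "temperature_c": temp,
            "c_addition": c, "date_c": date_c,
            "temperature_c:c_addition": temp * c,
            "temperature_c:date_c": temp * date_c}
    return np.array([vals[t] for t in term_names])


def interaction_effect_table(result, temperatures=None, c_additions=None,
                             date_c: float = 0.0) -> pd.DataFrame:
    """Prediction grid over the design cells with standard errors.

    Accepts a NutrientRegressionResult or an LmmResult; log-scale fits are
    back-transformed by exponentiating the point and the point ± 1 S.E.
    computed on the log scale.  For the mixed model, predictions are
    population-level (random intercept at zero) at centered date ``date_c``.
    """
    if c_additions is None:
        c_additions = DESIGN_C_ADDITIONS
    rows = []
    if isinstance(result, NutrientRegressionResult):
        if temperatures is None:
            temperatures = BELOW_ZERO_TEMPERATURES
        res = result._results
        grid = pd.DataFrame([(t, c) for t in temperatures for c in c_additions],
                            columns=["temperature_c", "c_addition"])
        pred = res.get_prediction(grid)
        point = pred.predicted_mean
        se = pred.se_mean
        log_scale = result.log_scale
        for (t, c), m, s in zip(grid.itertuples(index=False), point, se):
            rows.append(_grid_row(t, c, m, s, log_scale))
    elif isinstance(result, LmmResult):
        if temperatures is None:
            temperatures = (BELOW_ZERO_TEMPERATURES if result.subset == "below_zero"
                            else DESIGN_TEMPERATURES)
        terms = list(result.coefficients.index)
        beta = result.coefficients["estimate"].to_numpy()
        se_beta = result.coefficients["std_error"].to_numpy()
        for t in temperatures:
            for c in c_additions:
                x = _design_row(terms, t, c, date_c)
                m = float(x @ beta)
                # conservative SE ignoring off-diagonal parameter covariance
                s = float(np.sqrt(np.sum((x * se_beta) ** 2)))
                rows.append(_grid_row(t, c, m, s, log_scale=True))
    else:
        raise TypeError("result must be a NutrientRegressionResult or LmmResult")
    return pd.DataFrame(rows)


def _grid_row(t: float, c: float, m: float, s: float, log_scale: bool) -> dict:
    if log_scale:
        return {"temperature_c": t, "c_addition": c, "prediction": float(np.exp(m)),
                "lower_se": float(np.exp(m - s)), "upper_se": float(np.exp(m + s))}
    return {"temperature_c": t, "c_addition": c, "prediction": float(m),
            "lower_se": float(m - s), "upper_se": float(m + s)}
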