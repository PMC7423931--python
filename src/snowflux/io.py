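"""CSV schema validation and readers/writers for the pipeline's tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Structured CSV validation failure with row-level messages."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        msg = f"{path}: {len(problems)} validation problem(s):\n  " + "\n  ".join(
            problems[:20])
        if len(problems) > 20:
            msg += f"\n  ... and {len(problems) - 20} more"
        super().__init__(msg)


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # "float" | "int" | "str" | "bool"
    check: Callable[[float], bool] | None = None
    constraint: str = ""


SCHEMAS: dict[str, list[ColumnSpec]] = {
    "snow_pits": [
        ColumnSpec("pit_id", "str"),
        ColumnSpec("site", "str"),
        ColumnSpec("date", "str"),
        ColumnSpec("top_depth_cm", "float", lambda v: v >= 0, ">= 0"),
        ColumnSpec("density_g_per_l", "float", lambda v: 0 < v <= 973,
                   "in (0, 973] g/L (973 g/L is pure ice)"),
        ColumnSpec("temperature_c", "float", lambda v: -60 <= v <= 5,
                   "plausible snow temperature"),
    ],
    "gradients": [
        ColumnSpec("unit_id", "str"),
        ColumnSpec("site", "str"),
        ColumnSpec("date", "str"),
        ColumnSpec("year", "int"),
        ColumnSpec("treatment", "str"),
        ColumnSpec("phase", "str"),
        ColumnSpec("co2_surface_ppm", "float", lambda v: v >= 0, ">= 0 ppm"),
        ColumnSpec("co2_subnivean_ppm", "float", lambda v: v >= 0, ">= 0 ppm"),
        ColumnSpec("snow_depth_m", "float", lambda v: v > 0, "> 0 m"),
        ColumnSpec("soil_temperature_c", "float", lambda v: -60 <= v <= 30,
                   "plausible soil temperature"),
    ],
    "paired_plots": [
        ColumnSpec("plot_id", "str"),
        ColumnSpec("site", "str"),
        ColumnSpec("treatment", "str"),
        ColumnSpec("flux_pre", "float", lambda v: v > 0, "> 0 (log transform)"),
        ColumnSpec("flux_post", "float", lambda v: v > 0, "> 0 (log transform)"),
        ColumnSpec("snow_depth_pre_m", "float", lambda v: v > 0, "> 0 m"),
    ],
    "incubation_respiration": [
        ColumnSpec("jar_id", "str"),
        ColumnSpec("temperature_c", "float"),
        ColumnSpec("c_addition", "float", lambda v: v >= 0, ">= 0 mg C/g"),
        ColumnSpec("julian_date", "int"),
        ColumnSpec("respiration", "float", lambda v: v >= 0, ">= 0 ug C/g/day"),
        ColumnSpec("below_detection", "bool"),
    ],
    "incubation_nutrients": [
        ColumnSpec("jar_id", "str"),
        ColumnSpec("temperature_c", "float"),
        ColumnSpec("c_addition", "float", lambda v: v >= 0, ">= 0 mg C/g"),
        ColumnSpec("analyte", "str"),
        ColumnSpec("concentration", "float", lambda v: v >= 0, ">= 0"),
        ColumnSpec("below_detection", "bool"),
    ],
    "fluxes": [
        ColumnSpec("unit_id", "str"),
        ColumnSpec("date", "str"),
        ColumnSpec("flux_umol_m2_s", "float"),
        ColumnSpec("theta", "float", lambda v: 0 <= v <= 1, "in [0, 1]"),
        ColumnSpec("tau", "float", lambda v: 0 <= v <= 1, "in [0, 1]"),
        ColumnSpec("mean_temp_k", "float", lambda v: v > 0, "> 0 K"),
        ColumnSpec("qc_flag", "str"),
    ],
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a pipeline CSV against a documented schema.

    Raises SchemaError listing every missing column, non-coercible cell and
    out-of-range value with its (1-based, header-excluded) row number.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    problems: list[str] = []
    schema = SCHEMAS[schema_name]
    for col in schema:
        if col.name not in df.columns:
            problems.append(f"missing column {col.name!r}")
    if problems:
        raise SchemaError(path, problems)
    extra_order = [c.name for c in schema] + [
        c for c in df.columns if c not in {s.name for s in schema}]
    df = df[extra_order]
    for col in schema:
        series = df[col.name]
        if col.dtype in ("float", "int"):
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            for idx in df.index[bad]:
                problems.append(
                    f"row {idx + 1}: column {col.name!r} value "
                    f"{series[idx]!r} is not numeric")
            na = coerced.isna() & series.isna()
            for idx in df.index[na]:
                problems.append(f"row {idx + 1}: column {col.name!r} is empty")
            df[col.name] = coerced
            if col.check is not None:
                ok = coerced.map(lambda v: bool(col.check(v)) if np.isfinite(v) else True)
                for idx in df.index[~ok]:
                    problems.append(
                        f"row {idx + 1}: column {col.name!r} value "
                        f"{coerced[idx]} violates constraint: {col.constraint}")
        elif col.dtype == "bool":
            df[col.name] = series.map(
                lambda v: str(v).strip().lower() in ("true", "1", "yes"))
        else:
            df[col.name] = series.astype(str)
    if problems:
        raise SchemaError(path, problems)
    logger.info("read %d validated rows from %s (%s)", len(df), path, schema_name)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV at 12 significant digits so numeric round trips are lossless."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
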