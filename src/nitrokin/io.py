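"""Readers and writers for the package's CSV/JSON schemas.

Dialect: comma-separated, dot decimal, UTF-8, mandatory header;
``#``-prefixed lines carry ``key: value`` metadata. Schemas are
documented with examples in docs/formats.md. All writers are
deterministic: fixed column order and fixed decimal formatting, so the
same inputs always produce byte-identical files.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET
from .errors import SchemaError
from .intrinsic import IntrinsicParams
from .kinetics import Condition, ConversionSeries
from .nitronium import NitroniumTable

__all__ = [
    "read_conversion_series",
    "write_conversion_series",
    "read_rate_table",
    "write_rate_table",
    "read_nitronium_csv",
    "write_nitronium_csv",
    "write_report",
]

_SERIES_META_KEYS = ("temperature_C", "w_h2so4_percent", "c_io0_M", "c_hno3_0_M")


def _parse_metadata(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_conversion_series(path, time_unit: str = "s",
                           metadata: dict | None = None) -> ConversionSeries:
    """Read one conversion-time series.

    Columns: ``time_s`` (or ``time_min`` with ``time_unit='min'``) and
    ``x_io``. Condition metadata comes from ``#`` header lines
    (``# temperature_C: 30`` etc.) or the ``metadata`` override.
    Violations are reported with the offending data row number.
    """
    if time_unit not in ("s", "min"):
        raise SchemaError(f"time_unit must be 's' or 'min', got {time_unit!r}")
    meta = _parse_metadata(path)
    if metadata:
        meta.update(metadata)
    missing = [k for k in _SERIES_META_KEYS if k not in meta]
    if missing:
        raise SchemaError(f"{path}: missing condition metadata {missing}")
    frame = pd.read_csv(path, comment="#")
    time_col = "time_s" if time_unit == "s" else "time_min"
    for col in (time_col, "x_io"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    times = frame[time_col].to_numpy(float)
    x = frame["x_io"].to_numpy(float)
    for i, xi in enumerate(x, start=1):
        if not (0 <= xi < 1):
            raise SchemaError(f"{path}: row {i}, column x_io: {xi} outside [0, 1)")
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise SchemaError(
                f"{path}: row {i + 1}, column {time_col}: times not strictly increasing"
            )
    if time_unit == "min":
        times = times * 60.0
    cond = Condition(
        temperature=float(meta["temperature_C"]) + CELSIUS_OFFSET,
        w_h2so4=float(meta["w_h2so4_percent"]),
        c_io0=float(meta["c_io0_M"]),
        c_hno3_0=float(meta["c_hno3_0_M"]),
    )
    extra = {k: v for k, v in meta.items() if k not in _SERIES_META_KEYS}
    return ConversionSeries(times=times, conversions=x, condition=cond, metadata=extra)


def write_conversion_series(series: ConversionSeries, path) -> None:
    cond = series.condition
    buf = _io.StringIO()
    buf.write(f"# temperature_C: {cond.temperature - CELSIUS_OFFSET:.6g}\n")
    buf.write(f"# w_h2so4_percent: {cond.w_h2so4:.6g}\n")
    buf.write(f"# c_io0_M: {cond.c_io0:.6g}\n")
    buf.write(f"# c_hno3_0_M: {cond.c_hno3_0:.6g}\n")
    for key, value in sorted(series.metadata.items()):
        buf.write(f"# {key}: {value}\n")
    buf.write("time_s,x_io\n")
    for t, x in zip(series.times, series.conversions):
        buf.write(f"{t:.10g},{x:.10g}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


_RATE_COLS = ["temperature_C", "w_h2so4_percent", "k_L_per_mol_s", "r2", "intercept"]


def read_rate_table(path) -> pd.DataFrame:
    """Apparent-rate table CSV -> frame with kelvin temperatures
    (columns temperature_K, w_h2so4, k, r2, intercept)."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _RATE_COLS[:3] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = pd.DataFrame(
        {
            "temperature_K": frame["temperature_C"].astype(float) + CELSIUS_OFFSET,
            "w_h2so4": frame["w_h2so4_percent"].astype(float),
            "k": frame["k_L_per_mol_s"].astype(float),
        }
    )
    for i, k in enumerate(out["k"], start=1):
        if not (np.isfinite(k) and k > 0):
            raise SchemaError(f"{path}: row {i}, column k_L_per_mol_s: {k} must be > 0")
    out["r2"] = frame["r2"].astype(float) if "r2" in frame else np.nan
    out["intercept"] = frame["intercept"].astype(float) if "intercept" in frame else np.nan
    return out


def write_rate_table(table: pd.DataFrame, path) -> None:
    """Write the apparent-rate table. k is formatted to 4 significant
    figures (internal values stay plain SI; any x10^2-style display
    convention is a presentation concern only)."""
    buf = _io.StringIO()
    buf.write(",".join(_RATE_COLS) + "\n")
    frame = table.sort_values(["temperature_K", "w_h2so4"])
    for _, row in frame.iterrows():
        buf.write(
            f"{row['temperature_K'] - CELSIUS_OFFSET:.6g},"
            f"{row['w_h2so4']:.6g},"
            f"{row['k']:.4g},"
            f"{row.get('r2', float('nan')):.6f},"
            f"{row.get('intercept', float('nan')):.6f}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_nitronium_csv(path) -> NitroniumTable:
    """Nitronium table CSV (temperature_C, w_h2so4_percent, lg_ratio)."""
    frame = pd.read_csv(path, comment="#")
    required = ["temperature_C", "w_h2so4_percent", "lg_ratio"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    data = pd.DataFrame(
        {
            "temperature_K": frame["temperature_C"].astype(float) + CELSIUS_OFFSET,
            "w_h2so4": frame["w_h2so4_percent"].astype(float),
            "lg_ratio": frame["lg_ratio"].astype(float),
        }
    )
    return NitroniumTable(data=data)


def write_nitronium_csv(table: NitroniumTable, path) -> None:
    buf = _io.StringIO()
    buf.write("temperature_C,w_h2so4_percent,lg_ratio\n")
    frame = table.data.sort_values(["temperature_K", "w_h2so4"])
    for _, row in frame.iterrows():
        buf.write(
            f"{row['temperature_K'] - CELSIUS_OFFSET:.6g},"
            f"{row['w_h2so4']:.6g},{row['lg_ratio']:.10g}\n"
        )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_report(params: IntrinsicParams, path_prefix) -> tuple[Path, Path]:
    """Write the intrinsic-kinetics report: a per-temperature CSV
    (lg k0 to 4 decimals) and a JSON mirror with the Arrhenius block
    (Ea in kJ/mol to 2 decimals in the CSV summary line)."""
    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    buf = _io.StringIO()
    buf.write("temperature_C,n,lg_k0,r2\n")
    for _, row in params.rows.sort_values("temperature_K").iterrows():
        buf.write(
            f"{row['temperature_K'] - CELSIUS_OFFSET:.6g},"
            f"{row['n']:.4f},{row['lg_k0']:.4f},{row['r2']:.6f}\n"
        )
    buf.write(f"# ea_kJ_per_mol: {params.ea / 1000.0:.2f}\n")
    buf.write(f"# ln_a: {params.ln_a:.2f}\n")
    csv_path.write_text(buf.getvalue(), encoding="utf-8")
    json_path.write_text(
        json.dumps(params.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return csv_path, json_path
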