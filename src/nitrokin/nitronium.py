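"""Empirical nitronium-fraction model.

The nitronium ion NO2+ is the actual electrophile in mixed-acid
nitration; its abundance relative to total nitric acid is summarized by
lg(c_NO2+/c_HNO3). Literature tabulations give this quantity at discrete
temperatures and sulfuric-acid strengths. The model here mirrors the
standard two-stage graphical construction:

stage 1
    within each temperature group, ordinary least squares of lg_ratio on
    the H2SO4 mass fraction w;
stage 2
    the stage-1 lines are sampled on a grid of w values and, per grid
    point, lg_ratio is regressed on 1/T.

Evaluation interpolates linearly between the bracketing grid lines,
giving a surface affine in w between nodes and affine in 1/T
everywhere. Queries outside the calibration ranges are answered but
flagged as extrapolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .errors import FitError, SchemaError
from .kinetics import r_squared

__all__ = [
    "NitroniumTable",
    "NitroniumModel",
    "LinearFit",
    "LgRatio",
    "fit_stage1",
    "fit_stage2",
    "fit_nitronium",
]


@dataclass(frozen=True)
class LinearFit:
    """One ordinary-least-squares line y = slope*x + intercept."""

    slope: float
    intercept: float
    r2: float
    x_min: float
    x_max: float
    n_points: int

    def __call__(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0:
        raise FitError("regressor is constant; line is underdetermined")
    res = linregress(x, y)
    fitted = res.slope * x + res.intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else r_squared(y, fitted)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        x_min=float(x.min()),
        x_max=float(x.max()),
        n_points=len(x),
    )


@dataclass(frozen=True)
class NitroniumTable:
    """Literature (or synthetic) observations of lg(c_NO2+/c_HNO3).

    ``data`` columns: ``temperature_K``, ``w_h2so4``, ``lg_ratio``.
    At least two distinct mass fractions per temperature and at least
    two distinct temperatures are required for the two-stage fit.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"temperature_K", "w_h2so4", "lg_ratio"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"nitronium table missing columns: {sorted(missing)}")
        d = self.data
        if not np.isfinite(d[list(required)].to_numpy(float)).all():
            raise SchemaError("nitronium table contains non-finite values")
        if (d["temperature_K"] <= 0).any() or (d["w_h2so4"] <= 0).any():
            raise SchemaError("temperatures and mass fractions must be positive")
        if d["temperature_K"].nunique() < 2:
            raise SchemaError("need at least 2 distinct temperatures")

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.data["temperature_K"].unique())


class LgRatio(NamedTuple):
    """A lg(c_NO2+/c_HNO3) prediction with its extrapolation status."""

    value: float
    extrapolated: bool


def fit_stage1(table: NitroniumTable) -> dict[float, LinearFit]:
    """Per-temperature OLS of lg_ratio on mass fraction w."""
    fits: dict[float, LinearFit] = {}
    for temp, grp in table.data.groupby("temperature_K"):
        if grp["w_h2so4"].nunique() < 2:
            raise FitError(
                f"temperature group {temp} K has fewer than 2 distinct "
                "mass fractions; stage-1 line underdetermined"
            )
        fits[float(temp)] = _ols(grp["w_h2so4"].to_numpy(), grp["lg_ratio"].to_numpy())
    return fits


def fit_stage2(
    stage1: dict[float, LinearFit], w_grid: Sequence[float]
) -> dict[float, LinearFit]:
    """Per-grid-w OLS of stage-1 line values on 1/T."""
    if len(stage1) < 2:
        raise FitError("stage-2 fit needs stage-1 lines at >= 2 temperatures")
    w_grid = list(w_grid)
    if not w_grid:
        raise ValueError("w grid is empty")
    temps = np.array(sorted(stage1), float)
    inv_t = 1.0 / temps
    fits: dict[float, LinearFit] = {}
    for w in w_grid:
        y = np.array([stage1[t](w) for t in temps], float)
        fits[float(w)] = _ols(inv_t, y)
    return fits


@dataclass
class NitroniumModel:
    """Fitted two-stage surface lg(c_NO2+/c_HNO3)(w, T)."""

    stage1: dict[float, LinearFit]
    stage2: dict[float, LinearFit]
    w_range: tuple[float, float]
    t_range: tuple[float, float]
    w_grid: list[float] = field(init=False)

    def __post_init__(self):
        self.w_grid = sorted(self.stage2)
        if len(self.w_grid) < 1:
            raise FitError("nitronium model has an empty stage-2 grid")

    def lg_ratio(self, w: float, temperature: float) -> LgRatio:
        """Evaluate the surface at mass fraction ``w`` (percent) and
        ``temperature`` (kelvin); flags queries outside calibration."""
        w = float(w)
        t = float(temperature)
        if t <= 0:
            raise ValueError("temperature must be positive kelvin")
        grid = self.w_grid
        if len(grid) == 1:
            value = float(self.stage2[grid[0]](1.0 / t))
        else:
            # bracketing grid lines; end segments extend linearly outside
            j = int(np.clip(np.searchsorted(grid, w), 1, len(grid) - 1))
            w0, w1 = grid[j - 1], grid[j]
            y0 = float(self.stage2[w0](1.0 / t))
            y1 = float(self.stage2[w1](1.0 / t))
            value = y0 + (y1 - y0) * (w - w0) / (w1 - w0)
        extrapolated = not (
            self.w_range[0] - 1e-12 <= w <= self.w_range[1] + 1e-12
            and self.t_range[0] - 1e-12 <= t <= self.t_range[1] + 1e-12
        )
        return LgRatio(value=value, extrapolated=extrapolated)

    def __call__(self, w: float, temperature: float) -> float:
        return self.lg_ratio(w, temperature).value

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def fits(d):
            return {
                repr(k): {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r2": f.r2,
                    "x_min": f.x_min,
                    "x_max": f.x_max,
                    "n_points": f.n_points,
                }
                for k, f in d.items()
            }

        return {
            "stage1": fits(self.stage1),
            "stage2": fits(self.stage2),
            "w_range": list(self.w_range),
            "t_range": list(self.t_range),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "NitroniumModel":
        def fits(d):
            return {float(k): LinearFit(**v) for k, v in d.items()}

        return cls(
            stage1=fits(doc["stage1"]),
            stage2=fits(doc["stage2"]),
            w_range=tuple(doc["w_range"]),
            t_range=tuple(doc["t_range"]),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "NitroniumModel":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls.from_dict(doc)


def fit_nitronium(
    table: NitroniumTable, w_grid: Sequence[float] | None = None
) -> NitroniumModel:
    """Run both stages. Default grid: 1-point steps across the observed
    mass-fraction span (the discrete-curves construction of the source
    figures, made continuous by interpolation between grid lines)."""
    stage1 = fit_stage1(table)
    w = table.data["w_h2so4"].to_numpy(float)
    w_min, w_max = float(w.min()), float(w.max())
    if w_grid is None:
        w_grid = list(np.arange(np.ceil(w_min), np.floor(w_max) + 0.5, 1.0))
        if not w_grid:
            w_grid = [w_min, w_max]
        else:
            # keep exact span ends so grid covers the calibration range
            if w_grid[0] > w_min:
                w_grid.insert(0, w_min)
            if w_grid[-1] < w_max:
                w_grid.append(w_max)
    stage2 = fit_stage2(stage1, w_grid)
    temps = table.temperatures
    return NitroniumModel(
        stage1=stage1,
        stage2=stage2,
        w_range=(w_min, w_max),
        t_range=(float(temps.min()), float(temps.max())),
    )
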