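"""Sulfuric-acid medium properties.

Converts between H2SO4 mass fraction and molarity through a bundled
density lookup, and evaluates the Marziano-type activity-coefficient
function Mc — the empirical medium-acidity descriptor that links the
apparent nitration rate constant to the strength of the sulfuric acid.

Sign convention: the calibration polynomial is published for -Mc; every
public function here traffics in Mc itself, which is negative over the
molarity range of interest and decreases (grows more negative) with acid
strength.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import (
    CELSIUS_OFFSET,
    M_H2SO4,
    MC_CALIBRATION_RANGE,
    MC_POLY_COEFFS,
    MC_TEMP_A,
    MC_TEMP_B,
)
from .errors import RangeError

__all__ = [
    "AcidMedium",
    "load_density_table",
    "mass_fraction_to_molarity",
    "molarity_to_mass_fraction",
    "mc_at_298",
    "mc_at_temperature",
    "mc_of_mass_fraction",
]

_density_cache: pd.DataFrame | None = None


def load_density_table(path=None) -> pd.DataFrame:
    """Load an H2SO4 density lookup table.

    Parameters
    ----------
    path : str or Path, optional
        CSV with columns ``mass_fraction_percent, density_g_per_ml``
        (``#`` comment lines allowed). When omitted, the bundled
        handbook table (80-100 wt %, 1-point steps) is used.
    """
    global _density_cache
    if path is None:
        if _density_cache is None:
            ref = importlib.resources.files("nitrokin.data") / "h2so4_density.csv"
            with importlib.resources.as_file(ref) as p:
                _density_cache = pd.read_csv(p, comment="#")
        return _density_cache
    table = pd.read_csv(path, comment="#")
    missing = {"mass_fraction_percent", "density_g_per_ml"} - set(table.columns)
    if missing:
        raise RangeError(f"density table missing columns: {sorted(missing)}")
    return table.sort_values("mass_fraction_percent").reset_index(drop=True)


def _table_span(table: pd.DataFrame) -> tuple[float, float]:
    w = table["mass_fraction_percent"].to_numpy(float)
    return float(w.min()), float(w.max())


def mass_fraction_to_molarity(w_h2so4: float, table: pd.DataFrame | None = None) -> float:
    """Convert H2SO4 mass fraction (percent) to molarity (mol/L).

    molarity = density(w) * 1000 * (w/100) / 98.08, with density linearly
    interpolated between tabulated points.
    """
    table = load_density_table() if table is None else table
    lo, hi = _table_span(table)
    w = float(w_h2so4)
    if not (lo <= w <= hi):
        raise RangeError(
            f"mass fraction {w} wt % outside the density table range [{lo}, {hi}] wt %"
        )
    rho = float(
        np.interp(
            w,
            table["mass_fraction_percent"].to_numpy(float),
            table["density_g_per_ml"].to_numpy(float),
        )
    )
    return rho * 1000.0 * (w / 100.0) / M_H2SO4


def molarity_to_mass_fraction(c_h2so4: float, table: pd.DataFrame | None = None) -> float:
    """Invert :func:`mass_fraction_to_molarity` (root-find; w→c is strictly
    increasing over the table span)."""
    table = load_density_table() if table is None else table
    lo, hi = _table_span(table)
    c = float(c_h2so4)
    c_lo = mass_fraction_to_molarity(lo, table)
    c_hi = mass_fraction_to_molarity(hi, table)
    if not (c_lo <= c <= c_hi):
        raise RangeError(
            f"molarity {c} mol/L outside [{c_lo:.3f}, {c_hi:.3f}] mol/L "
            f"covered by the density table"
        )
    return float(brentq(lambda w: mass_fraction_to_molarity(w, table) - c, lo, hi, xtol=1e-12))


def mc_at_298(c_h2so4: float, enforce_range: bool = False) -> float:
    """Activity-coefficient function Mc at 298 K for molarity ``c_h2so4``.

    The calibration polynomial gives -Mc; this returns Mc (negative over
    the calibrated interval). Outside the calibrated molarity interval
    the value is still computed but a warning is emitted, unless
    ``enforce_range`` is set, in which case a :class:`RangeError` is
    raised instead (strict mode).
    """
    c = float(c_h2so4)
    if c <= 0:
        raise ValueError(f"molarity must be positive, got {c}")
    lo, hi = MC_CALIBRATION_RANGE
    if not (lo <= c <= hi):
        if enforce_range:
            raise RangeError(
                f"molarity {c} mol/L outside the Mc calibration range [{lo}, {hi}] mol/L"
            )
        warnings.warn(
            f"Mc evaluated at {c} mol/L, outside its calibration range [{lo}, {hi}] mol/L",
            stacklevel=2,
        )
    neg_mc = 0.0
    for power, coeff in enumerate(MC_POLY_COEFFS, start=1):
        neg_mc += coeff * c**power
    return -neg_mc


def mc_at_temperature(mc_298: float, temperature: float) -> float:
    """Scale Mc from 298 K to ``temperature`` (kelvin):
    Mc(T) = Mc(298 K) * (200/T + 0.3292)."""
    t = float(temperature)
    if t <= 0:
        raise ValueError(f"temperature must be positive kelvin, got {t}")
    return float(mc_298) * (MC_TEMP_A / t + MC_TEMP_B)


def mc_of_mass_fraction(
    w_h2so4: float,
    temperature: float,
    table: pd.DataFrame | None = None,
    enforce_range: bool = False,
) -> float:
    """Mc at (mass fraction, temperature): w -> molarity -> Mc(298 K) -> Mc(T)."""
    c = mass_fraction_to_molarity(w_h2so4, table)
    return mc_at_temperature(mc_at_298(c, enforce_range=enforce_range), temperature)


@dataclass(frozen=True)
class AcidMedium:
    """State of the sulfuric-acid medium.

    Attributes
    ----------
    w_h2so4 : float
        Mass fraction of H2SO4 in percent, 0 < w <= 100.
    c_h2so4 : float
        Molarity in mol/L, consistent with ``w_h2so4`` under the density
        table used to build the instance.
    temperature : float
        Kelvin.
    mc : float
        Activity-coefficient function value at ``temperature``
        (dimensionless, typically negative).
    """

    w_h2so4: float
    c_h2so4: float
    temperature: float
    mc: float

    def __post_init__(self):
        if not (0 < self.w_h2so4 <= 100):
            raise ValueError(f"mass fraction {self.w_h2so4} outside (0, 100]")
        if self.c_h2so4 <= 0:
            raise ValueError("molarity must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")

    @classmethod
    def from_mass_fraction(
        cls,
        w_h2so4: float,
        temperature: float,
        table: pd.DataFrame | None = None,
        enforce_range: bool = False,
    ) -> "AcidMedium":
        c = mass_fraction_to_molarity(w_h2so4, table)
        mc = mc_at_temperature(mc_at_298(c, enforce_range=enforce_range), temperature)
        return cls(w_h2so4=float(w_h2so4), c_h2so4=c, temperature=float(temperature), mc=mc)

    @classmethod
    def from_celsius(cls, w_h2so4: float, temperature_c: float, **kwargs) -> "AcidMedium":
        return cls.from_mass_fraction(w_h2so4, temperature_c + CELSIUS_OFFSET, **kwargs)
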