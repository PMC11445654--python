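"""Intrinsic NO2+-based kinetics and Arrhenius parameters.

The apparent second-order rate constant k (defined on total HNO3)
depends strongly on sulfuric-acid strength because the acid controls
both the nitronium fraction and the medium activity. The standard
decomposition for mixed-acid nitration is

    lg k = lg(c_NO2+/c_HNO3) + n * Mc + lg k0,

where k0 is the intrinsic rate constant defined on NO2+ (temperature
dependent only), n a compound-specific thermodynamic parameter, and Mc
the activity-coefficient function of the medium. At fixed temperature,
plotting lg k - lg(c_NO2+/c_HNO3) against Mc gives n as the slope and
lg k0 as the intercept. The temperature dependence of k0 follows
Arrhenius: ln k0 = -Ea/(R T) + ln A.

Base conventions: the decomposition is base-10 throughout ("lg"); the
Arrhenius fit is in natural log ("ln"). Conversions are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .constants import LN10, R_GAS
from .errors import FitError
from .kinetics import r_squared
from .medium import mc_of_mass_fraction
from .nitronium import NitroniumModel

__all__ = [
    "IntrinsicFit",
    "ArrheniusFit",
    "IntrinsicParams",
    "fit_intrinsic",
    "fit_arrhenius",
    "k0_at_temperature",
    "lg_k0_at_temperature",
]


@dataclass(frozen=True)
class IntrinsicFit:
    """Per-temperature intrinsic parameters (n, lg k0)."""

    temperature: float  # kelvin
    n: float
    lg_k0: float
    r2: float
    n_rows: int
    extrapolated: bool  # any nitronium value came from outside calibration


def fit_intrinsic(
    rate_table: pd.DataFrame,
    nitronium: NitroniumModel,
    temperature: float,
    density_table: pd.DataFrame | None = None,
    strict: bool = False,
    mc_enforce_range: bool = False,
) -> IntrinsicFit:
    """Fit (n, lg k0) at one temperature from the apparent-rate table.

    For each row at ``temperature``: y = lg k - lg(c_NO2+/c_HNO3)(w, T)
    and x = Mc(w, T); OLS of y on x gives slope n and intercept lg k0.
    Rows whose nitronium value is extrapolated are kept but flagged;
    with ``strict`` they are dropped instead.
    """
    sel = rate_table[np.isclose(rate_table["temperature_K"], temperature, atol=1e-6)]
    if len(sel) < 3:
        raise FitError(
            f"need >= 3 acid mass fractions at {temperature} K, found {len(sel)}"
        )
    xs, ys, flags = [], [], []
    for _, row in sel.iterrows():
        w = float(row["w_h2so4"])
        pred = nitronium.lg_ratio(w, temperature)
        if strict and pred.extrapolated:
            continue
        mc = mc_of_mass_fraction(w, temperature, table=density_table)
        xs.append(mc)
        ys.append(np.log10(row["k"]) - pred.value)
        flags.append(pred.extrapolated)
    if len(xs) < 3:
        raise FitError(
            f"only {len(xs)} usable rows at {temperature} K after strict "
            "filtering; need >= 3"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    res = linregress(x, y)
    return IntrinsicFit(
        temperature=float(temperature),
        n=float(res.slope),
        lg_k0=float(res.intercept),
        r2=r_squared(y, res.slope * x + res.intercept),
        n_rows=len(x),
        extrapolated=any(flags),
    )


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters from ln k0 vs 1/T."""

    ea: float  # J/mol
    ln_a: float
    r2: float


def fit_arrhenius(rows, gas_constant: float = R_GAS) -> ArrheniusFit:
    """Fit (Ea, ln A) from per-temperature (temperature_K, lg_k0) pairs.

    lg k0 is converted to ln k0 and regressed on 1/T by ordinary least
    squares over all temperatures simultaneously; Ea = -slope * R,
    ln A = intercept.
    """
    if isinstance(rows, pd.DataFrame):
        pairs = list(zip(rows["temperature_K"], rows["lg_k0"]))
    else:
        pairs = [(float(t), float(lg) ) for t, lg in rows]
    temps = np.array([p[0] for p in pairs], float)
    lg_k0 = np.array([p[1] for p in pairs], float)
    if len(np.unique(temps)) < 2:
        raise FitError("Arrhenius fit needs >= 2 distinct temperatures")
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive kelvin")
    inv_t = 1.0 / temps
    ln_k0 = lg_k0 * LN10
    res = linregress(inv_t, ln_k0)
    ea = -float(res.slope) * gas_constant
    if ea <= 0:
        raise FitError(f"non-physical activation energy {ea:.3e} J/mol (<= 0)")
    fitted = res.slope * inv_t + res.intercept
    r2 = 1.0 if np.ptp(ln_k0) == 0 else r_squared(ln_k0, fitted)
    return ArrheniusFit(ea=ea, ln_a=float(res.intercept), r2=r2)


def k0_at_temperature(ea: float, ln_a: float, temperature: float,
                      gas_constant: float = R_GAS) -> float:
    """Intrinsic rate constant k0 = exp(ln A - Ea/(R T))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive kelvin")
    return float(np.exp(ln_a - ea / (gas_constant * temperature)))


def lg_k0_at_temperature(ea: float, ln_a: float, temperature: float,
                         gas_constant: float = R_GAS) -> float:
    """Base-10 log of k0 at ``temperature``, evaluated in log space."""
    if temperature <= 0:
        raise ValueError("temperature must be positive kelvin")
    return (ln_a - ea / (gas_constant * temperature)) / LN10


@dataclass
class IntrinsicParams:
    """Per-temperature (n, lg k0) rows plus global Arrhenius parameters.

    ``rows`` columns: temperature_K, n, lg_k0, r2, extrapolated.
    """

    rows: pd.DataFrame
    ea: float
    ln_a: float
    gas_constant: float = R_GAS
    arrhenius_r2: float = field(default=float("nan"))

    def __post_init__(self):
        if len(self.rows) < 2:
            raise FitError("need per-temperature rows at >= 2 temperatures")
        if self.ea <= 0:
            raise ValueError("activation energy must be positive")

    @classmethod
    def fit(
        cls,
        rate_table: pd.DataFrame,
        nitronium: NitroniumModel,
        density_table: pd.DataFrame | None = None,
        strict: bool = False,
        gas_constant: float = R_GAS,
    ) -> "IntrinsicParams":
        """Full decomposition: per-temperature (n, lg k0) fits followed
        by the Arrhenius extraction across temperatures."""
        temps = np.sort(rate_table["temperature_K"].unique())
        fits = [
            fit_intrinsic(rate_table, nitronium, t, density_table, strict=strict)
            for t in temps
        ]
        rows = pd.DataFrame(
            {
                "temperature_K": [f.temperature for f in fits],
                "n": [f.n for f in fits],
                "lg_k0": [f.lg_k0 for f in fits],
                "r2": [f.r2 for f in fits],
                "extrapolated": [f.extrapolated for f in fits],
            }
        )
        arr = fit_arrhenius(rows, gas_constant=gas_constant)
        return cls(rows=rows, ea=arr.ea, ln_a=arr.ln_a,
                   gas_constant=gas_constant, arrhenius_r2=arr.r2)

    # -- evaluation ----------------------------------------------------
    def n_at(self, temperature: float) -> tuple[float, bool]:
        """Linear interpolation of n between fitted temperatures;
        linear extension (flagged) outside them — n varies only mildly
        with temperature for a given substrate."""
        t = np.asarray(self.rows["temperature_K"], float)
        n = np.asarray(self.rows["n"], float)
        order = np.argsort(t)
        t, n = t[order], n[order]
        temp = float(temperature)
        inside = t[0] <= temp <= t[-1]
        if len(t) == 1:
            return float(n[0]), not inside
        if temp < t[0]:
            slope = (n[1] - n[0]) / (t[1] - t[0])
            return float(n[0] + slope * (temp - t[0])), True
        if temp > t[-1]:
            slope = (n[-1] - n[-2]) / (t[-1] - t[-2])
            return float(n[-1] + slope * (temp - t[-1])), True
        return float(np.interp(temp, t, n)), False

    def lg_k0_at(self, temperature: float) -> float:
        return lg_k0_at_temperature(self.ea, self.ln_a, temperature, self.gas_constant)

    def to_dict(self) -> dict:
        return {
            "per_temperature": self.rows.to_dict(orient="records"),
            "ea_kJ_per_mol": self.ea / 1000.0,
            "ln_a": self.ln_a,
            "arrhenius_r2": self.arrhenius_r2,
            "gas_constant": self.gas_constant,
        }
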