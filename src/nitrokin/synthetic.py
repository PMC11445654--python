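"""Synthetic conversion-time campaigns and nitronium tables.

Every input the pipeline consumes can be generated here from known
ground-truth parameters, so each stage — apparent-rate fitting, the
two-stage nitronium model, the intrinsic decomposition, the Arrhenius
extraction, and forward prediction — is testable end to end against
recoverable truth.

What is emulated: multi-condition campaigns over 30-40 C, 88-98 wt %
H2SO4 and residence times of a few minutes at molar ratio M = 4.4 and
c_IO0 = 0.5 mol/L, with additive Gaussian noise on conversion
(triplicate-averaged chromatographic readouts are bounded, so noisy
conversions are truncated to [0, 0.999]). Not emulated:
mass-transfer-limited regimes, heteroscedastic or autocorrelated noise,
and replicate structure.

The default ground truth uses the published intrinsic parameters
(Ea = 192.57 kJ/mol, ln A = 102.55, n ~ 1.08-1.16) together with an
affine-in-(w, 1/T) nitronium structure chosen so that, at the stated
campaign design, apparent rate constants land near 1e-4..1e-3 L/(mol s)
and conversions stay informative (roughly 0.02-0.5) rather than
saturating; see docs/methods.md for the scale convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET, LN10, MC_POLY_COEFFS, R_GAS
from .kinetics import Condition, ConversionSeries, predict_conversion
from .medium import mass_fraction_to_molarity
from .nitronium import NitroniumTable

__all__ = [
    "NitroniumStructure",
    "GroundTruth",
    "generate_series",
    "generate_campaign",
    "generate_nitronium_table",
    "CampaignResult",
]


@dataclass(frozen=True)
class NitroniumStructure:
    """Exact surface lg_ratio = (a0 + a1 w)/T + (b0 + b1 w).

    Affine in w and in 1/T, i.e. precisely the structure the two-stage
    nitronium fit can recover without residual.
    """

    a0: float
    a1: float
    b0: float
    b1: float

    def lg_ratio(self, w: float, temperature: float) -> float:
        return (self.a0 + self.a1 * w) / temperature + (self.b0 + self.b1 * w)


# Frozen defaults: affine structure least-squares matched to the
# lg-ratio values implied by the published apparent-rate and intrinsic
# tables under the lg k = lg_ratio + n*Mc + lg k0 decomposition, with
# the intercept shifted by -2 lg units (see docs/methods.md).
_DEFAULT_NITRONIUM = NitroniumStructure(
    a0=-3216.2, a1=49.837, b0=-22.564, b1=0.18800
)

_DEFAULT_N_BY_T = {
    30.0 + CELSIUS_OFFSET: 1.0764,
    35.0 + CELSIUS_OFFSET: 1.1127,
    40.0 + CELSIUS_OFFSET: 1.1577,
}

DEFAULT_TEMPERATURES_C = (30.0, 35.0, 40.0)
DEFAULT_W_VALUES = (88.0, 90.0, 92.0, 94.0, 96.0, 98.0)
DEFAULT_T_GRID_MIN = (1.0, 2.0, 3.0, 4.0, 4.7)
DEFAULT_M = 4.4
DEFAULT_C_IO0 = 0.5
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for a synthetic campaign."""

    ea: float = 192570.0  # J/mol
    ln_a: float = 102.55
    n_by_temperature: dict = field(default_factory=lambda: dict(_DEFAULT_N_BY_T))
    mc_coeffs: tuple = MC_POLY_COEFFS  # ascending powers of -Mc(298 K)
    nitronium: NitroniumStructure = _DEFAULT_NITRONIUM
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    gas_constant: float = R_GAS

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    # -- truth evaluation ---------------------------------------------
    def mc(self, w: float, temperature: float,
           density_table: pd.DataFrame | None = None) -> float:
        c = mass_fraction_to_molarity(w, density_table)
        neg = sum(co * c**p for p, co in enumerate(self.mc_coeffs, start=1))
        return -neg * (200.0 / temperature + 0.3292)

    def n_at(self, temperature: float) -> float:
        temps = np.array(sorted(self.n_by_temperature), float)
        ns = np.array([self.n_by_temperature[t] for t in temps], float)
        if len(temps) == 1:
            return float(ns[0])
        return float(np.interp(temperature, temps, ns))

    def lg_k0(self, temperature: float) -> float:
        return (self.ln_a - self.ea / (self.gas_constant * temperature)) / LN10

    def lg_k(self, w: float, temperature: float,
             density_table: pd.DataFrame | None = None) -> float:
        return (
            self.nitronium.lg_ratio(w, temperature)
            + self.n_at(temperature) * self.mc(w, temperature, density_table)
            + self.lg_k0(temperature)
        )

    def k(self, w: float, temperature: float,
          density_table: pd.DataFrame | None = None) -> float:
        return float(10.0 ** self.lg_k(w, temperature, density_table))


def generate_series(
    k_true: float,
    m: float,
    c_io0: float,
    t_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    temperature: float = 303.15,
    w_h2so4: float = 94.0,
) -> ConversionSeries:
    """One conversion-time series from the integrated rate law with
    additive, truncated Gaussian noise on conversion (seconds grid)."""
    t = np.asarray(t_grid, float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("t_grid must be non-empty, >= 0, strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.asarray(predict_conversion(k_true, m, c_io0, t), float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    x = np.clip(x, 0.0, 0.999)
    cond = Condition(
        temperature=temperature, w_h2so4=w_h2so4, c_io0=c_io0, c_hno3_0=m * c_io0
    )
    meta = {
        "synthetic": True,
        "k_true": float(k_true),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
    }
    return ConversionSeries(times=t, conversions=x, condition=cond, metadata=meta)


@dataclass(frozen=True)
class CampaignResult:
    """All series of a campaign plus the noise-free truth rate table."""

    series: list
    true_k_table: pd.DataFrame  # temperature_K, w_h2so4, k_true
    truth: GroundTruth


def generate_campaign(
    truth: GroundTruth | None = None,
    temperatures_c: Sequence[float] = DEFAULT_TEMPERATURES_C,
    w_values: Sequence[float] = DEFAULT_W_VALUES,
    t_grid_min: Sequence[float] = DEFAULT_T_GRID_MIN,
    m: float = DEFAULT_M,
    c_io0: float = DEFAULT_C_IO0,
    noise_sd: float | None = None,
    seed: int | None = None,
    density_table: pd.DataFrame | None = None,
) -> CampaignResult:
    """A full multi-condition campaign: one series per (T, w) cell plus
    the noise-free truth k table for recovery scoring.

    ``t_grid_min`` is in minutes (the bench convention); series are
    emitted in seconds. Each cell gets an independent child seed from
    one spawned sequence, so the whole campaign is reproducible from a
    single integer.
    """
    truth = truth or GroundTruth()
    if len(temperatures_c) == 0 or len(w_values) == 0 or len(t_grid_min) == 0:
        raise ValueError("campaign design must be non-empty")
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    seed = truth.seed if seed is None else seed
    t_grid_s = np.asarray(t_grid_min, float) * 60.0

    n_cells = len(temperatures_c) * len(w_values)
    children = np.random.SeedSequence(seed).spawn(n_cells)
    series = []
    rows = []
    i = 0
    for tc in temperatures_c:
        temp = tc + CELSIUS_OFFSET
        for w in w_values:
            k_true = truth.k(w, temp, density_table)
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            series.append(
                generate_series(
                    k_true, m, c_io0, t_grid_s,
                    noise_sd=noise_sd, seed=child_seed,
                    temperature=temp, w_h2so4=w,
                )
            )
            rows.append({"temperature_K": temp, "w_h2so4": w, "k_true": k_true})
    return CampaignResult(
        series=series, true_k_table=pd.DataFrame(rows), truth=truth
    )


def generate_nitronium_table(
    structure: NitroniumStructure | None = None,
    w_points: Sequence[float] = DEFAULT_W_VALUES,
    temperatures_c: Sequence[float] = (23.0, 40.0, 60.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> NitroniumTable:
    """Synthetic stand-in for a literature nitronium-fraction table,
    generated from the exact affine structure plus optional noise."""
    structure = structure or _DEFAULT_NITRONIUM
    if len(w_points) < 2 or len(temperatures_c) < 2:
        raise ValueError("need >= 2 mass fractions and >= 2 temperatures")
    rng = np.random.default_rng(seed)
    rows = []
    for tc in temperatures_c:
        temp = tc + CELSIUS_OFFSET
        for w in w_points:
            val = structure.lg_ratio(w, temp)
            if noise_sd > 0:
                val += rng.normal(0.0, noise_sd)
            rows.append(
                {"temperature_K": temp, "w_h2so4": float(w), "lg_ratio": float(val)}
            )
    return NitroniumTable(data=pd.DataFrame(rows))
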