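"""Conversion-time preprocessing, integral-method order inference, and
apparent rate-constant estimation.

The reaction studied is second order overall: first order in the
limiting substrate (IO, an isouronium salt) and first order in nitric
acid, run with HNO3 in excess at molar ratio M = c_HNO3,0/c_IO,0 > 1.
The integrated rate law in conversion x of the limiting reagent is

    ln[(M - x) / (M (1 - x))] = (M - 1) c_IO0 k t,

so a plot of the left-hand transform against residence time is a line
through the origin with slope (M - 1) c_IO0 k. Order inference follows
the classical integral method: candidate linearizations are fitted by
ordinary least squares and the candidate with the highest R^2 wins;
wins by less than a configurable margin are flagged ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .errors import FitError

__all__ = [
    "Condition",
    "ConversionSeries",
    "ReactionOrders",
    "ApparentFit",
    "conversion_from_hplc",
    "residence_time",
    "transform_excess",
    "r_squared",
    "infer_orders",
    "fit_apparent_k",
    "fit_rate_table",
]

#: R^2 margin below which an integral-method order selection is flagged
#: ambiguous rather than silently decided.
DEFAULT_DELTA_R2 = 0.005


@dataclass(frozen=True)
class Condition:
    """Fixed reaction condition of one conversion-time series."""

    temperature: float  # kelvin
    w_h2so4: float  # percent
    c_io0: float  # mol/L
    c_hno3_0: float  # mol/L

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")
        if not (0 < self.w_h2so4 <= 100):
            raise ValueError("mass fraction must be in (0, 100]")
        if self.c_io0 <= 0 or self.c_hno3_0 <= 0:
            raise ValueError("initial concentrations must be positive")

    @property
    def m_ratio(self) -> float:
        return self.c_hno3_0 / self.c_io0


@dataclass(frozen=True)
class ConversionSeries:
    """A conversion-time dataset under one condition set — the atomic
    unit of kinetic fitting."""

    times: np.ndarray  # seconds, strictly increasing, >= 0
    conversions: np.ndarray  # in [0, 1)
    condition: Condition
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.times, float)
        x = np.asarray(self.conversions, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conversions", x)
        if t.ndim != 1 or x.shape != t.shape:
            raise ValueError("times and conversions must be matching 1-D arrays")
        if len(t) and t[0] < 0:
            raise ValueError("times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((x < 0) | (x >= 1)):
            raise ValueError("conversions must lie in [0, 1)")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def m_ratio(self) -> float:
        return self.condition.m_ratio


def conversion_from_hplc(c_io: float, c_nio: float) -> float:
    """Conversion from chromatographic signals of the substrate (IO) and
    nitrated product (NIO): x = 1 - c_IO/(c_IO + c_NIO)."""
    if c_io < 0 or c_nio < 0:
        raise ValueError("signals must be non-negative")
    total = c_io + c_nio
    if total == 0:
        raise ValueError("no analyte detected: both signals are zero")
    return 1.0 - c_io / total


def residence_time(volume_ml: float, q_io_ml_min: float, q_hno3_ml_min: float) -> float:
    """Residence time t = V / (Q_IO + Q_HNO3), returned in seconds."""
    if volume_ml <= 0:
        raise ValueError("reactor volume must be positive")
    total = q_io_ml_min + q_hno3_ml_min
    if total <= 0:
        raise ValueError("total flow rate must be positive")
    return volume_ml / total * 60.0


def transform_excess(x, m: float):
    """Excess-reagent second-order transform ln[(M-x)/(M(1-x))].

    Strictly increasing in x on [0, 1), zero at x = 0. Accepts scalars
    or arrays of x.
    """
    if m <= 1:
        raise ValueError(f"molar ratio M must exceed 1, got {m}")
    x_arr = np.asarray(x, float)
    if np.any((x_arr < 0) | (x_arr >= 1)) or np.any(x_arr >= m):
        raise ValueError("conversion must satisfy 0 <= x < 1 and x < M")
    out = np.log((m - x_arr) / (m * (1.0 - x_arr)))
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (SS_tot about the
    observed mean)."""
    obs = np.asarray(observed, float)
    fit = np.asarray(fitted, float)
    if obs.shape != fit.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and fitted must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot


def _line_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Free-intercept OLS of y on t; returns (slope, intercept, R^2).

    A constant response gives slope 0 and an undefined R^2 (nan) so
    callers can report the degenerate fit instead of crashing."""
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), float("nan")
    res = linregress(t, y)
    return float(res.slope), float(res.intercept), r_squared(y, res.slope * t + res.intercept)


@dataclass(frozen=True)
class ReactionOrders:
    """Outcome of integral-method order selection.

    alpha is the order in the limiting substrate (candidates {1, 2}),
    beta the order in nitric acid (candidates {0, 1}). ``ambiguous`` is
    set when either winning R^2 margin falls below the threshold.
    """

    alpha: int
    beta: int
    r2_by_candidate: dict[str, float]
    ambiguous: bool
    ambiguous_alpha: bool
    ambiguous_beta: bool


def infer_orders(
    pseudo_series: ConversionSeries,
    mixed_series: ConversionSeries,
    delta_r2: float = DEFAULT_DELTA_R2,
    min_pseudo_ratio: float = 10.0,
) -> ReactionOrders:
    """Determine reaction orders by the classical integral method.

    The substrate order alpha is read from ``pseudo_series``, run with a
    large nitric-acid excess so c_HNO3 is effectively constant: the
    first-order linearization ln(1-x) vs t competes against the
    second-order one 1/(1-x) vs t. The nitric-acid order beta is read
    from ``mixed_series`` at a practical excess: zero order (ln(1-x) vs
    t) competes against first order (the excess-reagent transform vs t).
    The beta discrimination assumes first order in the substrate.
    """
    ratio = pseudo_series.m_ratio
    if ratio < min_pseudo_ratio:
        raise ValueError(
            f"pseudo-order condition violated: c_HNO3,0/c_IO,0 = {ratio:.2f} "
            f"< required {min_pseudo_ratio}"
        )
    for name, s in (("pseudo", pseudo_series), ("mixed", mixed_series)):
        if len(s) < 4:
            raise FitError(f"{name} series has {len(s)} points; need >= 4")

    tp = pseudo_series.times
    xp = pseudo_series.conversions
    _, _, r2_a1 = _line_r2(tp, np.log(1.0 - xp))
    _, _, r2_a2 = _line_r2(tp, 1.0 / (1.0 - xp))

    tm = mixed_series.times
    xm = mixed_series.conversions
    _, _, r2_b0 = _line_r2(tm, np.log(1.0 - xm))
    _, _, r2_b1 = _line_r2(tm, transform_excess(xm, mixed_series.m_ratio))

    alpha = 1 if r2_a1 >= r2_a2 else 2
    beta = 1 if r2_b1 >= r2_b0 else 0
    amb_a = abs(r2_a1 - r2_a2) < delta_r2
    amb_b = abs(r2_b1 - r2_b0) < delta_r2
    return ReactionOrders(
        alpha=alpha,
        beta=beta,
        r2_by_candidate={
            "alpha=1": r2_a1,
            "alpha=2": r2_a2,
            "beta=0": r2_b0,
            "beta=1": r2_b1,
        },
        ambiguous=amb_a or amb_b,
        ambiguous_alpha=amb_a,
        ambiguous_beta=amb_b,
    )


@dataclass(frozen=True)
class ApparentFit:
    """An apparent second-order rate constant from one series."""

    k: float  # L/(mol s)
    r2: float
    intercept: float  # diagnostic; should be near zero
    slope: float


#: |intercept| above which an apparent fit is suspect (quench-delay or
#: baseline offset in the first samples).
INTERCEPT_WARN = 0.05


def fit_apparent_k(series: ConversionSeries) -> ApparentFit:
    """Estimate the apparent rate constant k from one series.

    OLS of the excess-reagent transform on time with a free intercept;
    k = slope / ((M - 1) c_IO0). A non-positive slope is non-physical
    and raises; a large intercept only warns.
    """
    if len(series) < 3:
        raise FitError(f"series has {len(series)} points; need >= 3 for a rate fit")
    m = series.m_ratio
    if m <= 1:
        raise ValueError(f"excess-acid fit requires M > 1, got M = {m:.3f}")
    y = transform_excess(series.conversions, m)
    slope, intercept, r2 = _line_r2(series.times, y)
    if slope <= 0:
        raise FitError(f"non-physical rate: fitted slope {slope:.3e} <= 0")
    if abs(intercept) > INTERCEPT_WARN:
        warnings.warn(
            f"apparent-rate fit intercept {intercept:.3f} exceeds "
            f"{INTERCEPT_WARN}; check the early samples",
            stacklevel=2,
        )
    k = slope / ((m - 1.0) * series.condition.c_io0)
    return ApparentFit(k=k, r2=r2, intercept=intercept, slope=slope)


def fit_rate_table(series_list) -> "pandas.DataFrame":  # noqa: F821
    """Fit every series and assemble the apparent-rate table
    (temperature_K, w_h2so4, k, r2, intercept)."""
    import pandas as pd

    rows = []
    for s in series_list:
        fit = fit_apparent_k(s)
        rows.append(
            {
                "temperature_K": s.condition.temperature,
                "w_h2so4": s.condition.w_h2so4,
                "k": fit.k,
                "r2": fit.r2,
                "intercept": fit.intercept,
            }
        )
    table = pd.DataFrame(rows).sort_values(["temperature_K", "w_h2so4"])
    return table.reset_index(drop=True)


def predict_conversion(k: float, m: float, c_io0: float, t):
    """Forward conversion from the integrated excess-reagent rate law.

    With z = (M-1) c_IO0 k t,  x = M (e^z - 1) / (M e^z - 1), the exact
    inverse of :func:`transform_excess`. Overflow-safe: for large z the
    asymptotic form x = 1 - (M-1)/(M e^z) is evaluated in log space.
    """
    if m <= 1:
        raise ValueError(f"molar ratio M must exceed 1, got {m}")
    if k < 0 or c_io0 <= 0:
        raise ValueError("k must be >= 0 and c_io0 > 0")
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    z = (m - 1.0) * c_io0 * k * t_arr
    with np.errstate(over="ignore"):
        safe = z < 700.0
        z_safe = np.where(safe, z, 0.0)
        ez = np.expm1(z_safe)
        x_exact = m * ez / (m * ez + (m - 1.0))
        x_asym = 1.0 - (m - 1.0) / m * np.exp(-np.where(safe, 0.0, z))
        x = np.where(safe, x_exact, x_asym)
    # the contract is x in [0, 1): keep saturation strictly below 1
    x = np.minimum(x, np.nextafter(1.0, 0.0))
    return float(x) if np.isscalar(t) or t_arr.ndim == 0 else x
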