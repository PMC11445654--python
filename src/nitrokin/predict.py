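"""Forward prediction, validation, and condition optimization.

Combines the fitted intrinsic parameters, the nitronium surface, and
the medium model into predicted apparent rate constants and plug-flow
conversions, generates response surfaces, scores predictions against
experimental observations, and grid-searches the operating window for
optimal conditions.

Every prediction carries a three-state calibration status: ``interior``
(inside the conditions the model was built from), ``soft`` (outside the
construction window but inside configured hard limits; answered with a
flag — prolonged residence times and modestly higher temperatures
extrapolate usefully), or rejected with an error beyond the hard
limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET
from .errors import EnvelopeError
from .intrinsic import IntrinsicParams
from .kinetics import predict_conversion, transform_excess  # noqa: F401 (re-export)
from .medium import mc_of_mass_fraction
from .nitronium import NitroniumModel

__all__ = [
    "PredictionRequest",
    "CalibrationEnvelope",
    "KPrediction",
    "predict_conversion",
    "predict_k",
    "predict_request",
    "response_surface",
    "SurfaceResult",
    "validate",
    "ValidationReport",
    "optimize_conditions",
    "OptimizationResult",
]

INTERIOR = "interior"
SOFT = "soft"
REJECTED = "rejected"


@dataclass(frozen=True)
class PredictionRequest:
    """One operating point to evaluate."""

    temperature: float  # kelvin
    w_h2so4: float  # percent
    c_io0: float  # mol/L
    m_ratio: float  # c_HNO3,0 / c_IO,0
    residence_time: float  # seconds

    def __post_init__(self):
        if min(self.temperature, self.w_h2so4, self.c_io0, self.residence_time) <= 0:
            raise ValueError("all request fields must be positive")
        if self.m_ratio <= 1:
            raise ValueError("molar ratio must exceed 1")


def _default_soft():
    return {
        "t_min": 30.0 + CELSIUS_OFFSET,
        "t_max": 40.0 + CELSIUS_OFFSET,
        "w_min": 88.0,
        "w_max": 98.0,
        "time_max": 4.7 * 60.0,
    }


def _default_hard():
    return {
        "t_min": 0.0 + CELSIUS_OFFSET,
        "t_max": 45.0 + CELSIUS_OFFSET,
        "w_min": 80.0,
        "w_max": 100.0,
        "time_max": 15.0 * 60.0,
    }


@dataclass
class CalibrationEnvelope:
    """Soft (model-construction) and hard (refuse-beyond) limits on
    temperature (K), acid mass fraction (%), and residence time (s)."""

    soft: dict = field(default_factory=_default_soft)
    hard: dict = field(default_factory=_default_hard)

    def __post_init__(self):
        s, h = self.soft, self.hard
        ok = (
            s["t_min"] >= h["t_min"]
            and s["t_max"] <= h["t_max"]
            and s["w_min"] >= h["w_min"]
            and s["w_max"] <= h["w_max"]
            and s["time_max"] <= h["time_max"]
        )
        if not ok:
            raise ValueError("soft envelope must be contained in the hard envelope")

    def classify(self, temperature: float, w_h2so4: float, residence_time: float) -> str:
        h, s = self.hard, self.soft
        if not (
            h["t_min"] <= temperature <= h["t_max"]
            and h["w_min"] <= w_h2so4 <= h["w_max"]
            and residence_time <= h["time_max"]
        ):
            return REJECTED
        if (
            s["t_min"] <= temperature <= s["t_max"]
            and s["w_min"] <= w_h2so4 <= s["w_max"]
            and residence_time <= s["time_max"]
        ):
            return INTERIOR
        return SOFT


@dataclass(frozen=True)
class KPrediction:
    """Predicted apparent rate constant with its decomposition."""

    k: float  # L/(mol s)
    lg_k: float
    lg_ratio: float
    n: float
    mc: float
    lg_k0: float
    extrapolated: bool


def predict_k(
    w_h2so4: float,
    temperature: float,
    params: IntrinsicParams,
    nitronium: NitroniumModel,
    density_table: pd.DataFrame | None = None,
) -> KPrediction:
    """Apparent rate constant from the intrinsic decomposition:
    lg k = lg(c_NO2+/c_HNO3) + n(T) Mc(w, T) + lg k0(T)."""
    lg_ratio = nitronium.lg_ratio(w_h2so4, temperature)
    n, n_extrap = params.n_at(temperature)
    mc = mc_of_mass_fraction(w_h2so4, temperature, table=density_table)
    lg_k0 = params.lg_k0_at(temperature)
    lg_k = lg_ratio.value + n * mc + lg_k0
    return KPrediction(
        k=float(10.0**lg_k),
        lg_k=float(lg_k),
        lg_ratio=lg_ratio.value,
        n=n,
        mc=mc,
        lg_k0=lg_k0,
        extrapolated=lg_ratio.extrapolated or n_extrap,
    )


@dataclass(frozen=True)
class ConversionPrediction:
    x: float
    k: float
    status: str
    extrapolated: bool  # model-input extrapolation (nitronium / n)


def predict_request(
    request: PredictionRequest,
    params: IntrinsicParams,
    nitronium: NitroniumModel,
    envelope: CalibrationEnvelope | None = None,
    density_table: pd.DataFrame | None = None,
    strict: bool = False,
) -> ConversionPrediction:
    """Predicted conversion at one operating point, with calibration
    status. Hard-envelope violations raise; with ``strict`` any
    non-interior point raises."""
    envelope = envelope or CalibrationEnvelope()
    status = envelope.classify(request.temperature, request.w_h2so4, request.residence_time)
    if status == REJECTED:
        raise EnvelopeError(
            f"condition (T={request.temperature} K, w={request.w_h2so4} %, "
            f"t={request.residence_time} s) violates the hard envelope"
        )
    if strict and status != INTERIOR:
        raise EnvelopeError(
            f"strict mode: condition is outside the model-construction window ({status})"
        )
    kp = predict_k(request.w_h2so4, request.temperature, params, nitronium, density_table)
    x = predict_conversion(kp.k, request.m_ratio, request.c_io0, request.residence_time)
    return ConversionPrediction(x=float(x), k=kp.k, status=status, extrapolated=kp.extrapolated)


@dataclass(frozen=True)
class SurfaceResult:
    """Response surface: conversion and status per grid cell."""

    x: np.ndarray  # shape (len(axis1), len(axis2))
    status: np.ndarray  # same shape, strings
    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray


def response_surface(
    params: IntrinsicParams,
    nitronium: NitroniumModel,
    m_ratio: float,
    c_io0: float,
    times: np.ndarray,
    temperatures: np.ndarray | None = None,
    w_values: np.ndarray | None = None,
    fixed_temperature: float | None = None,
    fixed_w: float | None = None,
    envelope: CalibrationEnvelope | None = None,
    density_table: pd.DataFrame | None = None,
) -> SurfaceResult:
    """Dense conversion surface over residence time x temperature (at
    fixed w) or residence time x mass fraction (at fixed T).

    Cells beyond the hard envelope abort with an error listing them.
    """
    envelope = envelope or CalibrationEnvelope()
    times = np.asarray(times, float)
    if temperatures is not None:
        if fixed_w is None:
            raise ValueError("surface over (t, T) needs fixed_w")
        axis2_name, axis2 = "temperature_K", np.asarray(temperatures, float)
        points = [(t, temp, fixed_w) for t in times for temp in axis2]
    elif w_values is not None:
        if fixed_temperature is None:
            raise ValueError("surface over (t, w) needs fixed_temperature")
        axis2_name, axis2 = "w_h2so4", np.asarray(w_values, float)
        points = [(t, fixed_temperature, w) for t in times for w in axis2]
    else:
        raise ValueError("provide either temperatures or w_values")

    bad = [
        (t, temp, w)
        for (t, temp, w) in points
        if envelope.classify(temp, w, t) == REJECTED
    ]
    if bad:
        raise EnvelopeError(
            f"{len(bad)} grid cell(s) violate the hard envelope; first few: {bad[:5]}"
        )

    x = np.empty((len(times), len(axis2)))
    status = np.empty_like(x, dtype=object)
    k_cache: dict[tuple[float, float], float] = {}
    for j, b in enumerate(axis2):
        temp, w = (b, fixed_w) if axis2_name == "temperature_K" else (fixed_temperature, b)
        key = (temp, w)
        if key not in k_cache:
            k_cache[key] = predict_k(w, temp, params, nitronium, density_table).k
        for i, t in enumerate(times):
            x[i, j] = predict_conversion(k_cache[key], m_ratio, c_io0, t)
            status[i, j] = envelope.classify(temp, w, t)
    return SurfaceResult(
        x=x, status=status, axis1_name="time_s", axis1=times,
        axis2_name=axis2_name, axis2=axis2,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Prediction-vs-observation discrepancies in percentage points of
    conversion (pairing is positional)."""

    per_point: np.ndarray  # |x_pred - x_obs| * 100
    mean: float
    max: float
    worst_index: int


def validate(predictions, observations) -> ValidationReport:
    pred = np.asarray(predictions, float)
    obs = np.asarray(observations, float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValueError("predictions and observations must be equal-length 1-D, n >= 1")
    err = np.abs(pred - obs) * 100.0
    worst = int(np.argmax(err))
    return ValidationReport(
        per_point=err, mean=float(err.mean()), max=float(err[worst]), worst_index=worst
    )


@dataclass(frozen=True)
class OptimizationResult:
    request: PredictionRequest
    predicted_x: float
    status: str
    on_boundary: bool
    boundary_axes: tuple[str, ...]


def optimize_conditions(
    params: IntrinsicParams,
    nitronium: NitroniumModel,
    m_ratio: float,
    c_io0: float,
    envelope: CalibrationEnvelope | None = None,
    objective: str | float = "max",
    t_step: float = 30.0,
    temp_step: float = 2.5,
    w_step: float = 1.0,
    allow_soft: bool = False,
    time_min: float = 30.0,
    density_table: pd.DataFrame | None = None,
) -> OptimizationResult:
    """Exhaustive grid search over (T, w, residence time).

    ``objective``: ``"max"`` maximizes conversion; a float targets that
    conversion (minimum absolute deviation). The search region is the
    soft envelope, or the hard envelope when ``allow_soft`` is set.
    Ties are broken by shorter residence time, then lower temperature,
    then lower acid strength. The result notes when the optimum sits on
    a search boundary.
    """
    envelope = envelope or CalibrationEnvelope()
    box = envelope.hard if allow_soft else envelope.soft
    temps = np.arange(box["t_min"], box["t_max"] + 1e-9, temp_step)
    ws = np.arange(box["w_min"], box["w_max"] + 1e-9, w_step)
    times = np.arange(time_min, box["time_max"] + 1e-9, t_step)
    if not (len(temps) and len(ws) and len(times)):
        raise ValueError("empty feasible grid: check envelope bounds and steps")

    best = None  # (score, t, T, w, x, status)
    for temp in temps:
        for w in ws:
            k = predict_k(w, temp, params, nitronium, density_table).k
            xs = predict_conversion(k, m_ratio, c_io0, times)
            for t, x in zip(times, np.atleast_1d(xs)):
                score = -x if objective == "max" else abs(x - float(objective))
                cand = (score, t, temp, w)
                if best is None or cand < best[:4]:
                    best = (score, float(t), float(temp), float(w), float(x))
    score, t, temp, w, x = best
    boundary_axes = []
    if np.isclose(t, times[-1]):
        boundary_axes.append("residence_time")
    if np.isclose(temp, temps[0]) or np.isclose(temp, temps[-1]):
        boundary_axes.append("temperature")
    if np.isclose(w, ws[0]) or np.isclose(w, ws[-1]):
        boundary_axes.append("w_h2so4")
    req = PredictionRequest(
        temperature=temp, w_h2so4=w, c_io0=c_io0, m_ratio=m_ratio, residence_time=t
    )
    return OptimizationResult(
        request=req,
        predicted_x=x,
        status=envelope.classify(temp, w, t),
        on_boundary=bool(boundary_axes),
        boundary_axes=tuple(boundary_axes),
    )
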