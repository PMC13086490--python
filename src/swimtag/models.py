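"""Linear calibration models and regression transfer.

The swim-tunnel calibration yields four families of simple linear models per
flow condition (steady / unsteady):

* external acceleration (m*g*) versus swimming speed,
* ODBA (m s-2) versus swimming speed,
* MO2 (mg kg-1 h-1) versus external acceleration,
* MO2 (mg kg-1 h-1) versus ODBA.

``published_models`` returns the eight fitted lines from the swim-tunnel
calibration of post-smolt Chinook salmon as constants.  A quirk of that
calibration, preserved here: the acceleration-versus-speed lines take speed
in m s-1, while the ODBA-versus-speed lines take speed as a 0.15 m s-1 step
index (speed / 0.15).  Each model therefore carries its own ``x_convention``
and ``predict`` converts a raw speed accordingly.

Regression transfer chains two models (speed -> activity metric -> MO2) to
estimate the metabolic rate of free-swimming fish from flow speed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationModel",
    "Prediction",
    "FieldEnergeticsReport",
    "fit_line",
    "predict",
    "chain_predict_mo2",
    "published_models",
    "build_report",
]

SPEED_STEP_MPS = 0.15

#: x_convention -> physical unit of x
_X_UNITS = {
    "speed_mps": "m s-1",
    "speed_step_index": "step of 0.15 m s-1",
    "ext_accel_mg": "mg",
    "odba_ms2": "ms2",
}
#: y_unit values understood by the chain checker
_Y_TO_XCONV = {"mg": "ext_accel_mg", "ms2": "odba_ms2"}


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted line y = slope * x + intercept with its x convention."""

    slope: float
    intercept: float
    r_squared: float
    x_convention: str  # speed_mps | speed_step_index | ext_accel_mg | odba_ms2
    y_unit: str  # mg | ms2 | mg_kg_h
    flow_condition: str = "steady"  # steady | unsteady
    speed_range_mps: tuple[float, float] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.x_convention not in _X_UNITS:
            raise ValueError(f"unknown x_convention {self.x_convention!r}")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class Prediction:
    value: float
    x_used: float
    extrapolated: bool


@dataclass(frozen=True)
class FieldEnergeticsReport:
    """Regression-transfer predictions for a free-swimming group."""

    flow_condition: str
    speed_mps: float
    predicted_ext_accel_mg: float
    predicted_odba_ms2: float
    predicted_mo2_from_accel: float
    predicted_mo2_from_odba: float
    observed: dict = field(default_factory=dict)


def fit_line(x, y, **meta) -> CalibrationModel:
    """Ordinary least squares line; R^2 is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; line is unidentifiable")
    res = stats.linregress(x, y)
    meta.setdefault("x_convention", "speed_mps")
    meta.setdefault("y_unit", "mg")
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        **meta,
    )


def _x_in_convention(model: CalibrationModel, x_raw: float, x_is_speed: bool) -> float:
    if model.x_convention == "speed_mps":
        if not x_is_speed:
            raise ValueError("model expects a swimming speed in m s-1")
        return x_raw
    if model.x_convention == "speed_step_index":
        if not x_is_speed:
            raise ValueError("model expects a swimming speed (converted to step index)")
        return x_raw / SPEED_STEP_MPS
    if x_is_speed:
        raise ValueError(f"model expects {model.x_convention}, not a speed")
    return x_raw


def predict(model: CalibrationModel, x_raw: float, *, x_is_speed: bool | None = None) -> Prediction:
    """Evaluate the line at ``x_raw``, converting speed to the model's x.

    ``x_is_speed`` defaults to True for speed-convention models.  Predictions
    outside the calibrated speed range are returned with an extrapolation
    flag.
    """
    if x_is_speed is None:
        x_is_speed = model.x_convention in ("speed_mps", "speed_step_index")
    x = _x_in_convention(model, x_raw, x_is_speed)
    extrapolated = False
    if model.speed_range_mps is not None and x_is_speed:
        lo, hi = model.speed_range_mps
        extrapolated = not (lo <= x_raw <= hi)
    return Prediction(
        value=model.slope * x + model.intercept, x_used=x, extrapolated=extrapolated
    )


def chain_predict_mo2(
    speed_model: CalibrationModel, mo2_model: CalibrationModel, speed_mps: float
) -> tuple[float, float]:
    """speed -> activity metric -> MO2; returns (mo2, intermediate metric).

    The unit of the first model's response must match the second model's
    regressor.
    """
    expected = _Y_TO_XCONV.get(speed_model.y_unit)
    if expected is None or mo2_model.x_convention != expected:
        raise ValueError(
            f"unit chain mismatch: {speed_model.y_unit!r} output cannot feed "
            f"a model in {mo2_model.x_convention!r}"
        )
    inter = predict(speed_model, speed_mps).value
    mo2 = predict(mo2_model, inter, x_is_speed=False).value
    return mo2, inter


def published_models() -> dict[str, dict[str, CalibrationModel]]:
    """The eight swim-tunnel calibration lines, as published.

    Keys: ``accel_vs_speed``, ``odba_vs_speed``, ``mo2_vs_accel``,
    ``mo2_vs_odba``; each maps ``steady`` / ``unsteady`` to a model.
    Acceleration-versus-speed lines were calibrated over 0.30-0.75 m s-1
    (burst-glide at 0.90 m s-1 breaks the linearity); ODBA lines over
    0.30-0.90 m s-1.
    """

    def m(slope, intercept, r2, xconv, yunit, cond, rng, desc):
        return CalibrationModel(
            slope=slope,
            intercept=intercept,
            r_squared=r2,
            x_convention=xconv,
            y_unit=yunit,
            flow_condition=cond,
            speed_range_mps=rng,
            provenance=f"swim-tunnel calibration, {cond} flow: {desc}",
        )

    accel_rng = (0.30, 0.75)
    odba_rng = (0.30, 0.90)
    return {
        "accel_vs_speed": {
            "steady": m(18.31, 3.88, 0.99, "speed_mps", "mg", "steady", accel_rng,
                        "external acceleration vs speed"),
            "unsteady": m(13.52, 6.99, 0.95, "speed_mps", "mg", "unsteady", accel_rng,
                          "external acceleration vs speed"),
        },
        "odba_vs_speed": {
            "steady": m(0.16, 0.54, 0.94, "speed_step_index", "ms2", "steady", odba_rng,
                        "ODBA vs speed-step index"),
            "unsteady": m(0.24, 0.53, 0.92, "speed_step_index", "ms2", "unsteady", odba_rng,
                          "ODBA vs speed-step index"),
        },
        "mo2_vs_accel": {
            "steady": m(4.17, 171.34, 0.56, "ext_accel_mg", "mg_kg_h", "steady", None,
                        "MO2 vs external acceleration"),
            "unsteady": m(6.85, 150.98, 0.79, "ext_accel_mg", "mg_kg_h", "unsteady", None,
                          "MO2 vs external acceleration"),
        },
        "mo2_vs_odba": {
            "steady": m(78.83, 151.99, 0.69, "odba_ms2", "mg_kg_h", "steady", None,
                        "MO2 vs ODBA"),
            "unsteady": m(59.94, 175.28, 0.71, "odba_ms2", "mg_kg_h", "unsteady", None,
                          "MO2 vs ODBA"),
        },
    }


def build_report(
    speed_mps: float,
    flow_condition: str,
    observed: dict | None = None,
    registry: dict | None = None,
) -> FieldEnergeticsReport:
    """Regression-transfer report for free-swimming fish at one speed."""
    if flow_condition not in ("steady", "unsteady"):
        raise ValueError("flow_condition must be 'steady' or 'unsteady'")
    reg = registry if registry is not None else published_models()
    accel = predict(reg["accel_vs_speed"][flow_condition], speed_mps).value
    odba_v = predict(reg["odba_vs_speed"][flow_condition], speed_mps).value
    mo2_a, _ = chain_predict_mo2(
        reg["accel_vs_speed"][flow_condition], reg["mo2_vs_accel"][flow_condition], speed_mps
    )
    mo2_o, _ = chain_predict_mo2(
        reg["odba_vs_speed"][flow_condition], reg["mo2_vs_odba"][flow_condition], speed_mps
    )
    return FieldEnergeticsReport(
        flow_condition=flow_condition,
        speed_mps=speed_mps,
        predicted_ext_accel_mg=accel,
        predicted_odba_ms2=odba_v,
        predicted_mo2_from_accel=mo2_a,
        predicted_mo2_from_odba=mo2_o,
        observed=dict(observed or {}),
    )
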