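"""Intermittent-flow swim-tunnel respirometry.

Oxygen consumption (MO2) is estimated from the linear decline of dissolved
oxygen during a closed measurement phase::

    MO2 = (dO2 / 100) * DO_max * V / (BM * t)      [mg kg-1 h-1]

where ``dO2`` is the percentage-saturation decline over the phase, ``DO_max``
the oxygen solubility at the working temperature/salinity (mg l-1), ``V`` the
respirometer volume (l), ``BM`` the fish body mass (kg) and ``t`` the phase
duration in hours.  Cost of transport divides MO2 by the distance swum per
hour, the critical swimming speed prorates the final increment of a ramped
speed test, and the optimal swimming speed is the vertex of a second-degree
polynomial fitted to COT versus speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RespiroConfig",
    "Mo2Record",
    "CotCurve",
    "UcritInput",
    "FishBiometrics",
    "compute_mo2",
    "iter_measure_phases",
    "session_summary",
    "subtract_background",
    "compute_cot",
    "fit_cot_curve",
    "compute_ucrit",
    "check_solid_blocking",
    "fulton_k",
]

#: minimum number of 2-s samples accepted for a slope fit
MIN_MEASURE_SAMPLES = 30

#: fraction of samples trimmed at each end of a measure phase (valve transients)
TRIM_FRACTION = 0.05

#: an estimated oxygen *increase* larger than this (% saturation over the
#: phase) is treated as a failed measurement rather than noise
POSITIVE_DECLINE_TOLERANCE = 0.1


@dataclass(frozen=True)
class RespiroConfig:
    """Chamber constants and protocol settings for one respirometry trial.

    Parameters
    ----------
    chamber_volume_l
        Respirometry measurement volume V in litres.
    do_max_mg_l
        Dissolved-oxygen content at 100% saturation, mg l-1.
    body_mass_kg
        Fish body mass BM in kg.
    speed_step_mps
        Prescribed velocity increment of the ramped test, m s-1.
    step_duration_min
        Prescribed time interval per velocity level, minutes.
    measure_duration_h
        Nominal closed measurement-phase duration, hours.
    """

    chamber_volume_l: float = 30.0
    do_max_mg_l: float = 8.0
    body_mass_kg: float = 0.46
    speed_step_mps: float = 0.15
    step_duration_min: float = 30.0
    measure_duration_h: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "chamber_volume_l",
            "do_max_mg_l",
            "body_mass_kg",
            "speed_step_mps",
            "step_duration_min",
            "measure_duration_h",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Mo2Record:
    """A single oxygen-consumption estimate at one swimming speed."""

    speed_mps: float
    mo2: float  # mg kg-1 h-1
    background_corrected: bool = False
    replicate: int = 1
    flagged: bool = False  # set when the O2 trace rose instead of declining


@dataclass(frozen=True)
class CotCurve:
    """Second-degree polynomial fit of COT versus swimming speed."""

    speeds: tuple
    cot: tuple
    poly_coeffs: tuple  # (c0, c1, c2), COT = c0 + c1*U + c2*U^2
    u_opt: float
    cot_min: float
    valid: bool


@dataclass(frozen=True)
class UcritInput:
    """Inputs of the prorated critical-swimming-speed formula."""

    u_i: float  # highest completed velocity, m s-1
    u_ii: float  # velocity increment, m s-1
    t_i: float  # time to fatigue at the final level, min
    t_ii: float  # prescribed interval, min

    def __post_init__(self) -> None:
        if self.u_ii <= 0:
            raise ValueError("u_ii must be > 0")
        if not 0 <= self.t_i <= self.t_ii:
            raise ValueError("t_i must satisfy 0 <= t_i <= t_ii")


@dataclass(frozen=True)
class FishBiometrics:
    body_mass_g: float
    standard_length_cm: float
    condition_factor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "condition_factor", fulton_k(self.body_mass_g, self.standard_length_cm)
        )


def compute_mo2(
    trace: pd.DataFrame,
    cfg: RespiroConfig,
    *,
    speed_mps: float | None = None,
    replicate: int = 1,
    trim_fraction: float = TRIM_FRACTION,
) -> Mo2Record:
    """Estimate MO2 from one closed measurement phase.

    ``trace`` must hold a single measure phase with columns ``time_s`` and
    ``do_percent`` (and optionally ``speed_mps``).  The percentage decline is
    taken as ``(-slope) * duration`` from an ordinary least-squares fit of
    saturation versus time, with the first and last 5% of samples trimmed to
    avoid valve transients.

    Raises
    ------
    ValueError
        If time is not strictly increasing or the phase has fewer than 30
        samples.  A significantly *positive* oxygen slope does not raise but
        returns a zero, flagged record with a warning.
    """
    time = np.asarray(trace["time_s"], dtype=float)
    do = np.asarray(trace["do_percent"], dtype=float)
    if time.size < MIN_MEASURE_SAMPLES:
        raise ValueError(
            f"measure phase has {time.size} samples; need >= {MIN_MEASURE_SAMPLES}"
        )
    if np.any(np.diff(time) <= 0):
        raise ValueError("time_s must be strictly increasing")

    if speed_mps is None:
        speed_mps = float(trace["speed_mps"].iloc[0]) if "speed_mps" in trace else float("nan")

    duration_s = time[-1] - time[0]
    n_trim = int(np.floor(trim_fraction * time.size))
    if n_trim:
        time_fit, do_fit = time[n_trim:-n_trim], do[n_trim:-n_trim]
    else:
        time_fit, do_fit = time, do
    slope = np.polyfit(time_fit, do_fit, 1)[0]  # % saturation per second

    delta_o2 = -slope * duration_s  # % decline over the full phase
    if delta_o2 < -POSITIVE_DECLINE_TOLERANCE:
        warnings.warn(
            f"oxygen rose by {-delta_o2:.2f}% during a measure phase; "
            "returning flagged zero MO2",
            stacklevel=2,
        )
        return Mo2Record(speed_mps=speed_mps, mo2=0.0, replicate=replicate, flagged=True)
    delta_o2 = max(delta_o2, 0.0)

    t_h = duration_s / 3600.0
    mo2 = (delta_o2 / 100.0) * cfg.do_max_mg_l * cfg.chamber_volume_l / (
        cfg.body_mass_kg * t_h
    )
    return Mo2Record(speed_mps=speed_mps, mo2=mo2, replicate=replicate)


def subtract_background(mo2: Mo2Record, background: Mo2Record) -> Mo2Record:
    """Subtract background (fish-free) respiration, clamping at zero.

    Both records must be expressed in mg kg-1 h-1 normalised by the
    experimental fish's body mass.
    """
    corrected = mo2.mo2 - background.mo2
    if corrected < 0:
        warnings.warn(
            f"background respiration ({background.mo2:.2f}) exceeds measured MO2 "
            f"({mo2.mo2:.2f}); clamping to 0",
            stacklevel=2,
        )
        corrected = 0.0
    return replace(mo2, mo2=corrected, background_corrected=True)


def compute_cot(mo2: float, speed_mps: float) -> float:
    """Cost of transport, mg kg-1 km-1: MO2 divided by speed in km h-1."""
    if speed_mps <= 0:
        raise ValueError("speed must be > 0 for COT")
    return mo2 / (speed_mps * 3.6)


def fit_cot_curve(records: list[tuple[float, float]]) -> CotCurve:
    """Fit COT = c0 + c1*U + c2*U^2 and locate the optimal swimming speed.

    The optimum is the vertex ``u_opt = -c1 / (2 c2)``; the fit is flagged
    invalid when the parabola opens downward or the vertex falls outside the
    tested speed range.
    """
    speeds = np.asarray([r[0] for r in records], dtype=float)
    cot = np.asarray([r[1] for r in records], dtype=float)
    if np.unique(speeds).size < 4:
        raise ValueError("need >= 4 distinct speeds for a COT curve")
    c2, c1, c0 = np.polyfit(speeds, cot, 2)
    valid = c2 > 0
    u_opt = -c1 / (2.0 * c2) if c2 != 0 else float("nan")
    cot_min = c0 + c1 * u_opt + c2 * u_opt**2
    if not (speeds.min() <= u_opt <= speeds.max()):
        valid = False
    return CotCurve(
        speeds=tuple(speeds),
        cot=tuple(cot),
        poly_coeffs=(c0, c1, c2),
        u_opt=float(u_opt),
        cot_min=float(cot_min),
        valid=bool(valid),
    )


def iter_measure_phases(trace: pd.DataFrame):
    """Yield ``(speed_mps, replicate, slice)`` for each contiguous measure phase.

    Replicates count from 1 within each speed.
    """
    is_measure = (trace["phase"] == "measure").to_numpy()
    block = np.cumsum(np.r_[0, np.diff(is_measure.astype(int)) != 0])
    reps: dict[float, int] = {}
    for _, grp in trace.groupby(block, sort=True):
        if grp["phase"].iloc[0] != "measure":
            continue
        speed = float(grp["speed_mps"].iloc[0])
        reps[speed] = reps.get(speed, 0) + 1
        yield speed, reps[speed], grp


def session_summary(
    trace: pd.DataFrame,
    cfg: RespiroConfig,
    background: Mo2Record | None = None,
) -> pd.DataFrame:
    """Per-speed MO2 (mean +/- s.e.m. across replicates) and COT.

    Runs ``compute_mo2`` on every measure phase, optionally subtracts
    background respiration, averages replicates with the mean, and derives
    COT from the per-speed mean.
    """
    records = []
    for speed, rep, grp in iter_measure_phases(trace):
        rec = compute_mo2(grp, cfg, speed_mps=speed, replicate=rep)
        if background is not None:
            rec = subtract_background(rec, background)
        records.append(rec)
    if not records:
        raise ValueError("trace contains no measure phases")
    df = pd.DataFrame({"speed_mps": [r.speed_mps for r in records],
                       "mo2": [r.mo2 for r in records]})
    out = df.groupby("speed_mps")["mo2"].agg(["mean", "sem", "count"]).reset_index()
    out = out.rename(columns={"mean": "mo2", "sem": "mo2_sem", "count": "n_replicates"})
    out["cot"] = [compute_cot(m, s) for m, s in zip(out["mo2"], out["speed_mps"])]
    return out


def compute_ucrit(inp: UcritInput) -> float:
    """Critical swimming speed: U_i + (t_i / t_ii) * U_ii."""
    return inp.u_i + (inp.t_i / inp.t_ii) * inp.u_ii


def check_solid_blocking(fish_cross_section_cm2: float, tunnel_cross_section_cm2: float) -> bool:
    """True when the fish occupies < 10% of the swim-section cross-section.

    Above that, a solid-blocking velocity correction would be required
    (not implemented here).
    """
    if fish_cross_section_cm2 <= 0 or tunnel_cross_section_cm2 <= 0:
        raise ValueError("cross-sections must be > 0")
    ratio = fish_cross_section_cm2 / tunnel_cross_section_cm2
    if ratio >= 1:
        raise ValueError("fish cross-section cannot fill or exceed the tunnel")
    return ratio < 0.10


def fulton_k(bm_g: float, sl_cm: float) -> float:
    """Fulton's condition factor K = 100 * BM[g] / SL[cm]^3."""
    if bm_g <= 0 or sl_cm <= 0:
        raise ValueError("body mass and standard length must be > 0")
    return 100.0 * bm_g / sl_cm**3
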