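"""Activity metrics from triaxial accelerometry.

A body-mounted accelerometer measures gravity (static) plus locomotor
(dynamic) acceleration on the surge (x), sway (y) and heave (z) axes.  The
static component is estimated with a centred running mean and removed; two
standard activity summaries are computed from the dynamic residual:

* external acceleration — the interval mean of the Euclidean norm
  sqrt(dx^2 + dy^2 + dz^2), reported in milli-g (m*g*), the archival-tag
  convention;
* ODBA (overall dynamic body acceleration) — the interval mean of the L1 sum
  |dx| + |dy| + |dz|, reported in m s-2 (g = 9.81 m s-2), the acoustic-tag
  convention.

VAR is the sample variance of successive external-acceleration values within
an aggregation interval (m*g*^2); sustained values above ~222 m*g*^2 indicate
burst-coast or erratic swimming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TriaxialTrace",
    "split_static_dynamic",
    "external_acceleration",
    "odba",
    "var_acceleration",
    "flag_erratic",
    "aggregate_activity",
]

G_MS2 = 9.81
DEFAULT_WINDOW_S = 3.0
VAR_ERRATIC_THRESHOLD_MG2 = 222.0


@dataclass(frozen=True)
class TriaxialTrace:
    """Raw triaxial acceleration in units of g (surge, sway, heave)."""

    time_s: np.ndarray
    ax_g: np.ndarray
    ay_g: np.ndarray
    az_g: np.ndarray
    rate_hz: float = 25.0

    def __post_init__(self) -> None:
        for name in ("time_s", "ax_g", "ay_g", "az_g"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time_s.size
        if not (self.ax_g.size == self.ay_g.size == self.az_g.size == n):
            raise ValueError("axes and time must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    @property
    def axes(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.ax_g, self.ay_g, self.az_g])


def split_static_dynamic(
    trace: TriaxialTrace, window_s: float = DEFAULT_WINDOW_S
) -> tuple[np.ndarray, np.ndarray]:
    """Separate gravity from locomotion with a centred running mean.

    Returns ``(static, dynamic)`` as (n, 3) arrays in g; ``static + dynamic``
    reconstructs the raw signal exactly.  The window must span at least two
    samples and must not exceed the trace.
    """
    if window_s < 2.0 / trace.rate_hz:
        raise ValueError("window must cover at least 2 samples")
    n_win = int(round(window_s * trace.rate_hz))
    n_win = max(n_win, 2)
    raw = trace.axes
    if n_win > raw.shape[0]:
        raise ValueError("trace shorter than the smoothing window")
    static = (
        pd.DataFrame(raw)
        .rolling(n_win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return static, raw - static


def external_acceleration(dynamic: np.ndarray) -> float:
    """Mean Euclidean norm of the dynamic vector, in milli-g."""
    dynamic = np.atleast_2d(np.asarray(dynamic, dtype=float))
    if dynamic.shape[0] == 0:
        raise ValueError("empty interval")
    return float(np.mean(np.linalg.norm(dynamic, axis=1))) * 1000.0


def odba(dynamic: np.ndarray) -> float:
    """Mean L1 sum of the dynamic axes, converted from g to m s-2."""
    dynamic = np.atleast_2d(np.asarray(dynamic, dtype=float))
    if dynamic.shape[0] == 0:
        raise ValueError("empty interval")
    return float(np.mean(np.sum(np.abs(dynamic), axis=1))) * G_MS2


def var_acceleration(ext_accel_samples_mg: np.ndarray) -> float:
    """Sample variance (ddof=1) of external-acceleration values, m*g*^2."""
    x = np.asarray(ext_accel_samples_mg, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 samples for a variance")
    return float(np.var(x, ddof=1))


def flag_erratic(var_value_mg2: float, threshold_mg2: float = VAR_ERRATIC_THRESHOLD_MG2) -> bool:
    """True when VAR strictly exceeds the burst-coast/distress threshold."""
    if var_value_mg2 < 0:
        raise ValueError("VAR cannot be negative")
    return var_value_mg2 > threshold_mg2


def aggregate_activity(
    trace: TriaxialTrace,
    interval_s: float,
    window_s: float = DEFAULT_WINDOW_S,
) -> pd.DataFrame:
    """Per-interval activity summaries of a triaxial stream.

    Splits the trace into consecutive intervals of ``interval_s`` seconds and
    returns one row per complete interval with columns ``time_s`` (interval
    start), ``ext_accel_mg``, ``odba_ms2`` and ``var_mg2`` (variance of 1-s
    external-acceleration sub-samples within the interval; NaN when fewer
    than two fit).
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    _, dyn = split_static_dynamic(trace, window_s)
    n_per = int(round(interval_s * trace.rate_hz))
    if n_per < 1:
        raise ValueError("interval shorter than one sample")
    n_sub = max(int(round(trace.rate_hz)), 1)  # 1-s sub-samples for VAR
    rows = []
    for start in range(0, dyn.shape[0] - n_per + 1, n_per):
        chunk = dyn[start : start + n_per]
        subs = [
            external_acceleration(chunk[i : i + n_sub])
            for i in range(0, n_per - n_sub + 1, n_sub)
        ]
        rows.append(
            {
                "time_s": float(trace.time_s[start]),
                "ext_accel_mg": external_acceleration(chunk),
                "odba_ms2": odba(chunk),
                "var_mg2": var_acceleration(subs) if len(subs) >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
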