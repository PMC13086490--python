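"""Synthetic sensor streams with controllable ground truth.

Every input the pipeline consumes can be generated here with the true
quantity returned alongside the data, so each stage has a closed-loop
recovery test.  Generator defaults encode the study conditions they emulate:

* respirometry — intermittent-flow cycles (5 min acclimation / 15 min
  measure / 10 min flush, 2 s oxygen sampling) at speeds 0.30-0.90 m s-1 in
  0.15 m s-1 steps, with true MO2 rising linearly from 213 to 307
  mg kg-1 h-1 and 0.5% saturation sensor noise;
* ECG — 7.5 s, 200 Hz bursts built from a Gaussian P-QRS-T template with
  additive noise and optional dropout/spike artifacts;
* triaxial acceleration — gravity on heave plus a tail-beat sinusoid on sway
  whose rectified mean (2A/pi) matches the swim-tunnel calibration line at
  the requested speed, with burst-glide attenuation above 0.75 m s-1;
* sentinel telemetry — 10-min epochs for 2 weeks of steady then 2 weeks of
  unsteady flow, per-fish random intercepts, day/night cell means set to the
  tank-study values, and feeding-time bumps at 09:00/16:00 that are
  mean-centred within each day/night class so cell means hold in
  expectation;
* transmitter detections — epochs with gaps uniform on [30, 50] s carrying
  the ODBA aggregated since the previous detection.

All draws come from one ``numpy`` Generator per call; identical seeds give
identical outputs.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd

from .cardio import EcgBurst
from .flow import generate_flow  # noqa: F401  (re-exported: flow is an input stream too)
from .kinematics import TriaxialTrace
from .models import published_models, predict
from .respirometry import RespiroConfig

__all__ = [
    "PROTOCOL_SPEEDS",
    "DEFAULT_TRUE_MO2",
    "SENTINEL_CELL_MEANS",
    "gen_respiro_session",
    "gen_ecg",
    "gen_triaxial",
    "gen_sentinel",
    "gen_transmitter_stream",
    "generate_flow",
]

#: ramped-test speeds (m s-1); 0.15 is the acclimation speed
PROTOCOL_SPEEDS = (0.30, 0.45, 0.60, 0.75, 0.90)

#: true MO2 per speed, mg kg-1 h-1 (linear between the study's endpoints)
DEFAULT_TRUE_MO2 = {0.30: 213.0, 0.45: 236.5, 0.60: 260.0, 0.75: 283.5, 0.90: 307.0}

#: mean external acceleration at 0.90 m s-1 once burst-glide sets in, m*g*
BURST_GLIDE_EXT_MG = {"steady": 14.30, "unsteady": 15.31}

#: sentinel cell means per metric: {(treatment, period): mean}
SENTINEL_CELL_MEANS = {
    "hr_bpm": {
        ("steady", "day"): 71.10,
        ("steady", "night"): 60.50,
        ("unsteady", "day"): 73.20,
        ("unsteady", "night"): 62.50,
    },
    "ext_accel_mg": {
        ("steady", "day"): 12.90,
        ("steady", "night"): 10.10,
        ("unsteady", "day"): 14.60,
        ("unsteady", "night"): 11.80,
    },
    "var_mg2": {
        ("steady", "day"): 90.0,
        ("steady", "night"): 51.0,
        ("unsteady", "day"): 128.0,
        ("unsteady", "night"): 86.0,
    },
    "odba_ms2": {
        ("steady", "day"): 1.10,
        ("steady", "night"): 0.86,
        ("unsteady", "day"): 1.13,
        ("unsteady", "night"): 0.88,
    },
}

SENTINEL_INTERCEPT_SD = {"hr_bpm": 4.0, "ext_accel_mg": 1.5, "var_mg2": 8.0, "odba_ms2": 0.05}
SENTINEL_RESID_SD = {"hr_bpm": 6.0, "ext_accel_mg": 3.0, "var_mg2": 20.0, "odba_ms2": 0.08}
SENTINEL_FEED_AMP = {"hr_bpm": 4.0, "ext_accel_mg": 1.5, "var_mg2": 15.0, "odba_ms2": 0.06}
FEED_TIMES_H = (9.0, 16.0)
FEED_SD_H = 1.5


def _rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def gen_respiro_session(
    true_mo2_by_speed: dict[float, float] | None = None,
    cfg: RespiroConfig | None = None,
    noise_sd_pct: float = 0.5,
    n_replicates: int = 3,
    sample_dt_s: float = 2.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Oxygen trace for a full ramped swim test.

    Each speed gets ``n_replicates`` cycles of 5 min acclimation, 15 min
    closed measurement and 10 min flush.  During measurement, saturation
    declines linearly with the slope implied by inverting the MO2 formula
    for the true rate; flush restores ~100% saturation.  Returns the trace
    (columns ``time_s, do_percent, phase, speed_mps``) and a truth dict.
    """
    cfg = cfg or RespiroConfig()
    truth = dict(true_mo2_by_speed or DEFAULT_TRUE_MO2)
    rng = _rng(seed, rng)
    rows = []
    t = 0.0
    phase_lens = (("acclimation", 300.0), ("measure", 900.0), ("flush", 600.0))
    for speed, mo2 in truth.items():
        # %-saturation decline per second that compute_mo2 inverts back to mo2
        slope = mo2 * cfg.body_mass_kg / (36.0 * cfg.do_max_mg_l * cfg.chamber_volume_l)
        for _rep in range(n_replicates):
            for phase, length in phase_lens:
                n = int(round(length / sample_dt_s))
                tt = t + np.arange(n) * sample_dt_s
                if phase == "measure":
                    do = 100.0 - slope * (tt - tt[0])
                else:
                    do = np.full(n, 100.0)
                if noise_sd_pct > 0:
                    do = do + rng.normal(0.0, noise_sd_pct, size=n)
                rows.append(
                    pd.DataFrame(
                        {"time_s": tt, "do_percent": do, "phase": phase, "speed_mps": speed}
                    )
                )
                t = tt[-1] + sample_dt_s
    trace = pd.concat(rows, ignore_index=True)
    return trace, {"true_mo2": truth, "cfg": cfg, "noise_sd_pct": noise_sd_pct}


def gen_ecg(
    hr_bpm: float,
    duration_s: float = 7.5,
    rate_hz: float = 200.0,
    noise_sd: float = 0.0,
    artifact_prob: float = 0.0,
    artifact: str = "dropout",
    artifact_span_s: float = 1.5,
    timestamp: datetime | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[EcgBurst, np.ndarray]:
    """One ECG burst plus its true R-peak times.

    The waveform sums Gaussian P, Q, R, S and T lobes per beat (R amplitude
    1, so ``noise_sd`` is relative to the R wave).  With probability
    ``artifact_prob`` a dropout (zeroed segment) or spike is injected; an
    ``artifact_span_s`` covering the whole burst produces a flat record.
    """
    if not 30.0 <= hr_bpm <= 150.0:
        raise ValueError("hr_bpm outside the supported 30-150 range")
    rng = _rng(seed, rng)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    period = 60.0 / hr_bpm
    peaks = np.arange(0.3, duration_s, period)

    waves = ((0.15, -0.16, 0.020), (-0.10, -0.024, 0.008), (1.00, 0.0, 0.008),
             (-0.15, 0.024, 0.008), (0.25, 0.22, 0.035))
    x = np.zeros(n)
    for tr in peaks:
        for amp, off, sd in waves:
            x += amp * np.exp(-((t - tr - off) ** 2) / (2 * sd**2))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    if artifact_prob > 0 and rng.random() < artifact_prob:
        span = min(artifact_span_s, duration_s)
        start = 0.0 if span >= duration_s else rng.uniform(0.0, duration_s - span)
        sl = slice(int(start * rate_hz), int((start + span) * rate_hz))
        if artifact == "dropout":
            x[sl] = 0.0
        else:  # spike
            x[sl] += rng.normal(0.0, 3.0, size=x[sl].size)
    return EcgBurst(samples=x, rate_hz=rate_hz, timestamp=timestamp), peaks


def gen_triaxial(
    speed_mps: float,
    flow_condition: str = "steady",
    duration_s: float = 30.0,
    rate_hz: float = 25.0,
    noise_sd_g: float = 5e-4,
    burst_glide: bool | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[TriaxialTrace, dict]:
    """Tail-beat acceleration stream at one swimming speed.

    Gravity (1 g) sits on heave; sway carries a sinusoid at tail-beat
    frequency ``1 + 2*speed`` Hz whose amplitude A satisfies
    ``1000 * 2A/pi = `` the calibration-line external acceleration at this
    speed.  Above 0.75 m s-1 burst-glide attenuation caps the target at the
    observed 0.90 m s-1 means.  Truth reports the target metric, amplitude
    and frequency.
    """
    if speed_mps < 0:
        raise ValueError("speed must be >= 0")
    rng = _rng(seed, rng)
    if burst_glide is None:
        burst_glide = speed_mps > 0.75
    if speed_mps == 0:
        target_mg = 0.0
    elif burst_glide and speed_mps > 0.75:
        target_mg = BURST_GLIDE_EXT_MG[flow_condition]
    else:
        model = published_models()["accel_vs_speed"][flow_condition]
        target_mg = predict(model, speed_mps).value
    amp_g = target_mg * np.pi / 2000.0
    freq = 1.0 + 2.0 * speed_mps
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    ax = np.zeros(n)
    ay = amp_g * np.sin(2 * np.pi * freq * t)
    az = np.ones(n)
    if noise_sd_g > 0:
        ax = ax + rng.normal(0.0, noise_sd_g, n)
        ay = ay + rng.normal(0.0, noise_sd_g, n)
        az = az + rng.normal(0.0, noise_sd_g, n)
    trace = TriaxialTrace(time_s=t, ax_g=ax, ay_g=ay, az_g=az, rate_hz=rate_hz)
    truth = {
        "target_ext_accel_mg": target_mg,
        "amplitude_g": amp_g,
        "tailbeat_hz": freq,
        "burst_glide": bool(burst_glide and speed_mps > 0.75),
    }
    return trace, truth


def gen_sentinel(
    n_fish: int = 10,
    weeks_per_phase: float = 2.0,
    epoch_min: float = 10.0,
    cell_means: dict | None = None,
    intercept_sd: dict | None = None,
    resid_sd: dict | None = None,
    feed_amp: dict | None = None,
    feed_times_h: tuple = FEED_TIMES_H,
    feed_sd_h: float = FEED_SD_H,
    start: str | datetime = "2023-09-18",
    day_hours: tuple[int, int] = (6, 17),
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Hourly-pattern telemetry for sentinel fish across two flow phases.

    Each metric value is ``cell mean + centred feeding bump + fish intercept
    + residual noise``.  The feeding bumps (Gaussian in clock time at the
    feeding hours) are mean-centred within each day/night class, so the
    configured cell means are reproduced in expectation while the hourly
    profile keeps its M shape.  VAR is clamped at zero.  Truth includes the
    implied day-night and treatment effects per metric.
    """
    if n_fish < 2:
        raise ValueError("need >= 2 sentinel fish")
    rng = _rng(seed, rng)
    cells = {m: dict(v) for m, v in SENTINEL_CELL_MEANS.items()}
    if cell_means:
        for m, v in cell_means.items():
            cells[m].update(v)
    isd = {**SENTINEL_INTERCEPT_SD, **(intercept_sd or {})}
    rsd = {**SENTINEL_RESID_SD, **(resid_sd or {})}
    famp = {**SENTINEL_FEED_AMP, **(feed_amp or {})}
    metrics = list(cells)

    epochs_per_phase = int(round(weeks_per_phase * 7 * 24 * 60 / epoch_min))
    start_ts = pd.Timestamp(start)
    ts = start_ts + pd.to_timedelta(
        np.arange(2 * epochs_per_phase) * epoch_min, unit="min"
    )
    treatment = np.where(np.arange(ts.size) < epochs_per_phase, "steady", "unsteady")
    hour_frac = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    is_day = (ts.hour >= day_hours[0]) & (ts.hour <= day_hours[1])

    bump = np.zeros(ts.size)
    for tf in feed_times_h:
        bump += np.exp(-((hour_frac - tf) ** 2) / (2 * feed_sd_h**2))
    centred = bump.copy()
    steady_mask = np.arange(ts.size) < epochs_per_phase
    for phase_mask in (steady_mask, ~steady_mask):
        for period_mask in (np.asarray(is_day), ~np.asarray(is_day)):
            cell = phase_mask & period_mask
            if cell.any():
                centred[cell] -= centred[cell].mean()

    intercepts = {m: rng.normal(0.0, isd[m], size=n_fish) for m in metrics}
    frames = []
    for f in range(n_fish):
        df = pd.DataFrame({"fish_id": f"fish{f + 1:02d}", "timestamp": ts, "treatment": treatment})
        for m in metrics:
            base = np.array(
                [cells[m][(tr, "day" if d else "night")] for tr, d in zip(treatment, is_day)]
            )
            val = base + famp[m] * centred + intercepts[m][f]
            val = val + rng.normal(0.0, rsd[m], size=ts.size)
            if m == "var_mg2":
                val = np.clip(val, 0.0, None)
            df[m] = val
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)

    truth = {"cell_means": cells, "intercepts": intercepts, "intercept_sd": isd,
             "resid_sd": rsd}
    truth["period_effect"] = {
        m: np.mean(
            [cells[m][(tr, "day")] - cells[m][(tr, "night")] for tr in ("steady", "unsteady")]
        )
        for m in metrics
    }
    truth["treatment_effect"] = {
        m: np.mean(
            [cells[m][("unsteady", p)] - cells[m][("steady", p)] for p in ("day", "night")]
        )
        for m in metrics
    }
    return data, truth


def gen_transmitter_stream(
    time_s: np.ndarray,
    odba_ms2: np.ndarray,
    min_gap_s: float = 30.0,
    max_gap_s: float = 50.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Acoustic-transmitter detections from a continuous ODBA series.

    Detection epochs arrive with gaps uniform on [min_gap, max_gap] seconds;
    each detection carries the mean ODBA since the previous epoch.
    """
    time_s = np.asarray(time_s, dtype=float)
    odba_ms2 = np.asarray(odba_ms2, dtype=float)
    if time_s.size != odba_ms2.size:
        raise ValueError("time and ODBA series must align")
    if time_s[-1] - time_s[0] <= max_gap_s:
        raise ValueError("series must be longer than the maximum gap")
    rng = _rng(seed, rng)
    rows = []
    prev = time_s[0]
    t = prev + rng.uniform(min_gap_s, max_gap_s)
    while t <= time_s[-1]:
        mask = (time_s > prev) & (time_s <= t)
        rows.append({"time_s": t, "odba_ms2": float(np.mean(odba_ms2[mask]))})
        prev = t
        t = t + rng.uniform(min_gap_s, max_gap_s)
    return pd.DataFrame(rows)
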