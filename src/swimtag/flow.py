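"""Steady and sinusoidal flow-speed series.

Unsteady (tidal/wave-like) flow is modelled as a unidirectional sinusoid,
u(t) = mean + A sin(2 pi t / T + phi).  The tank protocol modulates
0.50 +/- 0.05 m s-1 with a 100 s period; the swim-tunnel protocol uses
+/- 0.1 m s-1 with a 12 s period.  ``fit_sinusoid`` recovers the parameters
from a measured series by nonlinear least squares with FFT initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FlowProfile", "SinusoidFit", "generate_flow", "fit_sinusoid"]


@dataclass(frozen=True)
class FlowProfile:
    mean_speed: float
    amplitude: float
    period_s: float
    phase_rad: float
    dt_s: float
    time_s: np.ndarray
    speed_mps: np.ndarray


@dataclass(frozen=True)
class SinusoidFit:
    mean_speed: float
    amplitude: float
    period_s: float
    phase_rad: float
    residual_sd: float
    converged: bool
    period_identifiable: bool


def generate_flow(
    mean: float,
    amplitude: float,
    period_s: float,
    duration_s: float,
    dt_s: float = 1.0,
    noise_sd: float = 0.0,
    phase_rad: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FlowProfile:
    """Sinusoidal set-point plus optional Gaussian measurement noise.

    ``amplitude = 0`` yields steady flow.  The time step must resolve the
    wave: ``dt_s >= period_s / 2`` is rejected.
    """
    if amplitude < 0 or period_s <= 0 or duration_s <= 0 or dt_s <= 0:
        raise ValueError("amplitude >= 0 and period, duration, dt > 0 required")
    if dt_s >= period_s / 2:
        raise ValueError("dt must be < period/2 to resolve the wave")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(0.0, duration_s, dt_s)
    u = mean + amplitude * np.sin(2 * np.pi * t / period_s + phase_rad)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        u = u + rng.normal(0.0, noise_sd, size=t.size)
    return FlowProfile(mean, amplitude, period_s, phase_rad, dt_s, t, u)


def _model(t, mean, amp, period, phase):
    return mean + amp * np.sin(2 * np.pi * t / period + phase)


def fit_sinusoid(speed_mps: np.ndarray, dt_s: float) -> SinusoidFit:
    """Least-squares sinusoid fit with FFT period initialisation.

    The dominant FFT bin and its two neighbours seed a multi-start
    Levenberg-Marquardt fit; the best solution by residual sum of squares is
    normalised to amplitude >= 0, phase in [0, 2 pi).  The period is flagged
    unidentifiable when the fitted amplitude does not stand clear of the
    residual noise floor.
    """
    u = np.asarray(speed_mps, dtype=float)
    if u.size < 8:
        raise ValueError("series too short to fit a sinusoid")
    t = np.arange(u.size) * dt_s
    mean0 = float(np.mean(u))
    resid = u - mean0

    spec = np.abs(np.fft.rfft(resid))
    freqs = np.fft.rfftfreq(u.size, dt_s)
    k = int(np.argmax(spec[1:])) + 1  # skip DC
    candidates = {k + d for d in (-1, 0, 1) if 1 <= k + d < freqs.size}

    best = None
    amp0 = float(np.sqrt(2.0) * np.std(resid))
    for kc in sorted(candidates):
        period0 = 1.0 / freqs[kc]
        phase0 = float(np.angle(np.fft.rfft(resid)[kc]) + np.pi / 2)
        try:
            popt, _ = curve_fit(
                _model,
                t,
                u,
                p0=[mean0, amp0, period0, phase0],
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((u - _model(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)

    if best is None:
        return SinusoidFit(mean0, 0.0, float("nan"), 0.0, float(np.std(resid)), False, False)

    sse, (mean, amp, period, phase) = best
    if amp < 0:
        amp, phase = -amp, phase + np.pi
    phase = float(np.mod(phase, 2 * np.pi))
    period = float(abs(period))
    resid_sd = float(np.sqrt(sse / u.size))
    # amplitude must beat its own standard error by a wide margin for the
    # period to mean anything
    amp_se = resid_sd * np.sqrt(2.0 / u.size)
    identifiable = amp > 5.0 * amp_se
    return SinusoidFit(float(mean), float(amp), period, phase, resid_sd, True, identifiable)
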