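"""Heart rate from short ECG bursts.

Implanted archival tags record 7.5 s of ECG at 200 Hz every few minutes and
reduce each burst to a heart rate plus a 4-level quality index (QI0 excellent
... QI3 no R-R interval detected).  This module reproduces that reduction with
a Pan-Tompkins-style detector sized for short bursts: zero-phase band-pass,
squared derivative, adaptive threshold, refractory period, then HR from the
mean R-R interval.

QI thresholds operate on the coefficient of variation of the R-R intervals
and are calibration choices (the onboard algorithm is proprietary); they are
exposed as arguments.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy import signal

__all__ = [
    "EcgBurst",
    "HrRecord",
    "detect_r_peaks",
    "estimate_hr",
    "assign_qi",
    "burst_to_record",
    "filter_hr",
]

REFRACTORY_S = 0.2  # physiological minimum R-R spacing accepted
QI_CV_EXCELLENT = 0.05
QI_CV_GOOD = 0.15


@dataclass(frozen=True)
class EcgBurst:
    """A single ECG recording window (nominally 7.5 s at 200 Hz)."""

    samples: np.ndarray
    rate_hz: float = 200.0
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ValueError("ECG samples must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz


@dataclass(frozen=True)
class HrRecord:
    """Heart rate derived from one burst, with its quality index."""

    timestamp: datetime | None
    hr_bpm: float | None
    qi: int
    n_peaks: int = 0
    source: str = "derived"
    review_flag: bool = False

    def __post_init__(self) -> None:
        if self.qi not in (0, 1, 2, 3):
            raise ValueError("qi must be in {0, 1, 2, 3}")
        if self.qi == 3 and self.hr_bpm is not None:
            raise ValueError("QI3 records carry no heart rate")
        if self.hr_bpm is not None and self.hr_bpm <= 0:
            raise ValueError("hr_bpm must be > 0 when present")


def detect_r_peaks(
    burst: EcgBurst,
    *,
    band_hz: tuple[float, float] = (5.0, 40.0),
    threshold_frac: float = 0.4,
    threshold_percentile: float = 98.0,
    refractory_s: float = REFRACTORY_S,
) -> np.ndarray:
    """Detect R-peak times (seconds from burst start).

    Band-passed signal -> squared derivative -> peaks above
    ``threshold_frac`` x the ``threshold_percentile``-th percentile, spaced by
    the refractory period; each candidate is then refined to the local extremum
    of the band-passed waveform.  Relative thresholds make the detector
    amplitude-invariant.  A flat or pure-noise burst yields an empty array.
    """
    x = burst.samples
    fs = burst.rate_hz
    if x.size < 10 or np.ptp(x) == 0:
        return np.array([])

    sos = signal.butter(2, band_hz, btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    feat = np.gradient(bp) ** 2
    thr = threshold_frac * np.percentile(feat, threshold_percentile)
    if thr <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(feat, height=thr, distance=max(1, int(refractory_s * fs)))
    if idx.size == 0:
        return np.array([])

    # refine to the nearest extremum of |band-passed| within +/- 50 ms
    half = max(1, int(0.05 * fs))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)

    # enforce refractory spacing after refinement (keep the larger peak)
    kept: list[int] = []
    for i in refined:
        if kept and (i - kept[-1]) / fs < refractory_s:
            if np.abs(bp[i]) > np.abs(bp[kept[-1]]):
                kept[-1] = int(i)
        else:
            kept.append(int(i))
    return np.asarray(kept) / fs


def estimate_hr(peak_times_s: np.ndarray) -> float | None:
    """Heart rate as 60 / mean R-R interval; None when < 2 peaks.

    The mean R-R interval is preferred over peak counting because a 7.5 s
    window truncates partial beats at both edges.
    """
    peaks = np.asarray(peak_times_s, dtype=float)
    if peaks.size < 2:
        return None
    return 60.0 / float(np.mean(np.diff(peaks)))


def assign_qi(
    peak_times_s: np.ndarray,
    *,
    cv_excellent: float = QI_CV_EXCELLENT,
    cv_good: float = QI_CV_GOOD,
) -> int:
    """Quality index from R-R regularity.

    QI3 when fewer than two peaks were found; otherwise the coefficient of
    variation of the R-R intervals maps to QI0 (< ``cv_excellent``),
    QI1 (< ``cv_good``) or QI2.
    """
    peaks = np.asarray(peak_times_s, dtype=float)
    if peaks.size < 2:
        return 3
    rr = np.diff(peaks)
    cv = float(np.std(rr) / np.mean(rr))
    if cv < cv_excellent:
        return 0
    if cv < cv_good:
        return 1
    return 2


def burst_to_record(burst: EcgBurst, **detect_kwargs) -> HrRecord:
    """Full reduction of one burst: detect, rate, quality index."""
    peaks = detect_r_peaks(burst, **detect_kwargs)
    qi = assign_qi(peaks)
    hr = estimate_hr(peaks) if qi < 3 else None
    return HrRecord(
        timestamp=burst.timestamp,
        hr_bpm=hr,
        qi=qi,
        n_peaks=int(np.asarray(peaks).size),
        review_flag=qi in (1, 2),
    )


def filter_hr(records: list[HrRecord]) -> tuple[list[HrRecord], list[HrRecord], list[HrRecord]]:
    """Partition records into (kept, review_flagged, dropped).

    QI3 records are dropped; QI1/QI2 records are kept but flagged for manual
    review; QI0 records pass unflagged.
    """
    kept: list[HrRecord] = []
    flagged: list[HrRecord] = []
    dropped: list[HrRecord] = []
    for rec in records:
        if rec.qi == 3:
            dropped.append(rec)
            continue
        if rec.qi in (1, 2):
            rec = HrRecord(
                timestamp=rec.timestamp,
                hr_bpm=rec.hr_bpm,
                qi=rec.qi,
                n_peaks=rec.n_peaks,
                source=rec.source,
                review_flag=True,
            )
            flagged.append(rec)
        kept.append(rec)
    return kept, flagged, dropped
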