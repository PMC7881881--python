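"""Autonomic metrics from raw physiological channels.

Heart beats are localized in the ECG with the Pan-Tompkins chain (band-pass,
differentiate, square, moving-window integrate, adaptive dual thresholds with
a refractory period and search-back).  From the beat times we compute the
average heart rate (HR, bpm) and the root mean square of successive
RR-interval differences (RMSSD, ms — a time-domain vagal index) per
three-minute window; from the galvanic skin response the mean skin
conductance level (SCL, uS).  All metrics are reported relative to the
three-minute pre-exposure baseline as ΔHR, ΔRMSSD, ΔSCL.

Window membership: an RR interval belongs to a half-open window
``[start, end)`` iff both of its bounding beats fall inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .types import PhysioRecord

__all__ = [
    "detect_r_peaks",
    "heart_rate",
    "rmssd",
    "scl",
    "PhysioMetrics",
    "baseline_deltas",
    "window_metrics",
]


@dataclass
class PhysioMetrics:
    """Per-window autonomic metrics; NaN marks an undefined (flagged) value."""

    hr: float  # bpm
    rmssd: float  # ms
    scl: float  # uS
    window: tuple  # (start s, end s)


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------

def detect_r_peaks(
    ecg: PhysioRecord,
    zero_phase: bool = True,
    max_rr_jump: float | None = None,
) -> np.ndarray:
    """Pan-Tompkins beat localization; returns strictly increasing R-peak
    times in seconds.

    The chain: 5-15 Hz band-pass (zero-phase by default, to avoid beat-time
    bias; set ``zero_phase=False`` for the original causal filters),
    differentiation, squaring, 150 ms moving-window integration, then
    adaptive dual-threshold peak picking with a 200 ms refractory period and
    a search-back pass at half threshold when an expected beat is missed.
    Each detection is refined to the local maximum of the band-passed signal.

    ``max_rr_jump`` optionally rejects beats implying an RR change larger
    than this factor of the running RR average (no rejection by default).
    """
    if ecg.channel != "ECG":
        raise ValueError("detect_r_peaks requires an ECG channel")
    fs = ecg.rate
    if fs < 100:
        raise ValueError("sampling rate too low to resolve QRS (< 100 Hz)")
    x = ecg.values
    if len(x) < 5 * fs:
        raise ValueError("need at least 5 s of ECG")
    if np.ptp(x) == 0:
        warnings.warn("flat ECG signal: no beats detected", stacklevel=2)
        return np.array([])

    sos = _sig.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = _sig.sosfiltfilt(sos, x) if zero_phase else _sig.sosfilt(sos, x)

    deriv = np.gradient(bp) * fs
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integ = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    # candidate local maxima of the integrated signal
    cand, _ = _sig.find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        warnings.warn("no candidate peaks found", stacklevel=2)
        return np.array([])

    # adaptive thresholds (signal / noise running estimates)
    spki = float(np.percentile(integ[cand], 75)) * 0.5
    npki = float(np.percentile(integ[cand], 25)) * 0.5
    beats: list[int] = []
    rr_hist: list[float] = []

    def _accept(i: int) -> None:
        nonlocal spki
        spki = 0.125 * integ[i] + 0.875 * spki
        beats.append(i)
        if len(beats) > 1:
            rr_hist.append((beats[-1] - beats[-2]) / fs)
            del rr_hist[:-8]

    k = 0
    while k < len(cand):
        i = cand[k]
        thr = npki + 0.25 * (spki - npki)
        if integ[i] >= thr and (not beats or i - beats[-1] >= refractory):
            _accept(i)
        else:
            npki = 0.125 * integ[i] + 0.875 * npki
        # search-back: if the gap since the last beat exceeds 1.66x the
        # running RR average, accept the best missed candidate at half
        # threshold
        if beats and rr_hist:
            rr_avg = float(np.mean(rr_hist))
            if (i - beats[-1]) / fs > 1.66 * rr_avg:
                lo, hi = beats[-1] + refractory, i
                missed = [
                    j
                    for j in cand
                    if lo <= j < hi and integ[j] >= 0.5 * thr
                ]
                if missed:
                    j = max(missed, key=lambda m: integ[m])
                    if j - beats[-1] >= refractory and i - j >= refractory:
                        beats.append(j)
                        beats.sort()
                        spki = 0.125 * integ[j] + 0.875 * spki
        k += 1

    # refine each detection to the band-passed local maximum
    half = int(round(0.10 * fs))
    refined = []
    for i in sorted(set(beats)):
        lo, hi = max(i - half, 0), min(i + half + 1, len(bp))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = sorted(set(refined))

    # enforce refractory after refinement
    out: list[int] = []
    for i in refined:
        if out and i - out[-1] < refractory:
            if bp[i] > bp[out[-1]]:
                out[-1] = i
        else:
            out.append(i)

    times = np.asarray(out, dtype=float) / fs
    if max_rr_jump is not None and len(times) > 2:
        keep = [0, 1]
        for k in range(2, len(times)):
            rr_prev = times[keep[-1]] - times[keep[-2]]
            rr_new = times[k] - times[keep[-1]]
            if rr_new <= max_rr_jump * rr_prev:
                keep.append(k)
        times = times[keep]
    return times


# ---------------------------------------------------------------------------
# Windowed metrics
# ---------------------------------------------------------------------------

def _window_rr(beats: np.ndarray, window: tuple) -> np.ndarray:
    """RR intervals (s) whose bounding beats both fall in [start, end)."""
    beats = np.asarray(beats, dtype=float)
    start, end = window
    inside = beats[(beats >= start) & (beats < end)]
    return np.diff(inside)


def heart_rate(beats: np.ndarray, window: tuple) -> float:
    """Average heart rate in bpm over a window: 60 * n_intervals / sum(RR).

    Returns NaN (flagged undefined) with fewer than 2 beats in the window.
    """
    rr = _window_rr(beats, window)
    if len(rr) < 1:
        warnings.warn("fewer than 2 beats in window: HR undefined", stacklevel=2)
        return float("nan")
    return float(60.0 * len(rr) / rr.sum())


def rmssd(beats: np.ndarray, window: tuple) -> float:
    """Root mean square of successive RR differences, in ms.

    Returns NaN with fewer than 3 beats (no successive RR pair) in the window.
    """
    rr = _window_rr(beats, window)
    if len(rr) < 2:
        warnings.warn("fewer than 3 beats in window: RMSSD undefined", stacklevel=2)
        return float("nan")
    d = np.diff(rr) * 1000.0
    return float(np.sqrt(np.mean(d**2)))


def scl(gsr: PhysioRecord, window: tuple) -> float:
    """Mean skin conductance level (uS) over a half-open window."""
    if gsr.channel != "GSR":
        raise ValueError("scl requires a GSR channel")
    start, end = window
    t = gsr.times
    mask = (t >= start) & (t < end)
    if not mask.any():
        warnings.warn("no GSR samples in window: SCL undefined", stacklevel=2)
        return float("nan")
    return float(gsr.values[mask].mean())


def window_metrics(
    beats: np.ndarray, gsr: PhysioRecord, window: tuple
) -> PhysioMetrics:
    """HR, RMSSD and SCL for one window."""
    return PhysioMetrics(
        hr=heart_rate(beats, window),
        rmssd=rmssd(beats, window),
        scl=scl(gsr, window),
        window=tuple(window),
    )


def baseline_deltas(metrics: list, baseline: PhysioMetrics):
    """Per-window deltas relative to the pre-exposure baseline.

    Returns a list of dicts with keys ``delta_hr``, ``delta_rmssd``,
    ``delta_scl`` and ``window``; undefined inputs propagate as NaN.
    """
    out = []
    for m in metrics:
        out.append(
            {
                "window": m.window,
                "delta_hr": m.hr - baseline.hr,
                "delta_rmssd": m.rmssd - baseline.rmssd,
                "delta_scl": m.scl - baseline.scl,
            }
        )
    return out
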