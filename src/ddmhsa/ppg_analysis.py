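"""Systolic-peak detection on the PPG channel.

The finger pulse wave is smooth and quasi-periodic; its per-beat maximum
(the systolic peak) anchors the vascular-transit-time fusion rule. Detection
is a smoothed local-maximum search with a physiologic refractory period and
a prominence floor that rejects dicrotic notches, refined back onto the raw
signal so smoothing cannot bias peak times.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .signal_io import Waveform

__all__ = ["SystolicPeaks", "detect_systolic_peaks"]


@dataclass
class SystolicPeaks:
    """Detected systolic-peak times (seconds) and their prominences."""

    times: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("peak times must be strictly increasing")


def _smooth_ppg(x: np.ndarray, fs: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Band-limit the pulse wave to the cardiac band (default 0.5-8 Hz)."""
    low, high = band_hz
    high = min(high, 0.45 * fs)
    sos = _sig.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return _sig.sosfiltfilt(sos, x)


def detect_systolic_peaks(
    ppg: Waveform,
    min_hr_bpm: float = 40.0,
    max_hr_bpm: float = 180.0,
    smooth_band_hz: tuple[float, float] = (0.5, 8.0),
    prominence_frac: float = 0.3,
    refine_s: float = 0.025,
    refine_smooth_s: float = 0.080,
) -> SystolicPeaks:
    """Detect per-beat maxima of the PPG.

    Local maxima of the band-limited pulse are required to be at least
    ``60 / max_hr_bpm`` seconds apart and to have prominence at least
    ``prominence_frac`` times the median beat prominence; surviving peaks
    are refined within ``+-refine_s`` to the maximum of a lightly smoothed
    copy of the raw signal (Savitzky-Golay, ``refine_smooth_s`` window,
    degree 2 - the raw argmax under broadband noise drifts toward the flat
    diastolic side of the pulse). A flat signal yields an empty list.
    """
    x = np.asarray(ppg.samples, dtype=float)
    if x.size < 8 or float(np.ptp(x)) == 0.0:
        return SystolicPeaks(np.empty(0), np.empty(0))
    sm = _smooth_ppg(x, ppg.fs, smooth_band_hz)
    min_dist = max(1, int(round(60.0 / max_hr_bpm * ppg.fs)))
    idx, props = _sig.find_peaks(sm, distance=min_dist, prominence=1e-12)
    if idx.size == 0:
        return SystolicPeaks(np.empty(0), np.empty(0))
    prom = props["prominences"]
    # reference level ~ a typical true-beat prominence: beats are the tallest
    # cluster of candidates, so a high percentile is robust both when beats
    # dominate the candidate list and when spurious ripples outnumber sparse
    # pulses
    floor = prominence_frac * float(np.percentile(prom, 90))
    keep = prom >= floor
    idx, prom = idx[keep], prom[keep]
    # refine onto a denoised copy of the raw waveform
    win = max(5, int(round(refine_smooth_s * ppg.fs)) // 2 * 2 + 1)
    base = _sig.savgol_filter(x, win, 2) if x.size > win else x
    half = int(round(refine_s * ppg.fs))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmax(base[lo:hi])))
    refined = np.asarray(refined, dtype=int)
    order = np.argsort(refined)
    refined, prom = refined[order], prom[order]
    uniq, first = np.unique(refined, return_index=True)
    times = ppg.t0 + uniq / ppg.fs
    return SystolicPeaks(times, prom[first])
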