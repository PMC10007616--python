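"""The PCG branch: analytic envelope, envelope filtering, Shannon entropy,
smoothing, normalization and impulse conversion.

The chain turns a band-passed phonocardiogram into a sparse train of heart
sound candidates:

1. ``analytic_transform`` - Hilbert analytic signal; the modulus is the
   instantaneous envelope m(t) and s(t)/m(t) the instantaneous cosine phase.
2. ``envelope_filter`` - band-pass m(t), then rescale every supra-threshold
   burst region so its peak reaches the global (S1) amplitude level. This is
   what lifts the low-amplitude S2 bursts out of the noise; the boosted
   envelope times the cosine phase gives the working signal z(t).
3. ``shannon_entropy`` - the kernel -x·ln(x) applied to the min-max scaled
   magnitude sharpens burst peaks relative to the quiet baseline.
4. ``smooth_entropy`` - Savitzky-Golay smoothing (default window 0.45 s,
   i.e. 900 samples at 2 kHz, polynomial degree 3) merges the ragged
   per-sample entropy into one hump per heart sound.
5. ``normalize_minmax`` + ``impulse_detect`` - threshold the normalized
   entropy trace at sigma times a mean level, producing a binary impulse
   train whose runs mark S1/S2 events.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .preprocess import BandpassSpec, bandpass_array
from .signal_io import Waveform

__all__ = [
    "AnalyticEnvelope",
    "FilteredEnvelope",
    "EntropyTrace",
    "ImpulseTrain",
    "HeartSoundCandidates",
    "analytic_transform",
    "envelope_filter",
    "shannon_entropy",
    "smooth_entropy",
    "normalize_minmax",
    "impulse_detect",
    "extract_startpoints",
]

_EPS = 1e-12


@dataclass
class AnalyticEnvelope:
    """Instantaneous envelope |s_a(t)| and cosine phase s(t)/|s_a(t)|."""

    envelope: np.ndarray
    phase_cos: np.ndarray
    fs: float


@dataclass
class FilteredEnvelope:
    """Band-passed envelope m_f(t) and boosted working signal z(t)."""

    mfilt: np.ndarray
    z: np.ndarray
    threshold_value: float
    delta: float


@dataclass
class EntropyTrace:
    """Per-sample entropy SE(t), its smoothed version and normalized NSE(t)."""

    se: np.ndarray
    smoothed: np.ndarray
    nse: np.ndarray
    fs: float


@dataclass
class ImpulseTrain:
    """Binary event signal from thresholding NSE(t).

    ``start_indices`` are the 0->1 transitions (index 0 included when the
    train starts high); ``peak_indices`` locate the NSE maximum inside each
    supra-threshold run, an unbiased estimate of the burst center.
    """

    impulse: np.ndarray
    start_indices: np.ndarray
    fs: float
    sigma: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    peak_heights: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class HeartSoundCandidates:
    """Strictly increasing candidate event times (seconds, absolute clock)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("candidate times must be strictly increasing")


def analytic_transform(w: Waveform) -> AnalyticEnvelope:
    """Hilbert analytic-signal envelope and cosine phase of a waveform.

    The envelope dominates the rectified signal (|s_a| >= |s|) everywhere;
    an all-zero input yields all-zero envelope and phase without division
    errors.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    env = np.abs(_sig.hilbert(x))
    phase_cos = np.where(env > _EPS, x / np.maximum(env, _EPS), 0.0)
    return AnalyticEnvelope(env, np.clip(phase_cos, -1.0, 1.0), w.fs)


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and end (exclusive) indices of True runs."""
    m = np.asarray(mask, dtype=bool)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m.size and m[0]:
        starts = np.r_[0, starts]
    if m.size and m[-1]:
        ends = np.r_[ends, m.size]
    return starts, ends


def envelope_filter(
    ae: AnalyticEnvelope,
    delta: float = 2.0,
    band: BandpassSpec | None = BandpassSpec(),
    min_region_s: float = 0.020,
) -> FilteredEnvelope:
    """Equalize burst amplitudes: boost every supra-threshold envelope region
    to the global (S1) peak level.

    The envelope is band-passed when ``band`` is given (``None`` keeps it
    untouched, useful for already-smooth envelopes). The threshold is
    ``delta`` times the mean of the region signal - the magnitude envelope of
    m_f(t) when band-passed (the signed m_f oscillates, so its raw
    zero-crossings would shred each burst into slivers), m_f itself when not.
    Each contiguous supra-threshold region is rescaled so its peak equals the
    global maximum, then z(t) = boosted m_f(t) x cos(phi(t)).

    Regions shorter than ``min_region_s`` are left unboosted: no heart sound
    is that brief, and amplifying millisecond noise excursions to the S1
    level would swamp the downstream entropy statistics.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    env = np.asarray(ae.envelope, dtype=float)
    if band is not None:
        mfilt = bandpass_array(env, ae.fs, band)
        mag = np.abs(_sig.hilbert(mfilt))
    else:
        mfilt = env.copy()
        mag = mfilt
    threshold = delta * float(np.mean(mag))
    boosted = mfilt.copy()
    # A_ref is the S1 amplitude level. Use the raw envelope's maximum: the
    # band-passed envelope attenuates the smooth bursts far more than the
    # broadband noise riding on them, so *its* maximum is a noise-extreme
    # statistic that can swing severalfold between windows.
    a_ref = float(np.max(env)) if env.size else 0.0
    if a_ref > 0:
        min_len = int(round(min_region_s * ae.fs))
        starts, ends = _runs(mag > threshold)
        # close sub-min_len gaps first: a burst whose magnitude dips briefly
        # below threshold is one region, not several
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] < min_len:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < min_len:
                continue
            rmax = float(mag[s:e].max())
            if rmax > 0:
                boosted[s:e] *= a_ref / rmax
    z = boosted * ae.phase_cos
    return FilteredEnvelope(mfilt, z, threshold, delta)


def shannon_entropy(x: np.ndarray) -> np.ndarray:
    """Sample-wise Shannon entropy kernel -x_hat * ln(x_hat).

    ``x_hat`` is |x| min-max scaled to [0, 1]; constant input maps to zero.
    The output is bounded by 1/e (the kernel maximum, attained at x_hat=1/e),
    so mid-level flanks of a burst score higher than both the silent baseline
    and the saturated peak - which is what sharpens event humps.
    """
    xhat = normalize_minmax(np.abs(np.asarray(x, dtype=float)))
    out = np.zeros_like(xhat)
    pos = xhat > 0
    out[pos] = -xhat[pos] * np.log(xhat[pos])
    return out


def smooth_entropy(
    se: np.ndarray, fs: float, window_s: float = 0.45, polyorder: int = 3
) -> np.ndarray:
    """Savitzky-Golay smoothing of the entropy trace.

    The default window (0.45 s = 900 samples at 2 kHz, rounded up to the odd
    901) spans roughly the S1-S2 interval; degree-3 fitting preserves peak
    positions far better than a moving average. Polynomials up to the fit
    degree pass through unchanged.
    """
    window = int(round(window_s * fs))
    if window % 2 == 0:
        window += 1
    if window <= polyorder:
        raise ValueError("smoothing window must exceed the polynomial order")
    return _sig.savgol_filter(np.asarray(se, dtype=float), window, polyorder)


def normalize_minmax(x: np.ndarray) -> np.ndarray:
    """Min-max scaling to [0, 1]; a constant input maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one sample")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def impulse_detect(
    nse: np.ndarray,
    fs: float,
    sigma: float = 5.0,
    baseline_mean: float | None = None,
    summit_ratio: float = 0.65,
) -> ImpulseTrain:
    """Threshold the normalized entropy trace into a binary impulse train.

    ``impulse[i] = 1`` iff ``nse[i] > sigma * m`` where ``m`` is
    ``baseline_mean`` when given, else the mean of ``nse`` itself. The
    pipeline passes the mean of the *pre-normalization* smoothed entropy as
    the baseline: the normalized trace carries broad humps at every heart
    sound, so its own mean sits near half the maximum and a multiplier of
    sigma=5 would place the threshold above 1.

    Summit extraction: every local maximum inside a supra-threshold run is a
    candidate event - when two heart sounds of comparable amplitude sit
    closer than the smoothing window, their humps can merge into a single
    run with two summits. Within one run, secondary summits shorter than
    ``summit_ratio`` times the run's tallest summit are discarded: a much
    weaker side hump adjacent to a dominant sound is indistinguishable from
    structured noise around it. (This is what makes the second sound, whose
    amplitude is naturally well below the first, benefit from envelope
    boosting: equalized humps pass the gate.)
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    nse = np.asarray(nse, dtype=float)
    m = float(np.mean(nse)) if baseline_mean is None else float(baseline_mean)
    impulse = (nse > sigma * m).astype(np.int8)
    starts, ends = _runs(impulse.astype(bool))
    local_max, _ = _sig.find_peaks(nse, prominence=0.05)
    peaks: list[int] = []
    for s, e in zip(starts, ends):
        inside = local_max[(local_max >= s) & (local_max < e)]
        if inside.size:
            tallest = float(nse[inside].max())
            keep = inside[nse[inside] >= summit_ratio * tallest]
            peaks.extend(int(i) for i in keep)
        else:
            peaks.append(s + int(np.argmax(nse[s:e])))
    peaks_arr = np.asarray(sorted(peaks), dtype=int)
    return ImpulseTrain(
        impulse, starts.astype(int), fs, sigma, peaks_arr, nse[peaks_arr]
    )


def extract_startpoints(
    it: ImpulseTrain,
    t0: float = 0.0,
    min_gap_s: float = 0.1,
    use_peaks: bool = False,
) -> HeartSoundCandidates:
    """Convert impulse-train indices to candidate event times.

    By default the 0->1 transition index marks the event ("start point");
    ``use_peaks=True`` takes the NSE summits within each run instead, which
    centers events on the bursts (the smoothed-entropy onset leads the
    burst by an appreciable fraction of the smoothing window). Events closer
    than ``min_gap_s`` are merged - S1 and S2 are never that close at rest,
    so nearer detections are threshold chatter or shoulder wiggles. Start
    points merge keeping the first; summits merge keeping the tallest
    (non-maximum suppression), so a minor shoulder cannot displace the
    summit of a heart sound.
    """
    if use_peaks:
        idx = np.asarray(it.peak_indices, dtype=float)
        heights = np.asarray(it.peak_heights, dtype=float)
        if heights.size != idx.size:
            heights = np.zeros(idx.size)
        times = t0 + idx / it.fs
        order = np.argsort(-heights, kind="stable")
        accepted: list[float] = []
        for k in order:
            t = times[k]
            if all(abs(t - a) >= min_gap_s for a in accepted):
                accepted.append(t)
        return HeartSoundCandidates(np.sort(np.asarray(accepted)))
    times = t0 + np.asarray(it.start_indices, dtype=float) / it.fs
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap_s:
            kept.append(t)
    return HeartSoundCandidates(np.asarray(kept))
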