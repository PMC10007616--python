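"""Seeded generator of synchronized PCG+PPG recordings with ground truth.

Emulates the statistical structure the detector assumes: quasi-periodic
S1/S2 tone-burst pairs (S2 weaker than S1, roughly 300 ms after it), a
finger pulse whose systolic peak trails S1 by the vascular transit time,
and additive white Gaussian noise on both channels. Annotations carry the
exact construction times, so every pipeline stage is testable without a
clinical database.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_io import AnnotationSet, Channel, Recording, Waveform

__all__ = ["SyntheticSpec", "generate_recording", "generate_cohort"]

_START_MARGIN_S = 0.25  # first beat offset
_END_GUARD_S = 0.45  # room for the S2 burst tail of the last beat


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of one synthetic subject.

    Defaults reflect resting physiology: S1 bursts near 60 Hz, weaker S2
    bursts near 90 Hz about 300 ms later, a systolic PPG peak 200 ms after
    S1, and 20 dB broadband noise. ``snr_db=None`` disables noise.
    """

    duration_s: float = 60.0
    hr_bpm: float = 70.0
    hr_jitter_pct: float = 3.0
    s1_freq_hz: float = 60.0
    s2_freq_hz: float = 90.0
    s2_amp_ratio: float = 0.4
    s1_s2_gap_s: float = 0.300
    vtt_s: float = 0.200
    s2_peak_offset_s: float = 0.020
    snr_db: float | None = 20.0
    fs: float = 2000.0
    seed: int = 0
    amp_mod_depth: float = 0.30  # respiratory amplitude modulation of bursts
    amp_mod_freq_hz: float = 0.25  # ~15 breaths/min
    amp_jitter_pct: float = 10.0  # additional per-beat lognormal amplitude CV
    s1_width_s: float = 0.070  # ~4 sigma of the Gaussian window
    s2_width_s: float = 0.050
    ppg_rise_s: float = 0.150  # foot-to-peak time of the pulse wave
    ppg_shape: float = 3.0  # gamma shape: larger = sharper systolic peak

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 40 <= self.hr_bpm <= 180:
            raise ValueError("hr_bpm must be in [40, 180]")
        if not self.s1_s2_gap_s < 60.0 / self.hr_bpm:
            raise ValueError("s1_s2_gap_s must be shorter than a beat period")
        if not 0 < self.s2_amp_ratio <= 1:
            raise ValueError("s2_amp_ratio must be in (0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


def _beat_times(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    period = 60.0 / spec.hr_bpm
    cv = spec.hr_jitter_pct / 100.0
    t = _START_MARGIN_S
    end = spec.duration_s - _END_GUARD_S
    beats = []
    while t < end:
        beats.append(t)
        step = period * (1.0 + cv * rng.standard_normal()) if cv > 0 else period
        t += max(step, 0.3)
    return np.asarray(beats)


def _gauss_burst(t: np.ndarray, center: float, width_s: float, freq: float) -> np.ndarray:
    sigma = width_s / 4.0
    u = t - center
    return np.exp(-0.5 * (u / sigma) ** 2) * np.sin(2 * np.pi * freq * u)


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    p_sig = float(np.mean(x**2))
    if p_sig == 0:
        return x
    sigma = np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    return x + sigma * rng.standard_normal(x.size)


def generate_recording(spec: SyntheticSpec) -> tuple[Recording, AnnotationSet]:
    """Synthesize one synchronized PCG/PPG pair with exact annotations.

    PCG: per beat, an S1 burst (nominal amplitude 1) at the beat time and an
    S2 burst (amplitude ``s2_amp_ratio`` relative to its S1) ``s1_s2_gap_s``
    later. Burst amplitudes carry slow respiratory modulation
    (``amp_mod_depth`` at ``amp_mod_freq_hz``) plus per-beat lognormal
    jitter, applied to S1 and S2 of a beat together so their ratio is
    preserved. PPG: per beat, a gamma-like pulse (fast rise over
    ``ppg_rise_s``, slower decay) peaking ``vtt_s`` after the beat.
    Identical spec (same seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    beats = _beat_times(spec, rng)
    if beats.size == 0:
        raise ValueError("duration too short for a single beat")
    pcg = np.zeros(n)
    ppg = np.zeros(n)
    resp_phase = rng.uniform(0, 2 * np.pi)
    sigma_ln = np.log1p(spec.amp_jitter_pct / 100.0)
    for tk in beats:
        amp = 1.0 + spec.amp_mod_depth * np.sin(
            2 * np.pi * spec.amp_mod_freq_hz * tk + resp_phase
        )
        amp *= float(np.exp(sigma_ln * rng.standard_normal()))
        pcg += amp * _gauss_burst(t, tk, spec.s1_width_s, spec.s1_freq_hz)
        pcg += amp * spec.s2_amp_ratio * _gauss_burst(
            t, tk + spec.s1_s2_gap_s, spec.s2_width_s, spec.s2_freq_hz
        )
        # gamma-like pulse: fast rise from the foot, slower decay, peak at
        # tk + vtt_s (u/u_m)^a * exp(-a (u - u_m) / u_m) has its mode at u_m
        tp = tk + spec.vtt_s
        u = t - (tp - spec.ppg_rise_s)
        a, um = spec.ppg_shape, spec.ppg_rise_s
        pos = u > 0
        pulse = np.zeros(n)
        up = u[pos]
        pulse[pos] = np.exp(a * (np.log(up / um) - (up - um) / um))
        ppg += pulse
    if spec.snr_db is not None and np.isfinite(spec.snr_db):
        pcg = _add_noise(pcg, spec.snr_db, rng)
        ppg = _add_noise(ppg, spec.snr_db, rng)
    rec = Recording(
        Waveform(pcg, spec.fs, Channel.PCG),
        Waveform(ppg, spec.fs, Channel.PPG),
        subject_id=f"synthetic-seed{spec.seed}",
        metadata={"hr_bpm": f"{spec.hr_bpm:.4f}", "snr_db": str(spec.snr_db)},
    )
    ann = AnnotationSet(
        s1_times=beats,
        s2_times=beats + spec.s1_s2_gap_s,
        systolic_peak_times=beats + spec.vtt_s,
    )
    return rec, ann


def generate_cohort(
    n_subjects: int,
    base_spec: SyntheticSpec = SyntheticSpec(),
    hr_range_bpm: tuple[float, float] = (59.0, 87.0),
    seed: int = 0,
) -> list[tuple[Recording, AnnotationSet]]:
    """Generate a cohort with per-subject heart rates drawn uniformly.

    Per-subject seeds derive deterministically from the cohort seed, so the
    same cohort seed reproduces the same cohort bit-for-bit.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        hr = float(rng.uniform(*hr_range_bpm))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, hr_bpm=hr, seed=sub_seed)
        rec, ann = generate_recording(spec)
        rec.subject_id = f"SYN{i + 1:02d}"
        out.append((rec, ann))
    return out
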