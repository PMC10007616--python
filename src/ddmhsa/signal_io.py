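"""Waveform containers and readers/writers for WAV/CSV recordings and annotations.

Times are seconds from recording start; sample index ``i`` maps to time
``t0 + i / fs``. CSV files are comma-separated with a header row and '.'
decimal separator.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Channel",
    "Waveform",
    "Recording",
    "AnnotationSet",
    "read_recording",
    "read_wav",
    "write_wav",
    "resample",
    "read_annotations",
    "write_annotations",
]

_ANNOTATION_LABELS = ("S1", "S2", "SYS_PEAK")


class Channel(str, Enum):
    PCG = "PCG"
    PPG = "PPG"
    ECG = "ECG"
    OTHER = "OTHER"


@dataclass
class Waveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array of amplitudes (volts or normalized a.u.)
    fs : sampling rate in Hz, > 0
    channel : physiological channel label
    t0 : start-time offset in seconds relative to the recording clock
    """

    samples: np.ndarray
    fs: float
    channel: Channel = Channel.OTHER
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.channel = Channel(self.channel)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class Recording:
    """Synchronized PCG + PPG channel pair sharing one sample clock."""

    pcg: Waveform
    ppg: Waveform
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pcg.fs != self.ppg.fs:
            raise ValueError("fs mismatch")
        if abs(len(self.pcg.samples) - len(self.ppg.samples)) > 1:
            raise ValueError("channels must cover the same span within one sample")

    @property
    def fs(self) -> float:
        return self.pcg.fs

    @property
    def duration(self) -> float:
        return self.pcg.duration


def _as_sorted_times(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    if arr.size and np.any(np.diff(arr) <= 0):
        warnings.warn(f"{what} not strictly increasing; sorting", stacklevel=3)
        arr = np.unique(arr)
    return arr


@dataclass
class AnnotationSet:
    """Reference event times: S1 onsets, S2 onsets and PPG systolic peaks."""

    s1_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    s2_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    systolic_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.s1_times = _as_sorted_times(self.s1_times, "s1_times")
        self.s2_times = _as_sorted_times(self.s2_times, "s2_times")
        self.systolic_peak_times = _as_sorted_times(
            self.systolic_peak_times, "systolic_peak_times"
        )


def read_wav(path, channel: Channel = Channel.OTHER) -> Waveform | list[Waveform]:
    """Read a PCM16 or float32 WAV file; multichannel files yield one
    Waveform per column."""
    fs, data = wavfile.read(str(path))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if data.ndim == 1:
        return Waveform(data, fs, channel)
    return [Waveform(data[:, j], fs, Channel.OTHER) for j in range(data.shape[1])]


def write_wav(w: Waveform, path) -> None:
    """Write samples as float32 WAV (bit-exact round trip for float32 data)."""
    wavfile.write(str(path), int(round(w.fs)), w.samples.astype(np.float32))


def _read_csv_recording(path) -> tuple[np.ndarray, np.ndarray, float]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("time", "pcg", "ppg"):
        if required not in cols:
            raise ValueError(f"CSV must have columns time,pcg,ppg (missing {required!r})")
    t = df[cols["time"]].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("CSV recording needs at least two samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise ValueError("non-uniform CSV time grid")
    fs = 1.0 / dt[0]
    return df[cols["pcg"]].to_numpy(float), df[cols["ppg"]].to_numpy(float), fs


def read_recording(
    pcg_path,
    ppg_path=None,
    fmt: str | None = None,
    subject_id: str = "",
    resample_to: float | None = None,
    channel_order: tuple[str, str] = ("pcg", "ppg"),
) -> Recording:
    """Read a two-channel recording from WAV or CSV files.

    Accepts either two single-channel WAV files, one multichannel WAV
    (channel order declared by ``channel_order``), or a single CSV with
    columns ``time,pcg,ppg``. Channels with differing sampling rates raise
    "fs mismatch" unless ``resample_to`` is given.
    """
    pcg_path = Path(pcg_path)
    if fmt is None:
        fmt = "csv" if pcg_path.suffix.lower() == ".csv" else "wav"
    if fmt == "csv":
        pcg_arr, ppg_arr, fs = _read_csv_recording(pcg_path)
        pcg = Waveform(pcg_arr, fs, Channel.PCG)
        ppg = Waveform(ppg_arr, fs, Channel.PPG)
    elif fmt == "wav":
        if ppg_path is None:
            channels = read_wav(pcg_path)
            if not isinstance(channels, list) or len(channels) < 2:
                raise ValueError("single WAV path requires a multichannel file")
            order = {name: i for i, name in enumerate(channel_order)}
            pcg = channels[order["pcg"]]
            ppg = channels[order["ppg"]]
            pcg.channel, ppg.channel = Channel.PCG, Channel.PPG
        else:
            pcg = read_wav(pcg_path, Channel.PCG)
            ppg = read_wav(ppg_path, Channel.PPG)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if pcg.fs != ppg.fs:
        if resample_to is None:
            raise ValueError("fs mismatch")
        pcg, ppg = resample(pcg, resample_to), resample(ppg, resample_to)
    elif resample_to is not None and resample_to != pcg.fs:
        pcg, ppg = resample(pcg, resample_to), resample(ppg, resample_to)
    return Recording(pcg, ppg, subject_id=subject_id)


def resample(w: Waveform, target_fs: float) -> Waveform:
    """Polyphase resampling to ``target_fs``; identity when rates match."""
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == w.fs:
        return Waveform(w.samples.copy(), w.fs, w.channel, w.t0)
    ratio = Fraction(target_fs / w.fs).limit_denominator(10**6)
    out = resample_poly(w.samples, ratio.numerator, ratio.denominator)
    n_out = int(round(len(w.samples) * target_fs / w.fs))
    out = out[:n_out]
    return Waveform(out, target_fs, w.channel, w.t0)


def read_annotations(path) -> AnnotationSet:
    """Read an annotation CSV with columns ``label,time_s``."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "label" not in cols or "time_s" not in cols:
        raise ValueError("annotation CSV must have columns label,time_s")
    labels = df[cols["label"]].astype(str)
    unknown = set(labels) - set(_ANNOTATION_LABELS)
    if unknown:
        raise ValueError(f"unknown annotation label(s): {sorted(unknown)}")
    times = df[cols["time_s"]].to_numpy(float)
    by = {lab: times[(labels == lab).to_numpy()] for lab in _ANNOTATION_LABELS}
    return AnnotationSet(by["S1"], by["S2"], by["SYS_PEAK"])


def write_annotations(a: AnnotationSet, path) -> None:
    rows = (
        [("S1", t) for t in a.s1_times]
        + [("S2", t) for t in a.s2_times]
        + [("SYS_PEAK", t) for t in a.systolic_peak_times]
    )
    rows.sort(key=lambda r: (r[1], r[0]))
    pd.DataFrame(rows, columns=["label", "time_s"]).to_csv(
        path, index=False, float_format="%.9f"
    )
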