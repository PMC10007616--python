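"""End-to-end model variants and their evaluation.

Three variants of the detector are distinguished:

* Model I   - the basic pipeline on the whole recording.
* Model II  - Model I applied per analysis window (default 10 s), which
  localizes the amplitude normalization and entropy threshold.
* Model III - Model II plus envelope filtering, which boosts the weaker S2
  bursts to the S1 amplitude level before entropy detection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionCounts, MetricsReport, compute_metrics, match_events
from .fusion import LabeledHeartSounds, VttConfig, classify_heart_sounds, refine_s2
from .pcg_analysis import (
    HeartSoundCandidates,
    analytic_transform,
    envelope_filter,
    extract_startpoints,
    impulse_detect,
    normalize_minmax,
    shannon_entropy,
    smooth_entropy,
)
from .ppg_analysis import detect_systolic_peaks
from .preprocess import BandpassSpec, SegmentPlan, bandpass, merge_event_times, segment
from .signal_io import AnnotationSet, Recording

__all__ = ["ModelConfig", "run_model", "evaluate_run", "score_run"]

log = logging.getLogger("ddmhsa")


@dataclass(frozen=True)
class ModelConfig:
    """Full configuration of one detector variant.

    Invariants: variant I has neither segmentation nor envelope filtering;
    variant II has segmentation only; variant III has both.
    """

    variant: str = "III"
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    segment: SegmentPlan | None = field(default_factory=SegmentPlan)
    ef_delta: float | None = 2.0
    ef_band: BandpassSpec = field(default_factory=BandpassSpec)
    entropy_window_s: float = 0.45
    entropy_polyorder: int = 3
    sigma: float = 5.0
    vtt: VttConfig = field(default_factory=VttConfig)
    eval_tol_s: float = 0.060
    min_gap_s: float = 0.100
    merge_sep_s: float = 0.050
    ppg_min_hr_bpm: float = 40.0
    ppg_max_hr_bpm: float = 180.0

    def __post_init__(self) -> None:
        if self.variant not in ("I", "II", "III"):
            raise ValueError("variant must be 'I', 'II' or 'III'")
        if self.variant == "I" and (self.segment is not None or self.ef_delta is not None):
            raise ValueError("variant I takes no segmentation and no envelope filter")
        if self.variant == "II" and (self.segment is None or self.ef_delta is not None):
            raise ValueError("variant II takes segmentation but no envelope filter")
        if self.variant == "III" and (self.segment is None or self.ef_delta is None):
            raise ValueError("variant III takes segmentation and an envelope filter")

    @classmethod
    def for_model(cls, variant: str, **overrides) -> "ModelConfig":
        """Build the canonical configuration of a variant, then override."""
        base = {
            "I": dict(variant="I", segment=None, ef_delta=None),
            "II": dict(variant="II", segment=SegmentPlan(), ef_delta=None),
            "III": dict(variant="III", segment=SegmentPlan(), ef_delta=2.0),
        }[variant]
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelConfig":
        """Build from a nested mapping (e.g. parsed YAML)."""
        variant = str(cfg.get("variant", "III"))
        over: dict = {}
        if "bandpass" in cfg:
            over["bandpass"] = BandpassSpec(**cfg["bandpass"])
        if "segment" in cfg:
            over["segment"] = None if cfg["segment"] is None else SegmentPlan(**cfg["segment"])
        if "ef" in cfg:
            ef = cfg["ef"]
            if "delta" in ef:
                over["ef_delta"] = ef["delta"]
            if "band" in ef:
                over["ef_band"] = BandpassSpec(**ef["band"])
        if "entropy" in cfg:
            ent = cfg["entropy"]
            over["entropy_window_s"] = ent.get("window_s", 0.45)
            over["entropy_polyorder"] = ent.get("polyorder", 3)
        if "impulse" in cfg:
            over["sigma"] = cfg["impulse"].get("sigma", 5.0)
        if "fusion" in cfg:
            over["vtt"] = VttConfig(**cfg["fusion"])
        if "eval" in cfg:
            over["eval_tol_s"] = cfg["eval"].get("tol_s", 0.060)
        if "events" in cfg:
            over["min_gap_s"] = cfg["events"].get("min_gap_s", 0.100)
        if "ppg" in cfg:
            over["ppg_min_hr_bpm"] = cfg["ppg"].get("min_hr_bpm", 40.0)
            over["ppg_max_hr_bpm"] = cfg["ppg"].get("max_hr_bpm", 180.0)
        return cls.for_model(variant, **over)


_EDGE_PAD_S = 1.0  # reflect padding absorbs Hilbert/Savitzky-Golay edge transients


def _detect_segment_candidates(seg, cfg: ModelConfig) -> np.ndarray:
    """PCG branch on one (already band-passed) segment; absolute times out.

    The segment is reflect-padded on both sides before the analytic
    transform: the FFT-based Hilbert transform and the polynomial edge fit
    of the smoother otherwise leave transients at the window boundaries that
    can dominate the min-max normalization. Detections inside the padding
    are discarded.
    """
    from .signal_io import Waveform

    n_orig = len(seg.samples)
    t0 = seg.t0
    pad = min(int(round(_EDGE_PAD_S * seg.fs)), n_orig - 1)
    work_seg = seg
    if pad > 0:
        padded = np.concatenate(
            [seg.samples[pad:0:-1], seg.samples, seg.samples[-2 : -pad - 2 : -1]]
        )
        work_seg = Waveform(padded, seg.fs, seg.channel, t0 - pad / seg.fs)
    ae = analytic_transform(work_seg)
    if cfg.ef_delta is not None:
        fe = envelope_filter(ae, delta=cfg.ef_delta, band=cfg.ef_band)
        work = fe.z
    else:
        # unboosted working signal: envelope x cos(phi) = the band-passed PCG
        work = ae.envelope * ae.phase_cos
    se = shannon_entropy(work)
    smoothed = smooth_entropy(se, seg.fs, cfg.entropy_window_s, cfg.entropy_polyorder)
    # normalization/threshold statistics must come from real samples only:
    # reflected padding can mirror a burst into a taller artificial hump
    smoothed = smoothed[pad : pad + n_orig]
    nse = normalize_minmax(smoothed)
    train = impulse_detect(
        nse, seg.fs, sigma=cfg.sigma, baseline_mean=float(np.mean(smoothed))
    )
    cands = extract_startpoints(train, t0=t0, min_gap_s=cfg.min_gap_s, use_peaks=True)
    return cands.times


def run_model(rec: Recording, cfg: ModelConfig) -> LabeledHeartSounds:
    """Run one detector variant on a recording and label the events.

    Stages: band-pass -> [window] -> [envelope filter] -> Shannon entropy ->
    Savitzky-Golay smoothing -> min-max normalization -> impulse conversion
    -> candidate extraction on the PCG; systolic-peak detection on the PPG;
    then VTT fusion labeling and S2 revalidation.
    """
    window_samples = int(round(cfg.entropy_window_s * rec.fs))
    if len(rec.pcg.samples) <= window_samples:
        raise ValueError("recording shorter than one entropy window")
    filtered = bandpass(rec.pcg, cfg.bandpass)
    segments = segment(filtered, cfg.segment) if cfg.segment is not None else [filtered]
    all_times: list[np.ndarray] = []
    for seg in segments:
        if len(seg.samples) <= max(cfg.entropy_polyorder + 2, 8):
            continue
        times = _detect_segment_candidates(seg, cfg)
        log.debug("segment t0=%.1fs: %d candidates", seg.t0, times.size)
        all_times.append(times)
    merged = merge_event_times(
        np.concatenate(all_times) if all_times else np.empty(0), cfg.merge_sep_s
    )
    cands = HeartSoundCandidates(merged)
    peaks = detect_systolic_peaks(
        rec.ppg, min_hr_bpm=cfg.ppg_min_hr_bpm, max_hr_bpm=cfg.ppg_max_hr_bpm
    )
    log.info(
        "detected %d PCG candidates, %d systolic peaks", merged.size, peaks.times.size
    )
    labeled = classify_heart_sounds(cands, peaks, cfg.vtt)
    return refine_s2(labeled, peaks, cfg.vtt)


def evaluate_run(
    labeled: LabeledHeartSounds,
    truth: AnnotationSet,
    cfg: ModelConfig,
    span: tuple[float, float] | None = None,
) -> tuple[MetricsReport, MetricsReport]:
    """Score S1 and S2 events separately against reference annotations."""
    if truth.s1_times.size == 0 and truth.s2_times.size == 0:
        raise ValueError("empty reference annotations")
    reports = []
    for label, ref in (("S1", truth.s1_times), ("S2", truth.s2_times)):
        det = labeled.times(label)
        counts = match_events(det, ref, tol_s=cfg.eval_tol_s, span=span)
        reports.append(compute_metrics(counts))
    return reports[0], reports[1]


def score_run(
    labeled: LabeledHeartSounds,
    truth: AnnotationSet,
    cfg: ModelConfig,
    span: tuple[float, float] | None = None,
) -> dict[str, ConfusionCounts]:
    """Raw confusion counts per sound, for table-style reporting."""
    return {
        "S1": match_events(labeled.times("S1"), truth.s1_times, cfg.eval_tol_s, span),
        "S2": match_events(labeled.times("S2"), truth.s2_times, cfg.eval_tol_s, span),
    }
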