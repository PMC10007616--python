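"""S1/S2 labeling by fusing PCG candidates with PPG systolic-peak timing.

The pressure pulse needs a vascular transit time (VTT, nominally 200 ms) to
travel from the heart to the finger, so the systolic peak of the PPG trails
S1 by between beta (100 ms) and VTT. A PCG candidate T is therefore labeled

    S1  if  T_peak - VTT <= T <= T_peak - beta   (interval endpoints inclusive)
    S2  otherwise

for the nearest systolic peak in scope. Candidates with no peak in scope are
labeled by an alternation fallback (the first of a pair is taken as S1).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .pcg_analysis import HeartSoundCandidates
from .ppg_analysis import SystolicPeaks

__all__ = [
    "VttConfig",
    "LabeledEvent",
    "LabeledHeartSounds",
    "classify_heart_sounds",
    "refine_s2",
]


@dataclass(frozen=True)
class VttConfig:
    """Timing constants of the fusion rule (seconds).

    vtt_s: nominal vascular transit time from S1 to the finger pulse peak.
    beta_s: lower bound of the S1-to-peak delay.
    s2_window_s: neighborhood of the systolic peak in which S2 is expected.
    """

    vtt_s: float = 0.200
    beta_s: float = 0.100
    s2_window_s: float = 0.020

    def __post_init__(self) -> None:
        if not 0 < self.beta_s < self.vtt_s:
            raise ValueError("need 0 < beta_s < vtt_s")
        if self.s2_window_s <= 0:
            raise ValueError("s2_window_s must be positive")


@dataclass(frozen=True)
class LabeledEvent:
    time: float
    label: str  # "S1" or "S2"
    matched_peak_time: float | None = None
    low_confidence: bool = False


@dataclass
class LabeledHeartSounds:
    events: list[LabeledEvent] = field(default_factory=list)

    def times(self, label: str | None = None) -> np.ndarray:
        return np.asarray(
            [e.time for e in self.events if label is None or e.label == label]
        )


def classify_heart_sounds(
    cands: HeartSoundCandidates,
    peaks: SystolicPeaks,
    cfg: VttConfig = VttConfig(),
    edge_tol_s: float = 0.05,
    lookback_s: float = 0.15,
) -> LabeledHeartSounds:
    """Label each PCG candidate S1 or S2 against the systolic-peak train.

    Scope: the nearest peak within ``[T - lookback_s, T + vtt_s + 0.1]`` of a
    candidate at ``T`` (the look-back admits the common geometry where S2
    falls shortly *after* its systolic peak). The S1 interval test applies
    ``edge_tol_s`` of slack at both (inclusive) endpoints so that detection
    jitter at an interval boundary does not flip the label. Candidates with
    no peak in scope fall back to alternation: first of a close pair -> S1,
    then alternate.

    When two candidates claim the S1 interval of the same peak, the earlier
    keeps S1 and the later becomes S2 (one S1 per cardiac cycle).
    """
    pk = np.asarray(peaks.times, dtype=float)
    if pk.size == 0:
        warnings.warn("no systolic peaks; labeling all candidates by fallback")
    events: list[LabeledEvent] = []
    for t in cands.times:
        matched: float | None = None
        if pk.size:
            in_scope = (pk >= t - lookback_s) & (pk <= t + cfg.vtt_s + 0.1)
            if np.any(in_scope):
                scoped = pk[in_scope]
                matched = float(scoped[np.argmin(np.abs(scoped - t))])
        if matched is not None:
            lo = matched - cfg.vtt_s - edge_tol_s
            hi = matched - cfg.beta_s + edge_tol_s
            label = "S1" if lo <= t <= hi else "S2"
            events.append(LabeledEvent(t, label, matched))
        else:
            prev = events[-1] if events else None
            if prev is not None and t - prev.time <= 0.45:
                label = "S2" if prev.label == "S1" else "S1"
            else:
                label = "S1"
            events.append(LabeledEvent(t, label, None))
    # enforce one S1 per peak: later duplicates become S2
    seen: dict[float, float] = {}
    fixed: list[LabeledEvent] = []
    for e in events:
        if e.label == "S1" and e.matched_peak_time is not None:
            if e.matched_peak_time in seen:
                e = replace(e, label="S2")
            else:
                seen[e.matched_peak_time] = e.time
        fixed.append(e)
    return LabeledHeartSounds(fixed)


def refine_s2(
    labeled: LabeledHeartSounds,
    peaks: SystolicPeaks,
    cfg: VttConfig = VttConfig(),
    slack_s: float = 0.03,
) -> LabeledHeartSounds:
    """Revalidate S2 events against systolic-peak proximity.

    S2 is expected within ``s2_window_s`` (plus ``slack_s``) of a systolic
    peak; events farther than that from every peak are retained but flagged
    low-confidence. With no peaks at all, every S2 is flagged.
    """
    pk = np.asarray(peaks.times, dtype=float)
    out: list[LabeledEvent] = []
    tol = cfg.s2_window_s + slack_s
    for e in labeled.events:
        if e.label == "S2":
            near = pk.size > 0 and float(np.min(np.abs(pk - e.time))) <= tol
            out.append(replace(e, low_confidence=not near))
        else:
            out.append(e)
    return LabeledHeartSounds(out)
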