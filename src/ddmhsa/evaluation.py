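"""Event-detection scoring: confusion counts and SEN/PRE/SPE/ACC.

Detections are matched one-to-one to reference events within a tolerance
(default 60 ms, below half the minimum S1-S2 gap). True negatives need a
notion of "decision slots" in continuous time: the record is partitioned
into half-beat bins bounded by the reference events and the midpoints
between consecutive ones; a bin holding neither a reference nor a detection
counts as TN.

    SEN = TP/(TP+FN)  PRE = TP/(TP+FP)  SPE = TN/(TN+FP)
    ACC = (TP+TN)/(TP+TN+FP+FN)        (all x100)
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "match_events",
    "compute_metrics",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """Percent metrics; a metric is None when its denominator is zero."""

    sen: float | None
    pre: float | None
    spe: float | None
    acc: float | None


def _ensure_sorted(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size and np.any(np.diff(x) < 0):
        warnings.warn(f"{what} unsorted; sorting", stacklevel=3)
        x = np.sort(x)
    return x


def _greedy_match(detected: np.ndarray, reference: np.ndarray, tol_s: float) -> int:
    """One-to-one matching within tolerance; returns the number of pairs.

    Both trains are sorted, so each detection's compatible references form a
    contiguous interval and the greedy sweep (match each detection, in
    order, to the earliest unmatched reference within +-tol_s) attains the
    maximum-cardinality bipartite matching.
    """
    j = 0
    matched = 0
    for d in detected:
        while j < reference.size and reference[j] < d - tol_s:
            j += 1
        if j < reference.size and reference[j] <= d + tol_s:
            matched += 1
            j += 1
    return matched


def match_events(
    detected,
    reference,
    tol_s: float = 0.060,
    span: tuple[float, float] | None = None,
) -> ConfusionCounts:
    """Score a detection list against a reference list.

    Matched pair -> TP; unmatched detection -> FP; unmatched reference -> FN.
    TN counts the half-beat decision slots (see module docstring) containing
    neither kind of event; it requires ``span`` and at least two reference
    events, otherwise TN = 0.
    """
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")
    detected = _ensure_sorted(detected, "detected")
    reference = _ensure_sorted(reference, "reference")
    tp = _greedy_match(detected, reference, tol_s)
    fp = detected.size - tp
    fn = reference.size - tp
    tn = 0
    if span is not None and reference.size >= 2:
        t0, t1 = span
        mids = 0.5 * (reference[:-1] + reference[1:])
        bounds = np.unique(
            np.clip(np.concatenate([[t0], reference, mids, [t1]]), t0, t1)
        )
        # left-closed bins; a reference sits exactly on its left boundary
        ref_bins = set(np.searchsorted(bounds, reference, side="right") - 1)
        det_bins = set(np.searchsorted(bounds, detected, side="right") - 1)
        n_bins = bounds.size - 1
        tn = sum(1 for b in range(n_bins) if b not in ref_bins and b not in det_bins)
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, precision, specificity and accuracy in percent."""
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("all counts are zero")
    return MetricsReport(
        sen=_ratio(c.tp, c.tp + c.fn),
        pre=_ratio(c.tp, c.tp + c.fp),
        spe=_ratio(c.tn, c.tn + c.fp),
        acc=_ratio(c.tp + c.tn, total),
    )


def aggregate(reports: list[MetricsReport]) -> tuple[MetricsReport, MetricsReport]:
    """Per-metric mean and sample standard deviation (ddof=1) over subjects.

    None-valued (undefined) metrics are excluded metric-wise; a single
    report yields zero standard deviation.
    """
    if not reports:
        raise ValueError("empty report list")

    def stats(name: str) -> tuple[float | None, float | None]:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if not vals:
            return None, None
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return mean, sd

    means, sds = {}, {}
    for name in ("sen", "pre", "spe", "acc"):
        means[name], sds[name] = stats(name)
    return MetricsReport(**means), MetricsReport(**sds)
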