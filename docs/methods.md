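# Methods

This note documents the signal model, the processing chain and its
parameters, the synthetic data used for validation, and the numerical
choices made where the design was genuinely open.

## Signal model and assumptions

A recording is a synchronized two-channel pair sampled on one clock
(default 2 kHz): a chest phonocardiogram (PCG) containing the S1/S2
heart-sound bursts, and a finger photoplethysmogram (PPG) whose per-beat
maximum (systolic peak) trails ventricular contraction by the vascular
transit time (VTT). The method assumes resting sinus rhythm (40–180 bpm
admissible, 59–87 bpm typical), S1 louder than S2, and an S1→S2 separation
of roughly 300 ms. It does not model murmurs, S3/S4, arrhythmia or motion
artifacts.

## PCG branch

1. **Band-pass 20–200 Hz**, 4th-order Butterworth applied
   forward–backward (`sosfiltfilt`) so event timing is not shifted. The
   heart sounds live in this band; the filter removes baseline wander and
   high-frequency hiss.
2. **Analytic envelope.** The Hilbert analytic signal gives the envelope
   m(t) = |s_a(t)| and cosine phase cos φ(t) = s(t)/m(t). The envelope
   dominates the rectified signal everywhere (tested property).
3. **Envelope filter (EF, Model III only).** m(t) is band-passed with the
   same 20–200 Hz filter to give m_f(t). Burst regions are the contiguous
   stretches where the magnitude envelope of m_f exceeds δ·mean (δ = 2,
   configurable); gaps shorter than 20 ms are closed and regions shorter
   than 20 ms are ignored — no heart sound is that brief, and boosting
   millisecond noise excursions would swamp the entropy statistics
   downstream. Each region is rescaled so its peak reaches A_ref, the
   maximum of the raw envelope (the S1 amplitude level); the working
   signal is z(t) = m_boosted(t)·cos φ(t). The reference is taken from the
   *raw* envelope because the band-passed envelope attenuates the smooth
   bursts far more than the broadband noise riding on them, making its own
   maximum an unstable extreme-value statistic. For Models I–II the
   working signal is simply m(t)·cos φ(t), i.e. the band-passed PCG.
4. **Shannon entropy.** x̂ = |z| scaled to [0,1] by min–max;
   SE(t) = −x̂·ln x̂ (natural log; bounded by 1/e). The kernel scores the
   burst flanks above both the silent baseline and the saturated peak,
   sharpening one hump per heart sound after smoothing.
5. **Savitzky–Golay smoothing**, window 0.45 s (900 samples at 2 kHz,
   forced odd to 901) and degree 3. The window spans roughly the S1–S2
   interval; degree-3 fitting preserves peak positions and passes cubics
   exactly.
6. **Normalization and impulse conversion.** The smoothed trace is
   min–max normalized to NSE(t) and thresholded:
   `NSE(t) > σ·mean(SE)` with σ = 5, where mean(SE) is the mean of the
   smoothed trace *before* normalization. The normalized trace carries
   broad humps at every heart sound, so its own mean sits near half its
   maximum and a multiplier of 5 on that mean would exceed 1; the
   pre-normalization mean (≈ 0.04–0.15 depending on noise and heart rate)
   adapts the threshold to the record's noise floor.
7. **Event extraction.** Every local maximum (prominence ≥ 0.05) inside a
   supra-threshold run is a candidate event; within one run, secondary
   summits below 0.65× the run's tallest summit are discarded — a much
   weaker hump adjacent to a dominant sound cannot be distinguished from
   structured noise. This gate is what differentiates the model variants
   on S2: without EF the S2 hump typically fails it, with EF the
   equalized hump passes. Candidate times are the summit locations (the
   supra-threshold *onset* would lead the burst center systematically by
   100–160 ms because of the smoothing width, i.e. by more than the
   scoring tolerance; the summit of the symmetric smoother is unbiased).
   Candidates closer than 100 ms are merged keeping the tallest; segment
   results are merged on the absolute clock and deduplicated at 50 ms.

Each analysis window is reflect-padded by 1 s before step 2 and the
padding is cropped from the smoothed trace before step 6, so that FFT and
polynomial edge transients can neither create spurious events nor distort
the normalization statistics.

## PPG branch

Systolic peaks are local maxima of the 0.5–8 Hz band-limited pulse with a
minimum separation of 60/max_hr (default max_hr = 180 bpm) and prominence
at least 0.3× a robust (90th-percentile) beat prominence, which rejects
dicrotic notches. Peak times are refined within ±25 ms to the maximum of
an 80 ms quadratic Savitzky–Golay smoothed copy of the raw signal; the raw
argmax under broadband noise drifts toward the flatter diastolic side of
the pulse.

## Fusion

For each candidate T the nearest systolic peak within
[T − 0.15 s, T + VTT + 0.1 s] is taken as reference (the look-back admits
the geometry where S2 falls shortly after its peak). The candidate is S1
iff T_peak − VTT ≤ T ≤ T_peak − β (VTT = 200 ms, β = 100 ms, endpoints
inclusive), else S2. A ±50 ms slack is applied at the interval endpoints:
with the nominal timing the S1→peak delay sits exactly on the interval
edge, and detection jitter of a few tens of milliseconds would otherwise
flip labels arbitrarily. When two candidates claim the same peak's S1
interval, the earlier keeps S1. Candidates with no peak in scope alternate
from the previous label (first of a close pair → S1). S2 events farther
than 50 ms (20 ms window + 30 ms slack) from every peak are flagged
low-confidence but retained.

## Evaluation

Detections are matched one-to-one to reference events within 60 ms —
below half the minimum S1–S2 gap — by a sweep that attains the
maximum-cardinality matching (verified against an exhaustive oracle).
Matched pair → TP, unmatched detection → FP, unmatched reference → FN.
True negatives in continuous time are defined over half-beat decision
slots bounded by the reference events, the midpoints between consecutive
ones, and the record edges; a slot containing neither a reference nor a
detection is a TN. SEN = TP/(TP+FN), PRE = TP/(TP+FP), SPE = TN/(TN+FP),
ACC = (TP+TN)/total, all ×100; zero denominators yield an undefined flag.
Cohort summaries use the arithmetic mean and the sample standard
deviation (n−1), the convention that reproduces the published AVG/STD
rows from the published per-subject counts.

## Synthetic data

Each beat contributes an S1 burst (Gaussian-windowed 60 Hz tone, ~70 ms,
nominal amplitude 1) at the beat time, an S2 burst (90 Hz, ~50 ms,
amplitude 0.4× its S1) 300 ms later, and a gamma-shaped pulse wave (fast
150 ms rise, slower decay) peaking VTT = 200 ms after the beat. Beat
intervals follow the target heart rate with a 3% coefficient of
variation. Burst amplitudes carry slow respiratory modulation (depth
0.30 at 0.25 Hz) plus 10% per-beat lognormal jitter, applied jointly to a
beat's S1 and S2 so their ratio is fixed — beat-to-beat amplitude
variation is the phenomenon the windowed and envelope-filtered variants
exist to handle, and without it the three models are indistinguishable on
S2. White Gaussian noise is added to both channels at a configurable SNR
(default 20 dB). Annotations carry the exact construction times.

What the generator does **not** emulate: structured noises (speech,
rubbing, motion), murmurs and extra sounds, arrhythmic rhythms,
beat-shape variability of the pulse wave, and per-subject VTT spread.
Passing tests on this data therefore demonstrate the internal consistency
and noise robustness of the chain under its stated assumptions, not
clinical performance.

Note one deliberate timing inconsistency inherited from the method's own
constants: with the default gap of 300 ms and VTT of 200 ms, S2 falls
100 ms *after* the systolic peak rather than 20 ms before it (the two
published descriptions of this timing disagree); the S2-before-peak
construction identity holds exactly when gap = VTT − offset, and the
fusion rule handles both geometries through its look-back scope. As a
consequence, with default timing the S2 revalidation flag marks S2 events
low-confidence; the flag is informational and does not affect scoring.

## Model variants

| Variant | Windowing | Envelope filter |
|---------|-----------|-----------------|
| I       | none (whole record) | no |
| II      | 10 s, non-overlapping | no |
| III     | 10 s, non-overlapping | yes (δ = 2) |

With the window set to the record duration and EF disabled, Model II
reduces exactly to Model I (tested). On the 20-subject synthetic cohort
(59–87 bpm, 20 dB SNR) the S2 performance orders III > II > I, mirroring
the envelope filter's purpose; Model I still detects S1 nearly perfectly.

## Problem sizes and determinism

The shipped benchmarks use 20 subjects × 60 s at 2 kHz; all randomness
flows from explicit integer seeds through `numpy.random.default_rng`, and
identical seeds give bit-identical recordings and event sets. Key
defaults in one place: band-pass 20–200 Hz order 4; EF δ = 2, region
minimum/closing 20 ms; entropy window 0.45 s, degree 3; σ = 5; summit
prominence 0.05, summit gate 0.65; candidate merge 100 ms (50 ms across
windows); VTT 200 ms, β 100 ms, S2 window 20 ms, endpoint slack 50 ms;
matching tolerance 60 ms.

## Known limitations

The entropy-threshold stage is sensitive to the record's noise floor
through the pre-normalization entropy mean; very low-amplitude windows
raise the relative threshold and can cost sensitivity. The summit gate
assumes one dominant sound per run; pathological sounds of comparable
amplitude between S1 and S2 would pass it. The fusion rule uses one
nominal VTT for all subjects; label accuracy degrades as the true delay
leaves the [β, VTT] interval (tested property), and per-subject VTT
calibration is deliberately out of scope.
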