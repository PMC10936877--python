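"""Combining the two networks and the label-assignment heuristics.

The pipeline from probabilities to labels is:

1. median filter (10 ms window) each network's probability track;
2. merge: where the four-class argmax is unilateral or no-song, keep the
   four-class vector and ignore the two-class network; elsewhere average the
   bilateral and no-song probabilities of the two networks and renormalize;
3. per-sample assignment by maximum probability, subject to two gates —
   bilateral needs at least 1.25x the unilateral probability, overlap needs
   probability at least 0.85; a gated-out candidate falls back to the
   highest-probability class that passes its own gate (no-song always
   passes);
4. segment-level cleanup — bilateral segments within 40 ms before or 10 ms
   after unilateral song are reassigned to unilateral unless their bilateral
   probability is (numerically) 1 throughout; then bilateral segments
   shorter than 4 ms are discarded.

The "probability of 1" requirement is implemented as
``p >= prob_one_threshold`` (default 0.999): after median filtering, an
exact 1.0 is unattainable in floating point, and the threshold preserves the
rule's intent that only near-certain bilateral song survives adjacent to
unilateral song.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_core import AudioRecording, Segment, SongClass, labels_to_segments
from .segnet import ProbabilityTrack, SegNet, predict_probability_track


@dataclass(frozen=True)
class FusionConfig:
    """Fusion and heuristic thresholds (defaults: the published values)."""

    median_ms: float = 10.0
    bi_over_uni_ratio: float = 1.25
    overlap_min_prob: float = 0.85
    pre_uni_ms: float = 40.0
    post_uni_ms: float = 10.0
    prob_one_threshold: float = 0.999
    min_bilateral_ms: float = 4.0

    def __post_init__(self) -> None:
        for name in ("median_ms", "bi_over_uni_ratio", "overlap_min_prob",
                     "pre_uni_ms", "post_uni_ms", "min_bilateral_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.prob_one_threshold <= 1:
            raise ValueError("prob_one_threshold must lie in (0, 1]")


def median_filter_track(track: ProbabilityTrack, median_ms: float = 10.0) -> ProbabilityTrack:
    """Per-class sliding median over a centered window, then renormalize.

    The window holds ``round(median_ms * fs / 1000)`` samples (forced odd by
    adding one if even); at the track edges the window shrinks to what fits.
    Vectors are renormalized to sum to 1 after filtering (a degenerate
    all-zero median row becomes uniform).
    """
    if median_ms <= 0:
        raise ValueError("median_ms must be positive")
    w = int(round(median_ms * track.sample_rate_hz / 1000.0))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    probs = track.probs
    if w == 1 or probs.shape[0] <= 1:
        return track
    # pandas' rolling median (centered, min_periods=1) implements exactly the
    # shrinking-window edge behavior and is O(n log w)
    filtered = (
        pd.DataFrame(probs)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    sums = filtered.sum(axis=1, keepdims=True)
    degenerate = sums[:, 0] <= 0
    if np.any(degenerate):
        filtered[degenerate] = 1.0 / probs.shape[1]
        sums[degenerate] = 1.0
    return ProbabilityTrack(filtered / sums, track.class_order, track.sample_rate_hz)


def merge_networks(four: ProbabilityTrack, two: ProbabilityTrack) -> ProbabilityTrack:
    """Average the bilateral/no-song probabilities of the two networks.

    At samples where the four-class argmax is UNILATERAL or NONE the output
    equals the four-class vector (the two-class network is ignored there).
    Elsewhere the BILATERAL and NONE entries become arithmetic means of the
    two tracks' corresponding entries, the UNILATERAL and OVERLAP entries are
    kept from the four-class track, and the vector is renormalized.
    """
    if len(four) != len(two):
        raise ValueError(f"track lengths differ: {len(four)} vs {len(two)}")
    if four.sample_rate_hz != two.sample_rate_hz:
        raise ValueError("track sample rates differ")
    for cls in (SongClass.BILATERAL, SongClass.NONE):
        if cls not in two.class_order:
            raise ValueError("two-class track must carry BILATERAL and NONE")
    argmax = four.argmax_classes()
    keep_four = (argmax == SongClass.UNILATERAL) | (argmax == SongClass.NONE)
    merged = four.probs.copy()
    mix = ~keep_four
    for cls in (SongClass.BILATERAL, SongClass.NONE):
        i4 = four.class_order.index(cls)
        i2 = two.class_order.index(cls)
        merged[mix, i4] = 0.5 * (four.probs[mix, i4] + two.probs[mix, i2])
    sums = merged[mix].sum(axis=1, keepdims=True)
    merged[mix] = merged[mix] / sums
    return ProbabilityTrack(merged, four.class_order, four.sample_rate_hz)


def assign_classes(merged: ProbabilityTrack, cfg: FusionConfig) -> np.ndarray:
    """Per-sample labels: gated argmax over the merged probabilities.

    The candidate is the maximum-probability class; OVERLAP is admissible
    only with probability >= ``overlap_min_prob`` and BILATERAL only with
    probability >= ``bi_over_uni_ratio`` times the unilateral probability.  A
    gated-out candidate is replaced by the highest-probability class passing
    its own gate (NONE always passes).  Ties break toward the fixed order
    NONE < UNILATERAL < BILATERAL < OVERLAP.
    """
    order = (SongClass.NONE, SongClass.UNILATERAL, SongClass.BILATERAL, SongClass.OVERLAP)
    cols = {cls: merged.column(cls) for cls in order}
    p = np.stack([cols[cls] for cls in order], axis=1)
    allowed = np.ones_like(p, dtype=bool)
    allowed[:, 2] = cols[SongClass.BILATERAL] >= cfg.bi_over_uni_ratio * cols[SongClass.UNILATERAL]
    allowed[:, 3] = cols[SongClass.OVERLAP] >= cfg.overlap_min_prob
    gated = np.where(allowed, p, -1.0)
    # argmax returns the first maximum, i.e. the earliest class in the tie order
    winners = gated.argmax(axis=1)
    lut = np.array([int(cls) for cls in order], dtype=np.int8)
    return lut[winners]


def apply_segment_heuristics(
    labels: np.ndarray, merged: ProbabilityTrack, cfg: FusionConfig
) -> np.ndarray:
    """Segment-level cleanup of bilateral predictions.

    Rule 1 (adjacency): every BILATERAL segment intersecting the zone from
    40 ms before a unilateral onset to that onset, or from a unilateral
    offset to 10 ms after it, is relabeled UNILATERAL — unless its minimum
    bilateral probability reaches ``prob_one_threshold``.  Rule 2 (minimum
    duration): remaining BILATERAL segments shorter than 4 ms become NONE.
    Rules run in that order; zones come from the unilateral segments of the
    input labels.
    """
    labels = np.asarray(labels, dtype=np.int8).copy()
    fs = merged.sample_rate_hz
    pre = int(round(cfg.pre_uni_ms * fs / 1000.0))
    post = int(round(cfg.post_uni_ms * fs / 1000.0))
    n = labels.shape[0]
    segments = labels_to_segments(labels)

    zone = np.zeros(n, dtype=bool)
    for seg in segments:
        if seg.song_class == SongClass.UNILATERAL:
            zone[max(0, seg.onset_sample - pre) : seg.onset_sample] = True
            zone[seg.offset_sample : min(n, seg.offset_sample + post)] = True

    p_bi = merged.column(SongClass.BILATERAL)
    for seg in segments:
        if seg.song_class != SongClass.BILATERAL:
            continue
        if zone[seg.onset_sample : seg.offset_sample].any():
            min_p = p_bi[seg.onset_sample : seg.offset_sample].min()
            if min_p < cfg.prob_one_threshold:
                labels[seg.onset_sample : seg.offset_sample] = SongClass.UNILATERAL

    min_len = int(round(cfg.min_bilateral_ms * fs / 1000.0))
    for seg in labels_to_segments(labels):
        if seg.song_class == SongClass.BILATERAL and seg.n_samples < min_len:
            labels[seg.onset_sample : seg.offset_sample] = SongClass.NONE
    return labels


def segment_recording(
    recording: AudioRecording,
    model4: SegNet,
    model2: SegNet,
    cfg: FusionConfig | None = None,
    stride_samples: int | None = None,
) -> tuple[np.ndarray, list[Segment]]:
    """Full segmentation: predict, filter, merge, assign, clean up.

    Returns the final per-sample label track together with its segments.
    Deterministic given the models and the input.
    """
    cfg = cfg or FusionConfig()
    if model4.config.n_classes != 4 or model2.config.n_classes != 2:
        raise ValueError("segment_recording needs a four-class and a two-class model")
    p4 = predict_probability_track(model4, recording, stride_samples)
    p2 = predict_probability_track(model2, recording, stride_samples)
    f4 = median_filter_track(p4, cfg.median_ms)
    f2 = median_filter_track(p2, cfg.median_ms)
    merged = merge_networks(f4, f2)
    labels = assign_classes(merged, cfg)
    labels = apply_segment_heuristics(labels, merged, cfg)
    return labels, labels_to_segments(labels)
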