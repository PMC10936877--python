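"""Sample-wise scoring of predicted label tracks against ground truth.

For each song class, predictions are scored one-vs-rest per sample:
sensitivity (recall) = TP / (TP + FN), positive predictive value (precision)
= TP / (TP + FP), and F, their harmonic mean.  OVERLAP samples count as
positives for *both* the unilateral and the bilateral class, in either
track, mirroring the definition of overlap as both songs at once.

Scoring is sample-wise by default — the natural unit for a per-point
classifier.  ``evaluate_recording`` optionally dilates positives by a
symmetric time tolerance before counting, which forgives pure boundary
shifts (an event-level extension, off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from .audio_core import SongClass


@dataclass(frozen=True)
class ClassScore:
    """One-vs-rest sample counts and the derived metrics for one class.

    Undefined ratios (0/0) are reported as NaN, never silently as 0 or 1;
    check with ``math.isnan``.
    """

    true_positives: int
    false_positives: int
    false_negatives: int

    def __post_init__(self) -> None:
        if min(self.true_positives, self.false_positives, self.false_negatives) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else math.nan

    @property
    def ppv(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else math.nan

    @property
    def f(self) -> float:
        s, p = self.sensitivity, self.ppv
        if math.isnan(s) or math.isnan(p) or s + p == 0:
            return math.nan
        return 2.0 * s * p / (s + p)

    def as_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "f": self.f,
        }


def positive_mask(labels: np.ndarray, target_class: SongClass) -> np.ndarray:
    """One-vs-rest positives; OVERLAP counts for both song classes."""
    labels = np.asarray(labels)
    mask = labels == target_class
    if target_class in (SongClass.UNILATERAL, SongClass.BILATERAL):
        mask = mask | (labels == SongClass.OVERLAP)
    return mask


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, target_class: SongClass
) -> ClassScore:
    """Sample-wise TP/FP/FN for one class (equal-length tracks)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"track lengths differ: {pred.shape} vs {truth.shape}")
    p = positive_mask(pred, target_class)
    t = positive_mask(truth, target_class)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ClassScore(tp, fp, fn)


def score(counts) -> ClassScore:
    """Build a ClassScore from counts (a ClassScore or a (tp, fp, fn) triple)."""
    if isinstance(counts, ClassScore):
        return counts
    tp, fp, fn = counts
    return ClassScore(int(tp), int(fp), int(fn))


def run_synthetic_benchmark(
    seed: int,
    train_minutes: float = 3.0,
    test_minutes: float = 1.0,
    window_samples_4: int = 4001,
    window_samples_2: int = 2001,
    recording_s: float = 60.0,
) -> dict:
    """Train both networks on synthetic duets and score a held-out recording.

    The synthetic counterpart of the published two-network evaluation: trains
    the four-class network (six epochs) and the two-class network (three
    epochs, on the unilateral-stripped split plus extra noise) on
    ``train_minutes`` of generated duet audio, segments ``test_minutes`` of
    held-out audio with the full fusion pipeline, and returns sample-wise
    sensitivity / PPV / F per song class plus the trained models.

    Everything derives from ``seed``; window sizes are parameters so reduced
    sanity runs can reuse the protocol.
    """
    from dataclasses import replace

    from .audio_core import concatenate_recordings
    from .fusion import segment_recording
    from .segnet import SegNetConfig, build_network, extract_training_windows, train_network
    from .synth import (
        DuetConfig,
        EXTRA_NOISE_RATIO,
        _subseed,
        noise_only_config,
        strip_unilateral_portions,
        synth_duet,
    )

    base = DuetConfig(total_duration_s=recording_s, seed=seed)
    n_train = max(1, int(round(train_minutes * 60.0 / recording_s)))
    n_test = max(1, int(round(test_minutes * 60.0 / recording_s)))

    train_recs, train_tracks = [], []
    for i in range(n_train):
        rec, truth = synth_duet(replace(base, seed=_subseed(seed, i)))
        train_recs.append(rec)
        train_tracks.append(truth.labels)
    train_rec, train_labels = concatenate_recordings(train_recs, train_tracks)

    cfg4 = SegNetConfig(window_samples=window_samples_4, seed=seed)
    model4 = build_network(cfg4)
    train_network(model4, extract_training_windows(train_rec, train_labels, cfg4), cfg4)

    # two-class split: strip unilateral/overlap portions, append extra noise
    recs2, tracks2 = [], []
    for rec, labels in zip(train_recs, train_tracks):
        r, l = strip_unilateral_portions(rec, labels)
        recs2.append(r)
        tracks2.append(l)
    noise_s = EXTRA_NOISE_RATIO * train_minutes * 60.0
    n_noise = max(1, int(round(noise_s / recording_s)))
    for i in range(n_noise):
        rec, truth = synth_duet(
            noise_only_config(base, _subseed(seed, 100 + i), noise_s / n_noise)
        )
        recs2.append(rec)
        tracks2.append(truth.labels)
    rec2, labels2 = concatenate_recordings(recs2, tracks2)
    cfg2 = SegNetConfig.two_class(window_samples=window_samples_2, seed=seed)
    model2 = build_network(cfg2)
    train_network(model2, extract_training_windows(rec2, labels2, cfg2), cfg2)

    scores: dict[SongClass, ClassScore] = {}
    n_test_samples = 0
    pooled = {cls: np.zeros(3, dtype=np.int64)
              for cls in (SongClass.UNILATERAL, SongClass.BILATERAL)}
    for i in range(n_test):
        test_rec, test_truth = synth_duet(replace(base, seed=_subseed(seed, 200 + i)))
        labels, _ = segment_recording(test_rec, model4, model2)
        n_test_samples += len(test_rec)
        for cls, sc in evaluate_recording(labels, test_truth.labels).items():
            pooled[cls] += (sc.true_positives, sc.false_positives, sc.false_negatives)
    for cls, (tp, fp, fn) in pooled.items():
        scores[cls] = ClassScore(int(tp), int(fp), int(fn))

    return {
        "scores": scores,
        "model4": model4,
        "model2": model2,
        "n_train_samples": len(train_rec),
        "n_test_samples": n_test_samples,
    }


def evaluate_recording(
    pred: np.ndarray,
    truth: np.ndarray,
    tolerance_ms: float = 0.0,
    sample_rate_hz: float = 10_000.0,
) -> dict[SongClass, ClassScore]:
    """Scores for UNILATERAL and BILATERAL song on one recording.

    With ``tolerance_ms > 0`` the positive masks are dilated symmetrically by
    that amount before counting errors: a predicted positive within the
    tolerance of a true positive is not a false positive, and a true
    positive within the tolerance of a predicted positive is not a false
    negative.  Tolerance 0 (default) is exact sample-wise counting.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"track lengths differ: {pred.shape} vs {truth.shape}")
    radius = int(round(tolerance_ms * sample_rate_hz / 1000.0))
    out: dict[SongClass, ClassScore] = {}
    for cls in (SongClass.UNILATERAL, SongClass.BILATERAL):
        p = positive_mask(pred, cls)
        t = positive_mask(truth, cls)
        if radius > 0:
            t_dil = maximum_filter1d(t.astype(np.uint8), 2 * radius + 1).astype(bool)
            p_dil = maximum_filter1d(p.astype(np.uint8), 2 * radius + 1).astype(bool)
        else:
            t_dil, p_dil = t, p
        tp = int(np.count_nonzero(p & t_dil))
        fp = int(np.count_nonzero(p & ~t_dil))
        fn = int(np.count_nonzero(t & ~p_dil))
        out[cls] = ClassScore(tp, fp, fn)
    return out
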