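"""Network fusion, heuristic gates, and segment-level cleanup."""

import numpy as np
import pytest

from duetseg import (
    FusionConfig,
    ProbabilityTrack,
    SongClass,
    apply_segment_heuristics,
    assign_classes,
    median_filter_track,
    merge_networks,
    segment_recording,
)
from duetseg.segnet import FOUR_CLASS_ORDER, TWO_CLASS_ORDER

FS = 10_000.0
# column order used by the helpers below: (NONE, UNILATERAL, BILATERAL, OVERLAP)
N, U, B, O = 0, 1, 2, 3


def _track4(rows):
    return ProbabilityTrack(np.asarray(rows, dtype=float), FOUR_CLASS_ORDER, FS)


def _track2(rows):
    return ProbabilityTrack(np.asarray(rows, dtype=float), TWO_CLASS_ORDER, FS)


def _random_track(rng, n, k=4):
    raw = rng.dirichlet(np.ones(k), size=n)
    order = FOUR_CLASS_ORDER if k == 4 else TWO_CLASS_ORDER
    return ProbabilityTrack(raw, order, FS)


def _brute_force_median(probs, w):
    """Naive sliding median with a shrinking centered window."""
    n, c = probs.shape
    half = w // 2
    out = np.empty_like(probs)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = np.median(probs[lo:hi], axis=0)
    return out


class TestMedianFilter:
    def test_constant_track_unchanged(self):
        track = _track4(np.tile([0.1, 0.2, 0.3, 0.4], (500, 1)))
        out = median_filter_track(track, 10.0)
        np.testing.assert_allclose(out.probs, track.probs, atol=1e-12)

    def test_single_sample_spike_removed(self):
        probs = np.tile([0.9, 0.1, 0.0, 0.0], (400, 1))
        probs[200] = [0.0, 0.0, 1.0, 0.0]
        out = median_filter_track(_track4(probs), 10.0)  # 101-sample window
        assert out.argmax_classes()[200] == SongClass.NONE

    def test_matches_bruteforce_sliding_median(self, rng):
        track = _random_track(rng, 300)
        out = median_filter_track(track, 10.0)
        expected = _brute_force_median(track.probs, 101)
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.probs, expected, atol=1e-12)

    def test_commutes_with_class_permutation(self, rng):
        track = _random_track(rng, 300)
        perm = [2, 0, 3, 1]
        permuted = ProbabilityTrack(track.probs[:, perm], FOUR_CLASS_ORDER, FS)
        a = median_filter_track(permuted, 10.0).probs
        b = median_filter_track(track, 10.0).probs[:, perm]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestMergeNetworks:
    def test_four_class_kept_verbatim_where_argmax_uni_or_none(self):
        four = _track4([[0.5, 0.3, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1]])
        two = _track2([[0.1, 0.9], [0.1, 0.9]])
        merged = merge_networks(four, two)
        np.testing.assert_allclose(merged.probs, four.probs)

    def test_bilateral_and_none_averaged_then_renormalized(self):
        # spec-style arithmetic: four=(U .1, B .6, O 0, N .3), two=(B .8, N .2)
        four = _track4([[0.3, 0.1, 0.6, 0.0]])
        two = _track2([[0.2, 0.8]])
        merged = merge_networks(four, two)
        raw = np.array([0.25, 0.1, 0.7, 0.0])  # N, U, B, O before renorm
        np.testing.assert_allclose(merged.probs[0], raw / raw.sum(), atol=1e-12)

    def test_idempotent_when_tracks_agree(self):
        four = _track4([[0.2, 0.05, 0.7, 0.05]])
        two = _track2([[0.2 / 0.9, 0.7 / 0.9]])
        merged = merge_networks(four, two)
        # averaging equal (rescaled) values keeps the four-class argmax
        assert merged.argmax_classes()[0] == SongClass.BILATERAL

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="lengths differ"):
            merge_networks(_random_track(rng, 10), _random_track(rng, 9, k=2))


class TestAssignClasses:
    def test_bilateral_needs_ratio_over_unilateral(self):
        # p_B=.50 vs 1.25*p_U=.5625 -> unilateral wins
        track = _track4([[0.05, 0.45, 0.50, 0.0]])
        assert assign_classes(track, FusionConfig())[0] == SongClass.UNILATERAL
        # p_B=.55 vs 1.25*.40=.50 -> bilateral allowed
        track = _track4([[0.05, 0.40, 0.55, 0.0]])
        assert assign_classes(track, FusionConfig())[0] == SongClass.BILATERAL

    def test_overlap_needs_085_floor_with_fallback(self):
        # O=.84 fails the floor; B=.05 fails the ratio; N=.06 is next best
        track = _track4([[0.06, 0.05, 0.05, 0.84]])
        assert assign_classes(track, FusionConfig())[0] == SongClass.NONE
        track = _track4([[0.05, 0.04, 0.05, 0.86]])
        assert assign_classes(track, FusionConfig())[0] == SongClass.OVERLAP

    def test_reduces_to_argmax_with_permissive_gates(self, rng):
        track = _random_track(rng, 2000)
        cfg = FusionConfig(bi_over_uni_ratio=1e-9, overlap_min_prob=1e-9)
        labels = assign_classes(track, cfg)
        assert np.array_equal(labels, track.argmax_classes())

    def test_raising_ratio_never_adds_bilateral(self, rng):
        track = _random_track(rng, 3000)
        counts = []
        for ratio in (1.0, 1.25, 2.0, 5.0):
            cfg = FusionConfig(bi_over_uni_ratio=ratio)
            labels = assign_classes(track, cfg)
            counts.append(int(np.sum(labels == SongClass.BILATERAL)))
        assert counts == sorted(counts, reverse=True)

    def test_raising_overlap_floor_never_adds_overlap(self, rng):
        track = _random_track(rng, 3000)
        counts = []
        for floor in (0.05, 0.5, 0.85, 0.99):
            cfg = FusionConfig(overlap_min_prob=floor)
            labels = assign_classes(track, cfg)
            counts.append(int(np.sum(labels == SongClass.OVERLAP)))
        assert counts == sorted(counts, reverse=True)


def _track_with_bi(labels, p_bi_value=0.9):
    """A merged-style track whose bilateral probability is constant."""
    n = labels.size
    rest = np.array([0.5, 0.3, 0.0, 0.2]) * (1.0 - p_bi_value)  # N, U, B, O
    probs = np.tile(rest, (n, 1))
    probs[:, B] = p_bi_value
    return ProbabilityTrack(probs, FOUR_CLASS_ORDER, FS)


class TestSegmentHeuristics:
    def _labels(self, spans, n=20_000):
        labels = np.zeros(n, dtype=np.int8)
        for on, off, cls in spans:
            labels[on:off] = cls
        return labels

    def test_bilateral_before_unilateral_is_absorbed(self):
        # bilateral ends 20 ms before a unilateral onset, max p_B = 0.9
        labels = self._labels([
            (1000, 1500, SongClass.BILATERAL),
            (1700, 2500, SongClass.UNILATERAL),
        ])
        merged = _track_with_bi(labels, 0.9)
        out = apply_segment_heuristics(labels, merged, FusionConfig())
        assert np.all(out[1000:1500] == SongClass.UNILATERAL)

    def test_high_probability_bilateral_survives_adjacency(self):
        labels = self._labels([
            (1000, 1500, SongClass.BILATERAL),
            (1700, 2500, SongClass.UNILATERAL),
        ])
        merged = _track_with_bi(labels, 0.9995)
        out = apply_segment_heuristics(
            labels, merged, FusionConfig(prob_one_threshold=0.999)
        )
        assert np.all(out[1000:1500] == SongClass.BILATERAL)

    def test_short_isolated_bilateral_discarded(self):
        # 3 ms (30 samples at 10 kHz) < 4 ms minimum
        labels = self._labels([(5000, 5030, SongClass.BILATERAL)])
        out = apply_segment_heuristics(labels, _track_with_bi(labels), FusionConfig())
        assert np.all(out[5000:5030] == SongClass.NONE)

    def test_long_isolated_bilateral_unchanged(self):
        labels = self._labels([(5000, 5500, SongClass.BILATERAL)])  # 50 ms
        out = apply_segment_heuristics(labels, _track_with_bi(labels), FusionConfig())
        assert np.array_equal(out, labels)

    def test_bilateral_after_unilateral_within_10ms_absorbed(self):
        labels = self._labels([
            (1000, 2000, SongClass.UNILATERAL),
            (2050, 2600, SongClass.BILATERAL),  # 5 ms after the offset
        ])
        out = apply_segment_heuristics(labels, _track_with_bi(labels), FusionConfig())
        assert np.all(out[2050:2600] == SongClass.UNILATERAL)

    def test_far_bilateral_not_absorbed(self):
        labels = self._labels([
            (1000, 2000, SongClass.UNILATERAL),
            (3000, 3600, SongClass.BILATERAL),  # 100 ms after the offset
        ])
        out = apply_segment_heuristics(labels, _track_with_bi(labels), FusionConfig())
        assert np.all(out[3000:3600] == SongClass.BILATERAL)


class TestSegmentRecording:
    def test_idempotent_and_consistent(self, small_models, heldout_duet_60s):
        from duetseg import AudioRecording

        m4, m2 = small_models
        rec, _ = heldout_duet_60s
        short = AudioRecording(rec.samples[:50_000], rec.sample_rate_hz)
        labels1, segs1 = segment_recording(short, m4, m2)
        labels2, segs2 = segment_recording(short, m4, m2)
        assert np.array_equal(labels1, labels2)
        assert segs1 == segs2

    def test_pure_noise_recording_yields_no_song(self, small_models):
        from duetseg import DuetConfig, synth_duet

        m4, m2 = small_models
        cfg = DuetConfig(total_duration_s=10.0, uni_bout_rate_per_s=0.0,
                         transient_rate_per_s=0.0, seed=55)
        rec, _ = synth_duet(cfg)
        labels, segs = segment_recording(rec, m4, m2)
        # allow at most trace-level spurious song on pure background noise
        assert (labels != SongClass.NONE).mean() < 0.01

    def test_resubstitution_sensitivity(self, small_models, duet_60s):
        """Segmenting a training recording recovers nearly all song."""
        from duetseg import evaluate_recording

        m4, m2 = small_models
        rec, truth = duet_60s
        labels, _ = segment_recording(rec, m4, m2)
        scores = evaluate_recording(labels, truth.labels)
        assert scores[SongClass.UNILATERAL].sensitivity >= 0.90
        assert scores[SongClass.BILATERAL].sensitivity >= 0.90
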