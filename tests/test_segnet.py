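"""Window classifier: shapes, determinism, training dynamics, inference."""

import numpy as np
import pytest

from duetseg import (
    AudioRecording,
    SegNetConfig,
    SongClass,
    build_network,
    extract_training_windows,
    load_checkpoint,
    parameter_count,
    predict_probability_track,
    save_checkpoint,
    train_network,
    window_duration_ms,
)
from duetseg.segnet import WindowSet

FS = 10_000.0


class TestWindowDuration:
    @pytest.mark.parametrize(
        "window,rate,expected",
        [(4001, 10_000.0, 400.1), (2001, 10_000.0, 200.1), (1, 1000.0, 1.0)],
    )
    def test_durations(self, window, rate, expected):
        cfg = SegNetConfig(window_samples=window) if window % 2 else None
        cfg = SegNetConfig(window_samples=window)
        assert window_duration_ms(cfg, rate) == pytest.approx(expected)


class TestBuildNetwork:
    def test_output_is_normalized_probability_vector(self, rng):
        cfg = SegNetConfig(window_samples=201, seed=0)
        model = build_network(cfg)
        x = rng.standard_normal((7, 201))
        probs = model(x)
        assert probs.shape == (7, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_same_config_and_seed_give_identical_parameters(self):
        cfg = SegNetConfig(window_samples=201, seed=3)
        a, b = build_network(cfg), build_network(cfg)
        assert np.array_equal(a.conv_weights, b.conv_weights)
        assert np.array_equal(a.dense_weights, b.dense_weights)

    @pytest.mark.parametrize("cfg", [SegNetConfig(), SegNetConfig.two_class()])
    def test_parameter_count_matches_shape_arithmetic(self, cfg):
        model = build_network(cfg)
        # closed form from the layer shapes:
        # conv: kernel*filters + filters; dense: (conv_out//2)*filters*classes + classes
        conv_out = cfg.window_samples + 2 * cfg.padding - cfg.kernel_size + 1
        expected = (
            cfg.kernel_size * cfg.n_filters + cfg.n_filters
            + (conv_out // 2) * cfg.n_filters * cfg.n_classes + cfg.n_classes
        )
        assert model.n_parameters == expected == parameter_count(cfg)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            SegNetConfig(window_samples=4000)  # even window has no center
        with pytest.raises(ValueError):
            SegNetConfig(train_fraction=0.0)
        with pytest.raises(ValueError):
            SegNetConfig(n_classes=3)


class TestExtractTrainingWindows:
    def test_fraction_one_uses_every_sample(self):
        rec = AudioRecording(np.zeros(500), FS)
        cfg = SegNetConfig(window_samples=101, train_fraction=1.0)
        ws = extract_training_windows(rec, np.zeros(500, dtype=np.int8), cfg)
        assert len(ws) == 500

    def test_all_none_truth_labels_every_window_none(self, rng):
        rec = AudioRecording(rng.standard_normal(1000), FS)
        cfg = SegNetConfig(window_samples=101, train_fraction=0.5)
        ws = extract_training_windows(rec, np.zeros(1000, dtype=np.int8), cfg)
        assert np.all(ws.labels == 0)  # NONE is column 0

    def test_sampled_label_proportions_track_truth(self, rng):
        n = 100_000
        truth = rng.integers(0, 4, n).astype(np.int8)
        rec = AudioRecording(rng.standard_normal(n), FS)
        cfg = SegNetConfig(window_samples=101, train_fraction=0.1, seed=5)
        ws = extract_training_windows(rec, truth, cfg)
        assert len(ws) == 10_000
        true_props = np.bincount(truth, minlength=4) / n
        got_props = ws.class_counts() / len(ws)
        # 3-sigma hypergeometric bound for a 10% sample without replacement
        k = len(ws)
        sigma = np.sqrt(true_props * (1 - true_props) / k * (1 - k / n))
        assert np.all(np.abs(got_props - true_props) <= 3 * sigma)

    def test_recording_shorter_than_window_rejected(self):
        rec = AudioRecording(np.zeros(50), FS)
        cfg = SegNetConfig(window_samples=101)
        with pytest.raises(ValueError, match="shorter than one window"):
            extract_training_windows(rec, np.zeros(50, dtype=np.int8), cfg)

    def test_window_center_sample_matches_signal(self, rng):
        x = rng.standard_normal(300)
        rec = AudioRecording(x, FS)
        cfg = SegNetConfig(window_samples=31, train_fraction=1.0)
        ws = extract_training_windows(rec, np.zeros(300, dtype=np.int8), cfg)
        windows, _ = ws.materialize()
        np.testing.assert_allclose(windows[:, 15], x.astype(np.float32))


def _toy_windowset(rng, n=2000, window=51, n_classes=2):
    """Separable toy task: the window's DC offset sign determines the class."""
    offsets = rng.choice([-0.5, 0.5], size=n)
    windows = rng.standard_normal((n, window)).astype(np.float32) * 0.1
    windows += offsets[:, None]
    labels = (offsets > 0).astype(np.int64)
    padded = None

    class _Materialized(WindowSet):
        def batch(self, idx):
            return windows[idx], labels[idx]

    ws = _Materialized(
        padded=np.zeros(1, dtype=np.float32), centers=np.arange(n),
        labels=labels, window_samples=window,
        class_order=(SongClass.NONE, SongClass.BILATERAL),
    )
    return ws, windows, labels


class TestTrainNetwork:
    def test_separable_toy_problem_reaches_high_accuracy(self, rng):
        ws, windows, labels = _toy_windowset(rng)
        cfg = SegNetConfig.two_class(window_samples=51, epochs=5, seed=0,
                                     learning_rate=3e-3)
        model = build_network(cfg)
        _, losses = train_network(model, ws, cfg)
        assert len(losses) == 5
        assert losses[-1] <= losses[0]  # non-increasing first to last
        acc = (model(windows).argmax(axis=1) == labels).mean()
        assert acc >= 0.99

    def test_zero_epochs_leave_model_unchanged(self, rng):
        ws, _, _ = _toy_windowset(rng, n=200)
        cfg = SegNetConfig.two_class(window_samples=51, epochs=0, seed=0)
        model = build_network(cfg)
        before = model.conv_weights.copy()
        _, losses = train_network(model, ws, cfg)
        assert losses == []
        assert np.array_equal(model.conv_weights, before)

    def test_same_windows_and_seed_give_identical_parameters(self, rng):
        ws, _, _ = _toy_windowset(rng, n=500)
        cfg = SegNetConfig.two_class(window_samples=51, epochs=2, seed=4)
        m1, m2 = build_network(cfg), build_network(cfg)
        train_network(m1, ws, cfg)
        train_network(m2, ws, cfg)
        assert np.array_equal(m1.conv_weights, m2.conv_weights)
        assert np.array_equal(m1.dense_weights, m2.dense_weights)

    def test_absent_class_warns_but_trains(self, rng):
        ws, _, _ = _toy_windowset(rng, n=300)
        ws.labels[:] = 0  # only NONE present
        cfg = SegNetConfig.two_class(window_samples=51, epochs=1, seed=0)
        model = build_network(cfg)
        with pytest.warns(UserWarning, match="absent"):
            train_network(model, ws, cfg)


class TestPredictProbabilityTrack:
    def test_repeated_prediction_is_identical(self, rng):
        rec = AudioRecording(rng.standard_normal(2000), FS)
        cfg = SegNetConfig(window_samples=201, stride_samples=1, seed=0)
        model = build_network(cfg)
        a = predict_probability_track(model, rec)
        b = predict_probability_track(model, rec)
        assert np.array_equal(a.probs, b.probs)

    def test_constant_input_gives_constant_track(self):
        rec = AudioRecording(np.full(3000, 0.2), FS)
        cfg = SegNetConfig(window_samples=201, stride_samples=1, seed=1)
        model = build_network(cfg)
        track = predict_probability_track(model, rec)
        interior = track.probs[100:-100]  # away from edge padding effects
        assert np.abs(interior - interior[0]).max() <= 1e-6

    def test_track_length_and_normalization(self, rng):
        rec = AudioRecording(rng.standard_normal(2000), FS)
        cfg = SegNetConfig(window_samples=201, stride_samples=7, seed=0)
        model = build_network(cfg)
        track = predict_probability_track(model, rec)
        assert len(track) == 2000
        np.testing.assert_allclose(track.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_stride_10_nearly_matches_stride_1(self, small_models, heldout_duet_60s):
        """Strided inference with nearest-center fill disagrees with exact
        per-sample inference on <2% of samples (smooth synthetic song)."""
        m4, _ = small_models
        rec, _ = heldout_duet_60s
        short = AudioRecording(rec.samples[:30_000], rec.sample_rate_hz)
        exact = predict_probability_track(m4, short, stride_samples=1)
        strided = predict_probability_track(m4, short, stride_samples=10)
        disagree = (exact.argmax_classes() != strided.argmax_classes()).mean()
        assert disagree < 0.02

    def test_too_short_recording_rejected(self):
        cfg = SegNetConfig(window_samples=201)
        model = build_network(cfg)
        with pytest.raises(ValueError, match="shorter than one window"):
            predict_probability_track(model, AudioRecording(np.zeros(100), FS))


class TestHeldOutAccuracy:
    def test_center_sample_accuracy_on_clean_duets(
        self, small_models, heldout_duet_60s
    ):
        """Learning sanity at high SNR: held-out center-sample accuracy
        >= 0.90 (four-class) and >= 0.95 (two-class, on its own classes)."""
        m4, m2 = small_models
        rec, truth = heldout_duet_60s
        pred4 = predict_probability_track(m4, rec).argmax_classes()
        acc4 = (pred4 == truth.labels).mean()
        assert acc4 >= 0.90

        pred2 = predict_probability_track(m2, rec).argmax_classes()
        keep = (truth.labels == SongClass.BILATERAL) | (truth.labels == SongClass.NONE)
        acc2 = (pred2[keep] == truth.labels[keep]).mean()
        assert acc2 >= 0.95


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        cfg = SegNetConfig(window_samples=201, seed=2)
        model = build_network(cfg)
        x = rng.standard_normal((5, 201))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.config == cfg
        np.testing.assert_array_equal(model(x), back(x))
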