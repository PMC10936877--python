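"""Convolutional window classifiers for per-sample song classification.

Two networks share one architecture and differ only in configuration: a
four-class network (window 4001 samples = 400.1 ms at 10 kHz; classes none /
unilateral / bilateral / overlap; six training epochs) and a two-class
network (window 2001 samples = 200.1 ms; bilateral vs. no song; three
epochs).  Both take the raw microphone amplitudes of a window centered on
the sample being classified and emit a class-probability vector for that
center sample:

    conv1d (16 filters, kernel 9, zero padding 4) -> ReLU -> max pool (2)
    -> flatten -> dense -> softmax

Training draws a random fraction (default 10%) of the samples of the
annotated corpus as window centers, labels each window by its center
sample's class, and minimizes cross-entropy with Adam over a fixed number of
epochs at batch size 128.  Everything is seeded: config + seed + data fix
the trained parameters bit-for-bit.

The conv+pool forward and backward passes are fused numba kernels (the
windows of one batch never materialize their full conv feature maps), which
keeps minute-scale corpora trainable on one CPU; the dense layer runs on
BLAS.  Inference evaluates windows at a configurable stride (default 10
samples = 1 ms) and assigns every sample the probability vector of its
nearest evaluated center; stride 1 reproduces literal per-sample
classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .audio_core import AudioRecording, SongClass

FOUR_CLASS_ORDER = (
    SongClass.NONE, SongClass.UNILATERAL, SongClass.BILATERAL, SongClass.OVERLAP
)
TWO_CLASS_ORDER = (SongClass.NONE, SongClass.BILATERAL)


@dataclass(frozen=True)
class SegNetConfig:
    """Hyperparameters of one window classifier.

    Defaults are the published segmenter settings; ``learning_rate``,
    the optimizer, and ``stride_samples`` are artifact choices (the original
    description does not state them) and are exposed here.
    """

    n_classes: int = 4
    window_samples: int = 4001
    batch_size: int = 128
    epochs: int = 6
    n_filters: int = 16
    kernel_size: int = 9
    padding: int = 4
    pool_size: int = 2
    train_fraction: float = 0.10
    learning_rate: float = 1e-3
    stride_samples: int = 10
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if self.window_samples <= 0 or self.window_samples % 2 == 0:
            raise ValueError("window_samples must be odd (a window has a center sample)")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must lie in (0, 1]")
        if self.pool_size != 2:
            raise ValueError("only pool_size 2 is supported")
        if self.kernel_size <= 0 or self.n_filters <= 0 or self.batch_size <= 0:
            raise ValueError("kernel_size, n_filters and batch_size must be positive")
        if self.padding < 0 or self.epochs < 0 or self.stride_samples <= 0:
            raise ValueError("invalid padding, epochs, or stride_samples")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @classmethod
    def four_class(cls, **overrides) -> "SegNetConfig":
        return cls(**overrides)

    @classmethod
    def two_class(cls, **overrides) -> "SegNetConfig":
        defaults = dict(n_classes=2, window_samples=2001, epochs=3)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def conv_output_samples(self) -> int:
        return self.window_samples + 2 * self.padding - self.kernel_size + 1

    @property
    def pooled_samples(self) -> int:
        return self.conv_output_samples // self.pool_size

    @property
    def class_order(self) -> tuple[SongClass, ...]:
        return FOUR_CLASS_ORDER if self.n_classes == 4 else TWO_CLASS_ORDER


def window_duration_ms(config: SegNetConfig, sample_rate_hz: float = 10_000.0) -> float:
    """Window length in milliseconds (4001 samples at 10 kHz -> 400.1 ms)."""
    return config.window_samples / sample_rate_hz * 1000.0


@dataclass(frozen=True)
class ProbabilityTrack:
    """Per-sample class-probability vectors over a fixed class order."""

    probs: np.ndarray
    class_order: tuple[SongClass, ...]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != len(self.class_order):
            raise ValueError(
                f"probs must be (n_samples, {len(self.class_order)}), got {probs.shape}"
            )
        if np.any(probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=1)
        if probs.shape[0] and not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each probability vector must sum to 1 within 1e-6")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "class_order", tuple(self.class_order))

    def __len__(self) -> int:
        return self.probs.shape[0]

    def column(self, song_class: SongClass) -> np.ndarray:
        return self.probs[:, self.class_order.index(song_class)]

    def argmax_classes(self) -> np.ndarray:
        """Per-sample argmax as SongClass values (ties -> earliest in order)."""
        idx = self.probs.argmax(axis=1)
        lut = np.array([int(c) for c in self.class_order], dtype=np.int8)
        return lut[idx]


# ---------------------------------------------------------------------------
# Fused conv + bias + max-pool + ReLU kernels
# ---------------------------------------------------------------------------
# The input to each kernel is a batch of windows already zero-padded for the
# convolution: shape (B, window + 2*padding), float32.  `n_pooled` pooled
# positions cover conv outputs 0 .. 2*n_pooled-1.


@njit(cache=True, fastmath=True)
def _conv_pool_forward(xp, weights, bias, n_pooled):  # pragma: no cover - numba
    n_windows = xp.shape[0]
    kernel, n_filters = weights.shape
    act = np.empty((n_windows, n_pooled, n_filters), np.float32)
    sel = np.empty((n_windows, n_pooled, n_filters), np.uint8)
    a0 = np.empty(n_filters, np.float32)
    a1 = np.empty(n_filters, np.float32)
    for b in range(n_windows):
        x = xp[b]
        for j in range(n_pooled):
            base = 2 * j
            for f in range(n_filters):
                a0[f] = bias[f]
                a1[f] = bias[f]
            for k in range(kernel):
                xv0 = x[base + k]
                xv1 = x[base + 1 + k]
                wk = weights[k]
                for f in range(n_filters):
                    a0[f] += xv0 * wk[f]
                    a1[f] += xv1 * wk[f]
            for f in range(n_filters):
                if a0[f] >= a1[f]:
                    sel[b, j, f] = 0
                    act[b, j, f] = a0[f] if a0[f] > 0 else 0.0
                else:
                    sel[b, j, f] = 1
                    act[b, j, f] = a1[f] if a1[f] > 0 else 0.0
    return act, sel


@njit(cache=True, fastmath=True)
def _conv_pool_backward(xp, dact, act, sel, kernel):  # pragma: no cover - numba
    n_windows, n_pooled, n_filters = dact.shape
    n_conv = 2 * n_pooled
    d_weights = np.zeros((kernel, n_filters), np.float32)
    d_bias = np.zeros(n_filters, np.float32)
    dconv = np.empty((n_conv, n_filters), np.float32)
    for b in range(n_windows):
        x = xp[b]
        for j in range(n_conv):
            for f in range(n_filters):
                dconv[j, f] = 0.0
        for j in range(n_pooled):
            for f in range(n_filters):
                if act[b, j, f] > 0:
                    g = dact[b, j, f]
                    if g != 0.0:
                        dconv[2 * j + sel[b, j, f], f] = g
                        d_bias[f] += g
        for k in range(kernel):
            wrow = d_weights[k]
            for j in range(n_conv):
                xv = x[j + k]
                for f in range(n_filters):
                    wrow[f] += xv * dconv[j, f]
    return d_weights, d_bias


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class SegNet:
    """One window classifier with explicit float32 parameters."""

    def __init__(self, config: SegNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, f = config.kernel_size, config.n_filters
        n_dense_in = config.pooled_samples * f
        # He initialization for the conv, small Gaussian for the dense layer
        self.conv_weights = (
            rng.standard_normal((k, f)) * np.sqrt(2.0 / k)
        ).astype(np.float32)
        self.conv_bias = np.zeros(f, dtype=np.float32)
        self.dense_weights = (
            rng.standard_normal((n_dense_in, config.n_classes))
            * np.sqrt(1.0 / n_dense_in)
        ).astype(np.float32)
        self.dense_bias = np.zeros(config.n_classes, dtype=np.float32)

    @property
    def class_order(self) -> tuple[SongClass, ...]:
        return self.config.class_order

    @property
    def n_parameters(self) -> int:
        return (
            self.conv_weights.size + self.conv_bias.size
            + self.dense_weights.size + self.dense_bias.size
        )

    def _parameters(self):
        return [self.conv_weights, self.conv_bias, self.dense_weights, self.dense_bias]

    def _pad_windows(self, windows: np.ndarray) -> np.ndarray:
        pad = self.config.padding
        out = np.zeros(
            (windows.shape[0], windows.shape[1] + 2 * pad), dtype=np.float32
        )
        out[:, pad : pad + windows.shape[1]] = windows
        return out

    def forward(self, windows: np.ndarray, return_state: bool = False):
        """Probabilities for a batch of raw windows (B, window_samples)."""
        windows = np.asarray(windows, dtype=np.float32)
        if windows.ndim != 2 or windows.shape[1] != self.config.window_samples:
            raise ValueError(
                f"expected windows of shape (B, {self.config.window_samples}), "
                f"got {windows.shape}"
            )
        xp = self._pad_windows(windows)
        act, sel = _conv_pool_forward(
            xp, self.conv_weights, self.conv_bias, self.config.pooled_samples
        )
        flat = act.reshape(windows.shape[0], -1)
        logits = (flat @ self.dense_weights + self.dense_bias).astype(np.float64)
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        if return_state:
            return probs, (xp, act, sel, flat)
        return probs

    def __call__(self, windows: np.ndarray) -> np.ndarray:
        return self.forward(windows)


def build_network(config: SegNetConfig) -> SegNet:
    """Deterministically initialize a window classifier from its config."""
    return SegNet(config)


def parameter_count(config: SegNetConfig) -> int:
    """Closed-form parameter count implied by the layer shapes."""
    conv = config.kernel_size * config.n_filters + config.n_filters
    dense = config.pooled_samples * config.n_filters * config.n_classes + config.n_classes
    return conv + dense


# ---------------------------------------------------------------------------
# Training windows
# ---------------------------------------------------------------------------


@dataclass
class WindowSet:
    """Lazily materialized labeled training windows.

    Holds the symmetrically padded signal plus the sampled center indices
    and their labels; batches of raw windows are gathered on demand so that
    a 10% sample of a minutes-long corpus never materializes at once.
    """

    padded: np.ndarray          # float32, length n + window - 1
    centers: np.ndarray         # int64 center sample indices
    labels: np.ndarray          # int64 class-column indices
    window_samples: int
    class_order: tuple[SongClass, ...]

    def __len__(self) -> int:
        return self.centers.shape[0]

    def batch(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        view = np.lib.stride_tricks.sliding_window_view(
            self.padded, self.window_samples
        )
        return view[self.centers[idx]], self.labels[idx]

    def materialize(self) -> tuple[np.ndarray, np.ndarray]:
        return self.batch(np.arange(len(self)))

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_order))


def extract_training_windows(
    recording: AudioRecording,
    truth_labels: np.ndarray,
    config: SegNetConfig,
    seed: int | None = None,
) -> WindowSet:
    """Sample labeled training windows from an annotated recording.

    ``round(train_fraction * n)`` center samples are drawn uniformly at
    random without replacement; each window is the raw signal centered on
    its center sample (symmetric signal padding at the edges) and is labeled
    by the center sample's class.

    Raises
    ------
    ValueError
        If the recording is shorter than one window, or the truth track
        contains a class the network does not model.
    """
    n = len(recording)
    if n < config.window_samples:
        raise ValueError(
            f"recording of {n} samples is shorter than one window "
            f"({config.window_samples} samples)"
        )
    truth_labels = np.asarray(truth_labels)
    if truth_labels.shape[0] != n:
        raise ValueError("truth labels must align with the recording")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = int(round(config.train_fraction * n))
    k = max(1, min(k, n))
    centers = np.sort(rng.choice(n, size=k, replace=False))
    class_values = np.array([int(c) for c in config.class_order])
    lut = np.full(int(max(SongClass)) + 1, -1, dtype=np.int64)
    lut[class_values] = np.arange(len(class_values))
    labels = lut[truth_labels[centers]]
    if np.any(labels < 0):
        bad = {SongClass(int(v)).name for v in np.unique(truth_labels[centers])
               if lut[int(v)] < 0}
        raise ValueError(
            f"truth contains classes {sorted(bad)} not modeled by this network"
        )
    half = config.window_samples // 2
    padded = np.pad(recording.samples, half, mode="symmetric").astype(np.float32)
    return WindowSet(padded, centers, labels, config.window_samples, config.class_order)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)


def train_network(
    model: SegNet,
    windows: WindowSet,
    config: SegNetConfig | None = None,
) -> tuple[SegNet, list[float]]:
    """Train in place for ``config.epochs`` epochs; returns (model, loss log).

    Runs seeded shuffled mini-batches of ``batch_size`` windows with softmax
    cross-entropy loss and Adam updates.  The loss log holds the per-epoch
    mean training loss.  A class with no training windows triggers a warning
    (not an error).  ``epochs=0`` leaves the model untouched.
    """
    config = config or model.config
    counts = windows.class_counts()
    for cls, count in zip(windows.class_order, counts):
        if count == 0:
            warnings.warn(
                f"class {cls.name} absent from the training windows", stacklevel=2
            )
    if config.class_weighting:
        total = counts.sum()
        weights = np.where(counts > 0, total / np.maximum(counts, 1), 0.0)
        weights = (weights / weights[counts > 0].mean()).astype(np.float64)
    else:
        weights = np.ones(len(windows.class_order))

    rng = np.random.default_rng(config.seed + 1)
    params = model._parameters()
    adam = _Adam(params, config.learning_rate)
    loss_log: list[float] = []
    n = len(windows)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch_x, batch_y = windows.batch(idx)
            loss, grads = _loss_and_grads(model, batch_x, batch_y, weights)
            adam.step(params, grads)
            epoch_loss += loss * idx.shape[0]
        loss_log.append(epoch_loss / n)
    return model, loss_log


def _loss_and_grads(model, batch_x, batch_y, class_weights):
    b = batch_x.shape[0]
    probs, (xp, act, sel, flat) = model.forward(batch_x, return_state=True)
    w = class_weights[batch_y]
    w_norm = w / w.sum()
    eps = 1e-12
    loss = float(-(w_norm * np.log(probs[np.arange(b), batch_y] + eps)).sum())
    dlogits = probs * w_norm[:, None]
    dlogits[np.arange(b), batch_y] -= w_norm
    dlogits = dlogits.astype(np.float32)
    d_dense_w = flat.T @ dlogits
    d_dense_b = dlogits.sum(axis=0)
    dact = (dlogits @ model.dense_weights.T).reshape(act.shape)
    d_conv_w, d_conv_b = _conv_pool_backward(
        xp, dact, act, sel, model.config.kernel_size
    )
    return loss, [d_conv_w, d_conv_b, d_dense_w, d_dense_b]


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def predict_probability_track(
    model: SegNet,
    recording: AudioRecording,
    stride_samples: int | None = None,
    batch_windows: int = 256,
) -> ProbabilityTrack:
    """Class probabilities for every sample of a recording.

    Windows are evaluated at ``stride_samples`` (default from the model
    config) and every sample takes the vector of its nearest evaluated
    center; stride 1 evaluates literally every sample.  Edges use symmetric
    signal padding.
    """
    config = model.config
    stride = config.stride_samples if stride_samples is None else stride_samples
    if stride <= 0:
        raise ValueError("stride_samples must be positive")
    n = len(recording)
    if n < config.window_samples:
        raise ValueError(
            f"recording of {n} samples is shorter than one window "
            f"({config.window_samples} samples)"
        )
    half = config.window_samples // 2
    padded = np.pad(recording.samples, half, mode="symmetric").astype(np.float32)
    centers = np.arange(0, n, stride)
    probs_eval = np.empty((centers.shape[0], config.n_classes), dtype=np.float64)
    view = np.lib.stride_tricks.sliding_window_view(padded, config.window_samples)
    for start in range(0, centers.shape[0], batch_windows):
        chunk = centers[start : start + batch_windows]
        probs_eval[start : start + chunk.shape[0]] = model.forward(view[chunk])
    nearest = np.clip(
        np.round(np.arange(n) / stride).astype(np.int64), 0, centers.shape[0] - 1
    )
    return ProbabilityTrack(
        probs_eval[nearest], config.class_order, recording.sample_rate_hz
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegNet, path: str | Path) -> None:
    """Serialize config + parameters as a portable ``.npz`` checkpoint."""
    np.savez(
        path,
        config_json=np.array(json.dumps(asdict(model.config))),
        conv_weights=model.conv_weights,
        conv_bias=model.conv_bias,
        dense_weights=model.dense_weights,
        dense_bias=model.dense_bias,
    )


def load_checkpoint(path: str | Path) -> SegNet:
    with np.load(path, allow_pickle=False) as data:
        config = SegNetConfig(**json.loads(str(data["config_json"])))
        model = SegNet(config)
        model.conv_weights = data["conv_weights"].astype(np.float32)
        model.conv_bias = data["conv_bias"].astype(np.float32)
        model.dense_weights = data["dense_weights"].astype(np.float32)
        model.dense_bias = data["dense_bias"].astype(np.float32)
    return model
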