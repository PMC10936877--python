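"""Seeded synthetic duet-audio generator with exact ground truth.

No public corpus of annotated *D. virilis* duet recordings exists, so this
module generates microphone-like audio whose statistical structure emulates a
male/female duet: sparse unilateral (male) pulse bouts with short, stereotyped
IPIs; longer, more variable bilateral (female) pulse trains that follow each
bout after a response delay; occasional overlap of the two song types;
Gaussian background noise; and broadband non-song transients standing in for
grooming, jumping, and rolling noises.  Ground truth — per-sample labels, the
pulse event table, and bout structure — is exact by construction, which makes
every downstream stage trainable and testable without recorded data.

The pulse model is a Hann-windowed sinusoid.  No spectral model of
*D. virilis* wing song is published with the duet description this package
follows, so the carriers (250 Hz unilateral, 180 Hz bilateral) are arbitrary
but distinct artifact defaults, exposed in :class:`PulseParams`.

Default timing statistics are anchored to the published training-corpus
summary: ~0.31 unilateral bouts per second carrying ~160 ms of unilateral
song each, ~18 bilateral response pulses of ~46 ms per bout, so that long
recordings realize roughly 5% unilateral song, 25% bilateral song, and
occasional (<~1%) overlap.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .audio_core import (
    AudioRecording,
    SongClass,
    labels_to_segments,
    write_segments_csv,
    write_wav,
)
from .pulse_analysis import PulseEvent, write_pulses_csv
from .song_features import Bout

logger = logging.getLogger(__name__)

#: minutes of extra noise/quiet per minute of base training audio mixed into
#: the two-class training split (ratio of 21.5 extra min to 31.6 base min in
#: the original corpus).
EXTRA_NOISE_RATIO = 0.68


@dataclass(frozen=True)
class PulseParams:
    """Waveform and timing statistics for one song type's pulses.

    ``duration_ms``, ``amplitude`` and ``ipi_ms`` are ``(mean, sd)`` pairs;
    the within-bout IPI is the interval between consecutive pulse centers.
    """

    carrier_hz: float
    duration_ms: tuple[float, float]
    amplitude: tuple[float, float]
    ipi_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.carrier_hz <= 0:
            raise ValueError("carrier_hz must be positive")
        for name in ("duration_ms", "amplitude", "ipi_ms"):
            mean, sd = getattr(self, name)
            if mean <= 0:
                raise ValueError(f"{name} mean must be positive")
            if sd < 0:
                raise ValueError(f"{name} sd must be non-negative")
        if self.duration_ms[0] >= self.ipi_ms[0]:
            raise ValueError("mean pulse duration must be below the mean IPI")


def _uni_defaults() -> PulseParams:
    # stereotyped male song: tight IPI and duration spread; 8 pulses of 20 ms
    # per bout realize ~159 ms of unilateral song per bout
    return PulseParams(
        carrier_hz=250.0, duration_ms=(20.0, 2.0), amplitude=(0.5, 0.05),
        ipi_ms=(32.0, 3.0),
    )


def _bi_defaults() -> PulseParams:
    # female song: longer pulses (~46 ms), slower and more variable train
    return PulseParams(
        carrier_hz=180.0, duration_ms=(46.0, 6.0), amplitude=(0.45, 0.08),
        ipi_ms=(75.0, 12.0),
    )


@dataclass(frozen=True)
class DuetConfig:
    """Full configuration of one synthetic duet recording.

    The defaults define the study conditions: a song-dense duet whose
    realized label composition approaches ~5% unilateral / ~25% bilateral /
    ~1% overlap as the duration grows.  Each unilateral bout is placed by a
    renewal process (near-normal inter-onset intervals); every bout elicits
    one bilateral response train whose first pulse center follows the bout
    onset by ``response_delay_ms``, except that with probability
    ``overlap_prob`` the response instead begins inside the ongoing bout,
    producing overlap.
    """

    sample_rate_hz: float = 10_000.0
    total_duration_s: float = 60.0
    unilateral: PulseParams = field(default_factory=_uni_defaults)
    bilateral: PulseParams = field(default_factory=_bi_defaults)
    uni_pulses_per_bout: tuple[float, float] = (8.0, 1.0)
    uni_bout_rate_per_s: float = 0.31
    response_delay_ms: tuple[float, float] = (500.0, 80.0)
    pulses_per_response: tuple[float, float] = (18.0, 4.0)
    overlap_prob: float = 0.15
    noise_sd: float = 0.03
    transient_rate_per_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_prob <= 1:
            raise ValueError("overlap_prob must lie in [0, 1]")
        if self.uni_bout_rate_per_s < 0 or self.transient_rate_per_s < 0:
            raise ValueError("rates must be non-negative")
        if self.total_duration_s <= 0:
            raise ValueError("total_duration_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Exact truth channel for a generated recording."""

    labels: np.ndarray
    pulses: list[PulseEvent]
    bouts: list[Bout]

    def pulses_of(self, song_class: SongClass) -> list[PulseEvent]:
        return [p for p in self.pulses if p.song_class == song_class]


def synth_pulse(
    params: PulseParams,
    duration_ms: float,
    amplitude: float,
    sample_rate_hz: float,
    phase: float = 0.0,
) -> np.ndarray:
    """One song pulse: carrier sinusoid under a smooth symmetric envelope.

    The envelope is a Hann (raised-cosine) window: smooth, symmetric, with a
    unique maximum at the center sample, and — unlike a Gaussian — with its
    whole labeled extent above the background noise, so the truth boundaries
    of a generated pulse are acoustically meaningful.  The waveform has
    ``round(duration_ms * fs / 1000)`` samples.
    """
    if duration_ms <= 0:
        raise ValueError(f"duration_ms must be positive, got {duration_ms}")
    n = int(round(duration_ms * sample_rate_hz / 1000.0))
    n = max(n, 1)
    t = np.arange(n, dtype=np.float64)
    center = (n - 1) / 2.0
    envelope = np.sin(np.pi * (t + 0.5) / n) ** 2 if n > 1 else np.ones(1)
    carrier = np.sin(2.0 * math.pi * params.carrier_hz * (t - center) / sample_rate_hz + phase)
    return amplitude * envelope * carrier


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    return max(lo, float(rng.normal(mean, sd)))


def _place_train(
    rng: np.random.Generator,
    audio: np.ndarray,
    params: PulseParams,
    first_center: int,
    n_pulses: int,
    song_class: SongClass,
    sample_rate_hz: float,
) -> list[PulseEvent]:
    """Draw and add a pulse train; returns the pulses that fit the recording.

    Draw order per pulse: IPI to the next pulse (after the first), duration,
    amplitude, carrier phase.
    """
    n_total = audio.shape[0]
    pulses: list[PulseEvent] = []
    center = float(first_center)
    for i in range(n_pulses):
        if i > 0:
            ipi_ms = _clipped_normal(
                rng, params.ipi_ms[0], params.ipi_ms[1], params.duration_ms[0] * 1.05
            )
            center += ipi_ms * sample_rate_hz / 1000.0
        dur_ms = _clipped_normal(rng, params.duration_ms[0], params.duration_ms[1], 2.0)
        amp = _clipped_normal(rng, params.amplitude[0], params.amplitude[1], 0.0)
        phase = float(rng.uniform(0.0, 2.0 * math.pi))
        wave = synth_pulse(params, dur_ms, amp, sample_rate_hz, phase)
        onset = int(round(center)) - wave.shape[0] // 2
        offset = onset + wave.shape[0]
        if onset < 0 or offset > n_total:
            continue  # pulse would stick out of the recording
        audio[onset:offset] += wave
        # envelope peak = center sample of the Hann-windowed pulse
        peak = onset + (wave.shape[0] - 1) // 2
        pulses.append(PulseEvent(onset, offset, peak, song_class, sample_rate_hz))
    return pulses


def synth_duet(config: DuetConfig) -> tuple[AudioRecording, GroundTruth]:
    """Generate one seeded duet recording with exact ground truth.

    Deterministic for a fixed config (single RNG stream; draw order: noise,
    then per bout its timing / pulses / response, then transients).

    Raises
    ------
    ValueError
        If the configured unilateral bouts are so long relative to the bout
        rate that they cannot be placed without colliding.
    """
    fs = config.sample_rate_hz
    n = int(round(config.total_duration_s * fs))
    rng = np.random.default_rng(config.seed)
    audio = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)

    uni, bi = config.unilateral, config.bilateral
    pulses: list[PulseEvent] = []
    bouts: list[Bout] = []

    if config.uni_bout_rate_per_s > 0:
        mean_interval_s = 1.0 / config.uni_bout_rate_per_s
        bout_span_s = (
            (config.uni_pulses_per_bout[0] - 1) * uni.ipi_ms[0] + uni.duration_ms[0]
        ) / 1000.0
        if bout_span_s > 0.9 * mean_interval_s:
            raise ValueError(
                f"infeasible config: mean bout span {bout_span_s:.2f} s does not fit "
                f"the mean inter-bout interval {mean_interval_s:.2f} s"
            )
        onset_s = float(rng.uniform(0.1, 0.1 + mean_interval_s))
        while onset_s < config.total_duration_s:
            n_uni = max(4, int(round(rng.normal(*config.uni_pulses_per_bout))))
            first_center = int(round(onset_s * fs)) + int(
                round(uni.duration_ms[0] / 2 * fs / 1000.0)
            )
            bout_pulses = _place_train(
                rng, audio, uni, first_center, n_uni, SongClass.UNILATERAL, fs
            )
            if bout_pulses:
                pulses.extend(bout_pulses)
                bouts.append(Bout(SongClass.UNILATERAL, tuple(bout_pulses)))
                bout_onset_s = bout_pulses[0].onset_s
                bout_offset_s = bout_pulses[-1].offset_s
            else:
                bout_onset_s = onset_s
                bout_offset_s = onset_s + bout_span_s
            # bilateral response to this bout
            n_bi = max(1, int(round(rng.normal(*config.pulses_per_response))))
            if rng.random() < config.overlap_prob:
                # response starts inside the ongoing bout -> overlap
                delay_ms = float(
                    rng.uniform(bi.ipi_ms[0], max((bout_offset_s - bout_onset_s) * 1000.0,
                                                  bi.ipi_ms[0] + 1.0))
                )
            else:
                delay_ms = _clipped_normal(
                    rng, config.response_delay_ms[0], config.response_delay_ms[1],
                    bi.duration_ms[0],
                )
            first_bi_center = int(round(bout_onset_s * fs + delay_ms * fs / 1000.0))
            bi_pulses = _place_train(
                rng, audio, bi, first_bi_center, n_bi, SongClass.BILATERAL, fs
            )
            if bi_pulses:
                pulses.extend(bi_pulses)
                bouts.append(Bout(SongClass.BILATERAL, tuple(bi_pulses)))
            interval_s = max(
                float(rng.normal(mean_interval_s, 0.15 * mean_interval_s)),
                0.4 * mean_interval_s,
            )
            onset_s += interval_s

    # broadband non-song transients (grooming / jumping / rolling stand-ins)
    if config.transient_rate_per_s > 0:
        n_transients = int(rng.poisson(config.transient_rate_per_s * config.total_duration_s))
        for _ in range(n_transients):
            t0 = int(rng.uniform(0, n))
            dur = int(rng.uniform(0.010, 0.040) * fs)
            amp = float(rng.uniform(0.15, 0.45))
            end = min(t0 + dur, n)
            if end - t0 < 8:
                continue
            burst = rng.normal(0.0, 1.0, end - t0)
            burst *= amp * np.hanning(end - t0)
            audio[t0:end] += burst

    labels = _labels_from_pulses(pulses, n)
    audio = np.clip(audio, -1.0, 1.0)
    pulses.sort(key=lambda p: (p.peak_sample, p.song_class))
    truth = GroundTruth(labels=labels, pulses=pulses, bouts=bouts)
    comp = realized_composition(labels)
    logger.info(
        "synth_duet(seed=%d, %.0f s): %.1f%% unilateral, %.1f%% bilateral, "
        "%.2f%% overlap",
        config.seed, config.total_duration_s,
        100 * comp["unilateral"], 100 * comp["bilateral"], 100 * comp["overlap"],
    )
    return AudioRecording(audio, fs), truth


def _labels_from_pulses(pulses: list[PulseEvent], n: int) -> np.ndarray:
    """Per-sample truth labels: pulse extents, coincidences marked OVERLAP."""
    uni_mask = np.zeros(n, dtype=bool)
    bi_mask = np.zeros(n, dtype=bool)
    for p in pulses:
        mask = uni_mask if p.song_class == SongClass.UNILATERAL else bi_mask
        mask[p.onset_sample : p.offset_sample] = True
    labels = np.zeros(n, dtype=np.int8)
    labels[uni_mask] = SongClass.UNILATERAL
    labels[bi_mask] = SongClass.BILATERAL
    labels[uni_mask & bi_mask] = SongClass.OVERLAP
    return labels


def realized_composition(labels: np.ndarray) -> dict[str, float]:
    """Fraction of samples carrying each label."""
    labels = np.asarray(labels)
    n = max(labels.size, 1)
    return {
        "unilateral": float(np.count_nonzero(labels == SongClass.UNILATERAL)) / n,
        "bilateral": float(np.count_nonzero(labels == SongClass.BILATERAL)) / n,
        "overlap": float(np.count_nonzero(labels == SongClass.OVERLAP)) / n,
        "none": float(np.count_nonzero(labels == SongClass.NONE)) / n,
    }


def strip_unilateral_portions(
    recording: AudioRecording, labels: np.ndarray
) -> tuple[AudioRecording, np.ndarray]:
    """Cut unilateral- and overlap-labeled samples out of a recording.

    This is the two-class training recipe: the spliced result contains only
    bilateral song and no-song samples (splice discontinuities accepted).
    """
    labels = np.asarray(labels)
    keep = (labels != SongClass.UNILATERAL) & (labels != SongClass.OVERLAP)
    return (
        AudioRecording(recording.samples[keep], recording.sample_rate_hz),
        labels[keep].astype(np.int8),
    )


def noise_only_config(config: DuetConfig, seed: int, total_duration_s: float) -> DuetConfig:
    """A no-song variant of *config* (background noise and transients only)."""
    return DuetConfig(
        sample_rate_hz=config.sample_rate_hz,
        total_duration_s=total_duration_s,
        unilateral=config.unilateral,
        bilateral=config.bilateral,
        uni_bout_rate_per_s=0.0,
        noise_sd=config.noise_sd,
        transient_rate_per_s=config.transient_rate_per_s,
        seed=seed,
    )


def _subseed(seed: int, i: int) -> int:
    return (seed * 1_000_003 + i) % (2**31)


def make_benchmark_suite(
    config: DuetConfig,
    n_train_min: float,
    n_test_min: float,
    out_dir: str | Path,
    seed: int = 0,
) -> dict:
    """Write a train/test benchmark file set under *out_dir*.

    Generates recordings of ``config.total_duration_s`` each until the train
    and test splits reach the requested numbers of minutes.  For every
    recording a WAV, a truth segment CSV and a truth pulse CSV are written.
    The two-class training split removes unilateral/overlap portions from
    each training recording and appends extra noise-only recordings
    (:data:`EXTRA_NOISE_RATIO` minutes per training minute), mirroring how
    the original two-class training corpus was assembled.

    Returns a manifest dict (also written as ``benchmark.json``).
    """
    if n_train_min <= 0 or n_test_min <= 0:
        raise ValueError("train and test durations must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dur_min = config.total_duration_s / 60.0
    n_train = max(1, math.ceil(n_train_min / dur_min))
    n_test = max(1, math.ceil(n_test_min / dur_min))
    fs = config.sample_rate_hz

    manifest: dict = {
        "config": asdict(config),
        "train": [], "train_two_class": [], "test": [], "composition": {},
    }

    def _write(rec, truth_labels, truth_pulses, stem):
        wav = out_dir / f"{stem}.wav"
        write_wav(wav, rec)
        write_segments_csv(out_dir / f"{stem}.labels.csv",
                           labels_to_segments(truth_labels), fs)
        write_pulses_csv(out_dir / f"{stem}.pulses.csv", truth_pulses, fs)
        return wav.name

    all_labels = []
    for i in range(n_train):
        rec, truth = synth_duet(replace(config, seed=_subseed(seed, i)))
        all_labels.append(truth.labels)
        manifest["train"].append(_write(rec, truth.labels, truth.pulses, f"train_{i:02d}"))
        rec2, labels2 = strip_unilateral_portions(rec, truth.labels)
        manifest["train_two_class"].append(
            _write(rec2, labels2, [], f"train2c_{i:02d}")
        )
    # extra noise/quiet for the two-class split
    noise_total_s = EXTRA_NOISE_RATIO * n_train_min * 60.0
    n_noise = max(1, math.ceil(noise_total_s / config.total_duration_s))
    for i in range(n_noise):
        cfg = noise_only_config(config, _subseed(seed, 100 + i), config.total_duration_s)
        rec, truth = synth_duet(cfg)
        manifest["train_two_class"].append(
            _write(rec, truth.labels, truth.pulses, f"train2c_noise_{i:02d}")
        )
    for i in range(n_test):
        rec, truth = synth_duet(replace(config, seed=_subseed(seed, 200 + i)))
        manifest["test"].append(_write(rec, truth.labels, truth.pulses, f"test_{i:02d}"))

    manifest["composition"] = realized_composition(np.concatenate(all_labels))
    with open(out_dir / "benchmark.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
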