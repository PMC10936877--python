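"""Core time-series and annotation types for duet-song analysis.

Audio is represented as a 1-D float array plus a sampling rate (10 kHz by
default, matching single-microphone courtship-chamber recordings).  Per-sample
annotations use the four song classes of a *D. virilis* duet: unilateral
(one-winged, male-typical) song, bilateral (two-winged) song, overlap of the
two, and no song.  Annotations are interconvertible between a per-sample label
track and a sorted list of half-open labeled intervals.

Conventions
-----------
* 0-based sample indices, half-open ``[onset, offset)`` intervals.
* Annotation files on disk carry seconds; conversion is ``round(t * fs)``,
  which is lossless at 10 kHz for times quantized to 0.1 ms.
* Label tracks are plain ``numpy`` integer arrays holding ``SongClass``
  values; ``SongClass.NONE`` (0) marks unlabeled samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE_HZ = 10_000.0


class SongClass(enum.IntEnum):
    """The four per-sample signal classes of a courtship duet recording."""

    NONE = 0
    UNILATERAL = 1
    BILATERAL = 2
    OVERLAP = 3


#: CSV spellings for the three emitted (non-NONE) classes; NONE is implicit.
CLASS_TO_NAME = {
    SongClass.NONE: "none",
    SongClass.UNILATERAL: "unilateral",
    SongClass.BILATERAL: "bilateral",
    SongClass.OVERLAP: "overlap",
}
NAME_TO_CLASS = {v: k for k, v in CLASS_TO_NAME.items()}

#: The two song classes a pulse can belong to.
SONG_CLASSES = (SongClass.UNILATERAL, SongClass.BILATERAL)


@dataclass(frozen=True)
class AudioRecording:
    """A finite single-channel signal with a sampling rate.

    Parameters
    ----------
    samples
        Real-valued amplitudes in arbitrary units (WAV files are scaled to
        [-1, 1] on read).  Stored as a 1-D float array.
    sample_rate_hz
        Sampling rate in Hz; must be positive.
    """

    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def time_to_sample(self, t_s: float) -> int:
        """Convert a time in seconds to the nearest sample index."""
        return int(round(t_s * self.sample_rate_hz))


@dataclass(frozen=True)
class Segment:
    """A half-open labeled interval ``[onset_sample, offset_sample)``.

    Segments are the unit the fusion heuristics and pulse splitting act on;
    only non-NONE classes are ever emitted as segments.
    """

    onset_sample: int
    offset_sample: int
    song_class: SongClass

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError(f"onset_sample must be >= 0, got {self.onset_sample}")
        if self.offset_sample <= self.onset_sample:
            raise ValueError(
                f"offset_sample ({self.offset_sample}) must exceed onset_sample "
                f"({self.onset_sample})"
            )
        if self.song_class == SongClass.NONE:
            raise ValueError("segments carry a non-NONE song class")

    @property
    def n_samples(self) -> int:
        return self.offset_sample - self.onset_sample

    def duration_ms(self, sample_rate_hz: float) -> float:
        return self.n_samples / sample_rate_hz * 1000.0


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

_INT_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path: str | Path) -> AudioRecording:
    """Read a single-channel PCM or float WAV file.

    Integer PCM samples are divided by full scale (e.g. 32768 for 16-bit), so
    amplitudes land in [-1, 1].  No DC removal or resampling is performed.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For multi-channel or zero-length files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path.name}: expected a single channel, got shape {data.shape}; "
            "multi-channel recordings are not supported"
        )
    if data.shape[0] == 0:
        raise ValueError(f"{path.name}: zero-length recording")
    if data.dtype in _INT_SCALE:
        samples = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned with midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return AudioRecording(samples, float(rate))


def write_wav(path: str | Path, recording: AudioRecording, encoding: str = "float32") -> None:
    """Write a recording as WAV (``encoding``: ``"float32"`` or ``"pcm16"``)."""
    if len(recording) == 0:
        raise ValueError("refusing to write a zero-length recording")
    if encoding == "float32":
        data = recording.samples.astype(np.float32)
    elif encoding == "pcm16":
        clipped = np.clip(recording.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    wavfile.write(str(path), int(round(recording.sample_rate_hz)), data)


# ---------------------------------------------------------------------------
# Label track <-> segment conversions
# ---------------------------------------------------------------------------


def labels_to_segments(labels: np.ndarray) -> list[Segment]:
    """Convert a per-sample label track to maximal-run segments.

    Returns the maximal runs of identical non-NONE class as half-open
    segments sorted by onset.  Adjacent returned segments never share a class
    and never overlap.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [labels.size]))
    return [
        Segment(int(s), int(e), SongClass(int(labels[s])))
        for s, e in zip(starts, ends)
        if labels[s] != SongClass.NONE
    ]


def segments_to_labels(segments: list[Segment], n_samples: int) -> np.ndarray:
    """Paint non-overlapping segments onto a NONE-initialized label track.

    Exact inverse of :func:`labels_to_segments` on its output.

    Raises
    ------
    ValueError
        If segments overlap or extend beyond ``n_samples``.
    """
    labels = np.zeros(n_samples, dtype=np.int8)
    for seg in sorted(segments, key=lambda s: s.onset_sample):
        if seg.offset_sample > n_samples:
            raise ValueError(
                f"segment [{seg.onset_sample}, {seg.offset_sample}) extends past "
                f"track length {n_samples}"
            )
        if np.any(labels[seg.onset_sample : seg.offset_sample] != SongClass.NONE):
            raise ValueError(
                f"segment [{seg.onset_sample}, {seg.offset_sample}) overlaps another segment"
            )
        labels[seg.onset_sample : seg.offset_sample] = seg.song_class
    return labels


# ---------------------------------------------------------------------------
# Segment annotation CSV dialect: onset_s,offset_s,class
# ---------------------------------------------------------------------------


def write_segments_csv(
    path: str | Path, segments: list[Segment], sample_rate_hz: float
) -> None:
    """Write segments as ``onset_s,offset_s,class`` (times in seconds)."""
    rows = [
        {
            "onset_s": seg.onset_sample / sample_rate_hz,
            "offset_s": seg.offset_sample / sample_rate_hz,
            "class": CLASS_TO_NAME[seg.song_class],
        }
        for seg in segments
    ]
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "class"]).to_csv(path, index=False)


def read_segments_csv(path: str | Path, sample_rate_hz: float) -> list[Segment]:
    """Read the ``onset_s,offset_s,class`` dialect back into segments."""
    df = pd.read_csv(path)
    segments = []
    for row in df.itertuples(index=False):
        cls = NAME_TO_CLASS[str(row[2]).strip().lower()]
        onset = int(round(float(row[0]) * sample_rate_hz))
        offset = int(round(float(row[1]) * sample_rate_hz))
        segments.append(Segment(onset, offset, cls))
    return segments


def concatenate_recordings(
    recordings: list[AudioRecording], label_tracks: list[np.ndarray]
) -> tuple[AudioRecording, np.ndarray]:
    """Splice recordings (and their label tracks) end to end.

    Used to pool several annotated recordings into one training signal; the
    splice points introduce sub-window discontinuities, which is accepted the
    same way cutting portions out of a training recording is.
    """
    if len(recordings) != len(label_tracks):
        raise ValueError("need one label track per recording")
    rates = {rec.sample_rate_hz for rec in recordings}
    if len(rates) > 1:
        raise ValueError(f"sample rates differ: {sorted(rates)}")
    for rec, labels in zip(recordings, label_tracks):
        if len(rec) != len(labels):
            raise ValueError("label track length must equal recording length")
    samples = np.concatenate([rec.samples for rec in recordings])
    labels = np.concatenate([np.asarray(t, dtype=np.int8) for t in label_tracks])
    return AudioRecording(samples, recordings[0].sample_rate_hz), labels
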