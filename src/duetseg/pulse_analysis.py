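"""Splitting labeled song into pulses and measuring pulse timing.

Fly pulse song is a train of brief (~10 ms) sound pulses.  A contiguous
stretch of predicted song may span several pulses, so pulses are recovered
from the signal envelope: the difference between the upper and lower peak
envelopes (extrema at least 5 ms apart, spline-interpolated) is computed,
peaks in that difference mark pulse centers, and the envelope minima between
consecutive peaks mark where one pulse ends and the next begins.  Interpulse
intervals (IPIs) are the differences between consecutive envelope-peak times
of same-class pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .audio_core import AudioRecording, Segment, SongClass, labels_to_segments

DEFAULT_ENVELOPE_WIDTH_MS = 5.0
DEFAULT_MIN_PROMINENCE_FRAC = 0.1


@dataclass(frozen=True)
class PulseEvent:
    """A single song pulse: extent, envelope-peak time, and class."""

    onset_sample: int
    offset_sample: int
    peak_sample: int
    song_class: SongClass
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if not self.onset_sample <= self.peak_sample < self.offset_sample:
            raise ValueError(
                f"peak_sample {self.peak_sample} must lie in "
                f"[{self.onset_sample}, {self.offset_sample})"
            )
        if self.song_class not in (SongClass.UNILATERAL, SongClass.BILATERAL):
            raise ValueError("a pulse is either unilateral or bilateral")

    @property
    def duration_ms(self) -> float:
        return (self.offset_sample - self.onset_sample) / self.sample_rate_hz * 1000.0

    @property
    def onset_s(self) -> float:
        return self.onset_sample / self.sample_rate_hz

    @property
    def offset_s(self) -> float:
        return self.offset_sample / self.sample_rate_hz

    @property
    def peak_s(self) -> float:
        return self.peak_sample / self.sample_rate_hz

    @property
    def center_s(self) -> float:
        """Midpoint of onset and offset (the 'center' used for response times)."""
        return (self.onset_sample + self.offset_sample) / 2.0 / self.sample_rate_hz


@dataclass(frozen=True)
class EnvelopeTrack:
    """Upper-minus-lower peak envelope of a signal (non-negative)."""

    values: np.ndarray
    width_ms: float
    sample_rate_hz: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("envelope values must be 1-D")
        if np.any(values < 0):
            raise ValueError("envelope difference is non-negative by construction")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


def _peak_envelope(x: np.ndarray, min_separation: int) -> np.ndarray:
    """Spline interpolation through local maxima >= min_separation apart.

    The first and last samples anchor the spline so it is defined everywhere.
    With fewer than two interior maxima the envelope degrades gracefully to
    interpolation through the available anchor points.
    """
    n = x.shape[0]
    peaks, _ = find_peaks(x, distance=min_separation)
    knots = np.unique(np.concatenate(([0], peaks, [n - 1])))
    if knots.size < 2:  # n == 1
        return np.full(n, x[0])
    spline = CubicSpline(knots, x[knots])
    return spline(np.arange(n))


def envelope_difference(
    recording: AudioRecording, width_ms: float = DEFAULT_ENVELOPE_WIDTH_MS
) -> EnvelopeTrack:
    """Difference of the upper and lower peak envelopes of the signal.

    The upper envelope interpolates through local maxima separated by at
    least ``round(width_ms * fs / 1000)`` samples; the lower envelope does
    the same through local minima.  The output is clipped at zero.

    Raises
    ------
    ValueError
        If ``width_ms`` is not positive or the signal is shorter than one
        envelope width.
    """
    if width_ms <= 0:
        raise ValueError(f"width_ms must be positive, got {width_ms}")
    width = int(round(width_ms * recording.sample_rate_hz / 1000.0))
    width = max(width, 1)
    x = recording.samples
    if x.shape[0] < width:
        raise ValueError(
            f"signal of {x.shape[0]} samples is shorter than one envelope "
            f"width ({width} samples)"
        )
    upper = _peak_envelope(x, width)
    lower = -_peak_envelope(-x, width)
    values = np.clip(upper - lower, 0.0, None)
    return EnvelopeTrack(values, width_ms, recording.sample_rate_hz)


def detect_pulse_peaks(
    env: EnvelopeTrack, min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC
) -> np.ndarray:
    """Local maxima of the envelope difference, ascending sample indices.

    Peaks must have prominence at least ``min_prominence_frac`` of the global
    envelope maximum; a flat or all-zero envelope yields no peaks.
    """
    values = env.values
    global_max = values.max(initial=0.0)
    if global_max <= 0:
        return np.array([], dtype=np.int64)
    peaks, _ = find_peaks(values, prominence=min_prominence_frac * global_max)
    return peaks.astype(np.int64)


def split_segment_into_pulses(
    segment: Segment, env: EnvelopeTrack, peaks: np.ndarray
) -> list[PulseEvent]:
    """Split one labeled segment into pulses at inter-peak envelope minima.

    The first pulse starts at the segment onset and the last ends at the
    segment offset; each interior boundary is placed at the envelope minimum
    between a consecutive pair of peaks.  A segment containing no detected
    peak yields a single pulse spanning the segment, with its peak at the
    envelope argmax (the documented fallback for weak or flat envelopes).
    """
    values = env.values
    on, off = segment.onset_sample, segment.offset_sample
    inside = [int(p) for p in np.asarray(peaks) if on <= p < off]
    cls = segment.song_class
    fs = env.sample_rate_hz
    if not inside:
        peak = on + int(np.argmax(values[on:off]))
        return [PulseEvent(on, off, peak, cls, fs)]
    bounds = [on]
    for left, right in zip(inside[:-1], inside[1:]):
        # interior minimum strictly between the two peaks
        m = left + 1 + int(np.argmin(values[left + 1 : right]))
        bounds.append(m)
    bounds.append(off)
    return [
        PulseEvent(b0, b1, peak, cls, fs)
        for b0, b1, peak in zip(bounds[:-1], bounds[1:], inside)
    ]


def compute_ipis(pulses: list[PulseEvent]) -> np.ndarray:
    """Interpulse intervals in ms: successive envelope-peak time differences.

    Expects pulses of a single class sorted by peak time; fewer than two
    pulses yield an empty array.  Grouping across gaps (bout thresholds) is
    the caller's concern — see :mod:`duetseg.song_features`.
    """
    if len(pulses) < 2:
        return np.array([], dtype=np.float64)
    classes = {p.song_class for p in pulses}
    if len(classes) > 1:
        raise ValueError("IPIs are computed within a single song class")
    peaks = np.array([p.peak_sample for p in pulses], dtype=np.float64)
    if np.any(np.diff(peaks) < 0):
        raise ValueError("pulses must be sorted by peak time")
    fs = pulses[0].sample_rate_hz
    return np.diff(peaks) / fs * 1000.0


def write_pulses_csv(path, pulses: list[PulseEvent], sample_rate_hz: float) -> None:
    """Write a pulse table as ``onset_s,offset_s,peak_s,class,duration_ms``."""
    import pandas as pd

    from .audio_core import CLASS_TO_NAME

    rows = [
        {
            "onset_s": p.onset_sample / sample_rate_hz,
            "offset_s": p.offset_sample / sample_rate_hz,
            "peak_s": p.peak_sample / sample_rate_hz,
            "class": CLASS_TO_NAME[p.song_class],
            "duration_ms": p.duration_ms,
        }
        for p in pulses
    ]
    pd.DataFrame(
        rows, columns=["onset_s", "offset_s", "peak_s", "class", "duration_ms"]
    ).to_csv(path, index=False)


def read_pulses_csv(path, sample_rate_hz: float) -> list[PulseEvent]:
    """Read the pulse-table dialect back into :class:`PulseEvent` objects."""
    import pandas as pd

    from .audio_core import NAME_TO_CLASS

    df = pd.read_csv(path)
    return [
        PulseEvent(
            int(round(row["onset_s"] * sample_rate_hz)),
            int(round(row["offset_s"] * sample_rate_hz)),
            int(round(row["peak_s"] * sample_rate_hz)),
            NAME_TO_CLASS[str(row["class"]).strip().lower()],
            sample_rate_hz,
        )
        for _, row in df.iterrows()
    ]


def pulses_from_labels(
    labels: np.ndarray,
    recording: AudioRecording,
    width_ms: float = DEFAULT_ENVELOPE_WIDTH_MS,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> list[PulseEvent]:
    """Extract all pulses implied by a label track.

    For each song class, contiguous stretches labeled with that class *or*
    OVERLAP (overlap means both songs are present) are split into pulses via
    the envelope-difference peaks of the whole recording.  Returns pulses of
    both classes sorted by peak time.
    """
    labels = np.asarray(labels)
    env = envelope_difference(recording, width_ms)
    peaks = detect_pulse_peaks(env, min_prominence_frac)
    pulses: list[PulseEvent] = []
    for cls in (SongClass.UNILATERAL, SongClass.BILATERAL):
        mask = (labels == cls) | (labels == SongClass.OVERLAP)
        for seg in labels_to_segments(np.where(mask, int(cls), 0)):
            pulses.extend(split_segment_into_pulses(seg, env, peaks))
    return sorted(pulses, key=lambda p: (p.peak_sample, p.song_class))
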