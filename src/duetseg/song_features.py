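"""Bout grouping, response times, song amounts, and per-recording summaries.

Definitions
-----------
* A *unilateral bout* is a run of at least four unilateral pulses whose
  consecutive IPIs are all 60 ms or less.
* A *bilateral bout* is any number of bilateral pulses with consecutive IPIs
  of 100 ms or less.
* *Bilateral response time*: delay from a unilateral bout onset to the center
  of the first bilateral pulse at or after that onset.
* *Unilateral response time*: delay from a bilateral pulse offset to the
  onset of the next unilateral bout.  Response times of 1.5 s or more are
  excluded.
* *Song amount*: total time labeled with a class divided by courtship time
  (first to last pulse of either type, truncated at copulation when given).
  Overlap time counts toward both classes.
* A recording enters feature comparisons only with at least 10 unilateral
  and 10 bilateral pulses (before copulation when a copulation time is set).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .audio_core import SongClass
from .pulse_analysis import PulseEvent, compute_ipis

UNILATERAL_MAX_IPI_MS = 60.0
UNILATERAL_MIN_PULSES = 4
BILATERAL_MAX_IPI_MS = 100.0
BILATERAL_MIN_PULSES = 1
MAX_RESPONSE_S = 1.5
MIN_PULSES_FOR_INCLUSION = 10


@dataclass(frozen=True)
class Bout:
    """An ordered run of same-class pulses grouped by an IPI threshold."""

    song_class: SongClass
    pulses: tuple[PulseEvent, ...]

    def __post_init__(self) -> None:
        if len(self.pulses) == 0:
            raise ValueError("a bout contains at least one pulse")
        if any(p.song_class != self.song_class for p in self.pulses):
            raise ValueError("all pulses in a bout share its song class")
        object.__setattr__(self, "pulses", tuple(self.pulses))

    @property
    def onset_sample(self) -> int:
        return self.pulses[0].onset_sample

    @property
    def offset_sample(self) -> int:
        return self.pulses[-1].offset_sample

    @property
    def sample_rate_hz(self) -> float:
        return self.pulses[0].sample_rate_hz

    @property
    def onset_s(self) -> float:
        return self.onset_sample / self.sample_rate_hz

    @property
    def offset_s(self) -> float:
        return self.offset_sample / self.sample_rate_hz

    def __len__(self) -> int:
        return len(self.pulses)


def group_bouts(
    pulses: list[PulseEvent],
    song_class: SongClass,
    max_ipi_ms: float,
    min_pulses: int,
) -> list[Bout]:
    """Greedy left-to-right grouping of pulses into bouts.

    Consecutive pulses stay in the same bout while the IPI (envelope-peak
    time difference) is at most ``max_ipi_ms``; groups with fewer than
    ``min_pulses`` pulses are discarded.  Input pulses must be sorted by
    peak time and all belong to ``song_class``.
    """
    pulses = [p for p in pulses if p.song_class == song_class]
    if not pulses:
        return []
    peaks = np.array([p.peak_sample for p in pulses], dtype=np.float64)
    if np.any(np.diff(peaks) < 0):
        raise ValueError("pulses must be sorted by peak time")
    ipis_ms = np.diff(peaks) / pulses[0].sample_rate_hz * 1000.0
    bouts: list[Bout] = []
    start = 0
    for i in range(len(pulses)):
        last = i == len(pulses) - 1
        if last or ipis_ms[i] > max_ipi_ms:
            group = pulses[start : i + 1]
            if len(group) >= min_pulses:
                bouts.append(Bout(song_class, tuple(group)))
            start = i + 1
    return bouts


def group_unilateral_bouts(pulses: list[PulseEvent]) -> list[Bout]:
    """Unilateral bouts: >= 4 pulses, consecutive IPIs <= 60 ms."""
    return group_bouts(
        pulses, SongClass.UNILATERAL, UNILATERAL_MAX_IPI_MS, UNILATERAL_MIN_PULSES
    )


def group_bilateral_bouts(pulses: list[PulseEvent]) -> list[Bout]:
    """Bilateral bouts: any number of pulses, consecutive IPIs <= 100 ms."""
    return group_bouts(
        pulses, SongClass.BILATERAL, BILATERAL_MAX_IPI_MS, BILATERAL_MIN_PULSES
    )


def response_times(
    uni_bouts: list[Bout],
    bi_pulses: list[PulseEvent],
    max_response_s: float = MAX_RESPONSE_S,
) -> tuple[list[float], list[float]]:
    """Bilateral and unilateral response times in ms.

    Returns ``(bilateral_rts_ms, unilateral_rts_ms)``:

    * one bilateral response time per unilateral bout that is followed (at or
      after its onset) by a bilateral pulse center within ``max_response_s``;
    * one unilateral response time per bilateral pulse whose offset is
      followed by a unilateral bout onset within ``max_response_s``.
    """
    centers_s = np.array([p.center_s for p in bi_pulses])
    order = np.argsort(centers_s, kind="stable")
    centers_s = centers_s[order]
    bout_onsets_s = np.array([b.onset_s for b in uni_bouts])

    bilateral_rts: list[float] = []
    for onset in bout_onsets_s:
        i = int(np.searchsorted(centers_s, onset, side="left"))
        if i < centers_s.size:
            rt_s = centers_s[i] - onset
            if rt_s < max_response_s:
                bilateral_rts.append(rt_s * 1000.0)

    unilateral_rts: list[float] = []
    sorted_onsets = np.sort(bout_onsets_s)
    for pulse in bi_pulses:
        i = int(np.searchsorted(sorted_onsets, pulse.offset_s, side="left"))
        if i < sorted_onsets.size:
            rt_s = sorted_onsets[i] - pulse.offset_s
            if rt_s < max_response_s:
                unilateral_rts.append(rt_s * 1000.0)
    return bilateral_rts, unilateral_rts


def song_amounts(
    labels: np.ndarray,
    pulses: list[PulseEvent],
    sample_rate_hz: float,
    copulation_s: float | None = None,
) -> tuple[float, float, float]:
    """Fraction of courtship time spent in each song type.

    Courtship time runs from the onset of the first pulse to the offset of
    the last pulse (of either type); with a copulation time, only pulses and
    labels before copulation count.  Overlap-labeled samples count toward
    both classes.

    Returns ``(amount_unilateral, amount_bilateral, courtship_time_s)``.

    Raises
    ------
    ValueError
        With fewer than two pulses in the analyzed span, where courtship
        time is undefined.
    """
    labels = np.asarray(labels)
    if copulation_s is not None:
        cut = int(round(copulation_s * sample_rate_hz))
        pulses = [p for p in pulses if p.peak_sample < cut]
        labels = labels[:cut]
    if len(pulses) < 2:
        raise ValueError("courtship time needs at least two pulses")
    first = min(p.onset_sample for p in pulses)
    last = max(p.offset_sample for p in pulses)
    courtship_time_s = (last - first) / sample_rate_hz
    uni_s = float(np.count_nonzero(
        (labels == SongClass.UNILATERAL) | (labels == SongClass.OVERLAP)
    )) / sample_rate_hz
    bi_s = float(np.count_nonzero(
        (labels == SongClass.BILATERAL) | (labels == SongClass.OVERLAP)
    )) / sample_rate_hz
    return uni_s / courtship_time_s, bi_s / courtship_time_s, courtship_time_s


@dataclass
class DuetFeatureSummary:
    """Per-recording song-feature medians, amounts, and inclusion flag."""

    median_ipi_ms: dict[str, float] = field(default_factory=dict)
    median_pulse_duration_ms: dict[str, float] = field(default_factory=dict)
    n_pulses: dict[str, int] = field(default_factory=dict)
    amount_unilateral: float = math.nan
    amount_bilateral: float = math.nan
    relative_amount_bilateral: float = math.nan
    bilateral_response_times_ms: list[float] = field(default_factory=list)
    unilateral_response_times_ms: list[float] = field(default_factory=list)
    courtship_time_s: float = math.nan
    included: bool = False

    def to_dict(self) -> dict:
        return {
            "median_ipi_ms": self.median_ipi_ms,
            "median_pulse_duration_ms": self.median_pulse_duration_ms,
            "n_pulses": self.n_pulses,
            "amount_unilateral": self.amount_unilateral,
            "amount_bilateral": self.amount_bilateral,
            "relative_amount_bilateral": self.relative_amount_bilateral,
            "bilateral_response_times_ms": self.bilateral_response_times_ms,
            "unilateral_response_times_ms": self.unilateral_response_times_ms,
            "courtship_time_s": self.courtship_time_s,
            "included": self.included,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _median(values: np.ndarray | list[float]) -> float:
    arr = np.asarray(values, dtype=np.float64)
    return float(np.median(arr)) if arr.size else math.nan


def summarize_recording(
    pulses: list[PulseEvent],
    labels: np.ndarray,
    sample_rate_hz: float,
    copulation_s: float | None = None,
) -> DuetFeatureSummary:
    """Compute the full feature summary for one recording.

    Median IPIs are taken over within-bout intervals only (bout thresholds:
    60 ms / >= 4 pulses unilateral, 100 ms / any count bilateral); pulse
    durations are medians over all pulses of the class.  The inclusion flag
    requires at least 10 pulses of each class (before copulation when set).
    Pulses dropped from sub-minimum unilateral groups still count toward
    inclusion — the criterion concerns pulses, not bouts.
    """
    if copulation_s is not None:
        cut = int(round(copulation_s * sample_rate_hz))
        pulses = [p for p in pulses if p.peak_sample < cut]
    summary = DuetFeatureSummary()
    by_class = {
        "unilateral": [p for p in pulses if p.song_class == SongClass.UNILATERAL],
        "bilateral": [p for p in pulses if p.song_class == SongClass.BILATERAL],
    }
    uni_bouts = group_unilateral_bouts(by_class["unilateral"])
    bi_bouts = group_bilateral_bouts(by_class["bilateral"])
    bouts = {"unilateral": uni_bouts, "bilateral": bi_bouts}
    for name, cls_pulses in by_class.items():
        summary.n_pulses[name] = len(cls_pulses)
        summary.median_pulse_duration_ms[name] = _median(
            [p.duration_ms for p in cls_pulses]
        )
        within_bout_ipis = np.concatenate(
            [compute_ipis(list(b.pulses)) for b in bouts[name]]
        ) if bouts[name] else np.array([])
        summary.median_ipi_ms[name] = _median(within_bout_ipis)
    summary.bilateral_response_times_ms, summary.unilateral_response_times_ms = (
        response_times(uni_bouts, by_class["bilateral"])
    )
    try:
        uni_amt, bi_amt, courtship = song_amounts(
            labels, pulses, sample_rate_hz, copulation_s
        )
        summary.amount_unilateral = uni_amt
        summary.amount_bilateral = bi_amt
        summary.courtship_time_s = courtship
        if uni_amt > 0:
            summary.relative_amount_bilateral = bi_amt / uni_amt
    except ValueError:
        pass  # fewer than two pulses: amounts stay NaN (not computable)
    summary.included = (
        summary.n_pulses["unilateral"] >= MIN_PULSES_FOR_INCLUSION
        and summary.n_pulses["bilateral"] >= MIN_PULSES_FOR_INCLUSION
    )
    return summary
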