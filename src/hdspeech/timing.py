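"""Voiced/pause segmentation and timing features from word timestamps.

The word-level timestamps of a timed transcript are the source of truth:
voiced intervals are the (merged) word spans, pauses are the inter-word
gaps, and anything before the first word or after the last word is
treated as irrelevant audio and discarded.  Gaps shorter than
``min_pause`` count toward total pause time but not toward the pause
count or mean pause length — they are within-speech articulation gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import TimedTranscript

__all__ = [
    "Segmentation",
    "TimingFeatures",
    "segment_from_transcript",
    "timing_features",
    "DEFAULT_MIN_PAUSE_S",
]

DEFAULT_MIN_PAUSE_S = 0.10


class NoSpeechError(ValueError):
    """Raised when a transcript contains no words to segment."""


@dataclass(frozen=True)
class Segmentation:
    """Voiced and pause intervals within [signal_start, signal_end]."""

    voiced_intervals: tuple[tuple[float, float], ...]
    pause_intervals: tuple[tuple[float, float], ...]
    signal_start: float
    signal_end: float

    @property
    def total_voiced(self) -> float:
        return float(sum(e - s for s, e in self.voiced_intervals))

    @property
    def total_signal(self) -> float:
        return self.signal_end - self.signal_start

    @property
    def total_pause(self) -> float:
        # all non-voiced time, including sub-threshold gaps
        return self.total_signal - self.total_voiced


@dataclass(frozen=True)
class TimingFeatures:
    total_voiced_time: float
    total_pause_time: float
    total_signal_time: float
    speech_to_pause_ratio: float  # NaN when there is no pause time
    number_of_pauses: int
    mean_pause_length: float
    articulatory_rate: float  # words per second of voiced time

    def as_dict(self) -> dict[str, float]:
        return {
            "total_voiced_time_s": self.total_voiced_time,
            "total_pause_time_s": self.total_pause_time,
            "total_signal_time_s": self.total_signal_time,
            "speech_to_pause_ratio": self.speech_to_pause_ratio,
            "number_of_pauses": float(self.number_of_pauses),
            "mean_pause_length_s": self.mean_pause_length,
            "articulatory_rate_w_s": self.articulatory_rate,
        }


def segment_from_transcript(
    transcript: TimedTranscript,
    min_pause: float = DEFAULT_MIN_PAUSE_S,
    truncate_s: Optional[float] = None,
) -> Segmentation:
    """Derive voiced/pause structure from word timestamps.

    Parameters
    ----------
    transcript
        Non-empty timed transcript; words must be ordered and
        non-overlapping (enforced by the type).
    min_pause
        Minimum inter-word gap, in seconds, counted as a pause.
    truncate_s
        If given, drop words starting at or after this many seconds from
        the first word onset (task time limit enforcement; off by default).
    """
    if len(transcript) == 0:
        raise NoSpeechError("transcript contains no words")
    words = list(transcript.words)
    if truncate_s is not None:
        t0 = words[0].start
        words = [w for w in words if w.start - t0 < truncate_s]
    signal_start = words[0].start
    signal_end = words[-1].end

    # merge abutting/contiguous word spans into voiced intervals
    voiced: list[list[float]] = [[words[0].start, words[0].end]]
    for w in words[1:]:
        if w.start <= voiced[-1][1]:
            voiced[-1][1] = max(voiced[-1][1], w.end)
        else:
            voiced.append([w.start, w.end])

    pauses = [
        (prev[1], nxt[0])
        for prev, nxt in zip(voiced[:-1], voiced[1:])
        if nxt[0] - prev[1] >= min_pause
    ]
    return Segmentation(
        voiced_intervals=tuple((s, e) for s, e in voiced),
        pause_intervals=tuple(pauses),
        signal_start=signal_start,
        signal_end=signal_end,
    )


def timing_features(seg: Segmentation, word_count: int) -> TimingFeatures:
    """Compute the timing feature set for one segmented recording.

    Total voiced, pause and signal time are conserved by construction
    (voiced + pause = signal).  The speech-to-pause ratio is reported as
    NaN (missing) rather than infinity when there is no pause time, and
    the articulatory rate is words per second of *voiced* time.
    """
    if word_count < 1:
        raise ValueError("word_count must be >= 1")
    total_voiced = seg.total_voiced
    total_signal = seg.total_signal
    total_pause = total_signal - total_voiced
    ratio = total_voiced / total_pause if total_pause > 0 else float("nan")
    n_pauses = len(seg.pause_intervals)
    mean_pause = (
        float(np.mean([e - s for s, e in seg.pause_intervals])) if n_pauses else 0.0
    )
    rate = word_count / total_voiced if total_voiced > 0 else float("nan")
    return TimingFeatures(
        total_voiced_time=total_voiced,
        total_pause_time=total_pause,
        total_signal_time=total_signal,
        speech_to_pause_ratio=ratio,
        number_of_pauses=n_pauses,
        mean_pause_length=mean_pause,
        articulatory_rate=rate,
    )
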