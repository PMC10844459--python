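"""Counting-task parsing and scoring.

Two timed counting tasks: counting forward from 1 to 20, and counting
backward from 50 to 30 in steps of 3.  Number words are parsed from the
timed transcript (non-number chatter is dropped, compound forms such as
"forty seven" are joined) and scored by a chain rule: the first value
is correct iff it equals the task start, and each later value is
correct iff it equals the previously *spoken* value plus the step.
Participants were instructed to keep counting after a mistake, so the
chain rule forgives a single slip instead of cascading the error;
position-wise scoring against the canonical sequence is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import TimedTranscript, WordToken
from .timing import (
    DEFAULT_MIN_PAUSE_S,
    TimingFeatures,
    segment_from_transcript,
    timing_features,
)

__all__ = [
    "CountSequence",
    "CountingFeatures",
    "TASKS",
    "parse_numbers",
    "score_counting",
    "counting_features",
    "number_to_words",
]

#: task label -> (start value, step)
TASKS = {
    "forward_1_20": (1, 1),
    "backward_50_30_by3": (50, -3),
}

_ONES = {
    "zero": 0, "one": 1, "two": 2, "three": 3, "four": 4,
    "five": 5, "six": 6, "seven": 7, "eight": 8, "nine": 9,
}
_TEENS = {
    "ten": 10, "eleven": 11, "twelve": 12, "thirteen": 13, "fourteen": 14,
    "fifteen": 15, "sixteen": 16, "seventeen": 17, "eighteen": 18,
    "nineteen": 19,
}
_TENS = {
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
    "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90,
}

_ONES_REV = {v: k for k, v in _ONES.items() if v > 0}
_TEENS_REV = {v: k for k, v in _TEENS.items()}
_TENS_REV = {v: k for k, v in _TENS.items()}


class NoCountsError(ValueError):
    """Raised when a transcript contains no parseable numbers."""


def number_to_words(n: int) -> str:
    """Render 0-99 as English words ("forty seven"); inverse of parsing."""
    if not 0 <= n <= 99:
        raise ValueError(f"number-word rendering supports 0-99, got {n}")
    if n == 0:
        return "zero"
    if n < 10:
        return _ONES_REV[n]
    if n < 20:
        return _TEENS_REV[n]
    tens, ones = divmod(n, 10)
    word = _TENS_REV[tens * 10]
    return f"{word} {_ONES_REV[ones]}" if ones else word


@dataclass(frozen=True)
class CountSequence:
    """Parsed spoken numbers in order, with the time span of each."""

    values: tuple[int, ...]
    token_spans: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CountingFeatures:
    correct_counts: int
    incorrect_counts: int
    correct_counts_ratio: float
    counts_per_second: float
    timing: TimingFeatures

    def as_dict(self) -> dict[str, float]:
        d = {
            "correct_counts": float(self.correct_counts),
            "incorrect_counts": float(self.incorrect_counts),
            "correct_counts_ratio": self.correct_counts_ratio,
            "counts_per_second": self.counts_per_second,
        }
        d.update(self.timing.as_dict())
        return d


def parse_numbers(transcript: TimedTranscript) -> CountSequence:
    """Extract spoken integers from a transcript, dropping chatter.

    Handles single number words, digit strings, and compound
    tens + ones pairs ("forty" "seven" -> 47, span covering both
    tokens).  Raises NoCountsError when nothing parses.
    """
    words = list(transcript.words)
    values: list[int] = []
    spans: list[tuple[float, float]] = []
    i = 0
    while i < len(words):
        w = words[i]
        t = w.text
        if t.isdigit():
            values.append(int(t))
            spans.append((w.start, w.end))
        elif t in _TENS:
            if i + 1 < len(words) and words[i + 1].text in _ONES and _ONES[words[i + 1].text] > 0:
                values.append(_TENS[t] + _ONES[words[i + 1].text])
                spans.append((w.start, words[i + 1].end))
                i += 2
                continue
            values.append(_TENS[t])
            spans.append((w.start, w.end))
        elif t in _TEENS:
            values.append(_TEENS[t])
            spans.append((w.start, w.end))
        elif t in _ONES:
            values.append(_ONES[t])
            spans.append((w.start, w.end))
        i += 1
    if not values:
        raise NoCountsError("no number words found in transcript")
    return CountSequence(tuple(values), tuple(spans))


def score_counting(
    seq: CountSequence, task: str, canonical: bool = False
) -> tuple[int, int, float]:
    """Score a count sequence: (correct, incorrect, correct ratio).

    Chain rule (default): value i is correct iff it equals the previous
    spoken value plus the task step (the first iff it equals the task
    start).  With ``canonical=True`` each position is instead compared
    to the canonical task sequence.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    if len(seq) < 1:
        raise ValueError("empty count sequence")
    start, step = TASKS[task]
    correct = 0
    for i, v in enumerate(seq.values):
        if canonical:
            expected = start + i * step
        else:
            expected = start if i == 0 else seq.values[i - 1] + step
        if v == expected:
            correct += 1
    incorrect = len(seq) - correct
    return correct, incorrect, correct / len(seq)


def counting_features(
    transcript: TimedTranscript,
    task: str,
    min_pause: float = DEFAULT_MIN_PAUSE_S,
    canonical: bool = False,
) -> CountingFeatures:
    """Full counting-task feature set for one recording.

    Timing features are computed on the number tokens only (chatter is
    excluded before segmentation); counts per second uses total signal
    time, while the articulatory rate inside ``timing`` uses voiced
    time, as in the passage task.
    """
    seq = parse_numbers(transcript)
    number_tokens = [
        WordToken(str(v), s, e) for v, (s, e) in zip(seq.values, seq.token_spans)
    ]
    number_transcript = TimedTranscript(tuple(number_tokens), transcript.source_tag)
    seg = segment_from_transcript(number_transcript, min_pause=min_pause)
    timing = timing_features(seg, word_count=len(seq))
    correct, incorrect, ratio = score_counting(seq, task, canonical=canonical)
    total_signal = timing.total_signal_time
    cps = len(seq) / total_signal if total_signal > 0 else float("nan")
    return CountingFeatures(
        correct_counts=correct,
        incorrect_counts=incorrect,
        correct_counts_ratio=ratio,
        counts_per_second=cps,
        timing=timing,
    )
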