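"""Shared data model and file formats.

Audio is PCM WAV (16-bit integer or IEEE float), loaded mono with
amplitudes in [-1, 1].  Timed transcripts — the word-level output of any
external ASR/forced aligner — are consumed as JSON lists of
``{"text", "start", "end"}`` objects; all timing features downstream
treat these timestamps as the source of truth.  Visit-level feature
tables are plain CSV, one row per (subject, visit).
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "WordToken",
    "TimedTranscript",
    "VisitRecord",
    "GROUPS",
    "PASSAGE_FEATURES",
    "COUNTING_FEATURES",
    "normalize_text",
    "make_transcript",
    "load_audio",
    "save_audio",
    "read_timed_transcript",
    "write_timed_transcript",
    "visits_to_frame",
    "frame_to_visits",
]

GROUPS = ("HD", "pHD", "CTR")

#: Fixed catalogue of passage-reading feature names (CSV column names).
PASSAGE_FEATURES = (
    "total_voiced_time_s",
    "total_pause_time_s",
    "total_signal_time_s",
    "speech_to_pause_ratio",
    "number_of_pauses",
    "mean_pause_length_s",
    "articulatory_rate_w_s",
    "pitch_mean_hz",
    "pitch_sd_hz",
    "loudness_sone",
    "similarity_dtw",
    "intelligibility_dtw",
    "ratio_extra_words",
    "ratio_missing_words",
)

#: Counting-task feature names (per task, prefixed in visit tables).
COUNTING_FEATURES = (
    "correct_counts",
    "incorrect_counts",
    "correct_counts_ratio",
    "counts_per_second",
    "total_voiced_time_s",
    "total_pause_time_s",
    "total_signal_time_s",
    "speech_to_pause_ratio",
    "number_of_pauses",
    "mean_pause_length_s",
    "articulatory_rate_w_s",
)


class TranscriptError(ValueError):
    """Raised for malformed or ill-ordered timed transcripts."""


@dataclass(frozen=True)
class AudioSignal:
    """Mono audio: ``samples`` in [-1, 1] at ``rate`` Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


_WORD_RE = re.compile(r"[a-z']+")


def normalize_text(text: str) -> str:
    """Lower-case, split hyphens, strip everything outside a-z.

    Apostrophes are removed (``don't`` -> ``dont``); hyphenated words
    become two tokens.  Idempotent.
    """
    text = text.lower().replace("-", " ")
    words = []
    for raw in text.split():
        w = "".join(c for c in raw if c in string.ascii_lowercase)
        if w:
            words.append(w)
    return " ".join(words)


@dataclass(frozen=True)
class WordToken:
    """A transcribed word with its time span in seconds."""

    text: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise TranscriptError(f"negative start time {self.start} for {self.text!r}")
        if self.end < self.start:
            raise TranscriptError(
                f"end {self.end} precedes start {self.start} for {self.text!r}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TimedTranscript:
    """Ordered, non-overlapping word tokens plus a transcriber tag.

    ``source_tag`` identifies which recognizer produced the transcript
    (e.g. ``"medium"`` vs ``"small"``); the intelligibility measure
    compares transcripts from two differently-sized recognizers.
    """

    words: tuple[WordToken, ...]
    source_tag: str = "medium"

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", tuple(self.words))
        prev_start = -np.inf
        prev_end = 0.0
        for i, w in enumerate(self.words):
            if w.start < prev_start:
                raise TranscriptError(f"word {i} ({w.text!r}) starts before word {i - 1}")
            if w.start < prev_end:
                raise TranscriptError(f"word {i} ({w.text!r}) overlaps word {i - 1}")
            prev_start, prev_end = w.start, w.end

    def __len__(self) -> int:
        return len(self.words)

    def text(self) -> str:
        return " ".join(w.text for w in self.words)

    def with_tag(self, tag: str) -> "TimedTranscript":
        return replace(self, source_tag=tag)


def _normalize_tokens(raw: Iterable[tuple[str, float, float]]) -> list[WordToken]:
    out: list[WordToken] = []
    for text, start, end in raw:
        norm = normalize_text(text)
        if not norm:
            continue
        parts = norm.split()
        # hyphen-split words share the original span, divided evenly
        span = (end - start) / len(parts)
        for k, p in enumerate(parts):
            out.append(WordToken(p, start + k * span, start + (k + 1) * span))
    return out


def make_transcript(
    raw: Iterable[tuple[str, float, float]], source_tag: str = "medium"
) -> TimedTranscript:
    """Build a transcript from (text, start, end) triples, normalizing text."""
    return TimedTranscript(tuple(_normalize_tokens(raw)), source_tag=source_tag)


# ---------------------------------------------------------------------------
# Audio I/O


def load_audio(path: str | Path) -> AudioSignal:
    """Load a PCM WAV file as a mono [-1, 1] signal at its native rate."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize read failures
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty audio signal in {path}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 WAV
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples, int(rate))


def save_audio(signal: AudioSignal, path: str | Path, dtype: str = "int16") -> Path:
    """Write an AudioSignal to a PCM WAV file (int16 or float32)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "int16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(str(path), signal.rate, (clipped * 32767.0).astype(np.int16))
    elif dtype == "float32":
        wavfile.write(str(path), signal.rate, signal.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    return path


# ---------------------------------------------------------------------------
# Transcript I/O


def read_timed_transcript(path: str | Path) -> TimedTranscript:
    """Read a timed-transcript JSON file.

    Schema: ``{"source_tag": str, "words": [{"text","start","end"}, ...]}``
    or a bare list of word objects (tag defaults to "medium").
    """
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        words_raw, tag = payload, "medium"
    else:
        words_raw, tag = payload["words"], payload.get("source_tag", "medium")
    triples = []
    for i, obj in enumerate(words_raw):
        try:
            triples.append((str(obj["text"]), float(obj["start"]), float(obj["end"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise TranscriptError(f"malformed word object at index {i} in {path}") from exc
    try:
        return make_transcript(triples, source_tag=tag)
    except TranscriptError as exc:
        raise TranscriptError(f"{path}: {exc}") from exc


def write_timed_transcript(transcript: TimedTranscript, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "source_tag": transcript.source_tag,
        "words": [
            {"text": w.text, "start": w.start, "end": w.end} for w in transcript.words
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# Visit records


@dataclass
class VisitRecord:
    """One study visit: identity, clinical scores and extracted features.

    ``features`` maps catalogue feature names (optionally prefixed with a
    task, e.g. ``counting_forward__total_pause_time_s``) to real values;
    NaN marks a missing value.
    """

    subject_id: str
    visit_id: str
    group: str
    moca: float
    uhdrs_functional: float
    uhdrs_motor: float
    dysarthria: int
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.isnan(self.moca) and not (0 <= self.moca <= 30):
            raise ValueError(f"MoCA out of range [0, 30]: {self.moca}")
        if self.dysarthria not in (0, 1, 2, 3, 4):
            raise ValueError(f"dysarthria score must be in 0..4, got {self.dysarthria}")


_CLINICAL_COLS = ["subject_id", "visit_id", "group", "moca", "uhdrs_functional",
                  "uhdrs_motor", "dysarthria"]


def visits_to_frame(visits: Sequence[VisitRecord]) -> pd.DataFrame:
    """Flatten visit records to a DataFrame (one row per visit)."""
    rows = []
    for v in visits:
        row: dict[str, object] = {
            "subject_id": v.subject_id,
            "visit_id": v.visit_id,
            "group": v.group,
            "moca": v.moca,
            "uhdrs_functional": v.uhdrs_functional,
            "uhdrs_motor": v.uhdrs_motor,
            "dysarthria": v.dysarthria,
        }
        row.update(v.features)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_visits(df: pd.DataFrame) -> list[VisitRecord]:
    feature_cols = [c for c in df.columns if c not in _CLINICAL_COLS]
    visits = []
    for _, row in df.iterrows():
        visits.append(
            VisitRecord(
                subject_id=str(row["subject_id"]),
                visit_id=str(row["visit_id"]),
                group=str(row["group"]),
                moca=float(row["moca"]),
                uhdrs_functional=float(row["uhdrs_functional"]),
                uhdrs_motor=float(row["uhdrs_motor"]),
                dysarthria=int(row["dysarthria"]),
                features={c: float(row[c]) for c in feature_cols},
            )
        )
    return visits
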