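"""Per-recording feature extraction: one call per task recording.

Combines the timing, acoustic and intelligibility modules into the
passage-reading feature vector (14 features) and the counting-task
feature vector, keyed by the catalogue column names.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .acoustics import estimate_pitch_track, loudness_sone, pitch_stats
from .alignment import (
    extra_missing_ratios,
    intelligibility_dtw,
    rainbow_passage,
    similarity_dtw,
    word_alignment,
)
from .io import AudioSignal, TimedTranscript, normalize_text
from .timing import DEFAULT_MIN_PAUSE_S, segment_from_transcript, timing_features

__all__ = ["passage_features", "counting_task_features"]


def passage_features(
    transcript: TimedTranscript,
    audio: Optional[AudioSignal] = None,
    small_transcript: Optional[TimedTranscript] = None,
    reference_text: Optional[str] = None,
    min_pause: float = DEFAULT_MIN_PAUSE_S,
    truncate_s: Optional[float] = None,
) -> dict[str, float]:
    """The full passage-reading feature vector for one recording.

    Acoustic features need ``audio``; the intelligibility score needs a
    second transcript from a lower-capacity recognizer.  Features whose
    inputs are absent come back NaN rather than failing the row.
    """
    reference = reference_text if reference_text is not None else rainbow_passage()
    seg = segment_from_transcript(transcript, min_pause=min_pause, truncate_s=truncate_s)
    feats = timing_features(seg, word_count=len(transcript)).as_dict()

    if audio is not None:
        track = estimate_pitch_track(audio)
        mean_f0, sd_f0 = pitch_stats(track, seg)
        feats["pitch_mean_hz"] = mean_f0
        feats["pitch_sd_hz"] = sd_f0
        feats["loudness_sone"] = loudness_sone(audio, seg).mean_loudness
    else:
        feats["pitch_mean_hz"] = np.nan
        feats["pitch_sd_hz"] = np.nan
        feats["loudness_sone"] = np.nan

    feats["similarity_dtw"] = similarity_dtw(reference, transcript.text())
    if small_transcript is not None:
        feats["intelligibility_dtw"] = intelligibility_dtw(transcript, small_transcript)
    else:
        feats["intelligibility_dtw"] = np.nan

    ref_words = normalize_text(reference).split()
    al = word_alignment(ref_words, [w.text for w in transcript.words])
    extra, missing = extra_missing_ratios(al)
    feats["ratio_extra_words"] = extra
    feats["ratio_missing_words"] = missing
    return feats


def counting_task_features(
    transcript: TimedTranscript,
    task: str,
    audio: Optional[AudioSignal] = None,
    min_pause: float = DEFAULT_MIN_PAUSE_S,
    prefix: Optional[str] = None,
) -> dict[str, float]:
    """Counting-task features, optionally prefixed for visit tables."""
    from .counting import counting_features  # local import avoids cycle

    cf = counting_features(transcript, task, min_pause=min_pause)
    feats = cf.as_dict()
    if audio is not None:
        seg = segment_from_transcript(transcript, min_pause=min_pause)
        track = estimate_pitch_track(audio)
        mean_f0, sd_f0 = pitch_stats(track, seg)
        feats["pitch_mean_hz"] = mean_f0
        feats["pitch_sd_hz"] = sd_f0
    if prefix is None:
        prefix = "counting_forward__" if task == "forward_1_20" else "counting_backward__"
    return {prefix + k: v for k, v in feats.items()}
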