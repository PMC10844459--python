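"""Reading accuracy and intelligibility via letter-coded DTW.

The transcribed reading is compared with the reference passage two
ways: (1) a word-level minimum-edit alignment yielding the ratios of
extra and missing words, and (2) a character-level comparison in which
normalized text is encoded letter-by-letter (a=1 .. z=26, inter-word
space=0) and aligned by classic dynamic time warping; the similarity
score is 1 / (1 + DTW distance), so identical encodings score 1 and
greater distances decay toward 0.  The intelligibility score applies
the same similarity to transcripts of the same recording produced by a
higher-capacity ("medium") and a lower-capacity ("small") recognizer:
the harder the speech is to transcribe, the more the small model
diverges and the lower the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .io import TimedTranscript, normalize_text

__all__ = [
    "LetterCode",
    "WordAlignment",
    "encode_letters",
    "dtw_distance",
    "similarity_dtw",
    "intelligibility_dtw",
    "word_alignment",
    "extra_missing_ratios",
    "rainbow_passage",
]

#: Default letter-to-code table: a=1 .. z=26, word-separating space=0.
DEFAULT_ALPHABET = {c: i + 1 for i, c in enumerate("abcdefghijklmnopqrstuvwxyz")}
DEFAULT_ALPHABET[" "] = 0


def rainbow_passage() -> str:
    """The reference reading passage (first paragraph, raw text)."""
    return (
        resources.files("hdspeech").joinpath("assets/rainbow_passage.txt")
        .read_text()
        .strip()
    )


@dataclass(frozen=True)
class LetterCode:
    """Integer codes, one per character of normalized text."""

    codes: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.codes)


def encode_letters(text: str, alphabet: dict[str, int] | None = None) -> LetterCode:
    """Encode normalized text character-wise into integer codes."""
    table = DEFAULT_ALPHABET if alphabet is None else alphabet
    norm = normalize_text(text)
    return LetterCode(tuple(table[c] for c in norm))


def dtw_distance(a: LetterCode, b: LetterCode) -> float:
    """Classic DTW distance between two code sequences.

    Local cost |a_i - b_j|; allowed steps (1,0), (0,1), (1,1); the
    distance is the minimum cumulative cost over all monotone warping
    paths from (0,0) to (n-1, m-1).  Symmetric in its arguments.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("dtw_distance requires non-empty sequences")
    x = np.asarray(a.codes, dtype=np.float64)
    y = np.asarray(b.codes, dtype=np.float64)
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        c = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(acc[n, m])


def similarity_dtw(reference_text: str, transcript_text: str) -> float:
    """1 / (1 + DTW distance) between letter-encoded texts; in (0, 1].

    Returns NaN when the transcript is empty after normalization.
    """
    ref = encode_letters(reference_text)
    hyp = encode_letters(transcript_text)
    if len(ref) == 0:
        raise ValueError("reference text empty after normalization")
    if len(hyp) == 0:
        return float("nan")
    return 1.0 / (1.0 + dtw_distance(ref, hyp))


def intelligibility_dtw(medium: TimedTranscript, small: TimedTranscript) -> float:
    """Similarity between transcripts from two differently-sized recognizers.

    Lower values mean the lower-capacity model diverged more, i.e. less
    intelligible speech.
    """
    if medium.source_tag == small.source_tag:
        raise ValueError(
            "intelligibility requires transcripts from two distinct recognizers "
            f"(both tagged {medium.source_tag!r})"
        )
    return similarity_dtw(medium.text(), small.text())


@dataclass(frozen=True)
class WordAlignment:
    """Word-level alignment counts against a reference word sequence."""

    matches: int
    insertions: int  # transcript words with no reference match
    deletions: int  # reference words with no transcript match
    reference_length: int

    def __post_init__(self) -> None:
        assert self.matches + self.deletions == self.reference_length
        assert self.matches >= 0 and self.insertions >= 0 and self.deletions >= 0


def word_alignment(
    reference_words: list[str], transcript_words: list[str]
) -> WordAlignment:
    """Minimum-edit word alignment (match 0, indel 1, substitution = 2).

    A substitution decomposes into one insertion plus one deletion, so
    matches are exactly the longest common subsequence.
    """
    if not reference_words:
        raise ValueError("reference word sequence is empty")
    n, m = len(reference_words), len(transcript_words)
    # LCS table: substitution cost 2 makes edit distance = n + m - 2*LCS
    lcs = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if reference_words[i - 1] == transcript_words[j - 1]:
                lcs[i, j] = lcs[i - 1, j - 1] + 1
            else:
                lcs[i, j] = max(lcs[i - 1, j], lcs[i, j - 1])
    matches = int(lcs[n, m])
    return WordAlignment(
        matches=matches,
        insertions=m - matches,
        deletions=n - matches,
        reference_length=n,
    )


def extra_missing_ratios(al: WordAlignment) -> tuple[float, float]:
    """Ratios of extra and missing words, both relative to reference length."""
    if al.reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    return (
        al.insertions / al.reference_length,
        al.deletions / al.reference_length,
    )
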