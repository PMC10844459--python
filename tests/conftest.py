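import numpy as np
import pytest

from hdspeech.io import TimedTranscript, WordToken
from hdspeech.simulate import RecordingProfile, synthesize_recording


def make_transcript(spans, tag="medium"):
    """Transcript from (text, start, end) triples (already normalized)."""
    return TimedTranscript(
        tuple(WordToken(t, s, e) for t, s, e in spans), source_tag=tag
    )


@pytest.fixture
def two_word_transcript():
    return make_transcript([("hello", 0.0, 0.5), ("world", 0.7, 1.2)])


@pytest.fixture
def tone_recording():
    """2 s sustained 150 Hz harmonic tone inside a single word span."""
    profile = RecordingProfile(words=(("ah", 0.1, 2.1),), f0_hz=150.0)
    return synthesize_recording(profile, seed=0)


def random_transcript(rng, n_words=50, max_gap=0.6):
    """Random well-formed transcript with word/gap structure."""
    spans = []
    t = float(rng.uniform(0, 1))
    for i in range(n_words):
        dur = float(rng.uniform(0.1, 0.5))
        spans.append((f"w{i}", t, t + dur))
        t += dur + float(rng.uniform(0.0, max_gap))
    return make_transcript(spans)
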