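import itertools

import numpy as np
import pytest

from hdspeech.alignment import (
    LetterCode,
    dtw_distance,
    encode_letters,
    extra_missing_ratios,
    intelligibility_dtw,
    rainbow_passage,
    similarity_dtw,
    word_alignment,
)
from hdspeech.simulate import corrupt_transcript

from conftest import make_transcript


def brute_force_dtw(a, b):
    """Minimum cost over all monotone warping paths, by enumeration."""
    best = [np.inf]

    def walk(i, j, acc):
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        if i + 1 < len(a) and j + 1 < len(b):
            walk(i + 1, j + 1, acc)
        if i + 1 < len(a):
            walk(i + 1, j, acc)
        if j + 1 < len(b):
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_word_alignment(ref, hyp):
    """Max matches over all order-preserving word pairings (exhaustive)."""
    best = 0
    for k in range(min(len(ref), len(hyp)), 0, -1):
        for ref_idx in itertools.combinations(range(len(ref)), k):
            for hyp_idx in itertools.combinations(range(len(hyp)), k):
                if all(ref[i] == hyp[j] for i, j in zip(ref_idx, hyp_idx)):
                    return k
    return best


class TestEncoding:
    @pytest.mark.parametrize(
        "text,codes",
        [("abc", (1, 2, 3)), ("a b", (1, 0, 2)), ("", ()), ("z", (26,)),
         ("A-B", (1, 0, 2))],
    )
    def test_letter_codes(self, text, codes):
        assert encode_letters(text).codes == codes


class TestDtw:
    def test_identity_is_zero(self):
        code = encode_letters("rainbow")
        assert dtw_distance(code, code) == 0.0

    def test_small_example(self):
        assert dtw_distance(LetterCode((1, 2, 3)), LetterCode((1, 2, 4))) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dtw_distance(LetterCode(()), LetterCode((1,)))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            a = LetterCode(tuple(rng.integers(0, 27, rng.integers(1, 7))))
            b = LetterCode(tuple(rng.integers(0, 27, rng.integers(1, 7))))
            assert dtw_distance(a, b) == pytest.approx(
                brute_force_dtw(a.codes, b.codes)
            )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = LetterCode(tuple(rng.integers(0, 27, rng.integers(1, 9))))
            b = LetterCode(tuple(rng.integers(0, 27, rng.integers(1, 9))))
            assert dtw_distance(a, b) == dtw_distance(b, a)


class TestSimilarity:
    def test_identical_texts_score_one(self):
        assert similarity_dtw("abc", "abc") == 1.0
        assert similarity_dtw(rainbow_passage(), rainbow_passage()) == 1.0

    def test_one_letter_substitution(self):
        assert similarity_dtw("abc", "abd") == 0.5

    def test_range_and_identity_condition(self):
        rng = np.random.default_rng(2)
        words = "the quick brown fox jumps over the lazy dog".split()
        for _ in range(20):
            hyp = " ".join(rng.choice(words, size=rng.integers(1, 9)))
            s = similarity_dtw("the quick brown fox", hyp)
            assert 0 < s <= 1
            expected_one = encode_letters(hyp).codes == encode_letters(
                "the quick brown fox"
            ).codes
            assert (s == 1.0) == expected_one

    def test_corrupting_a_word_lowers_similarity(self):
        reference = " ".join(f"word{i:02d}" for i in range(20))
        clean = similarity_dtw(reference, reference)
        corrupted = reference.replace("word07", "word07 xq")
        assert similarity_dtw(reference, corrupted) < clean

    def test_empty_transcript_reported_missing(self):
        assert np.isnan(similarity_dtw("abc", ""))


class TestIntelligibility:
    def test_identical_transcripts(self):
        medium = make_transcript([("one", 0, 0.4), ("two", 0.5, 0.9)], tag="medium")
        small = make_transcript([("one", 0, 0.4), ("two", 0.5, 0.9)], tag="small")
        assert intelligibility_dtw(medium, small) == 1.0

    def test_same_tag_rejected(self):
        medium = make_transcript([("one", 0, 0.4)], tag="medium")
        assert intelligibility_dtw(medium, medium.with_tag("small")) == 1.0
        with pytest.raises(ValueError, match="distinct"):
            intelligibility_dtw(medium, medium)

    def test_worked_example_against_brute_force(self):
        medium = make_transcript(
            [("one", 0, 0.3), ("two", 0.4, 0.7), ("three", 0.8, 1.2)], tag="medium"
        )
        small = make_transcript(
            [("one", 0, 0.3), ("too", 0.4, 0.7), ("three", 0.8, 1.2)], tag="small"
        )
        a = encode_letters(medium.text()).codes
        b = encode_letters(small.text()).codes
        d = brute_force_dtw(a, b)
        assert intelligibility_dtw(medium, small) == pytest.approx(1.0 / (1.0 + d))

    def test_mean_similarity_decreases_with_error_rate(self):
        truth = make_transcript(
            [(w, i * 0.5, i * 0.5 + 0.4) for i, w in enumerate(
                "when the sunlight strikes raindrops in the air".split())],
            tag="medium",
        )
        means = []
        for rate_idx, rate in enumerate((0.0, 0.1, 0.2, 0.4)):
            sims = []
            for rep in range(60):
                small = corrupt_transcript(truth, rate, seed=rate_idx * 1000 + rep)
                if len(small) == 0:
                    sims.append(0.0)
                    continue
                sims.append(intelligibility_dtw(truth, small))
            means.append(np.mean(sims))
        assert all(m1 > m2 for m1, m2 in zip(means[:-1], means[1:]))


class TestWordAlignment:
    def test_perfect_match(self):
        al = word_alignment(["the", "quick", "fox"], ["the", "quick", "fox"])
        assert (al.matches, al.insertions, al.deletions) == (3, 0, 0)

    def test_substitution_decomposes(self):
        al = word_alignment(["the", "quick", "fox"], ["the", "fox", "over"])
        assert (al.matches, al.deletions, al.insertions) == (2, 1, 1)
        assert extra_missing_ratios(al) == (pytest.approx(1 / 3), pytest.approx(1 / 3))

    def test_empty_transcript(self):
        al = word_alignment(["a", "b", "c"], [])
        assert al.matches == 0
        assert al.deletions == 3

    def test_reference_repeated_twice(self):
        ref = ["when", "the", "sunlight"]
        al = word_alignment(ref, ref + ref)
        extra, missing = extra_missing_ratios(al)
        assert extra == pytest.approx(1.0)
        assert missing == 0.0

    def test_matches_exhaustive_oracle_on_small_pairs(self):
        rng = np.random.default_rng(9)
        vocab = ["a", "b", "c", "d"]
        for _ in range(60):
            ref = list(rng.choice(vocab, size=rng.integers(1, 6)))
            hyp = list(rng.choice(vocab, size=rng.integers(0, 6)))
            al = word_alignment(ref, hyp)
            assert al.matches == brute_force_word_alignment(ref, hyp)
            assert al.matches + al.deletions == len(ref)
            assert al.matches + al.insertions == len(hyp)
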