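"""Readability, clarity and language-feature extraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from questqual.metrics import (
    FEATURE_COLUMNS,
    FeatureVector,
    clarity,
    featurize,
    featurize_corpus,
    flesch_reading_ease,
    language_features,
)
from questqual.textlex import Lexicon, LexiconSet, tokenize


def fre(words, sentences, syllables):
    return 206.835 - 1.015 * (words / sentences) - 84.6 * (syllables / words)


def synthetic_text(n_sentences, words_per_sentence, extra_syllables=0):
    """Sentences of monosyllables, with `extra_syllables` supplied by
    swapping in two-syllable words."""
    words = ["test"] * (n_sentences * words_per_sentence)
    for i in range(extra_syllables):
        words[i] = "kidney"
    out = []
    for s in range(n_sentences):
        chunk = words[s * words_per_sentence:(s + 1) * words_per_sentence]
        out.append(" ".join(chunk) + ".")
    return " ".join(out)


class TestFleschReadingEase:
    # (n_sentences, words_per_sentence, two-syllable swaps)
    CASES = [
        (1, 1, 0),  # the minimal extreme: 206.835 - 1.015 - 84.6 = 121.22
        (1, 10, 5),
        (1, 10, 0),
        (2, 5, 3),
        (2, 8, 8),
        (3, 4, 2),
        (3, 12, 30),
        (4, 6, 1),
        (5, 20, 50),
        (6, 15, 45),
        (2, 25, 0),
    ]

    @pytest.mark.parametrize("n_sent, wps, swaps", CASES)
    def test_matches_hand_evaluated_formula(self, n_sent, wps, swaps):
        text = tokenize(synthetic_text(n_sent, wps, swaps))
        words = n_sent * wps
        expected = fre(words, n_sent, words + swaps)
        assert flesch_reading_ease(text) == pytest.approx(expected, abs=1e-9)

    def test_minimal_extreme_value(self):
        assert flesch_reading_ease(tokenize("Go.")) == pytest.approx(121.22, abs=1e-9)

    def test_doubling_text_leaves_score_unchanged(self):
        once = synthetic_text(2, 7, 3)
        score1 = flesch_reading_ease(tokenize(once))
        score2 = flesch_reading_ease(tokenize(once + " " + once))
        assert score2 == pytest.approx(score1, abs=1e-9)

    def test_empty_text_is_missing(self):
        assert math.isnan(flesch_reading_ease(tokenize("")))

    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=2, max_value=20),
        st.integers(min_value=0, max_value=10),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_decreasing_in_syllables_per_word(self, n_sent, wps, swaps):
        swaps = min(swaps, n_sent * wps)
        base = flesch_reading_ease(tokenize(synthetic_text(n_sent, wps, swaps)))
        heavier = flesch_reading_ease(
            tokenize(synthetic_text(n_sent, wps, min(swaps + 1, n_sent * wps)))
        )
        if swaps + 1 <= n_sent * wps:
            assert heavier < base

    def test_monotone_decreasing_in_words_per_sentence(self):
        short = flesch_reading_ease(tokenize(synthetic_text(2, 5, 0)))
        long = flesch_reading_ease(tokenize(synthetic_text(2, 15, 0)))
        assert long < short


class TestClarity:
    def test_q1_worked_example(self, q1_text, lexicons):
        c = clarity(tokenize(q1_text), lexicons["interrogative"])
        assert round(c, 2) == 19.44
        assert c == pytest.approx(100 * 7 / 36)

    def test_q2_worked_example(self, q2_text, lexicons):
        assert clarity(tokenize(q2_text), lexicons["interrogative"]) == 0.0

    def test_single_interrogative_token(self, lexicons):
        assert clarity(tokenize("Why?"), lexicons["interrogative"]) == 100.0

    def test_empty_text_is_zero(self, lexicons):
        assert clarity(tokenize(""), lexicons["interrogative"]) == 0.0

    def test_invariant_under_proportional_extension(self, lexicons):
        # one interrogative in four words, replicated k times: same ratio
        base = "what test test test."
        for k in (1, 2, 5):
            c = clarity(tokenize(" ".join([base] * k)), lexicons["interrogative"])
            assert c == pytest.approx(25.0)


class TestLanguageFeatures:
    def test_all_personal_pronouns(self, lexicons):
        feats = language_features(tokenize("I me my"), lexicons)
        assert feats["personal_pronouns"] == 100.0
        assert feats["total_pronouns"] == 100.0

    def test_no_hits_gives_zeros(self, lexicons):
        feats = language_features(tokenize("zzz qqq xxx"), lexicons)
        assert all(feats[name] == 0.0 for name in feats if name not in
                   ("word_count", "words_per_sentence"))

    def test_hand_counted_fixture_sentence(self, lexicons):
        """17-token sentence with every category count checked by hand
        against the packaged lexicons."""
        text = ("I am worried about my kidney disease and my doctor said "
                "my husband should help me now.")
        t = tokenize(text)
        assert t.n_tokens == 17
        feats = language_features(t, lexicons)
        expected_counts = {
            "total_pronouns": 5,      # i, my x3, me
            "personal_pronouns": 5,
            "impersonal_pronouns": 0,
            "social": 2,              # doctor, husband
            "family": 1,              # husband
            "friend": 0,
            "female_refs": 0,
            "male_refs": 1,           # husband
            "past_focus": 1,          # said
            "present_focus": 2,       # am, now
            "future_focus": 0,
            "body": 1,                # kidney
            "health": 2,              # disease, doctor
            "affect": 1,              # worried
            "positive_emotion": 0,
            "negative_emotion": 1,
            "anxiety": 1,
            "anger": 0,
            "sadness": 0,
        }
        for name, count in expected_counts.items():
            assert feats[name] == pytest.approx(100 * count / 17), name

    def test_missing_category_is_named(self):
        incomplete = LexiconSet([Lexicon("interrogative", frozenset({"why"}), ())])
        with pytest.raises(KeyError, match="total_pronouns"):
            language_features(tokenize("why"), incomplete)


class TestFeaturize:
    def test_q1_record(self, q1_text, lexicons):
        vec = featurize(q1_text, "", lexicons)
        assert round(vec.clarity, 2) == 19.44
        assert vec.word_count == 36

    def test_empty_record_degenerate_vector(self, lexicons):
        vec = featurize("", "", lexicons)
        assert math.isnan(vec.readability)
        assert vec.clarity == 0.0
        assert vec.word_count == 0
        assert all(getattr(vec, n) == 0.0 for n in
                   ("total_pronouns", "affect", "health"))

    def test_deterministic(self, q1_text, lexicons):
        a = featurize(q1_text, "more body text here", lexicons)
        b = featurize(q1_text, "more body text here", lexicons)
        assert a == b

    def test_title_and_body_are_concatenated(self, lexicons):
        both = featurize("What is this?", "My kidney hurts.", lexicons)
        title_only = featurize("What is this?", "", lexicons)
        assert both.word_count == title_only.word_count + 3

    def test_pronoun_subset_invariant_on_random_words(self, rng, lexicons):
        pool = ("i me it this doctor kidney what blood test good sad they "
                "them those something family").split()
        for _ in range(25):
            words = rng.choice(pool, size=rng.integers(1, 30))
            vec = featurize(" ".join(words), "", lexicons)
            assert (
                vec.personal_pronouns + vec.impersonal_pronouns
                <= vec.total_pronouns + 1e-9
            )

    def test_corpus_featurization_matches_per_record_calls(
        self, small_corpus, lexicons
    ):
        table = featurize_corpus(small_corpus, lexicons)
        assert list(table.columns) == ["id", *FEATURE_COLUMNS]
        assert table["id"].tolist() == small_corpus["id"].tolist()
        for i, rec in small_corpus.iterrows():
            vec = featurize(rec.title, rec.body, lexicons)
            row = table.iloc[i]
            for name in FEATURE_COLUMNS:
                got, want = row[name], getattr(vec, name)
                assert (got == want) or (np.isnan(got) and np.isnan(want))

    def test_out_of_range_vector_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(
                readability=50.0, clarity=120.0, word_count=5,
                words_per_sentence=5.0,
                **{n: 0.0 for n in FEATURE_COLUMNS[4:]},
            )
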