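"""Question-quality indicators and LIWC-style language features.

Two indicators drive the quality construct:

* **readability** — the Flesch Reading Ease score,
  ``206.835 - 1.015 * (words/sentences) - 84.6 * (syllables/words)``,
  reported unclamped (values outside the conventional 0-100 range are
  legal and meaningful at the extremes).
* **clarity** — interrogative words (who/what/where/when/why/how and
  their contractions) as a percentage of all word tokens. A question
  that never signals what it asks scores 0.

Language features are dictionary category percentages: for each
category, 100 * (matching tokens) / (total tokens).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import pandas as pd

from .textlex import (
    Lexicon,
    LexiconSet,
    TokenizedText,
    default_lexicon_set,
    match_category,
    tokenize,
)

__all__ = [
    "FeatureVector",
    "CATEGORY_NAMES",
    "FEATURE_COLUMNS",
    "flesch_reading_ease",
    "clarity",
    "language_features",
    "featurize",
    "featurize_corpus",
]

logger = logging.getLogger(__name__)

#: Dictionary categories reported as percentages, in column order.
CATEGORY_NAMES = (
    "total_pronouns",
    "personal_pronouns",
    "impersonal_pronouns",
    "social",
    "family",
    "friend",
    "female_refs",
    "male_refs",
    "past_focus",
    "present_focus",
    "future_focus",
    "body",
    "health",
    "affect",
    "positive_emotion",
    "negative_emotion",
    "anxiety",
    "anger",
    "sadness",
)


@dataclass(frozen=True)
class FeatureVector:
    """Per-question quality indicators and language-category percentages.

    ``readability`` is NaN for empty text (the degenerate policy:
    missing, never zero — a zero is a meaningful, very hard text).
    """

    readability: float
    clarity: float
    word_count: int
    words_per_sentence: float
    total_pronouns: float
    personal_pronouns: float
    impersonal_pronouns: float
    social: float
    family: float
    friend: float
    female_refs: float
    male_refs: float
    past_focus: float
    present_focus: float
    future_focus: float
    body: float
    health: float
    affect: float
    positive_emotion: float
    negative_emotion: float
    anxiety: float
    anger: float
    sadness: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.clarity <= 100.0:
            raise ValueError(f"clarity out of [0, 100]: {self.clarity}")
        for name in CATEGORY_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.personal_pronouns + self.impersonal_pronouns > self.total_pronouns + 1e-9:
            raise ValueError("pronoun sub-categories exceed total_pronouns")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Column order of the feature table (one row per question record).
FEATURE_COLUMNS = tuple(f.name for f in fields(FeatureVector))


def flesch_reading_ease(text: TokenizedText) -> float:
    """Flesch Reading Ease of a tokenized text; NaN when empty.

    Uses the standard constants 206.835, 1.015 and 84.6 on average
    sentence length (words/sentence) and average word length
    (syllables/word). The score is not clamped.
    """
    if text.n_tokens == 0:
        logger.warning("flesch_reading_ease on empty text; returning NaN")
        return math.nan
    asl = text.n_tokens / text.n_sentences
    asw = text.n_syllables / text.n_tokens
    return 206.835 - 1.015 * asl - 84.6 * asw


def clarity(text: TokenizedText, interrogatives: Lexicon) -> float:
    """Percent of tokens that are interrogative words; 0 when empty."""
    if text.n_tokens == 0:
        return 0.0
    return 100.0 * match_category(text, interrogatives) / text.n_tokens


def language_features(
    text: TokenizedText, lexicons: LexiconSet | None = None
) -> dict[str, float]:
    """Category percentages plus word_count and words_per_sentence.

    Raises ``KeyError`` naming the first missing category if the
    lexicon set does not cover every reported category.
    """
    lexicons = lexicons if lexicons is not None else default_lexicon_set()
    for name in CATEGORY_NAMES:
        if name not in lexicons:
            raise KeyError(f"lexicon set is missing required category {name!r}")
    n = text.n_tokens
    out: dict[str, float] = {
        "word_count": n,
        "words_per_sentence": n / text.n_sentences if n else 0.0,
    }
    for name in CATEGORY_NAMES:
        out[name] = 100.0 * match_category(text, lexicons[name]) / n if n else 0.0
    return out


def combined_text(title: str, body: str, body_only: bool = False) -> str:
    """Question text used for analysis: title + body (default) or body."""
    if body_only:
        return body or ""
    return " ".join(part for part in ((title or "").strip(), (body or "").strip()) if part)


def featurize(
    title: str,
    body: str = "",
    lexicons: LexiconSet | None = None,
    body_only: bool = False,
) -> FeatureVector:
    """Compute the full feature vector for one question.

    Deterministic: the same text and lexicons always yield a
    bit-identical vector.
    """
    lexicons = lexicons if lexicons is not None else default_lexicon_set()
    text = tokenize(combined_text(title, body, body_only=body_only))
    feats = language_features(text, lexicons)
    return FeatureVector(
        readability=flesch_reading_ease(text),
        clarity=clarity(text, lexicons["interrogative"]),
        **feats,
    )


def featurize_corpus(
    corpus: pd.DataFrame,
    lexicons: LexiconSet | None = None,
    body_only: bool = False,
) -> pd.DataFrame:
    """Feature table for a corpus DataFrame (columns: id, title, body).

    Returns one row per record, indexed like ``corpus``, with an ``id``
    column followed by :data:`FEATURE_COLUMNS`. Records with empty text
    get the degenerate vector (NaN readability); their count is logged
    because clustering will exclude them.
    """
    lexicons = lexicons if lexicons is not None else default_lexicon_set()
    rows = []
    n_empty = 0
    for rec in corpus.itertuples(index=False):
        try:
            vec = featurize(
                getattr(rec, "title", ""), getattr(rec, "body", ""),
                lexicons=lexicons, body_only=body_only,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with record id
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
        if vec.word_count == 0:
            n_empty += 1
        rows.append({"id": rec.id, **vec.as_dict()})
    if n_empty:
        logger.warning("%d record(s) have empty text; readability is missing", n_empty)
    return pd.DataFrame(rows, columns=("id",) + FEATURE_COLUMNS)
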