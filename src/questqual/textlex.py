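"""Deterministic text decomposition and lexicon matching.

This module is the substrate for every quality metric: it turns raw
question text into word tokens, sentence spans, and per-token syllable
counts, and it counts tokens falling into dictionary categories
(LIWC-style word lists, one file per category).

The tokenizer is intentionally simple and fully documented rather than
linguistically sophisticated: tokens are maximal runs of letters (with
internal apostrophes, so contractions like "what's" stay one token) or
maximal runs of digits; hyphens split tokens; digit tokens count one
syllable. Sentence boundaries fall at runs of ``.``, ``!`` or ``?``
followed by whitespace or end-of-text, except after a known
abbreviation; text without terminal punctuation is one sentence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "TokenizedText",
    "Lexicon",
    "LexiconSet",
    "tokenize",
    "count_syllables",
    "match_category",
    "load_lexicon",
    "load_lexicon_set",
    "default_lexicon_set",
    "expand_contraction",
]

# Apostrophe variants normalised to U+0027 before tokenization.
_APOSTROPHES = "’ʼ′`"

_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)*|[0-9]+")

# Sentence-terminal punctuation: a run of .!? counts as one boundary.
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")

# Abbreviations whose trailing period does not end a sentence.
_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr",
        "vs", "etc", "eg", "ie", "e.g", "i.e", "approx", "dept",
        "fig", "no", "al", "med", "rx",
    }
)

# Contraction surface form -> base word, used so "what's" can match a
# lexicon entry "what".  Only question-word and pronoun contractions are
# needed; category files may also list contracted forms directly.
_CONTRACTION_BASE: dict[str, str] = {}
for _base in ("who", "whom", "whose", "what", "which", "where", "when", "why", "how"):
    for _suf in ("'s", "'re", "'d", "'ll", "'ve"):
        _CONTRACTION_BASE[_base + _suf] = _base
for _base in ("i", "you", "he", "she", "it", "we", "they", "that", "there"):
    for _suf in ("'m", "'s", "'re", "'d", "'ll", "'ve"):
        _CONTRACTION_BASE[_base + _suf] = _base


def expand_contraction(token: str) -> str:
    """Return the base word of a known contraction, else the token itself."""
    return _CONTRACTION_BASE.get(token, token)


@dataclass(frozen=True)
class TokenizedText:
    """A tokenized text: surface tokens, sentence spans, syllable counts.

    ``sentences`` holds ``(start, stop)`` token-index ranges that
    partition ``[0, n_tokens)``; ``syllables`` is parallel to ``tokens``.
    """

    tokens: tuple[str, ...]
    lower: tuple[str, ...]
    sentences: tuple[tuple[int, int], ...]
    syllables: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.tokens) or len(self.syllables) != len(self.tokens):
            raise ValueError("tokens, lower and syllables must be parallel")
        pos = 0
        for start, stop in self.sentences:
            if start != pos or stop <= start:
                raise ValueError("sentence ranges must partition [0, n_tokens)")
            pos = stop
        if pos != len(self.tokens):
            raise ValueError("sentence ranges must cover all tokens")
        if any(s < 1 for s in self.syllables):
            raise ValueError("every token has at least one syllable")

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def n_syllables(self) -> int:
        return sum(self.syllables)

    def detokenize(self) -> str:
        """Re-join tokens with single spaces, sentence-terminated by periods."""
        parts = []
        for start, stop in self.sentences:
            parts.append(" ".join(self.tokens[start:stop]) + ".")
        return " ".join(parts)


# ---------------------------------------------------------------------------
# Syllables
# ---------------------------------------------------------------------------

_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")
_I_HIATUS_RE = re.compile(r"[^aeiouy]i[aeiouy]")
_VOWELS = "aeiouy"


def _heuristic_syllables(word: str) -> int:
    """Vowel-group count with hiatus, -ed and silent-e corrections.

    Rules, applied to the lowercased letters only:
    vowel groups (aeiouy runs) count one syllable each; "i" before
    another vowel splits its group ("dialysis") unless preceded by
    t/s/c/x/g ("-tion", "-cian" stay fused); a final "-ed" after a
    consonant other than t/d is silent ("diagnosed"); a final "e" is
    silent ("disease"), except that consonant+"le" is syllabic
    ("stable") and group-final e ("knee", "movie") is untouched.
    """
    n = len(_VOWEL_GROUP_RE.findall(word))
    for m in _I_HIATUS_RE.finditer(word):
        if m.group(0)[0] not in "tscxg":
            n += 1
    if n > 1 and word.endswith("ed") and len(word) > 2:
        before = word[-3]
        if before not in _VOWELS and before not in "td":
            n -= 1
    if n > 1 and word.endswith("le") and len(word) > 2:
        if word[-3] in _VOWELS:  # "male": silent; "stable": syllabic
            n -= 1
    elif (
        n > 1
        and word.endswith("e")
        and not word.endswith(("ee", "ie", "oe", "ye", "ue", "ae"))
    ):
        n -= 1
    return max(n, 1)


def _load_syllable_dict() -> dict[str, int]:
    out: dict[str, int] = {}
    text = resources.files("questqual.data").joinpath("syllables.txt").read_text()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        word, _, count = line.partition("\t")
        out[word.strip().lower()] = int(count)
    return out


_SYLLABLE_DICT: dict[str, int] | None = None


def _syllable_dict() -> dict[str, int]:
    global _SYLLABLE_DICT
    if _SYLLABLE_DICT is None:
        _SYLLABLE_DICT = _load_syllable_dict()
    return _SYLLABLE_DICT


def count_syllables(token: str) -> int:
    """Syllables in one word token.

    Dictionary lookup first (packaged word list), then a vowel-group
    heuristic with a silent-e rule. Tokens with no letters (digit
    tokens) count one syllable.
    """
    letters = re.sub(r"[^a-z]", "", token.lower())
    if not letters:
        return 1
    hit = _syllable_dict().get(letters)
    if hit is not None:
        return hit
    return _heuristic_syllables(letters)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------


def tokenize(text: str) -> TokenizedText:
    """Tokenize ``text`` into words, sentences and syllable counts.

    Empty or letterless input yields zero tokens and zero sentences.
    """
    for ch in _APOSTROPHES:
        text = text.replace(ch, "'")
    text = text.replace("-", " ")

    token_spans = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]
    tokens = tuple(t for t, _ in token_spans)
    lower = tuple(t.lower() for t in tokens)
    syllables = tuple(count_syllables(t) for t in tokens)

    boundaries: list[int] = []  # character offsets of sentence ends
    for m in _BOUNDARY_RE.finditer(text):
        if m.group(0) == ".":
            prev = text[: m.start()].rstrip()
            w = re.search(r"[A-Za-z.]+$", prev)
            if w and w.group(0).lower().rstrip(".") in _ABBREVIATIONS:
                continue
        boundaries.append(m.end())

    sentences: list[tuple[int, int]] = []
    start = 0
    for b in boundaries:
        stop = start
        while stop < len(token_spans) and token_spans[stop][1] < b:
            stop += 1
        if stop > start:
            sentences.append((start, stop))
            start = stop
    if start < len(token_spans):
        sentences.append((start, len(token_spans)))

    return TokenizedText(tokens, lower, tuple(sentences), syllables)


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lexicon:
    """One word-category dictionary.

    ``exact`` entries match whole (lowercased) tokens; ``prefixes``
    (from ``term*`` file entries, LIWC convention) match any token
    starting with the prefix. Contractions are matched both on their
    surface form and on their expanded base word.
    """

    name: str
    exact: frozenset[str]
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        for term in list(self.exact) + list(self.prefixes):
            if not term or term != term.lower() or any(c.isspace() for c in term):
                raise ValueError(
                    f"lexicon {self.name!r}: entries must be nonempty, "
                    f"lowercase and whitespace-free (got {term!r})"
                )

    def matches(self, token_lower: str) -> bool:
        for form in (token_lower, expand_contraction(token_lower)):
            if form in self.exact:
                return True
            for p in self.prefixes:
                if form.startswith(p):
                    return True
        return False

    @property
    def terms(self) -> frozenset[str]:
        return self.exact | frozenset(p + "*" for p in self.prefixes)

    def union(self, other: "Lexicon", name: str | None = None) -> "Lexicon":
        return Lexicon(
            name or f"{self.name}|{other.name}",
            self.exact | other.exact,
            tuple(sorted(set(self.prefixes) | set(other.prefixes))),
        )


class LexiconSet(Mapping[str, Lexicon]):
    """A named collection of lexicons with unique category names."""

    def __init__(self, lexicons: Iterable[Lexicon]):
        self._by_name: dict[str, Lexicon] = {}
        for lex in lexicons:
            if lex.name in self._by_name:
                raise ValueError(f"duplicate lexicon category {lex.name!r}")
            self._by_name[lex.name] = lex

    def __getitem__(self, name: str) -> Lexicon:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"lexicon set has no category {name!r}; "
                f"available: {sorted(self._by_name)}"
            ) from None

    def __iter__(self):
        return iter(self._by_name)

    def __len__(self) -> int:
        return len(self._by_name)


def match_category(text: TokenizedText, lexicon: Lexicon) -> int:
    """Number of tokens in ``text`` that fall in ``lexicon``.

    Case-insensitive; each token counts at most once per category.
    """
    return sum(1 for tok in text.lower if lexicon.matches(tok))


def _parse_lexicon(name: str, raw: str) -> Lexicon:
    exact: set[str] = set()
    prefixes: set[str] = set()
    for line in raw.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if not line:
            continue
        if line.endswith("*"):
            prefixes.add(line[:-1])
        else:
            exact.add(line)
    return Lexicon(name, frozenset(exact), tuple(sorted(prefixes)))


def load_lexicon(path_or_name, name: str | None = None) -> Lexicon:
    """Load one lexicon from a plain-text file (one entry per line,
    ``#`` comments, trailing ``*`` marks a prefix entry)."""
    import pathlib

    path = pathlib.Path(path_or_name)
    return _parse_lexicon(name or path.stem, path.read_text())


def _packaged_lexicon(stem: str) -> Lexicon:
    raw = resources.files("questqual.lexicons").joinpath(f"{stem}.txt").read_text()
    return _parse_lexicon(stem, raw)


#: Categories shipped with the package, in reporting order.
PACKAGED_CATEGORIES = (
    "interrogative",
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

_DEFAULT_SET: LexiconSet | None = None


def default_lexicon_set() -> LexiconSet:
    """The packaged open LIWC-style lexicon set (cached)."""
    global _DEFAULT_SET
    if _DEFAULT_SET is None:
        _DEFAULT_SET = LexiconSet(_packaged_lexicon(s) for s in PACKAGED_CATEGORIES)
    return _DEFAULT_SET


def load_lexicon_set(directory) -> LexiconSet:
    """Load every ``*.txt`` file in ``directory`` as a category."""
    import pathlib

    d = pathlib.Path(directory)
    return LexiconSet(load_lexicon(p) for p in sorted(d.glob("*.txt")))
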