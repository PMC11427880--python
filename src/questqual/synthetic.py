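"""Synthetic question corpora with planted statistical structure.

Real question streams from consumer health Q&A platforms cannot be
redistributed, so every pipeline stage is exercised on generated
corpora instead. The generator emulates the *shape* of a two-platform
health-question sample:

* two subpopulations ("webmd"-like expert site, "yahoo"-like community
  site) differing in question length, pronoun/affect/social word rates
  and the prevalence of shared medical/demographic information — the
  directions of the published platform contrasts;
* a planted three-tier quality structure in (readability, clarity)
  space: high-quality questions use short sentences, few polysyllabic
  words and many interrogative words; low-quality questions the
  opposite;
* content codes drawn per platform, and judge ratings derived from the
  planted tiers under symmetric flip noise.

Texts are bag-of-words samples from a packaged health-vocabulary bank
stratified by syllable count — not fluent language. Readability and
clarity targets are therefore analytically steerable, which is the
point; nothing here imitates grammar, spelling noise or topic drift in
real questions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .textlex import _syllable_dict

__all__ = [
    "TierProfile",
    "PlatformProfile",
    "SyntheticSpec",
    "generate_corpus",
    "generate_ratings",
    "generate_regression_sample",
    "PLANTED_COEFS",
]

QUALITY_LEVELS = (1, 2, 3)  # high, average, low

_INTERROGATIVES = ("what", "when", "why", "how", "where", "who", "which")
_PRONOUNS = ("i", "me", "my", "you", "your", "we", "he", "she", "they", "it", "this", "that")
_AFFECT = ("worried", "scared", "hope", "glad", "sad", "afraid", "happy", "upset")
_SOCIAL = ("doctor", "family", "friend", "mother", "husband", "people", "son", "nurse")


def _word_banks() -> tuple[list[str], list[str]]:
    """(monosyllabic, polysyllabic >= 3) strata of the packaged bank."""
    d = _syllable_dict()
    mono = sorted(w for w, c in d.items() if c == 1)
    poly = sorted(w for w, c in d.items() if c >= 3)
    return mono, poly


@dataclass(frozen=True)
class TierProfile:
    """Text-generation targets for one planted quality tier."""

    words_per_sentence: float
    poly_fraction: float  # chance a filler word is polysyllabic
    interrogative_rate: float  # chance a word slot is an interrogative

    def validate(self) -> None:
        for name in ("poly_fraction", "interrogative_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.words_per_sentence < 2:
            raise ValueError("words_per_sentence must be >= 2")


@dataclass(frozen=True)
class PlatformProfile:
    """Per-platform shifts: length, word-class rates, code prevalences."""

    n: int
    target_words: float  # mean question length in words
    pronoun_rate: float
    affect_rate: float
    social_rate: float
    p_demographic: float
    p_diagnostic: float
    p_treatment: float
    p_medical_extra: float  # medical info beyond diagnostic/treatment
    # Bernoulli prevalences of the independent stage indicators:
    # questions can mention several stages, so these need not sum to 1.
    stage_probs: tuple[float, float, float]  # preventative / diagnosis / treatment
    chronic_probs: tuple[float, float, float]  # when_chronic / stable / unstable

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in (
            "pronoun_rate", "affect_rate", "social_rate", "p_demographic",
            "p_diagnostic", "p_treatment", "p_medical_extra",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("stage_probs", "chronic_probs"):
            probs = getattr(self, name)
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"{name} entries must be rates in [0, 1]")


#: Published-contrast directions: the community-style platform asks
#: longer questions with more pronouns, affect and social words and
#: more demographic information; the expert-style platform shares more
#: medical (diagnostic/treatment) information.
DEFAULT_PLATFORMS: dict[str, PlatformProfile] = {
    "webmd": PlatformProfile(
        n=400, target_words=42.0,
        pronoun_rate=0.09, affect_rate=0.010, social_rate=0.033,
        p_demographic=0.19, p_diagnostic=0.50, p_treatment=0.31,
        p_medical_extra=0.05,
        stage_probs=(0.04, 0.32, 0.64),
        chronic_probs=(0.13, 0.06, 0.81),
    ),
    "yahoo": PlatformProfile(
        n=400, target_words=60.0,
        pronoun_rate=0.12, affect_rate=0.015, social_rate=0.066,
        p_demographic=0.32, p_diagnostic=0.35, p_treatment=0.25,
        p_medical_extra=0.05,
        stage_probs=(0.04, 0.62, 0.34),
        chronic_probs=(0.38, 0.16, 0.46),
    ),
}

#: Planted tier profiles, separated in (readability, clarity) with the
#: published cluster semantics: high-quality questions ask explicitly
#: (many interrogatives) while carrying polysyllabic medical detail, so
#: their clarity is top but their readability mid-range; average
#: questions are simple chatty posts (top readability, low clarity);
#: low-quality questions ramble in long, heavy sentences (bottom
#: readability, low clarity). The three tiers then sit near an
#: equilateral triangle in standardized indicator space, which keeps
#: the planted structure recoverable by both k-means and the elbow
#: criterion.
DEFAULT_TIERS: dict[int, TierProfile] = {
    1: TierProfile(words_per_sentence=10.0, poly_fraction=0.45, interrogative_rate=0.42),
    2: TierProfile(words_per_sentence=9.0, poly_fraction=0.04, interrogative_rate=0.04),
    3: TierProfile(words_per_sentence=23.0, poly_fraction=0.60, interrogative_rate=0.01),
}

#: Tier mix matching the published cluster-size proportions
#: (101/169/354 out of 624).
DEFAULT_TIER_PROPORTIONS: dict[int, float] = {1: 0.162, 2: 0.271, 3: 0.567}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic study corpus."""

    platforms: dict[str, PlatformProfile] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORMS)
    )
    tiers: dict[int, TierProfile] = field(default_factory=lambda: dict(DEFAULT_TIERS))
    tier_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER_PROPORTIONS)
    )
    seed: int = 0

    def validate(self) -> None:
        if set(self.tiers) != set(QUALITY_LEVELS) or set(self.tier_proportions) != set(
            QUALITY_LEVELS
        ):
            raise ValueError("tiers and tier_proportions must cover levels 1, 2, 3")
        if abs(sum(self.tier_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("tier proportions must sum to 1")
        if any(p < 0 for p in self.tier_proportions.values()):
            raise ValueError("tier proportions must be nonnegative")
        for tier in self.tiers.values():
            tier.validate()
        for plat in self.platforms.values():
            plat.validate()
        total_n = sum(p.n for p in self.platforms.values())
        if total_n < 9:  # n >= 3k keeps 3-cluster fits well posed
            raise ValueError("total corpus size must be at least 9")

    def scaled(self, n_per_platform: int) -> "SyntheticSpec":
        """Same recipe at a different per-platform sample size."""
        platforms = {
            name: replace(p, n=n_per_platform) for name, p in self.platforms.items()
        }
        return replace(self, platforms=platforms)

    @classmethod
    def well_separated(
        cls, n_per_platform: int = 100, seed: int = 0
    ) -> "SyntheticSpec":
        """Recipe for cluster-recovery simulations: equal tier mix and
        long questions (180 words), which shrinks the per-question
        sampling noise until every tier pair is at least eight
        within-cluster standard deviations apart."""
        platforms = {
            name: replace(p, n=n_per_platform, target_words=180.0)
            for name, p in DEFAULT_PLATFORMS.items()
        }
        return cls(
            platforms=platforms,
            tier_proportions={1: 1 / 3, 2: 1 / 3, 3: 1 / 3},
            seed=seed,
        )


def _make_sentence(
    rng: np.random.Generator,
    tier: TierProfile,
    plat: PlatformProfile,
    mono: list[str],
    poly: list[str],
) -> str:
    n_words = max(2, int(round(rng.normal(tier.words_per_sentence, 1.5))))
    words = []
    for _ in range(n_words):
        u = rng.random()
        if u < tier.interrogative_rate:
            words.append(rng.choice(_INTERROGATIVES))
        elif u < tier.interrogative_rate + plat.pronoun_rate:
            words.append(rng.choice(_PRONOUNS))
        elif u < tier.interrogative_rate + plat.pronoun_rate + plat.affect_rate:
            words.append(rng.choice(_AFFECT))
        elif u < (
            tier.interrogative_rate + plat.pronoun_rate + plat.affect_rate
            + plat.social_rate
        ):
            words.append(rng.choice(_SOCIAL))
        elif rng.random() < tier.poly_fraction:
            words.append(rng.choice(poly))
        else:
            words.append(rng.choice(mono))
    text = " ".join(words)
    return text[0].upper() + text[1:] + ("?" if rng.random() < 0.5 else ".")


def generate_corpus(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (corpus, planted tier labels, content codes).

    The corpus frame has columns id, platform, title, body, topic,
    n_answers; tiers is a Series of planted quality levels (1/2/3)
    indexed like the corpus; codes is a frame of binary content
    indicators. Fully reproducible from the spec seed (or the ``seed``
    override).
    """
    spec = spec if spec is not None else SyntheticSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mono, poly = _word_banks()

    tier_levels = np.array(sorted(spec.tier_proportions))
    tier_p = np.array([spec.tier_proportions[t] for t in tier_levels])

    recs, tiers, codes = [], [], []
    i = 0
    for plat_name in sorted(spec.platforms):
        plat = spec.platforms[plat_name]
        for _ in range(plat.n):
            tier_level = int(rng.choice(tier_levels, p=tier_p))
            tier = spec.tiers[tier_level]
            n_sent = max(1, int(round(plat.target_words / tier.words_per_sentence
                                      + rng.normal(0, 0.5))))
            sentences = [
                _make_sentence(rng, tier, plat, mono, poly) for _ in range(n_sent)
            ]
            title, body = sentences[0], " ".join(sentences[1:])

            diagnostic = int(rng.random() < plat.p_diagnostic)
            treatment = int(rng.random() < plat.p_treatment)
            medical = int(
                diagnostic or treatment or rng.random() < plat.p_medical_extra
            )
            demographic = int(rng.random() < plat.p_demographic)
            stage = rng.random(3) < np.asarray(plat.stage_probs)
            chronic = rng.random(3) < np.asarray(plat.chronic_probs)

            recs.append(
                {
                    "id": f"q{i:05d}",
                    "platform": plat_name,
                    "title": title,
                    "body": body,
                    "topic": "kidney",
                    "n_answers": int(rng.poisson(2)),
                }
            )
            tiers.append(tier_level)
            codes.append(
                {
                    "id": f"q{i:05d}",
                    "medical_info": medical,
                    "demographic_info": demographic,
                    "diagnostic_info": diagnostic,
                    "treatment_prevention_info": treatment,
                    "stage_preventative": int(stage[0]),
                    "stage_diagnosis": int(stage[1]),
                    "stage_treatment": int(stage[2]),
                    "when_chronic": int(chronic[0]),
                    "stable": int(chronic[1]),
                    "unstable": int(chronic[2]),
                }
            )
            i += 1
    corpus = pd.DataFrame(recs)
    return corpus, pd.Series(tiers, name="tier"), pd.DataFrame(codes)


def generate_ratings(
    tiers, judge_count: int = 3, noise: float = 0.10, seed: int = 0
) -> pd.DataFrame:
    """Long-format judge ratings derived from planted tiers.

    Each judge independently sees the true tier, flipped with
    probability ``noise`` to one of the other two levels uniformly.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    tiers = pd.Series(tiers)
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(judge_count):
        judge = f"judge_{j + 1}"
        for rec, true_level in tiers.items():
            rating = int(true_level)
            if rng.random() < noise:
                rating = int(rng.choice([lv for lv in QUALITY_LEVELS if lv != rating]))
            rows.append({"record_id": rec, "judge_id": judge, "rating": rating})
    return pd.DataFrame(rows)


#: Planted log-odds coefficients used in parameter-recovery and
#: sign-recovery simulations: per contrast against the high tier,
#: intercept first, then three predictors (two binary, one continuous).
PLANTED_COEFS: dict[str, dict[str, float]] = {
    "2 vs 1": {
        "intercept": 0.3,
        "demographic_info": -0.8,
        "diagnostic_info": 1.0,
        "word_count_z": -0.6,
    },
    "3 vs 1": {
        "intercept": 0.6,
        "demographic_info": -1.2,
        "diagnostic_info": 0.9,
        "word_count_z": -1.0,
    },
}


def generate_regression_sample(
    n: int = 2000,
    coefs: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw (predictors, quality levels) from a known softmax model.

    Binary predictors are Bernoulli(0.4/0.5); the continuous predictor
    is standard normal. Levels are 1 (reference), 2, 3 with the planted
    log-odds in ``coefs`` (defaults to :data:`PLANTED_COEFS`).
    """
    coefs = coefs if coefs is not None else PLANTED_COEFS
    rng = np.random.default_rng(seed)
    terms = [t for t in next(iter(coefs.values())) if t != "intercept"]
    X = pd.DataFrame(
        {
            "demographic_info": rng.random(n) < 0.4,
            "diagnostic_info": rng.random(n) < 0.5,
            "word_count_z": rng.normal(size=n),
        }
    ).astype(float)[terms]
    eta = np.zeros((n, 3))
    for k, contrast in enumerate(coefs, start=1):
        c = coefs[contrast]
        eta[:, k] = c["intercept"] + sum(
            c[t] * X[t].to_numpy() for t in terms
        )
    ex = np.exp(eta - eta.max(axis=1, keepdims=True))
    P = ex / ex.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = P.cumsum(axis=1)
    y = (u[:, None] > cum).sum(axis=1) + 1
    return X, pd.Series(y, name="quality")
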