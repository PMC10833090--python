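"""Lexicon-based multidimensional emotion scoring.

Word sentiment is the product of intensity and polarity, s(w) = v(w) * p(w),
so an anger word with intensity 7 scores -7 and a hope word with intensity 4
scores +4.  Document scoring scans tokens against the lexicon and accumulates
per-category intensity totals plus a signed polarity score; no negation or
intensifier grammar is applied (plain dictionary matching).  Multi-sense words
use their maximum-intensity entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import (
    LexiconEntry,
    MAIN_CATEGORIES,
    NEGATIVE_CATEGORIES,
    SentimentLexicon,
)

__all__ = [
    "EmotionProfile",
    "word_sentiment",
    "emotion_profile",
    "dominant_category",
    "classify_polarity",
    "negative_emotion_proportion",
]


@dataclass
class EmotionProfile:
    """Per-category intensity totals plus a signed polarity score for one document."""

    category_totals: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in MAIN_CATEGORIES}
    )
    polarity_score: float = 0.0
    matched_count: int = 0

    def __add__(self, other: "EmotionProfile") -> "EmotionProfile":
        totals = {
            c: self.category_totals[c] + other.category_totals[c]
            for c in MAIN_CATEGORIES
        }
        return EmotionProfile(
            category_totals=totals,
            polarity_score=self.polarity_score + other.polarity_score,
            matched_count=self.matched_count + other.matched_count,
        )


def word_sentiment(entry: LexiconEntry) -> int:
    """s(w) = v(w) * p(w): signed word sentiment, |s(w)| = intensity."""
    return entry.intensity * entry.polarity


def _best_entry(entries: Sequence[LexiconEntry]) -> LexiconEntry:
    # multi-sense rule: maximum |intensity| wins; ties by subcategory code for
    # determinism
    return max(entries, key=lambda e: (abs(e.intensity), e.subcategory))


def emotion_profile(
    tokens: Iterable[str], lexicon: SentimentLexicon
) -> EmotionProfile:
    """Scan tokens against the lexicon and accumulate an emotion profile.

    For each lexicon hit the entry's intensity is added to its main
    category's total and s(w) to the polarity score.  Non-lexicon tokens are
    ignored.  Order-invariant and additive over concatenation.
    """
    profile = EmotionProfile()
    tax = lexicon.taxonomy
    for tok in tokens:
        entries = lexicon.get(tok)
        if not entries:
            continue
        entry = _best_entry(entries)
        category = tax.main_category_of(entry.subcategory)
        profile.category_totals[category] += entry.intensity
        profile.polarity_score += word_sentiment(entry)
        profile.matched_count += 1
    return profile


def dominant_category(profile: EmotionProfile) -> str | None:
    """Main category with the largest intensity total.

    Ties resolve by the fixed order anger > disgust > fear > sadness >
    surprise > good > happy.  Returns None when no token matched.
    """
    if profile.matched_count == 0:
        return None
    return max(MAIN_CATEGORIES, key=lambda c: (profile.category_totals[c], -MAIN_CATEGORIES.index(c)))


def classify_polarity(profile: EmotionProfile, threshold: float = 0.0) -> int:
    """Binary polarity from the signed score: 1 if score > threshold else 0."""
    return 1 if profile.polarity_score > threshold else 0


def negative_emotion_proportion(profiles: Sequence[EmotionProfile]) -> float:
    """Fraction of profiles whose dominant category is a negative emotion.

    Documents with no lexicon hit count as non-negative.  Raises on an empty
    collection.
    """
    if len(profiles) == 0:
        raise ValueError("cannot compute a proportion of zero profiles")
    neg = sum(
        1 for p in profiles if (dominant_category(p) or "") in NEGATIVE_CATEGORIES
    )
    return neg / len(profiles)
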