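"""Plutchik's wheel of basic emotions.

The eight basic emotions — anger, sadness, joy, trust, anticipation, fear,
disgust and surprise — form the discrete state space used throughout the
package: lexicons, post scores, intensity profiles and transition models are
all indexed by this set, in the fixed order of :data:`EMOTIONS`.

The wheel arranges the emotions as four polar pairs; negated emotion
expressions ("not happy") are mapped onto the opposite pole rather than
discarded, which keeps all scored mass inside the eight-emotion space.
"""

from __future__ import annotations

EMOTIONS: tuple[str, ...] = (
    "anger",
    "sadness",
    "joy",
    "trust",
    "anticipation",
    "fear",
    "disgust",
    "surprise",
)

#: Index of each emotion in the canonical order.
EMOTION_INDEX: dict[str, int] = {e: i for i, e in enumerate(EMOTIONS)}

#: Polar opposites on the wheel (an involution: OPPOSITE[OPPOSITE[e]] == e).
OPPOSITE: dict[str, str] = {
    "joy": "sadness",
    "sadness": "joy",
    "trust": "disgust",
    "disgust": "trust",
    "fear": "anger",
    "anger": "fear",
    "anticipation": "surprise",
    "surprise": "anticipation",
}

#: Deterministic tie-break order used when several emotions share the
#: maximal score on a post (first listed wins).
DOMINANT_TIE_ORDER: tuple[str, ...] = (
    "anger",
    "sadness",
    "disgust",
    "fear",
    "joy",
    "surprise",
    "trust",
    "anticipation",
)

_TIE_RANK: dict[str, int] = {e: i for i, e in enumerate(DOMINANT_TIE_ORDER)}


def opposite(emotion: str) -> str:
    """Return the polar opposite of *emotion* on the wheel."""
    try:
        return OPPOSITE[emotion]
    except KeyError:
        raise ValueError(f"unknown emotion: {emotion!r}") from None


def tie_rank(emotion: str) -> int:
    """Rank of *emotion* in the documented dominant-label tie-break order."""
    return _TIE_RANK[emotion]
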