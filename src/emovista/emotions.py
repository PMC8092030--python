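"""Post-level emotion scoring and per-conversation emotion sequences.

Each post is scored against the eight expanded lexicons.  A lexicon match
of weight *w* contributes *w* times the product of any valence-modifier
factors (intensifiers > 1, inhibitors in (0,1)) found in the look-back
window before it.  A negator in that window flips the contribution to the
Plutchik opposite emotion (odd negator counts flip, even counts cancel, so
double negation restores the original emotion); a ``discard`` mode drops
negated contributions instead.  The dominant emotion is the argmax score,
with ties broken by a fixed documented order, and dominant labels are then
threaded into chronological per-conversation emotion sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .corpus import Post
from .plutchik import EMOTIONS, opposite, tie_rank

__all__ = ["EmotionMatch", "PostEmotion", "EmotionSequence",
           "score_post", "score_corpus", "build_sequences",
           "DEFAULT_MODIFIERS", "DEFAULT_NEGATORS"]

#: Default valence modifiers (intensifiers amplify, inhibitors attenuate).
DEFAULT_MODIFIERS: dict[str, float] = {
    "very": 1.5, "extremely": 2.0, "so": 1.5, "totally": 1.8,
    "really": 1.5, "slightly": 0.5, "somewhat": 0.6, "barely": 0.4,
    "hardly": 0.4,
}

DEFAULT_NEGATORS: frozenset[str] = frozenset({"not", "no", "never"})


@dataclass(frozen=True)
class EmotionMatch:
    term: str
    emotion: str  # emotion credited after any negation flip
    weight: float
    modifier_factor: float
    negated: bool


@dataclass
class PostEmotion:
    post_id: str
    scores: dict[str, float]
    dominant: str | None
    matches: list[EmotionMatch] = field(default_factory=list)


def score_post(
    tokens: Sequence[str],
    lexicon_lookup: Mapping[str, tuple[str, float]],
    negators: Iterable[str] = DEFAULT_NEGATORS,
    modifiers: Mapping[str, float] = DEFAULT_MODIFIERS,
    window: int = 3,
    post_id: str = "",
    negation_mode: str = "flip",
) -> PostEmotion:
    """Score one tokenized post against the emotion lexicons.

    *lexicon_lookup* maps term → (emotion, weight) (see
    :meth:`EmotionLexicon.term_lookup`).  *window* is how many tokens
    before a lexicon match are searched for negators and modifiers.
    ``negation_mode`` is ``"flip"`` (to the Plutchik opposite) or
    ``"discard"``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if negation_mode not in ("flip", "discard"):
        raise ValueError(f"unknown negation_mode {negation_mode!r}")
    negset = set(negators)
    scores = {e: 0.0 for e in EMOTIONS}
    matches: list[EmotionMatch] = []
    for i, tok in enumerate(tokens):
        hit = lexicon_lookup.get(tok)
        if hit is None:
            continue
        emotion, weight = hit
        factor = 1.0
        n_neg = 0
        for prev in tokens[max(0, i - window):i]:
            if prev in negset:
                n_neg += 1
            elif prev in modifiers:
                factor *= modifiers[prev]
        negated = n_neg % 2 == 1
        if negated and negation_mode == "discard":
            continue
        credited = opposite(emotion) if negated else emotion
        scores[credited] += weight * factor
        matches.append(EmotionMatch(tok, credited, weight, factor, negated))

    max_score = max(scores.values())
    dominant = None
    if max_score > 0:
        dominant = min((e for e in EMOTIONS if scores[e] == max_score),
                       key=tie_rank)
    return PostEmotion(post_id=post_id, scores=scores, dominant=dominant,
                       matches=matches)


def score_corpus(
    posts: Sequence[Post],
    lexicon_lookup: Mapping[str, tuple[str, float]],
    negators: Iterable[str] = DEFAULT_NEGATORS,
    modifiers: Mapping[str, float] = DEFAULT_MODIFIERS,
    window: int = 3,
    negation_mode: str = "flip",
) -> dict[str, PostEmotion]:
    """Score every post (requires ``clean_tokens``); returns post_id → result."""
    out: dict[str, PostEmotion] = {}
    for post in posts:
        if post.clean_tokens is None:
            raise ValueError(f"post {post.post_id} has no clean_tokens")
        out[post.post_id] = score_post(
            post.clean_tokens, lexicon_lookup, negators, modifiers,
            window=window, post_id=post.post_id, negation_mode=negation_mode)
    return out


@dataclass
class EmotionSequence:
    """Chronological dominant-emotion labels of one conversation in one phase."""

    conversation_id: str
    phase: str
    labels: list[str]

    def __len__(self) -> int:
        return len(self.labels)


def build_sequences(
    posts: Sequence[Post],
    post_emotions: Mapping[str, PostEmotion],
) -> list[EmotionSequence]:
    """Thread dominant labels into per-conversation, per-phase sequences.

    Posts with no dominant emotion are skipped; conversations whose posts
    are all neutral yield no sequence.  Ordering is by timestamp with
    post-id tie-break; conversations never share a sequence, so no
    cross-conversation adjacency can arise downstream.
    """
    groups: dict[tuple[str, str], list[Post]] = {}
    for post in posts:
        if post.phase is None:
            raise ValueError(f"post {post.post_id} has no phase")
        groups.setdefault((post.conversation_id, post.phase), []).append(post)

    sequences: list[EmotionSequence] = []
    for (cid, phase) in sorted(groups):
        thread = sorted(groups[(cid, phase)],
                        key=lambda p: (p.timestamp, p.post_id))
        labels = [post_emotions[p.post_id].dominant for p in thread
                  if p.post_id in post_emotions
                  and post_emotions[p.post_id].dominant is not None]
        if labels:
            sequences.append(EmotionSequence(cid, phase, labels))
    return sequences
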