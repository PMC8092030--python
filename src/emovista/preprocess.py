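"""Corpus cleaning, bot/duplicate filtering, anonymization and phase windows.

High-volume accounts (news feeds, bots) are removed by a per-user volume
quantile rule; within the remaining users, texts repeated beyond a
duplication threshold keep only their first occurrence.  Remaining author
ids are replaced by salted hashes.  Each post is then assigned to one of
the four pandemic phases by its calendar date.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Post

# Compact English function-word list; emotion-relevant negators and valence
# modifiers are deliberately absent (they are protected tokens downstream).
STOP_WORDS: frozenset[str] = frozenset(
    """
    a about above after again all am an and any are as at be because been
    before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers
    him his how i if in into is it its itself just me more most my myself
    of off on once only or other our ours out over own same she should so
    some such than that the their theirs them then there these they this
    those through to too under until up was we were what when where which
    while who whom why will with you your yours
    """.split()
)

#: Tokens that must survive stop-word removal because the emotion scorer
#: depends on them (negators and common valence modifiers).
PROTECTED_TOKENS: frozenset[str] = frozenset(
    {"not", "no", "never", "hardly", "barely", "very", "so", "extremely",
     "really", "totally", "slightly", "somewhat"}
)

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_HANDLE_RE = re.compile(r"@\w+")
_TOKEN_RE = re.compile(r"[a-z]+")


class OutOfPhaseRangeError(ValueError):
    """Raised when a timestamp falls outside every configured phase window."""


@dataclass(frozen=True)
class PhaseWindow:
    """One pandemic phase: a name and an inclusive calendar-date window."""

    name: str
    start: date
    end: date

    def contains(self, day: date) -> bool:
        return self.start <= day <= self.end


#: The four 2020 phase windows: pre-pandemic months, first lockdown, easing
#: of restrictions, second lockdown.
DEFAULT_PHASE_WINDOWS: tuple[PhaseWindow, ...] = (
    PhaseWindow("prepandemic", date(2020, 1, 1), date(2020, 2, 29)),
    PhaseWindow("first_lockdown", date(2020, 3, 1), date(2020, 5, 31)),
    PhaseWindow("easing_restrictions", date(2020, 6, 1), date(2020, 6, 30)),
    PhaseWindow("second_lockdown", date(2020, 7, 1), date(2020, 9, 30)),
)

PHASES: tuple[str, ...] = tuple(w.name for w in DEFAULT_PHASE_WINDOWS)


def clean_text(
    raw: str,
    stop_words: Iterable[str] = STOP_WORDS,
    protected: Iterable[str] = PROTECTED_TOKENS,
) -> list[str]:
    """Tokenize one raw post.

    Lowercases, strips URLs and @-handles, reduces ``#tag`` to ``tag``,
    keeps maximal alphabetic runs, and drops stop words.  Tokens in
    *protected* survive stop-word removal regardless.
    """
    stop = set(stop_words) - set(protected)
    text = _URL_RE.sub(" ", raw.lower())
    text = _HANDLE_RE.sub(" ", text)
    return [t for t in _TOKEN_RE.findall(text) if t not in stop]


def anonymize_user_id(user_id: str, salt: str = "emovista") -> str:
    """Deterministic salted hash of a raw author id (16 hex chars)."""
    return hashlib.sha256(f"{salt}:{user_id}".encode("utf-8")).hexdigest()[:16]


def filter_accounts(
    posts: Sequence[Post],
    volume_percentile: float = 0.99,
    dup_threshold: int = 1,
    salt: str = "emovista",
) -> tuple[list[Post], set[str]]:
    """Remove high-volume accounts and per-user duplicate texts; anonymize.

    Users whose post count strictly exceeds the *volume_percentile* quantile
    of per-user counts are dropped entirely.  Within a surviving user, a
    text occurring more than *dup_threshold* times keeps only its first
    (chronological) occurrence.  Surviving posts get salted-hash author ids.

    Returns ``(kept_posts, removed_user_ids)`` with removed ids raw (they
    never appear in any output artifact).
    """
    if not posts:
        raise ValueError("filter_accounts requires a non-empty post list")
    if not 0.0 < volume_percentile <= 1.0:
        raise ValueError(
            f"volume_percentile must lie in (0, 1], got {volume_percentile}"
        )

    counts: dict[str, int] = {}
    for post in posts:
        counts[post.user_id] = counts.get(post.user_id, 0) + 1
    cutoff = float(np.quantile(np.array(list(counts.values()), dtype=float),
                               volume_percentile))
    removed = {uid for uid, c in counts.items() if c > cutoff}

    seen: dict[tuple[str, str], int] = {}
    text_totals: dict[tuple[str, str], int] = {}
    for post in posts:
        if post.user_id in removed:
            continue
        text_totals[(post.user_id, post.raw_text)] = (
            text_totals.get((post.user_id, post.raw_text), 0) + 1
        )

    kept: list[Post] = []
    ordered = sorted(
        (p for p in posts if p.user_id not in removed),
        key=lambda p: (p.timestamp, p.post_id),
    )
    for post in ordered:
        key = (post.user_id, post.raw_text)
        seen[key] = seen.get(key, 0) + 1
        if text_totals[key] > dup_threshold and seen[key] > 1:
            continue
        kept.append(post.replace(user_id=anonymize_user_id(post.user_id, salt)))
    return kept, removed


def assign_phase(
    timestamp: datetime | date,
    windows: Sequence[PhaseWindow] = DEFAULT_PHASE_WINDOWS,
) -> str:
    """Name of the unique phase window containing *timestamp*'s date."""
    day = timestamp.date() if isinstance(timestamp, datetime) else timestamp
    for window in windows:
        if window.contains(day):
            return window.name
    raise OutOfPhaseRangeError(f"{day.isoformat()} falls outside all phase windows")


def preprocess_corpus(
    posts: Sequence[Post],
    windows: Sequence[PhaseWindow] = DEFAULT_PHASE_WINDOWS,
    stop_words: Iterable[str] = STOP_WORDS,
    volume_percentile: float = 0.99,
    dup_threshold: int = 1,
    salt: str = "emovista",
) -> tuple[list[Post], set[str]]:
    """Full cleaning pass: filter accounts, tokenize, assign phases.

    Posts dated outside every window are dropped (they belong to no phase).
    Returns the cleaned posts and the removed (bot/news) user ids.
    """
    kept, removed = filter_accounts(posts, volume_percentile, dup_threshold, salt)
    out: list[Post] = []
    for post in kept:
        try:
            phase = assign_phase(post.timestamp, windows)
        except OutOfPhaseRangeError:
            continue
        out.append(
            post.replace(clean_tokens=clean_text(post.raw_text, stop_words), phase=phase)
        )
    return out, removed


def load_stop_words(path: str | Path) -> frozenset[str]:
    """Read a one-term-per-line stop-word file."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return frozenset(t.strip().lower() for t in fh if t.strip())
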