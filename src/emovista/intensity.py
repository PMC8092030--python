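"""Per-phase normalized emotion-intensity profiles.

The raw intensity of emotion *e* in a phase is the sum of post-level *e*
scores over all posts of the phase; the normalized profile rescales the
eight raw totals to percentages summing to 100, the form in which phase
emotion climates are compared.  ``n_observations`` counts (post, emotion)
pairs with a nonzero contribution — observation level, not post level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .emotions import PostEmotion
from .plutchik import EMOTIONS

__all__ = ["IntensityProfile", "phase_intensity_profile", "intensity_table"]


@dataclass
class IntensityProfile:
    phase: str
    raw: dict[str, float]
    normalized: dict[str, float]  # percentages, sum to 100
    n_observations: int

    def proportion(self, emotion: str) -> float:
        """Normalized intensity as a proportion in [0, 1]."""
        return self.normalized[emotion] / 100.0


def phase_intensity_profile(
    post_emotions: Iterable[PostEmotion],
    phase: str,
) -> IntensityProfile:
    """Aggregate post scores into one phase's normalized profile.

    Raises ``ValueError`` when no post carries a nonzero score (an all-zero
    phase has no defined profile).
    """
    raw = {e: 0.0 for e in EMOTIONS}
    n_obs = 0
    for pe in post_emotions:
        for emo, score in pe.scores.items():
            if score > 0:
                raw[emo] += score
                n_obs += 1
    total = sum(raw.values())
    if total <= 0:
        raise ValueError(f"phase {phase!r} has no nonzero emotion scores")
    normalized = {e: 100.0 * raw[e] / total for e in EMOTIONS}
    return IntensityProfile(phase=phase, raw=raw, normalized=normalized,
                            n_observations=n_obs)


def intensity_table(profiles: Sequence[IntensityProfile]) -> pd.DataFrame:
    """Tidy (phase, emotion, raw, normalized, n) table for export."""
    rows = [
        {"phase": p.phase, "emotion": e, "raw": p.raw[e],
         "normalized": p.normalized[e], "n": p.n_observations}
        for p in profiles for e in EMOTIONS
    ]
    return pd.DataFrame(rows, columns=["phase", "emotion", "raw",
                                       "normalized", "n"])
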