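"""First-order Markov models of emotion transitions within conversations.

Adjacent dominant-emotion pairs are counted inside each conversation's
sequence (never across conversations), giving an 8×8 count matrix C per
phase; the transition matrix P row-normalizes C.  Source emotions never
observed leave their row undefined (reported as such rather than smoothed;
optional Laplace smoothing is available for downstream consumers).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .emotions import EmotionSequence
from .plutchik import EMOTIONS, EMOTION_INDEX

__all__ = ["TransitionModel", "estimate_transition_model", "top_transitions",
           "simulate_sequences", "transition_dot"]


@dataclass
class TransitionModel:
    phase: str
    labels: tuple[str, ...]
    C: np.ndarray  # (8, 8) integer counts
    P: np.ndarray  # (8, 8) row-stochastic; undefined rows are NaN
    n_transitions: int

    def defined_rows(self) -> np.ndarray:
        return self.C.sum(axis=1) > 0

    def probability(self, source: str, target: str) -> float:
        return float(self.P[EMOTION_INDEX[source], EMOTION_INDEX[target]])

    def smoothed(self, alpha: float = 1.0) -> np.ndarray:
        """Laplace-smoothed transition matrix (all rows defined)."""
        Cs = self.C + alpha
        return Cs / Cs.sum(axis=1, keepdims=True)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=list(self.labels),
                            columns=list(self.labels))

    def probs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.labels),
                            columns=list(self.labels))


def estimate_transition_model(
    sequences: Sequence[EmotionSequence],
    phase: str,
) -> TransitionModel:
    """Count adjacent pairs within each sequence of *phase* and normalize.

    Raises ``ValueError`` when no sequence of length ≥ 2 exists (no
    transition is observable).
    """
    C = np.zeros((8, 8), dtype=np.int64)
    for seq in sequences:
        if seq.phase != phase:
            raise ValueError(
                f"sequence {seq.conversation_id} belongs to {seq.phase}, "
                f"not {phase}")
        for a, b in zip(seq.labels, seq.labels[1:]):
            C[EMOTION_INDEX[a], EMOTION_INDEX[b]] += 1
    total = int(C.sum())
    if total == 0:
        raise ValueError(f"phase {phase!r} has no sequence of length >= 2")
    row_sums = C.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_sums > 0, C / row_sums, np.nan)
    return TransitionModel(phase=phase, labels=EMOTIONS, C=C, P=P,
                           n_transitions=total)


def top_transitions(model: TransitionModel, k: int = 5) -> list[tuple[str, str, float]]:
    """The k most probable observed transitions.

    Sorted by probability descending, ties by count descending, then by
    the fixed emotion-label order of source and target.
    """
    rows = []
    for i, src in enumerate(model.labels):
        for j, dst in enumerate(model.labels):
            if model.C[i, j] > 0:
                rows.append((src, dst, float(model.P[i, j]), int(model.C[i, j]),
                             i, j))
    rows.sort(key=lambda r: (-r[2], -r[3], r[4], r[5]))
    return [(src, dst, p) for src, dst, p, _c, _i, _j in rows[:k]]


def simulate_sequences(
    P: np.ndarray,
    n_sequences: int,
    seq_length: int,
    seed: int,
    phase: str = "simulated",
    initial: np.ndarray | None = None,
) -> list[EmotionSequence]:
    """Sample emotion sequences from a known row-stochastic matrix.

    Used for parameter-recovery checks: estimating a model on the output
    should recover *P* up to sampling error.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (8, 8) or np.abs(P.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("P must be 8x8 row-stochastic")
    rng = np.random.default_rng(seed)
    if initial is None:
        initial = np.full(8, 1 / 8)
    out = []
    for s in range(n_sequences):
        state = int(rng.choice(8, p=initial))
        labels = [EMOTIONS[state]]
        for _ in range(seq_length - 1):
            state = int(rng.choice(8, p=P[state]))
            labels.append(EMOTIONS[state])
        out.append(EmotionSequence(f"sim{s:06d}", phase, labels))
    return out


def transition_dot(model: TransitionModel, threshold: float = 0.2) -> str:
    """DOT-format digraph of transitions with probability ≥ *threshold*."""
    lines = [f'digraph "{model.phase}" {{', "  rankdir=LR;"]
    for i, src in enumerate(model.labels):
        for j, dst in enumerate(model.labels):
            p = model.P[i, j]
            if model.C[i, j] > 0 and p >= threshold:
                lines.append(f'  {src} -> {dst} [label="{p:.3f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
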