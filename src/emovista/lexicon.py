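"""Skip-gram embeddings and nearest-neighbor emotion-lexicon expansion.

Seed terms for the eight Plutchik emotions are grown into weighted lexicons
by training a skip-gram-with-negative-sampling (SGNS) word embedding on the
corpus and harvesting each seed's nearest in-vocabulary neighbors above a
cosine threshold.  A candidate term similar to several emotions' seeds is
assigned to the emotion of maximal similarity, so the expanded lexicons are
pairwise disjoint by construction.

The SGNS trainer is a compact, single-threaded numpy implementation
(mini-batch SGD over (center, context) pairs with unigram^0.75 negative
sampling and a linearly decaying learning rate).  Runs are exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .plutchik import EMOTIONS

__all__ = [
    "EmbeddingModel",
    "EmotionLexicon",
    "train_embeddings",
    "expand_lexicons",
    "load_default_seed_terms",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


@dataclass
class EmbeddingModel:
    """A trained word-embedding space: one d-dimensional vector per term."""

    vocabulary: list[str]
    vectors: np.ndarray  # shape (V, d)
    training_params: dict

    def __post_init__(self) -> None:
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.vocabulary)}
        norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        self._unit = self.vectors / norms

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self.index[term]]

    def cosine(self, a: str, b: str) -> float:
        return float(self._unit[self.index[a]] @ self._unit[self.index[b]])

    def similarities(self, term: str) -> np.ndarray:
        """Cosine similarity of *term* to every vocabulary entry."""
        return self._unit @ self._unit[self.index[term]]

    def most_similar(self, term: str, k: int = 10,
                     exclude: Iterable[str] = ()) -> list[tuple[str, float]]:
        sims = self.similarities(term)
        skip = set(exclude) | {term}
        order = np.argsort(-sims, kind="stable")
        out = []
        for i in order:
            t = self.vocabulary[int(i)]
            if t in skip:
                continue
            out.append((t, float(sims[int(i)])))
            if len(out) == k:
                break
        return out

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for term, vec in zip(self.vocabulary, self.vectors):
                fh.write(term + "\t" + " ".join(f"{x:.6g}" for x in vec) + "\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "EmbeddingModel":
        vocab, rows = [], []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                term, vec = line.rstrip("\n").split("\t")
                vocab.append(term)
                rows.append(np.fromstring(vec, sep=" "))
        return cls(vocab, np.vstack(rows), {"loaded_from": str(path)})


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    d: int = 100,
    window: int = 5,
    min_count: int = 3,
    epochs: int = 10,
    seed: int = 0,
    negative: int = 5,
    lr0: float = 0.025,
    batch_size: int = 2048,
) -> EmbeddingModel:
    """Train SGNS word vectors on tokenized posts.

    Terms occurring fewer than ``min_count`` times are dropped from the
    vocabulary.  Context windows are symmetric with fixed width ``window``
    and do not cross post boundaries.  Deterministic under a fixed seed.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted((t for t, c in counts.items() if c >= min_count),
                   key=lambda t: (-counts[t], t))
    if not vocab:
        raise ValueError(f"no term reaches min_count={min_count}")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    # (center, context) pair list, fixed symmetric window.
    centers, contexts = [], []
    for sent in corpus:
        ids = [index[t] for t in sent if t in index]
        n = len(ids)
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers)
    if n_pairs == 0:
        raise ValueError("corpus yields no training pairs")

    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    noise = freq ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    total = n_pairs * epochs
    done = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            batch = order[start:start + batch_size]
            c, o = centers[batch], contexts[batch]
            B = len(c)
            neg = rng.choice(V, size=(B, negative), p=noise)

            lr = max(lr0 * (1.0 - done / total), lr0 * 1e-4)
            v = W_in[c]  # (B, d)
            u_pos = W_out[o]  # (B, d)
            u_neg = W_out[neg]  # (B, k, d)

            g_pos = (1.0 - _sigmoid(np.einsum("bd,bd->b", v, u_pos))) * lr
            g_neg = -_sigmoid(np.einsum("bd,bkd->bk", v, u_neg)) * lr

            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(W_out, o, g_pos[:, None] * v)
            np.add.at(W_out, neg.ravel(),
                      (g_neg[:, :, None] * v[:, None, :]).reshape(-1, d))
            np.add.at(W_in, c, grad_v)
            done += B

    params = {"d": d, "window": window, "min_count": min_count,
              "epochs": epochs, "seed": seed, "negative": negative, "lr0": lr0}
    return EmbeddingModel(vocab, W_in, params)


@dataclass
class EmotionLexicon:
    """Weighted term sets for the eight emotions.

    ``entries`` maps emotion → {term: (weight, provenance)} with seeds at
    weight 1.0 and expanded terms at their seed-cosine weight.  Terms are
    unique across emotions.
    """

    entries: dict[str, dict[str, tuple[float, str]]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for emo, terms in self.entries.items():
            for term in terms:
                if term in seen:
                    raise ValueError(
                        f"term {term!r} in both {seen[term]} and {emo}")
                seen[term] = emo

    def terms(self, emotion: str) -> set[str]:
        return set(self.entries.get(emotion, {}))

    def term_lookup(self) -> dict[str, tuple[str, float]]:
        """Flat map term → (emotion, weight) used by the post scorer."""
        out: dict[str, tuple[str, float]] = {}
        for emo, terms in self.entries.items():
            for term, (w, _prov) in terms.items():
                out[term] = (emo, w)
        return out

    def scaled(self, factor: float) -> "EmotionLexicon":
        return EmotionLexicon({
            emo: {t: (w * factor, prov) for t, (w, prov) in terms.items()}
            for emo, terms in self.entries.items()
        })

    def save_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for emo in EMOTIONS:
                for term in sorted(self.entries.get(emo, {})):
                    w, prov = self.entries[emo][term]
                    fh.write(f"{emo}\t{term}\t{w:.6f}\t{prov}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "EmotionLexicon":
        entries: dict[str, dict[str, tuple[float, str]]] = {e: {} for e in EMOTIONS}
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                emo, term, w, prov = line.rstrip("\n").split("\t")
                entries[emo][term] = (float(w), prov)
        return cls(entries)


def load_default_seed_terms() -> dict[str, list[str]]:
    """Packaged Plutchik seed terms (emotion → seed word list)."""
    seeds: dict[str, list[str]] = {e: [] for e in EMOTIONS}
    text = resources.files("emovista.data").joinpath("plutchik_seeds.tsv") \
        .read_text(encoding="utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        emo, term = line.split("\t")
        seeds[emo].append(term)
    return seeds


def expand_lexicons(
    model: EmbeddingModel,
    seeds: Mapping[str, Sequence[str]],
    k: int = 20,
    tau: float = 0.35,
) -> EmotionLexicon:
    """Grow seed lexicons by nearest-neighbor querying of the embedding.

    For every seed, its *k* nearest in-vocabulary neighbors with cosine
    ≥ *tau* become candidate terms weighted by that cosine; a candidate
    close to several emotions goes to the emotion of maximal similarity
    (ties broken by lexicographic emotion order).  Seeds always enter their
    own emotion with weight 1; a seed missing from the vocabulary is kept
    (with a warning) but contributes no neighbors.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    all_seed_terms = {t for terms in seeds.values() for t in terms}
    # candidate term → {emotion: best cosine across that emotion's seeds}
    candidate: dict[str, dict[str, float]] = {}
    for emo in sorted(seeds):
        if not seeds[emo]:
            raise ValueError(f"emotion {emo} has no seed terms")
        for seed_term in seeds[emo]:
            if seed_term not in model:
                warnings.warn(
                    f"seed term {seed_term!r} ({emo}) absent from embedding "
                    "vocabulary; kept with weight 1, no neighbors",
                    stacklevel=2,
                )
                continue
            for term, sim in model.most_similar(seed_term, k=k,
                                                exclude=all_seed_terms):
                if sim < tau:
                    break  # neighbors sorted descending
                best = candidate.setdefault(term, {})
                if sim > best.get(emo, -1.0):
                    best[emo] = sim

    entries: dict[str, dict[str, tuple[float, str]]] = {
        emo: {t: (1.0, "seed") for t in seeds[emo]} for emo in seeds
    }
    for term in sorted(candidate):
        sims = candidate[term]
        best_emo = max(sorted(sims), key=lambda e: sims[e])
        entries[best_emo][term] = (min(sims[best_emo], 1.0), "expanded")
    return EmotionLexicon(entries)
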