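"""Per-phase LDA topic models, keyphrase extraction and cross-phase topic
association.

Documents (tokenized posts or conversations) are modeled with latent
Dirichlet allocation; each document gets a hard dominant-topic assignment,
and only documents whose dominant-topic probability clears a prominence
margin above the uniform baseline 1/K are counted toward topic volumes
(general chatter without a prominent topic is omitted).  Volumes are
reported as percentage shares of the counted documents.

Keyphrases are scored RAKE-style (degree/frequency word scores summed over
candidate phrases).  Topics from different phases are associated by the
cosine similarity of their top-term embedding centroids, yielding a
cross-phase association graph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .lexicon import EmbeddingModel

__all__ = ["TopicModel", "TopicAssociationMap", "fit_topics", "select_k",
           "volume_shares", "extract_keyphrases", "associate_topics"]


def _doc_term_matrix(docs: Sequence[Sequence[str]]) -> tuple[sparse.csr_matrix, list[str]]:
    vocab: dict[str, int] = {}
    rows, cols, data = [], [], []
    for d, doc in enumerate(docs):
        seen: dict[int, int] = {}
        for tok in doc:
            idx = vocab.setdefault(tok, len(vocab))
            seen[idx] = seen.get(idx, 0) + 1
        for idx, c in seen.items():
            rows.append(d)
            cols.append(idx)
            data.append(c)
    X = sparse.csr_matrix((data, (rows, cols)),
                          shape=(len(docs), max(len(vocab), 1)))
    terms = [t for t, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
    return X, terms


def volume_shares(volumes: Mapping[str, int]) -> dict[str, float]:
    """Percentage share of each topic's document volume (sums to 100)."""
    total = sum(volumes.values())
    if total <= 0:
        raise ValueError("total volume must be positive")
    return {k: 100.0 * v / total for k, v in volumes.items()}


@dataclass
class TopicModel:
    phase: str
    K: int
    topic_terms: dict[int, list[tuple[str, float]]]  # ranked (term, weight)
    doc_topic: list[int]  # dominant topic per document
    prominent: list[bool]  # documents counted toward volumes
    volumes: dict[int, int]
    shares: dict[int, float]
    labels: dict[int, str]

    def label_of(self, topic: int) -> str:
        return self.labels[topic]


def fit_topics(
    docs: Sequence[Sequence[str]],
    K: int,
    seed: int = 0,
    alpha: float | None = None,
    beta: float | None = None,
    phase: str = "",
    top_terms: int = 10,
    prominence_margin: float = 0.05,
    label_map: Mapping[int, str] | None = None,
) -> TopicModel:
    """Fit a K-topic LDA model to tokenized documents.

    Dominant topic = argmax of the document-topic distribution; documents
    whose maximum falls below ``1/K + prominence_margin`` are excluded from
    volume counting.  Labels default to the top-3 terms joined by "/",
    overridable through *label_map*.  Deterministic under a fixed seed.
    """
    if not docs:
        raise ValueError("docs must be non-empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(docs):
        raise ValueError(f"K={K} exceeds number of documents ({len(docs)})")
    X, terms = _doc_term_matrix(docs)
    lda = LatentDirichletAllocation(
        n_components=K,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        random_state=seed,
        max_iter=30,
    )
    theta = lda.fit_transform(X)  # (n_docs, K), rows sum to 1
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)

    topic_terms = {
        k: [(terms[i], float(phi[k, i]))
            for i in np.argsort(-phi[k], kind="stable")[:top_terms]]
        for k in range(K)
    }
    dominant = theta.argmax(axis=1)
    # prominence threshold capped at 1 so K=1 (max prob is exactly 1) and
    # very large margins remain satisfiable
    threshold = min(1.0 / K + prominence_margin, 1.0)
    prominent = theta.max(axis=1) >= threshold - 1e-12
    volumes = {k: int(((dominant == k) & prominent).sum()) for k in range(K)}
    counted = sum(volumes.values())
    shares = (volume_shares(volumes) if counted > 0
              else {k: 0.0 for k in range(K)})
    labels = {k: "/".join(t for t, _ in topic_terms[k][:3]) for k in range(K)}
    if label_map:
        labels.update(label_map)
    return TopicModel(phase=phase, K=K, topic_terms=topic_terms,
                      doc_topic=[int(t) for t in dominant],
                      prominent=[bool(p) for p in prominent],
                      volumes=volumes, shares=shares, labels=labels)


def _umass_coherence(top_terms: list[str], doc_sets: list[set[str]]) -> float:
    score = 0.0
    for i in range(1, len(top_terms)):
        for j in range(i):
            d_j = sum(1 for s in doc_sets if top_terms[j] in s)
            d_ij = sum(1 for s in doc_sets
                       if top_terms[i] in s and top_terms[j] in s)
            if d_j > 0:
                score += math.log((d_ij + 1) / d_j)
    return score


def select_k(
    docs: Sequence[Sequence[str]],
    k_grid: Iterable[int] = (2, 3, 4, 5, 6, 8),
    seed: int = 0,
    top_terms: int = 8,
) -> int:
    """Pick K from a grid by maximal mean UMass topic coherence."""
    doc_sets = [set(d) for d in docs]
    best_k, best_score = None, -math.inf
    for K in k_grid:
        if K > len(docs):
            continue
        model = fit_topics(docs, K, seed=seed, top_terms=top_terms)
        score = float(np.mean([
            _umass_coherence([t for t, _ in model.topic_terms[k]], doc_sets)
            for k in range(K)
        ]))
        if score > best_score:
            best_k, best_score = K, score
    if best_k is None:
        raise ValueError("no feasible K in grid")
    return best_k


def extract_keyphrases(
    docs: Sequence[Sequence[str]],
    stop_words: Iterable[str],
) -> list[tuple[str, float]]:
    """RAKE-style keyphrase ranking.

    Candidate phrases are maximal runs of non-stop alphabetic tokens within
    a document.  Each word scores degree/frequency (degree counts, per
    phrase occurrence, the phrase length); a phrase scores the sum of its
    word scores.  Returns distinct phrases sorted by score descending, ties
    alphabetically.
    """
    stop = set(stop_words)
    phrases: list[tuple[str, ...]] = []
    for doc in docs:
        current: list[str] = []
        for tok in doc:
            if tok in stop or not tok.isalpha():
                if current:
                    phrases.append(tuple(current))
                    current = []
            else:
                current.append(tok)
        if current:
            phrases.append(tuple(current))
    if not phrases:
        return []

    freq: dict[str, int] = {}
    degree: dict[str, int] = {}
    for phrase in phrases:
        for w in phrase:
            freq[w] = freq.get(w, 0) + 1
            degree[w] = degree.get(w, 0) + len(phrase)
    word_score = {w: degree[w] / freq[w] for w in freq}

    seen: dict[tuple[str, ...], float] = {}
    for phrase in phrases:
        if phrase not in seen:
            seen[phrase] = sum(word_score[w] for w in phrase)
    ranked = sorted(seen.items(), key=lambda kv: (-kv[1], " ".join(kv[0])))
    return [(" ".join(p), s) for p, s in ranked]


@dataclass
class TopicAssociationMap:
    """Cross-phase topic graph: nodes are (phase, label), edges carry the
    centroid cosine similarity (only between distinct phases)."""

    nodes: list[tuple[str, str]]
    edges: list[tuple[tuple[str, str], tuple[str, str], float]]

    def connected_components(self) -> list[set[tuple[str, str]]]:
        adj: dict[tuple[str, str], set[tuple[str, str]]] = {
            n: set() for n in self.nodes}
        for a, b, _ in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        seen: set[tuple[str, str]] = set()
        comps = []
        for node in self.nodes:
            if node in seen:
                continue
            stack, comp = [node], set()
            while stack:
                cur = stack.pop()
                if cur in comp:
                    continue
                comp.add(cur)
                stack.extend(adj[cur] - comp)
            seen |= comp
            comps.append(comp)
        return comps


def _topic_centroid(
    terms: list[tuple[str, float]],
    embedding: EmbeddingModel,
    m: int,
) -> np.ndarray | None:
    vecs, weights = [], []
    for term, w in terms[:m]:
        if term in embedding:
            vecs.append(embedding.vector(term))
            weights.append(w)
    if not vecs:
        return None
    weights_arr = np.asarray(weights)
    return np.average(np.vstack(vecs), axis=0, weights=weights_arr)


def associate_topics(
    models: Sequence[TopicModel],
    embedding: EmbeddingModel,
    m: int = 10,
    threshold: float = 0.6,
) -> TopicAssociationMap:
    """Link semantically similar topics across phases.

    Topic similarity is the cosine of the weight-averaged embedding
    centroids of the two topics' top-*m* terms, clipped to [0, 1]; an edge
    is created when it reaches *threshold*.  Topics with no embeddable
    terms are excluded with a warning.
    """
    if len({mod.phase for mod in models}) < 2:
        raise ValueError("associate_topics needs models from >= 2 phases")
    nodes: list[tuple[str, str]] = []
    centroids: dict[tuple[str, str], np.ndarray] = {}
    for model in models:
        for k in range(model.K):
            node = (model.phase, model.label_of(k))
            centroid = _topic_centroid(model.topic_terms[k], embedding, m)
            if centroid is None:
                warnings.warn(f"topic {node} has no embeddable terms; excluded",
                              stacklevel=2)
                continue
            nodes.append(node)
            centroids[node] = centroid

    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if a[0] == b[0]:
                continue  # same phase
            va, vb = centroids[a], centroids[b]
            denom = np.linalg.norm(va) * np.linalg.norm(vb)
            sim = float(va @ vb / denom) if denom > 0 else 0.0
            sim = max(0.0, min(1.0, sim))
            if sim >= threshold:
                edges.append((a, b, sim))
    return TopicAssociationMap(nodes=nodes, edges=edges)
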