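"""LDA topic models, volume shares, RAKE keyphrases, topic association."""

from collections import Counter

import numpy as np
import pytest

from emovista.lexicon import EmbeddingModel
from emovista.topics import (TopicModel, associate_topics, extract_keyphrases,
                             fit_topics, select_k, volume_shares)


def _planted_docs(n=300, seed=7):
    rng = np.random.default_rng(seed)
    a = ["school", "students", "teachers", "exams", "classes"]
    b = ["border", "flights", "airport", "overseas", "luggage"]
    docs, labels = [], []
    for i in range(n):
        src = a if i % 2 == 0 else b
        docs.append([src[int(rng.integers(5))] for _ in range(12)])
        labels.append(i % 2)
    return docs, labels


class TestVolumeShares:
    def test_published_share_arithmetic(self):
        """A 6021-document topic out of 15302 is a 39.35% share."""
        shares = volume_shares({"global_concern": 6021,
                                "rest": 15302 - 6021})
        assert round(shares["global_concern"], 2) == 39.35

    def test_shares_sum_to_100(self):
        shares = volume_shares({"a": 3, "b": 5, "c": 11})
        assert sum(shares.values()) == pytest.approx(100.0)


class TestFitTopics:
    def test_single_topic_takes_all_volume(self):
        docs, _ = _planted_docs(40)
        tm = fit_topics(docs, K=1, seed=0)
        assert tm.shares[0] == pytest.approx(100.0)
        assert tm.volumes[0] == 40

    def test_planted_partition_recovered(self):
        docs, labels = _planted_docs(300)
        tm = fit_topics(docs, K=2, seed=0)
        purity = 0
        for k in (0, 1):
            members = [labels[i] for i in range(300) if tm.doc_topic[i] == k]
            if members:
                purity += max(Counter(members).values())
        assert purity / 300 >= 0.9

    def test_k_exceeding_documents_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fit_topics([["a", "b"]], K=2)

    def test_deterministic_under_seed(self):
        docs, _ = _planted_docs(100)
        t1 = fit_topics(docs, K=2, seed=3)
        t2 = fit_topics(docs, K=2, seed=3)
        assert t1.doc_topic == t2.doc_topic
        assert t1.topic_terms == t2.topic_terms

    def test_select_k_returns_grid_member(self):
        docs, _ = _planted_docs(80)
        assert select_k(docs, k_grid=(2, 3), seed=0) in (2, 3)


class TestKeyphrases:
    def test_degree_frequency_worked_example(self):
        phrases = extract_keyphrases(
            [["panic", "buying", "spreads"],
             ["panic", "buying", "continues"]],
            stop_words={"spreads", "continues"})
        assert phrases[0] == ("panic buying", pytest.approx(4.0))

    def test_single_word_scores_one(self):
        assert extract_keyphrases([["covid"]], set()) == [("covid", 1.0)]

    def test_all_stopwords_gives_empty(self):
        assert extract_keyphrases([["the", "and"]], {"the", "and"}) == []


def _const_embedding(term_vectors):
    terms = sorted(term_vectors)
    return EmbeddingModel(terms, np.vstack([term_vectors[t] for t in terms]),
                          {})


def _topic_model(phase, terms):
    return TopicModel(phase=phase, K=1,
                      topic_terms={0: [(t, 1.0) for t in terms]},
                      doc_topic=[0], prominent=[True], volumes={0: 1},
                      shares={0: 100.0}, labels={0: "/".join(terms[:3])})


class TestAssociateTopics:
    def test_identical_term_sets_link_with_similarity_one(self):
        emb = _const_embedding({"school": np.array([1.0, 0.0]),
                                "exams": np.array([0.9, 0.1])})
        models = [_topic_model("phase_a", ["school", "exams"]),
                  _topic_model("phase_b", ["school", "exams"])]
        amap = associate_topics(models, emb, threshold=0.99)
        assert len(amap.edges) == 1
        assert amap.edges[0][2] == pytest.approx(1.0)

    def test_orthogonal_topics_do_not_link(self):
        emb = _const_embedding({"school": np.array([1.0, 0.0]),
                                "border": np.array([0.0, 1.0])})
        models = [_topic_model("phase_a", ["school"]),
                  _topic_model("phase_b", ["border"])]
        amap = associate_topics(models, emb, threshold=0.5)
        assert amap.edges == []

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(0)
        emb = _const_embedding({t: rng.normal(size=4)
                                for t in "abcdefgh"})
        models = [_topic_model(f"phase_{i}", list("abcdefgh")[i:i + 3])
                  for i in range(4)]
        loose = associate_topics(models, emb, threshold=0.2)
        tight = associate_topics(models, emb, threshold=0.7)
        loose_pairs = {(a, b) for a, b, _ in loose.edges}
        tight_pairs = {(a, b) for a, b, _ in tight.edges}
        assert tight_pairs <= loose_pairs

    def test_shared_vocabulary_forms_cross_phase_component(self, vocab):
        """A topic vocabulary planted in all four phases links into one
        four-phase connected component."""
        rng = np.random.default_rng(1)
        emb = _const_embedding({
            t: rng.normal(size=6)
            for topic in ("lockdown_policy", "education")
            for t in vocab.topic_vocab[topic]})
        phases = ["prepandemic", "first_lockdown", "easing_restrictions",
                  "second_lockdown"]
        models = [
            _topic_model(ph, list(vocab.topic_vocab["lockdown_policy"])[:5])
            for ph in phases
        ]
        amap = associate_topics(models, emb, threshold=0.9)
        comps = amap.connected_components()
        assert any({p for p, _ in comp} == set(phases) for comp in comps)

    def test_requires_two_phases(self):
        emb = _const_embedding({"a": np.array([1.0, 0.0])})
        with pytest.raises(ValueError, match=">= 2"):
            associate_topics([_topic_model("only", ["a"])], emb)
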