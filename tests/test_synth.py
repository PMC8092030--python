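"""The synthetic tweet-stream generator and its ground-truth contracts."""

import io
from collections import Counter
from datetime import date, datetime, timezone

import numpy as np
import pytest

from emovista.corpus import post_to_record, write_posts_jsonl
from emovista.plutchik import EMOTIONS
from emovista.synth import (PhaseScenario, build_default_vocabulary,
                            default_scenarios, generate_corpus)


def _scenario(**overrides):
    base = dict(
        phase="prepandemic",
        window=(date(2020, 1, 1), date(2020, 2, 29)),
        emotion_mixture={e: 1 / 8 for e in EMOTIONS},
        topic_mixture={"education": 0.5, "travel": 0.5},
        n_posts=200,
    )
    base.update(overrides)
    return PhaseScenario(**base)


class TestVocabulary:
    def test_deterministic(self):
        assert build_default_vocabulary(1) == build_default_vocabulary(1)

    def test_exactly_eight_plutchik_emotions(self, vocab):
        assert set(vocab.seeds) == set(EMOTIONS)
        assert set(vocab.satellites) == set(EMOTIONS)

    def test_emotion_term_sets_pairwise_disjoint(self, vocab):
        all_terms = [t for e in EMOTIONS for t in vocab.emotion_terms(e)]
        assert len(all_terms) == len(set(all_terms))

    def test_inventory_sizes(self, vocab):
        for e in EMOTIONS:
            assert len(vocab.seeds[e]) >= 5
            assert len(vocab.satellites[e]) >= 10
        assert len(vocab.negators) >= 3
        assert len(vocab.intensifiers) >= 3
        assert len(vocab.inhibitors) >= 3
        assert len(vocab.topic_vocab) >= 4


class TestScenarioValidation:
    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            _scenario(emotion_mixture={e: 0.2 for e in EMOTIONS})

    def test_non_stochastic_transition_matrix_rejected(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            _scenario(transition_matrix=np.ones((8, 8)))

    def test_overlapping_windows_rejected(self, vocab):
        s1 = _scenario()
        s2 = _scenario(window=(date(2020, 2, 1), date(2020, 3, 15)),
                       phase="first_lockdown")
        with pytest.raises(ValueError, match="disjoint"):
            generate_corpus(vocab, [s1, s2], seed=0)


class TestGenerateCorpus:
    def test_deterministic_byte_identical(self, vocab):
        bufs = []
        for _ in range(2):
            posts, _ = generate_corpus(vocab, [_scenario()], seed=7)
            buf = io.StringIO()
            for p in posts:
                buf.write(str(post_to_record(p)) + "\n")
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_no_bots_when_fraction_zero(self, vocab):
        posts, truth = generate_corpus(vocab, [_scenario()],
                                       bot_fraction=0.0, seed=0)
        assert truth.bot_user_ids == set()
        # conservation: organic post count equals the configured n_posts
        assert len(posts) == 200

    def test_degenerate_mixture_all_sadness(self, vocab):
        mixture = {e: 0.0 for e in EMOTIONS}
        mixture["sadness"] = 1.0
        posts, truth = generate_corpus(
            vocab, [_scenario(emotion_mixture=mixture)], seed=0)
        labels = {truth.post_emotion[p.post_id] for p in posts}
        assert labels == {"sadness"}

    def test_timestamps_inside_scenario_window(self, vocab):
        posts, _ = generate_corpus(vocab, [_scenario()], seed=3)
        lo = datetime(2020, 1, 1, tzinfo=timezone.utc)
        hi = datetime(2020, 3, 1, tzinfo=timezone.utc)
        assert all(lo <= p.timestamp < hi for p in posts)

    def test_label_text_consistency(self, vocab):
        """Every post labeled e contains at least one term of lexicon(e)."""
        posts, truth = generate_corpus(vocab, [_scenario()], seed=5,
                                       negation_prob=0.3)
        for p in posts:
            emo = truth.post_emotion[p.post_id]
            terms = set(vocab.emotion_terms(emo))
            assert terms & set(p.raw_text.split())

    def test_emotion_term_share_of_content_tokens(self, vocab):
        """≥60% of non-filler tokens come from the post's emotion lexicon."""
        posts, truth = generate_corpus(vocab, [_scenario()], seed=5,
                                       negation_prob=0.0)
        filler = set(vocab.filler)
        for p in posts[:50]:
            emo_terms = set(vocab.emotion_terms(truth.post_emotion[p.post_id]))
            content = [t for t in p.raw_text.split() if t not in filler]
            share = sum(t in emo_terms for t in content) / len(content)
            assert share >= 0.6

    def test_mixture_recovery_at_scale(self, vocab):
        """Empirical label frequencies within ±2 pp of the configured mix."""
        scen = _scenario(n_posts=10_000,
                         emotion_mixture={"anger": 0.10, "sadness": 0.30,
                                          "joy": 0.15, "trust": 0.05,
                                          "anticipation": 0.05, "fear": 0.20,
                                          "disgust": 0.10, "surprise": 0.05})
        posts, truth = generate_corpus(vocab, [scen], seed=2)
        counts = Counter(truth.post_emotion[p.post_id] for p in posts)
        for e in EMOTIONS:
            assert abs(counts[e] / 10_000 - scen.emotion_mixture[e]) < 0.02

    def test_markov_labels_follow_transition_matrix(self, vocab):
        """With a near-deterministic chain, conversations almost always
        repeat the previous emotion."""
        P = np.full((8, 8), 0.02 / 7)
        np.fill_diagonal(P, 0.98)
        scen = _scenario(n_posts=2000, transition_matrix=P)
        posts, truth = generate_corpus(vocab, [scen], seed=4,
                                       mean_thread_len=5.0)
        by_conv = {}
        for p in posts:
            by_conv.setdefault(p.conversation_id, []).append(p)
        same = total = 0
        for thread in by_conv.values():
            thread.sort(key=lambda p: (p.timestamp, p.post_id))
            labels = [truth.post_emotion[p.post_id] for p in thread]
            same += sum(a == b for a, b in zip(labels, labels[1:]))
            total += len(labels) - 1
        assert total > 500
        assert same / total > 0.9

    def test_bots_exceed_twenty_times_median_volume_with_duplicates(self, vocab):
        posts, truth = generate_corpus(
            vocab, [_scenario(n_posts=400)], n_users=50, bot_fraction=0.1,
            seed=6)
        counts = Counter(p.user_id for p in posts)
        organic = [c for u, c in counts.items()
                   if u not in truth.bot_user_ids]
        median = np.median(organic)
        for bot in truth.bot_user_ids:
            assert counts[bot] >= 20 * median
            texts = {p.raw_text for p in posts if p.user_id == bot}
            assert len(texts) == 1  # duplicated text

    def test_conservation_across_scenarios(self, vocab):
        posts, _ = generate_corpus(vocab, default_scenarios(250),
                                   bot_fraction=0.0, seed=0)
        assert len(posts) == 4 * 250
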