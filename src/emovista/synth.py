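"""Synthetic tweet-stream generator with known ground truth.

Real pandemic-era social-media corpora cannot be redistributed, so every
downstream stage of the pipeline is exercised on generated data whose
generating process is fully known: per-phase Plutchik emotion mixtures,
planted lexicon neighborhoods (satellite terms that only ever co-occur with
their emotion's seed terms), optional within-conversation Markov emotion
chains, planted per-user topic preferences, and a minority of high-volume
bot accounts emitting duplicated text.

The generator emits tweet-scale posts (8–25 tokens) threaded into
conversations of geometric length, with timestamps uniform inside each
phase window, and returns a :class:`GroundTruth` object recording every
latent variable so recovery can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus import Post
from .plutchik import EMOTIONS

__all__ = [
    "VocabularySpec",
    "PhaseScenario",
    "GroundTruth",
    "build_default_vocabulary",
    "default_scenarios",
    "generate_corpus",
]


@dataclass(frozen=True)
class VocabularySpec:
    """Term inventory driving the generator.

    ``seeds`` and ``satellites`` map each of the eight emotions to disjoint
    term sets; satellites are the planted embedding neighbors that lexicon
    expansion must recover.  ``intensifiers``/``inhibitors`` map modifier
    terms to multiplicative factors (>1 and in (0,1) respectively), and
    ``negators`` flip an emotion to its Plutchik opposite.
    """

    seeds: Mapping[str, tuple[str, ...]]
    satellites: Mapping[str, tuple[str, ...]]
    intensifiers: Mapping[str, float]
    inhibitors: Mapping[str, float]
    negators: tuple[str, ...]
    topic_vocab: Mapping[str, tuple[str, ...]]
    filler: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.seeds) != set(EMOTIONS) or set(self.satellites) != set(EMOTIONS):
            raise ValueError("seeds and satellites must cover exactly the 8 emotions")
        seen: dict[str, str] = {}
        for emo in EMOTIONS:
            if not self.seeds[emo] or not self.satellites[emo]:
                raise ValueError(f"emotion {emo} needs at least one seed and satellite")
            for term in tuple(self.seeds[emo]) + tuple(self.satellites[emo]):
                if term in seen and seen[term] != emo:
                    raise ValueError(
                        f"term {term!r} assigned to both {seen[term]} and {emo}"
                    )
                seen[term] = emo
        for factor_map, kind in ((self.intensifiers, "intensifier"),
                                 (self.inhibitors, "inhibitor")):
            for term, m in factor_map.items():
                if not math.isfinite(m) or m <= 0:
                    raise ValueError(f"{kind} {term!r} has invalid factor {m}")

    def emotion_terms(self, emotion: str) -> tuple[str, ...]:
        return tuple(self.seeds[emotion]) + tuple(self.satellites[emotion])

    @property
    def term_emotion(self) -> dict[str, str]:
        """Planted term → emotion assignment (seeds and satellites)."""
        out: dict[str, str] = {}
        for emo in EMOTIONS:
            for term in self.emotion_terms(emo):
                out[term] = emo
        return out


_SEEDS = {
    "anger": ("angry", "furious", "rage", "outraged", "mad", "irate"),
    "sadness": ("sad", "grief", "sorrow", "unhappy", "depressed", "miserable"),
    "joy": ("happy", "joyful", "delighted", "cheerful", "glad", "elated"),
    "trust": ("trust", "confidence", "faith", "reliable", "secure", "assured"),
    "anticipation": ("anticipation", "expectation", "eager", "hopeful",
                     "awaiting", "optimistic"),
    "fear": ("fear", "scared", "afraid", "terrified", "panic", "anxious"),
    "disgust": ("disgust", "disgusted", "gross", "revolting", "sickening",
                "repulsed"),
    "surprise": ("surprised", "astonished", "amazed", "shocked", "startled",
                 "stunned"),
}

_SATELLITES = {
    "anger": ("fuming", "livid", "seething", "enraged", "infuriated",
              "resentful", "hostile", "irritated", "annoyed", "exasperated",
              "indignant", "wrathful"),
    "sadness": ("mourning", "heartbroken", "gloomy", "despair", "tearful",
                "downcast", "melancholy", "dismal", "sorrowful", "weeping",
                "hopeless", "dejected"),
    "joy": ("thrilled", "ecstatic", "jubilant", "gleeful", "merry", "upbeat",
            "blissful", "overjoyed", "radiant", "exuberant", "chipper",
            "beaming"),
    "trust": ("dependable", "trustworthy", "loyal", "honest", "credible",
              "steadfast", "faithful", "devoted", "sincere", "reassured",
              "supportive", "believing"),
    "anticipation": ("expectant", "anticipating", "foresee", "forecast",
                     "keen", "yearning", "longing", "impatient", "preparing",
                     "awaited", "prospect", "upcoming"),
    "fear": ("frightened", "fearful", "horrified", "alarmed", "worried",
             "nervous", "dread", "petrified", "uneasy", "apprehensive",
             "spooked", "timid"),
    "disgust": ("nauseating", "vile", "foul", "loathing", "repugnant",
                "distasteful", "yuck", "nasty", "abhorrent", "revulsion",
                "queasy", "repellent"),
    "surprise": ("astounded", "flabbergasted", "speechless", "unexpected",
                 "sudden", "bewildered", "dumbfounded", "baffled",
                 "staggered", "wow", "unbelievable", "incredulous"),
}

_TOPIC_VOCAB = {
    "lockdown_policy": ("lockdown", "restrictions", "curfew", "rules",
                        "government", "premier", "mandate", "compliance"),
    "panic_buying": ("supermarket", "toilet", "hoarding", "shelves",
                     "stockpile", "groceries", "shortage", "checkout"),
    "education": ("school", "students", "homeschool", "classes",
                  "university", "teachers", "exams", "learning"),
    "health_care": ("hospital", "nurses", "doctors", "ventilator",
                    "testing", "clinic", "vaccine", "wards"),
    "travel": ("border", "flights", "quarantine", "overseas", "airport",
               "interstate", "tourism", "luggage"),
    "work": ("jobkeeper", "unemployment", "wages", "office", "remote",
             "employer", "payroll", "workforce"),
}

_FILLER = ("today", "tomorrow", "people", "everyone", "something", "thing",
           "things", "way", "world", "news", "update", "post", "read",
           "look", "see", "said", "told", "keep", "stay", "home", "house",
           "street", "city", "state", "online", "live", "watch", "morning",
           "evening", "night")


def build_default_vocabulary(seed: int = 0) -> VocabularySpec:
    """Deterministic default vocabulary (identical for identical seeds).

    Six seed terms and twelve planted satellite terms per emotion, four
    negators, four intensifiers and four inhibitors, six topical term sets
    and a neutral filler pool.  The *seed* argument is accepted for
    interface symmetry with the corpus generator; the default inventory is
    fixed, so any seed yields the same spec.
    """
    del seed
    return VocabularySpec(
        seeds=dict(_SEEDS),
        satellites=dict(_SATELLITES),
        intensifiers={"very": 1.5, "extremely": 2.0, "so": 1.5, "totally": 1.8},
        inhibitors={"slightly": 0.5, "somewhat": 0.6, "barely": 0.4,
                    "hardly": 0.4},
        negators=("not", "no", "never"),
        topic_vocab=dict(_TOPIC_VOCAB),
        filler=_FILLER,
    )


@dataclass(frozen=True)
class PhaseScenario:
    """Generating conditions for one pandemic phase."""

    phase: str
    window: tuple[date, date]
    emotion_mixture: Mapping[str, float]
    topic_mixture: Mapping[str, float]
    n_posts: int
    transition_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        start, end = self.window
        if not (date(2020, 1, 1) <= start <= end <= date(2020, 9, 30)):
            raise ValueError(f"window {self.window} outside 2020-01-01..2020-09-30")
        mix = np.array([self.emotion_mixture.get(e, 0.0) for e in EMOTIONS])
        if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("emotion_mixture must be non-negative and sum to 1")
        tmix = np.array(list(self.topic_mixture.values()), dtype=float)
        if len(tmix) == 0 or tmix.min() < 0 or abs(tmix.sum() - 1.0) > 1e-9:
            raise ValueError("topic_mixture must be non-negative and sum to 1")
        if self.n_posts < 1:
            raise ValueError("n_posts must be positive")
        if self.transition_matrix is not None:
            P = np.asarray(self.transition_matrix, dtype=float)
            if P.shape != (8, 8) or P.min() < 0 or np.abs(P.sum(axis=1) - 1).max() > 1e-9:
                raise ValueError("transition_matrix must be 8x8 row-stochastic")
            object.__setattr__(self, "transition_matrix", P)

    @property
    def mixture_vector(self) -> np.ndarray:
        return np.array([self.emotion_mixture.get(e, 0.0) for e in EMOTIONS])


@dataclass
class GroundTruth:
    """Latent generating variables, the oracle for every recovery test."""

    emotion_mixtures: dict[str, dict[str, float]]
    transition_matrices: dict[str, list[list[float]] | None]
    term_emotion: dict[str, str]
    user_cluster: dict[str, str]
    bot_user_ids: set[str]
    post_emotion: dict[str, str]  # post_id -> emotion or "neutral"
    post_topic: dict[str, str]  # post_id -> topic name or "none"
    post_phase: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "emotion_mixtures": self.emotion_mixtures,
            "transition_matrices": self.transition_matrices,
            "term_emotion": self.term_emotion,
            "user_cluster": self.user_cluster,
            "bot_user_ids": sorted(self.bot_user_ids),
            "post_emotion": self.post_emotion,
            "post_topic": self.post_topic,
            "post_phase": self.post_phase,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            emotion_mixtures=d["emotion_mixtures"],
            transition_matrices=d["transition_matrices"],
            term_emotion=d["term_emotion"],
            user_cluster=d["user_cluster"],
            bot_user_ids=set(d["bot_user_ids"]),
            post_emotion=d["post_emotion"],
            post_topic=d["post_topic"],
            post_phase=d["post_phase"],
        )


def _sticky_transition_matrix(mixture: np.ndarray, stickiness: float = 0.3) -> np.ndarray:
    """Row-stochastic matrix whose rows blend the phase mixture with
    self-persistence, so chains revisit the configured mixture while
    showing the self-transitions conversations exhibit."""
    P = np.tile(mixture, (8, 1)) * (1.0 - stickiness) + stickiness * np.eye(8)
    return P / P.sum(axis=1, keepdims=True)


#: Per-phase generating emotion mixtures.  The two lockdown phases use the
#: normalized intensity percentages reported for the comparable real-world
#: study phases; the pre-pandemic and easing phases follow the narrative
#: pattern (sadness/fear dominant early, joy peaking during easing).
DEFAULT_PHASE_MIXTURES: dict[str, dict[str, float]] = {
    "prepandemic": {"anger": 0.10, "sadness": 0.34, "joy": 0.08, "trust": 0.05,
                    "anticipation": 0.04, "fear": 0.28, "disgust": 0.08,
                    "surprise": 0.03},
    "first_lockdown": {"anger": 0.1384, "sadness": 0.3136, "joy": 0.1694,
                       "trust": 0.0656, "anticipation": 0.0259, "fear": 0.1758,
                       "disgust": 0.0981, "surprise": 0.0132},
    "easing_restrictions": {"anger": 0.09, "sadness": 0.22, "joy": 0.27,
                            "trust": 0.10, "anticipation": 0.09, "fear": 0.13,
                            "disgust": 0.06, "surprise": 0.04},
    "second_lockdown": {"anger": 0.1597, "sadness": 0.3101, "joy": 0.1256,
                        "trust": 0.0563, "anticipation": 0.0237, "fear": 0.1966,
                        "disgust": 0.1206, "surprise": 0.0074},
}

_DEFAULT_WINDOWS = {
    "prepandemic": (date(2020, 1, 1), date(2020, 2, 29)),
    "first_lockdown": (date(2020, 3, 1), date(2020, 5, 31)),
    "easing_restrictions": (date(2020, 6, 1), date(2020, 6, 30)),
    "second_lockdown": (date(2020, 7, 1), date(2020, 9, 30)),
}

_DEFAULT_TOPIC_MIXTURES = {
    "prepandemic": {"lockdown_policy": 0.30, "travel": 0.30, "health_care": 0.25,
                    "education": 0.15},
    "first_lockdown": {"work": 0.25, "education": 0.25, "lockdown_policy": 0.20,
                       "travel": 0.10, "panic_buying": 0.10, "health_care": 0.10},
    "easing_restrictions": {"lockdown_policy": 0.30, "travel": 0.30,
                            "work": 0.20, "health_care": 0.20},
    "second_lockdown": {"lockdown_policy": 0.25, "health_care": 0.25,
                        "work": 0.20, "travel": 0.10, "education": 0.20},
}


def default_scenarios(
    n_posts_per_phase: int | Mapping[str, int] = 2500,
    with_transitions: bool = True,
) -> list[PhaseScenario]:
    """The four bundled phase scenarios (study-condition defaults)."""
    scenarios = []
    for phase, window in _DEFAULT_WINDOWS.items():
        n = (n_posts_per_phase if isinstance(n_posts_per_phase, int)
             else n_posts_per_phase[phase])
        mixture = DEFAULT_PHASE_MIXTURES[phase]
        vec = np.array([mixture[e] for e in EMOTIONS])
        scenarios.append(
            PhaseScenario(
                phase=phase,
                window=window,
                emotion_mixture=mixture,
                topic_mixture=_DEFAULT_TOPIC_MIXTURES[phase],
                n_posts=n,
                transition_matrix=(_sticky_transition_matrix(vec)
                                   if with_transitions else None),
            )
        )
    return scenarios


def _compose_text(
    rng: np.random.Generator,
    vocab: VocabularySpec,
    emotion: str,
    topic: str,
    negation_prob: float,
    post_len: tuple[int, int],
) -> list[str]:
    # Token budget: ~30% neutral filler; of the rest, ≥65% emotion terms
    # (guaranteeing the ≥60% contract) incl. at least one seed, remainder
    # topical terms.
    L = int(rng.integers(post_len[0], post_len[1] + 1))
    n_filler = max(1, int(round(0.3 * L)))
    n_content = L - n_filler
    n_emo = max(1, int(math.ceil(0.65 * n_content)))
    n_topic = n_content - n_emo

    emo_terms = vocab.emotion_terms(emotion)
    seeds = vocab.seeds[emotion]
    tokens = [seeds[int(rng.integers(len(seeds)))]]
    for _ in range(n_emo - 1):
        tokens.append(emo_terms[int(rng.integers(len(emo_terms)))])
    topic_terms = vocab.topic_vocab[topic]
    for _ in range(n_topic):
        tokens.append(topic_terms[int(rng.integers(len(topic_terms)))])
    for _ in range(n_filler):
        tokens.append(vocab.filler[int(rng.integers(len(vocab.filler)))])
    order = rng.permutation(len(tokens))
    tokens = [tokens[i] for i in order]

    if rng.random() < negation_prob:
        emo_set = set(emo_terms)
        positions = [i for i, t in enumerate(tokens) if t in emo_set]
        pos = positions[int(rng.integers(len(positions)))]
        neg = vocab.negators[int(rng.integers(len(vocab.negators)))]
        tokens.insert(pos, neg)
    return tokens


def _thread_lengths(rng: np.random.Generator, n_posts: int, mean_len: float) -> list[int]:
    lengths: list[int] = []
    total = 0
    p = 1.0 / mean_len
    while total < n_posts:
        k = int(rng.geometric(p))
        k = min(k, n_posts - total)
        lengths.append(k)
        total += k
    return lengths


def generate_corpus(
    vocab: VocabularySpec,
    scenarios: Sequence[PhaseScenario],
    n_users: int = 400,
    bot_fraction: float = 0.0,
    seed: int = 0,
    negation_prob: float = 0.1,
    mean_thread_len: float = 4.0,
    post_len: tuple[int, int] = (8, 25),
    topic_loyalty: float = 0.8,
) -> tuple[list[Post], GroundTruth]:
    """Generate a threaded post corpus plus its generating ground truth.

    Each scenario contributes exactly ``n_posts`` organic posts; bot
    accounts (a ``bot_fraction`` share of users) then add duplicated-text
    posts at ≥20× the realized median organic per-user volume, which is
    what the volume filter downstream is meant to catch.  Users carry a
    planted topic preference (their cluster id) followed with probability
    ``topic_loyalty``.

    Deterministic: identical arguments yield a byte-identical corpus.
    """
    if not 0.0 <= bot_fraction < 1.0:
        raise ValueError("bot_fraction must lie in [0, 1)")
    windows = sorted(s.window for s in scenarios)
    for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
        if s2 <= e1:
            raise ValueError("scenario windows must be disjoint")

    rng = np.random.default_rng(seed)
    n_bots = int(round(bot_fraction * n_users))
    if n_users - n_bots < 2:
        raise ValueError("need at least two organic users")
    user_ids = [f"user{idx:05d}" for idx in range(n_users)]
    perm = rng.permutation(n_users)
    bot_ids = {user_ids[i] for i in perm[:n_bots]}
    organic = [user_ids[i] for i in perm[n_bots:]]

    topics = sorted({t for s in scenarios for t in s.topic_mixture})
    user_cluster = {u: topics[int(rng.integers(len(topics)))] for u in organic}

    posts: list[Post] = []
    post_emotion: dict[str, str] = {}
    post_topic: dict[str, str] = {}
    post_phase: dict[str, str] = {}
    pid = 0
    cid = 0

    for scenario in scenarios:
        mix = scenario.mixture_vector
        topic_names = list(scenario.topic_mixture)
        topic_probs = np.array([scenario.topic_mixture[t] for t in topic_names])
        start, end = scenario.window
        window_days = (end - start).days + 1

        for length in _thread_lengths(rng, scenario.n_posts, mean_thread_len):
            cid += 1
            conv_id = f"c{cid:06d}"
            n_participants = min(int(rng.integers(1, 4)), len(organic))
            participants = [organic[int(i)] for i in
                            rng.choice(len(organic), size=n_participants,
                                       replace=False)]
            day = int(rng.integers(window_days))
            t0 = datetime(start.year, start.month, start.day, tzinfo=timezone.utc) \
                + timedelta(days=day, seconds=int(rng.integers(0, 20 * 3600)))
            emotion_idx = int(rng.choice(8, p=mix))
            for j in range(length):
                if j > 0 and scenario.transition_matrix is not None:
                    emotion_idx = int(rng.choice(8, p=scenario.transition_matrix[emotion_idx]))
                elif j > 0:
                    emotion_idx = int(rng.choice(8, p=mix))
                emotion = EMOTIONS[emotion_idx]
                user = participants[j % len(participants)]
                if rng.random() < topic_loyalty and user_cluster[user] in topic_names:
                    topic = user_cluster[user]
                else:
                    topic = topic_names[int(rng.choice(len(topic_names), p=topic_probs))]
                tokens = _compose_text(rng, vocab, emotion, topic,
                                       negation_prob, post_len)
                pid += 1
                post_id = f"p{pid:08d}"
                ts = t0 + timedelta(seconds=j * int(rng.integers(60, 600)))
                end_of_window = datetime(end.year, end.month, end.day, 23, 59, 59,
                                         tzinfo=timezone.utc)
                ts = min(ts, end_of_window)
                posts.append(Post(post_id=post_id, user_id=user,
                                  conversation_id=conv_id, timestamp=ts,
                                  raw_text=" ".join(tokens)))
                post_emotion[post_id] = emotion
                post_topic[post_id] = topic
                post_phase[post_id] = scenario.phase

    if n_bots:
        counts: dict[str, int] = {}
        for post in posts:
            counts[post.user_id] = counts.get(post.user_id, 0) + 1
        median = float(np.median(list(counts.values()))) if counts else 1.0
        volume = max(1, int(math.ceil(20.0 * median)))
        all_topics = sorted(vocab.topic_vocab)
        scenario_cycle = list(scenarios)
        for b, bot in enumerate(sorted(bot_ids)):
            topic = all_topics[b % len(all_topics)]
            terms = vocab.topic_vocab[topic]
            text = " ".join(list(terms[:6]) + ["update", "news"])
            scenario = scenario_cycle[b % len(scenario_cycle)]
            start, end = scenario.window
            window_days = (end - start).days + 1
            for _ in range(volume):
                pid += 1
                cid += 1
                post_id = f"p{pid:08d}"
                ts = datetime(start.year, start.month, start.day,
                              tzinfo=timezone.utc) + timedelta(
                    days=int(rng.integers(window_days)),
                    seconds=int(rng.integers(0, 86400)))
                posts.append(Post(post_id=post_id, user_id=bot,
                                  conversation_id=f"c{cid:06d}",
                                  timestamp=ts, raw_text=text))
                post_emotion[post_id] = "neutral"
                post_topic[post_id] = topic
                post_phase[post_id] = scenario.phase

    truth = GroundTruth(
        emotion_mixtures={s.phase: {e: float(s.emotion_mixture.get(e, 0.0))
                                    for e in EMOTIONS} for s in scenarios},
        transition_matrices={
            s.phase: (s.transition_matrix.tolist()
                      if s.transition_matrix is not None else None)
            for s in scenarios
        },
        term_emotion=vocab.term_emotion,
        user_cluster=user_cluster,
        bot_user_ids=bot_ids,
        post_emotion=post_emotion,
        post_topic=post_topic,
        post_phase=post_phase,
    )
    return posts, truth
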