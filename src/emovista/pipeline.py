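"""End-to-end pipeline orchestration from a single configuration.

``run_pipeline`` executes simulate → preprocess → lexicon → emotions →
intensity → transitions → topics → gsom → stats in order, writing every
stage's artifact into an output directory plus a run manifest (parameter
values, record counts, SHA-256 hashes of all outputs).  Identical
configurations produce byte-identical numeric outputs; every random
operation draws from a named seed in the configuration.

A stage failure raises :class:`StageError` naming the stage; artifacts of
completed stages are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import read_posts_jsonl, write_posts_jsonl
from .emotions import (DEFAULT_MODIFIERS, DEFAULT_NEGATORS, build_sequences,
                       score_corpus)
from .gsom import GSOMConfig, build_user_features, derive_profiles, train_gsom
from .intensity import intensity_table, phase_intensity_profile
from .lexicon import expand_lexicons, train_embeddings
from .plutchik import EMOTIONS
from .preprocess import DEFAULT_PHASE_WINDOWS, preprocess_corpus
from .stats import compare_intensity_profiles, comparison_table
from .synth import build_default_vocabulary, default_scenarios, generate_corpus
from .topics import associate_topics, fit_topics, select_k
from .transitions import (estimate_transition_model, top_transitions,
                          transition_dot)

logger = logging.getLogger("emovista.pipeline")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    input_corpus: str | None = None  # JSONL path; mutually exclusive with simulate
    simulate: dict = field(default_factory=dict)  # n_posts_per_phase, n_users, ...
    bot_percentile: float = 0.99
    dup_threshold: int = 1
    salt: str = "emovista"
    embedding: dict = field(default_factory=dict)  # d, window, min_count, epochs
    tau: float = 0.35
    k_neighbors: int = 20
    negation_window: int = 3
    negation_mode: str = "flip"
    topics_k: int | str = "auto"
    topics_k_grid: tuple[int, ...] = (2, 3, 4, 5, 6)
    association_threshold: float = 0.6
    association_top_terms: int = 10
    gsom: dict = field(default_factory=dict)
    gsom_phases: tuple[str, ...] = ("first_lockdown", "second_lockdown")
    min_hits: int = 3
    compare_phases: tuple[str, str] = ("first_lockdown", "second_lockdown")
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.input_corpus is None and not self.simulate:
            raise ConfigError("config needs either 'input_corpus' or a "
                              "'simulate' block")
        if self.input_corpus is not None and self.simulate:
            raise ConfigError("'input_corpus' and 'simulate' are mutually "
                              "exclusive")
        if not 0.0 < self.bot_percentile <= 1.0:
            raise ConfigError("bot_percentile must lie in (0, 1]")
        if self.topics_k != "auto" and (not isinstance(self.topics_k, int)
                                        or self.topics_k < 1):
            raise ConfigError("topics_k must be 'auto' or a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("topics_k_grid", "gsom_phases", "compare_phases"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run the full pipeline, returning a summary dict (also written as
    ``manifest.json`` in *out_dir*)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "emovista_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }
    stage = "simulate"
    try:
        vocab = build_default_vocabulary(config.seed)
        if config.simulate:
            sim = dict(config.simulate)
            n_per_phase = sim.pop("n_posts_per_phase", 1500)
            posts, truth = generate_corpus(
                vocab,
                default_scenarios(n_per_phase),
                n_users=sim.pop("n_users", 300),
                bot_fraction=sim.pop("bot_fraction", 0.02),
                seed=sim.pop("seed", config.seed),
                **sim,
            )
            write_posts_jsonl(posts, out / "corpus.jsonl")
            truth.to_json(out / "ground_truth.json")
            manifest["stages"][stage] = {"n_posts": len(posts),
                                         "n_bots": len(truth.bot_user_ids)}
        else:
            posts = read_posts_jsonl(config.input_corpus)
            manifest["stages"][stage] = {"n_posts": len(posts),
                                         "source": config.input_corpus}
        logger.info("simulate/load: %d posts", len(posts))

        stage = "preprocess"
        clean, removed = preprocess_corpus(
            posts, DEFAULT_PHASE_WINDOWS,
            volume_percentile=config.bot_percentile,
            dup_threshold=config.dup_threshold, salt=config.salt)
        manifest["stages"][stage] = {
            "posts_kept": len(clean),
            "posts_removed": len(posts) - len(clean),
            "users_removed_by_volume_filter": len(removed),
        }
        logger.info("preprocess: kept %d posts, removed %d high-volume users",
                    len(clean), len(removed))

        stage = "lexicon"
        emb_params = dict(config.embedding)
        emb_params.setdefault("seed", config.seed)
        model = train_embeddings([p.clean_tokens for p in clean], **emb_params)
        lex = expand_lexicons(model, vocab.seeds, k=config.k_neighbors,
                              tau=config.tau)
        model.save_tsv(out / "embeddings.tsv")
        lex.save_tsv(out / "lexicon.tsv")
        n_expanded = sum(
            1 for terms in lex.entries.values()
            for _t, (_w, prov) in terms.items() if prov == "expanded")
        manifest["stages"][stage] = {"vocabulary": len(model.vocabulary),
                                     "expanded_terms": n_expanded}
        logger.info("lexicon: %d vocabulary terms, %d expanded",
                    len(model.vocabulary), n_expanded)

        stage = "emotions"
        lookup = lex.term_lookup()
        pes = score_corpus(clean, lookup, DEFAULT_NEGATORS, DEFAULT_MODIFIERS,
                           window=config.negation_window,
                           negation_mode=config.negation_mode)
        emo_rows = [
            {"post_id": p.post_id, "phase": p.phase,
             **{e: pes[p.post_id].scores[e] for e in EMOTIONS},
             "dominant": pes[p.post_id].dominant or "none"}
            for p in clean
        ]
        _write_csv(pd.DataFrame(emo_rows), out / "emotions.csv")
        sequences = build_sequences(clean, pes)
        with (out / "sequences.jsonl").open("w", encoding="utf-8") as fh:
            for seq in sequences:
                fh.write(json.dumps({"conversation_id": seq.conversation_id,
                                     "phase": seq.phase,
                                     "labels": seq.labels}) + "\n")
        manifest["stages"][stage] = {"n_scored": len(pes),
                                     "n_sequences": len(sequences)}

        phases = [w.name for w in DEFAULT_PHASE_WINDOWS
                  if any(p.phase == w.name for p in clean)]

        stage = "intensity"
        profiles = {}
        for phase in phases:
            phase_pes = [pes[p.post_id] for p in clean if p.phase == phase]
            profiles[phase] = phase_intensity_profile(phase_pes, phase)
        _write_csv(intensity_table([profiles[p] for p in phases]),
                   out / "intensity.csv")
        manifest["stages"][stage] = {
            p: {"n_observations": profiles[p].n_observations} for p in phases}

        stage = "transitions"
        top_rows = []
        for phase in phases:
            phase_seqs = [s for s in sequences if s.phase == phase]
            tmodel = estimate_transition_model(phase_seqs, phase)
            tmodel.counts_frame().to_csv(out / f"transitions_{phase}_counts.csv",
                                         lineterminator="\n")
            tmodel.probs_frame().to_csv(out / f"transitions_{phase}_probs.csv",
                                        float_format="%.10g",
                                        lineterminator="\n")
            (out / f"transitions_{phase}.dot").write_text(
                transition_dot(tmodel), encoding="utf-8")
            for src, dst, prob in top_transitions(tmodel, k=5):
                top_rows.append({"phase": phase, "from": src, "to": dst,
                                 "probability": prob})
        _write_csv(pd.DataFrame(top_rows), out / "top_transitions.csv")
        manifest["stages"][stage] = {"phases": phases}

        stage = "topics"
        topic_models = {}
        topic_rows = []
        for phase in phases:
            docs = [p.clean_tokens for p in clean if p.phase == phase]
            K = (select_k(docs, config.topics_k_grid, seed=config.seed)
                 if config.topics_k == "auto" else int(config.topics_k))
            tm = fit_topics(docs, K, seed=config.seed, phase=phase)
            topic_models[phase] = tm
            for k in range(tm.K):
                topic_rows.append({
                    "phase": phase, "topic": k, "label": tm.label_of(k),
                    "volume": tm.volumes[k],
                    "share_pct": round(tm.shares[k], 2)})
        _write_csv(pd.DataFrame(topic_rows), out / "topics.csv")
        assoc = associate_topics(list(topic_models.values()), model,
                                 m=config.association_top_terms,
                                 threshold=config.association_threshold)
        edge_rows = [{"phase_a": a[0], "topic_a": a[1], "phase_b": b[0],
                      "topic_b": b[1], "similarity": round(sim, 6)}
                     for a, b, sim in assoc.edges]
        _write_csv(pd.DataFrame(edge_rows,
                                columns=["phase_a", "topic_a", "phase_b",
                                         "topic_b", "similarity"]),
                   out / "topic_associations.csv")
        manifest["stages"][stage] = {p: {"K": topic_models[p].K}
                                     for p in phases}

        stage = "gsom"
        gsom_cfg = GSOMConfig(**{"seed": config.seed, **config.gsom})
        profile_rows = []
        n_profiles = {}
        for phase in config.gsom_phases:
            if phase not in phases:
                continue
            phase_posts = [p for p in clean if p.phase == phase]
            tm = topic_models[phase]
            doc_ids = [p.post_id for p in phase_posts]
            users, X, names = build_user_features(
                [p.user_id for p in phase_posts],
                [tm.label_of(tm.doc_topic[i]) for i in range(len(phase_posts))],
                [pes[pid].scores for pid in doc_ids],
                topic_names=[tm.label_of(k) for k in range(tm.K)],
                emotion_names=list(EMOTIONS))
            gmap = train_gsom(X, gsom_cfg)
            gmap.to_json(out / f"gsom_{phase}.json")
            clusters = derive_profiles(gmap, X, min_hits=config.min_hits,
                                       feature_names=names)
            n_profiles[phase] = len(clusters)
            for c in clusters:
                for dim, name in enumerate(names):
                    profile_rows.append({
                        "phase": phase, "profile_id": c.profile_id,
                        "label": c.label, "n_users": len(c.member_ids),
                        "feature": name,
                        "mean_strength": round(float(c.mean_vector[dim]), 6)})
        _write_csv(pd.DataFrame(profile_rows), out / "profiles.csv")
        manifest["stages"][stage] = {"n_profiles": n_profiles}

        stage = "stats"
        a, b = config.compare_phases
        if a in profiles and b in profiles:
            results = compare_intensity_profiles(profiles[a], profiles[b],
                                                 alpha=config.alpha)
            _write_csv(comparison_table(results), out / "comparison.csv")
            manifest["stages"][stage] = {
                "compared": [a, b],
                "significant": [r.emotion for r in results if r.significant]}
        else:
            manifest["stages"][stage] = {"compared": None}
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
        raise StageError(stage, exc) from exc

    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest
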