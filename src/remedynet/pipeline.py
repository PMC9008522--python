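"""End-to-end pipeline orchestration with plain-file stage handoff.

Stages communicate through TSV/JSONL artifacts in one output directory,
so each stage is independently runnable, testable and replaceable — a
third-party NER model can substitute for the gazetteer by writing the
same mention JSONL.  Every stage is deterministic given the config seed
and idempotent: rerunning with unchanged inputs reproduces byte-
identical artifacts.

Stage order: generate -> summarize -> extract -> evaluate -> normalize
-> network -> rank -> stats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from . import conet, corpus, entities, normalize, rank, stats, synthetic
from .errors import DependencyError, InvalidParameterError

logger = logging.getLogger("remedynet")

STAGES = (
    "generate",
    "summarize",
    "extract",
    "evaluate",
    "normalize",
    "network",
    "rank",
    "stats",
)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, round-trippable through YAML."""

    outdir: str = "remedynet_out"
    seed: int = 0

    # synthetic corpus
    n_substances: int = 12
    n_effects: int = 8
    variants_per_entity: int = 3
    n_comments: int = 4000
    deleted_fraction: float = 0.055
    n_strong_pairs: int = 10
    strength: float = 5.0
    comention_rate: float = 0.3

    # evaluation
    holdout_fraction: float = 0.2

    # embeddings / clustering
    embedding_d: int = 50
    embedding_window: int = 5
    embedding_min_freq: int = 5
    cluster_tau: float = 0.3

    # network / ranking
    min_count: int = 5
    top_k: int = 10
    excluded_categories: Tuple[str, ...] = ("opioid",)
    ego_min_ppmi: float = 1.5
    ego_min_count: int = 10
    symptom_list_path: Optional[str] = None  # default: planted symptoms file

    # rounding precision for stats output
    reduction_precision: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.deleted_fraction < 1):
            raise InvalidParameterError("deleted_fraction must be in [0, 1)")
        if not (0 < self.holdout_fraction < 1):
            raise InvalidParameterError("holdout_fraction must be in (0, 1)")
        if self.cluster_tau <= 0:
            raise InvalidParameterError("cluster_tau must be > 0")
        if min(self.n_substances, self.n_effects, self.variants_per_entity,
               self.n_comments) < 1:
            raise InvalidParameterError("corpus size parameters must be >= 1")

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def to_yaml(self, path: str) -> None:
        rec = dataclasses.asdict(self)
        rec["excluded_categories"] = list(self.excluded_categories)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(rec, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            rec = yaml.safe_load(fh) or {}
        if "excluded_categories" in rec:
            rec["excluded_categories"] = tuple(rec["excluded_categories"])
        return cls(**rec)


def _require(config: PipelineConfig, filename: str, producer: str) -> str:
    path = config.path(filename)
    if not os.path.exists(path):
        raise DependencyError(
            f"missing artifact {filename!r}; run stage {producer!r} first"
        )
    return path


def _write_json(path: str, obj: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_generate(config: PipelineConfig) -> None:
    lexicon = synthetic.build_lexicon(
        config.n_substances,
        config.n_effects,
        config.variants_per_entity,
        seed=config.seed,
    )
    model = synthetic.plant_associations(
        lexicon,
        n_strong_pairs=config.n_strong_pairs,
        strength=config.strength,
        seed=config.seed + 1,
        rate=config.comention_rate,
    )
    comments, gold = synthetic.generate_corpus(
        lexicon,
        model,
        n_comments=config.n_comments,
        deleted_fraction=config.deleted_fraction,
        seed=config.seed + 2,
    )
    corpus.write_comments(comments, config.path("corpus.jsonl"))
    entities.write_mentions_jsonl(gold.mentions, config.path("gold_mentions.jsonl"))
    lexicon.to_tsv(config.path("lexicon.tsv"))
    model.to_json(config.path("model.json"))
    symptoms = sorted({e for _, e in model.planted})
    with open(config.path("symptoms.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(symptoms) + "\n")
    logger.info(
        "generate: %d comments, %d gold mentions, %d planted pairs, seed=%d",
        len(comments), len(gold.mentions), len(model.planted), config.seed,
    )


def _stage_summarize(config: PipelineConfig) -> None:
    path = _require(config, "corpus.jsonl", "generate")
    table = corpus.corpus_summary(corpus.read_comments(path))
    table.to_csv(config.path("summary.tsv"), sep="\t", index=False)
    logger.info("summarize: %d subreddit rows", max(len(table) - 1, 0))


def _segmented_nondeleted(config: PipelineConfig):
    path = _require(config, "corpus.jsonl", "generate")
    stream, counts = corpus.filter_nondeleted(corpus.read_comments(path))
    for c in stream:
        yield c, corpus.segment_sentences(c)


def _stage_extract(config: PipelineConfig) -> None:
    lex_path = _require(config, "lexicon.tsv", "generate")
    lexicon = synthetic.SyntheticLexicon.from_tsv(lex_path)
    matcher = entities.compile_gazetteer(lexicon.surface_to_label)
    n_sentences = 0
    n_mentions = 0
    with open(config.path("mentions.jsonl"), "w", encoding="utf-8") as fh:
        for comment, sentences in _segmented_nondeleted(config):
            for sent in sentences:
                n_sentences += 1
                for m in entities.extract_mentions(sent, matcher):
                    fh.write(
                        json.dumps(
                            {
                                "comment_id": m.comment_id,
                                "sentence_index": m.sentence_index,
                                "start": m.start,
                                "end": m.end,
                                "surface": m.surface,
                                "label": m.label,
                            },
                            sort_keys=True,
                        )
                        + "\n"
                    )
                    n_mentions += 1
    _write_json(
        config.path("extract_meta.json"),
        {"n_sentences": n_sentences, "n_mentions": n_mentions},
    )
    logger.info("extract: %d mentions over %d sentences", n_mentions, n_sentences)


def _stage_evaluate(config: PipelineConfig) -> None:
    gold_path = _require(config, "gold_mentions.jsonl", "generate")
    pred_path = _require(config, "mentions.jsonl", "extract")
    gold = entities.read_mentions_jsonl(gold_path)
    pred = entities.read_mentions_jsonl(pred_path)
    comment_ids = sorted({m.comment_id for m in gold} | {m.comment_id for m in pred})
    _, test_ids = entities.split_holdout(
        comment_ids, config.holdout_fraction, seed=config.seed + 3
    )
    test_set = set(test_ids)
    scores = entities.evaluate_exact(
        [m for m in gold if m.comment_id in test_set],
        [m for m in pred if m.comment_id in test_set],
    )
    rec = {"n_test_comments": len(test_set)}
    for label, s in scores.per_label.items():
        rec[label.lower()] = {
            "tp": s.tp, "fp": s.fp, "fn": s.fn,
            "precision": s.precision, "recall": s.recall, "f1": s.f1,
        }
    o = scores.overall
    rec["overall"] = {
        "tp": o.tp, "fp": o.fp, "fn": o.fn,
        "precision": o.precision, "recall": o.recall, "f1": o.f1,
    }
    _write_json(config.path("eval.json"), rec)
    logger.info("evaluate: overall F1=%.3f on %d held-out comments",
                o.f1, len(test_set))


def _stage_normalize(config: PipelineConfig) -> None:
    _require(config, "mentions.jsonl", "extract")
    mentions = entities.read_mentions_jsonl(config.path("mentions.jsonl"))
    sentences = [
        s for _, sents in _segmented_nondeleted(config) for s in sents
    ]
    tokens = normalize.merge_entity_tokens(sentences, mentions)
    table = normalize.train_embeddings(
        tokens,
        d=config.embedding_d,
        window=config.embedding_window,
        min_freq=config.embedding_min_freq,
        seed=config.seed + 4,
    )
    surfaces: Dict[str, str] = {}
    freqs: Dict[str, int] = {}
    for m in mentions:
        tok = normalize.entity_token(m.surface)
        surfaces[tok] = m.label
        freqs[tok] = freqs.get(tok, 0) + 1
    clusters = normalize.cluster_entities(table, surfaces, tau=config.cluster_tau)
    cmap = normalize.canonicalize(clusters, freqs)
    cmap.validate()
    normalized = normalize.apply_map(mentions, cmap)
    entities.write_mentions_jsonl(normalized, config.path("normalized_mentions.jsonl"))
    cmap.to_tsv(config.path("canonical_map.tsv"))
    by_label_before: Dict[str, set] = {}
    by_label_after: Dict[str, set] = {}
    for tok, label in surfaces.items():
        by_label_before.setdefault(label, set()).add(tok)
        by_label_after.setdefault(label, set()).add(cmap.mapping[tok])
    _write_json(
        config.path("dedup_counts.json"),
        {
            "substances_before": len(by_label_before.get(entities.SUBSTANCE, ())),
            "substances_after": len(by_label_after.get(entities.SUBSTANCE, ())),
            "effects_before": len(by_label_before.get(entities.EFFECT, ())),
            "effects_after": len(by_label_after.get(entities.EFFECT, ())),
        },
    )
    logger.info(
        "normalize: %d surfaces -> %d canonicals", cmap.n_surfaces, cmap.n_canonicals
    )


def _stage_network(config: PipelineConfig) -> None:
    _require(config, "normalized_mentions.jsonl", "normalize")
    meta_path = _require(config, "extract_meta.json", "extract")
    lex_path = _require(config, "lexicon.tsv", "generate")
    with open(meta_path, "r", encoding="utf-8") as fh:
        N = json.load(fh)["n_sentences"]
    mentions = entities.read_mentions_jsonl(config.path("normalized_mentions.jsonl"))
    by_sentence: Dict[tuple, list] = {}
    for m in mentions:
        by_sentence.setdefault((m.comment_id, m.sentence_index), []).append(m)
    # node categories: canonical surface -> category of its lexicon entity
    # (stands in for the expert-review categorization step)
    lexicon = synthetic.SyntheticLexicon.from_tsv(lex_path)
    cat_by_canonical = {e.canonical: e.category for e in lexicon.entries}
    surf2canon = {
        normalize.entity_token(s): c
        for s, c in lexicon.surface_to_canonical.items()
    }
    categories = {
        name: cat_by_canonical.get(surf2canon.get(name, name), "")
        for ms in by_sentence.values()
        for name in (m.surface for m in ms)
    }
    net = conet.build_network(
        (by_sentence[k] for k in sorted(by_sentence)), N=N, categories=categories
    )
    conet.compute_ppmi(net)
    conet.export_network(net, config.path("network"))
    logger.info(
        "network: %d nodes, %d edges, N=%d", len(net.nodes), len(net.edges), net.N
    )


def _stage_rank(config: PipelineConfig) -> None:
    _require(config, "network.edges.tsv", "network")
    net = conet.import_network(config.path("network"))
    rank.edge_scores(net)
    conet.export_network(net, config.path("network"))  # persist scores
    symptom_path = config.symptom_list_path or _require(
        config, "symptoms.txt", "generate"
    )
    with open(symptom_path, "r", encoding="utf-8") as fh:
        symptoms = [
            normalize.entity_token(line.strip())
            for line in fh
            if line.strip() and not line.startswith("#")
        ]
    symptoms = [s for s in symptoms if s in net.nodes]
    table = rank.build_pair_table(
        net,
        symptoms,
        k=config.top_k,
        excluded_categories=config.excluded_categories,
        min_count=config.min_count,
    )
    table.to_csv(config.path("pair_table.tsv"), sep="\t", index=False)
    logger.info("rank: %d pairs over %d symptoms", len(table), len(symptoms))


def _stage_stats(config: PipelineConfig) -> None:
    dedup_path = _require(config, "dedup_counts.json", "normalize")
    with open(dedup_path, "r", encoding="utf-8") as fh:
        d = json.load(fh)
    p = config.reduction_precision
    rec = {
        "substance_reduction_pct": stats.percent_reduction(
            d["substances_before"], d["substances_after"], p
        )
        if d["substances_before"]
        else 0.0,
        "effect_reduction_pct": stats.percent_reduction(
            d["effects_before"], d["effects_after"], p
        )
        if d["effects_before"]
        else 0.0,
        **d,
    }
    _write_json(config.path("stats.json"), rec)
    logger.info(
        "stats: substances %s%% reduction, effects %s%% reduction",
        rec["substance_reduction_pct"], rec["effect_reduction_pct"],
    )


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "summarize": _stage_summarize,
    "extract": _stage_extract,
    "evaluate": _stage_evaluate,
    "normalize": _stage_normalize,
    "network": _stage_network,
    "rank": _stage_rank,
    "stats": _stage_stats,
}


def run_stage(stage: str, config: PipelineConfig) -> None:
    """Run one named stage; artifacts land in ``config.outdir``.

    Raises :class:`DependencyError` naming the stage to run first when
    an upstream artifact is missing.
    """
    if stage not in _STAGE_FUNCS:
        raise InvalidParameterError(
            f"unknown stage {stage!r}; choose from {', '.join(STAGES)}"
        )
    os.makedirs(config.outdir, exist_ok=True)
    _STAGE_FUNCS[stage](config)


def run_all(config: PipelineConfig) -> None:
    """Run the full chain in order."""
    for stage in STAGES:
        run_stage(stage, config)
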