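"""Synthetic comment corpora with known substance-effect structure.

The pipeline was designed for social-media comment streams that cannot
be redistributed, so every stage is exercised against corpora generated
here with a fully known ground truth:

* a lexicon of pseudo-word canonical entities with misspelling/slang
  style surface-form variants (edit-distance-1/2 perturbations and
  truncations), emulating the duplicate problem the deduplication stage
  solves;
* a planted joint distribution over (substance, effect) pairs — the
  analytic ground truth against which empirical PPMI is checked;
* a comment stream in the pushshift JSONL dialect, including a stated
  fraction of ``[deleted]``/``[removed]`` bodies, with gold character-
  offset annotations for every planted mention.

Sentence model.  Each sentence draws at most one *event*, mutually
exclusively: a (substance, effect) pair from the joint (probability
``rate``), a lone substance (probability ``sqrt(rate) - rate``), a lone
effect (same), or nothing.  The lone-mention rates are calibrated so the
sentence-level occurrence probabilities are p(s, e) = rate * joint(s, e)
and p(s) = sqrt(rate) * marginal(s): the sentence-level PMI then equals
the model's analytic PMI *exactly*, not just asymptotically.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .corpus import Comment
from .entities import EFFECT, SUBSTANCE, Mention
from .errors import InvalidParameterError, SchemaError, UndefinedPMIError

# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

_SYLLABLES = [
    "ka", "tro", "mi", "zol", "fen", "dex", "lor", "pam", "vex", "tan",
    "bu", "nor", "pra", "quil", "sed", "rix", "mal", "dro", "cet", "lin",
    "gab", "tin", "mor", "phal", "ster", "ox", "col", "dan", "zu", "rem",
]

# Substance categories cycle through a plausible pharmacology mix; the
# first slot is "opioid" so category-based exclusion is always exercised.
_SUBSTANCE_CATEGORIES = [
    "opioid", "supplement", "antidiarrheal", "antihistamine",
    "anticonvulsant", "otc analgesic", "other",
]

# Shared filler vocabulary (Zipf-weighted) for realistic token statistics.
FILLER_VOCAB = (
    "the and you that was for with this have not but they just like get "
    "when out all really then them some what time day week going good bad "
    "feel felt feeling been take took taking try tried trying help helps "
    "helped need needed want wanted much more less only still never always "
    "every about after before over under again first last next now today "
    "night morning thing things people doctor friend story post thread "
    "advice experience body mind long short hard easy slow fast little big "
    "sure maybe probably definitely honestly literally actually basically "
    "pretty very super way ways work works worked worse better best worst "
    "start started stop stopped keep kept stay stayed home life years "
    "months days hours weeks while since because though although anyone "
    "someone everyone nothing something everything"
).split()


@dataclass(frozen=True)
class LexiconEntry:
    canonical: str
    label: str
    category: str
    variants: Tuple[str, ...]
    base_freq: float

    @property
    def surfaces(self) -> Tuple[str, ...]:
        return (self.canonical,) + self.variants


@dataclass(frozen=True)
class SyntheticLexicon:
    """Entity lexicon: canonicals, their variants, categories, weights."""

    entries: Tuple[LexiconEntry, ...]

    def __post_init__(self) -> None:
        seen: Dict[str, str] = {}
        for e in self.entries:
            if e.label not in (SUBSTANCE, EFFECT):
                raise SchemaError(f"label must be SUBSTANCE or EFFECT, got {e.label!r}")
            if not e.surfaces:
                raise SchemaError(f"entry {e.canonical!r} has no surface forms")
            for s in e.surfaces:
                if s in seen:
                    raise SchemaError(f"surface {s!r} duplicated in lexicon")
                seen[s] = e.canonical

    def entries_for(self, label: str) -> List[LexiconEntry]:
        return [e for e in self.entries if e.label == label]

    @property
    def substances(self) -> List[LexiconEntry]:
        return self.entries_for(SUBSTANCE)

    @property
    def effects(self) -> List[LexiconEntry]:
        return self.entries_for(EFFECT)

    @property
    def surface_to_canonical(self) -> Dict[str, str]:
        return {s: e.canonical for e in self.entries for s in e.surfaces}

    @property
    def surface_to_label(self) -> Dict[str, str]:
        return {s: e.label for e in self.entries for s in e.surfaces}

    def category_of(self, canonical: str) -> Optional[str]:
        for e in self.entries:
            if e.canonical == canonical:
                return e.category
        return None

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["surface", "label", "canonical", "category", "is_canonical"])
            for e in self.entries:
                for s in e.surfaces:
                    w.writerow(
                        [s, e.label, e.canonical, e.category, int(s == e.canonical)]
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "SyntheticLexicon":
        groups: Dict[str, dict] = {}
        with open(path, "r", encoding="utf-8", newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if header[:3] != ["surface", "label", "canonical"]:
                raise SchemaError(f"unexpected lexicon header: {header}")
            for row in r:
                surface, label, canonical, category = row[0], row[1], row[2], row[3]
                g = groups.setdefault(
                    canonical, {"label": label, "category": category, "variants": []}
                )
                if surface != canonical:
                    g["variants"].append(surface)
        entries = tuple(
            LexiconEntry(
                canonical=c,
                label=g["label"],
                category=g["category"],
                variants=tuple(g["variants"]),
                base_freq=1.0,
            )
            for c, g in groups.items()
        )
        return cls(entries=entries)


def _pseudo_word(rng: np.random.Generator, taken: set) -> str:
    for _ in range(1000):
        k = int(rng.integers(2, 5))
        idx = rng.integers(0, len(_SYLLABLES), size=k)
        word = "".join(_SYLLABLES[i] for i in idx)
        if word not in taken and word not in _FILLER_SET:
            return word
    raise RuntimeError("could not generate a unique pseudo-word")


_FILLER_SET = frozenset(FILLER_VOCAB)


def _perturb(rng: np.random.Generator, word: str) -> str:
    """One edit-distance-1/2 perturbation or truncation of ``word``."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    ops = ["sub", "del", "ins", "swap", "trunc", "double"]
    op = ops[int(rng.integers(0, len(ops)))]
    chars = list(word)
    if op == "trunc" and len(word) >= 5:
        return word[: len(word) - int(rng.integers(1, 3))]
    if op == "del" and len(word) >= 4:
        i = int(rng.integers(0, len(chars)))
        del chars[i]
        return "".join(chars)
    if op == "swap" and len(word) >= 4:
        i = int(rng.integers(0, len(chars) - 1))
        chars[i], chars[i + 1] = chars[i + 1], chars[i]
        return "".join(chars)
    if op == "double":
        i = int(rng.integers(0, len(chars)))
        chars.insert(i, chars[i])
        return "".join(chars)
    if op == "ins":
        i = int(rng.integers(0, len(chars) + 1))
        chars.insert(i, letters[int(rng.integers(0, 26))])
        return "".join(chars)
    i = int(rng.integers(0, len(chars)))
    chars[i] = letters[int(rng.integers(0, 26))]
    return "".join(chars)


def build_lexicon(
    n_substances: int,
    n_effects: int,
    variants_per_entity: int,
    seed: int,
) -> SyntheticLexicon:
    """Generate a lexicon of unique pseudo-word entities with variants.

    Variants are edit-distance-1/2 perturbations or truncations of the
    canonical; collisions with any other surface form are resolved by
    re-sampling, so all surface forms are globally unique.  Base
    frequencies follow a Zipf profile within each label.
    """
    for name, v in (
        ("n_substances", n_substances),
        ("n_effects", n_effects),
        ("variants_per_entity", variants_per_entity),
    ):
        if v < 1:
            raise InvalidParameterError(f"{name} must be >= 1, got {v}")
    rng = np.random.default_rng(seed)
    taken: set = set()
    entries = []
    for label, count in ((SUBSTANCE, n_substances), (EFFECT, n_effects)):
        for rank in range(count):
            canonical = _pseudo_word(rng, taken)
            taken.add(canonical)
            variants = []
            while len(variants) < variants_per_entity:
                for _ in range(200):
                    v = _perturb(rng, canonical)
                    if v not in taken and v not in _FILLER_SET and len(v) >= 3:
                        break
                else:  # pragma: no cover - essentially unreachable
                    v = canonical + str(len(variants))
                taken.add(v)
                variants.append(v)
            if label == SUBSTANCE:
                category = _SUBSTANCE_CATEGORIES[rank % len(_SUBSTANCE_CATEGORIES)]
            else:
                category = "symptom"
            entries.append(
                LexiconEntry(
                    canonical=canonical,
                    label=label,
                    category=category,
                    variants=tuple(variants),
                    base_freq=1.0 / (rank + 1.0),
                )
            )
    return SyntheticLexicon(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Association model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationModel:
    """Planted joint distribution over (substance, effect) canonicals.

    ``joint[i, j]`` is the probability that a sentence-level pair event
    involves substance i and effect j; the table sums to 1.  ``rate`` is
    the per-sentence probability of a pair event (the background
    co-mention rate).  Marginals are the row/column sums.
    """

    substances: Tuple[str, ...]
    effects: Tuple[str, ...]
    joint: np.ndarray
    rate: float = 0.3
    planted: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        j = np.asarray(self.joint, dtype=float)
        if j.shape != (len(self.substances), len(self.effects)):
            raise InvalidParameterError("joint shape does not match name lists")
        if (j < 0).any():
            raise InvalidParameterError("joint probabilities must be >= 0")
        if abs(j.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(f"joint must sum to 1, got {j.sum()!r}")
        if not (0 < self.rate <= 1):
            raise InvalidParameterError(f"rate must be in (0, 1], got {self.rate}")
        object.__setattr__(self, "joint", j)

    @classmethod
    def from_joint(
        cls,
        substances: Sequence[str],
        effects: Sequence[str],
        joint: np.ndarray,
        rate: float = 0.3,
        planted: Sequence[Tuple[str, str]] = (),
    ) -> "AssociationModel":
        return cls(
            substances=tuple(substances),
            effects=tuple(effects),
            joint=np.asarray(joint, dtype=float),
            rate=rate,
            planted=tuple(planted),
        )

    @property
    def p_substance(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def p_effect(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "substances": list(self.substances),
                    "effects": list(self.effects),
                    "joint": [[repr(v) for v in row] for row in self.joint.tolist()],
                    "rate": repr(self.rate),
                    "planted": [list(p) for p in self.planted],
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "AssociationModel":
        with open(path, "r", encoding="utf-8") as fh:
            rec = json.load(fh)
        joint = np.array([[float(v) for v in row] for row in rec["joint"]])
        return cls.from_joint(
            rec["substances"],
            rec["effects"],
            joint,
            rate=float(rec["rate"]),
            planted=[tuple(p) for p in rec["planted"]],
        )


def plant_associations(
    lexicon: SyntheticLexicon,
    n_strong_pairs: int,
    strength: float,
    seed: int,
    rate: float = 0.3,
) -> AssociationModel:
    """Plant over-represented (substance, effect) pairs into a joint.

    Starts from the independence joint implied by the lexicon's base
    frequencies, multiplies ``n_strong_pairs`` distinct cells by
    ``strength`` and renormalizes.  With ``strength > 1`` every planted
    pair has analytic PMI > 0; ``strength == 1`` leaves the joint equal
    to the product of its marginals (all PMI zero).
    """
    if strength <= 0:
        raise InvalidParameterError(f"strength must be > 0, got {strength}")
    if n_strong_pairs < 0:
        raise InvalidParameterError("n_strong_pairs must be >= 0")
    subs = [e.canonical for e in lexicon.substances]
    effs = [e.canonical for e in lexicon.effects]
    if n_strong_pairs > len(subs) * len(effs):
        raise InvalidParameterError(
            f"n_strong_pairs={n_strong_pairs} exceeds "
            f"{len(subs)}x{len(effs)} possible pairs"
        )
    ps = np.array([e.base_freq for e in lexicon.substances], dtype=float)
    pe = np.array([e.base_freq for e in lexicon.effects], dtype=float)
    ps /= ps.sum()
    pe /= pe.sum()
    joint = np.outer(ps, pe)
    rng = np.random.default_rng(seed)
    flat = rng.choice(joint.size, size=n_strong_pairs, replace=False)
    planted = []
    for f in sorted(int(x) for x in flat):
        i, j = divmod(f, len(effs))
        joint[i, j] *= strength
        planted.append((subs[i], effs[j]))
    joint /= joint.sum()
    return AssociationModel.from_joint(subs, effs, joint, rate=rate, planted=planted)


def true_pmi(model: AssociationModel, substance: str, effect: str) -> float:
    """Analytic PMI, log base 2: log2(p(s,e) / (p(s) p(e))).

    May be negative; clipping at zero is the network module's concern.
    """
    try:
        i = model.substances.index(substance)
    except ValueError:
        raise LookupError(f"unknown substance {substance!r}") from None
    try:
        j = model.effects.index(effect)
    except ValueError:
        raise LookupError(f"unknown effect {effect!r}") from None
    p_s = model.p_substance[i]
    p_e = model.p_effect[j]
    if p_s == 0 or p_e == 0:
        raise UndefinedPMIError(
            f"marginal probability is zero for ({substance!r}, {effect!r})"
        )
    p_se = model.joint[i, j]
    if p_se == 0:
        return float("-inf")
    return math.log2(p_se / (p_s * p_e))


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


@dataclass
class GoldAnnotations:
    """Gold mentions plus the true surface→canonical mapping."""

    mentions: List[Mention] = field(default_factory=list)
    true_canonical: Dict[str, str] = field(default_factory=dict)

    def by_sentence(self) -> Dict[Tuple[str, int], List[Mention]]:
        out: Dict[Tuple[str, int], List[Mention]] = {}
        for m in self.mentions:
            out.setdefault((m.comment_id, m.sentence_index), []).append(m)
        return out


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_corpus(
    lexicon: SyntheticLexicon,
    model: AssociationModel,
    n_comments: int,
    deleted_fraction: float,
    seed: int,
    sentences_per_comment: Tuple[int, int] = (1, 4),
    canonical_share: float = 0.55,
    filler_range: Tuple[int, int] = (3, 8),
    ctx_tokens_per_entity: int = 3,
    subreddits: Tuple[str, str] = ("synthopiates", "synthrecovery"),
) -> Tuple[List[Comment], GoldAnnotations]:
    """Generate a pushshift-dialect comment stream with gold annotations.

    Each non-deleted comment holds 1-4 sentences.  Every entity owns a
    small set of dedicated context tokens that accompany its mentions —
    variants share their canonical's contexts, which is the signal the
    embedding-based deduplication stage learns from.  Entity mentions
    use the canonical surface with probability ``canonical_share`` and a
    uniformly chosen variant otherwise.  Approximately
    ``deleted_fraction`` of bodies are replaced by ``[deleted]`` or
    ``[removed]`` (half each) and carry no annotations.
    """
    if n_comments < 1:
        raise InvalidParameterError(f"n_comments must be >= 1, got {n_comments}")
    if not (0 <= deleted_fraction < 1):
        raise InvalidParameterError(
            f"deleted_fraction must be in [0, 1), got {deleted_fraction}"
        )
    rng = np.random.default_rng(seed)

    subs = [e for e in lexicon.substances]
    effs = [e for e in lexicon.effects]
    sub_names = [e.canonical for e in subs]
    eff_names = [e.canonical for e in effs]
    if tuple(sub_names) != model.substances or tuple(eff_names) != model.effects:
        raise InvalidParameterError("model canonicals do not match the lexicon")

    # per-entity context tokens, disjoint from every surface and filler
    ctx: Dict[str, List[str]] = {}
    for k, e in enumerate(subs + effs):
        ctx[e.canonical] = [
            f"ctx{k}{chr(ord('a') + t)}" for t in range(ctx_tokens_per_entity)
        ]

    rate = model.rate
    lone = math.sqrt(rate) - rate  # calibrated: sentence PMI == analytic PMI
    p_events = np.array([1.0 - rate - 2 * lone, rate, lone, lone])

    n_sent_per_comment = rng.integers(
        sentences_per_comment[0], sentences_per_comment[1] + 1, size=n_comments
    )
    deleted = rng.random(n_comments) < deleted_fraction

    # pre-draw event structure for all sentences of non-deleted comments
    total_sents = int(n_sent_per_comment[~deleted].sum())
    event_kind = rng.choice(4, size=total_sents, p=p_events)
    n_pair = int((event_kind == 1).sum())
    n_lone_s = int((event_kind == 2).sum())
    n_lone_e = int((event_kind == 3).sum())
    pair_flat = rng.choice(
        model.joint.size, size=n_pair, p=model.joint.ravel()
    )
    lone_s_idx = rng.choice(len(subs), size=n_lone_s, p=model.p_substance)
    lone_e_idx = rng.choice(len(effs), size=n_lone_e, p=model.p_effect)

    filler_probs = _zipf_probs(len(FILLER_VOCAB))
    n_fillers = rng.integers(
        filler_range[0], filler_range[1] + 1, size=total_sents
    )
    filler_pool = rng.choice(
        len(FILLER_VOCAB), size=int(n_fillers.sum()), p=filler_probs
    )

    comments: List[Comment] = []
    gold = GoldAnnotations(true_canonical=dict(lexicon.surface_to_canonical))
    sent_cursor = 0
    pair_cursor = lone_s_cursor = lone_e_cursor = 0
    filler_cursor = 0
    deleted_counter = 0
    base_utc = 1262304000  # 2010-01-01
    n_effs = len(effs)

    def pick_surface(entry: LexiconEntry) -> str:
        if not entry.variants or rng.random() < canonical_share:
            return entry.canonical
        return entry.variants[int(rng.integers(0, len(entry.variants)))]

    for ci in range(n_comments):
        cid = f"c{ci:08d}"
        created = base_utc + ci * 120
        subreddit = subreddits[0] if rng.random() < 0.7 else subreddits[1]
        parent = f"t3_p{ci // 12}" if rng.random() < 0.3 else f"t1_c{max(ci - 1, 0):08d}"
        if deleted[ci]:
            body = "[deleted]" if deleted_counter % 2 == 0 else "[removed]"
            deleted_counter += 1
            comments.append(
                Comment(
                    id=cid,
                    subreddit=subreddit,
                    created_utc=created,
                    body=body,
                    parent_id=parent,
                    author="[deleted]",
                )
            )
            continue
        sent_texts = []
        for si in range(int(n_sent_per_comment[ci])):
            kind = int(event_kind[sent_cursor])
            mention_entries: List[LexiconEntry] = []
            if kind == 1:
                f = int(pair_flat[pair_cursor])
                pair_cursor += 1
                mention_entries = [subs[f // n_effs], effs[f % n_effs]]
            elif kind == 2:
                mention_entries = [subs[int(lone_s_idx[lone_s_cursor])]]
                lone_s_cursor += 1
            elif kind == 3:
                mention_entries = [effs[int(lone_e_idx[lone_e_cursor])]]
                lone_e_cursor += 1

            nf = int(n_fillers[sent_cursor])
            tokens: List[Tuple[str, Optional[LexiconEntry]]] = [
                (FILLER_VOCAB[int(filler_pool[filler_cursor + t])], None)
                for t in range(nf)
            ]
            filler_cursor += nf
            for entry in mention_entries:
                ctoks = ctx[entry.canonical]
                n_ctx = 1 + int(rng.integers(0, 2))
                for t in rng.permutation(len(ctoks))[:n_ctx]:
                    tokens.append((ctoks[int(t)], None))
                tokens.append((pick_surface(entry), entry))
            order = rng.permutation(len(tokens))
            tokens = [tokens[int(i)] for i in order]

            # assemble sentence text + gold offsets
            parts = []
            offset = 0
            for tok, entry in tokens:
                if parts:
                    offset += 1  # separating space
                if entry is not None:
                    gold.mentions.append(
                        Mention(
                            comment_id=cid,
                            sentence_index=si,
                            start=offset,
                            end=offset + len(tok),
                            surface=tok,
                            label=entry.label,
                        )
                    )
                parts.append(tok)
                offset += len(tok)
            sent_texts.append(" ".join(parts) + ".")
            sent_cursor += 1
        comments.append(
            Comment(
                id=cid,
                subreddit=subreddit,
                created_utc=created,
                body=" ".join(sent_texts),
                parent_id=parent,
                author=f"user{int(rng.integers(0, max(2, n_comments // 3)))}",
            )
        )
    return comments, gold
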