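"""Entity mention extraction and exact-match evaluation.

Two entity types are recognised: SUBSTANCE (a drug, remedy, supplement
or other consumable) and EFFECT (a symptom or other consequence of using
or stopping a substance).  Extraction is behind a small interface so a
statistical NER model can replace the reference gazetteer by producing
the same mention JSONL; evaluation is exact-match — a prediction counts
only when sentence, boundaries and label all agree with a gold mention.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from math import floor
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .corpus import Sentence
from .errors import ConflictError, InvalidParameterError, ParseError, SchemaError

SUBSTANCE = "SUBSTANCE"
EFFECT = "EFFECT"
LABELS = (SUBSTANCE, EFFECT)


@dataclass(frozen=True, order=True)
class Mention:
    """A labeled character span within one sentence.

    Offsets are 0-based half-open into the *sentence* text, so
    ``sentence.text[start:end] == surface``.
    """

    comment_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise SchemaError(f"unknown label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise SchemaError(f"bad span [{self.start}, {self.end})")

    def key(self) -> Tuple[str, int, int, int, str]:
        """Identity used by exact-match evaluation."""
        return (self.comment_id, self.sentence_index, self.start, self.end, self.label)


def write_mentions_jsonl(mentions: Iterable[Mention], path: str) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
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
            )
            fh.write("\n")
            n += 1
    return n


def read_mentions_jsonl(path: str) -> List[Mention]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"malformed JSON on line {lineno}: {exc}") from exc
            try:
                out.append(
                    Mention(
                        comment_id=str(rec["comment_id"]),
                        sentence_index=int(rec["sentence_index"]),
                        start=int(rec["start"]),
                        end=int(rec["end"]),
                        surface=str(rec["surface"]),
                        label=str(rec["label"]),
                    )
                )
            except KeyError as exc:
                raise SchemaError(f"line {lineno} lacks field {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Gazetteer matcher
# ---------------------------------------------------------------------------

# A token boundary for matching purposes: alphanumerics end at anything
# that is not a letter or digit, so "kratom," matches but "kratoms" does
# not match the surface "kratom".
_BOUND_L = r"(?<![A-Za-z0-9])"
_BOUND_R = r"(?![A-Za-z0-9])"


class GazetteerMatcher:
    """Case-insensitive, word-boundary-anchored dictionary matcher.

    Matching is left-to-right, longest-match, non-overlapping: at each
    position the longest registered surface wins and scanning resumes at
    its end.
    """

    def __init__(self, surface_labels: Mapping[str, str]):
        self._labels: Dict[str, str] = {}
        for surface, label in surface_labels.items():
            key = surface.lower()
            if label not in LABELS:
                raise SchemaError(f"unknown label {label!r} for {surface!r}")
            if key in self._labels and self._labels[key] != label:
                raise ConflictError(
                    f"surface {surface!r} registered as both "
                    f"{self._labels[key]} and {label}"
                )
            self._labels[key] = label
        if not self._labels:
            raise InvalidParameterError("gazetteer needs at least one surface form")
        # longest alternative first => regex alternation is longest-match
        alts = sorted(self._labels, key=lambda s: (-len(s), s))
        pattern = _BOUND_L + "(?:" + "|".join(re.escape(s) for s in alts) + ")" + _BOUND_R
        self._re = re.compile(pattern, re.IGNORECASE)

    def label_of(self, surface: str) -> str:
        return self._labels[surface.lower()]

    def finditer(self, text: str):
        return self._re.finditer(text)

    def __len__(self) -> int:
        return len(self._labels)


def compile_gazetteer(
    surface_labels: Union[Mapping[str, str], Iterable[Tuple[str, str]]]
) -> GazetteerMatcher:
    """Compile surface→label pairs into a matcher.

    The same surface (case-insensitively) listed twice with conflicting
    labels raises :class:`ConflictError`.
    """
    if not isinstance(surface_labels, Mapping):
        collected: Dict[str, str] = {}
        for surface, label in surface_labels:
            key = surface.lower()
            if key in collected and collected[key] != label:
                raise ConflictError(
                    f"surface {surface!r} registered as both "
                    f"{collected[key]} and {label}"
                )
            collected[key] = label
        surface_labels = collected
    return GazetteerMatcher(surface_labels)


def extract_mentions(
    sentence: Union[Sentence, str], matcher: GazetteerMatcher
) -> List[Mention]:
    """Extract mentions from one sentence with the compiled gazetteer.

    Surfaces are reported as they appear in the text (original casing).
    A bare string is accepted for convenience (empty comment id, index 0).
    """
    if isinstance(sentence, str):
        text, comment_id, index = sentence, "", 0
    else:
        text, comment_id, index = sentence.text, sentence.comment_id, sentence.index
    out = []
    for m in matcher.finditer(text):
        out.append(
            Mention(
                comment_id=comment_id,
                sentence_index=index,
                start=m.start(),
                end=m.end(),
                surface=text[m.start() : m.end()],
                label=matcher.label_of(m.group(0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Exact-match evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelScores:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        """Percentage in [0, 100]; 0 when tp+fp == 0."""
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class EvalScores:
    per_label: Dict[str, LabelScores] = field(default_factory=dict)
    overall: LabelScores = field(default_factory=lambda: LabelScores(0, 0, 0))


def evaluate_exact(
    gold: Iterable[Mention], predicted: Iterable[Mention]
) -> EvalScores:
    """Exact-match precision/recall/F1, per label and overall.

    A predicted mention is a true positive iff a gold mention with the
    identical (comment, sentence, start, end, label) exists; matching is
    one-to-one (duplicates are counted with multiplicity).
    """
    gold_keys = Counter(m.key() for m in gold)
    pred_keys = Counter(m.key() for m in predicted)
    per_label = {}
    for label in LABELS:
        g = Counter({k: v for k, v in gold_keys.items() if k[4] == label})
        p = Counter({k: v for k, v in pred_keys.items() if k[4] == label})
        tp = sum((g & p).values())
        per_label[label] = LabelScores(
            tp=tp, fp=sum(p.values()) - tp, fn=sum(g.values()) - tp
        )
    tp = sum(s.tp for s in per_label.values())
    fp = sum(s.fp for s in per_label.values())
    fn = sum(s.fn for s in per_label.values())
    return EvalScores(per_label=per_label, overall=LabelScores(tp, fp, fn))


def split_holdout(
    items: Sequence, fraction: float, seed: int
) -> Tuple[list, list]:
    """Deterministic train/test split at the item (comment) level.

    ``|test| = round(fraction * n)`` with half-up rounding; both halves
    preserve the input order.
    """
    if not (0 < fraction < 1):
        raise InvalidParameterError(f"fraction must be in (0, 1), got {fraction}")
    items = list(items)
    n = len(items)
    n_test = int(floor(fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    test_idx = set(rng.permutation(n)[:n_test].tolist())
    train = [x for i, x in enumerate(items) if i not in test_idx]
    test = [x for i, x in enumerate(items) if i in test_idx]
    return train, test
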