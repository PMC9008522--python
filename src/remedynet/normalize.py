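"""Entity deduplication: embeddings, clustering, canonical mapping.

Raw extracted entities are riddled with misspellings and slang variants
("cigarettes", "ciggarettes", "ciggs", "cigs").  Deduplication trains
word embeddings on the corpus with each entity mention merged into a
single token, clusters entity surfaces whose embeddings are close, and
replaces every member of a cluster by its most frequent member.  An
expert-review table can then apply a second, manual many-to-one merge
and attach categories.

The embeddings are count-based: a windowed token-token co-occurrence
matrix is reweighted by positive PMI and factored with a truncated SVD
(the classic count-based construction that approximates skip-gram), then
augmented with hashed character-n-gram subword features so that surface
variants are close both distributionally and orthographically.  The
whole construction is deterministic given the seed.
"""

from __future__ import annotations

import csv
import re
import zlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.cluster import AgglomerativeClustering

from .corpus import Sentence
from .entities import Mention
from .errors import (
    CoverageError,
    InvalidAnnotationError,
    InvalidParameterError,
    SchemaError,
)

_WORD_RE = re.compile(r"[a-z0-9_]+")


def entity_token(surface: str) -> str:
    """The token form of an entity surface: lowercased, spaces → underscores."""
    return "_".join(surface.lower().split())


def merge_entity_tokens(
    sentences: Iterable[Sentence],
    mentions: Iterable[Mention],
) -> List[List[str]]:
    """Tokenize sentences with each entity mention merged into one token.

    Non-entity text is lowercased and split on non-alphanumerics; a
    mention's span becomes a single token with internal whitespace
    replaced by underscores.  Overlapping mentions raise
    :class:`InvalidAnnotationError`.
    """
    by_sent: Dict[Tuple[str, int], List[Mention]] = {}
    for m in mentions:
        by_sent.setdefault((m.comment_id, m.sentence_index), []).append(m)
    out = []
    for s in sentences:
        ms = sorted(by_sent.get((s.comment_id, s.index), []), key=lambda m: m.start)
        prev_end = 0
        tokens: List[str] = []
        for m in ms:
            if m.start < prev_end:
                raise InvalidAnnotationError(
                    f"overlapping mentions in {s.comment_id}[{s.index}] at {m.start}"
                )
            if m.end > len(s.text) or s.text[m.start : m.end] != m.surface:
                raise InvalidAnnotationError(
                    f"mention {m.surface!r} does not match sentence slice "
                    f"in {s.comment_id}[{s.index}]"
                )
            tokens.extend(_WORD_RE.findall(s.text[prev_end : m.start].lower()))
            tokens.append(entity_token(m.surface))
            prev_end = m.end
        tokens.extend(_WORD_RE.findall(s.text[prev_end:].lower()))
        out.append(tokens)
    return out


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Token → unit-norm vector table with training metadata."""

    tokens: List[str]
    matrix: np.ndarray  # (V, dim)
    frequencies: Dict[str, int]
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.tokens)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __len__(self) -> int:
        return len(self.tokens)

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self._index[token]]

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            return 0.0
        return float(va @ vb / (na * nb))


def _subword_vector(token: str, dim: int, n_lo: int = 3, n_hi: int = 4) -> np.ndarray:
    v = np.zeros(dim)
    padded = f"<{token}>"
    for n in range(n_lo, n_hi + 1):
        for i in range(max(0, len(padded) - n + 1)):
            gram = padded[i : i + n]
            v[zlib.crc32(gram.encode()) % dim] += 1.0
    norm = np.linalg.norm(v)
    return v / norm if norm else v


def train_embeddings(
    token_stream: Iterable[Sequence[str]],
    d: int = 50,
    window: int = 5,
    min_freq: int = 5,
    seed: int = 0,
    subword_dim: int = 32,
    subword_weight: float = 0.3,
) -> EmbeddingTable:
    """Train deterministic count-based embeddings.

    Pipeline: symmetric windowed co-occurrence counts → positive PMI
    reweighting → truncated SVD (ARPACK, seeded start vector, sign-fixed
    singular vectors) → L2 normalization, concatenated with a hashed
    character-n-gram subword block weighted by ``subword_weight``.  The
    vocabulary is every token with frequency >= ``min_freq``.
    """
    if d < 1 or window < 1 or min_freq < 1:
        raise InvalidParameterError("d, window and min_freq must all be >= 1")
    if not (0 <= subword_weight <= 1):
        raise InvalidParameterError("subword_weight must be in [0, 1]")
    sentences = [list(s) for s in token_stream]
    freq = Counter(t for s in sentences for t in s)
    vocab = sorted((t for t, c in freq.items() if c >= min_freq),
                   key=lambda t: (-freq[t], t))
    if not vocab:
        raise InvalidParameterError(
            "empty vocabulary: no token reaches min_freq"
        )
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    cooc: Counter = Counter()
    for s in sentences:
        ids = [index.get(t, -1) for t in s]
        for i, a in enumerate(ids):
            if a < 0:
                continue
            hi = min(len(ids), i + window + 1)
            for j in range(i + 1, hi):
                b = ids[j]
                if b >= 0:
                    cooc[a * V + b] += 1
                    cooc[b * V + a] += 1

    ctx = np.zeros((V, min(d, V)), dtype=float)
    if cooc:
        keys = np.fromiter(cooc.keys(), dtype=np.int64, count=len(cooc))
        vals = np.fromiter(cooc.values(), dtype=np.float64, count=len(cooc))
        rows, cols = keys // V, keys % V
        total = vals.sum()
        row_sums = np.bincount(rows, weights=vals, minlength=V)
        # context-distribution smoothing (exponent 0.75) damps the PMI
        # bias toward rare contexts
        ctx_w = np.bincount(cols, weights=vals, minlength=V) ** 0.75
        ctx_w /= ctx_w.sum()
        pmi = np.log2((vals / total) / ((row_sums[rows] / total) * ctx_w[cols]))
        keep = pmi > 0
        X = sp.csr_matrix(
            (pmi[keep], (rows[keep], cols[keep])), shape=(V, V)
        )
        # L2-normalize rows so token frequency does not dominate the SVD
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        inv = np.zeros_like(norms)
        np.divide(1.0, norms, out=inv, where=norms > 0)
        X = sp.diags(inv) @ X
        k = min(d, V - 1, X.nnz)
        if k >= 1:
            rng = np.random.default_rng(seed)
            v0 = rng.standard_normal(min(X.shape))
            u, s_vals, _ = svds(X, k=k, v0=v0)
            order = np.argsort(s_vals)[::-1]
            u, s_vals = u[:, order], s_vals[order]
            emb = u * np.sqrt(np.maximum(s_vals, 0.0))
            # deterministic sign: largest-|.| component of each column positive
            for c in range(emb.shape[1]):
                col = emb[:, c]
                if col[np.argmax(np.abs(col))] < 0:
                    emb[:, c] = -col
            ctx[:, :k] = emb
    norms = np.linalg.norm(ctx, axis=1, keepdims=True)
    np.divide(ctx, norms, out=ctx, where=norms > 0)

    sub = np.vstack([_subword_vector(t, subword_dim) for t in vocab])
    w = subword_weight
    matrix = np.hstack([np.sqrt(1.0 - w) * ctx, np.sqrt(w) * sub])
    pad = d - min(d, V)
    if pad > 0:  # keep the advertised dimension regardless of vocab size
        matrix = np.hstack([matrix, np.zeros((V, pad))])
    return EmbeddingTable(
        tokens=vocab,
        matrix=matrix,
        frequencies={t: freq[t] for t in vocab},
        meta={
            "d": d,
            "window": window,
            "min_freq": min_freq,
            "seed": seed,
            "subword_dim": subword_dim,
            "subword_weight": subword_weight,
        },
    )


# ---------------------------------------------------------------------------
# Clustering and canonicalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    label: str
    members: Tuple[str, ...]


def cluster_entities(
    embeddings: EmbeddingTable,
    surfaces: Mapping[str, str],
    tau: float = 0.3,
) -> List[Cluster]:
    """Partition entity surfaces by embedding similarity, per label.

    Agglomerative clustering, average linkage, cosine distance, cut at
    threshold ``tau``.  Substances and effects are clustered separately
    so no cluster ever mixes labels.  Surfaces absent from the embedding
    vocabulary become singletons rather than being dropped.
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    clusters: List[Cluster] = []
    by_label: Dict[str, List[str]] = {}
    for surf, label in surfaces.items():
        by_label.setdefault(label, []).append(surf)
    for label in sorted(by_label):
        surfs = sorted(by_label[label])
        known = [s for s in surfs if entity_token(s) in embeddings]
        unknown = [s for s in surfs if entity_token(s) not in embeddings]
        for s in unknown:
            clusters.append(Cluster(label=label, members=(s,)))
        if len(known) == 1:
            clusters.append(Cluster(label=label, members=(known[0],)))
        elif len(known) > 1:
            X = np.vstack([embeddings.vector(entity_token(s)) for s in known])
            model = AgglomerativeClustering(
                n_clusters=None,
                metric="cosine",
                linkage="average",
                distance_threshold=tau,
            )
            labels = model.fit_predict(X)
            groups: Dict[int, List[str]] = {}
            for s, c in zip(known, labels):
                groups.setdefault(int(c), []).append(s)
            for members in groups.values():
                clusters.append(Cluster(label=label, members=tuple(sorted(members))))
    return clusters


@dataclass
class CanonicalMap:
    """Many-to-one mapping from raw surfaces to canonical entities.

    ``mapping`` is total on observed surfaces, each canonical maps to
    itself, and the mapping never crosses labels.
    """

    mapping: Dict[str, str]
    labels: Dict[str, str]  # surface -> label
    frequencies: Dict[str, int]  # surface -> observed count
    categories: Dict[str, str] = field(default_factory=dict)  # canonical -> cat

    def canonical(self, surface: str) -> str:
        return self.mapping[surface]

    @property
    def canonicals(self) -> List[str]:
        return sorted(set(self.mapping.values()))

    @property
    def n_surfaces(self) -> int:
        return len(self.mapping)

    @property
    def n_canonicals(self) -> int:
        return len(set(self.mapping.values()))

    def validate(self) -> None:
        for surf, canon in self.mapping.items():
            if self.mapping.get(canon) != canon:
                raise SchemaError(f"canonical {canon!r} does not map to itself")
            if self.labels.get(surf) != self.labels.get(canon):
                raise SchemaError(
                    f"mapping crosses labels: {surf!r} -> {canon!r}"
                )

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["surface", "canonical", "label", "category", "frequency"])
            for surf in sorted(self.mapping):
                canon = self.mapping[surf]
                w.writerow(
                    [
                        surf,
                        canon,
                        self.labels[surf],
                        self.categories.get(canon, ""),
                        self.frequencies.get(surf, 0),
                    ]
                )

    @classmethod
    def from_tsv(cls, path: str) -> "CanonicalMap":
        mapping: Dict[str, str] = {}
        labels: Dict[str, str] = {}
        freqs: Dict[str, int] = {}
        categories: Dict[str, str] = {}
        with open(path, "r", encoding="utf-8", newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if header[:2] != ["surface", "canonical"]:
                raise SchemaError(f"unexpected canonical-map header: {header}")
            for row in r:
                surf, canon, label, category, freq = row
                mapping[surf] = canon
                labels[surf] = label
                freqs[surf] = int(freq)
                if category:
                    categories[canon] = category
        return cls(mapping=mapping, labels=labels, frequencies=freqs,
                   categories=categories)

    def export_review(self, path: str) -> None:
        """Write a review template: one row per canonical, identity names."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["canonical", "corrected_name", "category"])
            for canon in self.canonicals:
                w.writerow([canon, canon, self.categories.get(canon, "")])


def canonicalize(
    clusters: Iterable[Cluster],
    frequencies: Mapping[str, int],
) -> CanonicalMap:
    """Choose each cluster's canonical: highest frequency, ties broken
    by the lexicographically smallest surface."""
    mapping: Dict[str, str] = {}
    labels: Dict[str, str] = {}
    for cl in clusters:
        if not cl.members:
            continue
        canon = min(cl.members, key=lambda s: (-frequencies.get(s, 0), s))
        for s in cl.members:
            mapping[s] = canon
            labels[s] = cl.label
    return CanonicalMap(
        mapping=mapping,
        labels=labels,
        frequencies={s: int(frequencies.get(s, 0)) for s in mapping},
    )


def apply_map(
    mentions: Iterable[Mention], cmap: CanonicalMap
) -> List[Mention]:
    """Replace mention surfaces with their canonicals.

    Offsets and labels are preserved; idempotent because canonicals map
    to themselves.  Surfaces missing from the map raise
    :class:`CoverageError` listing every uncovered surface.
    """
    mentions = list(mentions)
    missing = {
        entity_token(m.surface)
        for m in mentions
        if entity_token(m.surface) not in cmap.mapping
    }
    if missing:
        raise CoverageError(missing)
    out = []
    for m in mentions:
        canon = cmap.mapping[entity_token(m.surface)]
        out.append(
            Mention(
                comment_id=m.comment_id,
                sentence_index=m.sentence_index,
                start=m.start,
                end=m.end,
                surface=canon,
                label=m.label,
            )
        )
    return out


def review_roundtrip(cmap: CanonicalMap, review_path: str) -> CanonicalMap:
    """Apply an expert-review table: corrected names and categories.

    The review file (TSV: canonical, corrected_name, category) defines a
    second many-to-one merge — distinct canonicals given the same
    corrected name collapse into one entity.  Rows naming unknown
    canonicals raise ``KeyError``; an identity review (as produced by
    :meth:`CanonicalMap.export_review`) leaves the map unchanged.
    """
    corrected: Dict[str, str] = {}
    categories: Dict[str, str] = {}
    known = set(cmap.mapping.values())
    with open(review_path, "r", encoding="utf-8", newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is not None and header[:2] != ["canonical", "corrected_name"]:
            raise SchemaError(f"unexpected review header: {header}")
        for row in r:
            if not row or not row[0]:
                continue
            canon, new_name = row[0], row[1] or row[0]
            category = row[2] if len(row) > 2 else ""
            if canon not in known:
                raise KeyError(f"review names unknown canonical {canon!r}")
            corrected[canon] = new_name
            if category:
                categories[new_name] = category

    # resolve chains (a->b, b->c) so one review pass is a fixpoint
    def _resolve(name: str) -> str:
        seen = set()
        while name in corrected and corrected[name] != name and name not in seen:
            seen.add(name)
            name = corrected[name]
        return name

    corrected = {old: _resolve(new) for old, new in corrected.items()}
    categories = {_resolve(c): v for c, v in categories.items()}

    mapping = dict(cmap.mapping)
    labels = dict(cmap.labels)
    freqs = dict(cmap.frequencies)
    for surf, canon in list(mapping.items()):
        if canon in corrected:
            mapping[surf] = corrected[canon]
    for old, new in corrected.items():
        if new not in mapping:
            mapping[new] = new
            labels[new] = labels[old]
            freqs.setdefault(new, 0)
        mapping[new] = new
    new_categories = dict(cmap.categories)
    new_categories.update(categories)
    # categories keyed by retired canonicals are dropped
    live = set(mapping.values())
    new_categories = {c: v for c, v in new_categories.items() if c in live}
    result = CanonicalMap(
        mapping=mapping, labels=labels, frequencies=freqs,
        categories=new_categories,
    )
    result.validate()
    return result
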