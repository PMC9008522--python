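"""Bipartite substance-effect co-occurrence network with PPMI weights.

Nodes are canonical entities typed SUBSTANCE or EFFECT; an edge links a
substance and an effect that appeared together in at least one sentence.
Counting uses presence semantics: a sentence contributes at most 1 to an
edge count and at most 1 to each node's occurrence count, regardless of
within-sentence repetition — this keeps p(s,e) <= min(p(s), p(e)).

With N the total number of sentences in the non-deleted corpus and
n(x) a node's sentence-occurrence count, the edge weight is

    ppmi = max(0, log2( (c/N) / ((n(s)/N) * (n(e)/N)) ))

i.e. pointwise mutual information in base 2, clipped at zero.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .entities import EFFECT, SUBSTANCE, Mention
from .errors import EmptyCorpusError, InvalidParameterError, ParseError

NodeKey = str
EdgeKey = Tuple[str, str]  # (substance, effect)


@dataclass(frozen=True)
class Node:
    name: str
    label: str  # SUBSTANCE or EFFECT
    n: int  # sentences containing the node at least once
    category: str = ""


@dataclass(frozen=True)
class CoocEdge:
    substance: str
    effect: str
    count: int  # sentences containing both
    ppmi: Optional[float] = None
    score: Optional[float] = None


@dataclass
class BipartiteNetwork:
    nodes: Dict[NodeKey, Node] = field(default_factory=dict)
    edges: Dict[EdgeKey, CoocEdge] = field(default_factory=dict)
    N: int = 0

    def node(self, name: str) -> Node:
        return self.nodes[name]

    def incident_edges(self, name: str) -> List[CoocEdge]:
        node = self.nodes[name]
        if node.label == SUBSTANCE:
            return [e for (s, _), e in sorted(self.edges.items()) if s == name]
        return [e for (_, f), e in sorted(self.edges.items()) if f == name]


@dataclass(frozen=True)
class EgoNetwork:
    """One node plus its surviving neighbors.  The network is bipartite,
    so there are never alter-alter edges."""

    ego: Node
    alters: Tuple[Node, ...]
    edges: Tuple[CoocEdge, ...]


def build_network(
    sentence_mentions: Iterable[Iterable[Mention]],
    N: int,
    categories: Optional[Dict[str, str]] = None,
) -> BipartiteNetwork:
    """Count sentence-level co-occurrence from normalized mentions.

    ``sentence_mentions`` yields one collection of mentions per sentence
    (mentions should already be canonicalized).  ``N`` is the total
    sentence count of the corpus — including sentences without mentions.
    """
    if N <= 0:
        raise EmptyCorpusError(f"N must be >= 1, got {N}")
    categories = categories or {}
    node_counts: Dict[str, int] = {}
    node_labels: Dict[str, str] = {}
    edge_counts: Dict[EdgeKey, int] = {}
    n_sentences = 0
    for mentions in sentence_mentions:
        mentions = list(mentions)
        if not mentions:
            continue
        n_sentences += 1
        subs = sorted({m.surface for m in mentions if m.label == SUBSTANCE})
        effs = sorted({m.surface for m in mentions if m.label == EFFECT})
        for name, label in [(s, SUBSTANCE) for s in subs] + [
            (e, EFFECT) for e in effs
        ]:
            node_counts[name] = node_counts.get(name, 0) + 1
            node_labels[name] = label
        for s in subs:
            for e in effs:
                edge_counts[(s, e)] = edge_counts.get((s, e), 0) + 1
    if N < n_sentences:
        raise InvalidParameterError(
            f"N={N} is smaller than the {n_sentences} distinct sentences seen"
        )
    net = BipartiteNetwork(N=N)
    for name in sorted(node_counts):
        net.nodes[name] = Node(
            name=name,
            label=node_labels[name],
            n=node_counts[name],
            category=categories.get(name, ""),
        )
    for key in sorted(edge_counts):
        s, e = key
        net.edges[key] = CoocEdge(substance=s, effect=e, count=edge_counts[key])
    return net


def compute_ppmi(network: BipartiteNetwork) -> BipartiteNetwork:
    """Fill each edge's PPMI in place (and return the network)."""
    N = network.N
    for key, edge in network.edges.items():
        n_s = network.nodes[edge.substance].n
        n_e = network.nodes[edge.effect].n
        pmi = math.log2((edge.count * N) / (n_s * n_e))
        network.edges[key] = replace(edge, ppmi=max(0.0, pmi))
    return network


def ego_network(
    network: BipartiteNetwork,
    node_name: str,
    min_ppmi: float = 1.5,
    min_count: int = 10,
) -> EgoNetwork:
    """Extract one node's ego network under PPMI/count filters.

    Keeps incident edges with ``ppmi >= min_ppmi`` and
    ``count >= min_count``; alters are the opposite endpoints of the
    kept edges.  Unknown node names raise ``KeyError``.
    """
    if node_name not in network.nodes:
        raise KeyError(f"unknown node {node_name!r}")
    ego = network.nodes[node_name]
    kept = [
        e
        for e in network.incident_edges(node_name)
        if (e.ppmi or 0.0) >= min_ppmi and e.count >= min_count
    ]
    alter_names = sorted(
        {e.effect if ego.label == SUBSTANCE else e.substance for e in kept}
    )
    return EgoNetwork(
        ego=ego,
        alters=tuple(network.nodes[a] for a in alter_names),
        edges=tuple(kept),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else repr(x)


def export_network(network: BipartiteNetwork, prefix: str) -> None:
    """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv`` losslessly.

    Floats are serialized with ``repr`` so the round trip is
    field-exact; N is stored on the nodes-file header line.
    """
    with open(prefix + ".nodes.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["#N", str(network.N)])
        w.writerow(["name", "label", "category", "n"])
        for name in sorted(network.nodes):
            node = network.nodes[name]
            w.writerow([node.name, node.label, node.category, node.n])
    with open(prefix + ".edges.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["substance", "effect", "count", "ppmi", "score"])
        for key in sorted(network.edges):
            e = network.edges[key]
            w.writerow([e.substance, e.effect, e.count, _fmt(e.ppmi), _fmt(e.score)])


def import_network(prefix: str) -> BipartiteNetwork:
    net = BipartiteNetwork()
    try:
        with open(prefix + ".nodes.tsv", "r", encoding="utf-8", newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            first = next(r)
            if len(first) != 2 or first[0] != "#N":
                raise ParseError(f"nodes file lacks #N header, got {first}")
            net.N = int(first[1])
            header = next(r)
            if header != ["name", "label", "category", "n"]:
                raise ParseError(f"unexpected nodes header: {header}")
            for row in r:
                name, label, category, n = row
                net.nodes[name] = Node(
                    name=name, label=label, category=category, n=int(n)
                )
        with open(prefix + ".edges.tsv", "r", encoding="utf-8", newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if header != ["substance", "effect", "count", "ppmi", "score"]:
                raise ParseError(f"unexpected edges header: {header}")
            for row in r:
                s, e, count, ppmi, score = row
                net.edges[(s, e)] = CoocEdge(
                    substance=s,
                    effect=e,
                    count=int(count),
                    ppmi=float(ppmi) if ppmi else None,
                    score=float(score) if score else None,
                )
    except (ValueError, StopIteration) as exc:
        raise ParseError(f"malformed network file under {prefix!r}: {exc}") from exc
    return net


def to_networkx(network: BipartiteNetwork):
    """Optional export to a networkx bipartite graph for visualization."""
    import networkx as nx

    g = nx.Graph()
    for node in network.nodes.values():
        g.add_node(
            node.name, label=node.label, category=node.category, n=node.n,
            bipartite=0 if node.label == SUBSTANCE else 1,
        )
    for e in network.edges.values():
        g.add_edge(e.substance, e.effect, count=e.count, ppmi=e.ppmi, score=e.score)
    return g
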