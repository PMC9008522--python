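"""Symptom-remedy association scoring and the validation pair table.

The composite association score for an edge combines how often a pair
co-occurs with how surprising the co-occurrence is: the edge count is
log-transformed (natural log, to reduce skewness), both the transformed
count and the PPMI are min-max scaled to [0, 1] over the full edge set,
and the two scaled components are averaged.  For each withdrawal
symptom, the top-k substances by this score are selected after dropping
excluded pharmacological categories (opioids by default) and edges below
a minimum count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .conet import BipartiteNetwork, CoocEdge
from .entities import EFFECT, SUBSTANCE
from .errors import InvalidParameterError
from .stats import round_half_up

#: Validation categories for symptom-remedy pairs.
CAT_TREATMENT = "approved/common treatment"
CAT_USEFUL = "potentially useful"
CAT_NATURAL = "home/natural remedy"
CAT_CAUSES = "causes symptom"
CAT_OTHER = "other/unclear"
PAIR_CATEGORIES = (CAT_TREATMENT, CAT_USEFUL, CAT_NATURAL, CAT_CAUSES, CAT_OTHER)
#: Categories counted as "potentially valid" treatments.
VALID_PAIR_CATEGORIES = (CAT_TREATMENT, CAT_USEFUL, CAT_NATURAL)

#: Substance categories excluded from remedy candidacy by default.
DEFAULT_EXCLUDED_CATEGORIES = frozenset({"opioid"})


def load_default_symptoms() -> List[str]:
    """The shipped withdrawal-symptom list (16 effects, editable file)."""
    text = (
        resources.files("remedynet.data")
        .joinpath("withdrawal_symptoms.txt")
        .read_text(encoding="utf-8")
    )
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def _minmax(values: Sequence[float]) -> List[float]:
    lo, hi = min(values), max(values)
    if hi == lo:  # degenerate: all equal scales to 0
        return [0.0 for _ in values]
    return [(v - lo) / (hi - lo) for v in values]


def edge_scores(network: BipartiteNetwork) -> BipartiteNetwork:
    """Fill each edge's composite score in place (and return the network).

    score = ( minmax(ln count) + minmax(ppmi) ) / 2, with min-max taken
    over all edges of the network.
    """
    if not network.edges:
        raise InvalidParameterError("network has no edges to score")
    keys = sorted(network.edges)
    log_counts = [math.log(network.edges[k].count) for k in keys]
    ppmis = [network.edges[k].ppmi or 0.0 for k in keys]
    sc = _minmax(log_counts)
    sp = _minmax(ppmis)
    for k, a, b in zip(keys, sc, sp):
        network.edges[k] = replace(network.edges[k], score=(a + b) / 2.0)
    return network


def top_remedies(
    network: BipartiteNetwork,
    symptom: str,
    k: int = 10,
    excluded_categories: Iterable[str] = DEFAULT_EXCLUDED_CATEGORIES,
    min_count: int = 5,
) -> List[CoocEdge]:
    """Top-k substances most strongly associated with a symptom.

    Candidates are incident substances with edge count >= ``min_count``
    whose category is not excluded, sorted by score descending; ties
    break toward the higher count, then the lexicographically smaller
    name.  Fewer than k rows are returned when fewer qualify.
    """
    if symptom not in network.nodes:
        raise KeyError(f"unknown symptom {symptom!r}")
    if network.nodes[symptom].label != EFFECT:
        raise InvalidParameterError(f"{symptom!r} is not an EFFECT node")
    excluded = set(excluded_categories)
    candidates = []
    for edge in network.incident_edges(symptom):
        if edge.count < min_count:
            continue
        if network.nodes[edge.substance].category in excluded:
            continue
        if edge.score is None:
            raise InvalidParameterError(
                "edge scores not computed; run edge_scores first"
            )
        candidates.append(edge)
    candidates.sort(key=lambda e: (-e.score, -e.count, e.substance))
    return candidates[:k]


def build_pair_table(
    network: BipartiteNetwork,
    symptoms: Sequence[str],
    k: int = 10,
    excluded_categories: Iterable[str] = DEFAULT_EXCLUDED_CATEGORIES,
    min_count: int = 5,
) -> pd.DataFrame:
    """Concatenate per-symptom top-k lists into one pair table.

    Columns: symptom, rank, substance, count, ppmi, score, category
    (validation label, initially empty).  Symptoms missing from the
    network are reported in a warning and skipped; symptoms with no
    eligible candidate contribute no rows, so the table may hold fewer
    than ``len(symptoms) * k`` rows.
    """
    if not symptoms:
        raise InvalidParameterError("symptom list must be non-empty")
    rows = []
    missing = []
    for symptom in symptoms:
        if symptom not in network.nodes:
            missing.append(symptom)
            continue
        for rank, edge in enumerate(
            top_remedies(network, symptom, k, excluded_categories, min_count),
            start=1,
        ):
            rows.append(
                {
                    "symptom": symptom,
                    "rank": rank,
                    "substance": edge.substance,
                    "count": edge.count,
                    "ppmi": edge.ppmi,
                    "score": edge.score,
                    "category": "",
                }
            )
    if missing:
        warnings.warn(
            f"symptoms not in network, skipped: {', '.join(missing)}",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["symptom", "rank", "substance", "count", "ppmi", "score",
                 "category"],
    )


def quintile_summary(
    table: pd.DataFrame,
    valid_categories: Iterable[str] = VALID_PAIR_CATEGORIES,
) -> pd.DataFrame:
    """Per-quintile validity of the pair table, strongest pairs first.

    Rows are ranked by score descending across the whole table; quintile
    q covers rows ceil((q-1)n/5)+1 .. ceil(qn/5).  ``percent_valid`` is
    the integer-rounded share of rows whose category is in
    ``valid_categories``.  Uncategorized rows raise an error.
    """
    if table.empty:
        raise InvalidParameterError("pair table is empty")
    if (table["category"] == "").any() or table["category"].isna().any():
        raise InvalidParameterError("all rows must be categorized")
    valid = set(valid_categories)
    ordered = table.sort_values(
        ["score", "count", "substance"], ascending=[False, False, True]
    ).reset_index(drop=True)
    n = len(ordered)
    out = []
    for q in range(1, 6):
        lo = math.ceil((q - 1) * n / 5)  # 0-based start
        hi = math.ceil(q * n / 5)
        chunk = ordered.iloc[lo:hi]
        if chunk.empty:
            out.append({"quintile": q, "n": 0, "n_valid": 0, "percent_valid": 0.0})
            continue
        n_valid = int(chunk["category"].isin(valid).sum())
        out.append(
            {
                "quintile": q,
                "n": len(chunk),
                "n_valid": n_valid,
                "percent_valid": round_half_up(100.0 * n_valid / len(chunk), 0),
            }
        )
    return pd.DataFrame(out, columns=["quintile", "n", "n_valid", "percent_valid"])


def attach_categories(
    table: pd.DataFrame, labels: Dict[tuple, str]
) -> pd.DataFrame:
    """Attach validation categories from a {(symptom, substance): cat} map."""
    out = table.copy()
    out["category"] = [
        labels.get((r.symptom, r.substance), r.category)
        for r in out.itertuples()
    ]
    return out
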