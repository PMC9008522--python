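"""Summary arithmetic: reduction percentages and frequency tables.

All percentages are rounded half-up at a caller-chosen precision, which
is the convention used in the published tables this mirrors (e.g. a
count of 61,783 out of 479,289 prints as 12.89%).  No formal statistical
tests are computed anywhere in the pipeline.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import InvalidParameterError


def round_half_up(x: float, precision: int) -> float:
    """Round half away from zero at ``precision`` decimal places."""
    q = Decimal(1).scaleb(-precision)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_reduction(before: int, after: int, precision: int = 2) -> float:
    """100 * (before - after) / before, rounded half-up."""
    if before <= 0:
        raise InvalidParameterError(f"before must be > 0, got {before}")
    if after < 0 or after > before:
        raise InvalidParameterError(
            f"need 0 <= after <= before, got after={after}, before={before}"
        )
    return round_half_up(100.0 * (before - after) / before, precision)


def percent_retained(before: int, after: int, precision: int = 2) -> float:
    """100 * after / before; complements :func:`percent_reduction`."""
    if before <= 0:
        raise InvalidParameterError(f"before must be > 0, got {before}")
    if after < 0 or after > before:
        raise InvalidParameterError(
            f"need 0 <= after <= before, got after={after}, before={before}"
        )
    return round_half_up(100.0 * after / before, precision)


def frequency_table(
    counts: Mapping[str, int],
    precision: int = 2,
    total: Optional[int] = None,
) -> pd.DataFrame:
    """Counts with percent-of-total, sorted by count desc then name.

    ``total`` defaults to the sum of counts but may be larger (e.g. when
    listing only the top rows of a bigger tally); percentages therefore
    need not sum to 100.
    """
    if not counts:
        raise InvalidParameterError("counts must be non-empty")
    if any(c < 0 for c in counts.values()):
        raise InvalidParameterError("counts must be >= 0")
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise InvalidParameterError(f"total must be > 0, got {total}")
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "name": [k for k, _ in rows],
            "count": [v for _, v in rows],
            "percent": [
                round_half_up(100.0 * v / total, precision) for _, v in rows
            ],
        }
    )


def validity_percent(
    category_counts: Mapping[str, int],
    valid_categories: Iterable[str],
    precision: int = 1,
) -> float:
    """Percent of items whose category is in ``valid_categories``."""
    valid = set(valid_categories)
    unknown = valid - set(category_counts)
    if unknown:
        raise InvalidParameterError(
            f"unknown categories: {sorted(unknown)}"
        )
    if any(c < 0 for c in category_counts.values()):
        raise InvalidParameterError("counts must be >= 0")
    total = sum(category_counts.values())
    if total <= 0:
        raise InvalidParameterError("total count must be > 0")
    hits = sum(c for k, c in category_counts.items() if k in valid)
    return round_half_up(100.0 * hits / total, precision)
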