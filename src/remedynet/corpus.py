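"""Reading and summarizing pushshift-style comment streams.

Comments arrive as JSON Lines, one object per line, with at least the
fields ``id``, ``subreddit``, ``created_utc`` and ``body``.  Deleted
comments keep their metadata but carry the literal body ``"[deleted]"``
or ``"[removed]"``; analyses run on the non-deleted remainder.  The
co-occurrence unit downstream is the sentence, so this module also owns
the rule-based sentence segmenter.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional, Union

import pandas as pd

from .errors import ParseError, SchemaError

#: Bodies that mark a comment as deleted on the platform.
DELETED_BODIES = frozenset({"[deleted]", "[removed]"})

_REQUIRED_FIELDS = ("id", "subreddit", "created_utc", "body")


@dataclass(frozen=True)
class Comment:
    """One comment record from the stream."""

    id: str
    subreddit: str
    created_utc: int
    body: str
    parent_id: Optional[str] = None
    author: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("comment id must be non-empty")
        if self.created_utc < 0:
            raise SchemaError("created_utc must be >= 0")

    @property
    def is_deleted(self) -> bool:
        return self.body in DELETED_BODIES

    def to_json(self) -> str:
        rec = {
            "id": self.id,
            "parent_id": self.parent_id,
            "subreddit": self.subreddit,
            "author": self.author,
            "created_utc": self.created_utc,
            "body": self.body,
        }
        return json.dumps(rec, sort_keys=True)


@dataclass(frozen=True)
class Sentence:
    """A sentence inside a comment body.

    ``span`` holds 0-based half-open character offsets into the body, so
    ``body[start:end] == text`` always holds.
    """

    comment_id: str
    index: int
    text: str
    start: int
    end: int


def read_comments(path_or_file: Union[str, "IO[str]"]) -> Iterator[Comment]:
    """Stream comments from a JSONL file, preserving input order.

    Unknown fields are ignored.  Raises :class:`ParseError` (naming the
    line number) on malformed JSON and :class:`SchemaError` when a line
    lacks a required field.
    """
    if isinstance(path_or_file, str):
        with open(path_or_file, "r", encoding="utf-8") as fh:
            yield from _read_stream(fh)
    else:
        yield from _read_stream(path_or_file)


def _read_stream(fh: "IO[str]") -> Iterator[Comment]:
    for lineno, line in enumerate(fh, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON on line {lineno}: {exc}") from exc
        missing = [f for f in _REQUIRED_FIELDS if f not in rec]
        if missing:
            raise SchemaError(
                f"line {lineno} lacks required field(s): {', '.join(missing)}"
            )
        yield Comment(
            id=str(rec["id"]),
            subreddit=str(rec["subreddit"]),
            created_utc=int(rec["created_utc"]),
            body=str(rec["body"]),
            parent_id=rec.get("parent_id"),
            author=rec.get("author"),
        )


def write_comments(comments: Iterable[Comment], path: str) -> int:
    """Write comments as JSONL; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(c.to_json())
            fh.write("\n")
            n += 1
    return n


class StreamCounts:
    """Total/kept tallies filled in while a filtered stream is consumed."""

    def __init__(self) -> None:
        self.total = 0
        self.nondeleted = 0

    def as_tuple(self) -> tuple:
        return (self.total, self.nondeleted)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StreamCounts(total={self.total}, nondeleted={self.nondeleted})"


def filter_nondeleted(stream: Iterable[Comment]):
    """Drop comments whose body is exactly ``[deleted]`` or ``[removed]``.

    Returns ``(iterator, counts)``.  The iterator is lazy (one comment in
    memory at a time); ``counts`` is final once the iterator is exhausted.
    """
    counts = StreamCounts()

    def gen() -> Iterator[Comment]:
        for c in stream:
            counts.total += 1
            if not c.is_deleted:
                counts.nondeleted += 1
                yield c

    return gen(), counts


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------
# Rule-based splitter tuned for noisy forum text: a sentence ends at a run
# of [.!?] (an ellipsis is a single run, never split internally) followed
# by whitespace, or at a newline.  A short dotted-abbreviation stop-list
# suppresses false splits.  The splitter is pluggable: any callable
# mapping body -> list[(start, end)] can replace `segment_spans`.

_TERMINATOR = re.compile(r"[.!?]+[\"')\]]*")
_ABBREV_TAIL = re.compile(
    r"(?:^|[\s(\[])(?:e\.g|i\.e|mr|mrs|ms|dr|vs|approx)[.]$", re.IGNORECASE
)


def segment_spans(body: str) -> list:
    """Return sentence spans ``(start, end)`` covering all non-whitespace."""
    spans = []
    for seg_start, seg_end in _newline_segments(body):
        spans.extend(_split_segment(body, seg_start, seg_end))
    return spans


def _newline_segments(body: str):
    start = None
    for i, ch in enumerate(body):
        if ch == "\n":
            if start is not None:
                yield start, i
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, len(body)


def _split_segment(body: str, seg_start: int, seg_end: int):
    spans = []
    cursor = seg_start
    for m in _TERMINATOR.finditer(body, seg_start, seg_end):
        end = m.end()
        if end < seg_end and not body[end].isspace():
            continue  # mid-token punctuation, e.g. "3.5" or "r/opiates"
        if _ABBREV_TAIL.search(body[max(seg_start, m.start() - 8) : m.end()]):
            continue
        # advance start past leading whitespace
        while cursor < end and body[cursor].isspace():
            cursor += 1
        if cursor < end:
            spans.append((cursor, end))
        cursor = end
    while cursor < seg_end and body[cursor].isspace():
        cursor += 1
    if cursor < seg_end:
        spans.append((cursor, seg_end))
    return spans


def segment_sentences(comment: Comment) -> list:
    """Segment a comment body into :class:`Sentence` objects.

    An empty (or all-whitespace) body yields an empty list.
    """
    out = []
    for idx, (start, end) in enumerate(segment_spans(comment.body)):
        out.append(
            Sentence(
                comment_id=comment.id,
                index=idx,
                text=comment.body[start:end],
                start=start,
                end=end,
            )
        )
    return out


def corpus_summary(stream: Iterable[Comment]) -> pd.DataFrame:
    """Per-subreddit corpus summary plus a total row.

    Columns: subreddit, first_utc, last_utc, count, count_nondeleted.
    The total row sums the count columns and takes min/max timestamps.
    """
    rows = {}
    for c in stream:
        r = rows.setdefault(
            c.subreddit,
            {"first_utc": c.created_utc, "last_utc": c.created_utc,
             "count": 0, "count_nondeleted": 0},
        )
        r["first_utc"] = min(r["first_utc"], c.created_utc)
        r["last_utc"] = max(r["last_utc"], c.created_utc)
        r["count"] += 1
        if not c.is_deleted:
            r["count_nondeleted"] += 1
    records = [
        {"subreddit": name, **vals} for name, vals in sorted(rows.items())
    ]
    if records:
        records.append(
            {
                "subreddit": "Total",
                "first_utc": min(r["first_utc"] for r in records),
                "last_utc": max(r["last_utc"] for r in records),
                "count": sum(r["count"] for r in records),
                "count_nondeleted": sum(r["count_nondeleted"] for r in records),
            }
        )
    return pd.DataFrame(
        records,
        columns=["subreddit", "first_utc", "last_utc", "count", "count_nondeleted"],
    )
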