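"""Corpus input/output, keyword filtering and calendar-quarter windowing.

A corpus is a list of :class:`TweetRecord` read from JSONL (one object per
line) or CSV (RFC-4180). Records carry the observables of one post — id,
raw text, UTC timestamp, author — plus an optional gender attribute supplied
by an external classifier upstream of this package.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "GENDERS",
    "STUDY_KEYWORDS",
    "STUDY_WINDOW",
    "CorpusFormatError",
    "KeywordSet",
    "QuarterIndex",
    "TweetRecord",
    "WindowError",
    "filter_by_keywords",
    "quarter_of",
    "quarters_in_window",
    "read_corpus",
    "read_labels",
    "write_corpus",
    "write_table",
]

GENDERS = ("female", "male", "unknown")

#: The fifteen search phrases used to harvest topical-fluoride posts.
STUDY_KEYWORDS: tuple[str, ...] = (
    "fluoride",
    "tooth decay",
    "child tooth",
    "pedodontics",
    "paediatric dentistry",
    "fluoride varnish",
    "fluoride polish",
    "teeth fluoride",
    "tooth fluoride",
    "toothpaste fluoride",
    "teeth varnish",
    "tooth varnish",
    "topical fluoride",
    "pineal calcification",
    "caries risk",
)

#: Collection window of the study corpus: [2017-01-01, 2020-01-01).
STUDY_WINDOW: tuple[date, date] = (date(2017, 1, 1), date(2020, 1, 1))

_REQUIRED_FIELDS = ("id", "text", "created_at", "author_id")


class CorpusFormatError(ValueError):
    """Malformed corpus or label file (bad row, missing field, bad id)."""


class WindowError(ValueError):
    """Timestamp outside the configured collection window."""


@dataclass(frozen=True)
class TweetRecord:
    """One post: identifier, raw text, UTC timestamp, author, gender."""

    id: str
    text: str
    created_at: datetime
    author_id: str
    gender: str = "unknown"
    source_meta: dict | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusFormatError("record id must be non-empty")
        if self.gender not in GENDERS:
            raise CorpusFormatError(
                f"record {self.id!r}: gender must be one of {GENDERS}, got {self.gender!r}"
            )
        if self.created_at.tzinfo is None:
            object.__setattr__(
                self, "created_at", self.created_at.replace(tzinfo=timezone.utc)
            )


@dataclass(frozen=True)
class KeywordSet:
    """Ordered lowercase phrases; a post matches if any phrase is a substring."""

    phrases: tuple[str, ...] = STUDY_KEYWORDS

    def __post_init__(self) -> None:
        phrases = tuple(p.lower() for p in self.phrases)
        if not phrases:
            raise ValueError("KeywordSet must contain at least one phrase")
        if len(set(phrases)) != len(phrases):
            raise ValueError("KeywordSet phrases must be unique")
        object.__setattr__(self, "phrases", phrases)


class QuarterIndex(NamedTuple):
    """A calendar quarter, ordered by (year, quarter)."""

    year: int
    quarter: int

    @property
    def label(self) -> str:
        return f"{self.year}Q{self.quarter}"


def _parse_timestamp(value: str, where: str) -> datetime:
    try:
        ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: unparseable created_at {value!r}") from exc
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _record_from_mapping(row: dict, where: str) -> TweetRecord:
    for key in _REQUIRED_FIELDS:
        if key not in row or row[key] in (None, ""):
            raise CorpusFormatError(f"{where}: missing required field {key!r}")
    gender = row.get("gender") or "unknown"
    if gender not in GENDERS:
        raise CorpusFormatError(f"{where}: unknown gender value {gender!r}")
    meta = row.get("source_meta")
    if meta is not None and not isinstance(meta, dict):
        raise CorpusFormatError(f"{where}: source_meta must be a mapping")
    return TweetRecord(
        id=str(row["id"]),
        text=str(row["text"]),
        created_at=_parse_timestamp(row["created_at"], where),
        author_id=str(row["author_id"]),
        gender=gender,
        source_meta=meta,
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unsupported corpus format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer corpus format from {path.name!r}")


def read_corpus(path: str | Path, format: str | None = None) -> list[TweetRecord]:
    """Read a corpus file into records, preserving file order.

    Raises :class:`CorpusFormatError` naming the offending line for malformed
    rows, and listing the ids for duplicate-id collisions (id collisions
    indicate corrupted input and are never silently merged).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[TweetRecord] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(
                        f"{path.name} line {lineno}: invalid JSON"
                    ) from exc
                records.append(_record_from_mapping(row, f"{path.name} line {lineno}"))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for key in _REQUIRED_FIELDS:
                if key not in header:
                    raise CorpusFormatError(f"{path.name}: missing column {key!r}")
            for lineno, row in enumerate(reader, 2):
                if None in row:
                    raise CorpusFormatError(f"{path.name} line {lineno}: extra fields")
                records.append(_record_from_mapping(row, f"{path.name} line {lineno}"))
    seen: dict[str, int] = {}
    dupes = []
    for rec in records:
        if rec.id in seen:
            dupes.append(rec.id)
        seen[rec.id] = 1
    if dupes:
        raise CorpusFormatError(f"duplicate record ids: {sorted(set(dupes))}")
    return records


def write_corpus(
    records: Sequence[TweetRecord], path: str | Path, format: str | None = None
) -> None:
    """Write records to JSONL or CSV; round-trips text byte-exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                row = {
                    "id": rec.id,
                    "text": rec.text,
                    "created_at": rec.created_at.isoformat(),
                    "author_id": rec.author_id,
                    "gender": rec.gender,
                }
                if rec.source_meta:
                    row["source_meta"] = rec.source_meta
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "text", "created_at", "author_id", "gender"])
            for rec in records:
                writer.writerow(
                    [rec.id, rec.text, rec.created_at.isoformat(), rec.author_id, rec.gender]
                )


def filter_by_keywords(
    records: Iterable[TweetRecord], kw: KeywordSet | None = None
) -> list[TweetRecord]:
    """Keep records whose lowercased raw text contains any keyword phrase.

    Matching is case-insensitive contiguous-substring on the *raw* text
    (pre-normalization), mirroring platform advanced-search semantics; the
    operation is idempotent and order-preserving.
    """
    kw = kw or KeywordSet()
    out = []
    for rec in records:
        low = rec.text.lower()
        if any(p in low for p in kw.phrases):
            out.append(rec)
    return out


def quarter_of(
    ts: datetime,
    window_start: date = STUDY_WINDOW[0],
    window_end: date = STUDY_WINDOW[1],
) -> QuarterIndex:
    """Calendar quarter containing ``ts``; window is half-open [start, end)."""
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    start = datetime(window_start.year, window_start.month, window_start.day, tzinfo=timezone.utc)
    end = datetime(window_end.year, window_end.month, window_end.day, tzinfo=timezone.utc)
    if not (start <= ts < end):
        raise WindowError(
            f"timestamp {ts.isoformat()} outside window [{start.date()}, {end.date()})"
        )
    return QuarterIndex(ts.year, (ts.month - 1) // 3 + 1)


def quarters_in_window(
    window_start: date = STUDY_WINDOW[0], window_end: date = STUDY_WINDOW[1]
) -> list[QuarterIndex]:
    """All quarters intersecting [start, end), in order (12 for the study window)."""
    if window_start >= window_end:
        raise ValueError("window start must precede window end")
    out = []
    year, q = window_start.year, (window_start.month - 1) // 3 + 1
    while date(year, 3 * (q - 1) + 1, 1) < window_end:
        out.append(QuarterIndex(year, q))
        q += 1
        if q == 5:
            year, q = year + 1, 1
    return out


def write_table(rows, path: str | Path, format: str = "csv") -> None:
    """Write a tabular result deterministically (stable columns, 4-dp floats)."""
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
    elif format == "json":
        def _clean(v):
            if isinstance(v, float):
                return round(v, 4)
            return v
        payload = [
            {k: _clean(v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unsupported table format {format!r}")


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a two-rater label CSV with columns tweet_id, rater_id, category."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"tweet_id", "rater_id", "category"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusFormatError(f"label file missing columns: {sorted(missing)}")
    return df
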