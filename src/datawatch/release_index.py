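"""Local release-index snapshot: "is this accession already public?"

A hit short-circuits the repository probe, so the pipeline only spends web
calls on accessions the snapshot does not know about.  Two dialects are
supported: a plain CSV and a single-file SQLite snapshot whose ``gse``
table mirrors the column subset of the GEOmetadb distribution.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional

from datawatch.dates import DateParseError, parse_partial_date

CSV_COLUMNS = ("accession", "repository", "submission_date", "release_date", "status_hint")
STATUS_HINTS = ("public", "private", "unknown")


class IndexError_(ValueError):
    """Malformed index file or invariant-violating record."""


@dataclass(frozen=True)
class ReleaseRecord:
    """One index entry: accession plus submission/release dates."""

    accession: str
    repository: str
    submission_date: date
    release_date: Optional[date] = None
    status_hint: str = "unknown"

    def __post_init__(self) -> None:
        if self.status_hint not in STATUS_HINTS:
            raise IndexError_(f"bad status_hint {self.status_hint!r}")
        if self.release_date is not None and self.release_date < self.submission_date:
            raise IndexError_(
                f"{self.accession}: release_date {self.release_date} precedes "
                f"submission_date {self.submission_date}"
            )
        if self.status_hint == "public" and self.release_date is None:
            raise IndexError_(f"{self.accession}: public record lacks release_date")


class ReleaseIndex:
    """Exact-match map from canonical accession string to ReleaseRecord."""

    def __init__(self, records: dict[str, ReleaseRecord] | None = None):
        self._records = dict(records or {})

    def lookup(self, accession: str) -> Optional[ReleaseRecord]:
        """The record for ``accession``, or None (not-found is a value)."""
        return self._records.get(accession)

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[ReleaseRecord]:
        return [self._records[k] for k in sorted(self._records)]


def _parse_row(row: dict, row_number: int) -> ReleaseRecord:
    try:
        submission = parse_partial_date(row["submission_date"])
        release_raw = (row.get("release_date") or "").strip()
        release = parse_partial_date(release_raw) if release_raw else None
    except DateParseError as exc:
        raise IndexError_(f"row {row_number}: {exc}") from exc
    try:
        return ReleaseRecord(
            accession=row["accession"].strip(),
            repository=row["repository"].strip(),
            submission_date=submission,
            release_date=release,
            status_hint=(row.get("status_hint") or "unknown").strip(),
        )
    except IndexError_ as exc:
        raise IndexError_(f"row {row_number}: {exc}") from exc


def _load_csv(path: Path) -> ReleaseIndex:
    records: dict[str, ReleaseRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(CSV_COLUMNS):
            raise IndexError_(
                f"index header must be {','.join(CSV_COLUMNS)}, got {reader.fieldnames!r}"
            )
        for row_number, row in enumerate(reader, start=2):
            rec = _parse_row(row, row_number)
            records[rec.accession] = rec
    return ReleaseIndex(records)


# GEOmetadb has no literal release_date column; last_update_date of a row in
# the snapshot is used as the public-release proxy (presence in the snapshot
# already implies the series is public).
_SNAPSHOT_QUERY = "SELECT gse, submission_date, last_update_date FROM gse"


def _load_snapshot_db(path: Path) -> ReleaseIndex:
    records: dict[str, ReleaseRecord] = {}
    con = sqlite3.connect(f"file:{path}?mode=ro", uri=True)
    try:
        try:
            rows = con.execute(_SNAPSHOT_QUERY).fetchall()
        except sqlite3.Error as exc:
            raise IndexError_(f"not a gse-table snapshot: {exc}") from exc
    finally:
        con.close()
    for i, (acc, sub, rel) in enumerate(rows, start=1):
        try:
            rec = ReleaseRecord(
                accession=str(acc),
                repository="GEO",
                submission_date=parse_partial_date(str(sub)),
                release_date=parse_partial_date(str(rel)),
                status_hint="public",
            )
        except (DateParseError, IndexError_) as exc:
            raise IndexError_(f"snapshot row {i}: {exc}") from exc
        records[rec.accession] = rec
    return ReleaseIndex(records)


def load_index(path: str | Path, dialect: str = "csv") -> ReleaseIndex:
    """Load a release index from ``path``.

    ``dialect`` is ``"csv"`` (columns accession,repository,submission_date,
    release_date,status_hint) or ``"snapshot_db"`` (SQLite file with a
    GEOmetadb-style ``gse`` table).  Malformed rows and date-invariant
    violations are hard errors naming the offending row.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _load_csv(path)
    if dialect == "snapshot_db":
        return _load_snapshot_db(path)
    raise ValueError(f"unknown index dialect {dialect!r}")
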