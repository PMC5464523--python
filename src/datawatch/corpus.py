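"""Load a corpus of article full texts from a manifest-plus-files layout.

The manifest is a UTF-8 CSV with header ``article_id,publication_date,text_path``;
dates are ISO-8601 prefixes at day, month, or year precision, and text paths
are relative to a caller-supplied root.  Each article's full text lives in
one plain-text file and is treated as opaque character data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterator, Sequence

from datawatch.dates import DateParseError, parse_partial_date

MANIFEST_COLUMNS = ("article_id", "publication_date", "text_path")


class ManifestError(ValueError):
    """Malformed manifest: bad header, duplicate id, or unparseable date."""


@dataclass(frozen=True)
class ArticleRecord:
    """One published article: identifier, publication date, full text."""

    article_id: str
    publication_date: date
    text: str
    source_path: str


@dataclass(frozen=True)
class SkippedRow:
    """A manifest row that could not be loaded (missing text file)."""

    article_id: str
    row_number: int
    reason: str


@dataclass
class Corpus(Sequence):
    """Loaded articles plus per-row load errors (skipped rows)."""

    records: list[ArticleRecord] = field(default_factory=list)
    skipped: list[SkippedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self.records)

    @property
    def article_ids(self) -> list[str]:
        return [r.article_id for r in self.records]


def load_corpus(manifest_path: str | Path, text_root: str | Path) -> Corpus:
    """Load articles listed in ``manifest_path``, texts under ``text_root``.

    Returns one :class:`ArticleRecord` per manifest row, in manifest order.
    A row whose text file is missing is collected into ``Corpus.skipped``
    rather than aborting the load; a duplicate ``article_id`` or an
    unparseable date is a hard :class:`ManifestError` naming the row.
    """
    manifest_path = Path(manifest_path)
    text_root = Path(text_root)
    corpus = Corpus()
    seen: set[str] = set()
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(
            MANIFEST_COLUMNS
        ):
            raise ManifestError(
                f"manifest header must be {','.join(MANIFEST_COLUMNS)}, "
                f"got {reader.fieldnames!r}"
            )
        for row_number, row in enumerate(reader, start=2):
            article_id = (row["article_id"] or "").strip()
            if not article_id:
                raise ManifestError(f"row {row_number}: empty article_id")
            if article_id in seen:
                raise ManifestError(f"row {row_number}: duplicate article_id {article_id!r}")
            seen.add(article_id)
            try:
                pub_date = parse_partial_date(row["publication_date"])
            except DateParseError as exc:
                raise ManifestError(f"row {row_number}: {exc}") from exc
            text_path = text_root / row["text_path"].strip()
            if not text_path.is_file():
                corpus.skipped.append(
                    SkippedRow(article_id, row_number, f"missing text file: {text_path}")
                )
                continue
            corpus.records.append(
                ArticleRecord(
                    article_id=article_id,
                    publication_date=pub_date,
                    text=text_path.read_text(encoding="utf-8"),
                    source_path=str(text_path),
                )
            )
    return corpus
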