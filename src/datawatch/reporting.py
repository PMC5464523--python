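"""Analytics over classified references and release records.

Three products, each exportable to CSV:

* an overdue-count time series on a monthly grid — how many datasets were
  already cited but not yet public at each grid date;
* submission-to-release delay statistics, averaged per release year, plus
  per-record whole-day and whole-year delay accessors;
* a detection-precision report from an evaluation breakdown of candidate
  detections (string false-matches and author typos count as errors;
  legitimately withheld datasets count as correct).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from datawatch.dates import days_between, whole_years_between
from datawatch.pipeline import RunResult
from datawatch.release_index import ReleaseRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverduePoint:
    t: date
    count: int


@dataclass(frozen=True)
class DelayStat:
    year: int
    mean_delay_days: float
    n: int


@dataclass(frozen=True)
class PrecisionReport:
    total_candidates: int
    correct: int
    errors_false_match: int
    errors_typo: int
    withheld_legitimate: int
    precision: float

    @property
    def percent(self) -> int:
        """Precision rendered to the nearest integer percent."""
        return round(self.precision * 100)

    @property
    def percent_str(self) -> str:
        return f"{self.percent}%"


def first_citations(result: RunResult) -> dict[str, date]:
    """Earliest citing-article publication date per accession."""
    first: dict[str, date] = {}
    for s in result.statuses:
        d = s.article_publication_date
        if s.accession not in first or d < first[s.accession]:
            first[s.accession] = d
    return first


def overdue_time_series(
    first_cited: Mapping[str, date],
    release_dates: Mapping[str, Optional[date]],
    grid: Sequence[date],
) -> list[OverduePoint]:
    """Count, at each grid date t, datasets cited on or before t and not yet
    released at t (release date absent or strictly after t).
    """
    if not grid:
        raise ValueError("empty grid")
    if list(grid) != sorted(set(grid)):
        raise ValueError("grid must be strictly increasing")
    points = []
    for t in grid:
        count = 0
        for accession, cited in first_cited.items():
            if cited > t:
                continue
            released = release_dates.get(accession)
            if released is None or released > t:
                count += 1
        points.append(OverduePoint(t=t, count=count))
    return points


def delay_days(submission: date, release: date) -> int:
    """Whole days from submission to release (month-precision convention:
    missing day components have already defaulted to the first of month)."""
    return days_between(submission, release)


def whole_years_elapsed(submission: date, release: date) -> int:
    """Whole calendar years from submission to release; Mar 2005 to Nov 2016
    is an 11-year wait."""
    return whole_years_between(submission, release)


def delay_statistics(
    records: Iterable[ReleaseRecord],
) -> tuple[list[DelayStat], list[ReleaseRecord]]:
    """Mean submission-to-release delay per release year.

    Records without a release date, or with release before submission, are
    excluded; the excluded list is returned (never silently dropped).
    Emitted rows are sorted by year and have n >= 1.
    """
    excluded: list[ReleaseRecord] = []
    by_year: dict[int, list[int]] = {}
    for rec in records:
        if rec.release_date is None or rec.release_date < rec.submission_date:
            logger.warning("excluding record %s from delay statistics", rec.accession)
            excluded.append(rec)
            continue
        by_year.setdefault(rec.release_date.year, []).append(
            delay_days(rec.submission_date, rec.release_date)
        )
    stats = [
        DelayStat(year=year, mean_delay_days=sum(delays) / len(delays), n=len(delays))
        for year, delays in sorted(by_year.items())
    ]
    return stats, excluded


def compute_precision(
    total: int,
    errors_false_match: int,
    errors_typo: int,
    withheld_legitimate: int,
) -> PrecisionReport:
    """Detection precision from an evaluation breakdown.

    ``correct = total - errors_false_match - errors_typo``: legitimately
    withheld datasets are genuine detections and count as correct.  With no
    detections at all the precision is vacuously 1.0.
    """
    counts = (total, errors_false_match, errors_typo, withheld_legitimate)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative counts: {counts}")
    if errors_false_match + errors_typo + withheld_legitimate > total:
        raise ValueError("error and withheld counts exceed total")
    correct = total - errors_false_match - errors_typo
    precision = correct / total if total else 1.0
    return PrecisionReport(
        total_candidates=total,
        correct=correct,
        errors_false_match=errors_false_match,
        errors_typo=errors_typo,
        withheld_legitimate=withheld_legitimate,
        precision=precision,
    )


def export_report(artifact, path: str | Path, kind: str) -> Path:
    """Write an analytics artifact as CSV.

    ``kind`` is ``"series"`` (date,count), ``"delays"``
    (year,mean_delay_days,n), or ``"precision"`` (labeled metric rows).
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if kind == "series":
            writer.writerow(["date", "count"])
            for point in artifact:
                writer.writerow([point.t.isoformat(), point.count])
        elif kind == "delays":
            writer.writerow(["year", "mean_delay_days", "n"])
            for stat in artifact:
                writer.writerow([stat.year, repr(stat.mean_delay_days), stat.n])
        elif kind == "precision":
            writer.writerow(["metric", "value"])
            writer.writerow(["total_candidates", artifact.total_candidates])
            writer.writerow(["correct", artifact.correct])
            writer.writerow(["errors_false_match", artifact.errors_false_match])
            writer.writerow(["errors_typo", artifact.errors_typo])
            writer.writerow(["withheld_legitimate", artifact.withheld_legitimate])
            writer.writerow(["precision", repr(artifact.precision)])
            writer.writerow(["precision_percent", artifact.percent_str])
        else:
            raise ValueError(f"unknown report kind {kind!r}")
    return path


def read_series(path: str | Path) -> list[OverduePoint]:
    """Round-trip reader for a ``series`` CSV export."""
    from datawatch.dates import parse_partial_date

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(OverduePoint(t=parse_partial_date(row["date"]), count=int(row["count"])))
    return out
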