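"""Orchestrate extraction -> index check -> probe -> classification.

Every deduplicated (article, accession) reference gets exactly one
classification:

* ``released`` — the accession was found in the local release index
  (evidence ``index_hit``) or the status page showed it public
  (``probe_public``);
* ``overdue``  — the page says the dataset is still private although the
  citing article is already published (``probe_private``);
* ``invalid``  — the page says no such accession exists (``probe_invalid``);
* ``unknown``  — the probe could not decide (``probe_unknown``).

Index hits are never probed, so the number of transport calls equals the
number of unique accessions missing from the index.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Optional

from datawatch.config import MonitorConfig
from datawatch.corpus import Corpus
from datawatch.dates import parse_partial_date
from datawatch.extraction import (
    AccessionCandidate,
    compile_patterns,
    deduplicate,
    extract_candidates,
)
from datawatch.probe import ProbeCache, ProbeResult, RateLimiter, Transport
from datawatch.probe import INVALID as PROBE_INVALID
from datawatch.probe import PRIVATE as PROBE_PRIVATE
from datawatch.probe import PUBLIC as PROBE_PUBLIC
from datawatch.probe import UNKNOWN as PROBE_UNKNOWN
from datawatch.probe import probe as _probe
from datawatch.release_index import ReleaseIndex, ReleaseRecord

logger = logging.getLogger(__name__)

RELEASED = "released"
OVERDUE = "overdue"
INVALID = "invalid"
UNKNOWN = "unknown"

EVIDENCE_INDEX_HIT = "index_hit"
EVIDENCE_PROBE = {
    PROBE_PUBLIC: "probe_public",
    PROBE_PRIVATE: "probe_private",
    PROBE_INVALID: "probe_invalid",
    PROBE_UNKNOWN: "probe_unknown",
}
CLASSIFICATION_BY_PROBE = {
    PROBE_PUBLIC: RELEASED,
    PROBE_PRIVATE: OVERDUE,
    PROBE_INVALID: INVALID,
    PROBE_UNKNOWN: UNKNOWN,
}


class PipelineContractError(RuntimeError):
    """Index hit and probe result supplied together, or neither."""


@dataclass(frozen=True)
class ReferenceStatus:
    """Final classification of one (article, accession) reference."""

    accession: str
    repository: str
    article_id: str
    article_publication_date: date
    classification: str
    release_date: Optional[date]
    evidence: str


@dataclass
class RunResult:
    statuses: list[ReferenceStatus]
    metadata: dict = field(default_factory=dict)

    @property
    def overdue(self) -> list[ReferenceStatus]:
        return sorted(
            (s for s in self.statuses if s.classification == OVERDUE),
            key=lambda s: (s.accession, s.article_id),
        )

    def counts(self) -> dict[str, int]:
        out = {RELEASED: 0, OVERDUE: 0, INVALID: 0, UNKNOWN: 0}
        for s in self.statuses:
            out[s.classification] += 1
        return out

    def classification_by_accession(self) -> dict[str, str]:
        return {s.accession: s.classification for s in self.statuses}


def classify_reference(
    candidate: AccessionCandidate,
    index_result: Optional[ReleaseRecord],
    probe_result: Optional[ProbeResult],
    article_date: date,
) -> ReferenceStatus:
    """Map (index lookup, probe outcome) to a ReferenceStatus.

    Exactly one of ``index_result`` / ``probe_result`` must be supplied:
    a hit short-circuits probing, a miss requires a probe.
    """
    if (index_result is None) == (probe_result is None):
        raise PipelineContractError(
            "exactly one of index_result / probe_result must be present "
            f"for {candidate.accession}"
        )
    if index_result is not None:
        classification, evidence = RELEASED, EVIDENCE_INDEX_HIT
        release_date = index_result.release_date
    else:
        assert probe_result is not None
        classification = CLASSIFICATION_BY_PROBE[probe_result.status]
        evidence = EVIDENCE_PROBE[probe_result.status]
        release_date = None
    return ReferenceStatus(
        accession=candidate.accession,
        repository=candidate.repository,
        article_id=candidate.article_id,
        article_publication_date=article_date,
        classification=classification,
        release_date=release_date,
        evidence=evidence,
    )


def run_monitor(
    corpus: Corpus,
    index: ReleaseIndex,
    transport: Transport,
    config: Optional[MonitorConfig] = None,
    run_date: Optional[date] = None,
    cache: Optional[ProbeCache] = None,
    run_store: Optional[str | Path] = None,
) -> RunResult:
    """Run the full monitor over a loaded corpus and index.

    Each unique accession is probed at most once per run; articles dated
    after ``run_date`` (default: today) are excluded with a warning.  When
    ``run_store`` is given the result is persisted there as a timestamped
    run directory.
    """
    config = config or MonitorConfig()
    run_date = run_date or date.today()
    registry = compile_patterns(config.patterns, case_sensitive=config.case_sensitive)
    rate_limiter = RateLimiter(config.rate_limit_seconds)

    articles = {a.article_id: a for a in corpus}
    candidates: list[AccessionCandidate] = []
    excluded_articles = []
    for article in corpus:
        if article.publication_date > run_date:
            logger.warning(
                "excluding article %s dated %s after run date %s",
                article.article_id,
                article.publication_date,
                run_date,
            )
            excluded_articles.append(article.article_id)
            continue
        candidates.extend(extract_candidates(article, registry, config.context_width))
    references = deduplicate(candidates)

    probe_results: dict[tuple[str, str], ProbeResult] = {}
    transport_calls = 0
    statuses: list[ReferenceStatus] = []
    for ref in references:
        index_hit = index.lookup(ref.accession)
        probe_result = None
        if index_hit is None:
            key = (ref.repository, ref.accession)
            if key not in probe_results:
                signatures = config.signatures.get(ref.repository)
                if signatures is None:
                    probe_results[key] = ProbeResult(
                        ref.accession,
                        ref.repository,
                        PROBE_UNKNOWN,
                        error=f"no signature set for {ref.repository}",
                    )
                else:
                    probe_results[key] = _probe(
                        ref.accession,
                        ref.repository,
                        transport,
                        signatures,
                        cache=cache,
                        rate_limiter=rate_limiter,
                        patterns=config.patterns,
                    )
                    transport_calls += 1
            probe_result = probe_results[key]
        statuses.append(
            classify_reference(
                ref, index_hit, probe_result, articles[ref.article_id].publication_date
            )
        )

    result = RunResult(
        statuses=statuses,
        metadata={
            "run_date": run_date.isoformat(),
            "n_articles": len(corpus),
            "n_articles_excluded": len(excluded_articles),
            "n_candidates": len(candidates),
            "n_references": len(references),
            "transport_calls": transport_calls,
            "counts": None,  # filled below
        },
    )
    result.metadata["counts"] = result.counts()
    logger.info("run complete: %s", result.metadata)
    if run_store is not None:
        save_run(result, Path(run_store))
    return result


# ---------------------------------------------------------------------------
# run persistence (append-only store of delimited run results)

_STATUS_COLUMNS = (
    "accession",
    "repository",
    "article_id",
    "article_publication_date",
    "classification",
    "release_date",
    "evidence",
)


def save_run(result: RunResult, run_dir: str | Path) -> Path:
    """Persist a run as ``<run_dir>/statuses.csv`` + ``meta.json``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    with open(run_dir / "statuses.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_STATUS_COLUMNS)
        for s in result.statuses:
            writer.writerow(
                [
                    s.accession,
                    s.repository,
                    s.article_id,
                    s.article_publication_date.isoformat(),
                    s.classification,
                    s.release_date.isoformat() if s.release_date else "",
                    s.evidence,
                ]
            )
    meta = dict(result.metadata)
    meta.setdefault("saved_at", datetime.now(timezone.utc).isoformat())
    (run_dir / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return run_dir


def load_run(run_dir: str | Path) -> RunResult:
    run_dir = Path(run_dir)
    statuses = []
    with open(run_dir / "statuses.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            statuses.append(
                ReferenceStatus(
                    accession=row["accession"],
                    repository=row["repository"],
                    article_id=row["article_id"],
                    article_publication_date=parse_partial_date(
                        row["article_publication_date"]
                    ),
                    classification=row["classification"],
                    release_date=(
                        parse_partial_date(row["release_date"]) if row["release_date"] else None
                    ),
                    evidence=row["evidence"],
                )
            )
    meta_path = run_dir / "meta.json"
    metadata = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.is_file() else {}
    return RunResult(statuses=statuses, metadata=metadata)


@dataclass(frozen=True)
class RunDiff:
    newly_overdue: tuple[str, ...]
    newly_released: tuple[str, ...]
    still_overdue: tuple[str, ...]


def diff_runs(previous: RunResult, current: RunResult) -> RunDiff:
    """Accession-level transitions between two runs of the same corpus scope.

    ``newly_released`` = overdue before, released now; ``newly_overdue`` =
    overdue now but not before (including accessions absent before);
    ``still_overdue`` = overdue in both.
    """
    prev = previous.classification_by_accession()
    cur = current.classification_by_accession()
    prev_overdue = {a for a, c in prev.items() if c == OVERDUE}
    cur_overdue = {a for a, c in cur.items() if c == OVERDUE}
    newly_released = {a for a in prev_overdue if cur.get(a) == RELEASED}
    return RunDiff(
        newly_overdue=tuple(sorted(cur_overdue - prev_overdue)),
        newly_released=tuple(sorted(newly_released)),
        still_overdue=tuple(sorted(prev_overdue & cur_overdue)),
    )
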