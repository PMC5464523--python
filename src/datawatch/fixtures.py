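"""Synthetic corpora, release indices, and status-page fixtures.

Everything the pipeline consumes in production — article texts with a
manifest, a release-index CSV, and repository status pages — is generated
here with a known ground truth, so every stage is testable offline.  One
seeded pseudo-random stream drives all choices; a fixed seed yields
byte-identical output.

Candidate labels mirror the three real-world detection modes:

* ``true_citation`` — a genuine dataset reference;
* ``typo``          — a well-formed accession that does not exist at the
  repository (the author cited a wrong number);
* ``spurious``      — an accession-shaped token in a non-dataset context
  (e.g. a soil-sample name that happens to look like a series accession).
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

from datawatch.dates import parse_partial_date
from datawatch.extraction import GEO, SRA
from datawatch.pipeline import OVERDUE, RunResult
from datawatch.reporting import PrecisionReport, compute_precision

TRUE_CITATION = "true_citation"
TYPO = "typo"
SPURIOUS = "spurious"

_PREFIX = {GEO: "GSE", SRA: "SRX"}

_FILLER_SENTENCES = (
    "We analyzed transcriptional profiles across multiple tissues.",
    "Differential expression was assessed with standard methods.",
    "All experiments were performed in triplicate.",
    "Samples were processed following the manufacturer's protocol.",
    "Statistical significance was evaluated at the usual threshold.",
)
_CITATION_TEMPLATES = (
    "The data have been deposited in the repository under accession {acc} and are described in the methods.",
    "Raw data are available from the archive under accession {acc} for all samples.",
    "Expression profiles were submitted under accession {acc} prior to publication.",
)
_SPURIOUS_TEMPLATE = (
    "Soil sample {acc} was collected from the northern plot during the field survey."
)

INVALID_PAGE_SIGNATURE = "Could not find a public or private accession"
PRIVATE_PAGE_SIGNATURE = "is currently private"


class FixtureSpecError(ValueError):
    """An impossible or inconsistent fixture specification."""


@dataclass(frozen=True)
class FixtureSpec:
    n_articles: int
    n_datasets: int
    fraction_private: float = 0.3
    typo_rate: float = 0.0
    spurious_rate: float = 0.0
    date_range: tuple[date, date] = (date(2014, 1, 1), date(2016, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 0 or self.n_datasets < 0:
            raise FixtureSpecError("counts must be non-negative")
        for name in ("fraction_private", "typo_rate", "spurious_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1], got {v}")
        start, end = self.date_range
        if start > end:
            raise FixtureSpecError("date_range start after end")
        if self.typo_rate > 0 and self.n_datasets == 0:
            raise FixtureSpecError("typo_rate > 0 requires n_datasets > 0")


@dataclass(frozen=True)
class TruthDataset:
    accession: str
    repository: str
    submission_date: date
    release_date: Optional[date]
    cited_by: tuple[str, ...]

    @property
    def is_private(self) -> bool:
        return self.release_date is None


@dataclass(frozen=True)
class TruthCandidate:
    accession: str
    article_id: str
    label: str


@dataclass
class GroundTruth:
    datasets: dict[str, TruthDataset] = field(default_factory=dict)
    candidates: list[TruthCandidate] = field(default_factory=list)

    def label_of(self, accession: str) -> Optional[str]:
        for cand in self.candidates:
            if cand.accession == accession:
                return cand.label
        return None

    def overdue_accessions(self) -> set[str]:
        """Cited, genuinely private dataset accessions (the overdue truth)."""
        return {
            d.accession for d in self.datasets.values() if d.is_private and d.cited_by
        }


@dataclass(frozen=True)
class Fixture:
    out_dir: Path
    manifest_path: Path
    text_root: Path
    index_path: Path
    pages_dir: Path
    truth: GroundTruth


def _random_date(rng: random.Random, start: date, end: date) -> date:
    return start + timedelta(days=rng.randint(0, (end - start).days))


def _write_truth(truth: GroundTruth, out_dir: Path) -> None:
    with open(out_dir / "truth_datasets.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession", "repository", "submission_date", "release_date", "cited_by"])
        for acc in sorted(truth.datasets):
            d = truth.datasets[acc]
            writer.writerow(
                [
                    d.accession,
                    d.repository,
                    d.submission_date.isoformat(),
                    d.release_date.isoformat() if d.release_date else "",
                    ";".join(d.cited_by),
                ]
            )
    with open(out_dir / "truth_candidates.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession", "article_id", "label"])
        for cand in truth.candidates:
            writer.writerow([cand.accession, cand.article_id, cand.label])


def load_truth(out_dir: str | Path) -> GroundTruth:
    out_dir = Path(out_dir)
    truth = GroundTruth()
    with open(out_dir / "truth_datasets.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            truth.datasets[row["accession"]] = TruthDataset(
                accession=row["accession"],
                repository=row["repository"],
                submission_date=parse_partial_date(row["submission_date"]),
                release_date=(
                    parse_partial_date(row["release_date"]) if row["release_date"] else None
                ),
                cited_by=tuple(row["cited_by"].split(";")) if row["cited_by"] else (),
            )
    with open(out_dir / "truth_candidates.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            truth.candidates.append(
                TruthCandidate(row["accession"], row["article_id"], row["label"])
            )
    return truth


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Write a complete offline fixture under ``out_dir``.

    Layout: ``manifest.csv`` + ``texts/<article_id>.txt`` (the corpus),
    ``index.csv`` (released datasets only), ``pages/<accession>.html``
    (status pages: public for released, private-signature for private,
    invalid-signature for typo'd and spurious accessions), and the two
    ground-truth CSVs.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    rng = random.Random(spec.seed)
    start, end = spec.date_range

    text_root = out_dir / "texts"
    pages_dir = out_dir / "pages"
    out_dir.mkdir(parents=True, exist_ok=True)
    text_root.mkdir(exist_ok=True)
    pages_dir.mkdir(exist_ok=True)

    truth = GroundTruth()
    article_ids = [f"PMC{1000000 + i}" for i in range(spec.n_articles)]
    article_dates = [_random_date(rng, start, end) for _ in article_ids]
    article_sentences: dict[str, list[str]] = {aid: [] for aid in article_ids}

    # With no articles nothing can be cited: empty corpus, empty truth.
    embed = spec.n_articles > 0
    n_typos = round(spec.typo_rate * spec.n_datasets) if embed else 0
    n_spurious = round(spec.spurious_rate * spec.n_datasets) if embed else 0

    # One shared pool of unique accession numbers across all candidate kinds.
    numbers = rng.sample(range(10000, 1000000), spec.n_datasets + n_typos + n_spurious)
    pages: dict[str, str] = {}
    index_rows: list[tuple[str, str, date, date]] = []

    if embed:
        n_private = round(spec.fraction_private * spec.n_datasets)
        for i in range(spec.n_datasets):
            repository = rng.choice((GEO, SRA))
            accession = f"{_PREFIX[repository]}{numbers[i]}"
            submission = _random_date(rng, start, end)
            private = i < n_private
            if private:
                release = None
                pages[accession] = (
                    f"<html><body>Accession {accession} {PRIVATE_PAGE_SIGNATURE} "
                    "and is scheduled to be released once the citing manuscript "
                    "is published.</body></html>"
                )
            else:
                release = _random_date(rng, submission, end)
                index_rows.append((accession, repository, submission, release))
                pages[accession] = (
                    f"<html><body>Series {accession}&nbsp;&nbsp;Status: Public "
                    f"on {release.isoformat()}</body></html>"
                )
            citing = rng.randrange(spec.n_articles)
            cited_by = [article_ids[citing]]
            if spec.n_articles > 1 and rng.random() < 0.2:
                other = rng.randrange(spec.n_articles)
                if article_ids[other] not in cited_by:
                    cited_by.append(article_ids[other])
            for aid in cited_by:
                template = rng.choice(_CITATION_TEMPLATES)
                article_sentences[aid].append(template.format(acc=accession))
                truth.candidates.append(TruthCandidate(accession, aid, TRUE_CITATION))
            truth.datasets[accession] = TruthDataset(
                accession=accession,
                repository=repository,
                submission_date=submission,
                release_date=release,
                cited_by=tuple(cited_by),
            )

        for j in range(n_typos):
            repository = rng.choice((GEO, SRA))
            accession = f"{_PREFIX[repository]}{numbers[spec.n_datasets + j]}"
            aid = article_ids[rng.randrange(spec.n_articles)]
            template = rng.choice(_CITATION_TEMPLATES)
            article_sentences[aid].append(template.format(acc=accession))
            truth.candidates.append(TruthCandidate(accession, aid, TYPO))
            pages[accession] = (
                f"<html><body>{INVALID_PAGE_SIGNATURE} &quot;{accession}&quot;."
                "</body></html>"
            )

        for j in range(n_spurious):
            repository = rng.choice((GEO, SRA))
            accession = f"{_PREFIX[repository]}{numbers[spec.n_datasets + n_typos + j]}"
            aid = article_ids[rng.randrange(spec.n_articles)]
            article_sentences[aid].append(_SPURIOUS_TEMPLATE.format(acc=accession))
            truth.candidates.append(TruthCandidate(accession, aid, SPURIOUS))
            pages[accession] = (
                f"<html><body>{INVALID_PAGE_SIGNATURE} &quot;{accession}&quot;."
                "</body></html>"
            )

    # Corpus files.
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["article_id", "publication_date", "text_path"])
        for aid, pub_date in zip(article_ids, article_dates):
            sentences = list(article_sentences[aid])
            filler = list(_FILLER_SENTENCES)
            rng.shuffle(filler)
            body = " ".join(filler[:2] + sentences + filler[2:4])
            (text_root / f"{aid}.txt").write_text(body, encoding="utf-8")
            writer.writerow([aid, pub_date.isoformat(), f"{aid}.txt"])

    # Release index: only released datasets appear.
    index_path = out_dir / "index.csv"
    with open(index_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession", "repository", "submission_date", "release_date", "status_hint"])
        for accession, repository, submission, release in sorted(index_rows):
            writer.writerow(
                [accession, repository, submission.isoformat(), release.isoformat(), "public"]
            )

    for accession in sorted(pages):
        (pages_dir / f"{accession}.html").write_text(pages[accession], encoding="utf-8")

    _write_truth(truth, out_dir)
    return Fixture(
        out_dir=out_dir,
        manifest_path=manifest_path,
        text_root=text_root,
        index_path=index_path,
        pages_dir=pages_dir,
        truth=truth,
    )


class TruthMismatchError(RuntimeError):
    """The run result references accessions the truth has never seen."""


def score_against_truth(result: RunResult, truth: GroundTruth) -> tuple[PrecisionReport, float]:
    """Score a pipeline run against the generator's ground truth.

    Detections are the unique accessions the run classified as overdue.
    Typo and spurious detections count as errors; recall is the fraction of
    truly overdue (cited, private) datasets that were detected.
    """
    labels: dict[str, str] = {}
    for cand in truth.candidates:
        labels[cand.accession] = cand.label
    detections = sorted({s.accession for s in result.statuses if s.classification == OVERDUE})
    unknown = [acc for acc in detections if acc not in labels]
    if unknown:
        raise TruthMismatchError(f"detections not present in ground truth: {unknown}")
    n_typo = sum(1 for acc in detections if labels[acc] == TYPO)
    n_spurious = sum(1 for acc in detections if labels[acc] == SPURIOUS)
    report = compute_precision(
        total=len(detections),
        errors_false_match=n_spurious,
        errors_typo=n_typo,
        withheld_legitimate=0,
    )
    truth_overdue = truth.overdue_accessions()
    if truth_overdue:
        recall = len(truth_overdue & set(detections)) / len(truth_overdue)
    else:
        recall = 1.0
    return report, recall
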