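"""Locate candidate dataset accession identifiers in article text.

Each repository contributes a prefix-plus-digits pattern (``GSE`` for GEO
series, ``SRX`` for SRA experiments by default).  Matching is literal and
boundary-aware: a hit is rejected when the character adjacent to either
end of the match is alphanumeric, so embedded tokens like ``XGSE123`` or
``GSE456ABC`` never produce candidates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from datawatch.corpus import ArticleRecord

GEO = "GEO"
SRA = "SRA"

DEFAULT_CONTEXT_WIDTH = 60

_ALNUM = "A-Za-z0-9"


class PatternError(ValueError):
    """Invalid or conflicting accession pattern specifications."""


@dataclass(frozen=True)
class AccessionPattern:
    """Prefix-plus-digit-run shape of one repository's accessions."""

    repository: str
    prefix: str
    digit_min: int = 1
    digit_max: int = 8

    def __post_init__(self) -> None:
        if not self.prefix or not self.prefix.isalpha() or not self.prefix.isupper():
            raise PatternError(f"prefix must be non-empty uppercase alphabetic: {self.prefix!r}")
        if not self.repository:
            raise PatternError("repository must be non-empty")
        if not (1 <= self.digit_min <= self.digit_max):
            raise PatternError(
                f"need 1 <= digit_min <= digit_max, got {self.digit_min}..{self.digit_max}"
            )

    def matches(self, accession: str, case_sensitive: bool = True) -> bool:
        """Whether ``accession`` as a whole token has this pattern's shape."""
        acc = accession if case_sensitive else accession.upper()
        if not acc.startswith(self.prefix):
            return False
        digits = acc[len(self.prefix) :]
        return digits.isdigit() and self.digit_min <= len(digits) <= self.digit_max


DEFAULT_PATTERNS: tuple[AccessionPattern, ...] = (
    AccessionPattern(repository=GEO, prefix="GSE"),
    AccessionPattern(repository=SRA, prefix="SRX"),
)


@dataclass(frozen=True)
class AccessionCandidate:
    """A located accession string inside one article.

    ``span`` is 0-based half-open over the article text; ``context`` is the
    surrounding text window, clipped at the text ends.
    """

    accession: str
    repository: str
    article_id: str
    start: int
    end: int
    context: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


class PatternRegistry:
    """Compiled, scan-ready set of accession patterns."""

    def __init__(self, specs: Sequence[AccessionPattern], case_sensitive: bool = True):
        if not specs:
            raise PatternError("at least one pattern spec is required")
        keys = [(s.repository, s.prefix) for s in specs]
        if len(set(keys)) != len(keys):
            raise PatternError("duplicate (repository, prefix) pattern spec")
        self.specs = tuple(specs)
        self.case_sensitive = case_sensitive
        flags = 0 if case_sensitive else re.IGNORECASE
        self._compiled = [
            (
                spec,
                re.compile(
                    rf"(?<![{_ALNUM}]){re.escape(spec.prefix)}"
                    rf"[0-9]{{{spec.digit_min},{spec.digit_max}}}(?![{_ALNUM}])",
                    flags,
                ),
            )
            for spec in specs
        ]

    def scan(self, text: str) -> list[tuple[AccessionPattern, int, int, str]]:
        """All boundary-respecting maximal matches, in span order."""
        hits = []
        for spec, rx in self._compiled:
            for m in rx.finditer(text):
                hits.append((spec, m.start(), m.end(), m.group(0)))
        hits.sort(key=lambda h: (h[1], h[2], h[0].repository))
        return hits

    def pattern_for(self, repository: str) -> AccessionPattern:
        for spec in self.specs:
            if spec.repository == repository:
                return spec
        raise PatternError(f"no pattern registered for repository {repository!r}")


def compile_patterns(
    specs: Sequence[AccessionPattern] = DEFAULT_PATTERNS, case_sensitive: bool = True
) -> PatternRegistry:
    """Build a registry that scans for all ``specs`` in one pass."""
    return PatternRegistry(specs, case_sensitive=case_sensitive)


def extract_candidates(
    article: ArticleRecord,
    registry: PatternRegistry,
    context_width: int = DEFAULT_CONTEXT_WIDTH,
) -> list[AccessionCandidate]:
    """All accession candidates in ``article.text``, left-to-right.

    Pure function of (text, registry): the accession is the matched text
    verbatim (leading zeros preserved), and ``text[start:end] == accession``.
    """
    text = article.text
    out = []
    for spec, start, end, matched in registry.scan(text):
        out.append(
            AccessionCandidate(
                accession=matched,
                repository=spec.repository,
                article_id=article.article_id,
                start=start,
                end=end,
                context=text[max(0, start - context_width) : end + context_width],
            )
        )
    return out


def deduplicate(candidates: Iterable[AccessionCandidate]) -> list[AccessionCandidate]:
    """One reference per distinct (accession, article_id) pair.

    The earliest mention's span/context is kept as representative; output is
    ordered by article then accession.  Idempotent.
    """
    best: dict[tuple[str, str], AccessionCandidate] = {}
    for cand in candidates:
        key = (cand.article_id, cand.accession)
        if key not in best or cand.start < best[key].start:
            best[key] = cand
    return [best[k] for k in sorted(best)]
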