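"""Query a repository's accession-status interface and parse the response.

Status is decided by substring search over the raw response body, not by
structural HTML parsing: known *invalid* signatures win over *private*
signatures, which win over the fallback *public* test (the accession string
itself appearing in the page).  A page with neither a signature nor the
accession is ``unknown`` — never silently public.

Transports are pluggable callables ``url -> body text`` (raising
:class:`TransportError` on failure), so the whole probe path runs against
on-disk fixture pages as readily as against the live endpoints.
"""

from __future__ import annotations

import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Optional

from datawatch.extraction import DEFAULT_PATTERNS, GEO, SRA, AccessionPattern

INVALID = "invalid"
PRIVATE = "private"
PUBLIC = "public"
UNKNOWN = "unknown"

URL_TEMPLATES = {
    GEO: "https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc={accession}",
    SRA: "https://www.ncbi.nlm.nih.gov/sra/?term={accession}",
}

DEFAULT_RATE_LIMIT_SECONDS = 0.4
DEFAULT_CACHE_TTL_SECONDS = 24 * 3600

Transport = Callable[[str], str]


class TransportError(Exception):
    """A transport failed to produce a response body."""


class ProbeConfigError(ValueError):
    """Unknown repository, malformed signatures, or mismatched accession."""


@dataclass(frozen=True)
class SignatureSet:
    """Literal response-page fragments that signal invalid/private status."""

    repository: str
    invalid_signatures: tuple[str, ...]
    private_signatures: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.invalid_signatures or not self.private_signatures:
            raise ProbeConfigError("signature lists must be non-empty")
        overlap = set(self.invalid_signatures) & set(self.private_signatures)
        if overlap:
            raise ProbeConfigError(f"signatures in both lists: {sorted(overlap)}")


def default_signatures() -> dict[str, SignatureSet]:
    """Per-repository defaults covering the two known NCBI status phrases."""
    return {
        repo: SignatureSet(
            repository=repo,
            invalid_signatures=("Could not find a public or private accession",),
            private_signatures=("is currently private",),
        )
        for repo in (GEO, SRA)
    }


@dataclass(frozen=True)
class ProbeResult:
    accession: str
    repository: str
    status: str
    matched_signature: Optional[str] = None
    retrieved_at: Optional[datetime] = None
    error: Optional[str] = None


def build_query_url(
    repository: str,
    accession: str,
    patterns: tuple[AccessionPattern, ...] = DEFAULT_PATTERNS,
) -> str:
    """The repository's status-page URL with ``accession`` substituted."""
    if repository not in URL_TEMPLATES:
        raise ProbeConfigError(f"no URL template for repository {repository!r}")
    for pattern in patterns:
        if pattern.repository == repository and pattern.matches(accession):
            break
    else:
        raise ProbeConfigError(
            f"accession {accession!r} does not match any {repository} pattern"
        )
    return URL_TEMPLATES[repository].format(accession=urllib.parse.quote(accession))


def parse_status_page(
    repository: str, page_text: str, signatures: SignatureSet, accession: str
) -> tuple[str, Optional[str]]:
    """Classify a response body; returns (status, matched signature or None).

    Precedence is total: invalid > private > public > unknown.
    """
    for sig in signatures.invalid_signatures:
        if sig in page_text:
            return INVALID, sig
    for sig in signatures.private_signatures:
        if sig in page_text:
            return PRIVATE, sig
    if accession in page_text:
        return PUBLIC, None
    return UNKNOWN, None


class RateLimiter:
    """Enforce a minimum wall-clock interval between live calls."""

    def __init__(self, min_interval: float = DEFAULT_RATE_LIMIT_SECONDS):
        self.min_interval = min_interval
        self._last: Optional[float] = None

    def wait(self) -> None:
        if self.min_interval <= 0:
            return
        now = time.monotonic()
        if self._last is not None:
            remaining = self._last + self.min_interval - now
            if remaining > 0:
                time.sleep(remaining)
                now = time.monotonic()
        self._last = now


@dataclass
class ProbeCache:
    """TTL cache keyed by (repository, accession)."""

    ttl_seconds: float = DEFAULT_CACHE_TTL_SECONDS
    _entries: dict[tuple[str, str], tuple[ProbeResult, float]] = field(default_factory=dict)

    def get(self, repository: str, accession: str) -> Optional[ProbeResult]:
        entry = self._entries.get((repository, accession))
        if entry is None:
            return None
        result, stored_at = entry
        if time.monotonic() - stored_at > self.ttl_seconds:
            del self._entries[(repository, accession)]
            return None
        return result

    def put(self, result: ProbeResult) -> None:
        self._entries[(result.repository, result.accession)] = (result, time.monotonic())


def probe(
    accession: str,
    repository: str,
    transport: Transport,
    signatures: SignatureSet,
    cache: Optional[ProbeCache] = None,
    rate_limiter: Optional[RateLimiter] = None,
    patterns: tuple[AccessionPattern, ...] = DEFAULT_PATTERNS,
) -> ProbeResult:
    """Resolve one accession's live status; never raises past the pipeline.

    A fresh cache entry is returned without any transport call; otherwise a
    single transport call is made (rate-limited), parsed, cached, returned.
    Transport failures degrade to status ``unknown`` with the error recorded.
    """
    if cache is not None:
        hit = cache.get(repository, accession)
        if hit is not None:
            return hit
    url = build_query_url(repository, accession, patterns=patterns)
    if rate_limiter is not None:
        rate_limiter.wait()
    now = datetime.now(timezone.utc)
    try:
        body = transport(url)
    except TransportError as exc:
        result = ProbeResult(accession, repository, UNKNOWN, retrieved_at=now, error=str(exc))
    else:
        status, sig = parse_status_page(repository, body, signatures, accession)
        result = ProbeResult(accession, repository, status, matched_signature=sig, retrieved_at=now)
    if cache is not None:
        cache.put(result)
    return result


class FixtureTransport:
    """On-disk transport: serves ``<pages_dir>/<accession>.html`` per URL."""

    def __init__(self, pages_dir: str | Path):
        self.pages_dir = Path(pages_dir)
        self.calls = 0

    @staticmethod
    def accession_from_url(url: str) -> str:
        query = urllib.parse.parse_qs(urllib.parse.urlparse(url).query)
        for key in ("acc", "term"):
            if key in query:
                return query[key][0]
        raise TransportError(f"no accession parameter in URL: {url}")

    def __call__(self, url: str) -> str:
        self.calls += 1
        accession = self.accession_from_url(url)
        page = self.pages_dir / f"{accession}.html"
        if not page.is_file():
            raise TransportError(f"no fixture page for {accession}")
        return page.read_text(encoding="utf-8")


class LiveTransport:
    """Plain HTTP GET transport for live probing."""

    def __init__(self, timeout: float = 30.0, retries: int = 2):
        self.timeout = timeout
        self.retries = retries

    def __call__(self, url: str) -> str:
        last_error: Exception | None = None
        for _ in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read().decode("utf-8", errors="replace")
            except Exception as exc:  # noqa: BLE001 - folded into TransportError
                last_error = exc
        raise TransportError(f"GET {url} failed: {last_error}")
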