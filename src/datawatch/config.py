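"""Run configuration: patterns, signatures, rate limit, cache TTL.

Loaded from a small YAML file; every field has a sensible default so the
pipeline runs with no configuration at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from datawatch.extraction import DEFAULT_CONTEXT_WIDTH, DEFAULT_PATTERNS, AccessionPattern
from datawatch.probe import (
    DEFAULT_CACHE_TTL_SECONDS,
    DEFAULT_RATE_LIMIT_SECONDS,
    SignatureSet,
    default_signatures,
)


@dataclass
class MonitorConfig:
    patterns: tuple[AccessionPattern, ...] = DEFAULT_PATTERNS
    signatures: dict[str, SignatureSet] = field(default_factory=default_signatures)
    rate_limit_seconds: float = DEFAULT_RATE_LIMIT_SECONDS
    cache_ttl_seconds: float = DEFAULT_CACHE_TTL_SECONDS
    context_width: int = DEFAULT_CONTEXT_WIDTH
    case_sensitive: bool = True


def load_config(path: str | Path) -> MonitorConfig:
    """Read a YAML config; absent keys keep their defaults.

    Recognized keys: ``patterns`` (list of {repository, prefix, digit_min,
    digit_max}), ``signatures`` (repository -> {invalid: [...], private:
    [...]}), ``rate_limit_seconds``, ``cache_ttl_seconds``,
    ``context_width``, ``case_sensitive``.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = MonitorConfig()
    if "patterns" in raw:
        cfg.patterns = tuple(
            AccessionPattern(
                repository=p["repository"],
                prefix=p["prefix"],
                digit_min=int(p.get("digit_min", 1)),
                digit_max=int(p.get("digit_max", 8)),
            )
            for p in raw["patterns"]
        )
    if "signatures" in raw:
        cfg.signatures = {
            repo: SignatureSet(
                repository=repo,
                invalid_signatures=tuple(spec["invalid"]),
                private_signatures=tuple(spec["private"]),
            )
            for repo, spec in raw["signatures"].items()
        }
    if "rate_limit_seconds" in raw:
        cfg.rate_limit_seconds = float(raw["rate_limit_seconds"])
    if "cache_ttl_seconds" in raw:
        cfg.cache_ttl_seconds = float(raw["cache_ttl_seconds"])
    if "context_width" in raw:
        cfg.context_width = int(raw["context_width"])
    if "case_sensitive" in raw:
        cfg.case_sensitive = bool(raw["case_sensitive"])
    return cfg
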