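from __future__ import annotations

from datetime import date
from pathlib import Path

import pytest

from datawatch.config import MonitorConfig
from datawatch.corpus import ArticleRecord, load_corpus
from datawatch.fixtures import FixtureSpec, generate_fixture
from datawatch.probe import FixtureTransport
from datawatch.release_index import load_index


@pytest.fixture
def fast_config() -> MonitorConfig:
    """Config with the rate limiter off: fixture transports need no politeness."""
    return MonitorConfig(rate_limit_seconds=0.0)


def make_article(text: str, article_id: str = "PMC1", pub: date = date(2016, 1, 1)) -> ArticleRecord:
    return ArticleRecord(
        article_id=article_id, publication_date=pub, text=text, source_path="<memory>"
    )


@pytest.fixture
def small_fixture(tmp_path: Path):
    """A small generated corpus/index/pages fixture with ground truth."""
    spec = FixtureSpec(
        n_articles=15,
        n_datasets=25,
        fraction_private=0.4,
        typo_rate=0.1,
        spurious_rate=0.1,
        seed=11,
    )
    return generate_fixture(spec, tmp_path / "fx")


@pytest.fixture
def loaded_fixture(small_fixture):
    corpus = load_corpus(small_fixture.manifest_path, small_fixture.text_root)
    index = load_index(small_fixture.index_path)
    transport = FixtureTransport(small_fixture.pages_dir)
    return small_fixture, corpus, index, transport
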