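# datawatch

Detect datasets that are cited in published articles yet remain private
("overdue") in genomics repositories.

The pipeline:

1. **Extract** — scan article full text for accession identifiers using
   per-repository patterns (GEO series `GSE…`, SRA experiments `SRX…` by
   default; extensible via config), with token-boundary rules so embedded
   strings like `XGSE123` are never matched.
2. **Index check** — look each unique accession up in a local release-index
   snapshot (plain CSV, or an SQLite file with a GEOmetadb-style `gse`
   table). A hit means the dataset is already public and no web call is made.
3. **Probe** — for index misses, fetch the repository status page through a
   pluggable transport (on-disk fixture pages or live HTTP) and classify it
   by signature substrings: "Could not find a public or private accession"
   → invalid, "is currently private" → private, page containing the
   accession → public, anything else → unknown.
4. **Classify & report** — every (article, accession) reference becomes
   `released`, `overdue`, `invalid`, or `unknown`; reporting computes the
   overdue-count time series, submission-to-release delay statistics, and
   detection precision, all exportable as CSV.

A synthetic fixture generator (`datawatch.fixtures`) produces complete
corpora, indices, and status pages with known ground truth, so the whole
pipeline is testable offline.

## CLI

```sh
# generate an offline fixture with known ground truth
datawatch fixture --spec fixture.yaml --out fx/

# extract deduplicated accession references from a corpus
datawatch scan --manifest fx/manifest.csv --text-root fx/texts --out run1/

# classify them against the index and status pages (or --live)
datawatch probe --index fx/index.csv --fixtures fx/pages --run run1/

# export the overdue list and overdue-count time series
datawatch report --run run1/ --format csv
```

`fixture.yaml` example:

```yaml
n_articles: 100
n_datasets: 150
fraction_private: 0.3
typo_rate: 0.05
spurious_rate: 0.02
seed: 7
```

A global `--config config.yaml` can override accession patterns, signature
strings, the probe rate limit (default 1 request / 400 ms), the probe cache
TTL (default 24 h), and the extraction context width.

## Layout

```
src/datawatch/
  corpus.py         manifest + text-file corpus loading
  extraction.py     accession patterns, boundary-aware scanning, dedup
  release_index.py  CSV / SQLite-snapshot release index
  probe.py          query URLs, signature parsing, cache, transports
  pipeline.py       orchestration, classification, run store, run diffs
  reporting.py      time series, delay stats, precision, CSV export
  fixtures.py       seeded synthetic corpora with ground truth
  config.py, cli.py
```
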