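from __future__ import annotations

import random
from datetime import date, timedelta

import pytest
from hypothesis import given
from hypothesis import strategies as st

from datawatch.dates import month_grid
from datawatch.release_index import ReleaseRecord
from datawatch.reporting import (
    compute_precision,
    delay_days,
    delay_statistics,
    export_report,
    overdue_time_series,
    read_series,
    whole_years_elapsed,
)


class TestOverdueTimeSeries:
    def test_hand_enumerated_example(self):
        # cited 2015-01, released 2015-06, grid 2015-01..2015-08:
        # overdue while cited <= t < release -> 1,1,1,1,1,0,0,0
        grid = month_grid(date(2015, 1, 1), date(2015, 8, 1))
        series = overdue_time_series(
            {"GSE1": date(2015, 1, 1)}, {"GSE1": date(2015, 6, 1)}, grid
        )
        assert [p.count for p in series] == [1, 1, 1, 1, 1, 0, 0, 0]

    def test_no_references_all_zero(self):
        grid = month_grid(date(2015, 1, 1), date(2015, 3, 1))
        assert [p.count for p in overdue_time_series({}, {}, grid)] == [0, 0, 0]

    def test_never_released_stays_counted(self):
        grid = month_grid(date(2015, 1, 1), date(2015, 4, 1))
        series = overdue_time_series({"GSE1": date(2015, 2, 1)}, {}, grid)
        assert [p.count for p in series] == [0, 1, 1, 1]

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            overdue_time_series({}, {}, [])

    def test_non_increasing_grid_is_error(self):
        with pytest.raises(ValueError):
            overdue_time_series({}, {}, [date(2015, 2, 1), date(2015, 1, 1)])

    def test_tail_equals_never_released_count(self):
        grid = month_grid(date(2015, 1, 1), date(2016, 12, 1))
        cited = {f"GSE{i}": date(2015, 1 + i % 3, 1) for i in range(6)}
        released = {"GSE0": date(2015, 6, 1), "GSE1": date(2015, 9, 1)}
        series = overdue_time_series(cited, released, grid)
        assert series[-1].count == 4  # 6 cited, 2 eventually released

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_response_to_release(self, seed):
        # Assigning a release date to an unreleased dataset never increases
        # any point of the series.
        rng = random.Random(seed)
        start = date(2014, 1, 1)
        cited = {
            f"GSE{i}": start + timedelta(days=rng.randint(0, 700)) for i in range(20)
        }
        released = {
            acc: cited[acc] + timedelta(days=rng.randint(0, 400))
            for acc in cited
            if rng.random() < 0.5
        }
        grid = month_grid(start, date(2016, 12, 1))
        base = overdue_time_series(cited, released, grid)
        unreleased = [a for a in cited if a not in released]
        if not unreleased:
            return
        target = rng.choice(unreleased)
        modified = dict(released)
        modified[target] = cited[target] + timedelta(days=rng.randint(0, 500))
        after = overdue_time_series(cited, modified, grid)
        assert all(a.count <= b.count for a, b in zip(after, base))


def record(acc, sub, rel):
    return ReleaseRecord(
        accession=acc,
        repository="GEO",
        submission_date=sub,
        release_date=rel,
        status_hint="public" if rel else "unknown",
    )


class TestDelayStatistics:
    def test_worked_example_march_2005_to_november_2016(self):
        sub, rel = date(2005, 3, 1), date(2016, 11, 1)
        assert whole_years_elapsed(sub, rel) == 11
        assert delay_days(sub, rel) == 4263

    def test_two_records_same_year(self):
        stats, excluded = delay_statistics(
            [
                record("GSE1", date(2016, 1, 1), date(2016, 1, 11)),
                record("GSE2", date(2016, 2, 1), date(2016, 2, 21)),
            ]
        )
        assert excluded == []
        (stat,) = stats
        assert (stat.year, stat.mean_delay_days, stat.n) == (2016, 15.0, 2)

    def test_empty_input(self):
        assert delay_statistics([]) == ([], [])

    def test_grouping_by_release_year_sorted(self):
        stats, _ = delay_statistics(
            [
                record("GSE2", date(2015, 12, 1), date(2016, 1, 1)),
                record("GSE1", date(2015, 1, 1), date(2015, 1, 31)),
            ]
        )
        assert [s.year for s in stats] == [2015, 2016]

    def test_missing_release_date_excluded_and_reported(self):
        stats, excluded = delay_statistics(
            [record("GSE1", date(2016, 1, 1), date(2016, 2, 1)), record("GSE2", date(2016, 1, 1), None)]
        )
        assert len(stats) == 1 and len(excluded) == 1
        assert excluded[0].accession == "GSE2"

    @given(
        st.lists(
            st.tuples(
                st.dates(min_value=date(2000, 1, 1), max_value=date(2016, 1, 1)),
                st.integers(min_value=0, max_value=2000),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_mean_matches_brute_force(self, pairs):
        records = [
            record(f"GSE{i}", sub, sub + timedelta(days=delta))
            for i, (sub, delta) in enumerate(pairs)
        ]
        stats, _ = delay_statistics(records)
        # independent brute-force mean per year
        for stat in stats:
            delays = [
                (r.release_date - r.submission_date).days
                for r in records
                if r.release_date.year == stat.year
            ]
            assert stat.n == len(delays)
            assert stat.mean_delay_days == pytest.approx(sum(delays) / len(delays))


class TestComputePrecision:
    def test_evaluation_breakdown_rounds_to_97_percent(self):
        report = compute_precision(473, 1, 14, 3)
        assert report.correct == 458
        assert report.precision == pytest.approx(458 / 473)
        assert report.percent_str == "97%"

    def test_all_correct(self):
        assert compute_precision(10, 0, 0, 0).precision == 1.0

    def test_all_wrong(self):
        assert compute_precision(10, 10, 0, 0).precision == 0.0

    def test_withheld_counts_as_correct(self):
        # 3 withheld-but-legitimate detections do not reduce precision
        assert compute_precision(10, 0, 0, 3).precision == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_precision(10, -1, 0, 0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_precision(10, 6, 6, 0)

    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=0, max_value=500),
    )
    def test_bounds_and_perfect_iff_no_errors(self, total, fm, typo):
        if fm + typo > total:
            with pytest.raises(ValueError):
                compute_precision(total, fm, typo, 0)
            return
        report = compute_precision(total, fm, typo, 0)
        assert 0.0 <= report.precision <= 1.0
        if total:
            assert (report.precision == 1.0) == (fm == 0 and typo == 0)


class TestExportReport:
    def test_series_file_shape_and_roundtrip(self, tmp_path):
        grid = month_grid(date(2015, 1, 1), date(2015, 3, 1))
        series = overdue_time_series({"GSE1": date(2015, 1, 1)}, {}, grid)
        path = export_report(series, tmp_path / "series.csv", "series")
        lines = path.read_text(encoding="utf-8").strip().splitlines()
        assert len(lines) == 4  # header + 3 points
        assert read_series(path) == series

    def test_empty_stats_header_only(self, tmp_path):
        path = export_report([], tmp_path / "delays.csv", "delays")
        assert path.read_text(encoding="utf-8").strip() == "year,mean_delay_days,n"

    def test_precision_export(self, tmp_path):
        path = export_report(compute_precision(473, 1, 14, 3), tmp_path / "p.csv", "precision")
        text = path.read_text(encoding="utf-8")
        assert "precision_percent,97%" in text

    def test_unknown_kind(self, tmp_path):
        with pytest.raises(ValueError):
            export_report([], tmp_path / "x.csv", "pdf")
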