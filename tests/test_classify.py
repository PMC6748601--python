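"""INN classification, summarisation, stratification and attribution."""

import pytest

from abmatch import (
    AntibodyType,
    Chain,
    Mode,
    Predicate,
    StudyMetadata,
    classify_inn,
    classify_names,
    rows_from_fixture,
    rows_from_results,
    source_attribution,
    stratify_by_type,
    summarize,
)
from abmatch.search import MatchResult
from abmatch.summarize import (
    ReportRow,
    UnclassifiableNameError,
    read_report,
    write_report,
)


class TestClassifyInn:
    @pytest.mark.parametrize("name, expected", [
        ("muromonab", AntibodyType.MOUSE),
        ("abagovomab", AntibodyType.MOUSE),
        ("racotumomab", AntibodyType.MOUSE),
        ("otelixizumab", AntibodyType.CHIMERIC),
        ("rituximab", AntibodyType.CHIMERIC),
        ("trastuzumab", AntibodyType.HUMANIZED),
        ("adalimumab", AntibodyType.FULLY_HUMAN),
        ("Adalimumab", AntibodyType.FULLY_HUMAN),   # case-insensitive
        ("TRASTUZUMAB", AntibodyType.HUMANIZED),
    ])
    def test_rules(self, name, expected):
        assert classify_inn(name) is expected

    def test_mouse_list_overrides_suffix(self):
        # the -momab era predates the suffix convention: only the explicit
        # list catches these names
        assert classify_inn("racotumomab") is AntibodyType.MOUSE
        with pytest.raises(UnclassifiableNameError):
            classify_inn("racotumomab", mouse_list=set())
        # and the list wins even over a name that a suffix rule would catch
        assert classify_inn("adalimumab", mouse_list={"adalimumab"}) is AntibodyType.MOUSE

    def test_unmatched_name_raises(self):
        with pytest.raises(UnclassifiableNameError):
            classify_inn("aspirin")
        with pytest.raises(UnclassifiableNameError):
            classify_inn("")

    def test_batch_maps_unmatched_to_unknown(self):
        out = classify_names(["adalimumab", "aspirin"])
        assert out["aspirin"] is AntibodyType.UNKNOWN

    def test_fixture_strata(self, fixture_rows):
        types = classify_names([r.name for r in fixture_rows])
        counts = {}
        for t in types.values():
            counts[t] = counts.get(t, 0) + 1
        assert counts[AntibodyType.FULLY_HUMAN] == 100
        assert counts[AntibodyType.HUMANIZED] == 105
        assert counts[AntibodyType.MOUSE] == 3
        assert counts[AntibodyType.CHIMERIC] == 34
        assert AntibodyType.UNKNOWN not in counts


def simple_row(name, ab_type=AntibodyType.FULLY_HUMAN, **percents):
    base = {c: None for c in ("heavy", "light", "heavy_cdrs", "light_cdrs", "cdrh3")}
    base.update(percents)
    return ReportRow(name=name, ab_type=ab_type, percents=base)


class TestSummarize:
    def test_single_perfect_row(self):
        report = summarize([simple_row("a", heavy=100, light=100, heavy_cdrs=100,
                                       light_cdrs=100, cdrh3=100)])
        entry = report.threshold_counts["heavy>=90"]
        assert entry["count"] == 1 and entry["percentage"] == "100.0"

    def test_no_match_fails_every_predicate(self):
        report = summarize([simple_row("a")])  # all columns None
        assert all(v["count"] == 0 for v in report.threshold_counts.values())

    def test_rows_sorted_by_heavy_descending_then_name(self):
        rows = [simple_row("b", heavy=90), simple_row("a", heavy=90),
                simple_row("c", heavy=95), simple_row("d")]
        report = summarize(rows)
        assert [r.name for r in report.rows] == ["c", "a", "b", "d"]

    def test_threshold_counts_monotone(self, fixture_rows):
        rows = rows_from_fixture(fixture_rows)
        for col in ("heavy", "light", "heavy_cdrs", "light_cdrs", "cdrh3"):
            counts = [
                summarize(rows, [Predicate((col,), "ge", t)]).threshold_counts[
                    f"{col}>={t}"]["count"]
                for t in (80, 90, 95, 100)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_permutation_invariant_counts(self, fixture_rows):
        rows = rows_from_fixture(fixture_rows)
        a = summarize(rows).threshold_counts
        b = summarize(list(reversed(rows))).threshold_counts
        assert a == b

    def test_duplicate_query_mode_rejected(self, study_meta):
        res = MatchResult(query_id="q", mode=Mode.FULL_CHAIN, best_value=1.0,
                          best_template_id="t", tie_count=1, source=study_meta,
                          matches=10, len_query=10, len_template=10)
        with pytest.raises(ValueError):
            rows_from_results([res, res])

    def test_raw_fraction_threshold_path(self, study_meta):
        # 113/119 = 0.9496: displays as 95 but is below the raw 0.95 cut
        res = MatchResult(query_id="adalimumab", mode=Mode.FULL_CHAIN,
                          best_value=113 / 119, best_template_id="t", tie_count=1,
                          source=study_meta, matches=113, len_query=119,
                          len_template=119)
        rows = rows_from_results([res])
        assert rows[0].percents["heavy"] == 95
        report = summarize(rows, [Predicate(("heavy",), "ge", 95)])
        assert report.threshold_counts["heavy>=95"]["count"] == 0


class TestStratify:
    def test_per_type_sizes_partition_fixture(self, fixture_rows):
        report = summarize(rows_from_fixture(fixture_rows))
        assert sum(s["n"] for s in report.strata.values()) == 242

    def test_humanized_median_below_fully_human(self, fixture_rows):
        report = summarize(rows_from_fixture(fixture_rows))
        hum = report.strata["humanized"]["columns"]["heavy"]["median"]
        fh = report.strata["fully_human"]["columns"]["heavy"]["median"]
        assert hum < fh

    def test_small_sample_flag(self, fixture_rows):
        report = summarize(rows_from_fixture(fixture_rows))
        assert report.strata["mouse"]["small_sample"] is True
        assert report.strata["fully_human"]["small_sample"] is False

    def test_single_type_input(self):
        report = summarize([simple_row("a", heavy=90), simple_row("b", heavy=80)])
        assert list(report.strata) == ["fully_human"]
        assert report.strata["fully_human"]["n"] == 2


class TestSourceAttribution:
    def res(self, qid, species, study, mode=Mode.FULL_CHAIN):
        meta = StudyMetadata(study_id=study, species=species, chain=Chain.HEAVY)
        return MatchResult(query_id=qid, mode=mode, best_value=1.0,
                           best_template_id="t", tie_count=1, source=meta,
                           matches=5, len_query=5, len_template=5)

    def test_species_counts_and_studies(self):
        types = {f"q{i}": AntibodyType.FULLY_HUMAN for i in range(10)}
        results = [self.res(f"q{i}", "human" if i < 7 else "mouse", "S1")
                   for i in range(10)]
        attribution, studies = source_attribution(results, types)
        bucket = attribution["fully_human:full_chain"]
        assert bucket == {"human": 7, "mouse": 3}
        assert studies == {"S1"}
        assert sum(bucket.values()) == 10  # fractions sum to 1

    def test_planted_single_study(self):
        results = [self.res("q0", "human", "S1"), self.res("q1", "human", "S1",
                                                           mode=Mode.CDRH3)]
        _, studies = source_attribution(results, {})
        assert studies == {"S1"}


class TestReportRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_write_read_preserves_rows_and_counts(self, tmp_path, fixture_rows, fmt):
        report = summarize(rows_from_fixture(fixture_rows))
        path = tmp_path / f"report.{fmt}"
        write_report(report, path, fmt)
        back = read_report(path, fmt)
        assert [r.name for r in back.rows] == [r.name for r in report.rows]
        assert [r.percents for r in back.rows] == [r.percents for r in report.rows]
        assert [r.ab_type for r in back.rows] == [r.ab_type for r in report.rows]
        assert {k: v["count"] for k, v in back.threshold_counts.items()} == {
            k: v["count"] for k, v in report.threshold_counts.items()}

    def test_empty_report_valid(self, tmp_path):
        report = summarize([])
        path = tmp_path / "empty.csv"
        write_report(report, path, "csv")
        assert read_report(path, "csv").rows == []
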