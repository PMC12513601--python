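"""Descriptive tables: demographics, SOC distributions, PT rankings,
overlap, and replay of published aggregates."""

import pytest

from pvsignal.descriptives import (
    breakdown_from_counts,
    demographic_table,
    overlap,
    round_half_up,
    soc_table,
    top_pt_table_from_counts,
    top_pts,
    UNMAPPED_SOC,
)
from pvsignal.replay import (
    published_demographics,
    published_soc_distribution,
    published_top_pt_table,
    replay_report_set,
)
from pvsignal.reports import AdeReport, PtDictionary, ReportSet, event_occurrences
from pvsignal.simulate import default_config, simulate


def _reports(*specs):
    return ReportSet(
        source_label="t",
        reports=[
            AdeReport(report_id=f"r{i}", drug=d, pts=frozenset(p), sex=kw.get("sex", "unknown"))
            for i, (d, p, kw) in enumerate(
                (s if len(s) == 3 else (*s, {}) for s in specs), start=1
            )
        ],
    )


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(27.456647, 27.46), (48.1936, 48.19), (0.125, 0.13), (2.675, 2.68), (23.405, 23.41)],
    )
    def test_half_up_display_rounding(self, value, expected):
        assert round_half_up(value) == expected


class TestDemographicTable:
    def test_all_unknown_sex_is_full_mass(self):
        rs = _reports(("D", {"Death"}), ("D", {"Rash"}))
        sex = next(b for b in demographic_table(rs) if b.category == "sex")
        assert sex.percent_of("unknown") == 100.00

    def test_counts_sum_to_reports_and_percents_to_100(self):
        rs = _reports(
            ("D", {"Death"}, {"sex": "male"}),
            ("D", {"Rash"}, {"sex": "female"}),
            ("E", {"Death"}, {"sex": "male"}),
        )
        for breakdown in demographic_table(rs):
            assert sum(n for _, n, _ in breakdown.rows) == 3
            assert sum(pct for _, _, pct in breakdown.rows) == pytest.approx(100.0)

    def test_unknown_level_is_last(self):
        rs = _reports(("D", {"Death"}, {"sex": "unknown"}), ("D", {"Rash"}, {"sex": "male"}))
        sex = next(b for b in demographic_table(rs) if b.category == "sex")
        assert [lv for lv, _, _ in sex.rows][-1] == "unknown"


class TestPublishedReplay:
    """Published aggregates must reproduce their printed percentages."""

    def test_demographics_cells(self):
        faers = published_demographics("faers")
        assert faers["sex"].percent_of("male") == 48.19
        assert faers["age_group"].percent_of("ge75") == 23.41
        vigi = published_demographics("vigiaccess")
        assert vigi["sex"].percent_of("male") == 52.50
        assert vigi["age_group"].percent_of("a65_74") == 12.98

    def test_soc_cells(self):
        faers = published_soc_distribution("faers")
        assert faers.percent_of("Gastrointestinal disorders") == 12.47
        assert faers.percent_of("General disorders and administration site conditions") == 31.79
        assert faers.total_events == 2246
        vigi = published_soc_distribution("vigiaccess")
        assert vigi.percent_of("Investigations") == 11.19
        assert vigi.total_events == 2555

    def test_top_pt_cells(self):
        faers = published_top_pt_table("faers")
        assert faers.rows[0][1] == "Death" and faers.percent_of("Death") == 23.15
        assert faers.percent_of("Blood potassium increased") == 3.61
        vigi = published_top_pt_table("vigiaccess")
        assert vigi.percent_of("Death") == 21.57

    def test_published_overlap_partition(self):
        result = overlap(published_top_pt_table("faers"), published_top_pt_table("vigiaccess"))
        assert len(result.shared) == 28
        assert result.only_a == {"pneumonia", "dysphagia"}
        assert result.only_b == {"rash", "peripheral swelling"}

    def test_replay_report_set_ranks_match_published_counts(self):
        rs = replay_report_set("faers")
        table = top_pts(rs, "Sodium zirconium cyclosilicate", 5)
        assert [(pt, n) for _, pt, n, _ in table.rows] == [
            ("Death", 520),
            ("Blood potassium increased", 81),
            ("Constipation", 56),
            ("Diarrhoea", 41),
            ("Oedema", 37),
        ]


class TestSocTable:
    def test_single_report_single_pt_is_total(self, dictionary):
        rs = _reports(("D", {"Death"}))
        table = soc_table(rs, dictionary, "D")
        assert len(table.rows) == 1
        assert table.rows[0][3] == 100.0

    def test_unmapped_pts_flagged_not_dropped(self, dictionary):
        rs = _reports(("D", {"Qwertyitis", "Death"}))
        table = soc_table(rs, dictionary, "D")
        assert table.total_events == 2
        assert any(soc == UNMAPPED_SOC for soc, *_ in table.rows)

    def test_event_totals_conserved_and_sorted(self, sim_dictionary):
        rs, _ = simulate(default_config(n_reports=2000, seed=2))
        table = soc_table(rs, sim_dictionary, "DRUG-X")
        assert table.total_events == len(event_occurrences(rs, "DRUG-X"))
        counts = [n for _, _, n, _ in table.rows]
        assert counts == sorted(counts, reverse=True)
        assert sum(pct for *_, pct in table.rows) == pytest.approx(100.0)

    def test_distinct_pt_counts(self):
        d = PtDictionary(entries={"A": "S1", "B": "S1", "C": "S2"})
        rs = _reports(("D", {"A", "B"}), ("D", {"A", "C"}))
        table = soc_table(rs, d, "D")
        by_soc = {soc: k for soc, k, _, _ in table.rows}
        assert by_soc == {"S1": 2, "S2": 1}


class TestTopPts:
    def test_ties_break_alphabetically(self):
        rs = _reports(("D", {"Beta", "Alpha"}), ("D", {"Beta", "Alpha"}), ("D", {"Gamma"}))
        table = top_pts(rs, "D", 3)
        assert table.pts() == ["Alpha", "Beta", "Gamma"]

    def test_n_larger_than_distinct_pt_count(self):
        rs = _reports(("D", {"A", "B"}))
        assert len(top_pts(rs, "D", 30).rows) == 2

    def test_ranks_increasing_counts_non_increasing(self):
        rs, _ = simulate(default_config(n_reports=2000, seed=4))
        table = top_pts(rs, "DRUG-X", 30)
        ranks = [r for r, *_ in table.rows]
        counts = [n for _, _, n, _ in table.rows]
        assert ranks == list(range(1, len(ranks) + 1))
        assert counts == sorted(counts, reverse=True)


class TestOverlap:
    def test_identical_lists_no_exclusive_sets(self):
        t = top_pt_table_from_counts([("A", 5), ("B", 3)], total_events=8)
        result = overlap(t, t)
        assert result.only_a == result.only_b == frozenset()

    def test_disjoint_lists(self):
        a = top_pt_table_from_counts([(f"A{i}", 2) for i in range(30)], total_events=60)
        b = top_pt_table_from_counts([(f"B{i}", 2) for i in range(30)], total_events=60)
        result = overlap(a, b)
        assert not result.shared and len(result.only_a) == len(result.only_b) == 30

    def test_symmetry_and_partition_sizes(self):
        a = top_pt_table_from_counts([("A", 5), ("B", 3), ("C", 2)], total_events=10)
        b = top_pt_table_from_counts([("b", 4), ("C", 3), ("D", 1)], total_events=8)
        fwd, rev = overlap(a, b), overlap(b, a)
        assert fwd.shared == rev.shared == {"b", "c"}
        assert len(fwd.shared) + len(fwd.only_a) == len(a.rows)
        assert len(fwd.shared) + len(fwd.only_b) == len(b.rows)


class TestReplayConstructors:
    def test_breakdown_from_counts_matches_report_route(self):
        rs = _reports(
            ("D", {"Death"}, {"sex": "male"}),
            ("D", {"Rash"}, {"sex": "male"}),
            ("D", {"Rash"}, {"sex": "female"}),
        )
        direct = next(b for b in demographic_table(rs) if b.category == "sex")
        replayed = breakdown_from_counts("sex", [(lv, n) for lv, n, _ in direct.rows])
        assert replayed.rows == direct.rows
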