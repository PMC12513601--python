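"""Disproportionality statistics: formula oracles, degenerate-cell
policy, positivity criteria, and the model/results interface."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal.reports import AdeReport, ReportSet
from pvsignal.screening import (
    ContingencyTable,
    DisproportionalityModel,
    ScreeningCriteria,
    contingency,
    prr_stats,
    ror_stats,
    screen,
)
from pvsignal.simulate import default_config, simulate

cells = st.integers(min_value=1, max_value=500)


class TestContingency:
    def test_exhaustive_partition_one_report_per_cell(self, small_universe):
        t = contingency(small_universe, "DRUG-X", "Nausea")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
        assert t.n == len(small_universe)

    def test_absent_drug_gives_empty_drug_arm(self, small_universe):
        t = contingency(small_universe, "NO-SUCH-DRUG", "Nausea")
        assert t.a == t.c == 0
        assert t.n == 4

    def test_matches_brute_force_recount_on_synthetic_draw(self, sim_dictionary):
        rs, _ = simulate(default_config(n_reports=1000, seed=8))
        for pt in ("Death", "Diarrhoea", "Blood potassium increased"):
            t = contingency(rs, "DRUG-X", pt)
            a = b = c = d = 0
            for r in rs:
                doi = r.drug == "DRUG-X" and r.role == "primary_suspect"
                has = pt in r.pts
                a += doi and has
                b += (not doi) and has
                c += doi and not has
                d += (not doi) and not has
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


class TestFormulas:
    def test_worked_example(self):
        t = ContingencyTable(10, 20, 30, 240)
        ror, lo, hi = ror_stats(t)
        prr, chi2 = prr_stats(t)
        assert ror == pytest.approx(4.000, abs=5e-4)
        assert lo == pytest.approx(1.712, abs=5e-4)
        assert hi == pytest.approx(9.346, abs=5e-4)
        assert prr == pytest.approx(3.000, abs=5e-4)
        assert chi2 == pytest.approx(11.538, abs=5e-4)

    @given(k=st.integers(min_value=1, max_value=1000))
    @settings(derandomize=True)
    def test_uniform_table_is_null(self, k):
        t = ContingencyTable(k, k, k, k)
        ror, lo, hi = ror_stats(t)
        prr, chi2 = prr_stats(t)
        assert ror == prr == 1.0
        assert chi2 == 0.0
        assert lo < 1.0 < hi

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(derandomize=True)
    def test_swapping_arms_inverts_ror(self, a, b, c, d):
        fwd, *_ = ror_stats(ContingencyTable(a, b, c, d))
        rev, *_ = ror_stats(ContingencyTable(b, a, d, c))
        assert fwd == pytest.approx(1.0 / rev, rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(derandomize=True)
    def test_chi2_invariant_under_transposition(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert prr_stats(t)[1] == pytest.approx(prr_stats(t.transpose())[1], rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells, inc=st.integers(min_value=1, max_value=50))
    @settings(derandomize=True)
    def test_ror_and_prr_monotone_in_a(self, a, b, c, d, inc):
        lo_t, hi_t = ContingencyTable(a, b, c, d), ContingencyTable(a + inc, b, c, d)
        assert ror_stats(hi_t)[0] >= ror_stats(lo_t)[0]
        assert prr_stats(hi_t)[0] >= prr_stats(lo_t)[0]

    def test_oracle_equivalence_on_random_tables(self):
        """Cross-product OR, share-ratio PRR and observed-vs-expected
        Pearson chi2, each derived independently, agree to 1e-9 relative."""
        rng = np.random.default_rng(2024)
        abcd = rng.integers(1, 500, size=(10_000, 4)).astype(float)
        for a, b, c, d in abcd:
            ror, lo, hi = ror_stats(ContingencyTable(a, b, c, d))
            prr, chi2 = prr_stats(ContingencyTable(a, b, c, d))
            # odds ratio as ratio of within-arm odds
            oracle_ror = (a / c) / (b / d)
            # PRR as ratio of the drug's share among event vs non-event reports
            oracle_prr = (a / (a + b)) / (c / (c + d))
            # Pearson statistic from expected counts under independence
            obs = np.array([[a, b], [c, d]])
            expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
            oracle_chi2 = ((obs - expected) ** 2 / expected).sum()
            assert ror == pytest.approx(oracle_ror, rel=1e-9)
            assert prr == pytest.approx(oracle_prr, rel=1e-9)
            assert chi2 == pytest.approx(oracle_chi2, rel=1e-9)
            assert lo <= ror <= hi

    def test_chi2_spot_check_against_scipy(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        for a, b, c, d in rng.integers(1, 500, size=(50, 4)):
            ours = prr_stats(ContingencyTable(a, b, c, d))[1]
            ref = chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert ours == pytest.approx(ref, rel=1e-9)


class TestZeroCellPolicy:
    def test_zero_denominator_is_infinite_not_exception(self):
        ror, lo, hi = ror_stats(ContingencyTable(5, 0, 10, 100))
        assert math.isinf(ror) and math.isnan(lo) and math.isnan(hi)

    def test_zero_a_gives_zero_ror_undefined_ci(self):
        ror, lo, hi = ror_stats(ContingencyTable(0, 5, 10, 100))
        assert ror == 0.0 and math.isnan(lo)

    def test_fully_degenerate_is_nan(self):
        ror, *_ = ror_stats(ContingencyTable(0, 0, 10, 100))
        assert math.isnan(ror)
        prr, chi2 = prr_stats(ContingencyTable(5, 3, 0, 0))
        assert math.isnan(prr)

    def test_continuity_correction_only_touches_zero_cell_tables(self):
        t = ContingencyTable(5, 0, 10, 100)
        corrected = t.with_continuity(0.5)
        assert (corrected.a, corrected.b) == (5.5, 0.5)
        untouched = ContingencyTable(5, 3, 10, 100).with_continuity(0.5)
        assert (untouched.a, untouched.b) == (5, 3)


def _universe(n_doi_with, n_doi_without, n_other_with, n_other_without, pt="Nausea"):
    reports = []
    i = 0
    for count, drug, pts in [
        (n_doi_with, "DRUG-X", {pt, "Filler"}),
        (n_doi_without, "DRUG-X", {"Filler"}),
        (n_other_with, "OTHER", {pt, "Filler"}),
        (n_other_without, "OTHER", {"Filler"}),
    ]:
        for _ in range(count):
            i += 1
            reports.append(AdeReport(report_id=f"u{i}", drug=drug, pts=frozenset(pts)))
    return ReportSet(source_label="u", reports=reports)


class TestScreen:
    def test_min_a_gate_blocks_huge_ror(self, dictionary):
        rs = _universe(2, 100, 1, 1000)
        stats = {s.pt: s for s in screen(rs, dictionary, "DRUG-X")}
        s = stats["Nausea"]
        assert s.ror > 10
        assert not s.ror_positive and not s.prr_positive and not s.combined_positive

    def test_planted_signal_is_combined_positive(self, sim_dictionary):
        rs, _ = simulate(default_config(n_reports=20_000, seed=1, effect_multipliers={"Rash": 8.0}))
        res = DisproportionalityModel(rs, sim_dictionary, "DRUG-X").fit()
        assert res["Rash"].combined_positive

    def test_combined_subset_of_each_criterion(self, sim_dictionary):
        rs, _ = simulate(default_config(n_reports=5000, seed=6))
        for s in screen(rs, sim_dictionary, "DRUG-X"):
            assert s.combined_positive == (s.ror_positive and s.prr_positive)

    def test_undefined_statistics_never_positive(self, dictionary):
        rs = _universe(5, 100, 0, 1000)  # b = 0 -> infinite ROR, no CI
        stats = {s.pt: s for s in screen(rs, dictionary, "DRUG-X")}
        assert math.isinf(stats["Nausea"].ror)
        assert not stats["Nausea"].ror_positive

    def test_sorted_combined_positives_first_by_ror(self, sim_dictionary):
        rs, _ = simulate(default_config(n_reports=20_000, seed=2))
        stats = screen(rs, sim_dictionary, "DRUG-X")
        flags = [s.combined_positive for s in stats]
        assert flags == sorted(flags, reverse=True)
        pos_rors = [s.ror for s in stats if s.combined_positive]
        assert pos_rors == sorted(pos_rors, reverse=True)

    def test_screen_counts_report_once_per_pt(self, dictionary):
        # one report coded with the PT contributes a=1 regardless of coding
        rs = _universe(1, 3, 2, 10)
        stats = {s.pt: s for s in screen(rs, dictionary, "DRUG-X")}
        assert stats["Nausea"].a == 1


class TestModelResults:
    def test_fit_returns_results_with_frames(self, sim_dictionary):
        rs, _ = simulate(default_config(n_reports=3000, seed=3))
        res = DisproportionalityModel(rs, sim_dictionary, "DRUG-X").fit()
        frame = res.to_frame()
        assert set(frame.columns) == {
            "pt", "soc", "a", "ror", "ror_ci_low", "ror_ci_high",
            "prr", "chi2", "ror_positive", "prr_positive", "combined_positive",
        }
        forest = res.forest_frame()
        assert list(forest.columns) == ["pt", "ror", "ci_low", "ci_high"]
        assert "positive signals" in res.summary()

    def test_from_dataframe_matches_reportset_route(self, dictionary):
        frame = pd.DataFrame(
            {
                "report_id": ["r1", "r2", "r3"],
                "drug": ["DRUG-X", "DRUG-X", "OTHER"],
                "role": ["primary_suspect"] * 3,
                "sex": ["male", "female", "unknown"],
                "age_group": ["ge75", "unknown", "unknown"],
                "region": ["americas", "asia", "unknown"],
                "year": ["2023", "unknown", "2022"],
                "pts": ["Death;Nausea", "Death", "Rash"],
            }
        )
        model = DisproportionalityModel.from_dataframe(frame, dictionary, "DRUG-X")
        assert len(model.reports) == 3
        res = model.fit()
        assert res["Death"].a == 2

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            ScreeningCriteria(min_a=0)
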