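"""Prevalence, Wilson interval, Z-test and TDT statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from triocnv.stats import (build_summary_tables, load_published_counts,
                           prevalence, table1_from_counts, table2_from_counts,
                           tdt, transmission_from_counts, two_prop_z, wilson_ci)


class TestWilson:
    @pytest.mark.parametrize("x, n, lo4, hi4", [
        (59, 12252, 37.35, 62.06),
        (20, 12252, 10.57, 25.2),
        (6, 12252, 2.24, 10.68),
        (25, 12252, 13.83, 30.11),
        (34, 12252, 19.87, 38.75),
    ])
    def test_published_cohort_intervals_per_10000(self, x, n, lo4, hi4):
        lo, hi = wilson_ci(x, n)
        assert round(lo * 1e4, 2) == pytest.approx(lo4)
        assert round(hi * 1e4, 2) == pytest.approx(hi4, abs=0.005)

    def test_zero_events_upper_bound(self):
        lo, hi = wilson_ci(0, 12252)
        assert lo == 0.0
        assert float(f"{hi:.1g}") == pytest.approx(3e-4)

    def test_all_events_upper_is_one(self):
        lo, hi = wilson_ci(40, 40)
        assert hi == pytest.approx(1.0, abs=1e-12)
        assert lo == pytest.approx(1.0 - wilson_ci(0, 40)[1])

    @pytest.mark.parametrize("x, n", [(0, 10), (3, 17), (59, 12252), (40, 40)])
    def test_matches_statsmodels(self, x, n):
        lo, hi = wilson_ci(x, n)
        sm_lo, sm_hi = proportion_confint(x, n, alpha=0.05, method="wilson")
        assert lo == pytest.approx(sm_lo, abs=1e-12)
        assert hi == pytest.approx(sm_hi, abs=1e-12)

    def test_interval_contains_point_and_narrows_with_n(self):
        widths = []
        for n in (100, 1000, 10000):
            x = n // 100
            lo, hi = wilson_ci(x, n)
            assert lo <= x / n <= hi
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 4)
        with pytest.raises(ValueError):
            wilson_ci(0, 0)

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(1, 100_000), frac=st.floats(0, 1))
    def test_interval_always_brackets_the_point(self, n, frac):
        x = int(round(frac * n))
        lo, hi = wilson_ci(x, n)
        assert 0.0 <= lo <= x / n <= hi <= 1.0


class TestTwoPropZ:
    @pytest.mark.parametrize("x1, x2, z2, p2", [
        (25, 34, -1.17, 0.24),
        (12, 27, -2.40, 0.016),
        (13, 7, 1.34, 0.18),
    ])
    def test_deletion_vs_duplication_counts(self, x1, x2, z2, p2):
        z, p = two_prop_z(x1, 12252, x2, 12252)
        assert round(z, 2) == pytest.approx(z2)
        assert p == pytest.approx(p2, abs=5e-3)

    def test_equal_counts_give_zero(self):
        z, p = two_prop_z(7, 100, 7, 100)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_under_swap(self):
        z1, p1 = two_prop_z(12, 500, 30, 600)
        z2, p2 = two_prop_z(30, 600, 12, 500)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_matches_statsmodels(self):
        z, p = two_prop_z(25, 12252, 34, 12252)
        sm_z, sm_p = proportions_ztest([25, 34], [12252, 12252])
        assert z == pytest.approx(sm_z)
        assert p == pytest.approx(sm_p)

    def test_degenerate_pool_raises(self):
        with pytest.raises(ValueError):
            two_prop_z(0, 10, 0, 10)


class TestTdt:
    def test_paternal_transmission_deficit(self):
        res = tdt(15, 44)
        assert res.rate == pytest.approx(0.3409, abs=1e-4)
        assert res.p == pytest.approx(0.03, abs=0.005)

    def test_combined_transmission_near_half(self):
        res = tdt(39, 87)
        assert res.p == pytest.approx(0.33, abs=0.005)

    def test_balanced_transmission(self):
        res = tdt(22, 44)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_symmetry_in_untransmitted(self):
        a, b = tdt(10, 44), tdt(34, 44)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)

    def test_exact_binomial_option(self):
        assert tdt(15, 44, exact=True).p == pytest.approx(
            2 * sum(math.comb(44, k) for k in range(16)) / 2**44, rel=1e-9)

    def test_invalid(self):
        with pytest.raises(ValueError):
            tdt(5, 0)
        with pytest.raises(ValueError):
            tdt(9, 8)

    @settings(deadline=None, derandomize=True)
    @given(n=st.integers(1, 10_000), frac=st.floats(0, 1))
    def test_transmitted_untransmitted_symmetry(self, n, frac):
        t = int(round(frac * n))
        a, b = tdt(t, n), tdt(n - t, n)
        assert a.chi2 == pytest.approx(b.chi2)
        assert a.p == pytest.approx(b.p)
        assert 0.0 < a.p <= 1.0


class TestCountTables:
    def test_cumulative_table_reproduces_published_cells(self):
        t1 = table1_from_counts(25, 34, 12, 27, 13, 7, 12252)
        a = t1.loc["all"]
        assert (round(a["del_prev"], 2), round(a["dup_prev"], 2),
                round(a["total_prev"], 2)) == (20.4, 27.75, 48.16)
        assert round(a["total_ci_low"], 2) == 37.35
        assert round(a["total_ci_high"], 2) == 62.06
        assert round(a["z"], 2) == -1.17 and round(a["p"], 2) == 0.24
        i = t1.loc["inherited"]
        assert (round(i["del_prev"], 2), round(i["dup_prev"], 2)) == (9.79, 22.04)
        assert round(i["z"], 2) == -2.40 and round(i["p"], 3) == 0.016
        d = t1.loc["de_novo"]
        assert round(d["total_ci_high"], 1) == 25.2
        assert round(d["z"], 2) == 1.34 and round(d["p"], 2) == 0.18

    def test_per_region_table_from_published_counts(self):
        c = load_published_counts()
        t2 = table2_from_counts(c["rows"], c["n_trios"])
        assert int(t2["n"].sum()) == 59
        assert int(t2["de_novo"].sum()) == 20
        assert int(t2["inherited_maternal"].sum()) == 24
        assert int(t2["inherited_paternal"].sum()) == 15
        row = t2[(t2["region"] == "1q21.1") & (t2["svclass"] == "del")].iloc[0]
        assert round(row["all_prev"], 1) == 4.9
        assert round(row["all_ci_low"], 2) == 2.24
        assert round(row["all_ci_high"], 2) == 10.68
        row = t2[(t2["region"] == "16p11.2_distal") & (t2["svclass"] == "dup")].iloc[0]
        assert (row["n"], round(row["all_prev"], 2)) == (8, 6.53)

    def test_transmission_rates_match_discussion(self):
        tr = transmission_from_counts(43, 24, 44, 15)
        assert round(tr.loc["maternal", "rate_percent"], 2) == 55.81
        assert round(tr.loc["paternal", "rate_percent"], 2) == 34.09
        assert tr.loc["paternal", "p"] == pytest.approx(0.03, abs=0.005)
        assert tr.loc["combined", "p"] == pytest.approx(0.33, abs=0.005)

    def test_row_counts_exceeding_total_rejected(self):
        bad = [{"region": "r", "svclass": "del", "n": 1, "de_novo": 1,
                "inherited_maternal": 1, "inherited_paternal": 0}]
        with pytest.raises(ValueError):
            table2_from_counts(bad, 100)


class TestBuildSummaryTables:
    @staticmethod
    def _classified():
        return pd.DataFrame({
            "region": ["1q21.1", "1q21.1", "17q12", "17q12"],
            "svclass": ["del", "dup", "del", "del"],
            "status": ["de_novo", "inherited_maternal", "de_novo",
                       "inherited_paternal"],
            "origin": ["paternal", "maternal", "maternal", "paternal"],
        })

    def test_reconciliation_identities(self, region_1q):
        from triocnv.regions import NddRegion
        regions = [region_1q,
                   NddRegion("17q12", "17", 34816572, 36215672)]
        tables = build_summary_tables(self._classified(), regions, 1000,
                                      mother_carriers=3, maternal_transmitted=1,
                                      father_carriers=2, paternal_transmitted=1)
        t1 = tables["table1"]
        for cls in ("del", "dup", "total"):
            assert (t1.loc["inherited", cls] + t1.loc["de_novo", cls]
                    == t1.loc["all", cls])
        t2 = tables["table2"]
        assert int(t2["n"].sum()) == int(t1.loc["all", "total"])
        assert (t2["de_novo"] + t2["inherited_maternal"]
                + t2["inherited_paternal"]).equals(t2["n"])

    def test_empty_call_set_gives_zero_rows(self, region_1q):
        empty = pd.DataFrame(columns=["region", "svclass", "status", "origin"])
        tables = build_summary_tables(empty, [region_1q], 500)
        t1 = tables["table1"]
        assert (t1[["del", "dup", "total"]].to_numpy() == 0).all()
        assert np.isnan(t1.loc["all", "z"])
        assert t1.loc["all", "total_ci_high"] > 0

    def test_calls_outside_region_list_rejected(self, region_1q):
        with pytest.raises(ValueError):
            build_summary_tables(self._classified(), [region_1q], 1000)

    def test_prevalence_helper_scales(self):
        est = prevalence(59, 12252)
        pt, lo, hi = est.per_10000()
        assert (pt, lo, hi) == (48.16, 37.35, 62.06)
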