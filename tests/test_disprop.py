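"""Shrinkage ROR/IC formulas, interval formulas and the signal rule."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from cardiopv.disprop import (
    AllCardiovascular,
    Comparator,
    ContingencyTable,
    PtEvent,
    UndefinedInputError,
    analyze,
    compute_signal,
    ic,
    ic_interval,
    ror_wald_ci,
    shrunk_ror,
)

cells = st.integers(min_value=0, max_value=10**6)


def tables(min_total=1):
    return (
        st.tuples(cells, cells, cells, cells)
        .filter(lambda t: sum(t) >= min_total)
        .map(lambda t: ContingencyTable(*t))
    )


class TestShrunkRor:
    def test_matches_hand_computed_ratio(self):
        # independent arithmetic: N_expected = (a+b)(a+c)/N_total
        t = ContingencyTable(a=10, b=90, c=100, d=9900)
        n_expected = (10 + 90) * (10 + 100) / (10 + 90 + 100 + 9900)
        assert t.n_expected == pytest.approx(n_expected)
        assert shrunk_ror(t) == pytest.approx((10 + 0.5) / (n_expected + 0.5))

    def test_neutral_when_observed_equals_expected(self):
        t = ContingencyTable(a=10, b=90, c=90, d=810)  # n_expected = 100*100/1000 = 10
        assert shrunk_ror(t) == pytest.approx(1.0)

    def test_empty_margin_shrinks_to_one(self):
        assert shrunk_ror(ContingencyTable(a=0, b=0, c=0, d=100)) == pytest.approx(1.0)

    def test_empty_table_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            shrunk_ror(ContingencyTable(a=0, b=0, c=0, d=0))

    @given(tables())
    @settings(derandomize=True, max_examples=200)
    def test_ic_is_log2_of_shrunk_ror(self, t):
        assert ic(t) == pytest.approx(math.log2(shrunk_ror(t)), abs=1e-12)

    @given(tables())
    @settings(derandomize=True, max_examples=200)
    def test_shrinkage_pulls_toward_null(self, t):
        # |log shrunk ratio| <= |log raw ratio| whenever the raw ratio is defined
        if t.a == 0 or t.n_expected == 0:
            return
        raw = math.log(t.a / t.n_expected)
        shrunk = math.log(shrunk_ror(t))
        assert abs(shrunk) <= abs(raw) + 1e-12


class TestIcInterval:
    # printed 3-decimal (IC, N, IC_025, IC_975) rows of the overall analysis
    PRINTED = [
        (0.605, 5263, 0.559, 0.638),
        (0.336, 67595, 0.323, 0.345),
        (0.138, 26059, 0.118, 0.153),
    ]

    @pytest.mark.parametrize("ic_value, n, lo, hi", PRINTED)
    def test_reproduces_printed_bounds(self, ic_value, n, lo, hi):
        # inputs are 3-decimal rounded, so agreement is to one unit in the
        # third decimal
        got_lo, got_hi = ic_interval(ic_value, n)
        assert got_lo == pytest.approx(lo, abs=1.05e-3)
        assert got_hi == pytest.approx(hi, abs=1.05e-3)

    def test_width_vanishes_for_large_counts(self):
        lo, hi = ic_interval(0.5, 10**12)
        assert lo == pytest.approx(0.5, abs=1e-5)
        assert hi == pytest.approx(0.5, abs=1e-5)

    @given(st.floats(-5, 5), st.integers(min_value=1, max_value=10**9))
    @settings(derandomize=True, max_examples=200)
    def test_ordering_and_monotone_width(self, ic_value, a):
        lo, hi = ic_interval(ic_value, a)
        assert lo < ic_value < hi
        lo2, hi2 = ic_interval(ic_value, a + 1)
        assert (hi2 - lo2) < (hi - lo)  # width strictly decreasing in a


class TestRorWaldCi:
    def test_closed_form_balanced_table(self):
        t = ContingencyTable(a=10, b=10, c=10, d=10)  # n_expected = 20*20/40 = 10
        r = shrunk_ror(t)
        assert r == pytest.approx(1.0)
        lo, hi = ror_wald_ci(t, r)
        half = 1.96 * math.sqrt(4 / 10)
        assert lo == pytest.approx(math.exp(-half))
        assert hi == pytest.approx(math.exp(half))

    @pytest.mark.parametrize("t", [ContingencyTable(0, 5, 5, 5), ContingencyTable(5, 5, 0, 5)])
    def test_zero_cell_leaves_bounds_undefined(self, t):
        lo, hi = ror_wald_ci(t, shrunk_ror(t))
        assert math.isnan(lo) and math.isnan(hi)
        assert math.isfinite(shrunk_ror(t))  # point estimate survives

    @given(st.tuples(*[st.integers(2, 10**4)] * 4))
    @settings(derandomize=True, max_examples=100)
    def test_halving_cells_widens_interval(self, cells4):
        a, b, c, d = (2 * (x // 2) for x in cells4)  # make divisible by 2
        big = ContingencyTable(a, b, c, d)
        small = ContingencyTable(a // 2, b // 2, c // 2, d // 2)
        lo_b, hi_b = ror_wald_ci(big, 1.0)
        lo_s, hi_s = ror_wald_ci(small, 1.0)
        assert (math.log(hi_s) - math.log(lo_s)) > (math.log(hi_b) - math.log(lo_b))


class TestSignalRule:
    def test_fewer_than_three_reports_never_signals(self):
        # arbitrarily strong disproportionality with a = 2 stays below the
        # report floor (rule checked directly: real tables with a = 2 cannot
        # even reach ic_025 > 0, since the penalty 3.3/sqrt(2.5) + 2/2.5^1.5
        # exceeds the shrinkage-capped ic of log2(5))
        res = compute_signal(ContingencyTable(a=2, b=1, c=1, d=10**6))
        assert not res.signal_by_ror and not res.signal_by_ic
        forced = type(res)(
            table=ContingencyTable(a=2, b=1, c=1, d=10**6),
            ror=50.0, ror_025=20.0, ror_975=100.0, ic=5.0, ic_025=4.0, ic_975=6.0,
        )
        assert not forced.signal_by_ror and not forced.signal_by_ic

    def test_three_reports_with_positive_ic_lower_bound_signals(self):
        res = compute_signal(ContingencyTable(a=3, b=1, c=1, d=10**6))
        assert res.ic_025 > 0
        assert res.signal_by_ic

    def test_ror_criterion_signals_with_enough_reports(self):
        res = compute_signal(ContingencyTable(a=30, b=70, c=30, d=10**4))
        assert res.ror_025 > 1
        assert res.signal_by_ror and res.signal_by_ic

    def test_boundary_is_strict(self):
        # ic_025 == 0 or ror_025 == 1 exactly must not signal (strict inequalities)
        res = compute_signal(ContingencyTable(a=100, b=100, c=100, d=100))
        at_zero = type(res)(
            table=res.table, ror=res.ror, ror_025=1.0, ror_975=res.ror_975,
            ic=res.ic, ic_025=0.0, ic_975=res.ic_975,
        )
        assert not at_zero.signal_by_ic and not at_zero.signal_by_ror

    @given(tables())
    @settings(derandomize=True, max_examples=200)
    def test_interval_invariants(self, t):
        res = compute_signal(t)
        assert res.ic_025 < res.ic < res.ic_975
        if min(t.a, t.b, t.c, t.d) > 0:
            assert res.ror_025 <= res.ror <= res.ror_975


class TestAnalyze:
    def test_absent_event_gives_null_ror(self, clean_cohort, smq_map):
        res = analyze(
            clean_cohort,
            group=__import__("cardiopv").ExposureGroup.ICI_ALONE,
            event=PtEvent("Completely absent event"),
            smq_map=smq_map,
        )
        assert res.ror == pytest.approx(1.0)  # 0.5/0.5 in the empty-margin limit
        assert not res.signal_by_ic

    def test_empty_comparator_raises(self, clean_cohort, smq_map):
        from cardiopv.model import ExposureGroup

        empty = clean_cohort.restrict_cases(
            clean_cohort.cases.loc[
                clean_cohort.cases["exposure_group"] == ExposureGroup.ICI_ALONE.value, "case_id"
            ]
        )
        with pytest.raises(Exception):
            analyze(empty, ExposureGroup.ICI_ALONE, AllCardiovascular(), smq_map,
                    comparator=Comparator.NEITHER)
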