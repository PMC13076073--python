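"""Unit and property tests for the disproportionality statistics."""
import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from pvsignal.stats import (
    ContingencyTable,
    SIGNAL,
    NO_SIGNAL,
    NOT_ESTIMABLE,
    SignalStats,
    StatsOptions,
    association_p,
    chi2_yates,
    classify_signal,
    compute_signal_stats,
    evans_criteria,
    ic_with_ic025,
    prr,
    ror_with_ci,
    rrr,
)


class TestRor:
    def test_symmetric_table_is_unity(self):
        assert ror_with_ci(ContingencyTable(10, 10, 10, 10))[0] == 1.0

    def test_point_estimate_and_woolf_interval(self):
        # frozen from direct evaluation of (a*d)/(b*c) and
        # exp(ln ROR +/- 1.96*sqrt(1/a+1/b+1/c+1/d))
        ror, lo, hi = ror_with_ci(ContingencyTable(20, 80, 10, 890))
        assert ror == 22.25
        assert lo == pytest.approx(10.069528700983788, rel=1e-12)
        assert hi == pytest.approx(49.16441620069395, rel=1e-12)

    @pytest.mark.parametrize("cells", [(0, 5, 5, 5), (5, 0, 5, 5), (5, 5, 0, 5), (5, 5, 5, 0)])
    def test_zero_cell_not_estimable(self, cells):
        assert ror_with_ci(ContingencyTable(*cells)) == (None, None, None)

    def test_continuity_mode_estimates_zero_cell_tables(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(0, 10, 10, 100), continuity=True)
        assert ror == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))
        assert lo < ror < hi


class TestSecondaryRatios:
    def test_prr_values(self):
        assert prr(ContingencyTable(10, 10, 10, 10)) == 1.0
        assert prr(ContingencyTable(20, 80, 10, 890)) == 18.0
        assert prr(ContingencyTable(5, 5, 0, 10)) is None  # c = 0

    def test_rrr_values(self):
        assert rrr(ContingencyTable(10, 90, 90, 810)) == 1.0  # observed = expected
        assert rrr(ContingencyTable(20, 80, 10, 890)) == pytest.approx(20 * 1000 / (100 * 30))
        assert rrr(ContingencyTable(0, 10, 10, 100)) == 0.0
        assert rrr(ContingencyTable(0, 0, 10, 100)) is None  # a+b = 0

    def test_chi2_values(self):
        assert chi2_yates(ContingencyTable(10, 10, 10, 10)) == 0.0
        assert chi2_yates(ContingencyTable(20, 80, 10, 890)) == pytest.approx(
            103.95189003436425, rel=1e-12
        )
        # |ad - bc| = 1 < N/2 = 5 -> floored
        assert chi2_yates(ContingencyTable(1, 2, 2, 5)) == 0.0
        assert chi2_yates(ContingencyTable(0, 0, 10, 10)) is None


class TestFisher:
    def test_modal_table_gives_one(self):
        assert association_p(ContingencyTable(10, 10, 10, 10)) == 1.0

    def test_extreme_five_five(self):
        # support C(10,5)=252; only a=5 and a=0 are as unlikely as observed
        assert association_p(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_strong_association_below_1e4(self):
        assert association_p(ContingencyTable(20, 80, 10, 890)) < 1e-4

    def test_degenerate_margin(self):
        assert association_p(ContingencyTable(0, 0, 5, 5)) == 1.0

    @pytest.mark.parametrize(
        "cells",
        [(1, 2, 3, 4), (0, 9, 4, 2), (7, 1, 0, 12), (3, 3, 3, 3), (12, 0, 0, 1)],
    )
    def test_matches_scipy_on_small_tables(self, cells):
        t = ContingencyTable(*cells)
        expected = sp_stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1]
        assert association_p(t) == pytest.approx(expected, rel=1e-9)


class TestInformationComponent:
    def test_zero_on_independence(self):
        ic, ic025 = ic_with_ic025(ContingencyTable(10, 90, 90, 810))
        assert ic == 0.0
        assert ic025 < 0.0

    def test_worked_example(self):
        ic, ic025_q = ic_with_ic025(ContingencyTable(20, 80, 10, 890))
        assert ic == pytest.approx(math.log2(20.5 / 3.5), rel=1e-12)
        _, ic025_a = ic_with_ic025(ContingencyTable(20, 80, 10, 890), mode="approx")
        assert ic025_a == pytest.approx(ic - 3.3 * 20.5**-0.5 - 2 * 20.5**-1.5)
        assert abs(ic025_q - ic025_a) < 0.15

    @pytest.mark.parametrize(
        "a,qgamma",
        # reference lower-2.5% gamma quantiles (shape a+1/2, rate 1),
        # frozen from R qgamma
        [(1, 0.107897641312), (2, 0.415605806743), (5, 1.907874126118), (20, 12.607259319056)],
    )
    def test_quantile_mode_matches_reference_gamma_quantiles(self, a, qgamma):
        t = ContingencyTable(a, 10, 10, 1000)
        ic, ic025 = ic_with_ic025(t)
        assert ic025 == pytest.approx(math.log2(qgamma / (t.expected + 0.5)), rel=1e-9)

    def test_defined_at_zero_cases(self):
        ic, ic025 = ic_with_ic025(ContingencyTable(0, 100, 200, 1000))
        assert ic < 0
        assert ic025 < ic


class TestEvansAndClassification:
    def test_case_count_strictly_greater_than_two(self):
        t = ContingencyTable(2, 10, 10, 10000)
        assert evans_criteria(t, ratio=50.0, chi2=100.0) is False

    def test_worked_example_meets_screen(self):
        t = ContingencyTable(20, 80, 10, 890)
        assert evans_criteria(t, ror_with_ci(t)[0], chi2_yates(t)) is True

    def test_not_estimable_fails_closed(self):
        t = ContingencyTable(5, 0, 10, 100)
        assert evans_criteria(t, None, 10.0) is False

    @pytest.mark.parametrize(
        "p,ic025,expected",
        [
            (5e-5, 2.74, SIGNAL),
            (0.015, -1.05, NO_SIGNAL),
            (0.51, -0.27, NO_SIGNAL),
        ],
    )
    def test_signal_rule_pairs(self, p, ic025, expected):
        s = SignalStats(
            ror=2.0, ror_ci_low=1.5, ror_ci_high=3.0, p_value=p, chi2=10.0,
            prr=2.0, rrr=2.0, expected=5.0, ic=ic025 + 1, ic025=ic025,
            n_cases=10, evans_met=True, classification="",
        )
        assert classify_signal(s) == expected

    def test_zero_cases_not_estimable(self):
        s = compute_signal_stats(ContingencyTable(0, 50, 100, 5000))
        assert s.ror is None and s.classification == NOT_ESTIMABLE

    def test_boundary_p_is_strict(self):
        s = SignalStats(
            ror=2.0, ror_ci_low=1.5, ror_ci_high=3.0, p_value=0.05, chi2=10.0,
            prr=2.0, rrr=2.0, expected=5.0, ic=1.0, ic025=0.5,
            n_cases=10, evans_met=True, classification="",
        )
        assert classify_signal(s) == NO_SIGNAL


class TestOptions:
    def test_evans_prr_mode(self):
        # ROR = 3 > 2 but PRR = 2 exactly (strictly-greater screen fails)
        t = ContingencyTable(50, 50, 100, 300)
        s_ror = compute_signal_stats(t, StatsOptions(evans_metric="ror"))
        s_prr = compute_signal_stats(t, StatsOptions(evans_metric="prr"))
        assert s_ror.evans_met != s_prr.evans_met

    def test_bad_options_rejected(self):
        with pytest.raises(ValueError):
            StatsOptions(ic_mode="bogus")
        with pytest.raises(ValueError):
            StatsOptions(evans_metric="bogus")


@st.composite
def tables(draw, max_cell=400):
    cells = [draw(st.integers(0, max_cell)) for _ in range(4)]
    if sum(cells) == 0:
        cells[3] = 1
    return ContingencyTable(*cells)


class TestTableProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(tables())
    def test_panel_invariants(self, t):
        s = compute_signal_stats(t)
        if s.ror is not None:
            assert s.ror_ci_low <= s.ror <= s.ror_ci_high
        assert 0.0 <= s.p_value <= 1.0
        assert s.ic025 < s.ic
        assert s.n_cases == t.a
        assert s.expected == pytest.approx((t.a + t.b) * (t.a + t.c) / t.n)
        if s.classification == SIGNAL:
            assert s.p_value < 0.05 and s.ic025 > 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(tables(max_cell=60))
    def test_ratios_match_exact_rationals(self, t):
        a, b, c, d = t.cells()
        if min(a, b, c, d) > 0:
            assert ror_with_ci(t)[0] == float(Fraction(a * d, b * c))
        if a + b > 0 and c > 0:
            assert prr(t) == float(Fraction(a * (c + d), c * (a + b)))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_ic_limit_is_unshrunk_ratio_at_scale(self):
        # as cells scale up with fixed proportions the shrinkage washes out
        base = (3, 7, 13, 77)
        target = math.log2(3 * 100 / (10 * 16))
        ics = []
        for k in (1, 10, 1000):
            t = ContingencyTable(*(k * x for x in base))
            ics.append(ic_with_ic025(t)[0])
        assert abs(ics[-1] - target) < 1e-3
        assert abs(ics[0] - target) > abs(ics[1] - target) > abs(ics[2] - target)
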