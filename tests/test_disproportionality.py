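"""Formula-level checks of ROR, PRR/chi-square, the information component
and the signal criteria, against independent implementations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pvsignal.disproportionality import (ContingencyTable, SignalThresholds,
                                         apply_criteria, bcpnn_ic,
                                         bcpnn_ic_mc, build_tables,
                                         compute_stats, prr_stats, ror_stats,
                                         signal_frame)
from pvsignal.dedup import Report


def brute_force_ror(a, b, c, d):
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, (ror * math.exp(-1.959963984540054 * se),
                 ror * math.exp(1.959963984540054 * se))


def make_report(i, events, outcomes=frozenset()):
    return Report(caseid=str(i), primaryid=i, fda_dt="20200101", sex="female",
                  age_years=40.0, age_band="18-44", country="US",
                  reporter="consumer", year="2020", events=list(events),
                  outcomes=set(outcomes),
                  serious_categories={"death"} if "DE" in outcomes else set(),
                  canonical_ps_drugs={"fingolimod"}, indication_group="Unknown")


@pytest.mark.parametrize("cells", [
    (10, 90, 100, 9900),
    (3, 297, 30, 9670),
    (449, 79935, 161, 17_000_000),
    (5, 50, 10, 100),
    (1, 1, 1, 1),
])
def test_statistics_match_independent_implementations(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    ror, ci, corrected = ror_stats(t)
    exp_ror, exp_ci = brute_force_ror(a, b, c, d)
    assert not corrected
    assert ror == pytest.approx(exp_ror, rel=1e-9)
    assert ci[0] == pytest.approx(exp_ci[0], rel=1e-9)
    assert ci[1] == pytest.approx(exp_ci[1], rel=1e-9)

    prr, chi2, _ = prr_stats(t)
    assert prr == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-9)
    scipy_chi2 = sps.chi2_contingency([[a, b], [c, d]], correction=False)[0]
    assert chi2 == pytest.approx(scipy_chi2, rel=1e-9)

    ic, ic025 = bcpnn_ic(t)
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    assert ic == pytest.approx(math.log2((a + 0.5) / (e + 0.5)), rel=1e-9)
    assert ic025 == pytest.approx(
        ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5, rel=1e-9)


def test_worked_example_values():
    t = ContingencyTable(10, 90, 100, 9900)
    assert ror_stats(t)[0] == pytest.approx(11.0, rel=1e-12)
    prr, chi2, _ = prr_stats(t)
    assert prr == pytest.approx(10.0, rel=1e-12)
    assert chi2 == pytest.approx(74.45, abs=0.01)
    ic, ic025 = bcpnn_ic(t)
    assert ic == pytest.approx(2.724, abs=0.001)
    assert ic025 == pytest.approx(ic - 1.077, abs=0.001)


def test_independence_table_is_null_on_all_measures():
    t = ContingencyTable(5, 50, 10, 100)
    assert ror_stats(t)[0] == pytest.approx(1.0)
    prr, chi2, _ = prr_stats(t)
    assert prr == pytest.approx(1.0)
    assert chi2 == 0.0
    # large-sample independence: IC -> 0
    big = ContingencyTable(1000, 9000, 10_000, 90_000)
    ic, _ = bcpnn_ic(big)
    assert abs(ic) < 0.001
    assert not apply_criteria(compute_stats("x", t)).signal


def test_zero_cells_take_haldane_correction_and_flag():
    t = ContingencyTable(10, 0, 0, 90)
    ror, ci, corrected = ror_stats(t)
    assert corrected and math.isfinite(ror) and math.isfinite(ci[1])
    prr, chi2, corrected2 = prr_stats(ContingencyTable(10, 90, 0, 900))
    assert corrected2 and math.isfinite(prr) and math.isfinite(chi2)


def test_ic_closed_form_tracks_posterior_quantile():
    """|closed-form IC025 - Monte-Carlo posterior quantile| <= 0.15 bits, a >= 3."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        a = int(rng.integers(3, 500))
        b = int(rng.integers(1, 5000))
        c = int(rng.integers(1, 5000))
        d = int(rng.integers(1000, 200_000))
        t = ContingencyTable(a, b, c, d)
        _, ic025 = bcpnn_ic(t)
        mc = bcpnn_ic_mc(t, n_samples=40_000, rng=rng)
        worst = max(worst, abs(ic025 - mc))
    assert worst <= 0.15


class TestCriteria:
    def test_small_count_gates_ror_and_prr(self):
        s = compute_stats("x", ContingencyTable(2, 8, 1, 989))
        assert s.ror > 100
        assert "ROR" not in s.criteria_met and "PRR" not in s.criteria_met

    def test_worked_example_meets_all_three(self):
        s = compute_stats("x", ContingencyTable(10, 90, 100, 9900))
        assert s.criteria_met == {"ROR", "PRR", "BCPNN"}

    def test_thresholds_are_overridable(self):
        strict = SignalThresholds(min_cases=20)
        s = compute_stats("x", ContingencyTable(10, 90, 100, 9900), thresholds=strict)
        assert "ROR" not in s.criteria_met

    @given(st.integers(1, 200), st.integers(1, 2000), st.integers(100, 50_000))
    @settings(max_examples=40)
    def test_signal_monotone_in_case_count(self, b, c, d):
        fired = False
        for a in range(1, 40):
            s = compute_stats("x", ContingencyTable(a, b, c, d))
            if fired:
                assert s.signal, (a, b, c, d)
            fired = fired or s.signal


@given(st.tuples(st.integers(1, 1000), st.integers(1, 1000),
                 st.integers(1, 1000), st.integers(1, 1000)))
def test_ror_exceeds_prr_whenever_ror_above_one(cells):
    t = ContingencyTable(*cells)
    ror = ror_stats(t)[0]
    if ror > 1:
        assert ror > prr_stats(t)[0]


class TestBuildTables:
    def test_separable_cohort(self):
        cohort = [make_report(i, ["PT_x"]) for i in range(10)]
        comparator = [make_report(100 + i, ["PT_y"]) for i in range(90)]
        t = build_tables(cohort, comparator)["pt_x"]
        assert (t.a, t.b, t.c, t.d) == (10, 0, 0, 90)

    def test_repeated_pt_counts_once_per_report(self):
        cohort = [make_report(1, ["PT_x", "PT_x", "PT_y"])]
        comparator = [make_report(2, ["PT_z"])]
        tables = build_tables(cohort, comparator)
        assert tables["pt_x"].a == 1 and tables["pt_y"].a == 1
        assert "pt_z" not in tables  # a = 0 events never emitted

    def test_soc_level_counts_once_per_soc(self):
        soc = {"PT_x": "Eye disorders", "PT_y": "Eye disorders"}
        cohort = [make_report(1, ["PT_x", "PT_y"])]
        comparator = [make_report(2, ["PT_x"])]
        tables = build_tables(cohort, comparator, level="soc", pt_to_soc=soc)
        assert tables["Eye disorders"].a == 1

    def test_empty_comparator_is_an_error(self):
        with pytest.raises(ValueError, match="comparator"):
            build_tables([make_report(1, ["PT_x"])], [])

    def test_signal_frame_columns(self):
        cohort = [make_report(i, ["PT_x"]) for i in range(5)]
        comparator = [make_report(10 + i, ["PT_y"]) for i in range(5)]
        frame = signal_frame(build_tables(cohort, comparator))
        assert list(frame.columns) == [
            "event", "soc", "a", "ror", "ror_l95", "ror_u95", "prr", "chi2",
            "ic", "ic025", "criteria_met", "corrected", "signal"]
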