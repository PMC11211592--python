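import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvhepascan.cohort import HRAE
from pvhepascan.disprop import (
    ConsistencyError,
    ContingencyTable,
    DisproportionalityResult,
    SignalCriteria,
    UndefinedResultError,
    derive_table,
    evaluate_signal,
    ic,
    relative_risk,
    ror,
    round_half_up,
    scan,
)

# the autoimmune-hepatitis 2×2 cells: 634 of 353,949 ICI event records vs
# 4,566 events among the remaining 49,568,379-record database
AIH = dict(n_observed=634, n_drug=353_949, n_event_comparator=4_566, n_total=49_568_379)


class TestDeriveTable:
    def test_external_comparator_cells(self):
        t = derive_table(**AIH, convention="external-comparator")
        assert (t.a, t.b, t.c, t.d) == (634, 353_315, 4_566, 49_209_864)

    def test_zero_counts(self):
        t = derive_table(0, 100, 0, 1000, convention="external-comparator")
        assert (t.a, t.b, t.c, t.d) == (0, 100, 0, 900)

    def test_d_is_total_minus_margins(self):
        t = derive_table(546, 353_949, 350, 49_568_379)
        assert t.d == 49_568_379 - 353_949 - 350 == 49_214_080

    def test_head_to_head_cells(self):
        t = derive_table(336, 268_517, 8, 22_903, convention="head-to-head")
        assert (t.a, t.b, t.c, t.d) == (336, 268_181, 8, 22_895)

    def test_negative_cell_is_an_error_naming_inputs(self):
        with pytest.raises(ConsistencyError, match="n_drug=50"):
            derive_table(60, 50, 0, 1000)


class TestRor:
    def test_reproduces_published_autoimmune_hepatitis_interval(self):
        r = ror(ContingencyTable(634, 353_315, 4_566, 49_209_864))
        assert round_half_up(r.estimate) == 19.34
        assert round_half_up(r.low) == 17.80
        assert round_half_up(r.high) == 21.02

    @pytest.mark.parametrize(
        "cells,expected",
        [((10, 10, 10, 10), 1.0), ((5, 5, 1, 10), 10.0)],
    )
    def test_point_estimates(self, cells, expected):
        assert ror(ContingencyTable(*cells)).estimate == pytest.approx(expected)

    def test_zero_observed_flags_undefined_bounds(self):
        r = ror(ContingencyTable(0, 100, 10, 1000))
        assert r.estimate == 0.0 and not r.defined_bounds
        assert math.isnan(r.low)

    def test_all_zero_table_raises(self):
        with pytest.raises(UndefinedResultError):
            ror(ContingencyTable(0, 0, 0, 0))

    def test_haldane_correction_defined_on_zero_cells(self):
        r = ror(ContingencyTable(5, 10, 0, 20), correction="haldane")
        assert r.estimate == pytest.approx((5.5 * 20.5) / (10.5 * 0.5))
        assert r.defined_bounds

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_exact_cross_product_and_symmetry(self, cells):
        """Estimate equals exact rational arithmetic; swapping roles inverts it."""
        a, b, c, d = cells
        t = ContingencyTable(a, b, c, d)
        exact = Fraction(a * d, b * c)
        r = ror(t)
        assert r.estimate == pytest.approx(float(exact), rel=1e-12)
        assert r.estimate * ror(t.swapped()).estimate == pytest.approx(1.0, abs=1e-9)
        assert r.low <= r.estimate <= r.high

    def test_interval_narrows_as_cells_scale(self):
        widths = []
        for k in (1, 2, 4, 8):
            r = ror(ContingencyTable(5 * k, 50 * k, 8 * k, 100 * k))
            widths.append(math.log(r.high) - math.log(r.low))
        assert widths == sorted(widths, reverse=True)

    def test_agrees_with_statsmodels_oracle(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = ContingencyTable(634, 353_315, 4_566, 49_209_864)
        oracle = sm_ct.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        r = ror(t)
        assert r.estimate == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = oracle.oddsratio_confint()
        # the oracle uses z=1.959964 vs the conventional 1.96 here
        assert r.low == pytest.approx(lo, rel=1e-4)
        assert r.high == pytest.approx(hi, rel=1e-4)


class TestIc:
    def test_zero_at_forced_equality_under_both_methods(self):
        # margins chosen so n_expected == n_observed == 37
        for method in ("plain", "shrunk"):
            est = ic(37, 100, 37, 100, method=method)
            assert est.n_expected == pytest.approx(37.0)
            assert est.ic == pytest.approx(0.0)

    def test_expected_count_formula(self):
        est = ic(634, 353_949, 5_200, 49_568_379)
        assert est.n_expected == pytest.approx(37.13, abs=0.01)

    def test_shrinkage_forces_negative_ic_at_zero_observed(self):
        est = ic(0, 100, 10, 10_000, method="shrunk")
        assert est.ic == pytest.approx(math.log2(0.5 / 0.6))
        assert est.ic < 0

    def test_plain_sign_agrees_with_observed_minus_expected(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n_total = int(rng.integers(1_000, 100_000))
            n_drug = int(rng.integers(10, n_total // 2))
            n_event = int(rng.integers(10, n_total // 2))
            n_obs = int(rng.integers(1, min(n_drug, n_event)))
            est = ic(n_obs, n_drug, n_event, n_total, method="plain")
            assert np.sign(est.ic) == np.sign(n_obs - est.n_expected)

    def test_bounds_bracket_the_estimate(self):
        est = ic(50, 1_000, 600, 100_000)
        assert est.ic025 <= est.ic <= est.ic975

    def test_zero_total_is_a_domain_error(self):
        with pytest.raises(ValueError):
            ic(1, 10, 10, 0)


class TestRelativeRisk:
    def test_published_pooled_trial_ratio(self):
        assert round_half_up(relative_risk(6.5, 3.8)) == 1.71

    @pytest.mark.parametrize("x", [0.5, 3.8, 42.0])
    def test_identity_and_zero(self, x):
        assert relative_risk(x, x) == pytest.approx(1.0)
        assert relative_risk(0, x) == 0.0

    def test_zero_comparator_raises(self):
        with pytest.raises(ValueError):
            relative_risk(5, 0)


class TestEvaluateSignal:
    def make(self, n, ror05, ic025):
        return DisproportionalityResult(
            event="E", cohort="C", n_observed=n, n_expected=1.0,
            ror=ror05 * 1.5, ror05=ror05, ror95=ror05 * 3,
            ic=ic025 + 1, ic025=ic025, ic975=ic025 + 2,
        )

    @pytest.mark.parametrize(
        "n,ror05,ic025,expected",
        [
            (634, 17.80, 2.43, True),   # designated hepatitis signal
            (9, 5.0, 1.0, False),       # below the ten-case minimum
            (85, 1.83, -0.50, False),   # ROR05 clears but IC025 does not
            (10, 1.01, 0.01, True),     # minimum is inclusive
        ],
    )
    def test_joint_criterion(self, n, ror05, ic025, expected):
        assert evaluate_signal(self.make(n, ror05, ic025), SignalCriteria()) is expected


class TestScan:
    def test_empty_cohort_yields_zero_rows_not_errors(self, fixture_store):
        results = scan(fixture_store, {"EMPTY": []}, HRAE)
        assert len(results) == len(HRAE.terms)
        assert all(r.n_observed == 0 and not r.defined and not r.signal for r in results)

    def test_store_without_matching_terms_counts_zero(self, fixture_store):
        from pvhepascan.cohort import EventTermSet

        absent = EventTermSet.from_terms("NONE", ["Completely absent term"])
        results = scan(fixture_store, {"ALL": list(fixture_store.demo["primaryid"])}, absent)
        assert [r.n_observed for r in results] == [0]

    def test_bonferroni_widens_intervals_and_never_adds_signals(self, synth_store):
        from pvhepascan.cohort import HEPATITIS_SCAN, label_regimens
        from pvhepascan.pipeline import strategy_cohorts

        cohorts = strategy_cohorts(label_regimens(synth_store))
        plain = scan(synth_store, cohorts, HEPATITIS_SCAN)
        adjusted = scan(synth_store, cohorts, HEPATITIS_SCAN, bonferroni=True)
        flagged_plain = {(r.event, r.cohort) for r in plain if r.signal}
        flagged_adj = {(r.event, r.cohort) for r in adjusted if r.signal}
        assert flagged_adj <= flagged_plain
        by_key = {(r.event, r.cohort): r for r in plain}
        for r in adjusted:
            p = by_key[(r.event, r.cohort)]
            if r.defined and p.defined and r.n_observed > 0:
                assert r.ror05 <= p.ror05 and r.ror95 >= p.ror95

    def test_rows_sorted_by_descending_count(self, synth_store):
        from pvhepascan.cohort import HEPATITIS_SCAN
        from pvhepascan.cohort import label_regimens
        from pvhepascan.pipeline import strategy_cohorts

        results = scan(synth_store, strategy_cohorts(label_regimens(synth_store)),
                       HEPATITIS_SCAN)
        counts = [r.n_observed for r in results]
        assert counts == sorted(counts, reverse=True)
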