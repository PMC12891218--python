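"""Tests for contingency tables, ROR/PRR estimates and confidence intervals."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from hypnovigil.case_selection import select_modified_smq
from hypnovigil.disproportionality import (
    ContingencyTable,
    OVERALL_EVENT,
    UndefinedTableError,
    make_table,
    prr,
    pt_frequency_filter,
    ror,
    run_analysis,
)
from tests.conftest import build_case

DORA_Z = ContingencyTable(a=262, b=9701, c=2063, d=11432)

cells = st.integers(min_value=1, max_value=5000)


class TestRor:
    def test_benchmark_table_point_estimate_and_ci(self):
        result = ror(DORA_Z)
        assert result.estimate == pytest.approx(0.1497, abs=5e-4)
        assert round(result.ci_low, 3) == 0.131
        assert round(result.ci_high, 3) == 0.171
        assert not result.continuity_corrected

    def test_identical_rows_give_unity(self):
        result = ror(ContingencyTable(a=10, b=90, c=10, d=90))
        assert result.estimate == pytest.approx(1.0)
        assert result.ci_low < 1 < result.ci_high

    @given(cells, cells, cells, cells)
    def test_reciprocal_symmetry(self, a, b, c, d):
        """Swapping index and reference rows inverts the estimate and mirrors the CI."""
        fwd = ror(ContingencyTable(a, b, c, d))
        rev = ror(ContingencyTable(c, d, a, b))
        assert fwd.estimate * rev.estimate == pytest.approx(1.0)
        assert fwd.ci_low == pytest.approx(1 / rev.ci_high)
        assert fwd.ci_high == pytest.approx(1 / rev.ci_low)

    @given(cells, cells, cells, cells)
    def test_cross_product_identity(self, a, b, c, d):
        result = ror(ContingencyTable(a, b, c, d))
        assert result.estimate == pytest.approx(a * d / (b * c))

    @given(cells, cells, cells, cells, st.integers(2, 10))
    def test_ci_width_shrinks_with_scale(self, a, b, c, d, k):
        base = ror(ContingencyTable(a, b, c, d))
        scaled = ror(ContingencyTable(a * k, b * k, c * k, d * k))
        base_width = math.log(base.ci_high) - math.log(base.ci_low)
        scaled_width = math.log(scaled.ci_high) - math.log(scaled.ci_low)
        assert scaled_width < base_width
        assert scaled.estimate == pytest.approx(base.estimate)

    @given(cells, cells, cells, cells)
    def test_matches_statsmodels_woolf_interval(self, a, b, c, d):
        """Independent cross-check: statsmodels' Table2x2 log-OR interval."""
        result = ror(ContingencyTable(a, b, c, d))
        table = Table2x2([[a, b], [c, d]])
        assert result.estimate == pytest.approx(table.oddsratio)
        low, high = table.oddsratio_confint(0.05)
        assert result.ci_low == pytest.approx(low)
        assert result.ci_high == pytest.approx(high)

    def test_zero_cell_continuity_correction(self):
        result = ror(ContingencyTable(a=0, b=50, c=5, d=45))
        assert result.continuity_corrected
        assert result.estimate == pytest.approx((0.5 / 50.5) / (5.5 / 45.5))
        assert 0 < result.ci_low <= result.estimate <= result.ci_high

    def test_fixed_z_option(self):
        exact = ror(DORA_Z)
        legacy = ror(DORA_Z, z_value=1.96)
        assert legacy.ci_low != exact.ci_low
        assert legacy.ci_low == pytest.approx(exact.ci_low, rel=1e-3)


class TestPrr:
    def test_identical_proportions_give_unity(self):
        assert prr(ContingencyTable(a=5, b=95, c=10, d=190)).estimate == pytest.approx(1.0)

    def test_benchmark_table_value(self):
        result = prr(DORA_Z)
        assert result.estimate == pytest.approx((262 / 9963) / (2063 / 13495))
        assert round(result.estimate, 3) == 0.172

    @given(cells, cells, cells, cells)
    def test_prr_below_ror_when_protective(self, a, b, c, d):
        """For estimates < 1 the PRR is attenuated toward 1 relative to the ROR."""
        r, p = ror(ContingencyTable(a, b, c, d)), prr(ContingencyTable(a, b, c, d))
        if r.estimate < 1:
            assert r.estimate <= p.estimate
        elif r.estimate > 1:
            assert p.estimate <= r.estimate

    @given(cells, cells, cells, cells)
    def test_ci_contains_estimate(self, a, b, c, d):
        for result in (ror(ContingencyTable(a, b, c, d)), prr(ContingencyTable(a, b, c, d))):
            assert result.ci_low <= result.estimate <= result.ci_high


class TestMakeTable:
    def zolpidem_case(self, i, event):
        return build_case(
            f"Z{i}",
            drugs=[("ZOLPIDEM", "PS")],
            reactions=["Drug abuse"] if event else ["Headache"],
        )

    def dora_case(self, i, event):
        return build_case(
            f"D{i}",
            drugs=[("SUVOREXANT", "PS")],
            reactions=["Drug abuse"] if event else ["Headache"],
        )

    def test_cells_match_brute_force_tally(self, groups, smq):
        rnd = random.Random(7)
        cases, flags = [], {}
        for i in range(120):
            is_dora = rnd.random() < 0.5
            event = rnd.random() < 0.3
            case = self.dora_case(i, event) if is_dora else self.zolpidem_case(i, event)
            cases.append(case)
            flags[case.case_id] = (is_dora, event)
        by_name = {g.name: g for g in groups}
        outcomes, _ = select_modified_smq(cases, smq)
        selected = {o.case_id for o in outcomes if o.selected}
        table = make_table(
            cases, by_name["dora"], by_name["z_drug"], lambda c: c.case_id in selected
        )
        a = sum(1 for cid, (d, e) in flags.items() if d and e)
        b = sum(1 for cid, (d, e) in flags.items() if d and not e)
        c = sum(1 for cid, (d, e) in flags.items() if not d and e)
        d = sum(1 for cid, (d_, e) in flags.items() if not d_ and not e)
        assert (table.a, table.b, table.c, table.d) == (a, b, c, d)

    def test_empty_margin_raises(self, groups):
        by_name = {g.name: g for g in groups}
        cases = [self.dora_case(0, True)]
        with pytest.raises(UndefinedTableError):
            make_table(cases, by_name["dora"], by_name["z_drug"], lambda c: True)

    def test_co_mention_counted_in_both_by_default(self, groups, smq):
        both = build_case("B0", drugs=[("SUVOREXANT", "PS"), ("ZOLPIDEM", "C")], reactions=["Drug abuse"])
        cases = [both, self.dora_case(1, False), self.zolpidem_case(2, False)]
        by_name = {g.name: g for g in groups}
        table = make_table(cases, by_name["dora"], by_name["z_drug"], lambda c: "Drug abuse" in c.reactions)
        assert (table.a, table.c) == (1, 1)
        with pytest.raises(UndefinedTableError):
            # exclusive mode drops the co-mention case, leaving the reference margin empty
            make_table(
                [both, self.dora_case(1, False)],
                by_name["dora"], by_name["z_drug"], lambda c: True, co_mention="exclusive",
            )

    def test_self_comparison_rejected(self, groups):
        dora = next(g for g in groups if g.name == "dora")
        with pytest.raises(ValueError):
            make_table([], dora, dora, lambda c: True)


class TestPtFrequencyFilter:
    def group_cases(self, prefix, drug, n, pt_counts):
        """n cases on one drug; pt_counts maps PT -> number of cases reporting it."""
        cases = []
        assignments = []
        for pt, k in pt_counts.items():
            assignments.extend([pt] * k)
        for i in range(n):
            reactions = [assignments[i]] if i < len(assignments) else ["Headache"]
            cases.append(build_case(f"{prefix}{i}", drugs=[(drug, "PS")], reactions=reactions))
        return cases

    def test_threshold_in_any_group_includes(self, smq):
        index = self.group_cases("a", "SUVOREXANT", 100, {"Drug abuse": 2})     # 2%
        reference = self.group_cases("b", "ZOLPIDEM", 1000, {"Drug abuse": 1})  # 0.1%
        kept = pt_frequency_filter({"dora": index, "z_drug": reference}, smq, threshold=0.01)
        assert kept == ["Drug abuse"]

    def test_below_threshold_everywhere_excluded(self, smq):
        index = self.group_cases("a", "SUVOREXANT", 1000, {"Drug abuse": 5})
        kept = pt_frequency_filter({"dora": index}, smq, threshold=0.01)
        assert kept == []

    def test_zero_threshold_returns_all_observed(self, smq):
        index = self.group_cases("a", "SUVOREXANT", 50, {"Drug abuse": 1, "Overdose": 1})
        kept = pt_frequency_filter({"dora": index}, smq, threshold=0.0)
        assert set(kept) == {"Drug abuse", "Overdose"}


class TestRunAnalysis:
    def build_corpus(self):
        cases = []
        for i in range(200):
            event = i % 10 == 0
            cases.append(build_case(f"D{i}", drugs=[("SUVOREXANT", "PS")],
                                    reactions=["Drug abuse"] if event else ["Headache"]))
        for i in range(200):
            event = i % 4 == 0
            cases.append(build_case(f"Z{i}", drugs=[("ZOLPIDEM", "PS")],
                                    reactions=["Drug abuse"] if event else ["Headache"]))
        return cases

    def test_overall_rows_first_and_ordering_deterministic(self, groups, smq):
        rows = run_analysis(self.build_corpus(), groups, smq, comparisons=[("dora", "z_drug")])
        assert rows[0].event == OVERALL_EVENT and rows[0].measure == "ROR"
        assert rows[1].event == OVERALL_EVENT and rows[1].measure == "PRR"
        assert all(r.group == "dora" and r.reference == "z_drug" for r in rows)
        again = run_analysis(self.build_corpus(), groups, smq, comparisons=[("dora", "z_drug")])
        assert rows == again

    def test_overall_cells_match_selection(self, groups, smq):
        rows = run_analysis(self.build_corpus(), groups, smq, comparisons=[("dora", "z_drug")])
        overall = rows[0]
        assert (overall.a, overall.b, overall.c, overall.d) == (20, 180, 50, 150)

    def test_self_comparison_rejected(self, groups, smq):
        with pytest.raises(ValueError):
            run_analysis([], groups, smq, comparisons=[("dora", "dora")])

    def test_missing_reference_group_fatal(self, smq, groups):
        with pytest.raises(KeyError):
            run_analysis([], groups, smq, comparisons=[("dora", "nonexistent")])
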