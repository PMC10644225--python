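"""ROR engine: point estimate, Woolf interval, signal rule, SOC
roll-up and stratified runs."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvror.cohort import COMPARATOR, TARGET, SafetyCase
from pvror.records import RawReport
from pvror.signals import (
    ContingencyTable,
    StratumSpec,
    analyze_stratum,
    build_contingency,
    classify_signal,
    event_pair_counts,
    ror,
    ror_ci,
    run_stratified,
    soc_long_table,
    soc_rollup,
)

_cells = st.integers(min_value=1, max_value=500)


class TestContingency:
    def test_worked_example(self):
        table = build_contingency((30, 62), (4888, 374575))
        assert (table.a, table.b, table.c, table.d) == (30, 4858, 62,
                                                        374513)

    def test_absent_everywhere(self):
        table = build_contingency((0, 0), (100, 200))
        assert table.a == 0 and table.c == 0

    def test_only_in_target(self):
        table = build_contingency((5, 0), (100, 200))
        assert table.c == 0 and table.d == 200

    def test_inconsistent_totals_fatal(self):
        with pytest.raises(ValueError):
            build_contingency((30, 5), (10, 200))

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestRor:
    def test_hand_computed_values(self):
        assert math.isclose(ror(ContingencyTable(10, 20, 30, 40)),
                            400 / 600)
        assert ror(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_published_drug_eruption_row(self):
        table = build_contingency((30, 62), (4888, 374575))
        assert round(ror(table), 2) == 37.30
        low, high = ror_ci(table)
        assert round(low, 2) == 24.10 and round(high, 2) == 57.74

    def test_zero_cell_is_missing_without_correction(self):
        table = ContingencyTable(0, 10, 5, 100)
        assert ror(table) is None
        assert ror_ci(table) == (None, None)

    def test_continuity_correction_behind_flag(self):
        table = ContingencyTable(0, 10, 5, 100)
        expected = (0.5 * 100.5) / (10.5 * 5.5)
        assert math.isclose(ror(table, continuity=True), expected)

    def test_woolf_interval_hand_computed(self):
        low, high = ror_ci(ContingencyTable(10, 20, 30, 40))
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40)
        assert math.isclose(low, math.exp(math.log(2 / 3) - 1.96 * se))
        assert round(low, 4) == 0.2725 and round(high, 4) == 1.6309

    @given(_cells, _cells, _cells, _cells)
    def test_group_swap_antisymmetry(self, a, b, c, d):
        product = (Fraction(a * d, b * c) * Fraction(c * b, d * a))
        assert product == 1
        swapped = ror(ContingencyTable(c, d, a, b))
        assert math.isclose(ror(ContingencyTable(a, b, c, d)) * swapped,
                            1.0, rel_tol=1e-12)

    @given(_cells, _cells, _cells, _cells, st.integers(2, 50))
    def test_scale_invariance(self, a, b, c, d, k):
        assert math.isclose(
            ror(ContingencyTable(k * a, k * b, c, d)),
            ror(ContingencyTable(a, b, c, d)), rel_tol=1e-12)

    @given(_cells, _cells, _cells, _cells)
    def test_ci_contains_point_estimate(self, a, b, c, d):
        table = ContingencyTable(a, b, c, d)
        low, high = ror_ci(table)
        assert low <= ror(table) <= high
        # symmetric about ln ROR on the log scale
        assert math.isclose(math.log(low) + math.log(high),
                            2 * math.log(ror(table)), rel_tol=1e-9,
                            abs_tol=1e-9)

    def test_interval_narrows_as_cells_grow(self):
        small = ror_ci(ContingencyTable(10, 20, 30, 40))
        big = ror_ci(ContingencyTable(1000, 2000, 3000, 4000))
        assert (big[1] - big[0]) < (small[1] - small[0])
        assert math.isclose(ror(ContingencyTable(1000, 2000, 3000, 4000)),
                            ror(ContingencyTable(10, 20, 30, 40)))

    def test_oracle_equivalence_statsmodels(self):
        """Point estimate agrees with an independent 2x2 implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 501, size=4)
            table = ContingencyTable(int(a), int(b), int(c), int(d))
            oracle = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
            assert math.isclose(ror(table), oracle.oddsratio,
                                rel_tol=1e-12)
            low, high = ror_ci(table)
            olow, ohigh = oracle.oddsratio_confint()
            # statsmodels uses the exact normal quantile, we use 1.96
            assert math.isclose(low, olow, rel_tol=1e-3)
            assert math.isclose(high, ohigh, rel_tol=1e-3)


class TestSignalRule:
    @pytest.mark.parametrize("n,ci_low,expected", [
        (3, 1.01, True),
        (2, 5.0, False),       # fewer than three reports never signals
        (10, 1.0, False),      # boundary: strictly greater than 1
        (100, 0.99, False),
        (3, None, False),
    ])
    def test_boundaries(self, n, ci_low, expected):
        assert classify_signal(n, ci_low) is expected


def _case(pid, group, events, sex=None, age=None, occ=None):
    return SafetyCase(
        report=RawReport(primary_id=pid, case_id=pid, sex=sex,
                         age_value=age,
                         age_code="YR" if age is not None else None,
                         occupation_code=occ),
        events=set(events), group=group)


class TestEventPairCounts:
    def test_duplicate_pt_in_one_report_counted_once(self):
        cohort = [_case(1, TARGET, {"Rash"})]
        counts, pairs, reports = event_pair_counts(cohort)
        assert counts["Rash"] == (1, 0) and pairs == (1, 0)

    def test_counts_accumulate_across_reports(self):
        cohort = [_case(1, TARGET, {"Diarrhoea"}),
                  _case(2, TARGET, {"Diarrhoea", "Rash"}),
                  _case(3, COMPARATOR, {"Diarrhoea"})]
        counts, pairs, reports = event_pair_counts(cohort)
        assert counts["Diarrhoea"] == (2, 1)
        assert pairs == (3, 1) and reports == (2, 1)

    def test_conservation_per_stratum(self, small_cohort):
        counts, pairs, _ = event_pair_counts(small_cohort)
        assert sum(t for t, _ in counts.values()) == pairs[0]
        assert sum(c for _, c in counts.values()) == pairs[1]


class TestSocRollup:
    def _results(self):
        return analyze_stratum(
            [_case(1, TARGET, {"Diarrhoea"}),
             _case(2, TARGET, {"Diarrhoea", "Rash"}),
             _case(3, TARGET, {"Diarrhoea"}),
             _case(4, COMPARATOR, {"Rash"}),
             _case(5, COMPARATOR, {"Rash"})], "overall")

    def test_mapping_annotates_soc(self):
        results, summary = soc_rollup(
            self._results(), {"Diarrhoea": "Gastrointestinal disorders",
                              "Rash": "Skin disorders"})
        by_pt = {r.event_pt: r.soc for r in results}
        assert by_pt["Diarrhoea"] == "Gastrointestinal disorders"

    def test_empty_mapping_warns_and_counts_zero(self):
        with pytest.warns(UserWarning, match="SOC mapping"):
            results, summary = soc_rollup(self._results(), {})
        assert all(r.soc is None for r in results)
        assert len(summary) == 0

    def test_toy_vocabulary_covers_generated_pts(self, small_cohort):
        import warnings

        from pvror.synthetic import toy_pt_to_soc

        results = analyze_stratum(small_cohort, "overall")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            annotated, _ = soc_rollup(results, toy_pt_to_soc())
        assert all(r.soc is not None for r in annotated)


class TestStratifiedRuns:
    def _cohort(self):
        cases = []
        for i in range(40):
            sex = "F" if i % 2 == 0 else "M"
            age = 70 if i % 4 == 0 else 40
            occ = "MD" if i % 3 == 0 else "CN"
            group = TARGET if i < 10 else COMPARATOR
            events = {"Diarrhoea"} if i % 5 == 0 else {"Rash"}
            cases.append(_case(i, group, events, sex=sex, age=age, occ=occ))
        cases.append(_case(99, TARGET, {"Rash"}))  # unknown age and sex
        return cases

    def test_age_and_sex_strata_exclude_unknowns(self):
        cohort = self._cohort()
        out = run_stratified(cohort)
        overall_n = out["overall"].n.sum()
        assert out["age_lt65"].n.sum() + out["age_ge65"].n.sum() \
            == overall_n - 1
        assert out["female"].n.sum() + out["male"].n.sum() == overall_n - 1

    def test_both_groups_filtered_identically(self):
        cohort = self._cohort()
        hp = [c for c in cohort
              if c.report.occupation_code == "MD"]
        expected_counts, _, _ = event_pair_counts(hp)
        frame = run_stratified(cohort)["health_professional"]
        for _, row in frame.iterrows():
            assert row.n == expected_counts[row.event_pt][0]

    def test_empty_target_stratum_warns(self):
        cohort = [_case(1, COMPARATOR, {"Rash"}, sex="F")]
        with pytest.warns(UserWarning, match="empty target group"):
            out = run_stratified(cohort,
                                 [StratumSpec("overall", lambda c: True)])
        assert len(out["overall"]) == 0

    def test_results_sorted_by_ror_within_soc(self, small_cohort):
        from pvror.synthetic import toy_pt_to_soc

        frame = run_stratified(
            small_cohort, [StratumSpec("overall", lambda c: True)],
            pt_to_soc=toy_pt_to_soc())["overall"]
        for _, sub in frame.dropna(subset=["ror"]).groupby("soc"):
            rors = sub.ror.tolist()
            assert rors == sorted(rors, reverse=True)

    def test_soc_long_table_matches_signal_counts(self, small_cohort):
        from pvror.synthetic import toy_pt_to_soc

        out = run_stratified(small_cohort, pt_to_soc=toy_pt_to_soc())
        long = soc_long_table(out)
        for name, frame in out.items():
            expected = int(frame[frame.soc.notna()].is_signal.sum())
            got = int(long[long.stratum == name].n_signals.sum())
            assert got == expected
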