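"""Descriptive characteristics: age handling, category mappings,
percentages and event rankings."""

import pytest

from pvror.cohort import COMPARATOR, TARGET, SafetyCase
from pvror.descriptives import (
    age_bin,
    age_in_years,
    characteristics,
    country_category,
    dosage_category,
    reporter_category,
    sex_ratio,
    sex_ratio_from_counts,
    top_events,
)
from pvror.records import DrugRecord, RawReport
from pvror.util import round_half_up


class TestAgeConversion:
    @pytest.mark.parametrize("value,code,years", [
        (65, "YR", 65.0),
        (24, "MON", 2.0),
        (7, "DEC", 70.0),
        (52, "WK", 1.0),
        (365.25, "DY", 1.0),
        (8766, "HR", 1.0),
        (None, "YR", None),
        (30, None, None),
    ])
    def test_unit_codes(self, value, code, years):
        assert age_in_years(value, code) == years

    def test_negative_age_is_unknown_with_warning(self):
        with pytest.warns(UserWarning, match="negative age"):
            assert age_in_years(-5, "YR") is None

    @pytest.mark.parametrize("years,label", [
        (17.9, "<18"), (18, "18–44"), (44, "18–44"), (44.9, "18–44"),
        (45, "45–64"), (64.9, "45–64"), (65, "≥65"), (100, "≥65"),
        (None, "Unknown"),
    ])
    def test_age_bins(self, years, label):
        assert age_bin(years) == label


class TestCategoryMappings:
    @pytest.mark.parametrize("code,category", [
        ("MD", "Health professional"), ("PH", "Health professional"),
        ("OT", "Health professional"), ("CN", "Non-Health professional"),
        ("LW", "Non-Health professional"), (None, "Unknown"),
    ])
    def test_reporter(self, code, category):
        assert reporter_category(code) == category

    @pytest.mark.parametrize("country,category", [
        ("US", "United States"), ("JP", "Japan"), ("Japan", "Japan"),
        ("GB", "Other countries"), (None, "Not Specified"),
    ])
    def test_country(self, country, category):
        assert country_category(country) == category

    @pytest.mark.parametrize("amount,unit,freq,category", [
        (800, "MG", "BID", "Dosage according to the label"),
        (400, "MG", "BID", "Dosage below the label"),
        (1600, "MG", "QD", "Dosage according to the label"),
        (1200, "MG", "BID", "Dosage above the label"),
        (None, None, None, "Unknown"),
        (800, "G", "BID", "Unknown"),        # unit not understood
        (800, "MG", "PRN", "Unknown"),       # frequency not understood
    ])
    def test_dosage(self, amount, unit, freq, category):
        drug = DrugRecord(primary_id=1, drug_seq=1, role_code="PS",
                          drug_name="MOLNUPIRAVIR", dose_amount=amount,
                          dose_unit=unit, dose_frequency=freq)
        assert dosage_category(drug) == category


def _case(pid, group, sex=None, age=None, occ=None, country=None,
          outcomes=(), events=()):
    return SafetyCase(
        report=RawReport(primary_id=pid, case_id=pid, age_value=age,
                         age_code="YR" if age is not None else None,
                         sex=sex, occupation_code=occ,
                         reporter_country=country),
        outcomes=set(outcomes), events=set(events), group=group)


class TestCharacteristics:
    def test_counts_sum_to_group_size(self, small_cohort):
        table = characteristics(small_cohort)
        for group in (TARGET, COMPARATOR):
            sub = table[table.group == group]
            n_group = sub[sub.characteristic == "Sex"].n.sum()
            for name in ("Age (years)", "Sex", "Type of reporter",
                         "Reporting country"):
                assert sub[sub.characteristic == name].n.sum() == n_group

    def test_all_unknown_ages(self):
        cohort = [_case(i, TARGET) for i in range(4)]
        table = characteristics(cohort)
        row = table[(table.characteristic == "Age (years)")
                    & (table.category == "Unknown")]
        assert row.n.item() == 4 and row.pct.item() == 100.0

    def test_multi_outcome_report_counted_in_each_row(self):
        cohort = [_case(1, TARGET, outcomes={"DE", "HO"}),
                  _case(2, TARGET)]
        table = characteristics(cohort)
        outcome = table[table.characteristic == "Outcome"].set_index(
            "category")
        assert outcome.loc["Death", "n"] == 1
        assert outcome.loc["Hospitalizations", "n"] == 1
        assert outcome.loc["Non-Serious", "n"] == 1

    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError):
            characteristics([])

    def test_synthetic_marginals_match_config_within_3_sigma(
            self, small_sample, small_cohort):
        """Observed category shares track the generator's configured
        probabilities (binomial 3σ), conditional on COVID retention
        being independent of demographics."""
        from pvror.synthetic import SyntheticConfig

        probs = dict(zip(["Female", "Male", "Unknown"],
                         SyntheticConfig().sex_probs))
        table = characteristics(small_cohort)
        sub = table[(table.group == COMPARATOR)
                    & (table.characteristic == "Sex")]
        n = sub.n.sum()
        for _, row in sub.iterrows():
            p = probs[row.category]
            sigma = (p * (1 - p) / n) ** 0.5
            assert abs(row.n / n - p) < 3 * sigma


class TestSexRatio:
    def test_published_ratios(self):
        assert sex_ratio_from_counts(968, 1139) == 0.85
        assert sex_ratio_from_counts(44563, 59484) == 0.75

    def test_equal_counts(self):
        cohort = [_case(1, TARGET, sex="M"), _case(2, TARGET, sex="F")]
        assert sex_ratio(cohort, TARGET) == 1.00

    def test_zero_females_is_missing(self):
        assert sex_ratio([_case(1, TARGET, sex="M")], TARGET) is None


class TestTopEvents:
    def _cohort(self):
        cases = [_case(i, TARGET, events={"Diarrhoea"}) for i in range(3)]
        cases += [_case(10 + i, TARGET, events={"Rash", "Nausea"},
                        outcomes={"DE"}) for i in range(2)]
        return cases

    def test_ranking_counts_unique_pairs(self):
        frame = top_events(self._cohort(), TARGET, k=2)
        assert list(frame.event_pt) == ["Diarrhoea", "Nausea"]
        assert list(frame["count"]) == [3, 2]

    def test_percent_denominator_is_total_pairs(self):
        frame = top_events(self._cohort(), TARGET, k=1)
        assert frame.pct_of_pairs.item() == round_half_up(100 * 3 / 7, 2)

    def test_ties_break_alphabetically(self):
        frame = top_events(self._cohort(), TARGET, k=3)
        assert list(frame.event_pt[1:]) == ["Nausea", "Rash"]

    def test_fatal_only_restricts_reports_not_denominator(self):
        frame = top_events(self._cohort(), TARGET, k=5,
                           weight="fatal-only")
        assert set(frame.event_pt) == {"Rash", "Nausea"}
        assert frame["count"].tolist() == [2, 2]
        assert frame.pct_of_pairs.tolist() == [round_half_up(200 / 7, 2)] * 2

    def test_k_larger_than_vocabulary_returns_all(self):
        assert len(top_events(self._cohort(), TARGET, k=99)) == 3

    def test_dominant_planted_event_ranks_first(self, small_cohort):
        frame = top_events(small_cohort, COMPARATOR, k=1)
        assert frame.event_pt.item() == "Diarrhoea"  # highest baseline


def test_round_half_up_matches_printed_convention():
    assert round_half_up(60.955, 2) == 60.96
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(2.904999, 2) == 2.90
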