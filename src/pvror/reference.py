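"""Published FAERS molnupiravir worked example, reconstructed.

A published disproportionality analysis of molnupiravir in FAERS
(2020 Q1 – 2022 Q4 quarters) reports a COVID-19 cohort of 116,576
deduplicated reports: 2,285 with molnupiravir as primary suspect
(4,888 event pairs) against 114,291 comparator reports (374,575 event
pairs), together with the molnupiravir group's characteristic
marginals and its most frequent events.  Those printed counts are
transcribed here and used as inputs: :func:`reference_target_cohort`
rebuilds a synthetic 2,285-report cohort whose marginals match the
published table exactly, so the descriptive statistics the package
computes can be compared against the published percentages.

The reconstruction assigns each characteristic independently (the
joint distribution across characteristics is not published), which is
exactly what marginal frequency tables and per-term contingency
tables need.  Event terms beyond the published top five are filled
with vocabulary terms at lower counts so the pair total is exact
without disturbing the ranking; the file is a synthetic stand-in for
the real extract, not FAERS data.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .cohort import CohortSpec, SafetyCase, build_cohort
from .dedup import deduplicate
from .records import (
    DrugRecord,
    IndicationRecord,
    OutcomeRecord,
    RawReport,
    ReactionRecord,
)
from .synthetic import DEFAULT_VOCABULARY

TARGET_N = 2_285
COMPARATOR_N = 114_291
TARGET_PAIRS = 4_888
COMPARATOR_PAIRS = 374_575

#: Molnupiravir-group marginal counts from the published
#: characteristics table (each section sums to 2,285 except Outcome,
#: where "Non-Serious" means no outcome code on the report).
AGE_COUNTS: Dict[str, int] = {
    "<18": 24, "18–44": 150, "45–64": 421, "≥65": 1_393, "Unknown": 297}
SEX_COUNTS: Dict[str, int] = {"Female": 1_139, "Male": 968, "Unknown": 178}
REPORTER_COUNTS: Dict[str, int] = {
    "Health professional": 1_830, "Non-Health professional": 307,
    "Unknown": 148}
COUNTRY_COUNTS: Dict[str, int] = {
    "United States": 360, "Japan": 1_667, "Other countries": 258,
    "Not Specified": 0}
OUTCOME_COUNTS: Dict[str, int] = {
    "Death": 277, "Life Threatening": 50, "Required Intervention": 16,
    "Disabled": 19, "Hospitalizations": 449, "Congenital Anomaly": 0,
    "Other Outcomes": 701, "Non-Serious": 773}
DOSAGE_COUNTS: Dict[str, int] = {
    "Dosage according to the label": 1_444, "Dosage below the label": 201,
    "Dosage above the label": 32, "Unknown": 608}

#: Comparator-group sex counts (for the published male/female ratio).
COMPARATOR_SEX_COUNTS: Dict[str, int] = {"Female": 59_484, "Male": 44_563}

#: Published top-five molnupiravir events (unique report counts).
TOP_EVENT_COUNTS: Dict[str, int] = {
    "Diarrhoea": 142, "Rash": 125, "Nausea": 97, "Dizziness": 83,
    "Vomiting": 80}

#: Drug eruption worked example: a = 30 target pairs; the comparator
#: count 62 is reconstructed from the published ROR 37.30
#: (95% CI 24.10–57.74) together with the pair totals above.
DRUG_ERUPTION_A = 30
DRUG_ERUPTION_C = 62

_AGE_FIELDS = {          # representative (value, code) per band
    "<18": (10.0, "YR"), "18–44": (30.0, "YR"), "45–64": (50.0, "YR"),
    "≥65": (70.0, "YR"), "Unknown": (None, None)}
_SEX_FIELDS = {"Female": "F", "Male": "M", "Unknown": None}
_REPORTER_FIELDS = {"Health professional": "MD",
                    "Non-Health professional": "CN", "Unknown": None}
_COUNTRY_FIELDS = {"United States": "US", "Japan": "JP",
                   "Other countries": "GB", "Not Specified": None}
_OUTCOME_FIELDS = {"Death": "DE", "Life Threatening": "LT",
                   "Required Intervention": "RI", "Disabled": "DS",
                   "Hospitalizations": "HO", "Congenital Anomaly": "CA",
                   "Other Outcomes": "OT"}
_DOSE_FIELDS = {
    "Dosage according to the label": (800.0, "MG", "BID"),
    "Dosage below the label": (400.0, "MG", "BID"),
    "Dosage above the label": (1200.0, "MG", "BID"),
    "Unknown": (None, None, None)}


def _assignments(counts: Dict[str, int]) -> List[str]:
    """Expand marginal counts to one category label per case index."""
    out: List[str] = []
    for label, count in counts.items():
        out.extend([label] * count)
    return out


def _event_assignments() -> List[Tuple[int, str]]:
    """(case index, PT) pairs: the published top five counts, then
    vocabulary filler terms capped below the fifth-ranked count so the
    ranking is preserved and the pair total is exactly 4,888."""
    pairs: List[Tuple[int, str]] = []
    offset = 0
    for pt, count in TOP_EVENT_COUNTS.items():
        for k in range(count):
            pairs.append(((offset + k) % TARGET_N, pt))
        offset += count
    remaining = TARGET_PAIRS - len(pairs)
    cap = min(TOP_EVENT_COUNTS.values()) - 1
    filler_pts = [pt for pt, _, _ in DEFAULT_VOCABULARY
                  if pt not in TOP_EVENT_COUNTS]
    for pt in filler_pts:
        if remaining <= 0:
            break
        count = min(cap, remaining)
        for k in range(count):
            pairs.append(((offset + k) % TARGET_N, pt))
        offset += count
        remaining -= count
    if remaining > 0:
        raise RuntimeError("filler vocabulary too small for pair total")
    return pairs


def reference_target_records() -> Tuple[List[RawReport], List[DrugRecord],
                                        List[ReactionRecord],
                                        List[IndicationRecord],
                                        List[OutcomeRecord]]:
    """The five synthetic tables of the reconstructed 2,285-report
    molnupiravir group."""
    ages = _assignments(AGE_COUNTS)
    sexes = _assignments(SEX_COUNTS)
    reporters = _assignments(REPORTER_COUNTS)
    countries = _assignments(COUNTRY_COUNTS)
    dosages = _assignments(DOSAGE_COUNTS)
    outcome_order = [(label, count) for label, count in OUTCOME_COUNTS.items()
                     if label != "Non-Serious"]

    demo: List[RawReport] = []
    drug: List[DrugRecord] = []
    indi: List[IndicationRecord] = []
    outc: List[OutcomeRecord] = []
    for i in range(TARGET_N):
        pid = 900_001 + i
        age_value, age_code = _AGE_FIELDS[ages[i]]
        demo.append(RawReport(
            primary_id=pid, case_id=pid, fda_dt=20220301,
            age_value=age_value, age_code=age_code,
            sex=_SEX_FIELDS[sexes[i]],
            occupation_code=_REPORTER_FIELDS[reporters[i]],
            reporter_country=_COUNTRY_FIELDS[countries[i]]))
        amount, unit, freq = _DOSE_FIELDS[dosages[i]]
        drug.append(DrugRecord(
            primary_id=pid, drug_seq=1, role_code="PS",
            drug_name="MOLNUPIRAVIR", product_ai="MOLNUPIRAVIR",
            dose_amount=amount, dose_unit=unit, dose_frequency=freq))
        indi.append(IndicationRecord(
            primary_id=pid, indication_drug_seq=1,
            indication_pt="COVID-19 treatment"))

    # Outcome codes are assigned to disjoint case ranges: the published
    # section sums to exactly 2,285, so no report needs two codes and
    # the remaining 773 reports carry none ("Non-Serious").
    index = 0
    for label, count in outcome_order:
        code = _OUTCOME_FIELDS[label]
        for _ in range(count):
            outc.append(OutcomeRecord(primary_id=900_001 + index,
                                      outcome_code=code))
            index += 1

    reac = [ReactionRecord(primary_id=900_001 + case_index, event_pt=pt)
            for case_index, pt in _event_assignments()]
    return demo, drug, reac, indi, outc


def reference_target_cohort(spec: CohortSpec = None) -> List[SafetyCase]:
    """Run the reconstructed records through the real pipeline
    (dedup, joins, group assignment, event filtering)."""
    demo, drug, reac, indi, outc = reference_target_records()
    return build_cohort(deduplicate(demo), drug, reac, indi, outc,
                        spec or CohortSpec())
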