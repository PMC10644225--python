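"""Descriptive characterisation of the cohort.

Produces the frequency/percentage table of report characteristics (age
band, sex, reporter type, reporting country, seriousness outcome and
label-conformance of the dose) per analysis group, plus ranked
most-common-event lists.

Conventions:

* Percentages are count / group size, rounded half-up to two decimals.
* Outcome rows count reports, and one report may carry several outcome
  codes, so outcome percentages need not sum to 100%.  "Non-Serious"
  means the report has no outcome code at all; "Other Outcomes" is the
  explicit OT code.
* Event rankings count unique (report, PT) pairs and use the group's
  total number of pairs as the percentage denominator.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort import COMPARATOR, TARGET, SafetyCase
from .records import DrugRecord
from .util import round_half_up

AGE_BIN_LABELS = ["<18", "18–44", "45–64", "≥65", "Unknown"]
SEX_LABELS = ["Female", "Male", "Unknown"]
REPORTER_LABELS = ["Health professional", "Non-Health professional",
                   "Unknown"]
COUNTRY_LABELS = ["United States", "Japan", "Other countries",
                  "Not Specified"]
OUTCOME_LABELS = ["Death", "Life Threatening", "Required Intervention",
                  "Disabled", "Hospitalizations", "Congenital Anomaly",
                  "Other Outcomes", "Non-Serious"]
DOSAGE_LABELS = ["Dosage according to the label", "Dosage below the label",
                 "Dosage above the label", "Unknown"]

_OUTCOME_CODE_LABEL = {
    "DE": "Death",
    "LT": "Life Threatening",
    "RI": "Required Intervention",
    "DS": "Disabled",
    "HO": "Hospitalizations",
    "CA": "Congenital Anomaly",
    "OT": "Other Outcomes",
}

# FAERS age unit codes -> multiplier into years
_AGE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_FREQUENCY_PER_DAY = {
    "QD": 1.0, "QDAY": 1.0, "DAILY": 1.0, "ONCE DAILY": 1.0, "OD": 1.0,
    "Q24H": 1.0,
    "BID": 2.0, "TWICE DAILY": 2.0, "Q12H": 2.0,
    "TID": 3.0, "Q8H": 3.0,
    "QID": 4.0, "Q6H": 4.0,
}

#: Reference molnupiravir daily dose: 800 mg every 12 hours.
DEFAULT_LABEL_DAILY_DOSE_MG = 1600.0


def age_in_years(age_value: Optional[float],
                 age_code: Optional[str]) -> Optional[float]:
    """Convert a FAERS (value, unit-code) age to years; None if unknown."""
    if age_value is None or age_code is None:
        return None
    factor = _AGE_FACTORS.get(age_code)
    if factor is None:
        return None
    if age_value < 0:
        warnings.warn(f"negative age {age_value} treated as unknown",
                      stacklevel=2)
        return None
    return age_value * factor


def age_bin(years: Optional[float]) -> str:
    """Assign an age in years to the reporting bands."""
    if years is None:
        return "Unknown"
    if years < 18:
        return "<18"
    if years < 45:
        return "18–44"
    if years < 65:
        return "45–64"
    return "≥65"


def reporter_category(occupation_code: Optional[str]) -> str:
    """Collapse FAERS occupation codes to health-professional status.

    Physicians (MD), pharmacists (PH) and other health professionals
    (OT) are "Health professional"; consumers (CN) and lawyers (LW)
    are "Non-Health professional".
    """
    if occupation_code in ("MD", "PH", "OT"):
        return "Health professional"
    if occupation_code in ("CN", "LW"):
        return "Non-Health professional"
    return "Unknown"


def country_category(country: Optional[str]) -> str:
    if country is None or str(country).strip() == "":
        return "Not Specified"
    code = str(country).strip().upper()
    if code in ("US", "USA", "UNITED STATES"):
        return "United States"
    if code in ("JP", "JAPAN"):
        return "Japan"
    return "Other countries"


def dosage_category(drug: DrugRecord,
                    label_daily_dose_mg: float = DEFAULT_LABEL_DAILY_DOSE_MG,
                    ) -> str:
    """Classify a drug entry's daily dose against the label dose.

    The daily dose is ``dose_amount`` (mg) times the administrations
    per day implied by ``dose_frequency``; anything unparseable is
    "Unknown".
    """
    if drug.dose_amount is None or drug.dose_unit is None:
        return "Unknown"
    if str(drug.dose_unit).strip().upper() != "MG":
        return "Unknown"
    freq_text = (drug.dose_frequency or "").strip().upper()
    per_day = _FREQUENCY_PER_DAY.get(freq_text)
    if per_day is None:
        return "Unknown"
    daily = drug.dose_amount * per_day
    if abs(daily - label_daily_dose_mg) <= 1e-9 * label_daily_dose_mg:
        return "Dosage according to the label"
    if daily < label_daily_dose_mg:
        return "Dosage below the label"
    return "Dosage above the label"


def _case_age_bin(case: SafetyCase) -> str:
    return age_bin(age_in_years(case.report.age_value, case.report.age_code))


def _case_sex(case: SafetyCase) -> str:
    return {"F": "Female", "M": "Male"}.get(case.report.sex or "", "Unknown")


def _case_dosage(case: SafetyCase, label_daily_dose_mg: float,
                 required_role: str = "PS") -> str:
    for drug in case.drugs:
        if drug.role_code == required_role:
            return dosage_category(drug, label_daily_dose_mg)
    return "Unknown"


def _counts(labels: Sequence[str], values: Iterable[str]) -> Dict[str, int]:
    out = {label: 0 for label in labels}
    for value in values:
        out[value] += 1
    return out


def characteristics(cohort: Sequence[SafetyCase],
                    label_daily_dose_mg: float = DEFAULT_LABEL_DAILY_DOSE_MG,
                    ) -> pd.DataFrame:
    """Tidy characteristics table: one row per (characteristic,
    category, group) with count and half-up percentage of group size.

    Dosage conformance is reported for the TARGET group only (it is
    defined against the target drug's label dose).
    """
    if not cohort:
        raise ValueError("characteristics() requires a nonempty cohort")
    rows: List[Tuple[str, str, str, int, float]] = []
    for group in (TARGET, COMPARATOR):
        cases = [c for c in cohort if c.group == group]
        if not cases:
            continue
        n_group = len(cases)

        sections: List[Tuple[str, Sequence[str], Dict[str, int]]] = [
            ("Age (years)", AGE_BIN_LABELS,
             _counts(AGE_BIN_LABELS, (_case_age_bin(c) for c in cases))),
            ("Sex", SEX_LABELS,
             _counts(SEX_LABELS, (_case_sex(c) for c in cases))),
            ("Type of reporter", REPORTER_LABELS,
             _counts(REPORTER_LABELS,
                     (reporter_category(c.report.occupation_code)
                      for c in cases))),
            ("Reporting country", COUNTRY_LABELS,
             _counts(COUNTRY_LABELS,
                     (country_category(c.report.reporter_country)
                      for c in cases))),
        ]
        outcome_counts = {label: 0 for label in OUTCOME_LABELS}
        for case in cases:
            if not case.outcomes:
                outcome_counts["Non-Serious"] += 1
            for code in case.outcomes:
                label = _OUTCOME_CODE_LABEL.get(code)
                if label:
                    outcome_counts[label] += 1
        sections.append(("Outcome", OUTCOME_LABELS, outcome_counts))
        if group == TARGET:
            sections.append(
                ("Dosage", DOSAGE_LABELS,
                 _counts(DOSAGE_LABELS,
                         (_case_dosage(c, label_daily_dose_mg)
                          for c in cases))))

        for characteristic, labels, counts in sections:
            for label in labels:
                count = counts[label]
                rows.append((characteristic, label, group, count,
                             round_half_up(100.0 * count / n_group, 2)))
    return pd.DataFrame(
        rows, columns=["characteristic", "category", "group", "n", "pct"])


def sex_ratio_from_counts(males: int, females: int) -> Optional[float]:
    """Male-to-female ratio rounded to two decimals; None if no females."""
    if females <= 0:
        return None
    return round_half_up(males / females, 2)


def sex_ratio(cohort: Sequence[SafetyCase], group: str) -> Optional[float]:
    """Male-to-female report ratio within one group."""
    males = sum(1 for c in cohort
                if c.group == group and c.report.sex == "M")
    females = sum(1 for c in cohort
                  if c.group == group and c.report.sex == "F")
    return sex_ratio_from_counts(males, females)


def top_events(cohort: Sequence[SafetyCase], group: str, k: int = 15,
               weight: str = "all-events") -> pd.DataFrame:
    """Rank the group's most frequent event PTs.

    Counts unique (report, PT) pairs.  ``weight="fatal-only"``
    restricts to reports carrying the death outcome (DE), while the
    percentage denominator stays the group's total event pairs.  Ties
    break alphabetically by PT.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if weight not in ("all-events", "fatal-only"):
        raise ValueError(f"unknown weight: {weight!r}")
    cases = [c for c in cohort if c.group == group]
    total_pairs = sum(len(c.events) for c in cases)
    if weight == "fatal-only":
        cases = [c for c in cases if "DE" in c.outcomes]
    counts: Dict[str, int] = {}
    for case in cases:
        for pt in case.events:
            counts[pt] = counts.get(pt, 0) + 1
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))[:k]
    return pd.DataFrame(
        [(pt, n,
          round_half_up(100.0 * n / total_pairs, 2) if total_pairs else 0.0)
         for pt, n in ranked],
        columns=["event_pt", "count", "pct_of_pairs"])
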