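"""COVID-19 cohort construction and target/comparator group assignment.

The study population is every deduplicated report whose INDI table
carries at least one COVID-19 indication, taken from the 18 preferred
terms of the narrow COVID-19 standardized MedDRA query (SMQ).  Within
that population, reports whose primary-suspect (PS) drug matches the
target-drug name patterns form the TARGET group and every other
COVID-19 report forms the COMPARATOR ("other drugs") group.  Reports
without a COVID-19 indication are dropped, even when they mention the
target drug.

Indications are matched as whole preferred terms (case-insensitive,
whitespace-trimmed) because SMQ entries are complete PTs; drug names
are matched as case-insensitive substrings, mirroring the SQL
``LIKE '%PATTERN%'`` idiom used against the free-text ``drugname`` and
``prod_ai`` columns.

Uninformative reaction terms (e.g. "Product use issue", "COVID-19"
reported as an event) are removed from each case's event set; the case
itself stays in the cohort denominator and simply contributes no
event pairs to disproportionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set

import yaml

from .records import (
    DrugRecord,
    IndicationRecord,
    OutcomeRecord,
    RawReport,
    ReactionRecord,
)

TARGET = "TARGET"
COMPARATOR = "COMPARATOR"

#: The narrow COVID-19 SMQ: 18 preferred terms used to retrieve
#: COVID-19 reports from the INDI table.
COVID_SMQ_TERMS: FrozenSet[str] = frozenset({
    "COVID-19",
    "COVID-19 pneumonia",
    "COVID-19 immunization",
    "COVID-19 prophylaxis",
    "COVID-19 treatment",
    "Suspected COVID-19",
    "Asymptomatic COVID-19",
    "SARS-CoV-2 test positive",
    "SARS-CoV-2 carrier",
    "SARS-CoV-2 test false negative",
    "SARS-CoV-2 antibody test positive",
    "SARS-CoV-2 sepsis",
    "SARS-CoV-2 viremia",
    "Occupational exposure to SARS-CoV-2",
    "Exposure to SARS-CoV-2",
    "Coronavirus infection",
    "Coronavirus test positive",
    "Multisystem inflammatory syndrome in children",
})

#: Molnupiravir name patterns; LAGEVRIO is the brand name and
#: LAGEVIRIO a misspelling seen in source material, kept for recall.
DEFAULT_DRUG_PATTERNS: FrozenSet[str] = frozenset(
    {"MOLNUPIRAVIR", "LAGEVRIO", "LAGEVIRIO"})

#: Reaction PTs that are not adverse events and are filtered out.
DEFAULT_EXCLUDED_EVENTS: FrozenSet[str] = frozenset({
    "Product use issue",
    "No adverse event",
    "Wrong technique in product usage process",
    "COVID-19",
})


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of cohort construction.

    ``indication_terms`` select the study population from INDI,
    ``drug_patterns`` and ``required_role`` define the target group,
    and ``excluded_event_terms`` are stripped from each case's events.
    """

    indication_terms: FrozenSet[str] = COVID_SMQ_TERMS
    drug_patterns: FrozenSet[str] = DEFAULT_DRUG_PATTERNS
    required_role: str = "PS"
    excluded_event_terms: FrozenSet[str] = DEFAULT_EXCLUDED_EVENTS

    def __post_init__(self):
        for name in ("indication_terms", "drug_patterns",
                     "excluded_event_terms"):
            if not getattr(self, name):
                raise ValueError(f"CohortSpec.{name} must be nonempty")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({
            "indication_terms": sorted(self.indication_terms),
            "drug_patterns": sorted(self.drug_patterns),
            "required_role": self.required_role,
            "excluded_event_terms": sorted(self.excluded_event_terms),
        }), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        kwargs = {}
        for key in ("indication_terms", "drug_patterns",
                    "excluded_event_terms"):
            if key in data:
                kwargs[key] = frozenset(data[key])
        if "required_role" in data:
            kwargs["required_role"] = data["required_role"]
        return cls(**kwargs)


@dataclass
class SafetyCase:
    """A deduplicated report joined to its drugs, events, indications
    and outcomes, with its analysis group label."""

    report: RawReport
    drugs: List[DrugRecord] = field(default_factory=list)
    events: Set[str] = field(default_factory=set)
    indications: Set[str] = field(default_factory=set)
    outcomes: Set[str] = field(default_factory=set)
    group: Optional[str] = None

    @property
    def primary_id(self) -> int:
        return self.report.primary_id


def _norm(term: str) -> str:
    return term.strip().casefold()


def covid_indication_ids(indications: Sequence[IndicationRecord],
                         spec: CohortSpec) -> Set[int]:
    """Report ids with at least one indication PT in the SMQ term set.

    Matching is whole-term, case-insensitive and whitespace-trimmed.
    """
    terms = {_norm(t) for t in spec.indication_terms}
    return {rec.primary_id for rec in indications
            if _norm(rec.indication_pt) in terms}


def target_drug_ids(drugs: Sequence[DrugRecord],
                    spec: CohortSpec) -> Set[int]:
    """Report ids with a required-role drug matching a name pattern.

    A drug matches when its ``drug_name`` or ``product_ai`` contains any
    pattern as a case-insensitive substring and its role equals
    ``spec.required_role`` (primary suspect by default).
    """
    patterns = [_norm(p) for p in spec.drug_patterns]
    out: Set[int] = set()
    for rec in drugs:
        if rec.role_code != spec.required_role:
            continue
        haystacks = (rec.drug_name or "", rec.product_ai or "")
        if any(p in _norm(h) for p in patterns for h in haystacks):
            out.add(rec.primary_id)
    return out


def build_cases(reports: Sequence[RawReport],
                drugs: Sequence[DrugRecord] = (),
                reactions: Sequence[ReactionRecord] = (),
                indications: Sequence[IndicationRecord] = (),
                outcomes: Sequence[OutcomeRecord] = ()) -> List[SafetyCase]:
    """Join the satellite tables onto deduplicated reports.

    Satellite rows whose ``primary_id`` does not survive deduplication
    are ignored (they belong to superseded report versions).
    """
    cases: Dict[int, SafetyCase] = {
        r.primary_id: SafetyCase(report=r) for r in reports}
    for rec in drugs:
        case = cases.get(rec.primary_id)
        if case is not None:
            case.drugs.append(rec)
    for rec in reactions:
        case = cases.get(rec.primary_id)
        if case is not None:
            case.events.add(rec.event_pt)
    for rec in indications:
        case = cases.get(rec.primary_id)
        if case is not None:
            case.indications.add(rec.indication_pt)
    for rec in outcomes:
        case = cases.get(rec.primary_id)
        if case is not None:
            case.outcomes.add(rec.outcome_code)
    return [cases[r.primary_id] for r in reports]


def assign_groups(cases: Iterable[SafetyCase],
                  covid_ids: Set[int],
                  target_ids: Set[int]) -> List[SafetyCase]:
    """Keep COVID-19 cases and label them TARGET or COMPARATOR.

    Cases outside ``covid_ids`` are dropped; within it, membership in
    ``target_ids`` decides the group, so the two groups partition the
    kept set.
    """
    cohort: List[SafetyCase] = []
    for case in cases:
        pid = case.primary_id
        if pid not in covid_ids:
            continue
        case.group = TARGET if pid in target_ids else COMPARATOR
        cohort.append(case)
    return cohort


def filter_events(case: SafetyCase, spec: CohortSpec) -> SafetyCase:
    """Remove excluded reaction terms from one case (in place)."""
    excluded = {_norm(t) for t in spec.excluded_event_terms}
    case.events = {e for e in case.events if _norm(e) not in excluded}
    return case


def build_cohort(reports: Sequence[RawReport],
                 drugs: Sequence[DrugRecord],
                 reactions: Sequence[ReactionRecord],
                 indications: Sequence[IndicationRecord],
                 outcomes: Sequence[OutcomeRecord],
                 spec: Optional[CohortSpec] = None) -> List[SafetyCase]:
    """Full cohort construction on deduplicated reports.

    Joins the tables, restricts to COVID-19 indications, assigns the
    TARGET/COMPARATOR label and strips excluded reaction terms.
    """
    spec = spec or CohortSpec()
    cases = build_cases(reports, drugs, reactions, indications, outcomes)
    covid = covid_indication_ids(indications, spec)
    target = target_drug_ids(drugs, spec)
    cohort = assign_groups(cases, covid, target)
    for case in cohort:
        filter_events(case, spec)
    return cohort
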