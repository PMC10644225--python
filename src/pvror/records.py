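"""Typed records for the five FAERS quarterly ASCII tables.

FAERS (the FDA Adverse Event Reporting System) distributes spontaneous
adverse-event reports as quarterly "$"-delimited ASCII tables.  One
individual case safety report (ICSR) is keyed by ``primary_id`` (a
report-version identifier); several versions of the same case share a
``case_id``.  The five tables modelled here are DEMO (demographics),
DRUG (suspect/concomitant drugs), REAC (adverse reactions), INDI
(indications for use) and OUTC (seriousness outcomes).

Dates are kept as YYYYMMDD integers: deduplication only needs their
ordering, and that is how FAERS prints them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, fields
from enum import Enum
from typing import Optional

AGE_CODES = frozenset({"YR", "DEC", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"F", "M"})
OCCUPATION_CODES = frozenset({"MD", "PH", "OT", "LW", "CN"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


class TableKind(Enum):
    """The five supported FAERS table kinds."""

    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    INDI = "INDI"
    OUTC = "OUTC"


@dataclass(frozen=True)
class RawReport:
    """One DEMO row: a single report version, before deduplication."""

    primary_id: int
    case_id: int
    fda_dt: Optional[int] = None
    age_value: Optional[float] = None
    age_code: Optional[str] = None
    sex: Optional[str] = None
    occupation_code: Optional[str] = None
    reporter_country: Optional[str] = None


@dataclass(frozen=True)
class DrugRecord:
    """One DRUG row: a drug entry on a report, with its role and dose."""

    primary_id: int
    drug_seq: int
    role_code: str
    drug_name: str = ""
    product_ai: Optional[str] = None
    dose_amount: Optional[float] = None
    dose_unit: Optional[str] = None
    dose_frequency: Optional[str] = None


@dataclass(frozen=True)
class ReactionRecord:
    """One REAC row: a MedDRA preferred term reported as an adverse event."""

    primary_id: int
    event_pt: str


@dataclass(frozen=True)
class IndicationRecord:
    """One INDI row: the indication PT for one drug entry on a report."""

    primary_id: int
    indication_drug_seq: int
    indication_pt: str


@dataclass(frozen=True)
class OutcomeRecord:
    """One OUTC row: a seriousness outcome code for a report."""

    primary_id: int
    outcome_code: str


RECORD_TYPES = {
    TableKind.DEMO: RawReport,
    TableKind.DRUG: DrugRecord,
    TableKind.REAC: ReactionRecord,
    TableKind.INDI: IndicationRecord,
    TableKind.OUTC: OutcomeRecord,
}


def valid_yyyymmdd(value: int) -> bool:
    """True iff ``value`` encodes a real calendar date as YYYYMMDD."""
    try:
        _dt.date(value // 10000, value // 100 % 100, value % 100)
    except ValueError:
        return False
    return True


def record_tuple(record) -> tuple:
    """All field values of a record, in declaration order."""
    return tuple(getattr(record, f.name) for f in fields(record))
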