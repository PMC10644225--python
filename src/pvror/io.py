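"""Reading and writing FAERS-format "$"-delimited quarterly ASCII tables.

The FAERS ASCII dialect has a header row, one record per line, fields
separated by ``$`` and no quoting mechanism; an embedded ``$`` in free
text is therefore indistinguishable from a delimiter and is reported as
a field-count issue on read.  The parser never raises on a malformed
line: every data line either yields exactly one record or exactly one
logged :class:`ParseIssue`, so ``len(records) + len(skipped issues)``
equals the number of data lines.

Enumerated fields are upper-cased on read because real quarters mix
case.  Unparseable *optional* fields (a bad date, an age code outside
the closed set) become missing with a logged issue; an unparseable
*required* field (the report identifier, a reaction PT) invalidates the
whole line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

from .records import (
    AGE_CODES,
    OCCUPATION_CODES,
    OUTCOME_CODES,
    RECORD_TYPES,
    ROLE_CODES,
    SEX_CODES,
    TableKind,
    record_tuple,
    valid_yyyymmdd,
)

DELIMITER = "$"


@dataclass(frozen=True)
class ParseIssue:
    """One problem found while parsing a data line."""

    line_no: int
    field: Optional[str]
    message: str
    skipped_line: bool


class FieldSpec:
    def __init__(self, name: str, parse: Callable[[str], object],
                 required: bool = False):
        self.name = name
        self.parse = parse
        self.required = required


def _parse_int(text: str) -> int:
    return int(text)


def _parse_float(text: str) -> float:
    value = float(text)
    if value != value or value in (float("inf"), float("-inf")):
        raise ValueError("non-finite number")
    return value


def _parse_nonneg_float(text: str) -> float:
    value = _parse_float(text)
    if value < 0:
        raise ValueError("negative value")
    return value


def _parse_date(text: str) -> int:
    value = int(text)
    if not valid_yyyymmdd(value):
        raise ValueError(f"{value} is not a valid YYYYMMDD date")
    return value


def _parse_text(text: str) -> str:
    return text.strip()


def _parse_nonempty_text(text: str) -> str:
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty text field")
    return stripped


def _enum_parser(allowed: frozenset) -> Callable[[str], str]:
    def parse(text: str) -> str:
        code = text.strip().upper()
        if code not in allowed:
            raise ValueError(f"{code!r} not in {sorted(allowed)}")
        return code

    return parse


TABLE_SCHEMAS = {
    TableKind.DEMO: [
        FieldSpec("primary_id", _parse_int, required=True),
        FieldSpec("case_id", _parse_int, required=True),
        FieldSpec("fda_dt", _parse_date),
        FieldSpec("age_value", _parse_nonneg_float),
        FieldSpec("age_code", _enum_parser(AGE_CODES)),
        FieldSpec("sex", _enum_parser(SEX_CODES)),
        FieldSpec("occupation_code", _enum_parser(OCCUPATION_CODES)),
        FieldSpec("reporter_country", _parse_text),
    ],
    TableKind.DRUG: [
        FieldSpec("primary_id", _parse_int, required=True),
        FieldSpec("drug_seq", _parse_int, required=True),
        FieldSpec("role_code", _enum_parser(ROLE_CODES), required=True),
        FieldSpec("drug_name", _parse_text),
        FieldSpec("product_ai", _parse_text),
        FieldSpec("dose_amount", _parse_nonneg_float),
        FieldSpec("dose_unit", _parse_text),
        FieldSpec("dose_frequency", _parse_text),
    ],
    TableKind.REAC: [
        FieldSpec("primary_id", _parse_int, required=True),
        FieldSpec("event_pt", _parse_nonempty_text, required=True),
    ],
    TableKind.INDI: [
        FieldSpec("primary_id", _parse_int, required=True),
        FieldSpec("indication_drug_seq", _parse_int, required=True),
        FieldSpec("indication_pt", _parse_nonempty_text, required=True),
    ],
    TableKind.OUTC: [
        FieldSpec("primary_id", _parse_int, required=True),
        FieldSpec("outcome_code", _enum_parser(OUTCOME_CODES), required=True),
    ],
}

# FAERS-style column headers, in file order.
TABLE_HEADERS = {
    TableKind.DEMO: ["primaryid", "caseid", "fda_dt", "age", "age_cod",
                     "sex", "occp_cod", "reporter_country"],
    TableKind.DRUG: ["primaryid", "drug_seq", "role_cod", "drugname",
                     "prod_ai", "dose_amt", "dose_unit", "dose_freq"],
    TableKind.REAC: ["primaryid", "pt"],
    TableKind.INDI: ["primaryid", "indi_drug_seq", "indi_pt"],
    TableKind.OUTC: ["primaryid", "outc_cod"],
}


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def read_table(path, table_kind: TableKind) -> Tuple[list, List[ParseIssue]]:
    """Parse one FAERS ASCII table into typed records plus an issue log.

    Parameters
    ----------
    path
        Path to a "$"-delimited file whose first line is the header.
    table_kind
        Which of the five tables the file contains.

    Returns
    -------
    (records, issues)
        ``records`` holds one typed record per well-formed data line, in
        file order.  ``issues`` records every malformed line (skipped)
        and every unparseable optional field (set to missing).
    """
    if not isinstance(table_kind, TableKind):
        raise ValueError(f"unknown table kind: {table_kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    schema = TABLE_SCHEMAS[table_kind]
    record_type = RECORD_TYPES[table_kind]
    records: list = []
    issues: List[ParseIssue] = []

    text = _read_text(path)
    if text == "":
        raise ValueError(f"{path}: empty file, expected a header line")
    # split on newlines only: free text may contain control characters
    # (e.g. form feed) that str.splitlines would treat as line breaks
    lines = [line.rstrip("\r") for line in text.split("\n")]
    if lines and lines[-1] == "":
        lines.pop()

    for line_no, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            continue
        parts = line.split(DELIMITER)
        if len(parts) != len(schema):
            issues.append(ParseIssue(
                line_no, None,
                f"expected {len(schema)} fields, found {len(parts)}",
                skipped_line=True))
            continue
        values = {}
        line_ok = True
        line_issues: List[ParseIssue] = []
        for spec, raw in zip(schema, parts):
            if raw.strip() == "":
                if spec.required:
                    line_issues.append(ParseIssue(
                        line_no, spec.name,
                        "required field is empty", skipped_line=True))
                    line_ok = False
                    break
                values[spec.name] = None
                continue
            try:
                values[spec.name] = spec.parse(raw)
            except (ValueError, OverflowError) as exc:
                if spec.required:
                    line_issues.append(ParseIssue(
                        line_no, spec.name,
                        f"invalid required field: {exc}", skipped_line=True))
                    line_ok = False
                    break
                values[spec.name] = None
                line_issues.append(ParseIssue(
                    line_no, spec.name,
                    f"unparseable value set to missing: {exc}",
                    skipped_line=False))
        issues.extend(line_issues)
        if line_ok:
            records.append(record_type(**values))
    return records, issues


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        # repr keeps full precision so write -> read is the identity
        return str(int(value)) if value.is_integer() else repr(value)
    text = str(value)
    if DELIMITER in text or "\n" in text or "\r" in text:
        raise ValueError(
            f"field value {text!r} contains the delimiter or a newline; "
            "the FAERS ASCII dialect has no quoting")
    return text


def write_table(records: Sequence, path, table_kind: TableKind) -> Path:
    """Write typed records as a FAERS ASCII table re-readable with no issues."""
    if not isinstance(table_kind, TableKind):
        raise ValueError(f"unknown table kind: {table_kind!r}")
    record_type = RECORD_TYPES[table_kind]
    for record in records:
        if not isinstance(record, record_type):
            raise TypeError(
                f"expected {record_type.__name__}, got {type(record).__name__}")
    path = Path(path)
    buffer = _io.StringIO()
    buffer.write(DELIMITER.join(TABLE_HEADERS[table_kind]) + "\n")
    for record in records:
        buffer.write(
            DELIMITER.join(_format_value(v) for v in record_tuple(record)))
        buffer.write("\n")
    path.write_text(buffer.getvalue(), encoding="utf-8")
    return path
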