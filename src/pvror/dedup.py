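"""Collapse multiple report versions into one row per case.

Spontaneous-reporting databases carry several versions of the same
case: follow-up reports share a ``case_id`` but get a new, higher
``primary_id``, and occasionally the same ``primary_id`` appears with
different FDA receipt dates.  Deduplication applies three rules, in
order:

1. byte-identical rows collapse to one;
2. among rows sharing a ``case_id``, only the greatest ``primary_id``
   survives (the newest report version);
3. among rows sharing a ``primary_id``, only the greatest ``fda_dt``
   survives (the latest receipt date).

A missing ``fda_dt`` sorts before any real date, so a dated version
always beats an undated one.  An exact tie on rule 3 (same
``primary_id`` and ``fda_dt`` but different other fields) is broken by
the lexicographically greatest field tuple, which keeps the outcome
independent of input order; a warning is emitted because the data are
then internally inconsistent.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Sequence

from .records import RawReport, record_tuple

_MISSING_DATE = -1


def _sort_key(report: RawReport) -> tuple:
    # total order over all fields; None sorts first within each slot
    return tuple(
        (value is not None, value) for value in record_tuple(report)
    )


def deduplicate(reports: Sequence[RawReport]) -> List[RawReport]:
    """Return one surviving :class:`RawReport` per case.

    The result is sorted by ``primary_id`` and contains unique
    ``case_id`` and ``primary_id`` values.  The operation is idempotent
    and invariant under permutations of the input.
    """
    # Rule 1: drop exact duplicates.
    unique: Dict[tuple, RawReport] = {}
    for report in reports:
        unique.setdefault(record_tuple(report), report)
    rows = list(unique.values())

    # Rule 2: per case_id keep only the greatest primary_id.
    best_pid: Dict[int, int] = {}
    for report in rows:
        pid = best_pid.get(report.case_id)
        if pid is None or report.primary_id > pid:
            best_pid[report.case_id] = report.primary_id
    rows = [r for r in rows if r.primary_id == best_pid[r.case_id]]

    # Rule 3: per primary_id keep only the greatest fda_dt.
    survivors: Dict[int, RawReport] = {}
    ties: Dict[int, List[RawReport]] = {}
    for report in rows:
        current = survivors.get(report.primary_id)
        if current is None:
            survivors[report.primary_id] = report
            continue
        new_dt = _MISSING_DATE if report.fda_dt is None else report.fda_dt
        cur_dt = _MISSING_DATE if current.fda_dt is None else current.fda_dt
        if new_dt > cur_dt:
            survivors[report.primary_id] = report
        elif new_dt == cur_dt:
            ties.setdefault(report.primary_id, [current]).append(report)
            if _sort_key(report) > _sort_key(current):
                survivors[report.primary_id] = report

    if ties:
        warnings.warn(
            f"{len(ties)} primary_id(s) had conflicting rows with identical "
            "fda_dt; kept the lexicographically greatest row",
            stacklevel=2)

    return sorted(survivors.values(), key=lambda r: r.primary_id)
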