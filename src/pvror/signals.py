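"""Disproportionality analysis with the reporting odds ratio (ROR).

For each adverse-event preferred term a 2x2 contingency table is built
from the cohort:

=============  ================  ===============
               target event      other events
=============  ================  ===============
target drug    a                 b
other drugs    c                 d
=============  ================  ===============

ROR = (a*d)/(b*c), with the Woolf (log-normal) 95% confidence interval
``exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.  A drug–event
pair is a signal when the event was reported at least three times in
the target group (a >= 3) and the lower CI bound exceeds 1.

By default ``a`` counts unique (report, PT) pairs and ``a + b`` is the
target group's total number of pairs; ``denominator="reports"``
switches to report counts (``a + b`` = reports in the group), the
convention under which a per-report planted odds multiplier equals the
true odds ratio.  Tables with a zero cell yield a missing ROR — no
continuity correction is applied unless requested — because the
signal rule's n >= 3 requirement already excludes them.

No multiple-testing adjustment is applied: every (PT, stratum) pair is
tested at the nominal level, as is conventional for hypothesis-free
signal screening; treat the output as hypothesis-generating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from scipy.stats import norm

from .cohort import TARGET, SafetyCase
from .descriptives import age_in_years, reporter_category
from .util import round_half_up

Z_95 = 1.96  # fixed conventional constant at the 95% level


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d counts for one event term in one stratum."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def with_continuity(self) -> "_CorrectedTable":
        return _CorrectedTable(self.a + 0.5, self.b + 0.5,
                               self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class _CorrectedTable:
    a: float
    b: float
    c: float
    d: float


@dataclass(frozen=True)
class SignalResult:
    """Disproportionality result for one PT in one stratum."""

    event_pt: str
    n: int
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    is_signal: bool
    stratum: str = "overall"
    soc: Optional[str] = None


@dataclass(frozen=True)
class StratumSpec:
    """A named case filter defining one sensitivity stratum."""

    name: str
    predicate: Callable[[SafetyCase], bool]

    def filter(self, cohort: Sequence[SafetyCase]) -> List[SafetyCase]:
        return [c for c in cohort if self.predicate(c)]


def default_strata() -> List[StratumSpec]:
    """Overall, health-professional, age (<65 / >=65) and sex strata.

    Cases with unknown age or sex are excluded from the corresponding
    strata; the comparator group is filtered identically to the target
    group.
    """
    def known_age(case: SafetyCase) -> Optional[float]:
        return age_in_years(case.report.age_value, case.report.age_code)

    return [
        StratumSpec("overall", lambda c: True),
        StratumSpec("health_professional",
                    lambda c: reporter_category(c.report.occupation_code)
                    == "Health professional"),
        StratumSpec("age_lt65",
                    lambda c: (known_age(c) is not None
                               and known_age(c) < 65)),
        StratumSpec("age_ge65",
                    lambda c: (known_age(c) is not None
                               and known_age(c) >= 65)),
        StratumSpec("female", lambda c: c.report.sex == "F"),
        StratumSpec("male", lambda c: c.report.sex == "M"),
    ]


def event_pair_counts(cohort: Sequence[SafetyCase],
                      ) -> Tuple[Dict[str, Tuple[int, int]],
                                 Tuple[int, int], Tuple[int, int]]:
    """Per-PT unique (report, PT) pair counts by group.

    Returns ``(counts, pair_totals, report_totals)`` where ``counts``
    maps PT -> (target count, comparator count), ``pair_totals`` is the
    (target, comparator) total pair count and ``report_totals`` the
    (target, comparator) report count.
    """
    counts: Dict[str, List[int]] = {}
    pair_totals = [0, 0]
    report_totals = [0, 0]
    for case in cohort:
        idx = 0 if case.group == TARGET else 1
        report_totals[idx] += 1
        pair_totals[idx] += len(case.events)
        for pt in case.events:
            counts.setdefault(pt, [0, 0])[idx] += 1
    return ({pt: (t, c) for pt, (t, c) in counts.items()},
            (pair_totals[0], pair_totals[1]),
            (report_totals[0], report_totals[1]))


def build_contingency(pt_counts: Tuple[int, int],
                      totals: Tuple[int, int]) -> ContingencyTable:
    """Build the 2x2 table from a PT's (target, comparator) counts and
    the group totals (pairs or reports, per the chosen denominator)."""
    a, c = pt_counts
    b = totals[0] - a
    d = totals[1] - c
    if b < 0 or d < 0:
        raise ValueError(
            f"totals {totals} inconsistent with counts {pt_counts}")
    return ContingencyTable(a, b, c, d)


def ror(table: ContingencyTable, continuity: bool = False,
        ) -> Optional[float]:
    """Reporting odds ratio (a*d)/(b*c); None when a cell is zero.

    ``continuity=True`` applies the Haldane–Anscombe +0.5 correction to
    every cell instead of returning missing.
    """
    t = table
    if min(t.a, t.b, t.c, t.d) == 0:
        if not continuity:
            return None
        t = table.with_continuity()
    return (t.a * t.d) / (t.b * t.c)


def ror_ci(table: ContingencyTable, level: float = 0.95,
           continuity: bool = False,
           ) -> Tuple[Optional[float], Optional[float]]:
    """Woolf confidence interval for the ROR.

    At the 95% level the constant 1.96 is used; other levels use the
    exact normal quantile.  Returns (None, None) for zero-cell tables
    unless ``continuity`` is set.
    """
    t = table
    if min(t.a, t.b, t.c, t.d) == 0:
        if not continuity:
            return (None, None)
        t = table.with_continuity()
    z = Z_95 if level == 0.95 else float(norm.ppf(0.5 + level / 2.0))
    log_ror = math.log((t.a * t.d) / (t.b * t.c))
    se = math.sqrt(1.0 / t.a + 1.0 / t.b + 1.0 / t.c + 1.0 / t.d)
    return (math.exp(log_ror - z * se), math.exp(log_ror + z * se))


def classify_signal(n: int, ci_low: Optional[float]) -> bool:
    """Signal rule: at least three target-group reports of the event
    and lower 95% CI bound strictly above 1."""
    if ci_low is None:
        return False
    return n >= 3 and ci_low > 1.0


def analyze_stratum(cohort: Sequence[SafetyCase], stratum_name: str,
                    denominator: str = "pairs",
                    continuity: bool = False) -> List[SignalResult]:
    """ROR, CI and signal flag for every PT observed in the stratum
    cohort (already filtered)."""
    if denominator not in ("pairs", "reports"):
        raise ValueError(f"unknown denominator: {denominator!r}")
    counts, pair_totals, report_totals = event_pair_counts(cohort)
    totals = pair_totals if denominator == "pairs" else report_totals
    results: List[SignalResult] = []
    for pt in sorted(counts):
        table = build_contingency(counts[pt], totals)
        estimate = ror(table, continuity=continuity)
        low, high = ror_ci(table, continuity=continuity)
        results.append(SignalResult(
            event_pt=pt, n=table.a, ror=estimate, ci_low=low, ci_high=high,
            is_signal=classify_signal(table.a, low), stratum=stratum_name))
    return results


def soc_rollup(results: Sequence[SignalResult],
               pt_to_soc: Mapping[str, str],
               ) -> Tuple[List[SignalResult], pd.DataFrame]:
    """Annotate results with each PT's primary system organ class and
    count signalled PTs per SOC.

    MedDRA itself is licensed, so the PT -> SOC mapping is supplied by
    the caller (the synthetic generator ships a toy vocabulary).
    Unmapped PTs stay unannotated with a warning.
    """
    annotated: List[SignalResult] = []
    unmapped = 0
    soc_counts: Dict[str, int] = {}
    for result in results:
        soc = pt_to_soc.get(result.event_pt)
        if soc is None:
            unmapped += 1
        annotated.append(SignalResult(
            event_pt=result.event_pt, n=result.n, ror=result.ror,
            ci_low=result.ci_low, ci_high=result.ci_high,
            is_signal=result.is_signal, stratum=result.stratum, soc=soc))
        if result.is_signal and soc is not None:
            soc_counts[soc] = soc_counts.get(soc, 0) + 1
    if unmapped:
        warnings.warn(f"{unmapped} PT(s) missing from the SOC mapping",
                      stacklevel=2)
    summary = pd.DataFrame(sorted(soc_counts.items(),
                                  key=lambda kv: (-kv[1], kv[0])),
                           columns=["soc", "n_signals"])
    return annotated, summary


def results_frame(results: Sequence[SignalResult],
                  round_output: bool = True) -> pd.DataFrame:
    """Signal results as a DataFrame sorted by SOC then descending ROR.

    Output ROR/CI columns are rounded to two decimals when
    ``round_output`` (full precision is kept in the result objects).
    """
    rows = []
    for r in results:
        rows.append({
            "stratum": r.stratum,
            "soc": r.soc,
            "event_pt": r.event_pt,
            "n": r.n,
            "ror": (round_half_up(r.ror, 2)
                    if round_output and r.ror is not None else r.ror),
            "ci_low": (round_half_up(r.ci_low, 2)
                       if round_output and r.ci_low is not None else r.ci_low),
            "ci_high": (round_half_up(r.ci_high, 2)
                        if round_output and r.ci_high is not None
                        else r.ci_high),
            "is_signal": r.is_signal,
        })
    frame = pd.DataFrame(rows, columns=["stratum", "soc", "event_pt", "n",
                                        "ror", "ci_low", "ci_high",
                                        "is_signal"])
    if len(frame):
        frame = frame.sort_values(
            ["soc", "ror", "event_pt"],
            ascending=[True, False, True],
            na_position="last").reset_index(drop=True)
    return frame


def run_stratified(cohort: Sequence[SafetyCase],
                   strata: Optional[Sequence[StratumSpec]] = None,
                   pt_to_soc: Optional[Mapping[str, str]] = None,
                   denominator: str = "pairs",
                   continuity: bool = False,
                   ) -> Dict[str, pd.DataFrame]:
    """Run the full disproportionality pipeline per stratum.

    Each stratum's predicate filters target and comparator groups
    identically; an empty target group yields an empty table with a
    warning.
    """
    strata = list(strata) if strata is not None else default_strata()
    out: Dict[str, pd.DataFrame] = {}
    for stratum in strata:
        sub = stratum.filter(cohort)
        if not any(c.group == TARGET for c in sub):
            warnings.warn(
                f"stratum {stratum.name!r} has an empty target group",
                stacklevel=2)
            out[stratum.name] = results_frame([])
            continue
        results = analyze_stratum(sub, stratum.name,
                                  denominator=denominator,
                                  continuity=continuity)
        if pt_to_soc is not None:
            results, _ = soc_rollup(results, pt_to_soc)
        out[stratum.name] = results_frame(results)
    return out


def soc_long_table(stratified: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format (stratum, SOC, signal count) table, the tabular
    analogue of a SOC-by-stratum heat map."""
    rows = []
    for name, frame in stratified.items():
        if not len(frame):
            continue
        signals = frame[frame["is_signal"] & frame["soc"].notna()]
        for soc, count in signals.groupby("soc").size().items():
            rows.append({"stratum": name, "soc": soc, "n_signals": count})
    return pd.DataFrame(rows, columns=["stratum", "soc", "n_signals"])
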