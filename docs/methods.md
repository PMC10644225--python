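# Methods

## Setting and model

Spontaneous adverse-event reporting systems collect individual case
safety reports (ICSRs) without an exposure denominator, so absolute
risks are not estimable.  Disproportionality analysis instead asks
whether an event term is over-represented among a target drug's
reports relative to all other drugs in the same database.  `pvror`
uses the reporting odds ratio: for event term *t*,

ROR(t) = (a·d)/(b·c),

where *a* is the target-drug count of *t*, *b* the target drug's
count of all other events, and *c*, *d* the comparator analogues.
The confidence interval is Woolf's log-normal interval,
exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)), with z fixed at the
conventional printed constant 1.96 at the 95% level (the exact normal
quantile is used for any other level).  A (drug, event) pair is a
*signal* when a ≥ 3 and the lower CI bound is strictly greater
than 1.

Interpretation caveats are inherent to the design: reporting rates
are not incidence rates, the comparator mix is heterogeneous, and no
multiple-testing adjustment is applied (none is conventional for this
screen); results are hypothesis-generating.

## Pipeline

1. **Parsing** (`io`): the FAERS quarterly ASCII dialect —
   `$`-delimited, header row, no quoting.  Every data line yields one
   typed record or one logged issue; unparseable optional fields
   (invalid calendar dates, unit codes outside the closed sets) become
   missing with a logged issue, while a bad required field skips the
   line.  Dates stay YYYYMMDD integers (deduplication needs only their
   ordering).  Enumerations are upper-cased on read because real
   quarters mix case.  Files are UTF-8 with a Latin-1 fallback.
2. **Deduplication** (`dedup`): three ordered rules — identical rows
   collapse; per `CASEID` keep the greatest `PRIMARYID`; per
   `PRIMARYID` keep the latest `FDA_DT`.  A missing date loses to any
   real date.  The procedure is idempotent and permutation-invariant;
   an exact date tie between inconsistent rows is resolved by the
   lexicographically greatest field tuple (with a warning) so the
   survivor does not depend on input order.
3. **Cohort** (`cohort`): the study population is every deduplicated
   report with at least one indication PT in the 18-term narrow
   COVID-19 SMQ.  Indication matching is whole-term and
   case-insensitive — SMQ entries are complete PTs, and substring
   matching would spuriously catch longer terms.  Drug matching is
   case-insensitive *substring* over `drugname` and `prod_ai`
   (mirroring SQL `LIKE '%…%'` practice against free-text names) and
   requires the primary-suspect role; the default patterns include
   the brand name LAGEVRIO and the misspelling LAGEVIRIO seen in
   source material.  Group membership is decided per report, not per
   drug-sequence linkage.  Excluded reaction terms ("Product use
   issue", "No adverse event", "Wrong technique in product usage
   process", "COVID-19" reported as an event — configurable) are
   removed from the event set; a case whose events are all excluded
   stays in the denominator and contributes no pairs.
4. **Descriptives** (`descriptives`): age is converted to years via
   the FAERS unit codes (YR, DEC×10, MON/12, WK/52, DY/365.25,
   HR/8766) and binned <18 / 18–44 / 45–64 / ≥65 / Unknown.
   MD/PH/OT report as health professionals, CN/LW as
   non-health-professionals.  Countries bucket to United States /
   Japan / Other countries / Not Specified.  Outcome rows count
   reports per code, so a report with several codes appears in several
   rows; "Non-Serious" is a report with no outcome code at all
   (FAERS has no explicit non-serious code) and "Other Outcomes" is
   the OT code.  Dose conformance compares amount × administrations
   per day against the 1,600 mg/day molnupiravir label dose (800 mg
   twice daily); anything unparseable is Unknown.  Percentages are
   count/group-size rounded half-up to two decimals, the convention
   of published tables.
5. **Signals** (`signals`): event counting uses unique (report, PT)
   pairs; with the default pair denominator `a+b` is the group's
   total pair count.  Tables with a zero cell yield a missing ROR —
   the Haldane–Anscombe +0.5 correction exists behind a flag but is
   off by default because the signal rule's a ≥ 3 already excludes
   those tables.  Strata (overall; health-professional reporters;
   age <65 / ≥65; female / male) filter target and comparator groups
   identically, and unknown-valued cases are excluded from the age
   and sex strata.  Output tables round ROR/CI to two decimals; full
   precision is kept on the result objects.

## Synthetic generator

`synthetic.SyntheticConfig` defines the emulated world: report
versioning (5% of cases get an extra DEMO row of one of the three
duplicate flavours the dedup rules target), demographics with
missingness (defaults follow the category frequencies observed in the
FAERS COVID-19 cohort: ~2% target share, ~34% unknown age, ~52%
female, consumer-dominated reporters, US-dominated countries), one
primary-suspect drug per case with free-text names, indications drawn
from the SMQ terms (plus 10% non-COVID cases the cohort step must
drop), independent per-code outcomes, label-relative dosing, and
events.

Events are independent Bernoulli draws per (report, PT) from a toy
vocabulary of ~65 real PT names across 18 system organ classes with
baseline probabilities between 0.0005 and 0.06 (about one event pair
per report on average).  The vocabulary is a constructed stand-in for
the licensed MedDRA dictionary; real analyses supply their own
PT→SOC mapping.  A planted effect multiplies the per-report
reporting *odds* of a PT in the target group by θ, so the true
per-report odds ratio is exactly θ and ROR with the report-count
denominator is a consistent estimator of it (with the pair
denominator the estimand differs from θ by a factor that vanishes as
event probabilities shrink).  The ground-truth ledger records group
sizes, pair totals and per-PT counts, which the pipeline must
reproduce *exactly*, plus the planted θ for estimator checks.

What the generator does **not** emulate — and hence what green tests
do not certify about real FAERS: correlated events within a report,
drug–drug interaction structure, duplicated cases under different
`CASEID`s, temporal reporting trends, demographic confounding of
event propensities, and free-text narrative fields.

## Reconstructed reference cohort

`reference.py` transcribes the published marginal counts of the
2,285-report molnupiravir COVID-19 cohort (FAERS 2020 Q1–2022 Q4) and
rebuilds a synthetic cohort matching them: characteristics are
assigned independently (the joint distribution is not published),
outcome codes go to disjoint report ranges (the published outcome
section sums exactly to the cohort size, so no report needs two
codes), and event terms beyond the published top five are filled from
the toy vocabulary at counts below the fifth rank so the ranking and
the 4,888 pair total are exact.  The Drug eruption comparator count
(c = 62) is back-derived from the published ROR and CI together with
the pair totals; the derivation is over-determined (point estimate
and both bounds agree), which validates the reconstruction.  This
fixture validates the descriptive and ROR code paths against printed
values; it is not FAERS data.

## Numerical and design choices

* Rounding is half-up at two decimals (`util.round_half_up`, via
  `decimal`), matching published tables; Python's built-in banker's
  rounding would differ on exact halves.
* Deduplication tie-breaks prefer the lexicographically greatest
  field tuple rather than input order, trading the convenience of
  "last read wins" for permutation invariance.
* The writer refuses fields containing `$` or newlines — the dialect
  has no quoting, so such values cannot round-trip; the reader logs
  the resulting field-count mismatch as a per-line issue.
* Group assignment intersects COVID-19 indication and target-drug
  match at the report level; linking the indication to the specific
  matched drug sequence is stricter but not used, since combination
  reports are rare in this cohort.
* Sampling sizes in tests: the replicated recovery experiment uses
  200 replicates of 4,500 cases at 50% target share (~2,000 target
  reports each, the scale at which Woolf-interval coverage is close
  to nominal) with a compact 8-PT vocabulary, which keeps the whole
  experiment around half a minute; the law-of-large-numbers
  calibration check uses one 50,000-case draw with family-wise 3σ
  (Bonferroni) bounds.

## Known limitations

* Only the ASCII FAERS dialect is supported (not XML), and only the
  five tables the analysis needs (no THER or RPSR).
* Free-text drug names are matched by substring; there is no
  ingredient normalisation (RxNorm-style), so unusual spellings
  outside the configured patterns are missed.
* CTCAE severity grading of PTs and time-to-onset analytics are out
  of scope (the former requires a licensed mapping, accepted only as
  a user-supplied lookup; FAERS public fields do not carry reliable
  per-case onset data).
* Other disproportionality estimators (PRR, EBGM/MGPS, BCPNN/IC) are
  not implemented.
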