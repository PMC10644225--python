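# pvror

Reporting-odds-ratio (ROR) signal detection for FAERS-style
spontaneous adverse-event reports.

Spontaneous-reporting databases such as the FDA Adverse Event
Reporting System (FAERS) have no denominator of exposed patients, so
post-marketing safety screening works by *disproportionality*: an
adverse event is suspicious for a drug when it makes up a larger share
of that drug's reports than of all other drugs' reports.  `pvror`
implements that workflow end to end for the COVID-19 antiviral setting
— molnupiravir against other COVID-19 drugs — and is intended for
pharmacovigilance analysts and methods researchers who want a tested,
scriptable pipeline rather than ad-hoc SQL.

The package covers:

* **FAERS ASCII IO** — the quarterly `$`-delimited DEMO / DRUG / REAC /
  INDI / OUTC tables, with per-line issue logging instead of silent
  drops (`pvror.io`);
* **case deduplication** — collapse report versions by the three-rule
  procedure: drop identical rows, keep the greatest `PRIMARYID` per
  `CASEID`, keep the latest `FDA_DT` per `PRIMARYID` (`pvror.dedup`);
* **cohort construction** — restrict to reports with a COVID-19
  indication (the 18-term narrow standardized MedDRA query), split
  into a target group (primary-suspect drug name matching
  `MOLNUPIRAVIR` / `LAGEVRIO`) and a comparator group, and strip
  uninformative reaction terms (`pvror.cohort`);
* **descriptives** — age bands, sex, reporter type, country,
  seriousness outcomes, label conformance of the dose, and
  most-common-event rankings (`pvror.descriptives`);
* **signal detection** — per-PT 2×2 tables, ROR with the Woolf 95% CI,
  the *n* ≥ 3 & CI-low > 1 signal rule, SOC roll-up, and stratified
  sensitivity runs (overall, health-professional reporters, age <65 /
  ≥65, female / male) (`pvror.signals`);
* **a synthetic FAERS generator** — seeded, with planted odds
  multipliers and an exact ground-truth ledger, so every stage is
  testable without downloading FAERS (`pvror.synthetic`).

## The statistic

For one event term and one stratum the reports are cross-classified as

|             | target event | other events |
|-------------|--------------|--------------|
| target drug | a            | b            |
| other drugs | c            | d            |

```
ROR = (a·d) / (b·c)
95% CI = exp( ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d) )
```

A drug–event pair is flagged as a **signal** when the event was
reported at least three times in the target group (a ≥ 3) and the
lower CI bound exceeds 1.  By default `a` counts unique (report, PT)
pairs and `a+b` is the target group's total pair count; a
`denominator="reports"` switch uses report counts instead, the
convention under which a per-report odds multiplier is the true odds
ratio.  No multiple-testing adjustment is applied — the output is a
screen, not a confirmatory analysis.

## Worked example

From published summary counts alone (see `examples/03_ror_from_counts.py`):

```python
from pvror import build_contingency, ror, ror_ci

table = build_contingency(pt_counts=(30, 62), totals=(4_888, 374_575))
print(ror(table), ror_ci(table))
```

prints `ROR = 37.30, 95% CI (24.10, 57.74)`: Drug eruption was
reported with molnupiravir 30 times among its 4,888 event pairs and
62 times among 374,575 comparator pairs, i.e. roughly 37-fold
disproportionality — a signal, since a ≥ 3 and the CI excludes 1.

A full synthetic run (`examples/02_full_pipeline.py`) prints the
identification flow and per-stratum signal counts:

```
Stage counts (each stage can only shrink the data):
  parsed_reports: 21003
  after_dedup: 20000
  covid_cohort: 17982
  target_group: 895
  comparator_group: 17087
Signals per stratum (n >= 3 reports and lower 95% CI of ROR > 1):
  overall: 4
  ...
```

21,003 parsed DEMO rows collapse to 20,000 cases (the generator
injected ~5% duplicate report versions), 10% of cases lack a COVID-19
indication and are dropped, and the remainder split 895 / 17,087 by
primary-suspect drug.  The planted effects (θ = 20, 5, 2 on three
PTs) surface among the flagged signals.

The same workflow is available from a shell:

```
pvror generate --config config.yaml --out data/
pvror run      --config config.yaml --out results/
pvror signals  --input data/ --out results/ --strata overall,female,male
```

One narrative script per capability lives in `examples/`.

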