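"""Generate a synthetic FAERS-like quarter with known ground truth.

Writes the five "$"-delimited ASCII tables (DEMO, DRUG, REAC, INDI,
OUTC) plus a JSON ledger recording exactly which drug-event effects
were planted, then parses the files back to show they round-trip.
"""

from pathlib import Path

from pvror import SyntheticConfig, TableKind, generate, read_table

out = Path("scratch/example_synthetic")
config = SyntheticConfig(n_cases=5_000, target_share=0.05, seed=7,
                         planted_effects={"Drug eruption": 20.0,
                                          "Dysphagia": 5.0,
                                          "Diarrhoea": 2.0})
paths = generate(config, out)
print(f"Wrote {len(paths) - 1} tables + ground-truth ledger to {out}/")

for kind in TableKind:
    records, issues = read_table(paths[kind.value], kind)
    print(f"  {kind.value}: {len(records)} records, {len(issues)} "
          "parse issues")

# The ledger is the generator's exact bookkeeping: group sizes, event
# pair totals and per-PT counts the pipeline must reproduce, plus the
# planted odds multipliers the ROR should recover.
from pvror import GroundTruth

ledger = GroundTruth.from_json(paths["ground_truth"])
print(f"ground truth: {ledger.n_target} target / "
      f"{ledger.n_comparator} comparator COVID-19 reports, "
      f"planted effects {ledger.planted_effects}")
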