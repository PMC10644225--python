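"""Reporting odds ratio from published summary counts.

Reproduces a published worked example: in the FAERS COVID-19 cohort
the molnupiravir group reported Drug eruption 30 times among 4,888
event pairs, against 62 times among 374,575 comparator pairs.  The
2x2 table, the ROR and its Woolf 95% CI follow from those four
numbers alone.
"""

from pvror import build_contingency, classify_signal, ror, ror_ci

table = build_contingency(pt_counts=(30, 62), totals=(4_888, 374_575))
print(f"2x2 table: a={table.a} b={table.b} c={table.c} d={table.d}")

estimate = ror(table)
low, high = ror_ci(table)
print(f"ROR = {estimate:.2f}, 95% CI ({low:.2f}, {high:.2f})")
print(f"signal (n >= 3 and CI low > 1): {classify_signal(table.a, low)}")
# ROR ~ 37 means Drug eruption is reported ~37x more often, relative
# to all other events, with molnupiravir than with comparator drugs;
# the published row prints 37.30 (24.10-57.74).
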