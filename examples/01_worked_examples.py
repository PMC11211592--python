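"""Recompute the published disproportionality statistics from printed counts.

The package bundles the published marginal counts (event counts among ICI
records, subgroup totals, per-drug totals, pooled trial incidences).  This
script rebuilds every 2×2 table and recomputes the reporting odds ratios,
their Wald 95% bounds, and the trial relative risk.
"""

from pvhepascan import worked_examples

table = worked_examples()
print(table.to_string(index=False))
print()
print("Each row rebuilds a 2x2 table from published marginal counts and")
print("recomputes the statistic; 'computed' matching 'published' confirms the")
print("Wald ROR implementation reproduces the reported values exactly at 2 dp.")
print("An ROR of 19.34 means autoimmune hepatitis is reported ~19x more often")
print("with ICIs than expected from the rest of the database.")
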