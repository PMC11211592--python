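"""Characterise the cases reporting designated hepatitis events.

Builds a synthetic database, restricts to reports carrying any of the three
designated hepatitis terms (autoimmune hepatitis, immune-mediated hepatitis,
hepatitis fulminant), and prints the clinical summary: region, reporter,
year band, sex, age, regimen, outcomes, indication organs.
"""

from pvhepascan import HRAE, deduplicate, fatal_fraction, label_regimens, summarize_cases
from pvhepascan.synthetic import default_config, generate

store = deduplicate(generate(default_config(n_cases=50_000, seed=3)).pooled).store
regimens = label_regimens(store)
summary = summarize_cases(store, HRAE, regimens=regimens)

print(f"cases with a designated hepatitis term: {summary.n_cases}")
print(f"age, years: median {summary.age_median:.1f} "
      f"(IQR {summary.age_q1:.1f}-{summary.age_q3:.1f}); n = {summary.age_n}")
print(f"fatal outcome fraction: {fatal_fraction(store, HRAE):.3f}")
print()
for variable in ("sex", "region", "regimen", "outcome"):
    print(variable)
    for category, (n, pct) in summary.categories[variable].items():
        if n:
            print(f"  {category:<28} {n:>5} ({pct}%)")

print("\nPercentages use all cases (including missing) as denominator; outcome")
print("categories overlap because one report can carry several outcome codes.")
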