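"""Generate a synthetic spontaneous-report database and scan it for signals.

Plants an odds-ratio-20 association between anti-PD-1 monotherapy and
immune-mediated hepatitis against a 0.1% background, then runs the full
in-memory pipeline: dedup -> regimen labelling -> event x strategy scan.
"""

from pvhepascan import HEPATITIS_SCAN, deduplicate, label_regimens, scan
from pvhepascan.pipeline import strategy_cohorts
from pvhepascan.synthetic import default_config, generate

config = default_config(n_cases=50_000, seed=7)
dataset = generate(config)
print("planted truth:", dataset.truth["planted"][0])

store = deduplicate(dataset.pooled).store
cohorts = strategy_cohorts(label_regimens(store))
results = scan(store, cohorts, HEPATITIS_SCAN, unit="events")

print(f"\n{'event':<28} {'cohort':<18} {'n':>4} {'ROR':>8} {'ROR05':>8} {'IC025':>7}  signal")
for r in results:
    if r.n_observed >= 5:
        print(f"{r.event:<28} {r.cohort:<18} {r.n_observed:>4} "
              f"{r.ror:>8.2f} {r.ror05:>8.2f} {r.ic025:>7.2f}  {r.signal}")

print("\nOnly the planted (event, cohort) cell and its enclosing cohorts should")
print("carry signal=True: n >= 10 cases, ROR05 > 1 and IC025 > 0 jointly.")
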