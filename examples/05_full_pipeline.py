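"""Run the whole configuration-driven pipeline and inspect its outputs.

One RunConfig drives synthesis (or ingestion), deduplication, cohort
construction, the disproportionality scan, head-to-head contrasts, the case
summary and the funnel log; everything lands in the output directory as CSV
and JSON.
"""

import tempfile
from pathlib import Path

from pvhepascan import RunConfig, run
from pvhepascan.synthetic import default_config

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        synth=default_config(n_cases=30_000),
        seed=11,
        output_dir=str(Path(tmp) / "out"),
    )
    result = run(config)

    print("case funnel:")
    print(result.funnel.render())
    print("outputs:", sorted(p.name for p in result.output_dir.iterdir()))

    flagged = result.scan_table[result.scan_table["signal"]]
    print("\nsignal-flagged cells:")
    print(flagged[["event", "cohort", "n_observed", "ror", "ror05", "ic025"]]
          .to_string(index=False))
    print("\nThe funnel shows record conservation at every stage; re-running the")
    print("copied run_config.json reproduces these outputs byte-for-byte.")
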