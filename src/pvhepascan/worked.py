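"""Worked examples: recompute the published statistics from their bundled counts.

The package ships the published 2×2 marginal counts (ICI event-record totals,
per-event counts against the full database, treatment-strategy subgroup
counts, per-drug counts, and pooled clinical-trial incidences) as a JSON data
file.  :func:`worked_examples` rebuilds every contingency table from those
counts and recomputes the reporting odds ratios, their Wald bounds, and the
trial relative risk, reporting computed next to published values.  This is
the desk-scale validation surface: it exercises exactly the same statistical
code paths the full pipeline uses, with no database download.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .disprop import derive_table, relative_risk, ror, round_half_up


def load_printed_counts() -> dict:
    with resources.files("pvhepascan.data").joinpath("printed_counts.json").open() as fh:
        return json.load(fh)


def worked_examples() -> pd.DataFrame:
    """Recompute each published statistic; returns one row per quantity.

    Columns: ``id`` (stable key), ``label``, ``n`` (table total used),
    ``computed`` (2-dp half-up) and ``published``.
    """
    counts = load_printed_counts()
    pub = counts["published"]
    db = counts["database"]
    n_ici = db["n_ici_event_records"]
    n_total = db["n_total_event_records"]
    rows = []

    def add(key: str, label: str, value: float, n: int) -> None:
        rows.append(
            {
                "id": key,
                "label": label,
                "n": n,
                "computed": round_half_up(value, 2),
                "published": pub.get(key),
            }
        )

    # ICI vs full database, external-comparator convention
    scan = counts["scan_counts"]
    for pt, (est_key, lo_key, hi_key) in {
        "Autoimmune hepatitis": ("t1", "t2", "t3"),
        "Immune-mediated hepatitis": ("t4", "imh_ror05", "imh_ror95"),
        "Hepatitis fulminant": ("t5", "t6", "fulminant_ror95"),
    }.items():
        c = scan[pt]
        table = derive_table(c["n_ici"], n_ici, c["n_other"], n_total,
                             convention="external-comparator")
        r = ror(table)
        add(est_key, f"ROR, {pt}, ICI vs full database", r.estimate, table.total)
        add(lo_key, f"ROR05, {pt}, ICI vs full database", r.low, table.total)
        add(hi_key, f"ROR95, {pt}, ICI vs full database", r.high, table.total)

    # head-to-head strategy contrasts
    totals = counts["strategy_totals"]
    strat = counts["strategy_counts"]
    mono_total = totals["pd1_pdl1_mono"] + totals["ctla4_mono"]

    imh = strat["Immune-mediated hepatitis"]
    t = derive_table(imh["pd1_pdl1_mono"], totals["pd1_pdl1_mono"],
                     imh["ctla4_mono"], totals["ctla4_mono"], convention="head-to-head")
    add("t7", "ROR, immune-mediated hepatitis, anti-PD-(L)1 vs anti-CTLA-4 monotherapy",
        ror(t).estimate, t.total)

    t = derive_table(imh["dual"], totals["dual"],
                     imh["pd1_pdl1_mono"] + imh["ctla4_mono"], mono_total,
                     convention="head-to-head")
    add("t8", "ROR, immune-mediated hepatitis, dual ICI vs ICI monotherapy",
        ror(t).estimate, t.total)

    aih = strat["Autoimmune hepatitis"]
    t = derive_table(aih["dual"], totals["dual"],
                     aih["pd1_pdl1_mono"] + aih["ctla4_mono"], mono_total,
                     convention="head-to-head")
    add("t9", "ROR, autoimmune hepatitis, dual ICI vs ICI monotherapy",
        ror(t).estimate, t.total)

    drugs = counts["per_drug_counts"]
    nivo, ipi = drugs["Nivolumab"], drugs["Ipilimumab"]
    t = derive_table(nivo["hrae"], nivo["total"], ipi["hrae"], ipi["total"],
                     convention="head-to-head")
    add("t10", "ROR, hepatitis-related adverse events, nivolumab vs ipilimumab",
        ror(t).estimate, t.total)

    inc = counts["trial_incidence_pct"]
    add("t11", "Relative risk, pooled trial incidence, dual ICI vs monotherapy",
        relative_risk(inc["dual"], inc["mono"]), 2)

    return pd.DataFrame(rows)
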