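"""Collapse multiple submitted versions of a case to its current report.

FAERS reports arrive as full-replacement versions sharing a CASEID.  The
FDA-recommended rule keeps, per case, the version with the most recent FDA
receipt date, breaking ties by the higher PRIMARYID.  Versions with a missing
receipt date sort below any dated version.  Entry tables (drugs, reactions,
outcomes, indications, therapies) of losing versions are discarded wholesale:
each version is a complete replacement, not a delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .faers_io import TABLES, QuarterBundle, id_sort_key


@dataclass
class DedupResult:
    """Survivors plus an audit count of dropped versions."""

    store: QuarterBundle
    n_input_versions: int
    n_survivors: int

    @property
    def n_dropped(self) -> int:
        return self.n_input_versions - self.n_survivors


def select_survivors(demo: pd.DataFrame) -> pd.DataFrame:
    """Return the surviving DEMO row per caseid, sorted by caseid.

    Survivor = argmax over (fda_dt, primaryid); missing fda_dt counts as 0.
    Deterministic regardless of input order.
    """
    if demo.empty:
        return demo.copy()
    df = demo.copy()
    dt = pd.to_numeric(df["fda_dt"].astype(str).str.strip(), errors="coerce")
    df["_dt"] = dt.fillna(0).astype(np.int64)
    keys = df["primaryid"].map(id_sort_key)
    df["_pid_text"] = [k[0] == 1 for k in keys]  # text ids sort above numeric
    df["_pid_num"] = [k[1] for k in keys]
    df["_pid_str"] = [k[2] for k in keys]
    ck = df["caseid"].map(id_sort_key)
    df["_case_text"] = [k[0] for k in ck]
    df["_case_num"] = [k[1] for k in ck]
    df["_case_str"] = [k[2] for k in ck]
    df = df.sort_values(
        ["_case_text", "_case_num", "_case_str", "_dt", "_pid_text", "_pid_num", "_pid_str"],
        kind="mergesort",
    )
    survivors = df.groupby("caseid", sort=False).tail(1)
    survivors = survivors.drop(
        columns=[c for c in survivors.columns if c.startswith("_")]
    )
    return survivors.reset_index(drop=True)


def deduplicate(bundle: QuarterBundle) -> DedupResult:
    """Apply the receipt-date/primaryid rule over a pooled (cross-quarter) store.

    Returns a store whose DEMO holds exactly one row per distinct caseid and
    whose entry tables are restricted to surviving primaryids.
    """
    survivors = select_survivors(bundle.demo)
    keep = set(survivors["primaryid"])
    frames = {"demo": survivors}
    for t in TABLES[1:]:
        df = bundle.table(t)
        frames[t] = df[df["primaryid"].isin(keep)].reset_index(drop=True)
    store = QuarterBundle(**frames, quarter=bundle.quarter, rejected=bundle.rejected)
    return DedupResult(
        store=store, n_input_versions=len(bundle.demo), n_survivors=len(survivors)
    )
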