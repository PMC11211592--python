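"""Clinical characterisation of case series: the report-level summary table.

Summarises a deduplicated, regimen-labelled case set matching an event term
set by reporting region, reporter occupation, receipt-year band, sex, age at
onset (median and IQR over non-missing parsed ages), treatment regimen,
report outcome, and indication organ.  Percentages use the full case count
(including missing) as denominator; outcome categories may overlap, since a
report can carry several outcome codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .cohort import (
    EventTermSet,
    Regimen,
    map_country_to_region,
    map_indication_to_organ,
    normalize_term,
)
from .faers_io import QuarterBundle, parse_age_series

HCP_CODES = frozenset({"MD", "PH", "OT", "HP"})
NON_HCP_CODES = frozenset({"CN", "LW"})

YEAR_BANDS = (
    ("2011-2015", 2011, 2015),
    ("2016-2020", 2016, 2020),
    ("2021-2023Q1", 2021, 2023),
)


@dataclass
class CaseSummary:
    """Per-category counts and percentages plus the age summary."""

    n_cases: int
    categories: dict[str, dict[str, tuple[int, float]]] = field(default_factory=dict)
    age_median: float = float("nan")
    age_q1: float = float("nan")
    age_q3: float = float("nan")
    age_n: int = 0

    def counts(self, variable: str) -> dict[str, int]:
        return {k: v[0] for k, v in self.categories.get(variable, {}).items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, cats in self.categories.items():
            for cat, (n, pct) in cats.items():
                rows.append({"variable": var, "category": cat, "n": n, "pct": pct})
        rows.append(
            {
                "variable": "age_years",
                "category": f"median (IQR); n = {self.age_n}",
                "n": self.age_n,
                "pct": float("nan"),
            }
        )
        return pd.DataFrame(rows)


def _pct(n: int, denom: int) -> float:
    if denom == 0:
        return 0.0
    # percentages at 1 dp, half-up, matching printed report tables
    return np.floor(1000.0 * n / denom + 0.5) / 10.0


def _tabulate(series: pd.Series, denom: int, order: list[str]) -> dict[str, tuple[int, float]]:
    vc = series.value_counts()
    out = {}
    for cat in order:
        n = int(vc.get(cat, 0))
        out[cat] = (n, _pct(n, denom))
    for cat in vc.index:
        if cat not in out:
            out[str(cat)] = (int(vc[cat]), _pct(int(vc[cat]), denom))
    return out


def _year_band(fda_dt: object) -> str:
    s = str(fda_dt).strip()
    if len(s) != 8 or not s.isdigit():
        return "other"
    year = int(s[:4])
    for label, lo, hi in YEAR_BANDS:
        if lo <= year <= hi:
            return label
    return "other"


def case_mask_for_events(store: QuarterBundle, events: EventTermSet) -> pd.Series:
    """Boolean mask over store.demo for reports carrying any term of *events*."""
    reac = store.reac
    pts = reac["pt"].map(normalize_term)
    hit_pids = set(reac.loc[pts.isin(events.terms), "primaryid"])
    return store.demo["primaryid"].isin(hit_pids)


def summarize_cases(
    store: QuarterBundle,
    events: EventTermSet,
    regimens: pd.Series | None = None,
) -> CaseSummary:
    """Build the case-characterisation summary for reports matching *events*.

    *regimens*, when given, is a label Series indexed by primaryid (from
    :func:`pvhepascan.cohort.label_regimens`).  An empty case set returns an
    all-zero summary.
    """
    mask = case_mask_for_events(store, events)
    demo = store.demo[mask].reset_index(drop=True)
    n = len(demo)
    summary = CaseSummary(n_cases=n)
    pids = demo["primaryid"]

    region = demo["reporter_country"].map(map_country_to_region)
    summary.categories["region"] = _tabulate(
        region, n, ["Americas", "Oceania", "Africa", "Europe", "Asia", "Missing"]
    )

    occ = demo["occp_cod"].fillna("").astype(str).str.strip().str.upper()
    reporter = pd.Series(
        np.where(occ.isin(HCP_CODES), "Healthcare professional",
                 np.where(occ.isin(NON_HCP_CODES), "Non-healthcare professional", "Missing")),
        index=demo.index,
    )
    summary.categories["reporter"] = _tabulate(
        reporter, n, ["Healthcare professional", "Non-healthcare professional", "Missing"]
    )

    band = demo["fda_dt"].map(_year_band)
    summary.categories["year_band"] = _tabulate(
        band, n, [b[0] for b in YEAR_BANDS] + ["other"]
    )

    sex = demo["sex"].fillna("").astype(str).str.strip().str.upper()
    sex = pd.Series(
        np.where(sex == "M", "Male", np.where(sex == "F", "Female", "Missing")),
        index=demo.index,
    )
    summary.categories["sex"] = _tabulate(sex, n, ["Male", "Female", "Missing"])

    ages = parse_age_series(demo["age"], demo["age_cod"]).dropna()
    summary.age_n = len(ages)
    if len(ages):
        # linear interpolation between order statistics, never imputed
        summary.age_q1, summary.age_median, summary.age_q3 = np.percentile(
            ages, [25, 50, 75], method="linear"
        )

    if regimens is not None:
        reg = regimens.reindex(pids.values).fillna(Regimen.NON_ICI.value)
        reg.index = demo.index
        summary.categories["regimen"] = _tabulate(
            reg, n, [r.value for r in Regimen]
        )

    outc = store.outc[store.outc["primaryid"].isin(set(pids))]
    codes = outc["outc_cod"].fillna("").astype(str).str.strip().str.upper()
    outcome_order = ["DE", "LT", "HO", "DS", "CA", "RI", "OT"]
    by_code = {
        code: outc.loc[codes == code, "primaryid"].nunique() for code in outcome_order
    }
    with_any = outc["primaryid"].nunique()
    cats = {code: (cnt, _pct(cnt, n)) for code, cnt in by_code.items()}
    cats["Missing"] = (n - with_any, _pct(n - with_any, n))
    summary.categories["outcome"] = cats

    indi = store.indi[store.indi["primaryid"].isin(set(pids))]
    organ_by_pid: dict[str, str] = {}
    for pid, ipt in zip(indi["primaryid"], indi["indi_pt"]):
        organ = map_indication_to_organ(ipt)
        prev = organ_by_pid.get(pid)
        # a specific organ wins over Unspecified when a report has several
        if prev is None or (prev == "Unspecified" and organ != "Unspecified"):
            organ_by_pid[pid] = organ
    organ = pids.map(lambda p: organ_by_pid.get(p, "Unspecified"))
    summary.categories["indication_organ"] = _tabulate(organ, n, [])
    return summary


def fatal_fraction(store: QuarterBundle, events: EventTermSet) -> float:
    """Fraction of event-matching cases with any death (DE) outcome.

    Returns NaN for an empty case set (flagged undefined rather than raised).
    """
    mask = case_mask_for_events(store, events)
    pids = set(store.demo.loc[mask, "primaryid"])
    if not pids:
        return float("nan")
    outc = store.outc
    codes = outc["outc_cod"].fillna("").astype(str).str.strip().str.upper()
    fatal = set(outc.loc[(codes == "DE") & outc["primaryid"].isin(pids), "primaryid"])
    return len(fatal) / len(pids)
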