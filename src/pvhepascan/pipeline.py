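"""End-to-end orchestration: ingest → dedup → cohorts → scan → descriptives.

A single :class:`RunConfig` drives the whole analysis; outputs are plain CSV
and JSON files plus a structured case funnel so every reported count is
traceable to the stage that produced it.  Inputs may be FAERS-style quarter
directories or a synthetic-data specification; either way the run is
deterministic given the config (and its seed, when synthesizing).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import cohort as cohort_mod
from .cohort import (
    BUILTIN_EVENT_SETS,
    DrugDictionary,
    EventTermSet,
    ICI_REGIMENS,
    Regimen,
    label_regimens,
)
from .dedup import deduplicate
from .descriptives import fatal_fraction, summarize_cases
from .disprop import (
    SignalCriteria,
    derive_table,
    results_frame,
    ror,
    scan,
)
from .faers_io import QuarterBundle, concat_bundles, read_quarter
from .synthetic import SyntheticConfig, generate


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class FunnelStage:
    stage: str
    n_in: int
    n_out: int
    reasons: dict[str, int] = dc_field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_out


@dataclass
class FunnelLog:
    """Ordered per-stage record counts; kept + dropped = input at each stage."""

    stages: list[FunnelStage] = dc_field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, reasons: dict[str, int] | None = None):
        st = FunnelStage(stage, n_in, n_out, reasons or {})
        if st.n_dropped < 0:
            raise ValueError(f"stage {stage!r} emits more records than it receives")
        if st.reasons and sum(st.reasons.values()) != st.n_dropped:
            raise ValueError(f"stage {stage!r}: drop reasons do not partition the drops")
        self.stages.append(st)
        return st

    def to_records(self) -> list[dict]:
        return [
            {"stage": s.stage, "in": s.n_in, "out": s.n_out,
             "dropped": s.n_dropped, "reasons": s.reasons}
            for s in self.stages
        ]

    def render(self) -> str:
        lines = []
        for s in self.stages:
            lines.append(f"{s.stage}: {s.n_in} -> {s.n_out} (dropped {s.n_dropped})")
            for reason, n in sorted(s.reasons.items()):
                lines.append(f"    {reason}: {n}")
        return "\n".join(lines) + "\n"


class SignalCriteriaConfig(BaseModel):
    min_cases: int = 10
    ror05_gt: float = 1.0
    ic025_gt: float = 0.0

    def build(self) -> SignalCriteria:
        return SignalCriteria(self.min_cases, self.ror05_gt, self.ic025_gt)


class RunConfig(BaseModel):
    """Serializable run specification; copied verbatim into the output."""

    input_quarters: list[str] = []
    synth: SyntheticConfig | None = None
    drug_dictionary_extensions: dict[str, tuple[str, str]] = {}
    event_set_overrides: dict[str, list[str]] = {}
    scan_event_set: str = "HEPATITIS_SCAN"
    hrae_event_set: str = "HRAE"
    unit: Literal["events", "reports"] = "events"
    descriptives_unit: Literal["reports"] = "reports"
    criteria: SignalCriteriaConfig = SignalCriteriaConfig()
    output_dir: str = "pvhepascan-out"
    seed: int = Field(default=0, ge=0)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def event_set(self, name: str) -> EventTermSet:
        if name in self.event_set_overrides:
            return EventTermSet.from_terms(name, self.event_set_overrides[name])
        return BUILTIN_EVENT_SETS[name]

    def dictionary(self) -> DrugDictionary:
        d = DrugDictionary.default()
        d.extend(self.drug_dictionary_extensions)
        return d


def strategy_cohorts(regimens: pd.Series) -> dict[str, list[str]]:
    """Treatment-strategy cohorts (primaryid lists) from a regimen labelling.

    ``ICI`` pools every ICI-exposed report; the monotherapy classes, dual
    therapy and chemo combination are also exposed individually, plus the
    pooled ``ICI_MONOTHERAPY``.
    """
    ici_vals = {r.value for r in ICI_REGIMENS}
    mono_vals = {
        Regimen.ANTI_PD1_MONO.value,
        Regimen.ANTI_PDL1_MONO.value,
        Regimen.ANTI_CTLA4_MONO.value,
    }
    out: dict[str, list[str]] = {
        "ICI": [str(p) for p, v in regimens.items() if v in ici_vals],
        "ICI_MONOTHERAPY": [str(p) for p, v in regimens.items() if v in mono_vals],
    }
    for reg in sorted(ici_vals):
        out[reg] = [str(p) for p, v in regimens.items() if v == reg]
    return out


@dataclass
class RunResult:
    output_dir: Path
    store: QuarterBundle
    regimens: pd.Series
    scan_table: pd.DataFrame
    contrasts: pd.DataFrame
    summary: pd.DataFrame
    forest: pd.DataFrame
    funnel: FunnelLog


def _head_to_head(store, regimens, events: EventTermSet, unit: str) -> pd.DataFrame:
    """Dual-vs-monotherapy and PD-(L)1-vs-CTLA-4 contrasts per event term."""
    from .disprop import _event_records  # shared record extraction

    cohorts = strategy_cohorts(regimens)
    records = _event_records(store)
    rows = []

    def cohort_counts(name: str, term: str) -> tuple[int, int]:
        members = set(cohorts.get(name, ()))
        sub = records[records["primaryid"].isin(members)]
        if unit == "events":
            return int((sub["pt"] == term).sum()), len(sub)
        return sub.loc[sub["pt"] == term, "primaryid"].nunique(), len(members)

    contrasts = [
        ("DUAL_ICI vs ICI_MONOTHERAPY", "DUAL_ICI", "ICI_MONOTHERAPY"),
        ("ANTI_PD1_MONO+ANTI_PDL1_MONO vs ANTI_CTLA4_MONO", "_PD_AXIS_MONO", "ANTI_CTLA4_MONO"),
    ]
    pd_axis = sorted(
        set(cohorts.get("ANTI_PD1_MONO", [])) | set(cohorts.get("ANTI_PDL1_MONO", []))
    )
    cohorts["_PD_AXIS_MONO"] = pd_axis
    for term in sorted(events.terms):
        for label, exp_name, comp_name in contrasts:
            a, na = cohort_counts(exp_name, term)
            c, nc = cohort_counts(comp_name, term)
            row = {"event": term, "contrast": label, "a": a, "n_exposed": na,
                   "c": c, "n_comparator": nc,
                   "ror": float("nan"), "ror05": float("nan"), "ror95": float("nan")}
            if na > 0 and nc > 0 and a < na and c < nc and a > 0 and c > 0:
                t = derive_table(a, na, c, nc, convention="head-to-head")
                r = ror(t)
                row.update(ror=r.estimate, ror05=r.low, ror95=r.high)
            rows.append(row)
    return pd.DataFrame(rows)


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline; outputs land in ``config.output_dir``.

    On stage failure, partial outputs are removed and :class:`StageError`
    names the failing stage.
    """
    out = Path(config.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    funnel = FunnelLog()
    stage = "configure"
    try:
        (out / "run_config.json").write_text(
            config.model_dump_json(indent=2) + "\n"
        )

        stage = "ingest"
        if config.synth is not None:
            synth_cfg = config.synth.model_copy(update={"seed": config.seed})
            dataset = generate(synth_cfg)
            bundles = list(dataset.bundles.values())
        elif config.input_quarters:
            bundles = [read_quarter(p) for p in config.input_quarters]
        else:
            raise ValueError("config names neither input_quarters nor synth")
        pooled = concat_bundles(bundles)
        n_source_rows = len(pooled.demo) + len(pooled.rejected[
            pooled.rejected.get("table", pd.Series(dtype=object)) == "demo"
        ]) if len(pooled.rejected) else len(pooled.demo)
        reasons = {}
        if len(pooled.rejected):
            demo_rej = pooled.rejected[pooled.rejected["table"] == "demo"]
            reasons = demo_rej["reason"].value_counts().to_dict()
        funnel.add("ingest", n_source_rows, len(pooled.demo), reasons)

        stage = "dedup"
        result = deduplicate(pooled)
        store = result.store
        funnel.add("dedup", result.n_input_versions, result.n_survivors,
                   {"superseded case version": result.n_dropped})

        stage = "cohort"
        dictionary = config.dictionary()
        regimens = label_regimens(store, dictionary)
        cohorts = strategy_cohorts(regimens)
        n_ici = len(cohorts["ICI"])
        funnel.add("ici-exposure", len(store.demo), n_ici,
                   {"no primary-suspect ICI drug": len(store.demo) - n_ici})

        stage = "disprop-scan"
        scan_set = config.event_set(config.scan_event_set)
        criteria = config.criteria.build()
        results = scan(store, cohorts, scan_set, criteria=criteria, unit=config.unit)
        scan_table = results_frame(results)
        scan_table.to_csv(out / "scan.csv", index=False)
        with open(out / "scan.json", "w") as fh:
            for r in results:
                fh.write(json.dumps(r.as_dict()) + "\n")

        stage = "disprop-contrasts"
        hrae_set = config.event_set(config.hrae_event_set)
        contrasts = _head_to_head(store, regimens, hrae_set, config.unit)
        contrasts.to_csv(out / "contrasts.csv", index=False)

        stage = "forest-export"
        forest_rows = [
            {"label": f"{r.event} | {r.cohort}", "estimate": r.ror,
             "low": r.ror05, "high": r.ror95}
            for r in results
            if r.defined and pd.notna(r.ror) and r.n_observed > 0
        ] + [
            {"label": f"{row.event} | {row.contrast}", "estimate": row.ror,
             "low": row.ror05, "high": row.ror95}
            for row in contrasts.itertuples()
            if pd.notna(row.ror)
        ]
        forest = pd.DataFrame(forest_rows, columns=["label", "estimate", "low", "high"])
        forest.to_csv(out / "forest.csv", index=False)

        stage = "descriptives"
        hrae_mask_n = int(
            store.demo["primaryid"]
            .isin(set(store.reac.loc[
                store.reac["pt"].map(cohort_mod.normalize_term).isin(hrae_set.terms),
                "primaryid"]))
            .sum()
        )
        funnel.add("hrae-cases", len(store.demo), hrae_mask_n,
                   {"no designated hepatitis term": len(store.demo) - hrae_mask_n})
        summary_obj = summarize_cases(store, hrae_set, regimens=regimens)
        summary = summary_obj.to_frame()
        summary.to_csv(out / "summary.csv", index=False)
        ff = fatal_fraction(store, hrae_set)
        (out / "descriptives.json").write_text(json.dumps({
            "n_cases": summary_obj.n_cases,
            "fatal_fraction": None if pd.isna(ff) else ff,
            "age_median": None if pd.isna(summary_obj.age_median) else summary_obj.age_median,
            "age_iqr": [None if pd.isna(v) else v
                        for v in (summary_obj.age_q1, summary_obj.age_q3)],
            "age_n": summary_obj.age_n,
        }, indent=2) + "\n")

        stage = "funnel-log"
        (out / "funnel.txt").write_text(funnel.render())
        (out / "funnel.json").write_text(json.dumps(funnel.to_records(), indent=2) + "\n")
    except Exception as exc:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in out.iterdir():
                p.unlink(missing_ok=True)
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunResult(
        output_dir=out, store=store, regimens=regimens, scan_table=scan_table,
        contrasts=contrasts, summary=summary, forest=forest, funnel=funnel,
    )
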