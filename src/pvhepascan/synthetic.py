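"""Synthetic FAERS-style data with known ground truth.

Every pipeline stage is exercisable without downloading anything: the
generator emits quarterly bundles in the same dialect the reader consumes,
with duplicate case versions, verbatim drug-name spellings (generic, brand
and combination strings), per-PT Bernoulli event draws, demographics,
outcomes and — crucially — drug–event associations planted at a known odds
ratio.  For a planted (cohort, PT, OR) with background rate ``p0``, cohort
members draw the event at ``p1`` satisfying ``p1/(1−p1) = OR·p0/(1−p0)``, so
the realized sample odds ratio converges to the target as n grows.

Generation is a pure function of (config, seed): identical configs produce
byte-identical written bundles.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .faers_io import TABLES, QuarterBundle, concat_bundles


class ConfigError(ValueError):
    pass


class ExposureSpec(BaseModel):
    """One exposure cohort: assignment probability and drug spellings.

    ``ps_drugs`` lists alternative primary-suspect entry sets; each case
    picks one alternative uniformly and gets one PS drug row per string in
    it (a string may itself be a combination like "NIVOLUMAB AND
    IPILIMUMAB").  ``concomitant`` strings are written with role C.
    """

    probability: float = Field(ge=0.0, le=1.0)
    ps_drugs: list[list[str]]
    concomitant: list[str] = []
    indications: dict[str, float] = {}


class PlantedAssociation(BaseModel):
    cohort: str
    pt: str
    odds_ratio: float = Field(gt=0.0)


class Demographics(BaseModel):
    sex: dict[str, float] = {"M": 0.45, "F": 0.45, "": 0.10}
    country: dict[str, float] = {
        "US": 0.35, "JP": 0.14, "DE": 0.10, "FR": 0.10, "GB": 0.08,
        "CA": 0.05, "AU": 0.04, "CN": 0.04, "ZA": 0.02, "": 0.08,
    }
    occupation: dict[str, float] = {"MD": 0.45, "PH": 0.15, "OT": 0.10, "CN": 0.18, "": 0.12}
    age_mean: float = 63.0
    age_sd: float = 12.0
    age_missing: float = 0.30


class SyntheticConfig(BaseModel):
    """Full generative specification for fixture quarters."""

    n_cases: int = Field(gt=0)
    duplicate_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    quarters: list[str] = ["2022Q2", "2022Q3", "2022Q4", "2023Q1"]
    drug_exposure: dict[str, ExposureSpec]
    background_event_rates: dict[str, float]
    planted_associations: list[PlantedAssociation] = []
    demographics: Demographics = Demographics()
    outcome_rates: dict[str, float] = {"HO": 0.25, "OT": 0.55}
    event_outcome_rates: dict[str, dict[str, float]] = {}
    filler_pt: str = "Drug ineffective"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        total_p = sum(s.probability for s in self.drug_exposure.values())
        if total_p > 1.0 + 1e-9:
            raise ConfigError(f"cohort probabilities sum to {total_p} > 1")
        for pt, p in self.background_event_rates.items():
            if not 0.0 <= p < 1.0:
                raise ConfigError(f"background rate for {pt!r} out of [0, 1): {p}")
        for pa in self.planted_associations:
            if pa.cohort not in self.drug_exposure:
                raise ConfigError(f"planted association references unknown cohort {pa.cohort!r}")
            if pa.pt not in self.background_event_rates:
                raise ConfigError(f"planted PT {pa.pt!r} has no background rate")
            planted_probability(self.background_event_rates[pa.pt], pa.odds_ratio)
        return self


def planted_probability(p0: float, odds_ratio: float) -> float:
    """Event probability giving the target odds ratio against background p0."""
    if not 0.0 < p0 < 1.0:
        raise ConfigError(f"background rate must be in (0, 1) to plant an odds ratio, got {p0}")
    odds = odds_ratio * p0 / (1.0 - p0)
    p1 = odds / (1.0 + odds)
    if not np.isfinite(p1) or p1 >= 1.0:
        raise ConfigError("odds ratio unachievable at this background rate")
    return p1


BACKGROUND_COHORT = "BACKGROUND"
_BACKGROUND_DRUGS = [["ASPIRIN"], ["METFORMIN"], ["ATORVASTATIN"], ["LISINOPRIL"], ["OMEPRAZOLE"]]
_BACKGROUND_INDICATIONS = {"Hypertension": 0.3, "Type 2 diabetes mellitus": 0.25,
                           "Pain": 0.25, "Product used for unknown indication": 0.2}


def default_config(
    n_cases: int = 50_000,
    seed: int = 0,
    planted: Sequence[tuple[str, str, float]] = (("ICI_PD1_MONO", "Immune-mediated hepatitis", 20.0),),
) -> SyntheticConfig:
    """Study-shaped defaults: a dominant non-ICI background, ICI cohorts in
    FAERS-like proportions, low hepatitis background rates, and one planted
    association at odds ratio 20 against a 0.001 background."""
    ici_indications = {
        "Malignant melanoma": 0.35, "Non-small cell lung cancer": 0.30,
        "Renal cell carcinoma": 0.12, "Product used for unknown indication": 0.10,
        "Hepatocellular carcinoma": 0.05, "Transitional cell carcinoma": 0.08,
    }
    return SyntheticConfig(
        n_cases=n_cases,
        seed=seed,
        drug_exposure={
            "ICI_PD1_MONO": ExposureSpec(
                probability=0.06,
                ps_drugs=[["NIVOLUMAB"], ["OPDIVO"], ["PEMBROLIZUMAB"], ["KEYTRUDA"]],
                indications=ici_indications,
            ),
            "ICI_DUAL": ExposureSpec(
                probability=0.02,
                ps_drugs=[["NIVOLUMAB", "IPILIMUMAB"], ["OPDIVO", "YERVOY"],
                          ["NIVOLUMAB AND IPILIMUMAB"]],
                indications=ici_indications,
            ),
            "ICI_CHEMO": ExposureSpec(
                probability=0.02,
                ps_drugs=[["PEMBROLIZUMAB"], ["NIVOLUMAB"]],
                concomitant=["CARBOPLATIN"],
                indications=ici_indications,
            ),
        },
        background_event_rates={
            "Immune-mediated hepatitis": 0.001,
            "Autoimmune hepatitis": 0.001,
            "Hepatitis fulminant": 0.0005,
            "Hepatitis C": 0.001,
            "Hepatitis acute": 0.001,
            "Nausea": 0.05,
            "Fatigue": 0.04,
            "Rash": 0.03,
        },
        planted_associations=[
            PlantedAssociation(cohort=c, pt=p, odds_ratio=o) for c, p, o in planted
        ],
        event_outcome_rates={
            "Immune-mediated hepatitis": {"DE": 0.25, "HO": 0.60, "LT": 0.12},
            "Autoimmune hepatitis": {"DE": 0.25, "HO": 0.60, "LT": 0.15},
            "Hepatitis fulminant": {"DE": 0.70, "HO": 0.65},
        },
    )


@dataclasses.dataclass
class SyntheticDataset:
    """Generated bundles plus the planted ground truth."""

    bundles: dict[str, QuarterBundle]
    truth: dict

    @property
    def pooled(self) -> QuarterBundle:
        return concat_bundles(self.bundles.values())


def _quarter_date_range(label: str) -> tuple[int, int]:
    year = int(label[:4])
    q = int(label[5])
    start_month = 3 * (q - 1) + 1
    return year, start_month


def _sample_categorical(rng, mapping: Mapping[str, float], size: int) -> np.ndarray:
    keys = list(mapping)
    probs = np.asarray([mapping[k] for k in keys], dtype=float)
    s = probs.sum()
    if s <= 0:
        return np.full(size, "", dtype=object)
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=size, p=probs / s)]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate quarter bundles per *config* (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    labels = list(config.drug_exposure) + [BACKGROUND_COHORT]
    probs = [config.drug_exposure[c].probability for c in config.drug_exposure]
    probs.append(max(0.0, 1.0 - sum(probs)))
    cohort = np.asarray(labels, dtype=object)[
        rng.choice(len(labels), size=n, p=np.asarray(probs) / sum(probs))
    ]

    caseid = (10_000_000 + np.arange(n)).astype(np.int64)
    quarter_idx = rng.integers(0, len(config.quarters), size=n)
    # survivor receipt date: a uniformly drawn day inside the case's quarter
    day = rng.integers(1, 29, size=n)
    month_off = rng.integers(0, 3, size=n)
    years = np.empty(n, dtype=np.int64)
    months = np.empty(n, dtype=np.int64)
    for i, q in enumerate(config.quarters):
        y, m0 = _quarter_date_range(q)
        sel = quarter_idx == i
        years[sel] = y
        months[sel] = m0
    months = months + month_off
    fda_dt = years * 10_000 + months * 100 + day

    # events: Bernoulli per PT, with planted cohorts at the odds-matched rate
    planted_by_pt: dict[str, list[PlantedAssociation]] = {}
    for pa in config.planted_associations:
        planted_by_pt.setdefault(pa.pt, []).append(pa)
    event_matrix: dict[str, np.ndarray] = {}
    for pt, p0 in config.background_event_rates.items():
        p = np.full(n, p0)
        for pa in planted_by_pt.get(pt, ()):
            p[cohort == pa.cohort] = planted_probability(p0, pa.odds_ratio)
        event_matrix[pt] = rng.random(n) < p

    demo_cfg = config.demographics
    sex = _sample_categorical(rng, demo_cfg.sex, n)
    country = _sample_categorical(rng, demo_cfg.country, n)
    occp = _sample_categorical(rng, demo_cfg.occupation, n)
    age = np.clip(rng.normal(demo_cfg.age_mean, demo_cfg.age_sd, size=n), 18, 95)
    age_missing = rng.random(n) < demo_cfg.age_missing
    age_str = np.char.mod("%d", np.round(age).astype(int)).astype(object)
    age_str[age_missing] = ""
    age_cod = np.where(age_missing, "", "YR").astype(object)

    # outcomes: per-code Bernoulli; event-keyed rates override the defaults
    outcome_codes = sorted(
        set(config.outcome_rates) | {c for m in config.event_outcome_rates.values() for c in m}
    )
    outcome_matrix: dict[str, np.ndarray] = {}
    for code in outcome_codes:
        p = np.full(n, config.outcome_rates.get(code, 0.0))
        for pt, rates in config.event_outcome_rates.items():
            if code in rates and pt in event_matrix:
                p = np.where(event_matrix[pt], rates[code], p)
        outcome_matrix[code] = rng.random(n) < p

    # duplicate versions: content-identical, strictly earlier receipt date
    has_dup = rng.random(n) < config.duplicate_rate
    # version suffix makes primaryid unique and ordered within a case
    pid_survivor = caseid * 10 + 2
    pid_earlier = caseid * 10 + 1
    earlier_dt = years * 10_000 + (months - month_off) * 100 + np.maximum(day - 1, 1)
    # guarantee strictly earlier: shift to the quarter's first month, day-1
    earlier_dt = np.minimum(earlier_dt, fda_dt - 1)

    # per-case drug rows
    drug_rows: dict[str, list] = {k: [] for k in ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai")}
    indi_rows: dict[str, list] = {k: [] for k in ("primaryid", "indi_drug_seq", "indi_pt")}
    background_spec = ExposureSpec(
        probability=0.0, ps_drugs=_BACKGROUND_DRUGS, indications=_BACKGROUND_INDICATIONS
    )
    specs = dict(config.drug_exposure)
    specs[BACKGROUND_COHORT] = background_spec
    alt_choice = {
        c: rng.integers(0, len(specs[c].ps_drugs), size=n) for c in specs
    }
    indication_draw = {
        c: _sample_categorical(rng, specs[c].indications, n) if specs[c].indications
        else np.full(n, "", dtype=object)
        for c in specs
    }

    pid_all: list[np.ndarray] = []
    version_rows: dict[str, list] = {
        k: [] for k in ("primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
                        "reporter_country", "occp_cod")
    }

    def emit_version(pids: np.ndarray, dts: np.ndarray, sel: np.ndarray) -> None:
        version_rows["primaryid"].append(pids[sel].astype(str))
        version_rows["caseid"].append(caseid[sel].astype(str))
        version_rows["fda_dt"].append(dts[sel].astype(str))
        version_rows["age"].append(age_str[sel])
        version_rows["age_cod"].append(age_cod[sel])
        version_rows["sex"].append(sex[sel])
        version_rows["reporter_country"].append(country[sel])
        version_rows["occp_cod"].append(occp[sel])

    all_cases = np.ones(n, dtype=bool)
    emit_version(pid_survivor, fda_dt, all_cases)
    emit_version(pid_earlier, earlier_dt, has_dup)

    demo = pd.DataFrame({k: np.concatenate(v) for k, v in version_rows.items()})

    # entry tables exist for every version (each version is a full replacement)
    def emit_entries(case_sel: np.ndarray, pids: np.ndarray) -> None:
        idx = np.flatnonzero(case_sel)
        for i in idx:
            pid = str(pids[i])
            c = cohort[i]
            spec = specs[c]
            seq = 1
            for name in spec.ps_drugs[alt_choice[c][i]]:
                drug_rows["primaryid"].append(pid)
                drug_rows["drug_seq"].append(str(seq))
                drug_rows["role_cod"].append("PS")
                drug_rows["drugname"].append(name)
                drug_rows["prod_ai"].append("")
                if seq == 1 and indication_draw[c][i]:
                    indi_rows["primaryid"].append(pid)
                    indi_rows["indi_drug_seq"].append("1")
                    indi_rows["indi_pt"].append(indication_draw[c][i])
                seq += 1
            for name in spec.concomitant:
                drug_rows["primaryid"].append(pid)
                drug_rows["drug_seq"].append(str(seq))
                drug_rows["role_cod"].append("C")
                drug_rows["drugname"].append(name)
                drug_rows["prod_ai"].append("")
                seq += 1

    emit_entries(all_cases, pid_survivor)
    emit_entries(has_dup, pid_earlier)

    reac_pid: list[np.ndarray] = []
    reac_pt: list[np.ndarray] = []
    any_event = np.zeros(n, dtype=bool)
    for pt, hit in event_matrix.items():
        any_event |= hit
        for pids, sel in ((pid_survivor, hit), (pid_earlier, hit & has_dup)):
            reac_pid.append(pids[sel].astype(str))
            reac_pt.append(np.full(int(sel.sum()), pt, dtype=object))
    no_event = ~any_event
    for pids, sel in ((pid_survivor, no_event), (pid_earlier, no_event & has_dup)):
        reac_pid.append(pids[sel].astype(str))
        reac_pt.append(np.full(int(sel.sum()), config.filler_pt, dtype=object))
    reac = pd.DataFrame({"primaryid": np.concatenate(reac_pid), "pt": np.concatenate(reac_pt)})

    outc_pid: list[np.ndarray] = []
    outc_cod: list[np.ndarray] = []
    for code, hit in outcome_matrix.items():
        for pids, sel in ((pid_survivor, hit), (pid_earlier, hit & has_dup)):
            outc_pid.append(pids[sel].astype(str))
            outc_cod.append(np.full(int(sel.sum()), code, dtype=object))
    outc = pd.DataFrame(
        {"primaryid": np.concatenate(outc_pid) if outc_pid else np.array([], dtype=object),
         "outc_cod": np.concatenate(outc_cod) if outc_cod else np.array([], dtype=object)}
    )

    drug = pd.DataFrame(drug_rows)
    indi = pd.DataFrame(indi_rows)
    ther = pd.DataFrame({"primaryid": demo["primaryid"], "dsg_drug_seq": "1",
                         "start_dt": demo["fda_dt"]})

    # split into quarter bundles by each version's receipt date
    pooled = QuarterBundle(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi, ther=ther)
    pooled.validate()
    version_quarter = np.concatenate(
        [np.asarray(config.quarters, dtype=object)[quarter_idx],
         np.asarray(config.quarters, dtype=object)[quarter_idx[has_dup]]]
    )
    pid_to_quarter = dict(zip(demo["primaryid"], version_quarter))
    bundles: dict[str, QuarterBundle] = {}
    for q in config.quarters:
        pids_q = {p for p, qq in pid_to_quarter.items() if qq == q}
        frames = {}
        for t in TABLES:
            df = pooled.table(t)
            frames[t] = df[df["primaryid"].isin(pids_q)].reset_index(drop=True)
        bundles[q] = QuarterBundle(**frames, quarter=q)

    # realized planted-cell counts among survivors, at the report unit
    realized = []
    for pa in config.planted_associations:
        exposed = cohort == pa.cohort
        hit = event_matrix[pa.pt]
        a = int((exposed & hit).sum())
        b = int((exposed & ~hit).sum())
        c = int((~exposed & hit).sum())
        d = int((~exposed & ~hit).sum())
        realized.append(
            {"cohort": pa.cohort, "pt": pa.pt, "target_odds_ratio": pa.odds_ratio,
             "a": a, "b": b, "c": c, "d": d,
             "sample_odds_ratio": (a * d) / (b * c) if b * c else float("nan")}
        )
    truth = {
        "n_cases": n,
        "n_versions": int(n + has_dup.sum()),
        "cohort_sizes": {c: int((cohort == c).sum()) for c in labels},
        "planted": realized,
        "seed": config.seed,
    }
    return SyntheticDataset(bundles=bundles, truth=truth)
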