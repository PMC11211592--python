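"""Exposure cohorts and event sets for the ICI hepatitis analysis.

Maps verbatim drug-name strings to the eight immune-checkpoint-inhibitor
agents (anti-PD-1: nivolumab, pembrolizumab, cemiplimab; anti-PD-L1:
atezolizumab, avelumab, durvalumab; anti-CTLA-4: ipilimumab, tremelimumab),
classifies each deduplicated report into a treatment-strategy regimen,
selects hepatitis preferred terms, and maps indications to organ categories
and reporter countries to continents.

ICI exposure is assessed over primary-suspect (PS) drug entries only;
chemotherapy co-exposure may sit in any role, since chemo partners are
typically coded as secondary-suspect or concomitant.  All string matching is
exact after normalisation (uppercase, trim, collapse whitespace) — the
dictionary, which is user-extensible, is the recall lever; there is no fuzzy
matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .faers_io import QuarterBundle
from ._countries import COUNTRY_TO_REGION


class DrugClass(str, Enum):
    ANTI_PD1 = "ANTI_PD1"
    ANTI_PDL1 = "ANTI_PDL1"
    ANTI_CTLA4 = "ANTI_CTLA4"
    CHEMO = "CHEMO"
    OTHER = "OTHER"


ICI_CLASSES = frozenset({DrugClass.ANTI_PD1, DrugClass.ANTI_PDL1, DrugClass.ANTI_CTLA4})
PD_AXIS = frozenset({DrugClass.ANTI_PD1, DrugClass.ANTI_PDL1})


class Regimen(str, Enum):
    ANTI_PD1_MONO = "ANTI_PD1_MONO"
    ANTI_PDL1_MONO = "ANTI_PDL1_MONO"
    ANTI_CTLA4_MONO = "ANTI_CTLA4_MONO"
    DUAL_ICI = "DUAL_ICI"
    ICI_PLUS_CHEMO = "ICI_PLUS_CHEMO"
    NON_ICI = "NON_ICI"


_MONO_BY_CLASS = {
    DrugClass.ANTI_PD1: Regimen.ANTI_PD1_MONO,
    DrugClass.ANTI_PDL1: Regimen.ANTI_PDL1_MONO,
    DrugClass.ANTI_CTLA4: Regimen.ANTI_CTLA4_MONO,
}

ICI_REGIMENS = frozenset(
    {
        Regimen.ANTI_PD1_MONO,
        Regimen.ANTI_PDL1_MONO,
        Regimen.ANTI_CTLA4_MONO,
        Regimen.DUAL_ICI,
        Regimen.ICI_PLUS_CHEMO,
    }
)

_WS = re.compile(r"\s+")


def normalize_term(s: object) -> str:
    """Uppercase, trim, collapse internal whitespace."""
    return _WS.sub(" ", str(s).strip()).upper()


# generic + brand synonyms for the eight ICI agents
_ICI_AGENTS: dict[str, tuple[DrugClass, tuple[str, ...]]] = {
    "nivolumab": (DrugClass.ANTI_PD1, ("NIVOLUMAB", "OPDIVO")),
    "pembrolizumab": (DrugClass.ANTI_PD1, ("PEMBROLIZUMAB", "KEYTRUDA", "LAMBROLIZUMAB")),
    "cemiplimab": (DrugClass.ANTI_PD1, ("CEMIPLIMAB", "CEMIPLIMAB-RWLC", "LIBTAYO")),
    "atezolizumab": (DrugClass.ANTI_PDL1, ("ATEZOLIZUMAB", "TECENTRIQ")),
    "avelumab": (DrugClass.ANTI_PDL1, ("AVELUMAB", "BAVENCIO")),
    "durvalumab": (DrugClass.ANTI_PDL1, ("DURVALUMAB", "IMFINZI")),
    "ipilimumab": (DrugClass.ANTI_CTLA4, ("IPILIMUMAB", "YERVOY")),
    "tremelimumab": (DrugClass.ANTI_CTLA4, ("TREMELIMUMAB", "TREMELIMUMAB-ACTL", "IMJUDO")),
}

# small curated chemotherapy list (platinums, taxanes, antimetabolites,
# anthracyclines and a few common partners); user-extensible via config
_CHEMO_AGENTS: dict[str, tuple[str, ...]] = {
    "carboplatin": ("CARBOPLATIN", "PARAPLATIN"),
    "cisplatin": ("CISPLATIN", "PLATINOL"),
    "oxaliplatin": ("OXALIPLATIN", "ELOXATIN"),
    "paclitaxel": ("PACLITAXEL", "TAXOL", "ABRAXANE", "NAB-PACLITAXEL"),
    "docetaxel": ("DOCETAXEL", "TAXOTERE"),
    "pemetrexed": ("PEMETREXED", "ALIMTA"),
    "gemcitabine": ("GEMCITABINE", "GEMZAR"),
    "fluorouracil": ("FLUOROURACIL", "5-FLUOROURACIL", "5-FU"),
    "capecitabine": ("CAPECITABINE", "XELODA"),
    "doxorubicin": ("DOXORUBICIN", "ADRIAMYCIN"),
    "epirubicin": ("EPIRUBICIN", "ELLENCE"),
    "etoposide": ("ETOPOSIDE", "VEPESID"),
    "irinotecan": ("IRINOTECAN", "CAMPTOSAR"),
    "cyclophosphamide": ("CYCLOPHOSPHAMIDE", "CYTOXAN"),
    "vinorelbine": ("VINORELBINE", "NAVELBINE"),
}


@dataclass
class DrugDictionary:
    """Uppercase synonym -> (agent, class) lookup with extension hooks."""

    entries: dict[str, tuple[str, DrugClass]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "DrugDictionary":
        d = cls()
        for agent, (klass, synonyms) in _ICI_AGENTS.items():
            for syn in synonyms:
                d.add(syn, agent, klass)
        for agent, synonyms in _CHEMO_AGENTS.items():
            for syn in synonyms:
                d.add(syn, agent, DrugClass.CHEMO)
        return d

    def add(self, synonym: str, agent: str, klass: DrugClass | str) -> None:
        self.entries[normalize_term(synonym)] = (agent, DrugClass(klass))

    def extend(self, mapping: Mapping[str, tuple[str, str]]) -> None:
        """Add ``{synonym: (agent, class)}`` entries, e.g. from a run config."""
        for syn, (agent, klass) in mapping.items():
            self.add(syn, agent, klass)

    def lookup(self, name: object) -> tuple[str, DrugClass] | None:
        return self.entries.get(normalize_term(name))

    def ici_agents(self) -> set[str]:
        return {a for a, k in self.entries.values() if k in ICI_CLASSES}


_COMPONENT_SPLIT = re.compile(r"[;+\\/,]|\bAND\b|\bWITH\b|\bPLUS\b")


def normalize_drug(
    drugname: object, prod_ai: object, dictionary: DrugDictionary
) -> list[tuple[str, DrugClass]]:
    """Resolve a verbatim drug string to dictionary agents.

    The active-ingredient field is tried first, then the drug name; each is
    matched whole and then component-wise on ";", "+", "/", "," and textual
    connectives, so combination strings like ``"NIVOLUMAB AND IPILIMUMAB"``
    yield both agents.  Returns an empty list when nothing matches.
    """
    for candidate in (prod_ai, drugname):
        if candidate is None:
            continue
        text = normalize_term(candidate)
        if not text:
            continue
        whole = dictionary.entries.get(text)
        if whole is not None:
            return [whole]
        hits: list[tuple[str, DrugClass]] = []
        seen: set[str] = set()
        for part in _COMPONENT_SPLIT.split(text):
            hit = dictionary.entries.get(part.strip())
            if hit is not None and hit[0] not in seen:
                hits.append(hit)
                seen.add(hit[0])
        if hits:
            return hits
    return []


def classify_regimen_from_entries(
    entries: Iterable[tuple[str, str | None, str]], dictionary: DrugDictionary
) -> Regimen:
    """Classify one report from its ``(drugname, prod_ai, role_cod)`` entries.

    ICI membership uses PS-role entries only; chemotherapy counts in any
    role.  Dual ICI = at least one anti-PD-(L)1 and one anti-CTLA-4 agent
    among PS drugs; an ICI plus chemo (and not dual) = combination therapy;
    a single distinct ICI agent without chemo = class monotherapy.  Reports
    listing several agents within the PD-1/PD-L1 axis (no CTLA-4, no chemo)
    are labelled by the class of the first PS entry.
    """
    ps_agents: list[tuple[str, DrugClass]] = []
    has_chemo = False
    seen_ps: set[str] = set()
    for drugname, prod_ai, role in entries:
        matches = normalize_drug(drugname, prod_ai, dictionary)
        for agent, klass in matches:
            if klass is DrugClass.CHEMO:
                has_chemo = True
            elif klass in ICI_CLASSES and str(role).strip().upper() == "PS":
                if agent not in seen_ps:
                    ps_agents.append((agent, klass))
                    seen_ps.add(agent)
    if not ps_agents:
        return Regimen.NON_ICI
    classes = {k for _, k in ps_agents}
    if classes & PD_AXIS and DrugClass.ANTI_CTLA4 in classes:
        return Regimen.DUAL_ICI
    if has_chemo:
        return Regimen.ICI_PLUS_CHEMO
    return _MONO_BY_CLASS[ps_agents[0][1]]


def label_regimens(store: QuarterBundle, dictionary: DrugDictionary | None = None) -> pd.Series:
    """Regimen label per surviving report, indexed by primaryid.

    Vectorised over the store's DRUG table; reports with no drug rows are
    NON_ICI.  Labels partition the store: every report gets exactly one.
    """
    dictionary = dictionary or DrugDictionary.default()
    pids = store.demo["primaryid"]
    drug = store.drug
    if drug.empty:
        return pd.Series(Regimen.NON_ICI.value, index=pids.values, name="regimen")

    pairs = drug[["drugname", "prod_ai"]].fillna("").astype(str)
    role = drug["role_cod"].fillna("").astype(str).str.strip().str.upper()

    by_pid: dict[str, list[tuple[str, str, str]]] = {}
    for pid, dn, ai, r in zip(drug["primaryid"], pairs["drugname"], pairs["prod_ai"], role):
        by_pid.setdefault(pid, []).append((dn, ai, r))

    # identical drug-entry signatures share one classification
    label_cache: dict[tuple, str] = {}
    out = {}
    for pid in pids:
        rows = by_pid.get(pid)
        if not rows:
            out[pid] = Regimen.NON_ICI.value
            continue
        sig = tuple(rows)
        lab = label_cache.get(sig)
        if lab is None:
            lab = classify_regimen_from_entries(rows, dictionary).value
            label_cache[sig] = lab
        out[pid] = lab
    return pd.Series(out, name="regimen").reindex(pids.values)


# ---------------------------------------------------------------------------
# Event term sets

#: the 35 hepatitis preferred terms scanned against the full database
HEPATITIS_SCAN_TERMS: tuple[str, ...] = (
    "Autoimmune hepatitis",
    "Immune-mediated hepatitis",
    "Hepatitis acute",
    "Hepatitis fulminant",
    "Hepatitis cholestatic",
    "Hepatitis toxic",
    "Hepatitis C",
    "Hepatitis B reactivation",
    "Hepatitis B",
    "Hepatitis E",
    "Ischaemic hepatitis",
    "Hepatitis viral",
    "Acute hepatitis B",
    "Cytomegalovirus hepatitis",
    "Chronic hepatitis",
    "Steatohepatitis",
    "Non-alcoholic steatohepatitis",
    "Hepatitis A",
    "Hepatitis B DNA increased",
    "Chronic hepatitis B",
    "Hepatitis C virus test positive",
    "Hepatitis A antibody positive",
    "Hepatitis B core antibody positive",
    "Hepatitis D",
    "Chronic hepatitis C",
    "Hepatitis alcoholic",
    "Hepatitis B surface antibody positive",
    "Hepatitis E virus test positive",
    "Hepatitis G",
    "Hepatitis B virus test positive",
    "Hepatitis B antigen positive",
    "Hepatitis B E antibody positive",
    "Hepatitis chronic persistent",
    "Radiation hepatitis",
    "Hepatitis virus-associated nephropathy",
)

#: the three PTs designated as ICI-related hepatitis adverse events
HRAE_TERMS: tuple[str, ...] = (
    "Autoimmune hepatitis",
    "Immune-mediated hepatitis",
    "Hepatitis fulminant",
)


@dataclass(frozen=True)
class EventTermSet:
    """Named set of MedDRA preferred terms, matched case-insensitively."""

    name: str
    terms: frozenset[str]

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"event term set {self.name!r} is empty")
        object.__setattr__(self, "terms", frozenset(normalize_term(t) for t in self.terms))

    @classmethod
    def from_terms(cls, name: str, terms: Iterable[str]) -> "EventTermSet":
        return cls(name=name, terms=frozenset(terms))

    def __contains__(self, pt: object) -> bool:
        return normalize_term(pt) in self.terms

    def match(self, pts: Iterable[object]) -> set[str]:
        return {normalize_term(p) for p in pts} & self.terms


HEPATITIS_SCAN = EventTermSet.from_terms("HEPATITIS_SCAN", HEPATITIS_SCAN_TERMS)
HRAE = EventTermSet.from_terms("HRAE", HRAE_TERMS)
#: reference superset for forest-plot contrasts; defaults to the scan set and
#: is meant to be replaced by a broader hepatobiliary list via config
HEPATOBILIARY = EventTermSet.from_terms("HEPATOBILIARY", HEPATITIS_SCAN_TERMS)

BUILTIN_EVENT_SETS = {s.name: s for s in (HEPATITIS_SCAN, HRAE, HEPATOBILIARY)}


def select_events(reaction_pts: Iterable[object], terms: EventTermSet) -> set[str]:
    """Case-insensitive intersection of a report's reaction PTs with *terms*."""
    return terms.match(reaction_pts)


# ---------------------------------------------------------------------------
# Indication organs and reporting regions

# keyword -> organ, checked in order; first hit wins
_ORGAN_RULES: tuple[tuple[str, str], ...] = (
    ("MELANOMA", "Skin"), ("SKIN", "Skin"), ("MERKEL", "Skin"),
    ("BASAL CELL", "Skin"), ("CUTANEOUS SQUAMOUS", "Skin"),
    ("LUNG", "Lung"), ("BRONCH", "Lung"), ("MESOTHELIOMA", "Pleura"),
    ("PLEURA", "Pleura"),
    ("RENAL", "Kidney"), ("KIDNEY", "Kidney"),
    ("HEPATOCELLULAR", "Liver"), ("HEPATIC", "Liver"), ("LIVER", "Liver"),
    ("HEAD AND NECK", "Head and neck"), ("LARYN", "Head and neck"),
    ("PHARYN", "Head and neck"), ("TONGUE", "Head and neck"),
    ("ORAL", "Head and neck"), ("NASOPHARYNGEAL", "Head and neck"),
    ("BLADDER", "Bladder"), ("UROTHELIAL", "Bladder"), ("TRANSITIONAL CELL", "Bladder"),
    ("GASTRIC", "Stomach"), ("STOMACH", "Stomach"), ("GASTROOESOPHAGEAL", "Stomach"),
    ("BREAST", "Breast"),
    ("PROSTAT", "Prostate"),
    ("UTER", "Uterus"), ("ENDOMETRI", "Uterus"), ("CERVI", "Uterus"),
    ("OESOPHAG", "Esophagus"), ("ESOPHAG", "Esophagus"),
    ("LYMPHOMA", "Lymphoid"), ("HODGKIN", "Lymphoid"), ("LYMPHOID", "Lymphoid"),
    ("OVAR", "Ovary"),
    ("PANCREA", "Pancreas"),
    ("BRAIN", "Brain"), ("GLIO", "Brain"),
    ("COLORECT", "Colon"), ("COLON", "Colon"), ("RECTAL", "Colon"), ("RECTUM", "Colon"),
    ("LEUKAEMIA", "Hematologic"), ("LEUKEMIA", "Hematologic"),
    ("MYELOMA", "Hematologic"), ("MYELODYSPLASTIC", "Hematologic"),
    ("GALLBLADDER", "Cholecyst"), ("CHOLANGIO", "Cholecyst"), ("BILIARY", "Cholecyst"),
    ("THYMOMA", "Thymoma"), ("THYMIC", "Thymoma"),
)

_UNSPECIFIED_INDICATIONS = {
    "",
    "PRODUCT USED FOR UNKNOWN INDICATION",
    "UNKNOWN INDICATION",
}

ORGAN_LABELS = tuple(dict.fromkeys([o for _, o in _ORGAN_RULES])) + ("Unspecified", "Others")


def map_indication_to_organ(indication_pt: object) -> str:
    """Map an indication preferred term to a coarse organ category."""
    if indication_pt is None:
        return "Unspecified"
    text = normalize_term(indication_pt)
    if text in _UNSPECIFIED_INDICATIONS or text == "NAN":
        return "Unspecified"
    for keyword, organ in _ORGAN_RULES:
        if keyword in text:
            return organ
    return "Others"


REGIONS = ("Americas", "Europe", "Asia", "Oceania", "Africa", "Missing")


def map_country_to_region(country: object) -> str:
    """Map an ISO-like country code or name to its reporting region."""
    if country is None:
        return "Missing"
    text = normalize_term(country)
    if not text or text == "NAN":
        return "Missing"
    return COUNTRY_TO_REGION.get(text, "Missing")
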