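"""Reading and writing FAERS-style quarterly ASCII bundles.

The FDA distributes its spontaneous-report database as quarterly bundles of
``$``-delimited text tables: DEMO (demographics and administration), DRUG,
REAC (MedDRA-coded reactions), OUTC (report-level outcomes), INDI
(indications) and THER (therapy dates).  This module parses those tables into
a :class:`QuarterBundle` of pandas DataFrames, quarantining malformed rows
with reasons instead of dropping them, and can write a bundle back out in the
same dialect so synthetic data and real data flow through one code path.

Only the modern (post-2012Q3) quarterly-data-extract dialect is implemented;
the ``dialect`` tag on :func:`read_quarter` records the extension point for
the legacy layout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical table tags, in the order files are written
TABLES = ("demo", "drug", "reac", "outc", "indi", "ther")

#: columns the model guarantees per table (extra source columns pass through)
TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": (
        "primaryid",
        "caseid",
        "fda_dt",
        "age",
        "age_cod",
        "sex",
        "reporter_country",
        "occp_cod",
    ),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: age-unit code -> factor converting the stored value into years
AGE_UNIT_TO_YEARS: Mapping[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_FDA_DT_RE = re.compile(r"^\d{8}$")


class FormatError(ValueError):
    """A quarter file violates the dialect (missing key column, bad header)."""


def _empty_table(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="object") for c in TABLE_COLUMNS[table]})


def _empty_rejects() -> pd.DataFrame:
    return pd.DataFrame(
        {c: pd.Series(dtype="object") for c in ("table", "source_row", "reason")}
    )


@dataclass
class QuarterBundle:
    """One parsed quarter: a DEMO frame plus entry tables keyed by primaryid.

    ``rejected`` holds quarantined source rows (table tag, verbatim row dict,
    reason) so funnel counts stay auditable: parsed + rejected = source rows.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    quarter: str = ""
    rejected: pd.DataFrame = field(default_factory=_empty_rejects)

    @classmethod
    def empty(cls, quarter: str = "") -> "QuarterBundle":
        return cls(*(_empty_table(t) for t in TABLES), quarter=quarter)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def n_versions(self) -> int:
        return len(self.demo)

    def validate(self) -> None:
        """Check the bundle invariants; raise ``ValueError`` on violation."""
        pid = self.demo["primaryid"]
        if pid.duplicated().any():
            dupes = pid[pid.duplicated()].unique()[:5]
            raise ValueError(f"duplicate primaryid in DEMO: {list(dupes)}")
        known = set(pid)
        for t in TABLES[1:]:
            tab = self.table(t)
            if len(tab) and not set(tab["primaryid"]).issubset(known):
                orphan = sorted(set(tab["primaryid"]) - known)[:5]
                raise ValueError(f"{t.upper()} rows reference unknown primaryid: {orphan}")

    def equals(self, other: "QuarterBundle") -> bool:
        """Field-for-field equality on the modeled columns of every table."""
        for t in TABLES:
            a, b = self.table(t), other.table(t)
            cols = list(TABLE_COLUMNS[t])
            if len(a) != len(b):
                return False
            ar = a[cols].reset_index(drop=True).fillna("")
            br = b[cols].reset_index(drop=True).fillna("")
            if not ar.astype(str).equals(br.astype(str)):
                return False
        return True


def _normalize_id(value: str) -> object:
    """Compare primaryid/caseid numerically when fully numeric, else as text."""
    s = str(value).strip()
    return int(s) if s.isdigit() else s


def id_sort_key(value: object) -> tuple[int, float, str]:
    """Total order on identifiers: numeric ids first by value, then text ids."""
    s = str(value).strip()
    if s.isdigit():
        return (0, float(int(s)), "")
    return (1, 0.0, s)


def parse_age(age_value: object, age_code: object) -> float:
    """Convert a FAERS (AGE, AGE_COD) pair to years.

    Returns NaN for absent/non-numeric values or unknown unit codes (the
    latter with a logged warning); never raises.
    """
    if age_value is None or (isinstance(age_value, float) and np.isnan(age_value)):
        return float("nan")
    s = str(age_value).strip()
    if not s:
        return float("nan")
    try:
        v = float(s)
    except ValueError:
        return float("nan")
    code = str(age_code).strip().upper() if age_code is not None else ""
    if code in ("", "NAN"):
        code = "YR"  # FAERS convention: missing unit means years
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        logger.warning("unknown age unit code %r; treating age as missing", code)
        return float("nan")
    years = v * factor
    if not np.isfinite(years) or years < 0:
        return float("nan")
    return years


def parse_age_series(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Vectorised :func:`parse_age` over aligned Series."""
    return pd.Series(
        [parse_age(a, c) for a, c in zip(age, age_cod)], index=age.index, dtype=float
    )


def _valid_fda_dt(s: str) -> bool:
    if not _FDA_DT_RE.match(s):
        return False
    month = int(s[4:6])
    return 1 <= month <= 12


def _read_table_file(path: Path, table: str) -> tuple[pd.DataFrame, list[dict]]:
    with open(path, encoding="latin-1", errors="replace") as fh:
        header = [c.strip().lower() for c in fh.readline().rstrip("\n").split("$")]
    if len(set(header)) != len(header):
        raise FormatError(f"{path.name}: duplicated column in header: {header}")
    df = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        encoding="latin-1",
        encoding_errors="replace",
        keep_default_na=False,
    )
    df.columns = header[: len(df.columns)]
    required = ("primaryid", "caseid") if table == "demo" else ("primaryid",)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: mandatory column {col!r} missing")
    for col in TABLE_COLUMNS[table]:
        if col not in df.columns:
            df[col] = ""

    rejects: list[dict] = []
    keep = pd.Series(True, index=df.index)
    blank_pid = df["primaryid"].str.strip() == ""
    for i in df.index[blank_pid]:
        rejects.append({"table": table, "source_row": df.loc[i].to_dict(), "reason": "empty primaryid"})
    keep &= ~blank_pid
    if table == "demo":
        blank_case = df["caseid"].str.strip() == ""
        for i in df.index[blank_case & keep]:
            rejects.append({"table": table, "source_row": df.loc[i].to_dict(), "reason": "empty caseid"})
        keep &= ~blank_case
        dt = df["fda_dt"].str.strip()
        bad_dt = (dt != "") & ~dt.map(_valid_fda_dt)
        for i in df.index[bad_dt & keep]:
            rejects.append(
                {
                    "table": table,
                    "source_row": df.loc[i].to_dict(),
                    "reason": f"malformed fda_dt {dt[i]!r}",
                }
            )
        keep &= ~bad_dt
    return df[keep].reset_index(drop=True), rejects


def _find_table_files(paths: Iterable[Path]) -> dict[str, Path]:
    """Map table tag -> file among *paths* by filename prefix (DEMO23Q1.txt...)."""
    found: dict[str, Path] = {}
    for p in paths:
        stem = p.name.lower()
        for t in TABLES:
            if stem.startswith(t):
                if t in found:
                    raise FormatError(f"two files match table {t.upper()}: {found[t].name}, {p.name}")
                found[t] = p
    return found


def read_quarter(source: Path | str | Iterable[Path | str], dialect: str = "qde-modern",
                 quarter: str = "") -> QuarterBundle:
    """Read one quarter's $-delimited tables into a :class:`QuarterBundle`.

    *source* is either a directory containing the table files or an explicit
    collection of file paths; files are matched to tables by name prefix
    (``DEMO…``, ``DRUG…``, …).  Missing entry tables are allowed and yield
    empty frames; a missing DEMO file is a format error.
    """
    if dialect != "qde-modern":
        raise NotImplementedError(
            f"dialect {dialect!r} not implemented; only 'qde-modern' is supported"
        )
    if isinstance(source, (str, Path)):
        src = Path(source)
        paths = sorted(src.iterdir()) if src.is_dir() else [src]
    else:
        paths = [Path(p) for p in source]
    files = _find_table_files(paths)
    if "demo" not in files:
        raise FormatError(f"no DEMO file found among {[p.name for p in paths]}")

    frames: dict[str, pd.DataFrame] = {}
    all_rejects: list[dict] = []
    for t in TABLES:
        if t in files:
            frames[t], rej = _read_table_file(files[t], t)
            all_rejects.extend(rej)
        else:
            frames[t] = _empty_table(t)
    # entry rows must belong to a parsed DEMO version; orphans are quarantined
    known = set(frames["demo"]["primaryid"])
    for t in TABLES[1:]:
        df = frames[t]
        orphan = ~df["primaryid"].isin(known)
        for i in df.index[orphan]:
            all_rejects.append(
                {"table": t, "source_row": df.loc[i].to_dict(), "reason": "primaryid not in DEMO"}
            )
        frames[t] = df[~orphan].reset_index(drop=True)

    rejected = pd.DataFrame(all_rejects) if all_rejects else _empty_rejects()
    bundle = QuarterBundle(**frames, quarter=quarter, rejected=rejected)
    bundle.validate()
    return bundle


def write_quarter(bundle: QuarterBundle, directory: Path | str, suffix: str = "") -> list[Path]:
    """Write *bundle* as six $-delimited files under *directory*.

    Output is bit-stable for a fixed bundle: tables are written with columns
    in canonical order and rows in their stored order.  Returns the paths.
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    tag = suffix or bundle.quarter.replace("Q", "q") or "data"
    paths = []
    for t in TABLES:
        df = bundle.table(t)
        cols = [c for c in TABLE_COLUMNS[t]] + [
            c for c in df.columns if c not in TABLE_COLUMNS[t]
        ]
        path = out / f"{t.upper()}{tag}.txt"
        df.reindex(columns=cols, fill_value="").fillna("").astype(str).to_csv(
            path, sep="$", index=False, lineterminator="\n", encoding="latin-1"
        )
        paths.append(path)
    return paths


def concat_bundles(bundles: Iterable[QuarterBundle]) -> QuarterBundle:
    """Pool several quarters into one bundle (the cross-quarter store)."""
    bundles = list(bundles)
    if not bundles:
        return QuarterBundle.empty()
    frames = {
        t: pd.concat([b.table(t) for b in bundles], ignore_index=True) for t in TABLES
    }
    rejected = pd.concat([b.rejected for b in bundles], ignore_index=True)
    quarters = ",".join(sorted({b.quarter for b in bundles if b.quarter}))
    return QuarterBundle(**frames, quarter=quarters, rejected=rejected)
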