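"""Disproportionality statistics: reporting odds ratio and information component.

Spontaneous-report signal detection compares how often a drug–event pair is
reported against its expectation under independence.  Two complementary
statistics are computed here:

* the frequentist **reporting odds ratio** (ROR), the cross-product ratio
  ``a·d / (b·c)`` of the exposure×event 2×2 table, with a Wald 95% interval
  ``exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))``;

* the Bayesian **information component** (IC) of the BCPNN tradition,
  ``log2(N_observed / N_expected)`` with ``N_expected = N_drug·N_event /
  N_total``.  The default "shrunk" variant applies the +0.5 shrinkage
  ``log2((N_obs+0.5)/(N_exp+0.5))`` with the standard percentile
  approximations for the 95% credibility bounds::

      IC025 = IC − 3.3·(N_obs+0.5)^(−1/2) − 2·(N_obs+0.5)^(−3/2)
      IC975 = IC + 2.4·(N_obs+0.5)^(−1/2) − 0.5·(N_obs+0.5)^(−3/2)

A drug–event pair is flagged as a signal when the case count reaches the
minimum (default 10), ROR05 > 1 and IC025 > 0 jointly hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import EventTermSet, normalize_term

Z95 = 1.96  # conventional two-sided 95% normal quantile used in the Wald CI


class ConsistencyError(ValueError):
    """Requested counts imply a negative 2×2 cell."""


class UndefinedResultError(ValueError):
    """The statistic is undefined for the given table (e.g. all cells zero)."""


@dataclass(frozen=True)
class ContingencyTable:
    """The 2×2 exposure×event table: a, b exposed with/without the event;
    c, d comparator with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_comparator(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exposure/comparator roles exchanged (ROR inverts)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


def derive_table(
    n_observed: int,
    n_drug: int,
    n_event_comparator: int,
    n_total: int,
    convention: Literal["external-comparator", "head-to-head"] = "external-comparator",
) -> ContingencyTable:
    """Build the 2×2 table from marginal counts.

    ``external-comparator``: the exposed cohort (total ``n_drug``) is compared
    against the rest of the database; ``n_event_comparator`` is the event
    count among non-exposed records and ``n_total`` the whole-database record
    count, so ``d = n_total − n_drug − n_event_comparator``.

    ``head-to-head``: two cohorts compared directly; the third and fourth
    arguments are the comparator cohort's event count and total, so
    ``d = n_total − n_event_comparator``.
    """
    a = int(n_observed)
    b = int(n_drug) - a
    c = int(n_event_comparator)
    if convention == "external-comparator":
        d = int(n_total) - int(n_drug) - c
    elif convention == "head-to-head":
        d = int(n_total) - c
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if min(a, b, c, d) < 0:
        raise ConsistencyError(
            f"negative derived cell from n_observed={n_observed}, n_drug={n_drug}, "
            f"n_event_comparator={n_event_comparator}, n_total={n_total} "
            f"({convention}): a={a}, b={b}, c={c}, d={d}"
        )
    return ContingencyTable(a, b, c, d)


@dataclass(frozen=True)
class RorEstimate:
    estimate: float
    low: float
    high: float
    defined_bounds: bool = True


def ror(
    table: ContingencyTable,
    correction: Literal["none", "haldane"] = "none",
    z: float = Z95,
) -> RorEstimate:
    """Reporting odds ratio with its Wald 95% confidence interval.

    With ``correction="haldane"`` 0.5 is added to every cell first (opt-in,
    never silent).  Without correction, a zero ``a`` cell yields estimate 0
    with undefined bounds flagged; a zero ``b`` or ``c`` cell is an error.
    *z* widens the interval for multiplicity-adjusted scans.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == b == c == d == 0:
        raise UndefinedResultError("all four cells are zero; ROR undefined")
    if correction == "haldane":
        af, bf, cf, df = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    elif correction == "none":
        if b * c == 0:
            if a == 0:
                return RorEstimate(0.0, math.nan, math.nan, defined_bounds=False)
            raise UndefinedResultError(
                f"zero cell (b={b}, c={c}) without correction; ROR undefined"
            )
        if a == 0 or d == 0:
            est = 0.0 if a == 0 else math.inf
            return RorEstimate(est, math.nan, math.nan, defined_bounds=False)
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    est = (af * df) / (bf * cf)
    se = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    return RorEstimate(est, est * math.exp(-z * se), est * math.exp(z * se))


@dataclass(frozen=True)
class IcEstimate:
    n_expected: float
    ic: float
    ic025: float
    ic975: float
    defined: bool = True


def ic(
    n_observed: int,
    n_drug: int,
    n_event: int,
    n_total: int,
    method: Literal["shrunk", "plain"] = "shrunk",
) -> IcEstimate:
    """Information component with 95% credibility bounds.

    ``n_event`` is the event count in the **full** database (exposed
    included), matching the expectation formula ``E = n_drug·n_event/n_total``.
    The plain method has no interval approximation (NaN bounds) and is
    undefined at zero observations (flagged, not raised).
    """
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if n_drug > n_total or n_event > n_total:
        raise ValueError("margins exceed the database total")
    n_expected = n_drug * n_event / n_total
    if method == "plain":
        if n_observed == 0:
            return IcEstimate(n_expected, -math.inf, math.nan, math.nan, defined=False)
        if n_expected == 0:
            return IcEstimate(n_expected, math.inf, math.nan, math.nan, defined=False)
        return IcEstimate(n_expected, math.log2(n_observed / n_expected), math.nan, math.nan)
    if method != "shrunk":
        raise ValueError(f"unknown method {method!r}")
    ns = n_observed + 0.5
    value = math.log2(ns / (n_expected + 0.5))
    ic025 = value - 3.3 * ns ** -0.5 - 2.0 * ns ** -1.5
    ic975 = value + 2.4 * ns ** -0.5 - 0.5 * ns ** -1.5
    return IcEstimate(n_expected, value, ic025, ic975)


def relative_risk(p_exposed: float, p_comparator: float) -> float:
    """Ratio of two incidence percentages (or proportions on a common scale)."""
    if p_comparator <= 0:
        raise ValueError(f"comparator incidence must be positive, got {p_comparator}")
    return p_exposed / p_comparator


@dataclass(frozen=True)
class SignalCriteria:
    """Joint signal rule: case minimum plus ROR05 and IC025 thresholds."""

    min_cases: int = 10
    ror05_gt: float = 1.0
    ic025_gt: float = 0.0

    def __post_init__(self):
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


@dataclass
class DisproportionalityResult:
    """One drug(-set)×event(-set) row of a scan."""

    event: str
    cohort: str
    n_observed: int
    n_expected: float
    ror: float
    ror05: float
    ror95: float
    ic: float
    ic025: float
    ic975: float
    signal: bool = False
    defined: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_signal(result: DisproportionalityResult, criteria: SignalCriteria) -> bool:
    """Apply the joint criterion; case minimum is inclusive (≥ min_cases)."""
    if not result.defined:
        return False
    return (
        result.n_observed >= criteria.min_cases
        and result.ror05 > criteria.ror05_gt
        and result.ic025 > criteria.ic025_gt
    )


def _event_records(store, terms: frozenset[str] | None = None) -> pd.DataFrame:
    """Report×PT records of a store, with normalised PT strings."""
    reac = store.reac
    df = pd.DataFrame(
        {
            "primaryid": reac["primaryid"],
            "pt": reac["pt"].map(normalize_term),
        }
    )
    if terms is not None:
        df = df[df["pt"].isin(terms)]
    return df.drop_duplicates()


def scan(
    store,
    cohorts: Mapping[str, Iterable[str]] | pd.Series,
    event_sets: Sequence[EventTermSet] | EventTermSet,
    criteria: SignalCriteria = SignalCriteria(),
    unit: Literal["events", "reports"] = "events",
    ic_method: Literal["shrunk", "plain"] = "shrunk",
    bonferroni: bool = False,
) -> list[DisproportionalityResult]:
    """Disproportionality of every event term × cohort pair vs the rest of the store.

    *cohorts* maps cohort name -> iterable of member primaryids (or is a
    Series of cohort labels indexed by primaryid).  With ``unit="events"``
    all denominators are report×PT records (each report contributes one
    record per distinct reaction PT); with ``unit="reports"`` they are
    distinct reports.  Empty cohorts yield rows with ``n_observed = 0`` and
    undefined-flagged statistics rather than raising.  Rows are sorted by
    descending observed count (ties by event, cohort).

    ``bonferroni=True`` (off by default) widens every Wald interval to the
    familywise 95% level across the term×cohort grid, so ROR05 and the
    signal flag become multiplicity-adjusted; the IC credibility band is
    left untouched.
    """
    if isinstance(cohorts, pd.Series):
        cohorts = {
            str(name): list(idx)
            for name, idx in cohorts.groupby(cohorts).groups.items()
        }
    if isinstance(event_sets, EventTermSet):
        terms = sorted(event_sets.terms)
    else:
        terms = sorted({t for s in event_sets for t in s.terms})

    records = _event_records(store)
    if unit == "events":
        n_total = len(records)
    elif unit == "reports":
        n_total = store.demo["primaryid"].nunique()
    else:
        raise ValueError(f"unknown unit {unit!r}")

    z = Z95
    if bonferroni:
        from statistics import NormalDist

        m = max(1, len(terms) * len(cohorts))
        z = NormalDist().inv_cdf(1 - 0.025 / m)

    event_pids = {t: set(records.loc[records["pt"] == t, "primaryid"]) for t in terms}
    results: list[DisproportionalityResult] = []
    for cname in sorted(cohorts):
        members = set(cohorts[cname])
        in_cohort = records["primaryid"].isin(members)
        if unit == "events":
            n_drug = int(in_cohort.sum())
        else:
            n_drug = len(members)
        cohort_records = records[in_cohort]
        for term in terms:
            if unit == "events":
                n_obs = int((cohort_records["pt"] == term).sum())
                n_event_all = int((records["pt"] == term).sum())
            else:
                n_obs = len(event_pids[term] & members)
                n_event_all = len(event_pids[term])
            n_event_comp = n_event_all - n_obs
            row = DisproportionalityResult(
                event=term, cohort=cname, n_observed=n_obs,
                n_expected=math.nan, ror=math.nan, ror05=math.nan, ror95=math.nan,
                ic=math.nan, ic025=math.nan, ic975=math.nan,
            )
            if n_drug == 0 or n_total == 0:
                row.defined = False
            else:
                table = derive_table(n_obs, n_drug, n_event_comp, n_total)
                try:
                    r = ror(table, z=z)
                except UndefinedResultError:
                    r = RorEstimate(math.nan, math.nan, math.nan, defined_bounds=False)
                i = ic(n_obs, n_drug, n_event_all, n_total, method=ic_method)
                row = replace_fields(row, r, i)
                row.defined = r.defined_bounds and i.defined
            row.signal = evaluate_signal(row, criteria)
            results.append(row)
    results.sort(key=lambda r: (-r.n_observed, r.event, r.cohort))
    return results


def replace_fields(
    row: DisproportionalityResult, r: RorEstimate, i: IcEstimate
) -> DisproportionalityResult:
    row.ror, row.ror05, row.ror95 = r.estimate, r.low, r.high
    row.n_expected, row.ic, row.ic025, row.ic975 = i.n_expected, i.ic, i.ic025, i.ic975
    return row


def results_frame(results: Sequence[DisproportionalityResult]) -> pd.DataFrame:
    """Tabulate scan rows for CSV export."""
    return pd.DataFrame([r.as_dict() for r in results])


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding matching printed report tables (half away from zero)."""
    if not np.isfinite(x):
        return x
    q = 10**ndigits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)
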