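# Methods

## Study unit and data model

The pipeline models a spontaneous-report database as versioned case
reports.  A *report version* is one DEMO row (primaryid, caseid, FDA
receipt date, demographics); entry tables (drugs, reactions, outcomes,
indications, therapies) are keyed by primaryid and are treated as full
replacements per version, not deltas.  Identifiers are compared numerically
when fully numeric and lexicographically otherwise, so "the higher
PRIMARYID" is always well defined; among mixed identifiers, textual ones
sort above numeric ones (a fixed, documented tie-break — FAERS identifiers
are numeric in practice).

Only the modern quarterly-data-extract ASCII dialect (`$`-delimited, header
row) is implemented; the reader's `dialect` tag records the extension point
for the pre-2012Q3 legacy layout.  Files are read as Latin-1 with
replacement of undecodable bytes so ingestion never fails on free-text
fields.  Rows with an unparseable mandatory key (missing primaryid/caseid,
malformed 8-digit receipt date, or an entry row whose primaryid has no DEMO
row) are quarantined with a reason string; parsed + quarantined always
equals the source row count, which keeps the case funnel auditable.

## Deduplication

One report survives per caseid: the argmax over (FDA receipt date,
primaryid).  A missing receipt date sorts lowest (a dated version always
beats an undated one).  Dedup operates over the pooled cross-quarter store,
and entry tables of losing versions are discarded wholesale.  The rule is
validated against a brute-force argmax oracle on randomized version sets
and is idempotent and permutation-invariant by construction (stable
mergesort on a total key).

## Exposure cohorts

ICI exposure is assessed over **primary-suspect (PS) drug entries only**;
chemotherapy co-exposure counts in any role, because chemo partners are
typically coded secondary-suspect or concomitant and the "ICI plus
chemotherapy" category would otherwise be unreachable.  Matching is exact
after normalisation (uppercase, trim, collapse whitespace), first on the
active-ingredient string, then the verbatim drug name, whole-string first
and then component-wise on `; + / ,` and the connectives AND/WITH/PLUS —
no fuzzy matching; the synonym dictionary (generic + brand names for the
eight agents, a curated chemotherapy list, user-extensible via config) is
the recall lever.

Regimen classification: dual ICI requires ≥1 anti-PD-(L)1 and ≥1
anti-CTLA-4 agent among PS drugs; an ICI with any chemo-class drug (and not
dual) is the chemo combination; a single distinct ICI agent with no chemo
is class monotherapy.  Several agents of one class stay monotherapy of that
class; the rare report listing both an anti-PD-1 and an anti-PD-L1 agent
(no CTLA-4, no chemo) is labelled by the class of its first PS entry — the
category scheme leaves this cell undefined and a deterministic tie-break
was preferred over a new category.

Event terms are opaque MedDRA preferred-term strings matched
case-insensitively.  Built-in sets: the 35-term hepatitis scan list, the
three designated hepatitis terms (autoimmune hepatitis, immune-mediated
hepatitis, hepatitis fulminant), and a configurable hepatobiliary reference
superset (defaulting to the scan list).  Indication organs come from an
ordered keyword table (melanoma→Skin, …; unmatched→Others, absent or
"unknown indication"→Unspecified); reporter countries map to five
continents through a static ISO-3166 table bundled with the package, with
anything unrecognised reported as Missing.

## Disproportionality

Two comparator conventions are implemented and named explicitly.
*External comparator*: the exposed cohort against the rest of the database,
`d = N_total − N_drug − c` with `c` the event count among non-exposed
records — this convention, with the comparator event count **excluding**
exposed records, is what reproduces the published RORs from their printed
counts.  *Head-to-head*: two cohorts compared directly.  For the IC,
`N_event` is the **inclusive** full-database event count, matching the
expectation formula `E = N_drug·N_event/N_total`.

Counting unit is a config switch: `events` (report×PT records, the
denominators disproportionality uses) or `reports` (distinct case reports,
used for descriptive counts).  Zero cells: the Haldane +0.5 correction is
opt-in, never silent; an undefined statistic is flagged, not guessed.  The
case minimum of the signal rule is inclusive (≥ 10) and configurable.  No
multiple-testing adjustment is applied by default (the joint ROR05/IC025
rule is the published criterion); a Bonferroni option exists on the scan
for users who want it.

The shrunk IC uses the +0.5 shrinkage with the standard percentile
approximations

    IC025 = IC − 3.3·(N_obs+0.5)^(−1/2) − 2·(N_obs+0.5)^(−3/2)
    IC975 = IC + 2.4·(N_obs+0.5)^(−1/2) − 0.5·(N_obs+0.5)^(−3/2)

Under independence simulations this band and the Wald ROR interval both
show ≈5% exclusion (checked at 1,000 tables in the test suite).  The IC025
values printed alongside the published scan table are **not** reproducible
from the printed counts under the plain IC, this shrinkage IC, or the
classical BCPNN variance approximation (all give materially higher values,
e.g. ≈3.9 where 2.43 is printed); the exact computation behind those
printed bounds is unknown, so IC behaviour is validated by properties
(sign, forced equality, coverage), never against those printed numbers.
Similarly, some published head-to-head intervals are not log-symmetric
about their estimates and are inconsistent with the Wald formula that
reproduces the point estimates; only point estimates are asserted for
those contrasts.

Report-table rounding is 2 decimals, half away from zero; descriptive
percentages are 1 decimal on the full case count (missing included).  Age
quartiles use linear interpolation between order statistics, which is the
convention that yields non-integer quartiles like 53.75 on integer ages;
missing ages are omitted, never imputed.

## Synthetic data

The generator emulates the structural features the analysis depends on:
duplicate case versions (content-identical, strictly earlier receipt date,
distinct primaryid), verbatim drug spellings including brand names and
single-string combinations, per-PT independent Bernoulli events (a report
may carry several PTs, so the events-vs-reports distinction is exercised),
demographics, and outcome codes whose rates may be keyed by event.  A
planted association (cohort, PT, odds ratio OR) draws the event for cohort
members at `p1` with `p1/(1−p1) = OR·p0/(1−p0)`; an unachievable target is
a config error.  Generation is a pure function of (config, seed).

Default conditions: a dominant non-ICI background, ICI cohorts at 6%/2%/2%
(anti-PD-1 monotherapy / dual / plus-chemo — FAERS-like single-percent
shares), hepatitis background rates of 0.05–0.1%, common-event rates of
3–5%, a planted odds ratio of 20 at background 0.001, duplicate rate 5%,
age ~N(63, 12²) truncated to 18–95 with 30% missing, and death-outcome
rates keyed to the hepatitis terms (0.25 for the autoimmune/immune-mediated
terms, 0.70 for fulminant hepatitis, mirroring the severity gradient of
reported cases).  What the generator does **not** emulate: free-text
narratives, misspellings, reporting-trend drift over calendar time, and
correlated polypharmacy.  Passing tests therefore demonstrate correctness
of the machinery and estimator calibration under clean conditions, not
robustness to real-world coding noise — on real data, recall is bounded by
the synonym dictionary.

A hand-readable 50-case fixture with fully enumerated expected outputs
(survivor choices, regimen counts, 2×2 cells, fatal fraction, age summary)
accompanies the generator for exact, human-checkable pipeline validation.

## Problem sizes used by the test suite

Statistical tests run at sizes chosen to make the assertions sharp yet keep
the suite quick: calibration and descriptive-recovery checks at 20,000
cases (3-standard-error bands), interval coverage at 1,000 independence
tables, dedup-vs-oracle at 10,000 version sets, planted-signal recovery at
200 replicates of 20,000 cases (flag + interval-coverage rates asserted at
≥90%), and a single 200,000-case replicate for odds-ratio convergence
(sample OR within [16, 25] of the planted 20).  The acceptance script runs
one 200,000-case replicate.

## Known limitations

- One dialect: modern QDE ASCII only; XML and legacy layouts are out of scope.
- PT strings are opaque: no MedDRA hierarchy or standardized-query support.
- The published upstream exclusion of "non-specific" hepatitis terms is not
  re-derived; the scan list is fixed to the 35 published terms.
- No probabilistic duplicate detection across distinct caseids.
- Signal detection methods beyond ROR/IC (PRR, EBGM, shrinkage regression)
  and time-to-onset analyses are not implemented.
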