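"""A hand-readable 50-case bundle with enumerated expected outputs.

Every pipeline stage has a known answer on this fixture: version/survivor
counts, the survivor chosen for each duplicated case, regimen label counts,
hepatitis case counts, the ICI×autoimmune-hepatitis 2×2 cells at the report
unit, the fatal fraction, and the age summary.  The expected values in
``EXPECTED`` were enumerated by hand from the rows constructed below; tests
compare pipeline output against them.

The fixture is fully synthetic — no row is taken from any real report.
"""

from __future__ import annotations

import pandas as pd

from .faers_io import QuarterBundle
from .synthetic import SyntheticDataset

#: hand-enumerated ground truth for the fixture
EXPECTED = {
    "n_versions": 53,
    "n_survivors": 50,
    "survivor_pid": {"9001": "90012", "9002": "90022", "9021": "90212"},
    "regimen_counts": {
        "ANTI_PD1_MONO": 15,
        "ANTI_PDL1_MONO": 0,
        "ANTI_CTLA4_MONO": 3,
        "DUAL_ICI": 8,
        "ICI_PLUS_CHEMO": 2,
        "NON_ICI": 22,
    },
    # reports carrying any of the three designated hepatitis terms
    "hrae_reports": 15,
    # exposure = any ICI regimen (28 reports), event = autoimmune hepatitis
    "aih_table_reports": {"a": 6, "b": 22, "c": 1, "d": 21},
    "fatal_de_in_hrae": 3,  # 9021, 9022, 9044
    "hrae_fatal_fraction": 3 / 15,
    "hrae_age": {"n": 3, "median": 63.0, "q1": 63.0, "q3": 66.5},
    # 50 reports are far below the default 10-case signal minimum, and the
    # Wald interval at a=6/c=1 spans 1: no cell may be flagged on the fixture
    "scan_signals_default": [],
}


def fixture_small() -> SyntheticDataset:
    """Build the 50-case fixture as a single pooled quarter bundle."""
    demo_rows: list[tuple] = []   # (pid, caseid, fda_dt, age, age_cod, sex, country, occp)
    drug_rows: list[tuple] = []   # (pid, seq, role, drugname, prod_ai)
    reac_rows: list[tuple] = []   # (pid, pt)
    outc_rows: list[tuple] = []   # (pid, code)
    indi_rows: list[tuple] = []   # (pid, seq, indication)

    def add_case(caseid, pid, fda_dt, drugs, reactions, outcomes=(), indication=None,
                 age="", age_cod="", sex="M", country="US", occp="MD"):
        demo_rows.append((pid, caseid, fda_dt, age, age_cod, sex, country, occp))
        for seq, (role, name) in enumerate(drugs, start=1):
            drug_rows.append((pid, str(seq), role, name, ""))
        for pt in reactions:
            reac_rows.append((pid, pt))
        for code in outcomes:
            outc_rows.append((pid, code))
        if indication:
            indi_rows.append((pid, "1", indication))

    ps = lambda name: ("PS", name)
    con = lambda name: ("C", name)

    # --- background, non-ICI: 9001–9020 and 9049–9050 (22 cases) ------------
    # 9001 has two versions (later date wins); 9002 two versions on the same
    # date (higher primaryid wins).
    add_case("9001", "90011", "20220101", [ps("ASPIRIN")], ["Nausea"], ["OT"],
             indication="Hypertension")
    add_case("9001", "90012", "20220601", [ps("ASPIRIN")], ["Nausea"], ["OT"],
             indication="Hypertension")
    add_case("9002", "90021", "20220315", [ps("ASPIRIN")], ["Nausea"], ["OT"],
             indication="Hypertension")
    add_case("9002", "90022", "20220315", [ps("ASPIRIN")], ["Nausea"], ["OT"],
             indication="Hypertension")
    for i in range(3, 11):  # 9003–9010: aspirin, nausea
        add_case(f"90{i:02d}", f"90{i:02d}2", "20220715", [ps("ASPIRIN")],
                 ["Nausea"], ["OT"], indication="Hypertension", sex="F" if i % 2 else "M")
    for i in range(11, 19):  # 9011–9018: metformin, nausea
        add_case(f"90{i}", f"90{i}2", "20220715", [ps("METFORMIN")],
                 ["Nausea"], ["OT"], indication="Type 2 diabetes mellitus")
    # background hepatitis: one autoimmune hepatitis, one hepatitis C
    add_case("9019", "90192", "20220715", [ps("METFORMIN")],
             ["Autoimmune hepatitis"], ["OT"], indication="Type 2 diabetes mellitus")
    add_case("9020", "90202", "20220715", [ps("METFORMIN")],
             ["Hepatitis C"], ["OT"], indication="Type 2 diabetes mellitus")
    add_case("9049", "90492", "20220715", [ps("METFORMIN")], ["Headache"], ["OT"],
             indication="Type 2 diabetes mellitus")
    add_case("9050", "90502", "20220715", [ps("METFORMIN")], ["Headache"], ["OT"],
             indication="Type 2 diabetes mellitus")

    # --- anti-PD-1 monotherapy: 9021–9035 (15 cases) ------------------------
    # 9021 also has a stale earlier version whose reaction must be discarded
    add_case("9021", "90211", "20220210", [ps("NIVOLUMAB")], ["Nausea"], ["OT"],
             indication="Malignant melanoma")
    add_case("9021", "90212", "20220810", [ps("NIVOLUMAB")],
             ["Autoimmune hepatitis"], ["DE"], indication="Malignant melanoma",
             age="63", age_cod="YR")
    add_case("9022", "90222", "20220810", [ps("NIVOLUMAB")],
             ["Autoimmune hepatitis"], ["DE", "HO"], indication="Malignant melanoma",
             age="756", age_cod="MON")
    add_case("9023", "90232", "20220810", [ps("NIVOLUMAB")],
             ["Autoimmune hepatitis"], ["HO"], indication="Malignant melanoma",
             age="70", age_cod="YR")
    for i in (24, 25):
        add_case(f"90{i}", f"90{i}2", "20220810", [ps("NIVOLUMAB")],
                 ["Autoimmune hepatitis"], ["HO"], indication="Malignant melanoma")
    for i in (26, 27):
        add_case(f"90{i}", f"90{i}2", "20220810", [ps("NIVOLUMAB")],
                 ["Immune-mediated hepatitis"], ["HO"], indication="Malignant melanoma")
    for i in (28, 29, 30):
        add_case(f"90{i}", f"90{i}2", "20220810", [ps("NIVOLUMAB")],
                 ["Fatigue"], ["OT"], indication="Malignant melanoma")
    for i in (31, 32, 33):  # brand-name spelling
        add_case(f"90{i}", f"90{i}2", "20220810", [ps("OPDIVO")],
                 ["Fatigue"], ["OT"], indication="Non-small cell lung cancer")
    for i in (34, 35):
        add_case(f"90{i}", f"90{i}2", "20220810", [ps("PEMBROLIZUMAB")],
                 ["Fatigue"], ["OT"], indication="Non-small cell lung cancer")

    # --- dual ICI therapy: 9036–9043 (8 cases) ------------------------------
    for i in (36, 37, 38, 39):
        add_case(f"90{i}", f"90{i}2", "20220901",
                 [ps("NIVOLUMAB"), ps("IPILIMUMAB")],
                 ["Immune-mediated hepatitis"], ["HO"], indication="Renal cell carcinoma")
    add_case("9040", "90402", "20220901", [ps("NIVOLUMAB"), ps("IPILIMUMAB")],
             ["Autoimmune hepatitis"], ["HO"], indication="Renal cell carcinoma")
    # combination spelled as a single verbatim string
    add_case("9041", "90412", "20220901", [ps("NIVOLUMAB AND IPILIMUMAB")],
             ["Rash"], ["OT"], indication="Renal cell carcinoma")
    for i in (42, 43):
        add_case(f"90{i}", f"90{i}2", "20220901",
                 [ps("OPDIVO"), ps("YERVOY")], ["Rash"], ["OT"],
                 indication="Renal cell carcinoma")

    # --- anti-CTLA-4 monotherapy: 9044–9046 (3 cases) -----------------------
    add_case("9044", "90442", "20220901", [ps("IPILIMUMAB")],
             ["Hepatitis fulminant"], ["DE"], indication="Malignant melanoma")
    add_case("9045", "90452", "20220901", [ps("IPILIMUMAB")],
             ["Colitis"], ["HO"], indication="Malignant melanoma")
    add_case("9046", "90462", "20220901", [ps("YERVOY")],
             ["Colitis"], ["HO"], indication="Malignant melanoma")

    # --- ICI plus chemotherapy: 9047–9048 (2 cases) -------------------------
    add_case("9047", "90472", "20220901",
             [ps("PEMBROLIZUMAB"), con("CARBOPLATIN")],
             ["Immune-mediated hepatitis"], ["HO"], indication="Non-small cell lung cancer")
    add_case("9048", "90482", "20220901",
             [ps("PEMBROLIZUMAB"), con("CARBOPLATIN")],
             ["Nausea"], ["HO"], indication="Non-small cell lung cancer")

    demo = pd.DataFrame(
        demo_rows,
        columns=["primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
                 "reporter_country", "occp_cod"],
    )
    drug = pd.DataFrame(
        drug_rows, columns=["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"]
    )
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"])
    indi = pd.DataFrame(indi_rows, columns=["primaryid", "indi_drug_seq", "indi_pt"])
    ther = pd.DataFrame(
        {"primaryid": demo["primaryid"], "dsg_drug_seq": "1", "start_dt": demo["fda_dt"]}
    )
    bundle = QuarterBundle(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi,
                           ther=ther, quarter="2022Q3")
    bundle.validate()
    return SyntheticDataset(bundles={"2022Q3": bundle}, truth=dict(EXPECTED))
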