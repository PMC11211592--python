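import pytest

from pvhepascan.cohort import (
    HEPATITIS_SCAN,
    HRAE,
    DrugClass,
    DrugDictionary,
    Regimen,
    classify_regimen_from_entries,
    label_regimens,
    map_country_to_region,
    map_indication_to_organ,
    normalize_drug,
    select_events,
)

DICT = DrugDictionary.default()


class TestNormalizeDrug:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("OPDIVO", [("nivolumab", DrugClass.ANTI_PD1)]),
            ("  opdivo ", [("nivolumab", DrugClass.ANTI_PD1)]),
            ("KEYTRUDA", [("pembrolizumab", DrugClass.ANTI_PD1)]),
            ("YERVOY", [("ipilimumab", DrugClass.ANTI_CTLA4)]),
            ("TECENTRIQ", [("atezolizumab", DrugClass.ANTI_PDL1)]),
            ("ASPIRIN", []),
            ("", []),
        ],
    )
    def test_single_names(self, name, expected):
        assert normalize_drug(name, None, DICT) == expected

    def test_combination_string_matches_componentwise(self):
        hits = normalize_drug("NIVOLUMAB AND IPILIMUMAB", None, DICT)
        assert hits == [
            ("nivolumab", DrugClass.ANTI_PD1),
            ("ipilimumab", DrugClass.ANTI_CTLA4),
        ]

    @pytest.mark.parametrize("sep", [";", "+", "/", ","])
    def test_component_separators(self, sep):
        hits = normalize_drug(f"PEMBROLIZUMAB{sep}CARBOPLATIN", None, DICT)
        assert {a for a, _ in hits} == {"pembrolizumab", "carboplatin"}

    def test_active_ingredient_takes_priority(self):
        hits = normalize_drug("SOME BRAND NAME", "DURVALUMAB", DICT)
        assert hits == [("durvalumab", DrugClass.ANTI_PDL1)]

    def test_eight_agents_present_with_brands(self):
        agents = DICT.ici_agents()
        assert agents == {
            "nivolumab", "pembrolizumab", "cemiplimab",
            "atezolizumab", "avelumab", "durvalumab",
            "ipilimumab", "tremelimumab",
        }


class TestClassifyRegimen:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            ([("NIVOLUMAB", "", "PS")], Regimen.ANTI_PD1_MONO),
            ([("DURVALUMAB", "", "PS")], Regimen.ANTI_PDL1_MONO),
            ([("IPILIMUMAB", "", "PS")], Regimen.ANTI_CTLA4_MONO),
            (
                [("NIVOLUMAB", "", "PS"), ("IPILIMUMAB", "", "PS")],
                Regimen.DUAL_ICI,
            ),
            # combination as one verbatim string
            ([("NIVOLUMAB AND IPILIMUMAB", "", "PS")], Regimen.DUAL_ICI),
            (
                [("PEMBROLIZUMAB", "", "PS"), ("CARBOPLATIN", "", "C")],
                Regimen.ICI_PLUS_CHEMO,
            ),
            # ICI in a non-PS role does not create exposure
            ([("NIVOLUMAB", "", "SS"), ("ASPIRIN", "", "PS")], Regimen.NON_ICI),
            ([("ASPIRIN", "", "PS")], Regimen.NON_ICI),
            ([], Regimen.NON_ICI),
            # same-agent double listing stays monotherapy
            (
                [("NIVOLUMAB", "", "PS"), ("OPDIVO", "", "PS")],
                Regimen.ANTI_PD1_MONO,
            ),
        ],
    )
    def test_labels(self, entries, expected):
        assert classify_regimen_from_entries(entries, DICT) is expected

    def test_order_invariance(self):
        entries = [("IPILIMUMAB", "", "PS"), ("NIVOLUMAB", "", "PS"), ("CARBOPLATIN", "", "C")]
        labels = {
            classify_regimen_from_entries(perm, DICT)
            for perm in ([entries[i] for i in order] for order in
                         ((0, 1, 2), (1, 0, 2), (2, 1, 0), (1, 2, 0)))
        }
        assert labels == {Regimen.DUAL_ICI}

    def test_labels_partition_store(self, synth_store):
        regimens = label_regimens(synth_store)
        assert len(regimens) == len(synth_store.demo)
        assert regimens.notna().all()
        valid = {r.value for r in Regimen}
        assert set(regimens.unique()) <= valid

    def test_strategy_counts_sum_to_ici_total(self, synth_store):
        regimens = label_regimens(synth_store)
        counts = regimens.value_counts()
        ici_total = sum(
            counts.get(r.value, 0) for r in Regimen if r is not Regimen.NON_ICI
        )
        assert ici_total + counts.get(Regimen.NON_ICI.value, 0) == len(regimens)


class TestEventSets:
    def test_scan_set_has_35_terms_and_contains_hrae(self):
        assert len(HEPATITIS_SCAN.terms) == 35
        assert HRAE.terms <= HEPATITIS_SCAN.terms
        assert len(HRAE.terms) == 3

    @pytest.mark.parametrize(
        "reactions,term_set,expected",
        [
            (["Autoimmune hepatitis", "Nausea"], HRAE, {"AUTOIMMUNE HEPATITIS"}),
            (["AUTOIMMUNE HEPATITIS"], HRAE, {"AUTOIMMUNE HEPATITIS"}),
            (["Hepatitis C"], HRAE, set()),
            (["Hepatitis C"], HEPATITIS_SCAN, {"HEPATITIS C"}),
            ([], HRAE, set()),
        ],
    )
    def test_select_events(self, reactions, term_set, expected):
        assert select_events(reactions, term_set) == expected


class TestMappings:
    @pytest.mark.parametrize(
        "indication,organ",
        [
            ("Malignant melanoma", "Skin"),
            ("Non-small cell lung cancer", "Lung"),
            ("Renal cell carcinoma", "Kidney"),
            ("Hepatocellular carcinoma", "Liver"),
            ("Transitional cell carcinoma", "Bladder"),
            ("Product used for unknown indication", "Unspecified"),
            (None, "Unspecified"),
            ("", "Unspecified"),
            ("Cryptic neoplasm", "Others"),
        ],
    )
    def test_indication_to_organ(self, indication, organ):
        assert map_indication_to_organ(indication) == organ

    @pytest.mark.parametrize(
        "country,region",
        [
            ("US", "Americas"), ("JP", "Asia"), ("DE", "Europe"),
            ("AU", "Oceania"), ("ZA", "Africa"), ("JAPAN", "Asia"),
            ("", "Missing"), (None, "Missing"), ("XYZ", "Missing"),
        ],
    )
    def test_country_to_region(self, country, region):
        assert map_country_to_region(country) == region
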