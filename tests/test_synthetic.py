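import math

import pytest

from pvhepascan.dedup import deduplicate
from pvhepascan.faers_io import read_quarter, write_quarter
from pvhepascan.synthetic import (
    ConfigError,
    SyntheticConfig,
    default_config,
    generate,
    planted_probability,
)


class TestPlantedProbability:
    def test_odds_formula(self):
        p1 = planted_probability(0.001, 20.0)
        odds0 = 0.001 / 0.999
        assert p1 / (1 - p1) == pytest.approx(20.0 * odds0)

    def test_neutral_odds_ratio_preserves_background(self):
        assert planted_probability(0.05, 1.0) == pytest.approx(0.05)

    @pytest.mark.parametrize("p0", [0.0, 1.0, 1.5])
    def test_degenerate_background_rejected(self, p0):
        with pytest.raises(ConfigError):
            planted_probability(p0, 20.0)

    def test_unachievable_odds_ratio_is_a_config_error(self):
        with pytest.raises(ConfigError, match="unachievable"):
            planted_probability(0.5, float("inf"))


class TestConfigValidation:
    def test_unknown_planted_cohort_rejected(self):
        cfg = default_config(n_cases=10)
        with pytest.raises((ConfigError, ValueError)):
            SyntheticConfig(
                **{**cfg.model_dump(),
                   "planted_associations": [
                       {"cohort": "NO_SUCH", "pt": "Nausea", "odds_ratio": 2.0}
                   ]}
            )

    def test_cohort_probabilities_must_not_exceed_one(self):
        cfg = default_config(n_cases=10).model_dump()
        for spec in cfg["drug_exposure"].values():
            spec["probability"] = 0.5
        with pytest.raises((ConfigError, ValueError)):
            SyntheticConfig(**cfg)


class TestGenerate:
    def test_deterministic_files_for_fixed_seed(self, tmp_path):
        cfg = default_config(n_cases=500, seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            ds = generate(cfg)
            for quarter, bundle in ds.bundles.items():
                write_quarter(bundle, d / quarter)
        for p1 in sorted(d1.rglob("*.txt")):
            p2 = d2 / p1.relative_to(d1)
            assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate(default_config(n_cases=500, seed=1))
        b = generate(default_config(n_cases=500, seed=2))
        assert not a.pooled.demo.equals(b.pooled.demo)

    def test_zero_duplicate_rate_dedups_to_n_cases(self):
        cfg = default_config(n_cases=400, seed=6).model_copy(update={"duplicate_rate": 0.0})
        ds = generate(cfg)
        assert deduplicate(ds.pooled).n_survivors == 400
        assert ds.truth["n_versions"] == 400

    def test_duplicates_share_caseid_with_earlier_date(self):
        cfg = default_config(n_cases=2_000, seed=9).model_copy(update={"duplicate_rate": 0.3})
        demo = generate(cfg).pooled.demo
        dupes = demo[demo.duplicated("caseid", keep=False)]
        assert len(dupes) > 0
        for _, grp in dupes.groupby("caseid"):
            assert len(grp) == 2
            by_pid = grp.sort_values("primaryid")
            assert int(by_pid.iloc[0]["fda_dt"]) < int(by_pid.iloc[1]["fda_dt"])

    def test_round_trip_through_files(self, tmp_path):
        ds = generate(default_config(n_cases=300, seed=4))
        quarter, bundle = next(iter(ds.bundles.items()))
        write_quarter(bundle, tmp_path)
        assert bundle.equals(read_quarter(tmp_path, quarter=quarter))

    def test_marginal_calibration_within_three_se(self, synth_dataset):
        """Cohort sizes and background event rates match the config at n=20,000."""
        cfg = default_config(n_cases=20_000, seed=11)
        n = cfg.n_cases
        sizes = synth_dataset.truth["cohort_sizes"]
        for name, spec in cfg.drug_exposure.items():
            se = math.sqrt(spec.probability * (1 - spec.probability) * n)
            assert abs(sizes[name] - spec.probability * n) <= 3 * se, name
        # background rate of an unplanted PT among unexposed reports
        store = deduplicate(synth_dataset.pooled).store
        p0 = cfg.background_event_rates["Hepatitis C"]
        hits = store.reac[store.reac["pt"] == "Hepatitis C"]["primaryid"].nunique()
        se = math.sqrt(p0 * (1 - p0) * n)
        assert abs(hits - p0 * n) <= 3 * se


class TestOddsRatioPlanting:
    def test_realized_odds_ratio_converges_at_large_n(self):
        """At n = 200,000 and target 20, the sample odds ratio lands in [16, 25]."""
        ds = generate(default_config(n_cases=200_000, seed=13))
        planted = ds.truth["planted"][0]
        assert planted["target_odds_ratio"] == 20.0
        assert 16.0 <= planted["sample_odds_ratio"] <= 25.0


class TestFixtureSmall:
    def test_dedup_survivor_count_matches_expected_file(self, fixture_dataset):
        result = deduplicate(fixture_dataset.pooled)
        assert result.n_survivors == fixture_dataset.truth["n_survivors"]

    def test_same_date_tie_resolved_by_higher_primaryid(self, fixture_dataset):
        result = deduplicate(fixture_dataset.pooled)
        surv = dict(zip(result.store.demo["caseid"], result.store.demo["primaryid"]))
        assert surv["9002"] == "90022"

    def test_planted_dual_ici_case_classifies_as_dual(self, fixture_store):
        from pvhepascan.cohort import Regimen, label_regimens

        regimens = label_regimens(fixture_store)
        assert regimens["90412"] == Regimen.DUAL_ICI.value  # combination string
        assert regimens["90362"] == Regimen.DUAL_ICI.value  # two PS rows

    def test_regimen_counts(self, fixture_store, fixture_expected):
        from pvhepascan.cohort import label_regimens

        counts = label_regimens(fixture_store).value_counts().to_dict()
        expected = {k: v for k, v in fixture_expected["regimen_counts"].items() if v}
        assert counts == expected

    def test_contingency_cells(self, fixture_store, fixture_expected):
        from pvhepascan.cohort import HRAE, ICI_REGIMENS, label_regimens
        from pvhepascan.disprop import scan

        regimens = label_regimens(fixture_store)
        ici = [p for p, v in regimens.items() if v in {r.value for r in ICI_REGIMENS}]
        [row] = [
            r for r in scan(fixture_store, {"ICI": ici}, HRAE, unit="reports")
            if r.event == "AUTOIMMUNE HEPATITIS"
        ]
        exp = fixture_expected["aih_table_reports"]
        assert row.n_observed == exp["a"]
        n_total = len(fixture_store.demo)
        assert len(ici) == exp["a"] + exp["b"]
        assert n_total - len(ici) == exp["c"] + exp["d"]
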