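"""The resolution cascade: worked examples, presets, oracle equivalence."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ethnirec import (
    AlgorithmConfig,
    ENGLAND_CENSUS_2021,
    EthnicCategory,
    PRESETS,
    brute_force_derive,
    derive_cohort,
    derive_patient,
    preset,
)
from ethnirec.derivation import CensusDistribution

from conftest import make_record, random_record_set, records_to_frame

W, A, B, M, O, U = (
    EthnicCategory.WHITE,
    EthnicCategory.ASIAN,
    EthnicCategory.BLACK,
    EthnicCategory.MIXED,
    EthnicCategory.OTHER,
    EthnicCategory.UNKNOWN,
)


class TestPresets:
    def test_algorithm1_prioritises_secondary_care(self):
        assert preset("algorithm1").source_priority == "secondary"

    def test_algorithm3_prioritises_recency_first(self):
        assert preset("algorithm3").step_order_first == "recency"
        assert preset("algorithm3").step_order == ("recency", "frequency")

    def test_algorithm4_does_not_prioritise_non_other(self):
        assert preset("algorithm4").prioritise_non_other is False

    def test_algorithm2_is_the_primary_frequency_base(self):
        config = preset("algorithm2")
        assert config.step_order == ("frequency", "recency")
        assert config.source_priority == "primary"
        assert config.prioritise_non_other is True

    def test_unknown_preset_rejected_with_valid_names(self):
        with pytest.raises(ValueError, match="algorithm1"):
            preset("algorithm9")

    def test_census_order_default_follows_england_2021(self):
        assert preset("algorithm2").census_order == (W, A, B, M, O)


class TestConfigValidation:
    def test_census_order_must_cover_exactly_five(self):
        with pytest.raises(ValueError):
            AlgorithmConfig(census_order=(W, A, B, M))
        with pytest.raises(ValueError):
            AlgorithmConfig(census_order=(W, A, B, M, O, U))

    def test_empty_census_order_rejected(self):
        with pytest.raises(ValueError):
            AlgorithmConfig(census_order=())

    def test_census_distribution_must_sum_to_100(self):
        with pytest.raises(ValueError, match="100"):
            CensusDistribution({W: 50.0, A: 20.0, B: 10.0, M: 10.0, O: 5.0})

    def test_default_census_rank_order(self):
        assert ENGLAND_CENSUS_2021.rank_order == (W, A, B, M, O)


class TestWorkedExamples:
    """The six rule-forced resolutions, each isolating one cascade step."""

    def test_frequency_forces_majority_category(self):
        records = [make_record(W), make_record(W), make_record(A)]
        result = derive_patient(records, preset("algorithm2"))
        assert (result.category, result.deciding_step) == (W, "frequency")

    def test_recency_breaks_frequency_tie_and_leads_algorithm3(self):
        records = [
            make_record(W, record_date=date(2020, 1, 1)),
            make_record(A, record_date=date(2022, 1, 1)),
        ]
        r2 = derive_patient(records, preset("algorithm2"))
        assert (r2.category, r2.deciding_step) == (A, "recency")
        r3 = derive_patient(records, preset("algorithm3"))
        assert (r3.category, r3.deciding_step) == (A, "recency")

    def test_source_priority_split_between_algorithms_1_and_2(self):
        records = [
            make_record(W, source="hes_apc", record_date=date(2021, 6, 1)),
            make_record(A, source="cprd_aurum", record_date=date(2021, 6, 1)),
        ]
        r1 = derive_patient(records, preset("algorithm1"))
        assert (r1.category, r1.deciding_step) == (W, "source_priority")
        r2 = derive_patient(records, preset("algorithm2"))
        assert (r2.category, r2.deciding_step) == (A, "source_priority")

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_census_ranks_black_above_mixed(self, name):
        records = [
            make_record(B, source="cprd_gold", record_date=date(2021, 6, 1)),
            make_record(M, source="cprd_aurum", record_date=date(2021, 6, 1)),
        ]
        result = derive_patient(records, preset(name))
        assert (result.category, result.deciding_step) == (B, "census")

    def test_non_other_rewrite_versus_algorithm4(self):
        records = [make_record(O), make_record(O), make_record(B)]
        r2 = derive_patient(records, preset("algorithm2"))
        assert (r2.category, r2.deciding_step) == (B, "non_other_rewrite")
        r4 = derive_patient(records, preset("algorithm4"))
        assert (r4.category, r4.deciding_step) == (O, "frequency")

    def test_empty_and_all_unknown_give_unknown(self):
        for records in ([], [make_record(U), make_record(U)]):
            result = derive_patient(records, preset("algorithm2"))
            assert result.category is U
            assert result.deciding_step == "no_usable_records"
            assert result.n_usable_records == 0


class TestCascadeEdges:
    def test_single_record_is_unanimous(self):
        result = derive_patient([make_record(B)], preset("algorithm1"))
        assert (result.category, result.deciding_step) == (B, "unanimous")

    def test_unknown_records_discarded_before_anything_else(self):
        records = [make_record(U)] * 4 + [make_record(M)]
        result = derive_patient(records, preset("algorithm2"))
        assert (result.category, result.deciding_step) == (M, "unanimous")
        assert result.n_usable_records == 1

    def test_missing_dates_sort_strictly_oldest(self):
        records = [
            make_record(W, record_date=None),
            make_record(A, record_date=date(2010, 1, 1)),
        ]
        result = derive_patient(records, preset("algorithm2"))
        assert (result.category, result.deciding_step) == (A, "recency")

    def test_tier_step_non_discriminating_when_all_share_tier(self):
        records = [
            make_record(B, source="cprd_gold", record_date=date(2020, 1, 1)),
            make_record(M, source="cprd_aurum", record_date=date(2020, 1, 1)),
        ]
        result = derive_patient(records, preset("algorithm2"))
        assert result.deciding_step == "census"

    def test_unanimous_other_is_not_rewritten(self):
        result = derive_patient([make_record(O), make_record(O)], preset("algorithm2"))
        assert (result.category, result.deciding_step) == (O, "unanimous")

    def test_rewrite_reruns_full_cascade_on_remainder(self):
        # after removing Other, W and A tie on frequency; recency decides
        records = [
            make_record(O, record_date=date(2021, 1, 1)),
            make_record(O, record_date=date(2021, 1, 2)),
            make_record(W, record_date=date(2019, 1, 1)),
            make_record(A, record_date=date(2020, 1, 1)),
        ]
        result = derive_patient(records, preset("algorithm2"))
        assert (result.category, result.deciding_step) == (A, "non_other_rewrite")

    def test_records_spanning_patients_rejected(self):
        records = [make_record(W, patient_id="p1"), make_record(W, patient_id="p2")]
        with pytest.raises(ValueError, match="single patient"):
            derive_patient(records, preset("algorithm2"))

    def test_unanimity_dominates_every_config(self):
        records = [
            make_record(M, source=s, record_date=date(2020, 1, 1))
            for s in ("cprd_gold", "hes_apc", "hes_op")
        ]
        for name in PRESETS:
            assert derive_patient(records, preset(name)).category is M


class TestOracleEquivalence:
    """Aggregated cascade vs literal record-filtering oracle."""

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_agreement_on_randomised_record_sets(self, name):
        rng = np.random.default_rng(20240901)
        config = preset(name)
        for _ in range(2500):
            records = random_record_set(rng)
            fast = derive_patient(records, config)
            oracle = brute_force_derive(records, config)
            assert fast.category is oracle.category
            assert fast.deciding_step == oracle.deciding_step
            assert fast.n_usable_records == oracle.n_usable_records

    def test_oracle_on_the_worked_examples(self):
        cases = [
            ([make_record(W), make_record(W), make_record(A)], "algorithm2", W),
            (
                [
                    make_record(W, record_date=date(2020, 1, 1)),
                    make_record(A, record_date=date(2022, 1, 1)),
                ],
                "algorithm2",
                A,
            ),
            ([make_record(O), make_record(O), make_record(B)], "algorithm2", B),
            ([make_record(O), make_record(O), make_record(B)], "algorithm4", O),
        ]
        for records, name, expected in cases:
            assert brute_force_derive(records, preset(name)).category is expected


class TestDeriveCohort:
    @staticmethod
    def meta_for(*patient_ids):
        return pd.DataFrame(
            {
                "patient_id": list(patient_ids),
                "database": "aurum",
                "practice_id": "a001",
                "acceptable": True,
                "linkage_eligible": True,
                "currently_registered": True,
                "sex": "female",
            }
        )

    def test_three_patient_fixture_includes_recordless_as_unknown(self):
        records = records_to_frame(
            [
                make_record(W, patient_id="p1"),
                make_record(W, patient_id="p1"),
                make_record(B, patient_id="p2", record_date=date(2020, 1, 1)),
                make_record(M, patient_id="p2", record_date=date(2020, 1, 1)),
            ]
        )
        out = derive_cohort(records, self.meta_for("p1", "p2", "p3"), preset("algorithm2"))
        assert len(out) == 3
        by_id = out.set_index("patient_id")
        assert by_id.loc["p1", "ethnicity"] == "White"
        assert by_id.loc["p2", "ethnicity"] == "Black"  # census tie-break
        assert by_id.loc["p3", "ethnicity"] == "Unknown"
        assert by_id.loc["p3", "deciding_step"] == "no_usable_records"
        assert by_id.loc["p3", "n_usable_records"] == 0

    def test_row_order_independence(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(40):
            records.extend(random_record_set(rng, patient_id=f"p{i}"))
        frame = records_to_frame(records)
        meta = self.meta_for(*[f"p{i}" for i in range(40)])
        base = derive_cohort(frame, meta, preset("algorithm1"))
        shuffled = derive_cohort(
            frame.sample(frac=1.0, random_state=11), meta, preset("algorithm1")
        )
        pd.testing.assert_frame_equal(base, shuffled)

    @pytest.mark.parametrize("name", sorted(PRESETS))
    def test_cohort_equals_independent_per_patient_derivation(self, name):
        rng = np.random.default_rng(99)
        per_patient = {}
        records = []
        for i in range(60):
            patient = f"p{i:03d}"
            record_set = random_record_set(rng, patient_id=patient)
            records.extend(record_set)
            per_patient[patient] = record_set
        frame = records_to_frame(records)
        meta = self.meta_for(*sorted(per_patient))
        cohort = derive_cohort(frame, meta, preset(name)).set_index("patient_id")
        for patient, record_set in per_patient.items():
            expected = derive_patient(record_set, preset(name)) if record_set else None
            row = cohort.loc[patient]
            if not record_set:
                assert row["ethnicity"] == "Unknown"
            else:
                assert row["ethnicity"] == expected.category.value
                assert row["deciding_step"] == expected.deciding_step
                assert row["n_usable_records"] == expected.n_usable_records

    def test_orphan_records_warned_and_excluded(self, caplog):
        records = records_to_frame([make_record(W, patient_id="ghost")])
        with caplog.at_level("WARNING"):
            out = derive_cohort(records, self.meta_for("p1"), preset("algorithm2"))
        assert list(out["ethnicity"]) == ["Unknown"]
        assert any("absent from metadata" in r.message for r in caplog.records)


class TestCohortProperties:
    @staticmethod
    def random_cohort(n=300, seed=7):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            records.extend(random_record_set(rng, patient_id=f"p{i:04d}"))
        frame = records_to_frame(records)
        meta = TestDeriveCohort.meta_for(*[f"p{i:04d}" for i in range(n)])
        return frame, meta

    def test_unknown_set_identical_across_presets(self):
        frame, meta = self.random_cohort()
        unknown_sets = []
        for name in sorted(PRESETS):
            out = derive_cohort(frame, meta, preset(name))
            unknown_sets.append(
                frozenset(out.loc[out["ethnicity"] == "Unknown", "patient_id"])
            )
        assert len(set(unknown_sets)) == 1

    def test_other_count_monotone_without_rewrite(self):
        frame, meta = self.random_cohort(seed=13)
        count = {
            name: (derive_cohort(frame, meta, preset(name))["ethnicity"] == "Other").sum()
            for name in ("algorithm2", "algorithm4")
        }
        assert count["algorithm4"] >= count["algorithm2"]

    def test_algorithm1_vs_2_differ_only_at_tier_split_patients(self):
        frame, meta = self.random_cohort(seed=21)
        out1 = derive_cohort(frame, meta, preset("algorithm1")).set_index("patient_id")
        out2 = derive_cohort(frame, meta, preset("algorithm2")).set_index("patient_id")
        differing = out1.index[out1["ethnicity"] != out2["ethnicity"]]
        for patient in differing:
            steps = {out1.loc[patient, "deciding_step"], out2.loc[patient, "deciding_step"]}
            # a difference can only arise at or after the tier decision
            assert steps & {"source_priority", "census", "non_other_rewrite"}

    def test_adding_a_source_never_increases_unknowns(self):
        frame, meta = self.random_cohort(seed=31)
        unknowns = {}
        for source_set in ("cprd_only", "cprd_hes_apc", "all_sources"):
            out = derive_cohort(frame, meta, preset("algorithm2"), source_set)
            unknowns[source_set] = (out["ethnicity"] == "Unknown").sum()
        assert unknowns["all_sources"] <= unknowns["cprd_hes_apc"] <= unknowns["cprd_only"]
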