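import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nicu_los as nl
from nicu_los.guidelines import MedicationDeviation
from nicu_los.orders import DailyNutritionOrder, MedicationOrder

from conftest import make_record


class TestDeviationFactor:
    def test_identical_vectors_give_exactly_zero(self):
        for n in (1, 5, 30):
            v = np.linspace(40, 120, n)
            assert nl.deviation_factor(v, v) == 0.0

    def test_hand_computed_example(self):
        # gaps (10, 10, 10): sqrt(300)/3
        result = nl.deviation_factor([100, 110, 120], [90, 100, 130])
        assert result == pytest.approx(math.sqrt(300) / 3)

    def test_single_day_reduces_to_absolute_gap(self):
        assert nl.deviation_factor([100.0], [93.5]) == pytest.approx(6.5)
        assert nl.deviation_factor([100.0], [106.5]) == pytest.approx(6.5)

    def test_alternative_normalizations(self):
        rec, orded = [100, 110], [90, 120]
        assert nl.deviation_factor(rec, orded, "l2_raw") == pytest.approx(math.sqrt(200))
        assert nl.deviation_factor(rec, orded, "mean_abs") == pytest.approx(10.0)

    @pytest.mark.parametrize("bad", [([], []), ([1.0], [1.0, 2.0])])
    def test_empty_or_mismatched_vectors_raise(self, bad):
        with pytest.raises(ValueError):
            nl.deviation_factor(*bad)

    def test_unknown_normalization_raises(self):
        with pytest.raises(ValueError):
            nl.deviation_factor([1.0], [1.0], "l3")

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=20),
        st.floats(min_value=0, max_value=10),
    )
    def test_scaling_gaps_scales_factor(self, gaps, c):
        rec = np.zeros(len(gaps))
        base = nl.deviation_factor(rec, np.array(gaps))
        scaled = nl.deviation_factor(rec, c * np.array(gaps))
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=15), st.randoms())
    def test_day_order_irrelevant(self, gaps, rnd):
        rec = np.zeros(len(gaps))
        shuffled = list(gaps)
        rnd.shuffle(shuffled)
        assert nl.deviation_factor(rec, np.array(shuffled)) == pytest.approx(
            nl.deviation_factor(rec, np.array(gaps)), rel=1e-12, abs=1e-12
        )


class TestDailyNutritionDeviation:
    def test_order_matching_recommendation_has_zero_gap(self, guidelines):
        record = make_record(birth_weight_g=1800.0)
        rec = nl.recommend_nutrition(guidelines, 1800.0, 2, "EN", "energy_kcal_per_kg")
        order = DailyNutritionOrder("P1", 2, "EN", rec, 2.0)
        assert nl.daily_nutrition_deviation(order, record, guidelines, "energy_kcal_per_kg") == 0.0

    def test_withheld_feeds_day_scored_against_pn_table(self, guidelines):
        record = make_record(birth_weight_g=1800.0)
        pn_rec = nl.recommend_nutrition(guidelines, 1800.0, 5, "PN", "energy_kcal_per_kg")
        order = DailyNutritionOrder("P1", 5, "PN", pn_rec - 12.0, 2.0)
        gap = nl.daily_nutrition_deviation(order, record, guidelines, "energy_kcal_per_kg")
        assert gap == pytest.approx(12.0)

    def test_combined_mode_gap_uses_max_rule(self, guidelines):
        record = make_record(birth_weight_g=1800.0)
        en = nl.recommend_nutrition(guidelines, 1800.0, 10, "EN", "energy_kcal_per_kg")
        order = DailyNutritionOrder("P1", 10, "BOTH", en - 10.0, 2.0)
        gap = nl.daily_nutrition_deviation(order, record, guidelines, "energy_kcal_per_kg")
        assert gap == pytest.approx(10.0)  # EN table dominates PN at day 10


class TestQuartileCode:
    def test_values_one_to_eight(self):
        values = {f"P{i}": float(i) for i in range(1, 9)}
        codes = nl.quartile_code(values)
        assert {p for p, c in codes.items() if c == "Q4"} == {"P7", "P8"}

    def test_all_equal_values_empty_top_quartile(self):
        codes = nl.quartile_code({f"P{i}": 3.3 for i in range(10)})
        assert all(c == "remaining" for c in codes.values())

    def test_extreme_outlier_lands_in_top_quartile(self):
        rng = np.random.default_rng(0)
        values = {f"P{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 99))}
        values["OUT"] = 1e6
        assert nl.quartile_code(values)["OUT"] == "Q4"

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError, match="at least 8"):
            nl.quartile_code({f"P{i}": float(i) for i in range(7)})

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=8, max_size=60, unique=True))
    def test_partition_and_size_bound(self, values):
        mapping = {f"P{i}": v for i, v in enumerate(values)}
        codes = nl.quartile_code(mapping)
        n = len(values)
        q4 = [p for p, c in codes.items() if c == "Q4"]
        assert set(codes) == set(mapping)
        # distinct values: top quartile holds n - ceil(0.75 n) patients
        assert len(q4) == n - math.ceil(0.75 * n)

    def test_relabeling_patients_keeps_coding(self):
        values = {f"P{i}": float(i**2) for i in range(12)}
        renamed = {f"ZZ{i}": v for (_, v), i in zip(values.items(), range(12))}
        base = nl.quartile_code(values)
        relabeled = nl.quartile_code(renamed)
        assert [c for _, c in sorted(base.items())] == [c for _, c in sorted(relabeled.items())]


class TestSummarizeMedication:
    def test_supplements_only_is_not_required(self, guidelines):
        orders = [
            MedicationOrder("P1", d, drug, dose, 1)
            for d in (1, 2)
            for drug, dose in (("vitamin_d", 400.0), ("iron", 2.0))
        ]
        assert nl.summarize_medication(orders, guidelines, 1800, 5) == ("not_required", 0)

    def test_on_reference_doses_is_no_deviation(self, guidelines):
        ref = guidelines.medication_reference("amikacin")
        orders = [MedicationOrder("P1", d, "amikacin", ref.dose_per_kg, ref.frequency_per_day) for d in range(1, 6)]
        assert nl.summarize_medication(orders, guidelines, 1800, 5) == ("no_deviation", 0)

    def test_three_deviating_days_counted(self, guidelines):
        ref = guidelines.medication_reference("amikacin")
        orders = [
            MedicationOrder("P1", d, "amikacin", ref.dose_per_kg * (1.12 if d <= 3 else 1.0), 1)
            for d in range(1, 6)
        ]
        assert nl.summarize_medication(orders, guidelines, 1800, 5) == ("deviation", 3)

    def test_frequency_deviation_does_not_count_as_deviation_day(self, guidelines):
        ref = guidelines.medication_reference("amikacin")
        orders = [MedicationOrder("P1", 1, "amikacin", ref.dose_per_kg, ref.frequency_per_day + 1)]
        category, days = nl.summarize_medication(orders, guidelines, 1800, 3)
        assert (category, days) == ("no_deviation", 0)

    def test_order_beyond_stay_raises(self, guidelines):
        orders = [MedicationOrder("P1", 9, "amikacin", 15.0, 1)]
        with pytest.raises(ValueError, match="beyond stay"):
            nl.summarize_medication(orders, guidelines, 1800, 5)


class TestPipelineConsistency:
    def test_deviation_factors_match_generator_ground_truth(self, small_cohort, small_summaries):
        """The analyzer recomputes exactly the deviation scales the generator drew."""
        _, truth = small_cohort
        tp = truth.per_patient.set_index("patient_id")
        for pid, s in small_summaries.items():
            assert s.deviation_factors["energy_kcal_per_kg"] == pytest.approx(
                tp.loc[pid, "energy_scale"], abs=1e-9
            )
            assert (s.quartile_codes["energy_kcal_per_kg"] == "Q4") == bool(tp.loc[pid, "energy_q4"])
            assert (s.medication_category == "deviation") == bool(tp.loc[pid, "medication_deviation"])

    def test_zero_gap_cohort_conserves_exact_adherence(self, guidelines):
        config = nl.SimulationConfig.zero_deviation(n_patients=60, seed=5)
        cohort, _ = nl.simulate_cohort(config, guidelines)
        summaries = nl.compute_deviation_summaries(cohort, guidelines)
        for s in summaries.values():
            assert all(v == 0.0 for v in s.deviation_factors.values())
            assert all(c == "remaining" for c in s.quartile_codes.values())
            assert s.medication_category in {"not_required", "no_deviation"}
            assert s.medication_deviation_days == 0
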