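import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import nicu_los as nl
from nicu_los.regression import (
    FAMILIES,
    build_design_table,
    compare_families,
    day_effects,
    fit_model,
    ordinary_marginal_means,
    predict_los,
    select_significant,
    validate,
    validate_combinations,
)


def toy_frame(rng, n=120, beta=(0.6, 0.3), sigma=0.25, base=2.0):
    """Two binary factors, log-scale response with known effects."""
    a = rng.random(n) < 0.4
    b = rng.random(n) < 0.5
    z = base + beta[0] * a + beta[1] * b + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "gestation_category": "toy",
            "los_days": np.exp(z),
            "a": a,
            "b": b,
        }
    )


def brute_force_omm(model, factor):
    """Independent enumeration of frequency-weighted marginal means."""
    cats = [t for t in model.design.terms if t.kind == "categorical"]
    target = next(t for t in cats if t.name == factor)
    out = {}
    for level in target.levels:
        total_w, acc = 0.0, 0.0
        others = [t for t in cats if t.name != factor]
        for combo in itertools.product(*(t.levels for t in others)):
            row = {factor: level}
            w = 1.0
            for t, lv in zip(others, combo):
                row[t.name] = lv
                w *= model.level_weights[t.name][lv]
            for t in model.design.terms:
                if t.kind == "continuous":
                    row[t.name] = t.mean
            X = model.design.build(pd.DataFrame([row]))
            z = float((X.to_numpy() @ model.coefficients.to_numpy())[0])
            acc += w * z
            total_w += w
        out[level] = acc / total_w
    return out


class TestModelFamilies:
    @pytest.mark.parametrize("name", list(FAMILIES))
    def test_inverse_of_transform_is_identity(self, name):
        fam = FAMILIES[name]
        y = np.linspace(1.0, 60.0, 50)
        assert np.allclose(fam.inverse(fam.transform(y)), y, atol=1e-12)

    def test_back_transform_clamps_to_one_day(self):
        assert FAMILIES["log"].back_transform(np.array([-3.0]))[0] == 1.0


class TestCompareFamilies:
    def test_single_iteration_deterministic(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        r1 = compare_families(sub, n_iterations=1, seed=3)
        r2 = compare_families(sub, n_iterations=1, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_row_order_invariance(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        shuffled = sub.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            compare_families(sub, seed=5), compare_families(shuffled, seed=5)
        )

    def test_log_generated_data_prefers_log_family(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        ranking = compare_families(sub, seed=11)
        assert ranking["family"].iloc[0] == "log"

    def test_aliased_terms_raise(self):
        rng = np.random.default_rng(0)
        data = toy_frame(rng)
        data["a_copy"] = data["a"]
        with pytest.raises(ValueError, match="aliased|singular"):
            compare_families(data, terms=("a", "a_copy"), seed=0)

    def test_too_small_stratum_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match=">= 20"):
            compare_families(toy_frame(rng, n=10), terms=("a",))


class TestSelectSignificant:
    def test_strong_term_retained(self):
        rng = np.random.default_rng(1)
        data = toy_frame(rng, n=200, beta=(0.5, 0.0))
        model = select_significant(data, "log", terms=("a", "b"))
        assert "a" in model.significant_terms

    def test_null_terms_rarely_selected(self):
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            data = toy_frame(rng, n=150, beta=(0.0, 0.0))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = select_significant(data, "log", terms=("a", "b"))
            hits += len(model.significant_terms)
        # 60 null-term screens at alpha 0.05
        assert hits <= 12

    def test_constant_term_dropped(self):
        rng = np.random.default_rng(2)
        data = toy_frame(rng)
        data["const"] = True
        model = fit_model(data, "log", terms=("a", "const"))
        assert "const" not in model.terms

    def test_no_significant_terms_warns_and_returns_intercept_only(self):
        rng = np.random.default_rng(3)
        data = toy_frame(rng, n=60, beta=(0.0, 0.0))
        with pytest.warns(UserWarning, match="no term significant"):
            model = select_significant(data, "log", terms=("a", "b"))
        assert model.design.terms == []
        expected = np.exp(np.mean(np.log(data["los_days"])))
        assert predict_los(model, data)[0] == pytest.approx(expected)


class TestOrdinaryMarginalMeans:
    def test_matches_brute_force_enumeration(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        model = fit_model(sub, "log", terms=("sepsis", "energy_quartile", "medication_category"))
        for factor in ("sepsis", "energy_quartile", "medication_category"):
            omm = ordinary_marginal_means(model, factor)
            oracle = brute_force_omm(model, factor)
            for level in omm:
                assert omm[level] == pytest.approx(oracle[level], abs=1e-9)

    def test_balanced_design_equals_uniform_emm(self):
        rows = []
        for i, (a, b) in enumerate(itertools.product([False, True], repeat=2)):
            for j in range(10):
                rows.append({"patient_id": f"P{i}_{j}", "los_days": 3.0 + 2 * a + b + 0.1 * j, "a": a, "b": b})
        data = pd.DataFrame(rows).assign(gestation_category="toy")
        model = fit_model(data, "identity", terms=("a", "b"))
        omm = ordinary_marginal_means(model, "a")
        # uniform weights over the balanced nuisance factor
        X = model.design
        for level in (False, True):
            grid = pd.DataFrame([{"a": level, "b": lv} for lv in (False, True)])
            z = X.build(grid).to_numpy() @ model.coefficients.to_numpy()
            assert omm[level] == pytest.approx(z.mean(), abs=1e-8)

    def test_single_factor_omm_is_group_mean(self):
        rng = np.random.default_rng(4)
        data = toy_frame(rng, n=80)
        model = fit_model(data, "log", terms=("a",))
        omm = ordinary_marginal_means(model, "a")
        logged = np.log(data["los_days"])
        for level in (False, True):
            assert omm[level] == pytest.approx(logged[data["a"] == level].mean(), abs=1e-9)

    def test_hand_weighted_two_factor_prediction(self):
        rng = np.random.default_rng(5)
        data = toy_frame(rng, n=400)
        model = fit_model(data, "log", terms=("a", "b"))
        model.level_weights["b"] = {False: 0.75, True: 0.25}
        omm = ordinary_marginal_means(model, "a")
        for level in (False, True):
            grid = pd.DataFrame([{"a": level, "b": False}, {"a": level, "b": True}])
            z = model.design.build(grid).to_numpy() @ model.coefficients.to_numpy()
            assert omm[level] == pytest.approx(0.75 * z[0] + 0.25 * z[1], abs=1e-9)

    def test_weighted_average_identity(self, small_design):
        sub = small_design[small_design.gestation_category == "34-37"]
        model = fit_model(sub, "log", terms=("sepsis", "energy_quartile"))
        for factor in ("sepsis", "energy_quartile"):
            omm = ordinary_marginal_means(model, factor)
            w = model.level_weights[factor]
            grand = sum(w[lv] * omm[lv] for lv in omm)
            other = "energy_quartile" if factor == "sepsis" else "sepsis"
            omm_o = ordinary_marginal_means(model, other)
            w_o = model.level_weights[other]
            grand_o = sum(w_o[lv] * omm_o[lv] for lv in omm_o)
            assert grand == pytest.approx(grand_o, abs=1e-9)

    def test_grid_cap_enforced(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        model = fit_model(sub, "log", terms=("sepsis", "energy_quartile", "medication_category"))
        with pytest.raises(ValueError, match="cap"):
            ordinary_marginal_means(model, "sepsis", grid_cap=3)

    def test_unmodelled_factor_raises(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        model = fit_model(sub, "log", terms=("sepsis",))
        with pytest.raises(KeyError):
            ordinary_marginal_means(model, "energy_quartile")


class TestDayEffects:
    def test_level_at_grand_mean_has_zero_days(self):
        rows = []
        for i in range(40):
            rows.append({"patient_id": f"P{i}", "los_days": 6.0, "a": i % 2 == 0})
        data = pd.DataFrame(rows).assign(gestation_category="toy")
        model = fit_model(data, "log", terms=("a",))
        table = day_effects(model)
        assert set(table.effects["effect_days"]) == {0}

    def test_quartile_effect_shape_mirrors_published_layout(self, small_design):
        """Q4 level positive, remaining negative, shared p-value."""
        sub = small_design[small_design.gestation_category == ">=37"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = select_significant(sub, "log")
        table = day_effects(model)
        eff = table.effects[table.effects["factor"] == "energy_quartile"]
        assert len(eff) == 2
        q4 = int(eff[eff["level"] == "Q4"]["effect_days"].iloc[0])
        rem = int(eff[eff["level"] == "remaining"]["effect_days"].iloc[0])
        assert q4 > 0 and rem <= 0
        assert eff["p_value"].nunique() == 1

    def test_injected_effect_recovered_within_one_day(self, small_cohort, guidelines):
        """~+5-day top-quartile energy effect recovered on a fresh n=800 cohort."""
        config = nl.SimulationConfig(n_patients=800, seed=77)
        cohort, _ = nl.simulate_cohort(config, guidelines)
        summaries = nl.compute_deviation_summaries(cohort, guidelines)
        table = build_design_table(cohort.records, summaries)
        sub = table[table.gestation_category == ">=37"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = select_significant(sub, "log")
        effect = day_effects(model).effect("energy_quartile", "Q4")
        assert abs(effect - 5) <= 1


class TestPrediction:
    def test_intercept_only_log_model_predicts_exp_intercept(self):
        data = pd.DataFrame(
            {"patient_id": ["A", "B"], "gestation_category": "toy", "los_days": [4.0, 9.0]}
        )
        model = fit_model(data, "log", terms=())
        b = float(model.coefficients["Intercept"])
        assert np.allclose(predict_los(model, data), np.exp(b))

    def test_positive_coefficient_orders_predictions(self):
        rng = np.random.default_rng(6)
        data = toy_frame(rng, n=200, beta=(0.7, 0.0))
        model = fit_model(data, "log", terms=("a",))
        grid = pd.DataFrame([{"a": False}, {"a": True}])
        lo, hi = predict_los(model, grid)
        assert hi > lo

    def test_intercept_shift_multiplies_log_predictions(self):
        rng = np.random.default_rng(7)
        data = toy_frame(rng)
        model = fit_model(data, "log", terms=("a",))
        base = predict_los(model, data)
        model.results.params["Intercept"] += 0.3
        shifted = predict_los(model, data)
        assert np.allclose(shifted, base * np.exp(0.3), rtol=1e-9)

    def test_unseen_level_error_and_fallback(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        model = fit_model(sub, "log", terms=("medication_category",))
        new = sub.iloc[[0]].copy()
        new["medication_category"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            predict_los(model, new)
        with pytest.warns(UserWarning, match="mystery"):
            fallback = predict_los(model, new, unseen_level_policy="fallback")
        assert fallback[0] >= 1.0

    def test_noiseless_cohort_predictions_match_ground_truth(self, guidelines):
        config = nl.SimulationConfig(n_patients=400, seed=13, noise_sd_log=1e-6)
        cohort, truth = nl.simulate_cohort(config, guidelines)
        summaries = nl.compute_deviation_summaries(cohort, guidelines)
        table = build_design_table(cohort.records, summaries)
        tp = truth.per_patient.set_index("patient_id")
        for cat in sorted(table.gestation_category.unique()):
            sub = table[table.gestation_category == cat]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_model(sub, "log")
            pred = predict_los(model, sub)
            target = tp.loc[sub.patient_id, "noiseless_los"].to_numpy(float)
            # LOS is recorded in whole (ceiled) days, so fits on the rounded
            # response can sit up to ~2 days above the continuous target
            assert np.max(np.abs(pred - target)) <= 2.1


class TestValidation:
    def test_perfect_predictions_give_rmse_zero_r2_one(self):
        data = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(30)],
                "gestation_category": "toy",
                "los_days": np.exp(2.0 + 0.5 * (np.arange(30) % 2)),
                "a": (np.arange(30) % 2).astype(bool),
            }
        )
        model = fit_model(data, "log", terms=("a",))
        metrics = validate({"toy": model}, data)
        assert metrics["rmse_days"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert metrics["r_squared"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_predictor_at_mean_gives_r2_zero(self):
        data = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C", "D"],
                "gestation_category": "toy",
                "los_days": [4.0, 6.0, 5.0, 5.0],
            }
        )
        model = fit_model(data, "identity", terms=())
        metrics = validate({"toy": model}, data)
        assert metrics["r_squared"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_empty_category_reports_nan_not_zero(self, small_design):
        sub = small_design[small_design.gestation_category == ">=37"]
        model = fit_model(sub, "log", terms=("sepsis",))
        metrics = validate({"ghost": model}, sub)
        assert metrics["n"].iloc[0] == 0 and np.isnan(metrics["rmse_days"].iloc[0])

    def test_combination_grid_has_seven_rows(self, small_design):
        train = small_design[small_design.gestation_category.isin(["34-37", ">=37"])]
        combos = validate_combinations(train, train)
        assert len(combos) == 7
        assert combos["risk_factor_sets"].iloc[0] == "antenatal_perinatal"
        assert np.isfinite(combos[["34-37", ">=37"]].to_numpy(float)).all()
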