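"""Candidate set, AICc ranking, model averaging, VIF and predicted means."""

import numpy as np
import pandas as pd
import pytest

from roostnrg import (
    CandidateModelSpec,
    aicc,
    aicc_rank,
    build_box_day_table,
    build_candidate_set,
    confidence_set_average,
    dee_table,
    filter_for_overheating_model,
    fit_candidates,
    overheating_table,
    predict_means,
    select_models,
    vif_screen,
)
from roostnrg.selection import FittedCandidate, prepare_factors


@pytest.fixture(scope="module")
def box_day_table(small_study):
    dee = dee_table(small_study.grids)
    heat = overheating_table(small_study.grids)
    return build_box_day_table(
        dee, heat, small_study.weather, small_study.bat_counts, small_study.metadata
    )


@pytest.fixture(scope="module")
def endo_fits(box_day_table):
    return fit_candidates(box_day_table, "dee_endothermic")


class TestCandidateSet:
    def test_fourteen_specs(self):
        specs = build_candidate_set()
        assert len(specs) == 14
        assert [s.name for s in specs] == ["null"] + [f"m{i}" for i in range(2, 15)]

    def test_null_model_is_intercept_only(self):
        null = build_candidate_set()[0]
        assert null.terms == ()
        assert null.formula("dee_endothermic") == "dee_endothermic ~ 1"

    def test_m4_terms(self):
        m4 = {s.name: s for s in build_candidate_set()}["m4"]
        assert m4.terms == ("Design", "Placement", "Design:Placement")

    def test_m10_terms(self):
        m10 = {s.name: s for s in build_candidate_set()}["m10"]
        assert m10.terms == (
            "Design", "Placement", "Total_Bats", "Max_Temp", "Max_Wind",
            "Design:Placement", "Design:Total_Bats", "Placement:Max_Temp",
            "Placement:Max_Wind",
        )

    def test_log_response_formula(self):
        m2 = {s.name: s for s in build_candidate_set()}["m2"]
        assert m2.formula("dee_heterothermic") == "np.log(dee_heterothermic) ~ design"


class TestFitCandidates:
    def test_all_candidates_estimable_on_balanced_data(self, endo_fits):
        assert len(endo_fits) == 14
        assert all(f.ok for f in endo_fits)

    def test_identical_row_set_across_candidates(self, endo_fits):
        nobs = {int(f.result.nobs) for f in endo_fits}
        assert len(nobs) == 1

    def test_reference_levels_are_ref_and_open(self, endo_fits):
        m4 = next(f for f in endo_fits if f.spec.name == "m4")
        names = list(m4.result.params.index)
        assert not any("[T.REF]" in n or "[T.open]" in n for n in names)
        assert any("design[T.VR]" in n for n in names)
        assert any("placement[T.east]" in n for n in names)

    def test_deterministic_refit(self, box_day_table):
        spec = [CandidateModelSpec("m2", ("Design",))]
        a = fit_candidates(box_day_table, "dee_endothermic", specs=spec)[0]
        b = fit_candidates(box_day_table, "dee_endothermic", specs=spec)[0]
        assert np.array_equal(a.result.params.values, b.result.params.values)

    def test_poisson_with_forest_rows_rejected(self, box_day_table):
        with pytest.raises(ValueError, match="forest"):
            fit_candidates(box_day_table, "n_overheating_events")

    def test_poisson_fits_after_forest_filter(self, box_day_table):
        table = filter_for_overheating_model(box_day_table)
        fits = fit_candidates(table, "n_overheating_events")
        assert all(f.ok for f in fits)
        over = {f.spec.name: f.overdispersion() for f in fits}
        assert all(v is not None and v > 0 for v in over.values())

    def test_rank_deficient_candidate_flagged_not_fatal(self, box_day_table):
        # remove every VR box from open placements: Design:Placement cell empty
        broken = box_day_table[
            ~((box_day_table["design"] == "VR") & (box_day_table["placement"] == "open"))
        ]
        with pytest.warns(UserWarning, match="not estimable"):
            fits = fit_candidates(broken, "dee_endothermic")
        status = {f.spec.name: f.ok for f in fits}
        assert status["m2"] and not status["m4"]
        ranking = aicc_rank(fits)
        assert "m4" not in set(ranking["name"])

    def test_unknown_response_rejected(self, box_day_table):
        with pytest.raises(ValueError, match="unknown response"):
            fit_candidates(box_day_table, "dee_total")


class TestAicc:
    def test_hand_computed_value(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(200 + 6 + 24 / 46)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)

    def test_equal_models_share_weight(self):
        class Stub:
            def __init__(self):
                self.llf, self.nobs = -100.0, 50
                self.params = pd.Series({"Intercept": 1.0})
                self.bse = pd.Series({"Intercept": 0.1})

        fits = [
            FittedCandidate(CandidateModelSpec(n, ()), Stub(), "poisson", True)
            for n in ("a", "b")
        ]
        ranking = aicc_rank(fits)
        assert np.allclose(ranking["weight"], [0.5, 0.5])
        assert ranking["delta"].iloc[0] == 0.0

    def test_weights_sum_to_one_and_best_delta_zero(self, endo_fits):
        ranking = aicc_rank(endo_fits)
        assert ranking["weight"].sum() == pytest.approx(1.0)
        assert ranking["delta"].iloc[0] == 0.0
        assert ranking["aicc"].is_monotonic_increasing

    def test_ranking_invariant_to_input_order(self, endo_fits):
        forward = aicc_rank(endo_fits)
        backward = aicc_rank(list(reversed(endo_fits)))
        pd.testing.assert_frame_equal(forward, backward)


class TestConfidenceSetAverage:
    def test_single_model_set_returns_its_coefficients(self, box_day_table):
        specs = [CandidateModelSpec("m2", ("Design",))]
        fits = fit_candidates(box_day_table, "dee_endothermic", specs=specs)
        result = confidence_set_average(aicc_rank(fits), fits)
        assert result.confidence_set == ["m2"]
        expected = fits[0].result.params
        got = result.averaged.set_index("term")["estimate"]
        assert np.allclose(got[expected.index], expected.values)

    def test_full_averaging_structural_zero(self):
        class Stub:
            def __init__(self, params, bse, llf):
                self.params = pd.Series(params)
                self.bse = pd.Series(bse)
                self.llf, self.nobs = llf, 200

        # choose llf_b so the AICc gap is exactly 2*ln(0.6/0.4) -> weights 0.6/0.4
        delta = 2 * np.log(0.6 / 0.4)
        a = Stub({"Intercept": 0.0, "x": 1.0}, {"Intercept": 0.1, "x": 0.0}, -100.0)
        llf_b = -(aicc(-100.0, 2, 200) + delta - 2 * 1 - 2 * 1 * 2 / (200 - 1 - 1)) / 2
        b = Stub({"Intercept": 0.0}, {"Intercept": 0.1}, llf_b)
        fits = [
            FittedCandidate(CandidateModelSpec("with_x", ("Max_Temp",)), a, "poisson", True),
            FittedCandidate(CandidateModelSpec("null", ()), b, "poisson", True),
        ]
        ranking = aicc_rank(fits)
        assert np.allclose(ranking["weight"], [0.6, 0.4], atol=1e-9)
        full = confidence_set_average(ranking, fits, level=0.99, method="full")
        assert full.averaged.set_index("term").loc["x", "estimate"] == pytest.approx(0.6)
        conditional = confidence_set_average(ranking, fits, level=0.99, method="conditional")
        assert conditional.averaged.set_index("term").loc["x", "estimate"] == pytest.approx(1.0)

    def test_confidence_set_is_smallest_prefix(self, endo_fits):
        ranking = aicc_rank(endo_fits)
        result = confidence_set_average(ranking, endo_fits)
        weights = ranking.set_index("name")["weight"]
        cum = weights.loc[result.confidence_set].sum()
        assert cum >= 0.90
        assert weights.loc[result.confidence_set[:-1]].sum() < 0.90

    def test_competing_models_within_two_aicc(self, endo_fits):
        ranking = aicc_rank(endo_fits)
        result = confidence_set_average(ranking, endo_fits)
        deltas = ranking.set_index("name")["delta"]
        assert all(deltas[name] <= 2.0 for name in result.competing)

    def test_informative_sign_rule(self):
        from roostnrg.selection import ModelSelectionResult  # noqa: F401

        class Stub:
            def __init__(self):
                self.params = pd.Series({"pos": 0.3, "straddle": 0.05})
                self.bse = pd.Series({"pos": 0.1, "straddle": 0.1})
                self.llf, self.nobs = -10.0, 100

        fits = [FittedCandidate(CandidateModelSpec("m", ()), Stub(), "poisson", True)]
        result = confidence_set_average(aicc_rank(fits), fits)
        flags = result.averaged.set_index("term")["informative"]
        assert bool(flags["pos"]) is True       # CI (0.156, 0.444) excludes 0
        assert bool(flags["straddle"]) is False  # CI (-0.094, 0.194) straddles 0


class TestVif:
    def test_independent_predictors_near_one(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        out = vif_screen(table, ["a", "b"])
        assert np.allclose(out["vif"], 1.0, atol=0.1)

    def test_duplicated_predictor_flagged_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        table = pd.DataFrame({"a": x, "b": x})
        out = vif_screen(table, ["a", "b"])
        assert out["collinear"].all()
        assert np.isinf(out["vif"]).all()

    def test_single_predictor_is_one_by_convention(self):
        table = pd.DataFrame({"a": np.arange(50.0)})
        out = vif_screen(table, ["a"])
        assert out["vif"].tolist() == [1.0]

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(2)
        a = rng.standard_normal(2000)
        b = 0.7 * a + rng.standard_normal(2000)
        c = rng.standard_normal(2000)
        table = pd.DataFrame({"a": a, "b": b, "c": c})
        ours = vif_screen(table, ["a", "b", "c"]).set_index("predictor")["vif"]
        X = np.column_stack([np.ones(2000), a, b, c])
        for j, name in enumerate(["a", "b", "c"], start=1):
            assert ours[name] == pytest.approx(variance_inflation_factor(X, j))

    def test_study_predictors_pass_screen(self, box_day_table):
        out = vif_screen(
            box_day_table, ["design", "placement", "total_bats", "max_temp", "max_wind"]
        )
        assert out["vif"].max() < 2.0  # balanced layout keeps predictors orthogonal


class TestPredictMeans:
    def test_intercept_only_returns_grand_mean(self, box_day_table):
        fits = fit_candidates(
            box_day_table, "dee_endothermic",
            specs=[CandidateModelSpec("null", ())],
        )
        means = predict_means(fits[0], box_day_table, "design")
        grand = box_day_table["dee_endothermic"].mean()
        assert np.allclose(means["mean"], grand)

    def test_single_factor_model_reads_off_coefficients(self, box_day_table):
        fits = fit_candidates(
            box_day_table, "dee_endothermic",
            specs=[CandidateModelSpec("m2", ("Design",))],
        )
        means = predict_means(fits[0], box_day_table, "design").set_index("design")
        params = fits[0].result.params
        assert means.loc["REF", "mean"] == pytest.approx(params["Intercept"])
        assert means.loc["VR", "mean"] == pytest.approx(
            params["Intercept"] + params["design[T.VR]"]
        )

    def test_balanced_two_factor_matches_cell_enumeration(self, box_day_table):
        fits = fit_candidates(
            box_day_table, "dee_endothermic",
            specs=[CandidateModelSpec("m4", ("Design", "Placement", "Design:Placement"))],
        )
        means = predict_means(fits[0], box_day_table, "design").set_index("design")
        data = prepare_factors(box_day_table)
        # brute-force: predict each (design, placement) cell and average by hand
        design_levels = list(data["design"].cat.categories)
        placement_levels = list(data["placement"].cat.categories)
        for design in ("REF", "EJW"):
            cells = []
            for placement in placement_levels:
                cell = pd.DataFrame(
                    {
                        "design": pd.Categorical([design], categories=design_levels),
                        "placement": pd.Categorical([placement], categories=placement_levels),
                    }
                )
                cells.append(float(fits[0].result.predict(cell)[0]))
            assert means.loc[design, "mean"] == pytest.approx(np.mean(cells))

    def test_poisson_means_on_count_scale(self, box_day_table):
        table = filter_for_overheating_model(box_day_table)
        fits = fit_candidates(
            table, "n_overheating_events",
            specs=[CandidateModelSpec("m2", ("Design",))],
        )
        means = predict_means(fits[0], table, "design")
        assert (means["mean"] >= 0).all()
        observed = table.groupby("design", observed=True)["n_overheating_events"].mean()
        # single-factor Poisson: fitted level means equal observed level means
        assert np.allclose(
            means.set_index("design")["mean"], observed[means["design"]], rtol=1e-6
        )

    def test_log_response_backtransforms_labelled(self, box_day_table):
        fits = fit_candidates(
            box_day_table, "dee_heterothermic",
            specs=[CandidateModelSpec("m3", ("Placement",))],
        )
        means = predict_means(
            fits[0], box_day_table, "placement", backtransform_log=True
        )
        assert {"mean", "mean_backtransformed", "mean_backtransformed_biascorr"} <= set(
            means.columns
        )
        assert (means["mean_backtransformed_biascorr"] > means["mean_backtransformed"]).all()


class TestEndToEndSelection:
    def test_truth_structure_recovered_from_m3_generator(self, box_day_table):
        # refit on a response generated from a placement-only (m3) truth
        rng = np.random.default_rng(99)
        table = box_day_table.copy()
        effect = {"open": 0.0, "east": 1.0, "west": 2.0, "forest": 5.0}
        table["dee_endothermic"] = (
            20.0
            + table["placement"].astype(str).map(effect)
            + rng.normal(0, 1.0, len(table))
        )
        result = select_models(table, "dee_endothermic")
        top = result.ranking.iloc[0]["name"]
        nesting_m3 = {"m3", "m4", "m6", "m8", "m10", "m12", "m14"}
        assert top in nesting_m3
        deltas = result.ranking.set_index("name")["delta"]
        assert deltas["m3"] <= 2.0 or top == "m3"

    def test_select_models_runs_all_three_responses(self, box_day_table):
        endo = select_models(box_day_table, "dee_endothermic")
        hetero = select_models(box_day_table, "dee_heterothermic")
        heat = select_models(
            filter_for_overheating_model(box_day_table), "n_overheating_events"
        )
        for result in (endo, hetero, heat):
            assert result.ranking["weight"].sum() == pytest.approx(1.0)
            assert len(result.confidence_set) >= 1
            assert {"term", "estimate", "se", "ci_low", "ci_high", "informative"} <= set(
                result.averaged.columns
            )
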