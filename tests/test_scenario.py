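"""Scenario construction and ensemble projection physics."""

import numpy as np
import pytest

from prairie_ch4.landscape_model import (
    FrostFreeWindow,
    TrueResponsePredictor,
    delineate_wetlands,
    derive_predictor_stack,
    predict_pixel_flux,
    rates_to_grid,
)
from prairie_ch4.scenario import (
    ScenarioMember,
    ScenarioSpec,
    apply_scenario,
    fold_change,
    make_ensemble_members,
    run_ensemble,
)
from prairie_ch4.truth import TrueResponse
from prairie_ch4.upscale import integrate_annual, summarize_region
from prairie_ch4.wetlandscape import WetlandscapeConfig, generate_wetlandscape

WINDOW = FrostFreeWindow(60, 325)


def uniform_member(delta: float, window=WINDOW, mid="m"):
    return ScenarioMember(mid, {m: delta for m in range(1, 13)}, window)


@pytest.fixture(scope="module")
def world():
    cfg = WetlandscapeConfig(grid_shape=(128, 128), n_wetlands=80)
    wet = generate_wetlandscape(cfg, seed=5)
    from dataclasses import replace
    dry = generate_wetlandscape(replace(cfg, wetness=0.6), seed=5)
    return {"wet": wet, "dry": dry}


def historical_summary(truth, world_one, window=WINDOW):
    stack = world_one.rasters
    wl = delineate_wetlands(stack)
    pred = derive_predictor_stack(stack, wl, window)
    flux = predict_pixel_flux(TrueResponsePredictor(truth), pred)
    rates = rates_to_grid(pred, flux, stack.n_steps, stack.grid_shape)
    annual = integrate_annual(rates, stack, window)
    return summarize_region(annual, rates, wl, stack, window)


class TestApplyScenario:
    def test_identity_for_zero_deltas(self, world):
        stack = world["wet"].rasters
        out, win = apply_scenario(stack, WINDOW, uniform_member(0.0))
        assert win == WINDOW
        assert np.array_equal(out.temperature, stack.temperature)
        assert np.array_equal(out.water_mask, stack.water_mask)

    def test_uniform_delta_shifts_every_cell(self, world):
        stack = world["wet"].rasters
        out, _ = apply_scenario(stack, WINDOW, uniform_member(2.7))
        assert np.allclose(out.temperature - stack.temperature, 2.7)

    def test_season_extension_step_count(self, world):
        """266 -> 323 frost-free days adds ceil(57/14) = 5 biweekly steps."""
        stack = world["wet"].rasters
        hist = FrostFreeWindow(60, 325)          # 266 days -> 19 steps
        future = FrostFreeWindow(32, 354)        # 323 days -> 24 steps
        out, win = apply_scenario(stack, hist, uniform_member(0.0, future))
        assert out.n_steps - stack.n_steps == 5
        assert win.length == 323

    def test_shoulder_steps_replicate_boundaries(self, world):
        stack = world["wet"].rasters
        future = FrostFreeWindow(32, 354)
        out, _ = apply_scenario(stack, WINDOW, uniform_member(0.0, future))
        assert np.array_equal(out.water_mask[0], stack.water_mask[0])
        assert np.array_equal(out.water_mask[-1], stack.water_mask[-1])
        assert np.array_equal(out.ndvi[0], stack.ndvi[0])

    def test_shorter_window_rejected(self, world):
        stack = world["wet"].rasters
        with pytest.raises(ValueError, match="shorter"):
            apply_scenario(stack, WINDOW,
                           uniform_member(1.0, FrostFreeWindow(100, 200)))


class TestRunEnsemble:
    def test_zero_delta_reproduces_historical_exactly(self, world):
        truth = TrueResponse()
        oracle = TrueResponsePredictor(truth)
        spec = ScenarioSpec("null", "wet", "moderate",
                            (uniform_member(0.0),))
        res = run_ensemble(oracle, {"wet": world["wet"].rasters}, WINDOW,
                           [spec])[0]
        hist = historical_summary(truth, world["wet"])
        assert res.mean_total_Gg == hist.total_emission_Gg

    def test_identical_members_zero_cv(self, world):
        truth = TrueResponse()
        members = tuple(uniform_member(1.5, mid=f"m{i}") for i in range(13))
        spec = ScenarioSpec("same", "wet", "moderate", members)
        res = run_ensemble(TrueResponsePredictor(truth),
                           {"wet": world["wet"].rasters}, WINDOW, [spec])[0]
        assert res.cv_percent == 0.0
        assert res.member_range_Gg[0] == res.member_range_Gg[1]

    def test_q10_oracle_fold_change(self, world):
        """Uniform +3.5 degC with the q10=2 generating response (temperature
        lag disabled) multiplies total emission by 2^0.35 exactly."""
        truth = TrueResponse(q10_true=2.0, lag_weights=(0.3, 0.0, 0.3))
        oracle = TrueResponsePredictor(truth)
        spec = ScenarioSpec("warm", "wet", "moderate",
                            (uniform_member(3.5),))
        res = run_ensemble(oracle, {"wet": world["wet"].rasters}, WINDOW,
                           [spec])[0]
        hist = historical_summary(truth, world["wet"])
        fold = res.mean_total_Gg / hist.total_emission_Gg
        assert fold == pytest.approx(2**0.35, rel=1e-6)

    def test_warming_never_decreases_total_with_monotone_model(self, world):
        truth = TrueResponse()
        oracle = TrueResponsePredictor(truth)
        hist = historical_summary(truth, world["dry"])
        spec = ScenarioSpec("warm", "dry", "severe", (uniform_member(2.0),))
        res = run_ensemble(oracle, {"dry": world["dry"].rasters}, WINDOW,
                           [spec])[0]
        assert res.mean_total_Gg >= hist.total_emission_Gg

    def test_wet_bookend_exceeds_dry_when_superset(self, world):
        truth = TrueResponse()
        oracle = TrueResponsePredictor(truth)
        member = (uniform_member(1.0),)
        specs = [ScenarioSpec("w", "wet", "moderate", member),
                 ScenarioSpec("d", "dry", "moderate", member)]
        stacks = {k: v.rasters for k, v in world.items()}
        res = {r.spec.scenario_id: r for r in
               run_ensemble(oracle, stacks, WINDOW, specs)}
        assert res["w"].mean_total_Gg > res["d"].mean_total_Gg

    def test_member_order_invariance(self, world):
        truth = TrueResponse()
        oracle = TrueResponsePredictor(truth)
        members = make_ensemble_members("moderate", WINDOW, n_members=3, seed=1)
        stacks = {"wet": world["wet"].rasters}
        a = run_ensemble(oracle, stacks, WINDOW,
                         [ScenarioSpec("a", "wet", "moderate", members)])[0]
        b = run_ensemble(oracle, stacks, WINDOW,
                         [ScenarioSpec("b", "wet", "moderate", members[::-1])])[0]
        assert a.mean_total_Gg == pytest.approx(b.mean_total_Gg, rel=1e-12)
        assert a.cv_percent == pytest.approx(b.cv_percent, rel=1e-9)

    def test_missing_bookend_and_failing_member(self, world):
        oracle = TrueResponsePredictor(TrueResponse())
        spec = ScenarioSpec("x", "dry", "moderate", (uniform_member(0.0),))
        with pytest.raises(KeyError, match="bookend"):
            run_ensemble(oracle, {"wet": world["wet"].rasters}, WINDOW, [spec])

        class Broken:
            def predict_records(self, records):
                raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="member m"):
            run_ensemble(Broken(), {"dry": world["dry"].rasters}, WINDOW,
                         [spec])


class TestMembersAndFoldChange:
    def test_member_generation_contract(self):
        members = make_ensemble_members("severe", WINDOW, n_members=13, seed=3)
        assert len(members) == 13
        for m in members:
            assert m.frost_free.length >= WINDOW.length
            assert set(m.monthly_deltas) == set(range(1, 13))
        mean_warming = np.mean([np.mean(list(m.monthly_deltas.values()))
                                for m in members])
        assert mean_warming == pytest.approx(2.7, abs=0.6)

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValueError):
            make_ensemble_members("extreme", WINDOW)

    def test_fold_change_table_arithmetic(self, world):
        """Future totals over a dry/wet baseline reproduce hand ratios:
        e.g. (710.4+1270.9)/2 over (351.8+620.7)/2 = 2.04."""
        from prairie_ch4.upscale import EmissionSummary

        def summ(total, scen):
            return EmissionSummary(
                region="r", scenario=scen, total_emission_Gg=total,
                mean_flux_rate_mg_m2_h=1.0, growing_season_days=266,
                inundated_area_km2=1.0, mean_inundated_area_km2=1.0,
                wetland_count=1, mean_ndvi=0.2, mean_soil_temp_C=12.0,
                mean_hydroperiod_days=120.0)

        def fake_result(pathway, bookend, total):
            spec = ScenarioSpec(f"{pathway}-{bookend}", bookend, pathway,
                                (uniform_member(1.0),))
            from prairie_ch4.scenario import ScenarioResult
            return ScenarioResult(spec=spec, member_summaries=(),
                                  mean_total_Gg=total, cv_percent=0.0,
                                  member_range_Gg=(total, total))

        results = [fake_result("moderate", "dry", 710.4),
                   fake_result("moderate", "wet", 1270.9),
                   fake_result("severe", "dry", 971.5),
                   fake_result("severe", "wet", 1669.6)]
        folds = fold_change(results, summ(351.8, "dry"), summ(620.7, "wet"))
        assert folds["moderate"]["fold_change"] == pytest.approx(2.04, abs=0.01)
        assert folds["severe"]["fold_change"] == pytest.approx(2.72, abs=0.01)

    def test_identity_fold_change(self, world):
        truth = TrueResponse()
        oracle = TrueResponsePredictor(truth)
        dry = historical_summary(truth, world["dry"])
        wet = historical_summary(truth, world["wet"])
        specs = [ScenarioSpec("m-d", "dry", "moderate", (uniform_member(0.0),)),
                 ScenarioSpec("m-w", "wet", "moderate", (uniform_member(0.0),))]
        stacks = {k: v.rasters for k, v in world.items()}
        res = run_ensemble(oracle, stacks, WINDOW, specs)
        folds = fold_change(res, dry, wet)
        assert folds["moderate"]["fold_change"] == pytest.approx(1.0, rel=1e-12)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec("s", "damp", "moderate", (uniform_member(0.0),))
        with pytest.raises(ValueError):
            ScenarioSpec("s", "dry", "moderate", ())
        with pytest.raises(ValueError):
            ScenarioMember("m", {1: np.inf}, WINDOW)
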