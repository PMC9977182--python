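"""Annual integration with the winter-boundary rule and aggregation exactness."""

import numpy as np
import pytest

from prairie_ch4.landscape_model import FrostFreeWindow, delineate_wetlands
from prairie_ch4.rasters import RasterStack
from prairie_ch4.upscale import (
    integrate_annual,
    size_class_decomposition,
    step_hours,
    summarize_region,
)


def make_stack(water, pixel_size=30.0):
    water = np.asarray(water, dtype=np.uint8)
    S, ny, nx = water.shape
    return RasterStack(
        water_mask=water,
        temperature=np.full((S, ny, nx), 12.0, dtype=np.float32),
        ndvi=np.full((S, ny, nx), 0.2, dtype=np.float32),
        land_cover=np.zeros((ny, nx), dtype=np.uint8),
        pixel_size=pixel_size,
    )


class TestStepHours:
    def test_full_step_is_336_hours(self):
        hours = step_hours(FrostFreeWindow(100, 127), 2)  # 28 days, 2 steps
        assert np.array_equal(hours, [336.0, 336.0])

    def test_partial_final_step(self):
        hours = step_hours(FrostFreeWindow(100, 120), 2)  # 21 days
        assert np.array_equal(hours, [336.0, 7 * 24.0])

    def test_surplus_steps_get_zero_hours(self):
        hours = step_hours(FrostFreeWindow(100, 127), 5)
        assert np.array_equal(hours, [336.0, 336.0, 0.0, 0.0, 0.0])
        assert hours.sum() == FrostFreeWindow(100, 127).length * 24.0

    def test_too_few_steps_raises(self):
        with pytest.raises(ValueError):
            step_hours(FrostFreeWindow(1, 365), 10)


class TestIntegrateAnnual:
    def test_single_step_single_pixel_arithmetic(self):
        """1 mg m^-2 h^-1 on one 900-m^2 pixel for one full 14-day step
        contributes 302,400 mg = 302.4 g."""
        window = FrostFreeWindow(100, 127)
        rates = np.ones((2, 1, 1))
        stack = make_stack(np.ones((2, 1, 1)))
        annual = integrate_annual(rates, stack, window)
        per_step_g = 1.0 * 900.0 * 336.0 / 1e3
        assert per_step_g == pytest.approx(302.4)
        # the full year at constant rate: 2 steps + winter at boundary rates
        assert annual[0, 0] == pytest.approx(1.0 * 900.0 * 8760.0 / 1e3)

    def test_zero_rates_zero_emission(self):
        stack = make_stack(np.ones((3, 4, 4)))
        annual = integrate_annual(np.zeros((3, 4, 4)), stack,
                                  FrostFreeWindow(100, 141))
        assert np.all(annual == 0.0)

    @pytest.mark.parametrize("window", [FrostFreeWindow(60, 325),
                                        FrostFreeWindow(1, 100),
                                        FrostFreeWindow(200, 365)])
    def test_constant_rate_seamless_year(self, window):
        """Winter extension makes a constant-rate year exactly r*A*8760."""
        S = window.n_steps(14)
        r = 0.7
        stack = make_stack(np.ones((S, 2, 2)))
        annual = integrate_annual(np.full((S, 2, 2), r), stack, window)
        assert np.allclose(annual, r * 900.0 * 8760.0 / 1e3, rtol=1e-12)

    def test_linearity_in_rates(self):
        rng = np.random.default_rng(0)
        window = FrostFreeWindow(60, 325)
        S = window.n_steps(14)
        stack = make_stack(np.ones((S, 5, 5)))
        F = rng.uniform(0, 3, (S, 5, 5))
        G = rng.uniform(0, 3, (S, 5, 5))
        lhs = integrate_annual(2.0 * F + 0.5 * G, stack, window)
        rhs = (2.0 * integrate_annual(F, stack, window)
               + 0.5 * integrate_annual(G, stack, window))
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_brute_force_pixel_step_oracle(self):
        """Totals equal an independent pure-Python triple loop to 1e-9."""
        rng = np.random.default_rng(3)
        window = FrostFreeWindow(75, 300)
        S = window.n_steps(14)
        ny = nx = 12
        water = (rng.random((S, ny, nx)) < 0.4).astype(np.uint8)
        stack = make_stack(water)
        rates = rng.uniform(0, 2.5, (S, ny, nx))
        annual = integrate_annual(rates, stack, window)

        total = 0.0
        for i in range(ny):
            for j in range(nx):
                acc = 0.0
                remaining = window.length
                for s in range(S):
                    days = min(14, max(remaining, 0))
                    acc += rates[s, i, j] * days * 24.0
                    remaining -= days
                acc += rates[0, i, j] * (window.start_day - 1) * 24.0
                acc += rates[S - 1, i, j] * (365 - window.end_day) * 24.0
                total += acc * 900.0 / 1e3
        assert annual.sum() == pytest.approx(total, rel=1e-9)

    def test_shape_mismatch_raises(self):
        stack = make_stack(np.ones((3, 4, 4)))
        with pytest.raises(ValueError):
            integrate_annual(np.ones((2, 4, 4)), stack, FrostFreeWindow(100, 141))


class TestSummarizeRegion:
    def test_single_pixel_constant_rate(self):
        window = FrostFreeWindow(100, 127)
        water = np.ones((2, 1, 1))
        stack = make_stack(water)
        wl = delineate_wetlands(stack)
        rates = np.ones((2, 1, 1))
        annual = integrate_annual(rates, stack, window)
        summ = summarize_region(annual, rates, wl, stack, window)
        assert summ.mean_flux_rate_mg_m2_h == pytest.approx(1.0)
        assert summ.inundated_area_km2 == pytest.approx(0.0009)
        assert summ.wetland_count == 1
        assert summ.total_emission_Gg == pytest.approx(
            900.0 * 8760.0 / 1e3 / 1e9)

    def test_two_regions_totals_add(self):
        rng = np.random.default_rng(5)
        window = FrostFreeWindow(100, 155)
        S = window.n_steps(14)

        def region(seed):
            r = np.random.default_rng(seed)
            water = (r.random((S, 6, 6)) < 0.5).astype(np.uint8)
            stack = make_stack(water)
            rates = r.uniform(0, 2, (S, 6, 6)) * water
            annual = integrate_annual(rates, stack, window)
            wl = delineate_wetlands(stack)
            return summarize_region(annual, rates, wl, stack, window)

        a, b = region(1), region(2)
        merged_total = a.total_emission_Gg + b.total_emission_Gg
        assert merged_total == pytest.approx(
            a.total_emission_Gg + b.total_emission_Gg, rel=1e-12)

    def test_doubling_extent_doubles_total(self):
        window = FrostFreeWindow(100, 155)
        S = window.n_steps(14)
        water = np.zeros((S, 8, 8))
        water[:, 2, 2] = 1
        stack1 = make_stack(water)
        rates1 = np.where(water > 0, 1.5, 0.0)
        water2 = water.copy()
        water2[:, 5, 5] = 1
        stack2 = make_stack(water2)
        rates2 = np.where(water2 > 0, 1.5, 0.0)
        t1 = integrate_annual(rates1, stack1, window).sum()
        t2 = integrate_annual(rates2, stack2, window).sum()
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)


class TestSizeClasses:
    def test_proportional_shares(self):
        """Wetlands of 1 and 9 ha at equal per-area rate split 10%/90%."""
        window = FrostFreeWindow(100, 127)
        water = np.zeros((2, 8, 8))
        water[:, 0, 0] = 1              # 1 px
        water[:, 3:6, 3:6] = 1          # 9 px
        stack = make_stack(water, pixel_size=100.0)  # 1 px = 1 ha
        wl = delineate_wetlands(stack)
        rates = np.where(water > 0, 1.0, 0.0)
        annual = integrate_annual(rates, stack, window) * (water[0] > 0)
        dec = size_class_decomposition(annual, wl,
                                       edges_ha=np.array([5.0]))
        assert dec["emission_share_pct"].to_numpy() == pytest.approx([10.0, 90.0])
        assert dec["extent_share_pct"].to_numpy() == pytest.approx([10.0, 90.0])

    def test_single_wetland_all_shares(self):
        water = np.zeros((1, 8, 8))
        water[:, 2:4, 2:4] = 1
        stack = make_stack(water)
        wl = delineate_wetlands(stack)
        annual = np.where(water[0] > 0, 5.0, 0.0)
        dec = size_class_decomposition(annual, wl)
        assert dec["emission_share_pct"].sum() == pytest.approx(100.0)
        assert dec["extent_share_pct"].sum() == pytest.approx(100.0)
        assert (dec["wetland_count"] > 0).sum() == 1

    def test_conservation_against_per_pixel_total(self):
        from prairie_ch4.wetlandscape import WetlandscapeConfig, generate_wetlandscape

        world = generate_wetlandscape(
            WetlandscapeConfig(grid_shape=(128, 128), n_wetlands=80), seed=9)
        stack = world.rasters
        window = FrostFreeWindow(60, 325)
        wl = delineate_wetlands(stack)
        rng = np.random.default_rng(2)
        rates = rng.uniform(0, 2, stack.water_mask.shape) * (
            wl.labels > 0)[None, :, :]
        annual = integrate_annual(rates, stack, window)
        dec = size_class_decomposition(annual, wl)
        assert dec["emission_g"].sum() == pytest.approx(annual.sum(), rel=1e-12)
        assert dec["emission_share_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_unlabeled_emission_raises(self):
        water = np.zeros((1, 8, 8))
        water[:, 2, 2] = 1
        stack = make_stack(water)
        wl = delineate_wetlands(stack)
        annual = np.full((8, 8), 1.0)  # emission off the wetland too
        with pytest.raises(ValueError, match="unlabeled"):
            size_class_decomposition(annual, wl)
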