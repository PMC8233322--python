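"""Daily/seasonal/regional flux model and the crust-depth evolution."""

import numpy as np
import pytest

from crustflux.fluxes import (
    Catchment,
    CrustDepthModel,
    accumulation_vs_export,
    carbon_flux,
    crust_depth,
    daily_cell_flux,
    delivery_fraction,
    regional_upscale,
    seasonal_export,
    specific_fluxes,
)
from crustflux.hydraulics import CrustProperties, darcian_velocity, specific_discharge
from crustflux.synthetic import SyntheticConfig, gen_catchment_table

STUDY_CATCHMENT = Catchment(bank_area_m2=6.84e4)


class TestDailyFlux:
    def test_study_site_flux(self, crust):
        q = specific_discharge(darcian_velocity(crust), crust)
        flux = daily_cell_flux(q, STUDY_CATCHMENT.bank_length, 2.28e4)
        assert flux == pytest.approx(2.80e12, rel=0.01)

    def test_zero_abundance(self):
        assert daily_cell_flux(0.0018, 6.84e4, 0.0) == 0.0

    def test_maximum_velocity_case(self):
        crust_max = CrustProperties(K=1.3)
        q = specific_discharge(darcian_velocity(crust_max), crust_max)
        flux = daily_cell_flux(q, STUDY_CATCHMENT.bank_length, 2.28e4)
        assert flux == pytest.approx(1.27e13, rel=0.03)

    def test_linear_in_abundance(self, crust):
        q = specific_discharge(darcian_velocity(crust), crust)
        f1 = daily_cell_flux(q, 6.84e4, 1e4)
        f2 = daily_cell_flux(q, 6.84e4, 2e4)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)


class TestSpecificFluxes:
    def test_catchment_area_derived_from_bank_fraction(self):
        assert STUDY_CATCHMENT.area_km2 == pytest.approx(6.84e4 / 0.14 / 1e6, rel=1e-12)

    def test_per_km2_and_per_bank_m2(self):
        per_km2, per_m2 = specific_fluxes(2.80e12, STUDY_CATCHMENT)
        assert per_km2 == pytest.approx(5.73e12, rel=0.01)
        assert per_m2 == pytest.approx(4.1e7, rel=0.01)

    def test_zero_flux(self):
        assert specific_fluxes(0.0, STUDY_CATCHMENT) == (0.0, 0.0)


class TestCarbonFlux:
    def test_all_bacteria_constant_low(self):
        got = carbon_flux(5.73e12, (1, 0, 0, 0, 0, 0), "constant_low")
        assert got == pytest.approx(6.3e-5, rel=0.01)

    def test_zero_flux(self, proportions):
        assert carbon_flux(0.0, proportions, "allometric") == 0.0

    def test_printed_envelope_within_order_of_magnitude(self, proportions):
        """The minimum (constant-low, <=15 um) and maximum (biovolume-ratio,
        incl. >15 um) method results under the synthetic size mix fall within
        an order of magnitude of the printed 8.36e-5 and 0.055 kg C/km2/d
        conservative-velocity band."""
        lo = carbon_flux(5.73e12, proportions, "constant_low")
        hi = carbon_flux(5.73e12, proportions, "biovolume_ratio", include_large_algae=True)
        assert abs(np.log10(lo / 8.36e-5)) < 1.0
        assert abs(np.log10(hi / 0.055)) < 1.0
        assert lo < hi


class TestCrustDepth:
    def test_short_duration_peak(self):
        assert crust_depth(196.0, 20.0) == pytest.approx(0.0076 * 20, rel=1e-9)

    def test_long_duration_plateaus(self):
        assert crust_depth(196.0, 68.0) == pytest.approx(0.29, rel=1e-9)

    def test_zero_outside_window(self):
        assert crust_depth(100.0, 68.0) == 0.0
        assert crust_depth(300.0, 68.0) == 0.0

    def test_zero_at_window_edges(self):
        assert crust_depth(196.0 - 34.0, 68.0) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_about_centre(self):
        for off in (5.0, 15.0, 30.0):
            assert crust_depth(196 - off, 68.0) == pytest.approx(crust_depth(196 + off, 68.0))

    def test_model_consistency_enforced(self):
        with pytest.raises(ValueError):
            CrustDepthModel(d_max=0.29, growth_coeff=0.01, plateau_threshold=38.0)


class TestSeasonalExport:
    def test_2014_season_magnitude(self, crust):
        led = seasonal_export(STUDY_CATCHMENT, crust, 2.28e4)
        assert led.seasonal_cells == pytest.approx(1.4e14, rel=0.20)

    def test_zero_duration(self, crust):
        cat = Catchment(bank_area_m2=6.84e4, b_i=0.0)
        led = seasonal_export(cat, crust, 2.28e4)
        assert led.seasonal_cells == 0.0

    def test_bounded_by_daily_flux_times_duration(self, crust):
        led = seasonal_export(STUDY_CATCHMENT, crust, 2.28e4)
        assert led.seasonal_cells <= led.cells_per_day * 68.0

    def test_doubling_short_duration_more_than_doubles_export(self, crust):
        led15 = seasonal_export(Catchment(bank_area_m2=6.84e4, b_i=15.0), crust, 2.28e4)
        led30 = seasonal_export(Catchment(bank_area_m2=6.84e4, b_i=30.0), crust, 2.28e4)
        assert led30.seasonal_cells > 2.0 * led15.seasonal_cells

    def test_linear_in_abundance(self, crust):
        a = seasonal_export(STUDY_CATCHMENT, crust, 1e4)
        b = seasonal_export(STUDY_CATCHMENT, crust, 3e4)
        assert b.seasonal_cells == pytest.approx(3 * a.seasonal_cells, rel=1e-12)

    def test_halving_bank_fraction_halves_export(self, crust):
        full = seasonal_export(
            Catchment(area_km2=0.4886, bank_fraction=0.14), crust, 2.28e4
        )
        half = seasonal_export(
            Catchment(area_km2=0.4886, bank_fraction=0.07), crust, 2.28e4
        )
        assert half.seasonal_cells == pytest.approx(0.5 * full.seasonal_cells, rel=1e-12)

    def test_algae_inclusion_never_decreases_carbon(self, crust, proportions):
        led = seasonal_export(STUDY_CATCHMENT, crust, 2.28e4, proportions=proportions)
        for method in ("constant_low", "constant_high", "allometric", "biovolume_ratio"):
            assert (
                led.seasonal_carbon_kg[(method, "incl_gt15")]
                >= led.seasonal_carbon_kg[(method, "le15")]
            )


class TestBalance:
    def test_best_estimate_accumulates(self):
        res = accumulation_vs_export(0.07, 0.01)
        assert res.net == pytest.approx(0.06)
        assert res.accumulating

    def test_equal_rates_not_accumulating(self):
        res = accumulation_vs_export(0.5, 0.5)
        assert res.net == 0.0
        assert not res.accumulating

    def test_combined_habitat_estimate_accumulates(self):
        assert accumulation_vs_export(0.82, 0.25).accumulating


class TestRegionalUpscale:
    def test_duplicated_catchment_additivity(self, crust, proportions):
        import pandas as pd

        one = pd.DataFrame(
            {"catchment_id": ["c0"], "area_km2": [0.5], "bank_fraction": [0.14], "b_i_days": [68.0]}
        )
        five = pd.concat([one] * 5, ignore_index=True)
        _, s1 = regional_upscale(one, crust, 2.28e4, proportions=proportions)
        _, s5 = regional_upscale(five, crust, 2.28e4, proportions=proportions)
        assert s5["total_seasonal_cells"] == pytest.approx(5 * s1["total_seasonal_cells"], rel=1e-12)
        assert s5["total_seasonal_carbon_kg_le15"] == pytest.approx(
            5 * s1["total_seasonal_carbon_kg_le15"], rel=1e-12
        )

    def test_zero_durations_zero_totals(self, crust):
        df = gen_catchment_table(
            SyntheticConfig(seed=1, n_catchments=10, bare_ice_duration_range=(1e-9, 1e-9))
        )
        df["b_i_days"] = 0.0
        table, summary = regional_upscale(df, crust, 2.28e4)
        assert summary["total_seasonal_cells"] == 0.0

    def test_missing_duration_skipped_with_count(self, crust):
        df = gen_catchment_table(SyntheticConfig(seed=2, n_catchments=10))
        df.loc[3, "b_i_days"] = np.nan
        table, summary = regional_upscale(df, crust, 2.28e4)
        assert summary["n_catchments"] == 9
        assert summary["n_skipped"] == 1

    def test_regional_carbon_scale(self, crust, proportions):
        """795 synthetic catchments with durations 40-90 d give a mean
        per-km2 seasonal carbon on the printed kg-per-km2 order."""
        df = gen_catchment_table(SyntheticConfig(seed=3, n_catchments=795))
        _, summary = regional_upscale(df, crust, 2.28e4, proportions=proportions)
        mean_per_km2 = summary["mean_seasonal_carbon_kg_per_km2_le15"]
        assert 1.0 < mean_per_km2 < 100.0


class TestDeliveryFraction:
    def test_monotone_in_velocity(self):
        d = np.array([[0.5, 2.0, 5.0, 10.0, np.inf]])
        fracs = [delivery_fraction(d, v) for v in (0.01, 0.05, 0.2)]
        assert fracs == sorted(fracs)

    def test_infinite_paths_never_delivered(self):
        d = np.array([[np.inf, np.inf]])
        assert delivery_fraction(d, 10.0) == 0.0

    def test_all_cells_within_reach(self):
        d = np.array([[0.1, 0.2]])
        assert delivery_fraction(d, 1.0, season_days=70) == 1.0
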