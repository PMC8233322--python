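"""DEM conditioning, D8 routing, stream extraction and bank geometry,
checked against brute-force path-walking oracles on small grids."""

import math

import numpy as np
import pytest

from conftest import brute_force_accumulation, brute_force_flow_distance

from crustflux.dem import (
    DemGrid,
    HydroParams,
    bank_geometry,
    d8_route,
    derive_streams,
    detrend,
    extract_streams,
    fill_sinks,
    flow_distance_to_stream,
    gaussian_smooth,
    mean_slope,
    read_ascii_grid,
    write_ascii_grid,
)
from crustflux.synthetic import SyntheticConfig, gen_dem


def plane(nrows=20, ncols=20, sx=0.5, sy=0.0, res=1.0):
    rows, cols = np.mgrid[0:nrows, 0:ncols].astype(float)
    return DemGrid(z=100.0 - sx * cols * res - sy * rows * res, resolution=res)


class TestDetrend:
    def test_plane_has_no_high_frequency(self):
        dem = plane(sx=0.3, sy=0.2)
        low, high = detrend(dem, window=7)
        assert np.nanmax(np.abs(high.z)) < 1e-8

    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(0)
        dem = DemGrid(z=rng.normal(size=(24, 24)))
        low, high = detrend(dem, window=9)
        np.testing.assert_allclose(low.z + high.z, dem.z, atol=1e-10)

    def test_spike_goes_to_high_frequency(self):
        dem = plane(sx=0.3)
        z = dem.z.copy()
        z[10, 10] += 5.0
        low, high = detrend(DemGrid(z=z), window=7)
        assert high.z[10, 10] > 4.0  # spike lands in high
        assert abs(low.z[10, 10] - dem.z[10, 10]) < 0.5  # attenuated in low

    def test_window_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            detrend(plane(8, 8), window=31)


class TestGaussianSmooth:
    def test_constant_field_unchanged(self):
        dem = DemGrid(z=np.full((20, 20), 7.0))
        out = gaussian_smooth(dem, kernel=11)
        np.testing.assert_allclose(out.z, 7.0, atol=1e-10)

    def test_unit_impulse_gives_normalised_kernel(self):
        z = np.zeros((21, 21))
        z[10, 10] = 1.0
        out = gaussian_smooth(DemGrid(z=z), kernel=11)
        assert out.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.z[10, 10] == out.z.max()
        np.testing.assert_allclose(out.z, out.z[::-1, ::-1], atol=1e-12)  # symmetric

    def test_white_noise_variance_shrinks(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(50, 50))
        out = gaussian_smooth(DemGrid(z=z), kernel=11)
        assert out.z.var() < 0.5 * z.var()


def dem_with_pit(depth, nrows=12, ncols=12):
    dem = plane(nrows, ncols, sx=0.1)
    z = dem.z.copy()
    z[5:8, 5:8] -= depth  # flat-bottomed pit, pour level at the rim
    return DemGrid(z=z)


class TestFillSinks:
    def test_shallow_pit_filled_to_pour_level(self):
        dem = dem_with_pit(0.3)
        filled = fill_sinks(dem)
        # interior of the pit is raised; no closed depression remains
        assert np.all(filled.z >= dem.z - 1e-12)
        assert np.any(filled.z > dem.z)
        again = d8_route(filled)
        assert not again.unresolved

    def test_deep_pit_retained(self):
        # 0.8 m carve on the 0.1 m/cell slope leaves a 0.7 m-deep depression
        dem = dem_with_pit(0.8)
        filled = fill_sinks(dem)
        np.testing.assert_array_equal(filled.z, dem.z)

    def test_depressionless_plane_unchanged(self):
        dem = plane()
        np.testing.assert_array_equal(fill_sinks(dem).z, dem.z)

    def test_idempotent(self):
        for depth in (0.3, 0.8):
            dem = dem_with_pit(depth)
            once = fill_sinks(dem)
            twice = fill_sinks(once)
            np.testing.assert_array_equal(once.z, twice.z)

    def test_never_modifies_outside_depressions(self):
        dem = dem_with_pit(0.3)
        filled = fill_sinks(dem)
        changed = filled.z != dem.z
        assert changed.sum() <= 9  # only the pit cells

    def test_all_nodata_rejected(self):
        with pytest.raises(ValueError):
            fill_sinks(DemGrid(z=np.full((8, 8), np.nan)))


class TestD8:
    def test_east_tilted_plane_routes_east(self):
        dem = plane(sx=0.5, sy=0.0)
        res = d8_route(dem)
        interior = res.directions[1:-1, 1:-1]
        assert np.all(interior == 0)  # code 0 = east
        # accumulation grows linearly along each row
        row = res.accumulation[5, :]
        np.testing.assert_allclose(row, np.arange(1, 21, dtype=float))

    def test_outlet_accumulation_conserves_area(self, small_valley):
        res = d8_route(small_valley)
        outlet_sum = res.accumulation[res.directions == -1].sum()
        assert outlet_sum == pytest.approx(64.0)

    def test_accumulation_matches_brute_force(self, small_valley):
        res = d8_route(small_valley)
        oracle = brute_force_accumulation(res.directions, small_valley.valid, 1.0)
        np.testing.assert_allclose(res.accumulation, oracle)

    def test_accumulation_matches_brute_force_on_noisy_filled_grid(self):
        rng = np.random.default_rng(7)
        z = 10 - 0.4 * np.arange(12)[None, :] + rng.normal(0, 0.2, (12, 12))
        dem = fill_sinks(DemGrid(z=z))
        res = d8_route(dem)
        oracle = brute_force_accumulation(res.directions, dem.valid, 1.0)
        np.testing.assert_allclose(res.accumulation, oracle)

    def test_nodata_respected(self):
        dem = plane(10, 10)
        z = dem.z.copy()
        z[0:3, 0:3] = np.nan
        res = d8_route(DemGrid(z=z))
        assert np.all(res.directions[0:3, 0:3] == -2)
        valid = np.isfinite(z)
        outlet_sum = res.accumulation[res.directions == -1].sum()
        assert outlet_sum == pytest.approx(float(valid.sum()))


class TestStreams:
    def test_threshold_above_max_gives_empty_mask(self, small_valley):
        res = d8_route(small_valley)
        mask = extract_streams(res.accumulation, HydroParams(stream_accum_threshold=1e6))
        assert not mask.any()

    def test_threshold_at_cell_area_selects_all(self, small_valley):
        res = d8_route(small_valley)
        mask = extract_streams(res.accumulation, HydroParams(stream_accum_threshold=1.0))
        assert mask.all()

    def test_stream_sensitivity_is_modest(self):
        """A 10% higher stream threshold changes the mean flow distance by a
        small fraction on a synthetic catchment."""
        dem = gen_dem(SyntheticConfig(seed=2))
        base = derive_streams(dem, HydroParams(stream_accum_threshold=165.0))
        pert = derive_streams(dem, HydroParams(stream_accum_threshold=165.0 * 1.1))
        change = abs(pert.bank.mean_distance - base.bank.mean_distance) / base.bank.mean_distance
        assert change < 0.15

    def test_raising_threshold_never_shortens_distances(self, small_valley):
        res = d8_route(small_valley)
        lo = extract_streams(res.accumulation, HydroParams(stream_accum_threshold=4.0))
        hi = extract_streams(res.accumulation, HydroParams(stream_accum_threshold=8.0))
        d_lo = flow_distance_to_stream(res.directions, lo, 1.0)
        d_hi = flow_distance_to_stream(res.directions, hi, 1.0)
        assert np.all(d_hi >= d_lo - 1e-12)


class TestFlowDistance:
    def test_single_steps(self):
        dem = plane(6, 6, sx=0.5)
        res = d8_route(dem)
        mask = np.zeros((6, 6), bool)
        mask[:, 4] = True  # stream column
        d = flow_distance_to_stream(res.directions, mask, 1.0)
        assert d[2, 3] == pytest.approx(1.0)  # one cardinal step east
        assert d[2, 4] == 0.0
        assert d[2, 2] == pytest.approx(2.0)

    def test_diagonal_step_is_sqrt2(self):
        z = np.array(
            [
                [3.0, 3.0, 3.0],
                [3.0, 2.0, 3.0],
                [3.0, 3.0, 1.0],
            ]
        )
        res = d8_route(DemGrid(z=z))
        assert res.directions[1, 1] == 1  # SE
        mask = np.zeros((3, 3), bool)
        mask[2, 2] = True
        d = flow_distance_to_stream(res.directions, mask, 1.0)
        assert d[1, 1] == pytest.approx(math.sqrt(2.0))

    def test_matches_brute_force_on_12x12(self):
        rng = np.random.default_rng(13)
        z = 20 - 0.5 * np.arange(12)[None, :] + rng.normal(0, 0.3, (12, 12))
        dem = fill_sinks(DemGrid(z=z))
        res = d8_route(dem)
        mask = extract_streams(res.accumulation, HydroParams(stream_accum_threshold=8.0))
        d = flow_distance_to_stream(res.directions, mask, 1.0)
        oracle = brute_force_flow_distance(res.directions, mask, 1.0)
        np.testing.assert_allclose(d, oracle)

    def test_zero_on_streams_positive_elsewhere(self, small_valley):
        res = d8_route(small_valley)
        mask = extract_streams(res.accumulation, HydroParams(stream_accum_threshold=8.0))
        d = flow_distance_to_stream(res.directions, mask, 1.0)
        assert np.all(d[mask] == 0.0)
        assert np.all(d[~mask & np.isfinite(d)] > 0.0)


class TestBankGeometry:
    def test_straight_stream_has_two_banks(self):
        nrows, ncols = 7, 100
        rows = np.arange(nrows, dtype=float)
        # valley: everything drains toward the centre row, which drains east
        z = np.abs(rows - 3)[:, None] * 0.5 + np.tile(
            100 - 0.01 * np.arange(ncols, dtype=float), (nrows, 1)
        )
        res = d8_route(DemGrid(z=z))
        mask = np.zeros((nrows, ncols), bool)
        mask[3, :] = True
        d = flow_distance_to_stream(res.directions, mask, 1.0)
        bank = bank_geometry(d, mask, HydroParams(bank_width=1.0), 1.0)
        assert bank.bank_area == pytest.approx(200.0)
        assert bank.bank_length == pytest.approx(200.0)

    def test_empty_stream_mask(self, small_valley):
        res = d8_route(small_valley)
        mask = np.zeros((8, 8), bool)
        d = flow_distance_to_stream(res.directions, mask, 1.0)
        bank = bank_geometry(d, mask, HydroParams(), 1.0)
        assert bank.bank_area == 0.0
        assert math.isinf(bank.mean_distance)


class TestMeanSlope:
    def test_plane_slope_exact(self):
        dem = plane(sx=0.022, sy=0.0)
        assert mean_slope(dem) == pytest.approx(0.022, rel=1e-9)

    def test_flat_grid_zero(self):
        assert mean_slope(DemGrid(z=np.full((10, 10), 3.0))) == 0.0


class TestAsciiGrid:
    def test_round_trip_with_nodata(self, tmp_path):
        z = np.arange(20, dtype=float).reshape(4, 5)
        z[1, 2] = np.nan
        dem = DemGrid(z=z, resolution=2.0, origin=(10.0, 20.0))
        path = tmp_path / "grid.asc"
        write_ascii_grid(dem, path)
        back = read_ascii_grid(path)
        assert back.resolution == 2.0
        assert back.origin == (10.0, 20.0)
        np.testing.assert_allclose(back.z[~np.isnan(z)], z[~np.isnan(z)], atol=1e-6)
        assert np.isnan(back.z[1, 2])
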