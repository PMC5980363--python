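"""Synthetic landscape generator: determinism, physical contracts, and
sampling behavior of the virtual species."""

import numpy as np
import pandas as pd
import pytest

from rangeshift.raster import RasterStack
from rangeshift.synthetic import (
    GCM_NAMES,
    LandscapeConfig,
    RCP_WARMING,
    ScenarioDelta,
    VirtualSpecies,
    apply_scenario,
    default_scenarios,
    generate_climate,
    generate_dem,
    generate_riparian_mask,
    sample_occurrences,
    write_fixture_set,
)
from rangeshift.terrain import tri

SMALL = dict(shape=(60, 60))


class TestDem:
    def test_same_seed_identical(self):
        a = generate_dem(LandscapeConfig(**SMALL, seed=3))
        b = generate_dem(LandscapeConfig(**SMALL, seed=3))
        assert np.array_equal(a.values, b.values)

    def test_range_endpoints_exact(self):
        dem = generate_dem(LandscapeConfig(**SMALL, seed=4))
        assert dem.values.min() == pytest.approx(3300.0)
        assert dem.values.max() == pytest.approx(7300.0)

    def test_long_correlation_yields_near_planar_surface(self):
        smooth = generate_dem(
            LandscapeConfig(**SMALL, seed=5, correlation_length_cells=60.0, roughness_amplitude=0.0)
        )
        rough = generate_dem(LandscapeConfig(**SMALL, seed=5))
        t_smooth = tri(smooth)
        t_rough = tri(rough)
        assert t_smooth.values[t_smooth.valid].mean() < 0.2 * t_rough.values[t_rough.valid].mean()

    def test_north_higher_than_south(self):
        dem = generate_dem(LandscapeConfig(**SMALL, seed=6))
        assert dem.values[:10].mean() > dem.values[-10:].mean()

    def test_bad_correlation_length_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(correlation_length_cells=0.0)

    def test_unordered_elevation_range_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(elevation_range_m=(5000.0, 4000.0))


class TestClimate:
    def test_lapse_rate_exact_without_noise(self):
        cfg = LandscapeConfig(**SMALL, seed=7, temperature_noise_c=0.0)
        dem = generate_dem(cfg)
        stack = generate_climate(dem, cfg)
        b1 = stack["bio1"].values
        dz = dem.values - dem.values[0, 0]
        dt = b1 - b1[0, 0]
        assert np.allclose(dt, -6.5 * dz / 1000.0)

    def test_temperature_anticorrelated_with_elevation(self):
        cfg = LandscapeConfig(**SMALL, seed=8)
        dem = generate_dem(cfg)
        stack = generate_climate(dem, cfg)
        r = np.corrcoef(stack["bio1"].values.ravel(), dem.values.ravel())[0, 1]
        assert r < -0.8

    def test_same_seed_identical_stack(self):
        cfg = LandscapeConfig(**SMALL, seed=9)
        dem = generate_dem(cfg)
        s1 = generate_climate(dem, cfg)
        s2 = generate_climate(dem, cfg)
        for name in s1.names:
            assert np.array_equal(s1[name].values, s2[name].values)

    def test_precipitation_positive(self):
        cfg = LandscapeConfig(**SMALL, seed=10)
        stack = generate_climate(generate_dem(cfg), cfg)
        assert np.all(stack["bio18"].values > 0)


class TestScenarios:
    def _stack(self, cfg):
        dem = generate_dem(cfg)
        return generate_climate(dem, cfg)

    def test_identity_delta_is_identity(self):
        cfg = LandscapeConfig(**SMALL, seed=11)
        stack = self._stack(cfg)
        delta = ScenarioDelta(scenario="s", gcm="g", temp_offsets={"bio1": 0.0}, noise_scale_c=0.0)
        out = apply_scenario(stack, delta, cfg)
        for name in stack.names:
            assert np.array_equal(out[name].values, stack[name].values)

    def test_additive_offset_exact(self):
        cfg = LandscapeConfig(**SMALL, seed=12)
        stack = self._stack(cfg)
        delta = ScenarioDelta(scenario="s", gcm="g", temp_offsets={"bio1": 2.0}, noise_scale_c=0.0)
        out = apply_scenario(stack, delta, cfg)
        assert np.allclose(out["bio1"].values - stack["bio1"].values, 2.0)
        assert np.array_equal(out["bio9"].values, stack["bio9"].values)

    def test_multiplicative_precipitation(self):
        cfg = LandscapeConfig(**SMALL, seed=13)
        stack = self._stack(cfg)
        delta = ScenarioDelta(scenario="s", gcm="g", precip_factors={"bio18": 0.9})
        out = apply_scenario(stack, delta, cfg)
        assert np.allclose(out["bio18"].values, stack["bio18"].values * 0.9)

    def test_gcm_ensemble_mean_recovers_offset(self):
        cfg = LandscapeConfig(**SMALL, seed=14)
        stack = self._stack(cfg)
        outs = []
        for i in range(4):
            delta = ScenarioDelta(
                scenario="s", gcm=f"g{i}", temp_offsets={"bio1": 1.5}, noise_scale_c=0.4, seed=100 + i
            )
            outs.append(apply_scenario(stack, delta, cfg)["bio1"].values)
        mean_shift = np.mean([o - stack["bio1"].values for o in outs])
        assert mean_shift == pytest.approx(1.5, abs=1e-9)  # noise fields are zero-mean

    def test_unknown_layer_rejected(self):
        cfg = LandscapeConfig(**SMALL, seed=15)
        stack = self._stack(cfg)
        with pytest.raises(KeyError):
            apply_scenario(stack, ScenarioDelta(scenario="s", gcm="g", temp_offsets={"tmax": 1.0}), cfg)

    def test_default_scenario_grid_ordering(self):
        scens = default_scenarios(seed=0)
        assert set(scens) == {"rcp45_2050", "rcp45_2070", "rcp85_2050", "rcp85_2070"}
        for per_gcm in scens.values():
            assert set(per_gcm) == set(GCM_NAMES)
        # RCP 8.5 warms at least as much as 4.5; 2070 at least as much as 2050
        assert RCP_WARMING[("rcp85", 2050)] >= RCP_WARMING[("rcp45", 2050)]
        assert RCP_WARMING[("rcp85", 2070)] >= RCP_WARMING[("rcp45", 2070)]
        assert RCP_WARMING[("rcp45", 2070)] >= RCP_WARMING[("rcp45", 2050)]
        assert RCP_WARMING[("rcp85", 2070)] >= RCP_WARMING[("rcp85", 2050)]


class TestOccurrenceSampling:
    def _uniform_truth_stack(self, cfg):
        dem = generate_dem(cfg)
        grid = dem.with_values(np.full(dem.shape, 100.0), name="tri")
        rip = dem.with_values(np.zeros(dem.shape), name="dist_riparian")
        temp = dem.with_values(np.full(dem.shape, -9.0), name="bio1")
        return RasterStack([temp, grid, rip])

    def test_uniform_truth_samples_uniformly(self):
        cfg = LandscapeConfig(**SMALL, seed=16)
        stack = self._uniform_truth_stack(cfg)
        truth = VirtualSpecies()
        occ = sample_occurrences(truth, stack, n=2000, seed=1)
        # mean position near the grid center under uniform sampling
        assert occ.points.lat.mean() == pytest.approx(
            cfg.north - cfg.shape[0] * cfg.cell_deg / 2, abs=0.05
        )

    def test_step_truth_restricts_support(self):
        cfg = LandscapeConfig(**SMALL, seed=17)
        dem = generate_dem(cfg)
        north_half = np.zeros(dem.shape)
        north_half[:30] = 200.0  # rugged (suitable) only in the north
        stack = RasterStack(
            [
                dem.with_values(np.full(dem.shape, -9.0), name="bio1"),
                dem.with_values(north_half, name="tri"),
                dem.with_values(np.zeros(dem.shape), name="dist_riparian"),
            ]
        )
        occ = sample_occurrences(VirtualSpecies(), stack, n=300, seed=2)
        mid_lat = cfg.north - 30 * cfg.cell_deg
        assert (occ.points.lat > mid_lat).all()

    def test_gaussian_niche_mean_near_optimum(self):
        cfg = LandscapeConfig(**SMALL, seed=18)
        dem = generate_dem(cfg)
        climate = generate_climate(dem, cfg)
        stack = RasterStack(
            [
                climate["bio1"],
                dem.with_values(np.full(dem.shape, 500.0), name="tri"),
                dem.with_values(np.zeros(dem.shape), name="dist_riparian"),
            ]
        )
        truth = VirtualSpecies()  # temperature-only in effect
        occ = sample_occurrences(truth, stack, n=1000, seed=3)
        sampled = stack["bio1"].value_at(occ.points.lon.values, occ.points.lat.values)
        assert abs(sampled.mean() - truth.temp_optimum_c) < 0.5

    def test_all_zero_suitability_raises(self):
        cfg = LandscapeConfig(**SMALL, seed=19)
        dem = generate_dem(cfg)
        stack = RasterStack(
            [
                dem.with_values(np.full(dem.shape, 50.0), name="bio1"),  # hopelessly warm
                dem.with_values(np.zeros(dem.shape), name="tri"),        # and flat
                dem.with_values(np.zeros(dem.shape), name="dist_riparian"),
            ]
        )
        with pytest.raises(ValueError, match="zero"):
            sample_occurrences(VirtualSpecies(), stack, n=10, seed=0)

    def test_same_seed_identical_points(self, mini_landscape):
        a = sample_occurrences(mini_landscape.truth, mini_landscape.predictors, n=50, seed=9)
        b = sample_occurrences(mini_landscape.truth, mini_landscape.predictors, n=50, seed=9)
        pd.testing.assert_frame_equal(a.points, b.points)


class TestFixtures:
    def test_riparian_mask_fraction(self):
        cfg = LandscapeConfig(**SMALL, seed=20)
        mask = generate_riparian_mask(generate_dem(cfg), cfg)
        frac = mask.mean()
        assert 0.01 <= frac <= 0.06

    def test_fixture_set_round_trips(self, tmp_path, mini_landscape):
        from rangeshift.raster import read_raster

        out = write_fixture_set(mini_landscape, tmp_path / "fx")
        dem = read_raster(out / "dem.tif")
        assert np.array_equal(dem.values, mini_landscape.dem.values)
        occ = pd.read_csv(out / "occurrences.csv")
        assert {"lon", "lat"} <= set(occ.columns)
        assert len(occ) == len(mini_landscape.occurrences)
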