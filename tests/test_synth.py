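"""Synthetic-scene generator: determinism, stand statistics, sensor models."""

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import Polygon, box

from agbupscale.grids import Grid
from agbupscale.lidar import IntensityCorrectionParams, correct_intensity
from agbupscale.synth import (AllometryModel, SceneConfig, SyntheticStand,
                              generate_stand, make_dem, make_masks,
                              simulate_imagery, simulate_point_cloud, stand_agb,
                              stand_to_agb_raster, OPTICAL_BANDS)


class TestGenerateStand:
    def test_poisson_count_and_dbh_floor(self):
        """1-ha at 600 stems/ha: count inside the Poisson 99% interval, DBH >= 5."""
        stand = generate_stand({"larch": 1.0}, 600.0, (0, 0, 100, 100), seed=1)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 600)
        assert lo <= len(stand) <= hi
        assert (stand.stems["dbh"] >= 5.0).all()
        assert (stand.stems["height"] > 1.3).all()

    def test_determinism(self):
        a = generate_stand({"larch": 0.6, "chinese_pine": 0.4}, 400, (0, 0, 80, 80), 9)
        b = generate_stand({"larch": 0.6, "chinese_pine": 0.4}, 400, (0, 0, 80, 80), 9)
        assert a.stems.equals(b.stems)

    def test_near_zero_density_can_be_empty(self):
        stand = generate_stand({"larch": 1.0}, 0.1, (0, 0, 20, 20), seed=0)
        assert len(stand) <= 2  # expected count 0.004

    @pytest.mark.parametrize("bad", [
        dict(region=(0, 0, 0, 100)), dict(density=-5), dict(mix={"oak": 1.0})])
    def test_errors(self, bad):
        region = bad.get("region", (0, 0, 100, 100))
        density = bad.get("density", 100)
        mix = bad.get("mix", {"larch": 1.0})
        with pytest.raises(ValueError):
            generate_stand(mix, density, region, seed=0)

    def test_density_variation_preserves_mean(self):
        counts = [len(generate_stand({"larch": 1.0}, 500, (0, 0, 400, 400), s,
                                     density_variation=0.5)) for s in range(6)]
        assert 0.6 * 500 * 16 < np.mean(counts) < 1.4 * 500 * 16


class TestStandAgb:
    def test_single_stem_closed_form(self):
        import pandas as pd
        stems = pd.DataFrame({"x": [10.0], "y": [10.0], "species": ["larch"],
                              "dbh": [20.0], "height": [18.0]})
        stand = SyntheticStand(stems, (0, 0, 25, 25), seed=0)
        allo = AllometryModel({"larch": (0.1, 2.4)})
        expected = (0.1 * 20.0 ** 2.4 / 1000.0) / (625.0 / 1e4)
        assert stand_agb(stand, allo, box(0, 0, 25, 25)) == pytest.approx(expected)

    def test_empty_polygon_zero(self, one_ha_stand, allometry):
        assert stand_agb(one_ha_stand, allometry, box(200, 200, 225, 225)) == 0.0

    def test_monotone_in_dbh(self, one_ha_stand, allometry):
        poly = box(0, 0, 100, 100)
        a0 = stand_agb(one_ha_stand, allometry, poly)
        bigger = SyntheticStand(one_ha_stand.stems.assign(
            dbh=one_ha_stand.stems["dbh"] * 2), one_ha_stand.region, 0)
        assert stand_agb(bigger, allometry, poly) > a0

    def test_zero_area_polygon_errors(self, one_ha_stand, allometry):
        with pytest.raises(ValueError, match="zero area"):
            stand_agb(one_ha_stand, allometry, Polygon([(0, 0), (1, 1), (0, 0)]))

    def test_raster_matches_polygon_totals(self, one_ha_stand, allometry):
        grid = Grid(xmin=0, ymax=100, nrows=10, ncols=10, px=10.0)
        ras = stand_to_agb_raster(one_ha_stand, allometry, grid)
        total_poly = stand_agb(one_ha_stand, allometry, box(0, 0, 100, 100))
        assert ras.mean() == pytest.approx(total_poly, rel=1e-9)


class TestPointCloud:
    def test_flat_ground_only(self):
        stand = SyntheticStand(
            __import__("pandas").DataFrame(columns=["x", "y", "species", "dbh",
                                                    "height"]), (0, 0, 30, 30), 0)
        cfg = SceneConfig(point_density=10, seed=1)
        pc = simulate_point_cloud(stand, cfg)
        assert (pc.cls == 2).all()
        assert np.allclose(pc.z, 0.0)

    def test_count_poisson(self, one_ha_stand):
        cfg = SceneConfig(point_density=40, seed=2)
        pc = simulate_point_cloud(one_ha_stand, cfg, extent=(0, 0, 25, 25))
        assert abs(len(pc) - 25000) < 2500  # ±10%; Poisson 99% is ~±410

    def test_intensity_model_inverts(self, one_ha_stand):
        """Applying the range/scan-angle correction to noise-free output
        recovers I0 × material exactly."""
        cfg = SceneConfig(point_density=20, intensity_noise_sd=0.0, seed=3)
        pc = simulate_point_cloud(one_ha_stand, cfg, extent=(0, 0, 50, 50))
        out = correct_intensity(pc, IntensityCorrectionParams(cfg.r_ref))
        material = np.where(pc.cls == 5, cfg.material_canopy, cfg.material_ground)
        assert np.allclose(out.intensity, cfg.i0 * material, atol=1e-9)

    def test_determinism(self, one_ha_stand):
        cfg = SceneConfig(point_density=5, seed=11)
        a = simulate_point_cloud(one_ha_stand, cfg)
        b = simulate_point_cloud(one_ha_stand, cfg)
        assert a.df.equals(b.df)


class TestImagery:
    def _stack(self, agb_value, noise=0.0, shape=(32, 32), sat=150.0):
        grid = Grid(xmin=0, ymax=shape[0] * 10.0, nrows=shape[0], ncols=shape[1])
        cfg = SceneConfig(optical_noise_sd=noise, sar_noise_sd=0.0,
                          saturation_scale=sat, seed=5)
        agb = np.full(shape, float(agb_value))
        dem = np.zeros(shape)
        return simulate_imagery(agb, dem, cfg, grid), cfg

    def test_constant_scene_constant_bands(self):
        stack, _ = self._stack(80.0)
        for b in OPTICAL_BANDS:
            assert np.ptp(stack[b]) < 1e-12

    def test_zero_agb_at_floor(self):
        stack, _ = self._stack(0.0)
        for b, (floor, _) in OPTICAL_BANDS.items():
            assert stack[b].mean() == pytest.approx(floor)

    def test_monotone_below_saturation(self):
        lo, _ = self._stack(40.0)
        hi, _ = self._stack(100.0)
        for b in OPTICAL_BANDS:
            assert hi[b].mean() > lo[b].mean()

    def test_asymptotic_flatness_above_saturation(self):
        """Band-vs-AGB slope above 2× the saturation scale is < 10% of the
        low-AGB slope."""
        sat = 150.0
        def band_at(a):
            return self._stack(a, sat=sat)[0]["B8"].mean()
        low_slope = (band_at(10.0) - band_at(0.0)) / 10.0
        high_slope = (band_at(4 * sat) - band_at(2 * sat)) / (2 * sat)
        assert high_slope < 0.10 * low_slope

    def test_grid_mismatch_errors(self):
        grid = Grid(xmin=0, ymax=100, nrows=10, ncols=10)
        with pytest.raises(ValueError):
            simulate_imagery(np.zeros((5, 5)), np.zeros((10, 10)),
                             SceneConfig(), grid)


class TestMasks:
    def test_strip_and_road_masks(self):
        region = (0, 0, 500, 500)
        strip_mask, road_mask, species, grid = make_masks(
            region, [region], [], {"larch": 1, "chinese_pine": 1,
                                   "other_conifer": 1}, seed=0)
        assert strip_mask.all()
        assert not road_mask.any()
        assert set(np.unique(species)) == {1, 2, 3}

    def test_road_buffer_marked(self):
        region = (0, 0, 300, 300)
        _, road_mask, _, grid = make_masks(
            region, [], [(((150.0, 0.0), (150.0, 300.0)), 30.0)],
            {"larch": 1.0}, seed=0)
        assert road_mask.any()
        X, _ = grid.cell_centers()
        assert road_mask[:, np.abs(X[0] - 150.0) < 10].all()

    def test_strip_outside_region_errors(self):
        with pytest.raises(ValueError):
            make_masks((0, 0, 100, 100), [(0, 0, 200, 50)], [], {"larch": 1}, 0)
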