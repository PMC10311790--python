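"""Terrain correction, vegetation indices, GLCM textures and stack assembly."""

import numpy as np
import pytest

from agbupscale.features import (BIOPHYSICAL_NAMES, OPTICAL_BAND_NAMES, VI_NAMES,
                                 assemble_feature_stack, biophysical_proxies,
                                 feature_manifest, sar_backscatter,
                                 vegetation_indices)
from agbupscale.glcm import STATISTICS, glcm_textures, quantize
from agbupscale.grids import Grid, RasterStack
from agbupscale.terrain import c_correction, cos_incidence, slope_aspect
from agbupscale.synth import SceneConfig, make_dem


def _plane_dem(grid, slope_deg, aspect_deg):
    """DEM whose downslope azimuth is ``aspect_deg`` at slope ``slope_deg``."""
    X, Y = grid.cell_centers()
    m = np.tan(np.radians(slope_deg))
    az = np.radians(aspect_deg)
    # gradient (uphill) points opposite the downslope azimuth
    gx = -m * np.sin(az)
    gy = -m * np.cos(az)
    return gx * X + gy * Y


class TestCosIncidence:
    grid = Grid(xmin=0, ymax=300, nrows=30, ncols=30, px=10.0)

    def test_flat_equals_cos_sz(self):
        ci = cos_incidence(np.zeros((30, 30)), 30.0, 150.0, 10.0)
        assert np.allclose(ci, np.cos(np.radians(30.0)))

    def test_sun_aligned_slope_gives_unity(self):
        """sz = tz = 30° and sa = ta → cos i = cos²30 + sin²30 = 1."""
        dem = _plane_dem(self.grid, 30.0, 180.0)
        ci = cos_incidence(dem, 30.0, 180.0, 10.0)
        assert np.allclose(ci[5:-5, 5:-5], 1.0, atol=1e-6)

    def test_opposed_slope_gives_zero(self):
        """sz = tz = 45° and sa − ta = 180° → cos i = 0.5 − 0.5 = 0."""
        dem = _plane_dem(self.grid, 45.0, 0.0)
        ci = cos_incidence(dem, 45.0, 180.0, 10.0)
        assert np.allclose(ci[5:-5, 5:-5], 0.0, atol=1e-6)

    def test_slope_aspect_recovery(self):
        dem = _plane_dem(self.grid, 20.0, 135.0)
        tz, ta = slope_aspect(dem, 10.0)
        assert np.allclose(tz[5:-5, 5:-5], 20.0, atol=1e-6)
        assert np.allclose(ta[5:-5, 5:-5], 135.0, atol=1e-6)


class TestCCorrection:
    def test_flat_terrain_noop(self):
        band = np.random.default_rng(0).uniform(0.1, 0.4, (20, 20))
        cos_i = np.full((20, 20), np.cos(np.radians(30.0)))
        out, info = c_correction(band, cos_i, 30.0)
        assert info.skipped
        assert np.array_equal(out, band)

    def test_constructed_linear_band_flattens(self, rng):
        """Band = m·cos i + b: recovered C = b/m and the corrected band is
        exactly constant m·cos sz + b."""
        grid = Grid(xmin=0, ymax=400, nrows=40, ncols=40, px=10.0)
        dem = make_dem(grid, terrain=(20.0, 0.7), seed=4)
        cos_i = cos_incidence(dem, 35.0, 140.0, 10.0)
        m, b = 0.3, 0.05
        band = m * cos_i + b
        out, info = c_correction(band, cos_i, 35.0)
        assert not info.skipped
        assert info.c == pytest.approx(b / m, abs=1e-6)
        assert np.allclose(out, m * np.cos(np.radians(35.0)) + b, atol=1e-9)

    def test_guarded_division_counts_nodata(self):
        cos_i = np.linspace(-0.2, 0.9, 100).reshape(10, 10)
        band = 0.5 * cos_i + 0.05  # C = 0.1 -> cos_i + C crosses 0
        out, info = c_correction(band, cos_i, 30.0)
        assert info.n_nodata == int(np.isnan(out).sum()) > 0


class TestVegetationIndices:
    def _stack(self, **bands):
        grid = Grid(xmin=0, ymax=20, nrows=2, ncols=2, px=10.0)
        st = RasterStack(grid)
        defaults = {b: 0.2 for b in OPTICAL_BAND_NAMES}
        defaults.update(bands)
        for b, v in defaults.items():
            st.add(b, np.full((2, 2), float(v)), group="a")
        return st

    def test_ndvi_hand_value(self):
        vi = vegetation_indices(self._stack(B8=0.5, B4=0.1))
        assert vi["NDVI"][0, 0] == pytest.approx(0.4 / 0.6)
        vi0 = vegetation_indices(self._stack(B8=0.3, B4=0.3))
        assert vi0["NDVI"][0, 0] == pytest.approx(0.0)

    def test_s2rep_bracket_zero(self):
        """B4 + B7 = 2·B5 makes the red-edge bracket vanish → S2REP = 705."""
        vi = vegetation_indices(self._stack(B4=0.1, B7=0.3, B5=0.2, B6=0.35))
        assert vi["S2REP"][0, 0] == pytest.approx(705.0)

    def test_reip_divide_by_zero_is_nodata(self):
        vi = vegetation_indices(self._stack(B5=0.25, B6=0.25, B4=0.1, B7=0.3))
        assert np.isnan(vi["REIP"]).all()

    def test_all_19_present(self):
        vi = vegetation_indices(self._stack())
        assert set(vi) == set(VI_NAMES) and len(vi) == 19

    def test_missing_band_named_in_error(self):
        grid = Grid(xmin=0, ymax=20, nrows=2, ncols=2, px=10.0)
        st = RasterStack(grid)
        st.add("B2", np.zeros((2, 2)))
        with pytest.raises(KeyError, match="B3"):
            vegetation_indices(st)

    def test_rvi_psra_hand(self):
        vi = vegetation_indices(self._stack(B8=0.6, B4=0.15, B7=0.45))
        assert vi["RVI"][0, 0] == pytest.approx(4.0)
        assert vi["PSSRa"][0, 0] == pytest.approx(3.0)


class TestBiophysical:
    def test_proxy_fvc_zero_at_ndvi_zero(self):
        grid = Grid(xmin=0, ymax=20, nrows=2, ncols=2, px=10.0)
        st = RasterStack(grid)
        for b in OPTICAL_BAND_NAMES:
            st.add(b, np.full((2, 2), 0.2))
        out = biophysical_proxies(st, mode="proxy")
        assert np.allclose(out["FVC"], 0.0)
        assert set(out) == set(BIOPHYSICAL_NAMES)

    def test_supplied_passthrough(self):
        grid = Grid(xmin=0, ymax=20, nrows=2, ncols=2, px=10.0)
        st = RasterStack(grid)
        vals = {}
        for b in BIOPHYSICAL_NAMES:
            vals[b] = np.random.default_rng(1).uniform(0, 3, (2, 2))
            st.add(b, vals[b])
        out = biophysical_proxies(st, mode="supplied")
        for b in BIOPHYSICAL_NAMES:
            assert np.array_equal(out[b], vals[b])

    def test_proxy_monotone_in_ndvi(self):
        grid = Grid(xmin=0, ymax=10, nrows=1, ncols=50, px=10.0)
        st = RasterStack(grid)
        b4 = np.linspace(0.30, 0.05, 50)[None, :]
        for b in OPTICAL_BAND_NAMES:
            st.add(b, np.full((1, 50), 0.4) if b != "B4" else b4)
        out = biophysical_proxies(st, mode="proxy")
        assert (np.diff(out["FVC"][0]) >= 0).all()
        assert (np.diff(out["LAI"][0]) >= 0).all()


def _glcm_oracle(band, levels=32):
    """Naive per-pixel symmetric co-occurrence statistics at 45° in 3×3."""
    q = quantize(band, levels)
    qp = np.pad(q, 1, mode="reflect")
    H, W = q.shape
    out = {s: np.zeros((H, W)) for s in STATISTICS}
    for r in range(H):
        for c in range(W):
            win = qp[r:r + 3, c:c + 3]
            pairs = []
            for wr in range(1, 3):
                for wc in range(0, 2):
                    i, j = win[wr, wc], win[wr - 1, wc + 1]
                    pairs += [(i, j), (j, i)]
            P = {}
            for p in pairs:
                P[p] = P.get(p, 0) + 1.0 / len(pairs)
            mean = sum(pr * i for (i, j), pr in P.items())
            var = sum(pr * (i - mean) ** 2 for (i, j), pr in P.items())
            out["mean"][r, c] = mean
            out["var"][r, c] = var
            out["con"][r, c] = sum(pr * (i - j) ** 2 for (i, j), pr in P.items())
            out["dis"][r, c] = sum(pr * abs(i - j) for (i, j), pr in P.items())
            out["hom"][r, c] = sum(pr / (1 + (i - j) ** 2) for (i, j), pr in P.items())
            out["asm"][r, c] = sum(pr ** 2 for pr in P.values())
            out["ent"][r, c] = -sum(pr * np.log(pr) for pr in P.values())
            if var > 0:
                out["cor"][r, c] = sum(pr * (i - mean) * (j - mean)
                                       for (i, j), pr in P.items()) / var
    return out


class TestGlcm:
    def test_constant_image_conventions(self):
        out = glcm_textures(np.full((5, 5), 7.0))
        assert np.allclose(out["con"], 0) and np.allclose(out["dis"], 0)
        assert np.allclose(out["hom"], 1) and np.allclose(out["asm"], 1)
        assert np.allclose(out["ent"], 0) and np.allclose(out["cor"], 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        band = rng.uniform(0, 1, (8, 8))
        got = glcm_textures(band)
        want = _glcm_oracle(band)
        for s in STATISTICS:
            assert np.allclose(got[s], want[s], atol=1e-10), s

    def test_checkerboard_against_oracle(self):
        band = np.indices((6, 6)).sum(axis=0) % 2 * 1.0
        got = glcm_textures(band)
        want = _glcm_oracle(band)
        for s in STATISTICS:
            assert np.allclose(got[s], want[s], atol=1e-10), s


class TestAssemble:
    def test_full_stack_has_197_features(self, optical_stack, sar_stack):
        dem = np.zeros((64, 64))
        stack = assemble_feature_stack(optical_stack, sar_stack, dem)
        man = feature_manifest(stack)
        counts = man.groupby("group").size().to_dict()
        assert counts["a"] == 34 and counts["b"] == 120
        assert counts["c"] == 19 and counts["d"] == 24
        assert len(stack) == 197
        assert (man["source"] == "optical").sum() == 154
        assert (man["source"] == "sar").sum() == 43
        # GLCM band naming covers both polarisations
        for pol in ("VH", "VV"):
            for s in STATISTICS:
                assert f"{pol}_{s}" in stack

    def test_optical_only(self, optical_stack):
        stack = assemble_feature_stack(optical_stack, None, None)
        assert len(stack) == 154
        assert set(stack.manifest()["group"]) == {"a", "b"}

    def test_manifest_rows_equal_band_count(self, optical_stack, sar_stack):
        stack = assemble_feature_stack(optical_stack, sar_stack, None)
        assert len(feature_manifest(stack)) == len(stack)

    def test_duplicate_band_name_rejected(self):
        grid = Grid(xmin=0, ymax=20, nrows=2, ncols=2, px=10.0)
        st = RasterStack(grid)
        st.add("B2", np.zeros((2, 2)))
        with pytest.raises(ValueError, match="duplicate"):
            st.add("B2", np.ones((2, 2)))

    def test_sar_ratio_is_linear_power_ratio(self, sar_stack):
        bs = sar_backscatter(sar_stack)
        expect = 10 ** ((sar_stack["VH"] - sar_stack["VV"]) / 10.0)
        assert np.allclose(bs["VH/VV"], expect)
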