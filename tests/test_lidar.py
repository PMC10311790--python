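"""Point-cloud preprocessing and the 58-metric extractor."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agbupscale.lidar import (IntensityCorrectionParams, METRIC_NAMES,
                              classify_ground_normalize, clip_to_plot,
                              compute_metrics, correct_intensity, denoise)
from agbupscale.pointcloud import GROUND, NOISE, VEGETATION, PointCloud


def _cloud(x, y, z, **kw):
    return PointCloud.from_arrays(np.asarray(x, float), np.asarray(y, float),
                                  np.asarray(z, float), **kw)


class TestDenoise:
    def test_all_inside_unchanged(self, rng):
        pc = _cloud(rng.uniform(0, 10, 50), rng.uniform(0, 10, 50),
                    rng.uniform(0, 30, 50))
        out = denoise(pc, -10, 50)
        assert out.df.equals(pc.df)

    def test_flagging_not_deletion(self, rng):
        z = np.concatenate([rng.uniform(0, 10, 90), rng.uniform(90, 120, 10)])
        pc = _cloud(np.arange(100), np.arange(100), z)
        out = denoise(pc, 0, 50)
        assert len(out) == 100                       # count conserved
        n_out = int((z > 50).sum())
        assert (out.cls == NOISE).sum() == n_out
        assert len(out.valid()) == 100 - n_out

    def test_bad_bounds(self, rng):
        pc = _cloud([0], [0], [0])
        with pytest.raises(ValueError):
            denoise(pc, 5, 5)


class TestGroundNormalize:
    def test_level_plane_all_ground(self, rng):
        x, y = rng.uniform(0, 40, 2000), rng.uniform(0, 40, 2000)
        pc = _cloud(x, y, np.full(2000, 3.0))
        out, dem, grid = classify_ground_normalize(pc)
        assert np.abs(out.hn).max() < 1e-6
        assert (out.cls == GROUND).all()
        assert np.abs(dem - 3.0).max() < 1e-6

    @given(a=st.floats(-0.3, 0.3), b=st.floats(-0.3, 0.3), c=st.floats(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_affine_plane_height_recovery(self, a, b, c):
        """Normalised heights on any affine-plane ground are 0 within 1e-6 m."""
        rng = np.random.default_rng(99)
        x, y = rng.uniform(0, 30, 1500), rng.uniform(0, 30, 1500)
        pc = _cloud(x, y, a * x + b * y + c)
        out, _, _ = classify_ground_normalize(pc)
        assert np.abs(out.hn).max() < 1e-6

    def test_tilted_plane_plus_tree(self, rng):
        x, y = rng.uniform(0, 30, 1500), rng.uniform(0, 30, 1500)
        z = 0.2 * x + 0.1 * y + 1.0
        x = np.append(x, 15.0)
        y = np.append(y, 15.0)
        z = np.append(z, 0.2 * 15 + 0.1 * 15 + 1.0 + 5.0)  # 5 m above the plane
        out, _, _ = classify_ground_normalize(_cloud(x, y, z))
        assert out.hn[-1] == pytest.approx(5.0, abs=1e-6)
        assert out.cls[-1] == VEGETATION

    def test_threshold_is_strict(self, rng):
        """A return exactly 0.2 m above ground stays ground."""
        x, y = rng.uniform(0, 20, 1200), rng.uniform(0, 20, 1200)
        z = np.zeros(1200)
        x = np.append(x, [10.0, 10.5])
        y = np.append(y, [10.0, 10.5])
        z = np.append(z, [0.2, 0.2000001])
        out, _, _ = classify_ground_normalize(_cloud(x, y, z))
        assert out.cls[-2] == GROUND
        assert out.cls[-1] == VEGETATION

    def test_degenerate_geometry_errors(self):
        pc = _cloud([0, 1, 2, 3], [0, 0, 0, 0], [1, 1, 1, 1])  # collinear
        with pytest.raises(ValueError, match="[Cc]ollinear|degenerate"):
            classify_ground_normalize(pc, cell=0.5)


class TestIntensityCorrection:
    def test_identity_at_reference_range(self):
        pc = _cloud([0], [0], [0], intensity=[50.0], range_=[1000.0],
                    scan_angle=[0.0])
        out = correct_intensity(pc, IntensityCorrectionParams(1000.0))
        assert out.intensity[0] == pytest.approx(50.0)

    def test_hand_case(self):
        """I=100, R=2000, R_ref=1000, θ=60° → 100·4/0.5 = 800."""
        pc = _cloud([0], [0], [0], intensity=[100.0], range_=[2000.0],
                    scan_angle=[60.0])
        out = correct_intensity(pc, IntensityCorrectionParams(1000.0))
        assert out.intensity[0] == pytest.approx(800.0)

    def test_linear_in_raw_intensity(self, rng):
        i = rng.uniform(10, 100, 30)
        mk = lambda ii: _cloud(np.zeros(30), np.zeros(30), np.zeros(30),
                               intensity=ii, range_=rng.uniform(200, 400, 30),
                               scan_angle=rng.uniform(-20, 20, 30))
        r = rng.uniform(200, 400, 30)
        th = rng.uniform(-20, 20, 30)
        mk = lambda ii: _cloud(np.zeros(30), np.zeros(30), np.zeros(30),
                               intensity=ii, range_=r, scan_angle=th)
        a = correct_intensity(mk(i)).intensity
        b = correct_intensity(mk(3.0 * i)).intensity
        assert np.allclose(b, 3.0 * a)

    def test_scan_angle_at_90_rejected(self):
        with pytest.raises(ValueError):
            _cloud([0], [0], [0], intensity=[1.0], range_=[100.0],
                   scan_angle=[90.0])


class TestClipToPlot:
    def test_half_open_edges(self):
        pc = _cloud([-12.5, 12.5, 0.0, 0.0], [0.0, 0.0, -12.5, 12.5],
                    [0, 0, 0, 0])
        out = clip_to_plot(pc, (0.0, 0.0), side=25.0)
        # west and south edges included; east and north excluded
        assert len(out) == 2
        assert set(zip(out.x, out.y)) == {(-12.5, 0.0), (0.0, -12.5)}

    def test_empty_result_ok(self, rng):
        pc = _cloud(rng.uniform(100, 200, 40), rng.uniform(100, 200, 40),
                    np.zeros(40))
        assert len(clip_to_plot(pc, (0, 0))) == 0

    def test_matches_bruteforce_membership(self, rng):
        x, y = rng.uniform(-40, 40, 500), rng.uniform(-40, 40, 500)
        pc = _cloud(x, y, np.zeros(500))
        out = clip_to_plot(pc, (5.0, -3.0), side=25.0)
        expect = {(xi, yi) for xi, yi in zip(x, y)
                  if 5.0 - 12.5 <= xi < 5.0 + 12.5 and -3.0 - 12.5 <= yi < -3.0 + 12.5}
        assert set(zip(out.x, out.y)) == expect


def _oracle_percentile(v, q):
    """Independent linear-interpolation order-statistic percentile."""
    s = np.sort(np.asarray(v, float))
    h = (len(s) - 1) * q / 100.0
    f = int(np.floor(h))
    if f == len(s) - 1:
        return s[-1]
    return s[f] + (h - f) * (s[f + 1] - s[f])


class TestMetrics:
    def test_exactly_58_named_metrics(self, normalized_cloud):
        vec = compute_metrics(normalized_cloud)
        assert list(vec.index) == METRIC_NAMES
        assert len(vec) == 58

    def test_percentiles_match_sort_oracle(self, rng):
        hv = rng.gamma(4.0, 3.0, 1000) + 0.3
        pc = PointCloud.from_arrays(rng.uniform(0, 25, 1000),
                                    rng.uniform(0, 25, 1000), hv,
                                    intensity=rng.uniform(0, 500, 1000))
        pc.df["hn"] = hv
        pc.df["cls"] = VEGETATION
        vec = compute_metrics(pc)
        for q in (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99):
            assert vec[f"H{q:02d}"] == pytest.approx(_oracle_percentile(hv, q))
            assert vec[f"I{q:02d}"] == pytest.approx(
                _oracle_percentile(pc.intensity, q))

    def test_percentile_monotonicity_and_density_normalisation(self, rng):
        for _ in range(5):
            hv = rng.uniform(0.3, 30, 200)
            pc = PointCloud.from_arrays(np.zeros(200), np.zeros(200), hv)
            pc.df["hn"] = hv
            pc.df["cls"] = VEGETATION
            vec = compute_metrics(pc)
            hs = [vec[f"H{q:02d}"] for q in (1, 5, 10, 20, 25, 30, 40, 50, 60,
                                             70, 75, 80, 90, 95, 99)] + [vec["Hmax"]]
            assert np.all(np.diff(hs) >= -1e-12)
            d = np.array([vec[f"D{i:02d}"] for i in range(1, 11)])
            assert d.sum() == pytest.approx(1.0)
            assert ((d >= 0) & (d <= 1)).all()

    def test_gap_fraction_and_relief(self):
        """20 ground of 100 → G.F = 0.2; veg heights {5,10,15} → C.R.R = 0.5."""
        hn = np.concatenate([np.full(20, 0.1),
                             np.repeat([5.0, 10.0, 15.0], [20, 40, 20])])
        pc = PointCloud.from_arrays(np.zeros(100), np.zeros(100), hn)
        pc.df["hn"] = hn
        pc.df["cls"] = np.where(hn > 0.2, VEGETATION, GROUND)
        vec = compute_metrics(pc)
        assert vec["G.F"] == pytest.approx(0.2)
        assert vec["C.R.R"] == pytest.approx(0.5)
        assert vec["C.C"] == pytest.approx(0.8)  # first-return veg fraction

    def test_lai_closed_form(self):
        """ang = 0, G.F = 1/4, k = 0.5 → LAI = −ln(0.25)/0.5."""
        hn = np.concatenate([np.full(25, 0.0), np.full(75, 8.0)])
        pc = PointCloud.from_arrays(np.zeros(100), np.zeros(100), hn,
                                    scan_angle=np.zeros(100))
        pc.df["hn"] = hn
        pc.df["cls"] = np.where(hn > 0.2, VEGETATION, GROUND)
        vec = compute_metrics(pc, k_extinction=0.5)
        assert vec["LAI"] == pytest.approx(-np.log(0.25) / 0.5)

    def test_undefined_metrics_flagged(self):
        hn = np.full(50, 7.0)  # no ground returns, single height
        pc = PointCloud.from_arrays(np.zeros(50), np.zeros(50), hn)
        pc.df["hn"] = hn
        pc.df["cls"] = VEGETATION
        with pytest.warns(UserWarning):
            vec = compute_metrics(pc)
        assert np.isnan(vec["LAI"])     # G.F = 0
        assert np.isnan(vec["C.R.R"])   # Hmax == Hmin
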