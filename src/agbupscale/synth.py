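"""Seeded synthetic coniferous-forest scenes.

Everything downstream of this module — canopy-metric extraction, terrain
correction, texture features, two-stage model fitting — is exercised against
scenes produced here: a stem map with allometric AGB truth, a first-return
LiDAR point cloud whose raw intensity follows the inverse of the range/scan-
angle correction model (so the correction is exactly recoverable), optical and
SAR rasters whose signal saturates at high biomass, a hillshade-relevant DEM,
and strip/road/species masks. Every generator is a pure function of its
parameters and seed.

The stand model is deliberately plain: Poisson stem counts, truncated
lognormal DBH (≥ 5 cm, mirroring the field measurement rule), a saturating
species-specific height–DBH curve, and single-stem allometry
``AGB_tree = a · DBH^b`` (kg, DBH in cm). Crowns are vertical envelopes —
no radiative transfer, no multi-return waveforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, LineString, box
import shapely

from .grids import Grid, RasterStack
from .pointcloud import PointCloud, GROUND, VEGETATION

SPECIES = ("larch", "chinese_pine", "other_conifer")
SPECIES_CODES = {"larch": 1, "chinese_pine": 2, "other_conifer": 3}
CODE_TO_SPECIES = {v: k for k, v in SPECIES_CODES.items()}

Region = tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)


def _check_region(region: Region) -> Region:
    xmin, ymin, xmax, ymax = region
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate region {region}")
    return region


# ---------------------------------------------------------------------------
# allometry

@dataclass(frozen=True)
class AllometryModel:
    """Single-tree allometry AGB = a · DBH^b (+ optional height factor H^c).

    Coefficients are per species, on DBH in cm and AGB in kg. Defaults are
    generic conifer values (a = 0.1, b = 2.4); only relative recovery
    behaviour, not absolute biomass, is meaningful for synthetic scenes.
    """

    coefficients: dict = field(default_factory=lambda: {
        s: (0.1, 2.4) for s in SPECIES})
    height_exponent: float = 0.0

    def __post_init__(self):
        for sp, cf in self.coefficients.items():
            a, b = cf[0], cf[1]
            if a <= 0 or b <= 0:
                raise ValueError(f"allometric coefficients must be positive ({sp})")

    def tree_agb_kg(self, species, dbh_cm, height_m=None) -> np.ndarray:
        species = np.asarray(species)
        dbh = np.asarray(dbh_cm, float)
        out = np.empty(dbh.shape, float)
        for sp in np.unique(species):
            if sp not in self.coefficients:
                raise KeyError(f"no allometric coefficients for species {sp!r}")
            a, b = self.coefficients[sp]
            m = species == sp
            out[m] = a * dbh[m] ** b
        if self.height_exponent and height_m is not None:
            out = out * np.asarray(height_m, float) ** self.height_exponent
        return out


# ---------------------------------------------------------------------------
# stand generation

# per-species (median DBH cm, lognormal sigma, asymptotic height m, height rate)
_STAND_PARAMS = {
    "larch": (20.0, 0.35, 28.0, 0.055),
    "chinese_pine": (22.0, 0.30, 22.0, 0.065),
    "other_conifer": (16.0, 0.40, 20.0, 0.060),
}


@dataclass
class SyntheticStand:
    """A stem map: one row per tree (x, y, species, dbh [cm], height [m])."""

    stems: pd.DataFrame
    region: Region
    seed: int

    def __post_init__(self):
        _check_region(self.region)
        if len(self.stems):
            if (self.stems["dbh"].to_numpy() < 5.0).any():
                raise ValueError("all stems must have DBH >= 5 cm")
            if (self.stems["height"].to_numpy() <= 1.3).any():
                raise ValueError("all stems must be taller than breast height (1.3 m)")
            xmin, ymin, xmax, ymax = self.region
            x, y = self.stems["x"].to_numpy(), self.stems["y"].to_numpy()
            if ((x < xmin) | (x >= xmax) | (y < ymin) | (y >= ymax)).any():
                raise ValueError("stems must lie inside the region")

    def __len__(self):
        return len(self.stems)


def generate_stand(species_mix: dict, stem_density: float, region: Region,
                   seed: int, density_variation: float = 0.0,
                   density_scale: float = 250.0) -> SyntheticStand:
    """Poisson forest with truncated-lognormal DBH and height–DBH curve.

    ``species_mix`` maps species name to mixing weight; ``stem_density`` is in
    stems/ha. With ``density_variation`` > 0 the intensity is modulated by a
    smooth lognormal field (sd on the log scale, correlation length
    ``density_scale`` m) — an inhomogeneous Poisson process emulating
    age/site-quality mosaics; the mean density is preserved. Deterministic
    per seed.
    """
    _check_region(region)
    if stem_density <= 0:
        raise ValueError("stem_density must be > 0")
    unknown = set(species_mix) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = region
    area_ha = (xmax - xmin) * (ymax - ymin) / 1e4
    names = sorted(species_mix)
    w = np.array([species_mix[s] for s in names], float)
    w = w / w.sum()
    if density_variation > 0:
        # thinned inhomogeneous Poisson: simulate at the field's peak rate
        cell = 25.0
        fgrid = Grid.from_extent(xmin, ymin, xmax, ymax, px=cell)
        sigma_px = max(density_scale / cell, 1.0)
        fld = ndimage.gaussian_filter(rng.standard_normal(fgrid.shape), sigma_px,
                                      mode="reflect")
        sd = fld.std()
        fld = fld / sd * density_variation if sd > 0 else fld
        rate = np.exp(fld - np.log(np.mean(np.exp(fld))))  # mean-one lognormal
        peak = rate.max()
        n0 = rng.poisson(stem_density * area_ha * peak)
        x0 = rng.uniform(xmin, xmax, n0)
        y0 = rng.uniform(ymin, ymax, n0)
        r0, c0 = fgrid.rowcol(x0, y0)
        r0 = np.clip(r0, 0, fgrid.nrows - 1)
        c0 = np.clip(c0, 0, fgrid.ncols - 1)
        keep = rng.uniform(0, 1, n0) < rate[r0, c0] / peak
        x, y = x0[keep], y0[keep]
        n = len(x)
    else:
        n = rng.poisson(stem_density * area_ha)
        x = rng.uniform(xmin, xmax, n)
        y = rng.uniform(ymin, ymax, n)
    sp = rng.choice(names, size=n, p=w)
    dbh = np.empty(n)
    height = np.empty(n)
    for s in names:
        m = sp == s
        med, sig, hmax, rate = _STAND_PARAMS[s]
        d = med * np.exp(rng.normal(0.0, sig, m.sum()))
        # truncate at the 5 cm measurement floor by resampling the tail
        bad = d < 5.0
        while bad.any():
            d[bad] = med * np.exp(rng.normal(0.0, sig, bad.sum()))
            bad = d < 5.0
        h = 1.3 + hmax * (1.0 - np.exp(-rate * d))
        h = h * np.exp(rng.normal(0.0, 0.05, m.sum()))
        dbh[m] = d
        height[m] = np.maximum(h, 1.31)
    stems = pd.DataFrame({"x": x, "y": y, "species": sp, "dbh": dbh, "height": height})
    return SyntheticStand(stems=stems, region=region, seed=seed)


def stand_agb(stand: SyntheticStand, allometry: AllometryModel,
              plot_polygon: Polygon) -> float:
    """Plot AGB in Mg/ha: summed tree allometry over stems inside the polygon."""
    area_m2 = plot_polygon.area
    if area_m2 <= 0:
        raise ValueError("plot polygon has zero area")
    if len(stand) == 0:
        return 0.0
    inside = shapely.contains_xy(plot_polygon, stand.stems["x"].to_numpy(),
                                 stand.stems["y"].to_numpy())
    if not inside.any():
        return 0.0
    sub = stand.stems[inside]
    kg = allometry.tree_agb_kg(sub["species"].to_numpy(), sub["dbh"].to_numpy(),
                               sub["height"].to_numpy())
    return float(kg.sum() / 1000.0 / (area_m2 / 1e4))


def stand_to_agb_raster(stand: SyntheticStand, allometry: AllometryModel,
                        grid: Grid) -> np.ndarray:
    """Per-pixel true AGB (Mg/ha) by binning stem biomass onto the grid."""
    out = np.zeros(grid.shape)
    if len(stand) == 0:
        return out
    row, col = grid.rowcol(stand.stems["x"].to_numpy(), stand.stems["y"].to_numpy())
    ok = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    kg = allometry.tree_agb_kg(stand.stems["species"].to_numpy()[ok],
                               stand.stems["dbh"].to_numpy()[ok],
                               stand.stems["height"].to_numpy()[ok])
    np.add.at(out, (row[ok], col[ok]), kg)
    px_ha = grid.px ** 2 / 1e4
    return out / 1000.0 / px_ha


def stems_to_geojson(stand: SyntheticStand, path) -> None:
    """Write the stem map as a GeoJSON point collection."""
    import json

    feats = [{"type": "Feature",
              "geometry": {"type": "Point", "coordinates": [row.x, row.y]},
              "properties": {"species": row.species, "dbh": row.dbh,
                             "height": row.height}}
             for row in stand.stems.itertuples()]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# scene configuration

@dataclass
class SceneConfig:
    """Stated world for a synthetic scene.

    Defaults follow the emulated acquisition: ~40 first returns/m² from a
    280 m flight altitude, 10 m imagery whose optical signal saturates with a
    150 Mg/ha e-folding scale while SAR saturates twice as high, additive
    Gaussian optical noise and speckle-like multiplicative SAR noise, and a
    small per-species optical gain (species differ in canopy reflectance).
    """

    point_density: float = 40.0          # first returns / m²
    flight_altitude: float = 280.0       # m above mean ground
    strip_geometry: list = field(default_factory=list)  # list of Region rects
    optical_noise_sd: float = 0.01       # reflectance units
    sar_noise_sd: float = 0.2            # speckle coefficient of variation
    intensity_noise_sd: float = 0.0      # additive, raw intensity units
    saturation_scale: float = 150.0      # Mg/ha, optical e-folding scale
    sar_saturation_mult: float = 2.0     # SAR saturates at mult × optical scale
    terrain: tuple = (15.0, 0.5)         # (max slope deg, roughness 0..1)
    solar_zenith: float = 30.0           # deg
    solar_azimuth: float = 150.0         # deg
    species_gain: dict = field(default_factory=lambda: {
        "larch": 1.06, "chinese_pine": 0.94, "other_conifer": 1.00})
    i0: float = 1000.0                   # emitted-intensity constant
    r_ref: float = 1000.0                # standard range of the correction model
    material_ground: float = 0.8
    material_canopy: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.point_density <= 0:
            raise ValueError("point_density must be > 0")
        if self.saturation_scale <= 0:
            raise ValueError("saturation_scale must be > 0")


# per-band (floor, dynamic range) of the saturating reflectance response
OPTICAL_BANDS = {
    "B2": (0.030, 0.045), "B3": (0.040, 0.065), "B4": (0.030, 0.060),
    "B5": (0.050, 0.095), "B6": (0.080, 0.150), "B7": (0.100, 0.180),
    "B8": (0.120, 0.220), "B8a": (0.120, 0.225), "B11": (0.080, 0.120),
    "B12": (0.050, 0.080),
}
SAR_BANDS = {"VH": (-24.0, 10.0), "VV": (-16.0, 8.0)}  # (floor dB, rise dB)


def make_dem(grid: Grid, terrain=(15.0, 0.5), seed: int = 0) -> np.ndarray:
    """Smooth synthetic terrain: a regional tilt plus filtered-noise hills.

    ``terrain = (max_slope_deg, roughness)``; the tilt contributes about half
    the slope budget and the hills the rest, scaled by roughness.
    """
    max_slope, rough = terrain
    rng = np.random.default_rng(seed)
    Y, X = np.mgrid[0:grid.nrows, 0:grid.ncols].astype(float)
    theta = rng.uniform(0, 2 * np.pi)
    tilt = np.tan(np.radians(max_slope * 0.5)) * grid.px
    dem = tilt * (np.cos(theta) * X + np.sin(theta) * Y)
    if rough > 0:
        noise = rng.standard_normal(grid.shape)
        hills = ndimage.gaussian_filter(noise, sigma=8.0, mode="reflect")
        g = np.hypot(*np.gradient(hills, grid.px))
        gmax = g.max() if g.max() > 0 else 1.0
        dem = dem + hills * (np.tan(np.radians(max_slope * 0.5)) * rough / gmax)
    return dem - dem.min()


def _dem_sampler(dem: np.ndarray | None, grid: Grid | None):
    if dem is None or grid is None:
        return lambda x, y: np.zeros(np.shape(x))
    from scipy.interpolate import RegularGridInterpolator
    ys = grid.ymax - (np.arange(grid.nrows) + 0.5) * grid.px
    xs = grid.xmin + (np.arange(grid.ncols) + 0.5) * grid.px
    itp = RegularGridInterpolator((ys[::-1], xs), dem[::-1], bounds_error=False,
                                  fill_value=None)
    return lambda x, y: itp(np.column_stack([np.ravel(y), np.ravel(x)])).reshape(np.shape(x))


def simulate_point_cloud(stand: SyntheticStand, config: SceneConfig,
                         dem: np.ndarray | None = None, grid: Grid | None = None,
                         extent: Region | None = None, seed=None) -> PointCloud:
    """First-return point cloud over the stand (optionally clipped to ``extent``).

    Each pulse lands uniformly in the extent; pulses inside a crown footprint
    return from the upper crown of the nearest stem, the rest from the DEM.
    Raw intensity follows ``I0·cosθ·R_ref²/R² · material (+ noise)`` — the
    exact inverse of the range/scan-angle intensity correction, so applying
    the correction with the matching R_ref recovers ``I0 · material``.
    """
    if config.point_density <= 0:
        raise ValueError("point density must be > 0")
    region = _check_region(extent if extent is not None else stand.region)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    xmin, ymin, xmax, ymax = region
    area = (xmax - xmin) * (ymax - ymin)
    n = rng.poisson(config.point_density * area)
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    ground_at = _dem_sampler(dem, grid)
    zg = np.asarray(ground_at(x, y), float)

    z = zg.copy()
    cls = np.full(n, GROUND, int)
    material = np.full(n, config.material_ground)
    if len(stand):
        stems = stand.stems
        crown_r = 0.5 + 0.045 * stems["dbh"].to_numpy()
        tree = cKDTree(np.column_stack([stems["x"], stems["y"]]))
        dist, idx = tree.query(np.column_stack([x, y]), k=1)
        hit = dist <= crown_r[idx]
        if hit.any():
            h = stems["height"].to_numpy()[idx[hit]]
            # first returns intercept the upper half of the crown envelope
            rel = 0.5 + 0.5 * rng.beta(2.0, 1.2, hit.sum())
            z[hit] = zg[hit] + h * rel
            cls[hit] = VEGETATION
            material[hit] = config.material_canopy

    # nadir-ish sensor above the extent centroid
    sx, sy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    sz_sensor = float(np.mean(zg)) + config.flight_altitude
    horiz = np.hypot(x - sx, y - sy)
    dz = sz_sensor - z
    rng_i = np.hypot(horiz, dz)
    theta = np.degrees(np.arctan2(horiz, dz))
    i_raw = (config.i0 * np.cos(np.radians(theta)) * config.r_ref ** 2
             / rng_i ** 2 * material)
    if config.intensity_noise_sd > 0:
        i_raw = i_raw + rng.normal(0.0, config.intensity_noise_sd, n)
    return PointCloud.from_arrays(x, y, z, intensity=i_raw, range_=rng_i,
                                  scan_angle=theta, cls_code=cls)


def simulate_imagery(agb: np.ndarray, dem: np.ndarray, config: SceneConfig,
                     grid: Grid, species: np.ndarray | None = None,
                     seed=None) -> RasterStack:
    """Optical + SAR rasters as saturating functions of AGB.

    Optical band b: ``floor_b + range_b·(1 − exp(−AGB/S))·gain(species)``
    modulated by the illumination ratio cos(i)/cos(sz) (so terrain correction
    has signal to remove) plus autocorrelated Gaussian noise. SAR (dB):
    saturating rise with e-folding scale ``sar_saturation_mult × S`` and
    speckle-like multiplicative gamma noise applied in linear power.
    """
    agb = np.asarray(agb, float)
    dem = np.asarray(dem, float)
    if agb.shape != grid.shape or dem.shape != grid.shape:
        raise ValueError("agb/dem grids do not match the target grid")
    if species is not None and np.asarray(species).shape != grid.shape:
        raise ValueError("species raster does not match the target grid")
    from .terrain import cos_incidence

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    # the sensor sees canopy, not stems: smooth the stem-binned AGB slightly
    agb_s = ndimage.gaussian_filter(agb, sigma=1.0, mode="reflect")
    cos_i = cos_incidence(dem, config.solar_zenith, config.solar_azimuth, grid.px)
    cos_sz = np.cos(np.radians(config.solar_zenith))
    illum = np.clip(cos_i, 0.05, None) / cos_sz

    gain = np.ones(grid.shape)
    if species is not None:
        for name, code in SPECIES_CODES.items():
            gain[np.asarray(species) == code] = config.species_gain.get(name, 1.0)

    stack = RasterStack(grid)
    sat = config.saturation_scale
    for name, (floor, rng_b) in OPTICAL_BANDS.items():
        signal = floor + rng_b * (1.0 - np.exp(-agb_s / sat)) * gain
        band = signal * illum
        if config.optical_noise_sd > 0:
            white = rng.standard_normal(grid.shape)
            corr = ndimage.gaussian_filter(white, 1.5, mode="reflect")
            corr *= 1.0 / corr.std() if corr.std() > 0 else 1.0
            band = band + config.optical_noise_sd * corr
        stack.add(name, band, group="a")

    sar_sat = config.sar_saturation_mult * sat
    for name, (floor_db, rise_db) in SAR_BANDS.items():
        db = floor_db + rise_db * (1.0 - np.exp(-agb_s / sar_sat))
        power = 10.0 ** (db / 10.0)
        if config.sar_noise_sd > 0:
            looks = 1.0 / config.sar_noise_sd ** 2
            power = power * rng.gamma(looks, 1.0 / looks, grid.shape)
        stack.add(name, 10.0 * np.log10(power), group="c")

    stack.add("DEM", dem, group="aux")
    stack.add("AGB_TRUE", agb, group="aux")
    return stack


# ---------------------------------------------------------------------------
# masks

def make_masks(region: Region, strips: list, road_spec: list,
               species_layout: dict, seed: int = 0, px: float = 10.0):
    """Strip-coverage, road-buffer and species-stratum rasters.

    ``strips`` are rectangles (xmin, ymin, xmax, ymax) that must lie inside
    the region; ``road_spec`` is a list of ``(coords, width_m)`` polylines;
    ``species_layout`` maps species name to an area weight — strata are laid
    out as contiguous vertical bands with widths proportional to weight.
    Returns ``(strip_mask, road_mask, species_raster, grid)``.
    """
    xmin, ymin, xmax, ymax = _check_region(region)
    grid = Grid.from_extent(xmin, ymin, xmax, ymax, px=px)
    X, Y = grid.cell_centers()

    strip_mask = np.zeros(grid.shape, bool)
    for sxmin, symin, sxmax, symax in strips:
        if sxmin < xmin or symin < ymin or sxmax > xmax or symax > ymax:
            raise ValueError("strip extends outside the region")
        strip_mask |= (X >= sxmin) & (X < sxmax) & (Y >= symin) & (Y < symax)

    road_mask = np.zeros(grid.shape, bool)
    for coords, width in road_spec:
        buf = LineString(coords).buffer(width / 2.0)
        road_mask |= shapely.contains_xy(buf, X.ravel(), Y.ravel()).reshape(grid.shape)

    unknown = set(species_layout) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species {sorted(unknown)}")
    names = [s for s in SPECIES if s in species_layout]
    w = np.array([species_layout[s] for s in names], float)
    edges = xmin + (xmax - xmin) * np.concatenate([[0.0], np.cumsum(w) / w.sum()])
    species = np.zeros(grid.shape, int)
    for i, s in enumerate(names):
        m = (X >= edges[i]) & (X < edges[i + 1] if i < len(names) - 1 else X <= edges[i + 1])
        species[m] = SPECIES_CODES[s]
    return strip_mask, road_mask, species, grid
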