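"""Point-cloud preprocessing and plot-level canopy metrics.

The preprocessing chain mirrors a standard first-return workflow: height
thresholding flags noise, the lowest return per cell seeds a Delaunay TIN
whose linear interpolation is the DEM, heights are normalised against it,
and returns higher than 0.2 m above ground become vegetation (strictly
greater — a return at exactly 0.2 m is ground). Raw intensities are corrected
for range and scan angle,

    I_C = I_raw · R_i² / (R_ref² · cos θ_i),

with R_ref the standard range (default 1000 m).

``compute_metrics`` emits the fixed 58-metric vector per plot or grid cell:
22 height metrics (15 percentiles + max/min/mean/median/cv/skew/kurtosis over
vegetation returns), 10 canopy return-density slices, 22 intensity metrics
(same shape), and 4 canopy structure indices (LAI, gap fraction G.F, canopy
relief ratio C.R.R, canopy cover C.C). Percentiles interpolate linearly
between order statistics; skewness and kurtosis are population moments
(kurtosis non-excess); cv = sd/mean with the population sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .grids import Grid
from .pointcloud import PointCloud, GROUND, VEGETATION, NOISE

VEG_HEIGHT_THRESHOLD = 0.2  # m; strictly above -> vegetation

_PCT = (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99)


def metric_names() -> list[str]:
    """The 58 canopy-metric names, in canonical order."""
    names = [f"H{p:02d}" for p in _PCT]
    names += ["Hmax", "Hmin", "Hmean", "Hmedian", "H.cv", "H.ske", "H.kur"]
    names += [f"D{i:02d}" for i in range(1, 11)]
    names += [f"I{p:02d}" for p in _PCT]
    names += ["Imax", "Imin", "Imean", "Imedian", "I.cv", "I.ske", "I.kur"]
    names += ["LAI", "G.F", "C.R.R", "C.C"]
    return names


METRIC_NAMES = metric_names()
assert len(METRIC_NAMES) == 58


# ---------------------------------------------------------------------------
# preprocessing

def denoise(points: PointCloud, z_low: float, z_high: float) -> PointCloud:
    """Flag returns with z outside [z_low, z_high] as noise (no deletion)."""
    if z_low >= z_high:
        raise ValueError("z_low must be < z_high")
    out = points.copy()
    bad = (out.df["z"] < z_low) | (out.df["z"] > z_high)
    out.df.loc[bad, "cls"] = NOISE
    return out


def _plane_fit(x, y, z):
    A = np.column_stack([x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    return coef


def classify_ground_normalize(points: PointCloud, cell: float = 2.0,
                              veg_threshold: float = VEG_HEIGHT_THRESHOLD,
                              dem_px: float | None = None):
    """Ground model + height normalisation + ground/vegetation classes.

    Ground seeds are the lowest non-noise return per ``cell`` × ``cell``
    square; the DEM is their Delaunay TIN (linear within triangles, with a
    least-squares plane fallback outside the seed hull). Normalised height
    ``hn = z − DEM(x, y)`` is clamped at ≥ 0; class is vegetation iff
    ``hn > veg_threshold`` (strict), else ground. Returns
    ``(cloud, dem_raster, dem_grid)``.
    """
    out = points.copy()
    df = out.df
    ok = df["cls"] != NOISE
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-noise points for a ground model")
    x = df.loc[ok, "x"].to_numpy()
    y = df.loc[ok, "y"].to_numpy()
    z = df.loc[ok, "z"].to_numpy()

    cx = np.floor(x / cell).astype(np.int64)
    cy = np.floor(y / cell).astype(np.int64)
    flat = (cx - cx.min()) * (cy.max() - cy.min() + 1) + (cy - cy.min())
    order = np.lexsort((z, flat))
    first = np.ones(len(order), bool)
    first[1:] = flat[order][1:] != flat[order][:-1]
    seed_idx = order[first]                    # lowest return per cell
    lx, ly, lz = x[seed_idx], y[seed_idx], z[seed_idx]

    plane = _plane_fit(lx, ly, lz)
    try:
        tin = LinearNDInterpolator(np.column_stack([lx, ly]), lz)
    except QhullError as err:
        raise ValueError(
            "ground seeds are collinear or degenerate; Delaunay triangulation "
            "failed") from err

    # rasterise the TIN once, then sample points bilinearly from the DEM —
    # orders of magnitude cheaper than a barycentric walk per return
    px = dem_px if dem_px is not None else cell
    grid = Grid.from_extent(x.min(), y.min(), max(x.max(), x.min() + px),
                            max(y.max(), y.min() + px), px=px)
    X, Y = grid.cell_centers()
    dem = tin(np.column_stack([X.ravel(), Y.ravel()])).reshape(grid.shape)
    miss = ~np.isfinite(dem)
    dem[miss] = (plane[0] * X[miss] + plane[1] * Y[miss] + plane[2])

    from scipy.interpolate import RegularGridInterpolator
    ys = grid.ymax - (np.arange(grid.nrows) + 0.5) * grid.px
    xs = grid.xmin + (np.arange(grid.ncols) + 0.5) * grid.px
    if grid.nrows > 1 and grid.ncols > 1:
        itp = RegularGridInterpolator((ys[::-1], xs), dem[::-1],
                                      bounds_error=False, fill_value=None)
        dem_at = itp(np.column_stack([y, x]))
    else:
        dem_at = np.full(len(x), dem.mean())

    hn = np.clip(z - dem_at, 0.0, None)
    df["hn"] = np.nan
    df.loc[ok, "hn"] = hn
    cls = np.where(hn > veg_threshold, VEGETATION, GROUND)
    df.loc[ok, "cls"] = cls
    return out, dem, grid


@dataclass(frozen=True)
class IntensityCorrectionParams:
    r_ref: float = 1000.0  # standard range, m

    def __post_init__(self):
        if self.r_ref <= 0:
            raise ValueError("R_ref must be > 0")


def correct_intensity(points: PointCloud,
                      params: IntensityCorrectionParams = IntensityCorrectionParams()
                      ) -> PointCloud:
    """Range/scan-angle intensity normalisation to the standard range."""
    theta = points.scan_angle
    cos_t = np.cos(np.radians(theta))
    if (cos_t <= 0).any():
        raise ValueError("scan angle at or beyond 90 degrees: cos(theta) <= 0")
    out = points.copy()
    out.df["intensity"] = (points.intensity * points.range ** 2
                           / (params.r_ref ** 2 * cos_t))
    return out


def clip_to_plot(points: PointCloud, plot_center, side: float = 25.0) -> PointCloud:
    """Axis-aligned (due-north) square clip, half-open on the east/north edges."""
    if side <= 0:
        raise ValueError("side must be > 0")
    cx, cy = plot_center
    h = side / 2.0
    df = points.df
    keep = ((df["x"] >= cx - h) & (df["x"] < cx + h)
            & (df["y"] >= cy - h) & (df["y"] < cy + h))
    return PointCloud(df[keep])


# ---------------------------------------------------------------------------
# metrics

def _moments(v: np.ndarray) -> dict:
    mean = v.mean()
    sd = np.sqrt(np.mean((v - mean) ** 2))
    if sd > 0:
        ske = np.mean((v - mean) ** 3) / sd ** 3
        kur = np.mean((v - mean) ** 4) / sd ** 4
    else:
        ske = kur = np.nan
    cv = sd / mean if mean != 0 else np.nan
    return {"max": v.max(), "min": v.min(), "mean": mean,
            "median": np.median(v), "cv": cv, "ske": ske, "kur": kur}


def compute_metrics(points: PointCloud, k_extinction: float = 0.5,
                    intensity_scope: str = "vegetation") -> pd.Series:
    """The 58-metric vector of one plot/cell of a normalised, corrected cloud.

    Height (and by default intensity) statistics are over vegetation returns;
    density slices D01..D10 split the [0, Hmax] height span of the vegetation
    returns into ten equal slices (boundary points belong to the upper slice,
    Hmax to D10). G.F uses all non-noise returns; canopy cover is the first-
    return vegetation fraction; LAI = −cos(ang)·ln(G.F)/k with ang the mean
    absolute scan angle. Undefined metrics (G.F = 0 → LAI; Hmax = Hmin →
    C.R.R) come back NaN with a warning.
    """
    if intensity_scope not in ("vegetation", "all"):
        raise ValueError("intensity_scope must be 'vegetation' or 'all'")
    df = points.df[points.df["cls"] != NOISE]
    n = len(df)
    if n == 0:
        raise ValueError("empty cloud: no non-noise points in plot")
    if "hn" not in df.columns or df["hn"].isna().any():
        raise ValueError("cloud must be height-normalised first")
    hn = df["hn"].to_numpy()
    veg = hn > VEG_HEIGHT_THRESHOLD
    n_veg = int(veg.sum())
    if n_veg == 0:
        raise ValueError("no vegetation returns in plot; metrics undefined")

    h = hn[veg]
    inten = df["intensity"].to_numpy()[veg if intensity_scope == "vegetation" else slice(None)]

    out = {}
    for p in _PCT:
        out[f"H{p:02d}"] = np.percentile(h, p)
    hm = _moments(h)
    out.update({"Hmax": hm["max"], "Hmin": hm["min"], "Hmean": hm["mean"],
                "Hmedian": hm["median"], "H.cv": hm["cv"], "H.ske": hm["ske"],
                "H.kur": hm["kur"]})

    hmax = h.max()
    width = hmax / 10.0
    idx = np.minimum(np.floor(h / width).astype(int), 9) if width > 0 else np.zeros(len(h), int)
    counts = np.bincount(idx, minlength=10)
    for i in range(10):
        out[f"D{i + 1:02d}"] = counts[i] / n_veg

    for p in _PCT:
        out[f"I{p:02d}"] = np.percentile(inten, p)
    im = _moments(inten)
    out.update({"Imax": im["max"], "Imin": im["min"], "Imean": im["mean"],
                "Imedian": im["median"], "I.cv": im["cv"], "I.ske": im["ske"],
                "I.kur": im["kur"]})

    gf = (n - n_veg) / n
    out["G.F"] = gf
    ang = np.mean(np.abs(df["scan_angle"].to_numpy()))
    if gf > 0:
        out["LAI"] = -np.cos(np.radians(ang)) * np.log(gf) / k_extinction
    else:
        warnings.warn("gap fraction is 0: LAI undefined", stacklevel=2)
        out["LAI"] = np.nan
    if hm["max"] > hm["min"]:
        out["C.R.R"] = (hm["mean"] - hm["min"]) / (hm["max"] - hm["min"])
    else:
        warnings.warn("Hmax equals Hmin: canopy relief ratio undefined", stacklevel=2)
        out["C.R.R"] = np.nan
    first = df["return_number"].to_numpy() == 1
    n_first = int(first.sum())
    out["C.C"] = (veg & first).sum() / n_first if n_first else np.nan

    return pd.Series(out, index=METRIC_NAMES, dtype=float)


def metrics_grid(points: PointCloud, grid: Grid, k_extinction: float = 0.5,
                 min_points: int = 10) -> dict:
    """Per-cell 58-metric rasters over ``grid`` (typically 25 m cells).

    Cells with fewer than ``min_points`` non-noise returns, or without
    vegetation returns, come back NaN.
    """
    df = points.df[points.df["cls"] != NOISE]
    row, col = grid.rowcol(df["x"].to_numpy(), df["y"].to_numpy())
    ok = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    df = df[ok].assign(_row=row[ok], _col=col[ok])
    out = {m: np.full(grid.shape, np.nan) for m in METRIC_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for (r, c), sub in df.groupby(["_row", "_col"]):
            if len(sub) < min_points or (sub["hn"] > VEG_HEIGHT_THRESHOLD).sum() == 0:
                continue
            vec = compute_metrics(PointCloud(sub.drop(columns=["_row", "_col"])),
                                  k_extinction=k_extinction)
            for m in METRIC_NAMES:
                out[m][r, c] = vec[m]
    return out
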