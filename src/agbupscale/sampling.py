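"""Line stage: stratified placement of 25 m × 25 m north-aligned sampling
plots inside the LiDAR strip coverage.

The field campaign this emulates picked pure-stand plots by visual
interpretation, uniformly spread, away from roads, inside the strip
footprints. Here a deterministic rule-based sampler replaces the analyst:
candidate centres sit on a coarse jittered grid (jitter bounded so the grid
spacing guarantees the minimum pairwise distance), and a candidate survives
if its square lies fully inside the strips, touches no road buffer, and at
least ``purity`` of its pixels carry one stratum's label. Per stratum, the
requested number of survivors is drawn with the seeded generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .grids import Grid, overlap_weights
from .synth import CODE_TO_SPECIES, SPECIES_CODES

PLOT_SIDE = 25.0


@dataclass
class SamplingPlot:
    id: int
    stratum: str
    x: float          # centre easting, m
    y: float          # centre northing, m
    agb_lidar: float = np.nan
    source: str = "lidar_sample"

    @property
    def polygon(self):
        h = PLOT_SIDE / 2.0
        return box(self.x - h, self.y - h, self.x + h, self.y + h)

    @property
    def bounds(self):
        h = PLOT_SIDE / 2.0
        return (self.x - h, self.y - h, self.x + h, self.y + h)


def _window_ok(mask: np.ndarray, grid: Grid, bounds, want: bool = True) -> bool:
    rows, cols, w = overlap_weights(grid, *bounds)
    if w.size == 0 or w.sum() < (PLOT_SIDE ** 2) * 0.999:
        return False
    sub = mask[np.ix_(rows, cols)]
    if want:
        return bool(((w > 1e-9) <= sub).all())     # every overlapped pixel True
    return not bool(sub[w > 1e-9].any())           # no overlapped pixel True


def _purity(species: np.ndarray, grid: Grid, bounds):
    rows, cols, w = overlap_weights(grid, *bounds)
    if w.size == 0:
        return None, 0.0
    sub = species[np.ix_(rows, cols)]
    total = w.sum()
    best_code, best_frac = None, 0.0
    for code in np.unique(sub):
        frac = w[sub == code].sum() / total
        if frac > best_frac:
            best_code, best_frac = int(code), frac
    return best_code, best_frac


def sample_plots(strip_mask: np.ndarray, species_raster: np.ndarray,
                 road_mask: np.ndarray, grid: Grid, n_per_stratum: dict,
                 min_spacing: float = 100.0, purity: float = 0.9,
                 seed: int = 0) -> list[SamplingPlot]:
    """Stratified, seeded, quasi-uniform plot placement.

    Candidate centres sit on a 25 m lattice; geometrically valid candidates
    (square inside strips, off roads, stratum-pure) are accepted in seeded
    random order subject to the hard-core ``min_spacing`` constraint against
    every already-accepted plot — a deterministic stand-in for an analyst
    spreading plots uniformly. Raises with the achievable counts when a
    request is infeasible.
    """
    if min_spacing < PLOT_SIDE:
        raise ValueError("min_spacing must be at least the 25 m plot side")
    rng = np.random.default_rng(seed)
    species = np.asarray(species_raster)
    roads = np.asarray(road_mask, bool)
    strip = np.asarray(strip_mask, bool)

    h = PLOT_SIDE / 2.0
    xs = np.arange(grid.xmin + h, grid.xmax - h + 1e-9, PLOT_SIDE)
    ys = np.arange(grid.ymin + h, grid.ymax - h + 1e-9, PLOT_SIDE)
    GX, GY = np.meshgrid(xs, ys)
    cx, cy = GX.ravel(), GY.ravel()
    # cheap prefilter on the centre pixel before the exact window tests
    row, col = grid.rowcol(cx, cy)
    inb = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    pre = np.zeros(len(cx), bool)
    pre[inb] = strip[row[inb], col[inb]] & ~roads[row[inb], col[inb]]

    candidates: dict[str, list] = {s: [] for s in n_per_stratum}
    for x, y in zip(cx[pre], cy[pre]):
        bounds = (x - h, y - h, x + h, y + h)
        if not _window_ok(strip, grid, bounds, want=True):
            continue
        if not _window_ok(~roads, grid, bounds, want=True):
            continue
        code, frac = _purity(species, grid, bounds)
        if code is None or code not in CODE_TO_SPECIES or frac < purity:
            continue
        stratum = CODE_TO_SPECIES[code]
        if stratum in candidates:
            candidates[stratum].append((x, y))

    plots, pid = [], 0
    accepted: list[tuple] = []
    achievable = {}
    for stratum in sorted(n_per_stratum):
        pool = candidates[stratum]
        order = rng.permutation(len(pool))
        taken = 0
        for i in order:
            if taken >= n_per_stratum[stratum]:
                break
            x, y = pool[i]
            if any((x - ax) ** 2 + (y - ay) ** 2 < min_spacing ** 2
                   for ax, ay in accepted):
                continue
            accepted.append((x, y))
            plots.append(SamplingPlot(id=pid, stratum=stratum, x=x, y=y))
            pid += 1
            taken += 1
        achievable[stratum] = taken
    short = {s: n for s, n in n_per_stratum.items() if achievable.get(s, 0) < n}
    if short:
        raise ValueError(
            f"infeasible sampling request {short}; achievable counts: {achievable}")
    return plots


def attach_reference_agb(plots: list[SamplingPlot], agb_raster: np.ndarray,
                         grid: Grid, max_nodata_frac: float = 0.5
                         ) -> list[SamplingPlot]:
    """Area-weighted mean of the AGB raster over each plot square.

    Plots with more than ``max_nodata_frac`` of their area over NaN cells are
    dropped with a warning.
    """
    agb = np.asarray(agb_raster, float)
    kept = []
    dropped = 0
    for p in plots:
        rows, cols, w = overlap_weights(grid, *p.bounds)
        if w.size == 0:
            dropped += 1
            continue
        sub = agb[np.ix_(rows, cols)]
        finite = np.isfinite(sub)
        if w[~finite].sum() > max_nodata_frac * (PLOT_SIDE ** 2):
            dropped += 1
            continue
        val = (sub[finite] * w[finite]).sum() / w[finite].sum()
        kept.append(SamplingPlot(p.id, p.stratum, p.x, p.y, agb_lidar=float(val),
                                 source=p.source))
    if dropped:
        warnings.warn(f"dropped {dropped} plot(s) dominated by nodata", stacklevel=2)
    return kept


def plots_frame(plots: list[SamplingPlot]) -> pd.DataFrame:
    return pd.DataFrame([{"id": p.id, "stratum": p.stratum, "x": p.x, "y": p.y,
                          "AGB_LiDAR": p.agb_lidar, "source": p.source}
                         for p in plots])


def plots_to_geojson(plots: list[SamplingPlot], path) -> None:
    import json

    feats = []
    for p in plots:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": [list(p.polygon.exterior.coords)]},
            "properties": {"id": p.id, "stratum": p.stratum,
                           "AGB_LiDAR": None if np.isnan(p.agb_lidar) else p.agb_lidar,
                           "source": p.source},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
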