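"""North-up raster grids and named multiband stacks.

Rasters here are plain numpy arrays tied to a :class:`Grid` that maps planar
metre coordinates (origin at the region corner) to row/column indices. Pixels
own the half-open interval ``[x, x + px)`` in easting and, symmetrically,
``(y_top - (r+1)*px, y_top - r*px]`` in northing, so a point is never claimed
by two pixels. Row 0 is the northern edge (row-major, north-up). The value of
a pixel represents the whole pixel area.

Nodata is ``NaN`` throughout; there is no separate mask plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Grid:
    """A north-up rectilinear pixel grid in planar metre coordinates."""

    xmin: float
    ymax: float
    nrows: int
    ncols: int
    px: float = 10.0

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0 or self.px <= 0:
            raise ValueError("grid must have positive shape and pixel size")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.px

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.px

    @classmethod
    def from_extent(cls, xmin: float, ymin: float, xmax: float, ymax: float,
                    px: float = 10.0) -> "Grid":
        ncols = int(np.ceil((xmax - xmin) / px))
        nrows = int(np.ceil((ymax - ymin) / px))
        return cls(xmin=xmin, ymax=ymin + nrows * px, nrows=nrows, ncols=ncols, px=px)

    def rowcol(self, x, y):
        """Map coordinates to (row, col); no bounds clipping."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xmin) / self.px).astype(int)
        row = np.floor((self.ymax - y) / self.px).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.rowcol(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of pixel-centre coordinates, shape (nrows, ncols)."""
        xs = self.xmin + (np.arange(self.ncols) + 0.5) * self.px
        ys = self.ymax - (np.arange(self.nrows) + 0.5) * self.px
        return np.meshgrid(xs, ys)

    def same_as(self, other: "Grid") -> bool:
        return (self.shape == other.shape and self.px == other.px
                and np.isclose(self.xmin, other.xmin)
                and np.isclose(self.ymax, other.ymax))


def overlap_weights(grid: Grid, xmin: float, ymin: float, xmax: float, ymax: float):
    """Exact area-overlap weights of an axis-aligned rectangle against a grid.

    Returns ``(rows, cols, w)`` where ``w[i, j]`` is the overlap area (m²) of
    the rectangle with pixel ``(rows[i], cols[j])``. Used for area-weighted
    plot aggregation of 25 m plots over 10 m pixels.
    """
    px = grid.px
    c0 = int(np.floor((xmin - grid.xmin) / px))
    c1 = int(np.ceil((xmax - grid.xmin) / px))
    r0 = int(np.floor((grid.ymax - ymax) / px))
    r1 = int(np.ceil((grid.ymax - ymin) / px))
    c0, c1 = max(c0, 0), min(c1, grid.ncols)
    r0, r1 = max(r0, 0), min(r1, grid.nrows)
    if c0 >= c1 or r0 >= r1:
        return np.array([], int), np.array([], int), np.zeros((0, 0))
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    # 1-D overlap lengths along each axis; outer product gives areas
    cell_x0 = grid.xmin + cols * px
    wx = np.minimum(cell_x0 + px, xmax) - np.maximum(cell_x0, xmin)
    cell_y1 = grid.ymax - rows * px
    wy = np.minimum(cell_y1, ymax) - np.maximum(cell_y1 - px, ymin)
    w = np.outer(np.clip(wy, 0, None), np.clip(wx, 0, None))
    return rows, cols, w


class RasterStack:
    """A registry of co-gridded named bands with variable-group tags.

    Groups follow the experiment bookkeeping of the upscaling workflow:
    ``a`` spectral + vegetation indices + biophysical, ``b`` optical wavelet
    textures, ``c`` SAR backscatter + GLCM textures, ``d`` SAR wavelet
    textures. Auxiliary layers (DEM, masks, truth) carry group ``aux``.
    """

    def __init__(self, grid: Grid):
        self.grid = grid
        self._bands: dict[str, np.ndarray] = {}
        self._groups: dict[str, str] = {}

    def add(self, name: str, data: np.ndarray, group: str = "aux") -> None:
        data = np.asarray(data, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"band {name!r} shape {data.shape} does not match grid {self.grid.shape}")
        if name in self._bands:
            raise ValueError(f"duplicate band name {name!r}")
        self._bands[name] = data
        self._groups[name] = group

    def __getitem__(self, name: str) -> np.ndarray:
        return self._bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self._bands

    def __len__(self) -> int:
        return len(self._bands)

    @property
    def names(self) -> list[str]:
        return list(self._bands)

    def group(self, name: str) -> str:
        return self._groups[name]

    def names_in_groups(self, groups) -> list[str]:
        groups = set(groups)
        return [n for n in self._bands if self._groups[n] in groups]

    def manifest(self) -> pd.DataFrame:
        """One row per band: name and variable group."""
        return pd.DataFrame({"name": self.names,
                             "group": [self._groups[n] for n in self.names]})

    def subset(self, names) -> "RasterStack":
        out = RasterStack(self.grid)
        for n in names:
            out.add(n, self._bands[n], self._groups[n])
        return out

    def to_array(self, names=None) -> np.ndarray:
        names = self.names if names is None else list(names)
        return np.stack([self._bands[n] for n in names])

    def sample(self, x, y, names=None) -> pd.DataFrame:
        """Point-sample bands at coordinates; out-of-grid rows are NaN."""
        names = self.names if names is None else list(names)
        row, col = self.grid.rowcol(x, y)
        ok = (row >= 0) & (row < self.grid.nrows) & (col >= 0) & (col < self.grid.ncols)
        out = {}
        for n in names:
            v = np.full(row.shape, np.nan)
            v[ok] = self._bands[n][row[ok], col[ok]]
            out[n] = v
        return pd.DataFrame(out)

    def write_tiff(self, path) -> None:
        """Export bands as a multi-page 32-bit TIFF (one page per band)."""
        import tifffile

        arr = self.to_array().astype(np.float32)
        tifffile.imwrite(path, arr, metadata={
            "band_names": self.names,
            "groups": [self._groups[n] for n in self.names],
            "xmin": self.grid.xmin, "ymax": self.grid.ymax, "px": self.grid.px,
        })
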