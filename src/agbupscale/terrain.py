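"""Topographic illumination (C-model) correction for optical bands.

The local solar incidence angle i on a slope follows

    cos i = cos(sz) cos(tz) + sin(sz) sin(tz) cos(sa - ta)

with solar zenith sz, solar azimuth sa, terrain slope tz and terrain aspect
ta. The C model corrects a band L_T to the horizontal-equivalent radiance

    L_H = L_T * (cos sz + C) / (cos i + C),   C = b / m

where m, b are the slope and intercept of the per-band linear regression of
L_T on cos i. Slope/aspect come from the 3×3 Horn gradient of the DEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]) / 8.0
_HORN_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]]) / 8.0  # row 0 = north


def horn_gradient(dem: np.ndarray, px: float):
    """(dz/dx east, dz/dy north) by Horn's 3×3 weighted differences."""
    dem = np.asarray(dem, float)
    gx = ndimage.correlate(dem, _HORN_X, mode="nearest") / px
    gy = ndimage.correlate(dem, _HORN_Y, mode="nearest") / px
    return gx, gy


def slope_aspect(dem: np.ndarray, px: float):
    """Terrain slope tz and aspect ta (degrees; aspect = downslope azimuth,
    clockwise from north). Flat pixels get aspect 0 by convention."""
    gx, gy = horn_gradient(dem, px)
    tz = np.degrees(np.arctan(np.hypot(gx, gy)))
    ta = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    return tz, ta


def cos_incidence(dem: np.ndarray, solar_zenith: float, solar_azimuth: float,
                  px: float) -> np.ndarray:
    """Per-pixel cos i from the DEM and the solar geometry (all in degrees)."""
    tz, ta = slope_aspect(dem, px)
    sz = np.radians(solar_zenith)
    sa = np.radians(solar_azimuth)
    tzr = np.radians(tz)
    tar = np.radians(ta)
    return (np.cos(sz) * np.cos(tzr)
            + np.sin(sz) * np.sin(tzr) * np.cos(sa - tar))


@dataclass
class CCorrectionInfo:
    """Per-band fit diagnostics of the C correction."""
    c: float | None          # b/m; None when the correction was skipped
    slope_m: float
    intercept_b: float
    n_fit: int
    n_nodata: int            # pixels where cos i + C ~ 0
    skipped: bool
    reason: str = ""


def c_correction(band: np.ndarray, cos_i: np.ndarray, solar_zenith: float,
                 mask: np.ndarray | None = None, min_slope: float = 1e-8,
                 guard: float = 1e-6):
    """Apply the C model to one band; returns (corrected, CCorrectionInfo).

    The regression runs over finite pixels (optionally restricted by
    ``mask``). When the band shows no usable dependence on cos i (|m| below
    tolerance, e.g. flat terrain where cos i is constant), the band is
    returned unchanged and the skip is recorded. Pixels where |cos i + C|
    falls under ``guard`` become NaN and are counted.
    """
    band = np.asarray(band, float)
    cos_i = np.asarray(cos_i, float)
    if band.shape != cos_i.shape:
        raise ValueError("band and cos_i are not co-registered")
    valid = np.isfinite(band) & np.isfinite(cos_i)
    if mask is not None:
        valid &= np.asarray(mask, bool)
    xv, yv = cos_i[valid], band[valid]
    if xv.size < 3 or np.ptp(xv) < 1e-12:
        return band.copy(), CCorrectionInfo(None, 0.0, float(yv.mean()) if yv.size else np.nan,
                                            int(xv.size), 0, True, "cos_i has no variation")
    m, b = np.polyfit(xv, yv, 1)
    if abs(m) < min_slope:
        return band.copy(), CCorrectionInfo(None, float(m), float(b), int(xv.size),
                                            0, True, "regression slope ~ 0")
    c = b / m
    denom = cos_i + c
    bad = np.abs(denom) < guard
    out = np.where(bad, np.nan,
                   band * (np.cos(np.radians(solar_zenith)) + c) / np.where(bad, 1.0, denom))
    return out, CCorrectionInfo(float(c), float(m), float(b), int(xv.size),
                                int(bad.sum()), False)
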