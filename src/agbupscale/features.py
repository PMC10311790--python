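"""The 197-variable satellite feature stack.

Four variable groups feed the upscaling experiments:

* ``a`` — 10 surface-reflectance bands (B2…B12, terrain-corrected),
  19 vegetation indices and 5 biophysical variables (34);
* ``b`` — 120 optical multi-scale wavelet textures (10 bands × 3 levels ×
  4 subbands);
* ``c`` — 3 backscatter variables (VV, VH, VH/VV) and 16 GLCM spatial
  textures of the two polarisations (19);
* ``d`` — 24 SAR multi-scale wavelet textures (2 channels × 3 levels × 4).

Totals: 154 optical, 43 SAR, 197 features.

Biophysical variables are normally retrieved by an external biophysical
processor; in ``proxy`` mode they are replaced by documented monotone
NDVI/infrared-index surrogates and flagged as such in the manifest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .glcm import glcm_textures, STATISTICS
from .grids import Grid, RasterStack
from .terrain import c_correction, cos_incidence
from .wavelets import WaveletConfig, dwt_textures

OPTICAL_BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8a", "B11", "B12")
VI_NAMES = ("ARVI", "CIg", "CIre", "II", "MCARI", "S2REP", "MidIR", "MSI", "NDVI",
            "NDI45", "RVI", "SAVI", "IPVI", "PVI", "PSSRa", "PSRI", "REIP",
            "TNDVI", "VARI")
BIOPHYSICAL_NAMES = ("LAI", "FVC", "FAPAR", "Cab", "Cwc")


def _safe_div(num, den):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(np.isfinite(out), out, np.nan)


def vegetation_indices(stack: RasterStack) -> dict:
    """The 19 vegetation-index bands from B2…B12 (division by zero → NaN)."""
    missing = [b for b in OPTICAL_BAND_NAMES if b not in stack]
    if missing:
        raise KeyError(f"missing optical band(s): {missing}")
    B = {n: stack[n] for n in OPTICAL_BAND_NAMES}
    s45 = np.sin(np.radians(45.0))
    c45 = np.cos(np.radians(45.0))
    re_mid = (B["B4"] + B["B7"]) / 2.0 - B["B5"]
    out = {
        "ARVI": _safe_div(B["B8"] - (2 * B["B4"] - B["B2"]),
                          B["B8"] + (2 * B["B4"] - B["B2"])),
        "CIg": _safe_div(B["B8"], B["B3"]) - 1.0,
        "CIre": _safe_div(B["B7"], B["B5"]) - 1.0,
        "II": _safe_div(B["B8"] - B["B11"], B["B8"] + B["B11"]),
        "MCARI": ((B["B5"] - B["B4"]) - 0.2 * (B["B5"] - B["B3"])) * (B["B5"] - B["B4"]),
        "S2REP": 705.0 + 35.0 * re_mid * (B["B6"] - B["B5"]),
        "MidIR": _safe_div(B["B11"], B["B12"]),
        "MSI": _safe_div(B["B11"], B["B8"]),
        "NDVI": _safe_div(B["B8"] - B["B4"], B["B8"] + B["B4"]),
        "NDI45": _safe_div(B["B5"] - B["B4"], B["B5"] + B["B4"]),
        "RVI": _safe_div(B["B8"], B["B4"]),
        "SAVI": _safe_div(1.5 * (B["B8"] - B["B4"]), B["B8"] + B["B4"] + 0.5),
        "IPVI": _safe_div(B["B8"], B["B8"] + B["B4"]),
        "PVI": s45 * B["B8"] - c45 * B["B4"],
        "PSSRa": _safe_div(B["B7"], B["B4"]),
        "PSRI": _safe_div(B["B4"] - B["B3"], B["B6"]),
        "REIP": 700.0 + 40.0 * _safe_div(re_mid, B["B6"] - B["B5"]),
        "VARI": _safe_div(B["B3"] - B["B4"], B["B3"] + B["B4"] - B["B2"]),
    }
    ndvi = out["NDVI"]
    with np.errstate(invalid="ignore"):
        out["TNDVI"] = np.sqrt(np.where(ndvi + 0.5 >= 0, ndvi + 0.5, np.nan))
    return {k: out[k] for k in VI_NAMES}


def biophysical_proxies(stack: RasterStack, mode: str = "proxy") -> dict:
    """LAI/FVC/FAPAR/Cab/Cwc bands.

    ``supplied`` passes through user bands of those names; ``proxy`` computes
    monotone surrogates from NDVI and the infrared index:
    FVC = clip(NDVI, 0, 1)², LAI = −2·ln(1 − min(FVC, 0.99)),
    FAPAR = 0.95·FVC, Cab = 60·FVC, Cwc = 0.2·clip((II + 1)/2, 0, 1).
    These are explicit stand-ins, not radiative-transfer retrievals.
    """
    if mode == "supplied":
        missing = [b for b in BIOPHYSICAL_NAMES if b not in stack]
        if missing:
            raise KeyError(f"supplied mode but missing band(s): {missing}")
        return {b: stack[b] for b in BIOPHYSICAL_NAMES}
    if mode != "proxy":
        raise ValueError("mode must be 'supplied' or 'proxy'")
    vi = vegetation_indices(stack)
    fvc = np.clip(vi["NDVI"], 0.0, 1.0) ** 2
    lai = -2.0 * np.log(1.0 - np.minimum(fvc, 0.99))
    return {"LAI": lai, "FVC": fvc, "FAPAR": 0.95 * fvc, "Cab": 60.0 * fvc,
            "Cwc": 0.2 * np.clip((vi["II"] + 1.0) / 2.0, 0.0, 1.0)}


def sar_backscatter(stack: RasterStack) -> dict:
    """VV, VH (dB) and the linear-power VH/VV ratio."""
    for b in ("VV", "VH"):
        if b not in stack:
            raise KeyError(f"missing SAR band {b}")
    ratio = 10.0 ** ((stack["VH"] - stack["VV"]) / 10.0)
    return {"VV": stack["VV"], "VH": stack["VH"], "VH/VV": ratio}


def assemble_feature_stack(optical: RasterStack, sar: RasterStack | None,
                           dem: np.ndarray | None, solar_zenith: float = 30.0,
                           solar_azimuth: float = 150.0,
                           biophysical_mode: str = "proxy",
                           wavelet: WaveletConfig = WaveletConfig(),
                           glcm_levels: int = 32,
                           terrain_correct: bool = True) -> RasterStack:
    """Build the tagged feature stack (groups a/b/c/d) on the optical grid.

    With SAR input the stack holds 197 bands (154 optical + 43 SAR); without
    it, groups a and b only (154). Optical reflectance is C-corrected against
    the DEM illumination and clipped to [0, 1] (clip counts recorded in
    ``stack.c_correction_log``).
    """
    grid = optical.grid
    if sar is not None and not sar.grid.same_as(grid):
        raise ValueError("optical and SAR stacks are not co-registered")
    out = RasterStack(grid)
    log = {"c_correction": {}, "clipped": {}}

    corrected = {}
    cos_i = None
    if terrain_correct and dem is not None:
        if np.asarray(dem).shape != grid.shape:
            raise ValueError("DEM does not match the optical grid")
        cos_i = cos_incidence(dem, solar_zenith, solar_azimuth, grid.px)
    for name in OPTICAL_BAND_NAMES:
        if name not in optical:
            raise KeyError(f"missing optical band {name}")
        band = optical[name]
        if cos_i is not None:
            band, info = c_correction(band, cos_i, solar_zenith)
            log["c_correction"][name] = info
        n_clip = int(((band < 0) | (band > 1)).sum())
        if n_clip:
            log["clipped"][name] = n_clip
        corrected[name] = np.clip(band, 0.0, 1.0)
        out.add(name, corrected[name], group="a")

    corr_stack = RasterStack(grid)
    for n, b in corrected.items():
        corr_stack.add(n, b, group="a")
    for n, b in vegetation_indices(corr_stack).items():
        out.add(n, b, group="a")
    for n, b in biophysical_proxies(
            corr_stack if biophysical_mode == "proxy" else optical,
            mode=biophysical_mode).items():
        out.add(n, b, group="a")

    for name in OPTICAL_BAND_NAMES:
        tex = dwt_textures(corrected[name], wavelet)
        for key, arr in tex.items():  # key like "a_1"
            out.add(f"{key}_{name}", arr, group="b")

    if sar is not None:
        for n, b in sar_backscatter(sar).items():
            out.add(n, b, group="c")
        for pol in ("VH", "VV"):
            for n, b in glcm_textures(sar[pol], levels=glcm_levels,
                                      prefix=f"{pol}_").items():
                out.add(n, b, group="c")
        # SAR texture channel convention: B1 = VH, B2 = VV
        for chan, pol in (("B1", "VH"), ("B2", "VV")):
            tex = dwt_textures(sar[pol], wavelet)
            for key, arr in tex.items():
                out.add(f"{key}_{chan}_sar", arr, group="d")

    out.c_correction_log = log
    return out


def feature_manifest(stack: RasterStack) -> pd.DataFrame:
    """Band manifest with group tags and optical/SAR source labels."""
    m = stack.manifest()
    m["source"] = np.where(m["group"].isin(["a", "b"]), "optical",
                           np.where(m["group"].isin(["c", "d"]), "sar", "aux"))
    return m
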