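"""Separable 2-D discrete wavelet transform and multi-scale texture bands.

A three-level 2-D DWT with the Sym5 (least-asymmetric, 5-vanishing-moment
Symlet) basis decomposes each image into an approximation subband (LL) and
horizontal / vertical / diagonal detail subbands (HL, LH, HH) per level; each
further level re-decomposes the previous LL only. Subband magnitudes,
replicated back to the input grid, serve as frequency-domain texture
features.

The filter bank is hard-coded (no wavelet library in the runtime) and is an
orthonormal QMF pair: the analysis matrix of the periodized transform is
orthogonal, so reconstruction is exact to rounding error — asserted in the
test suite. The default boundary mode is periodization (level-j subbands
have exactly ceil(N/2^j) coefficients, which replicate cleanly to the pixel
grid); symmetric half-point extension is available for analysis/textures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Sym5 decomposition low-pass filter (orthonormal scaling coefficients).
SYM5_DEC_LO = np.array([
    0.027333068345077982, 0.029519490925774643, -0.039134249302383094,
    0.199397533977393920, 0.723407690402420600, 0.633978963458211900,
    0.016602105764522319, -0.175328089908450470, -0.021101834024758855,
    0.019538882735286728,
])


def qmf_pair(dec_lo: np.ndarray = SYM5_DEC_LO):
    """High-pass partner by the quadrature-mirror relation g[n] = (-1)^n h[L-1-n]."""
    L = len(dec_lo)
    signs = (-1.0) ** np.arange(L)
    dec_hi = signs * dec_lo[::-1]
    return np.asarray(dec_lo, float), dec_hi


@dataclass
class WaveletConfig:
    """Wavelet basis, decomposition depth and boundary handling."""

    wavelet: str = "sym5"
    levels: int = 3
    mode: str = "periodization"  # or "symmetric" (analysis only)

    def __post_init__(self):
        if self.wavelet != "sym5":
            raise ValueError("only the sym5 basis is provided")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.mode not in ("periodization", "symmetric"):
            raise ValueError(f"unknown boundary mode {self.mode!r}")

    @property
    def filters(self):
        return qmf_pair()


def _dwt1d_per(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Periodized single-level DWT along the last axis (odd lengths edge-pad)."""
    n = x.shape[-1]
    if n % 2:
        x = np.concatenate([x, x[..., -1:]], axis=-1)
        n += 1
    L = len(lo)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n
    win = x[..., idx]                       # (..., n/2, L)
    return win @ lo, win @ hi


def _idwt1d_per(ca: np.ndarray, cd: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                out_len: int):
    """Inverse of :func:`_dwt1d_per` (transpose of the orthogonal analysis)."""
    m = ca.shape[-1]
    n = 2 * m
    L = len(lo)
    x = np.zeros(ca.shape[:-1] + (n,))
    for t in range(L):
        pos = (2 * np.arange(m) + t) % n
        np.add.at(x, (..., pos), ca * lo[t] + cd * hi[t])
    return x[..., :out_len]


def _dwt1d_sym(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Symmetric (half-point) extension DWT along the last axis; analysis only."""
    L = len(lo)
    ext = np.concatenate([x[..., :L - 1][..., ::-1], x, x[..., -(L - 1):][..., ::-1]],
                         axis=-1)
    n_out = (x.shape[-1] + L - 1) // 2
    idx = 2 * np.arange(n_out)[:, None] + 1 + np.arange(L)[None, :]
    win = ext[..., idx]
    return win @ lo[::-1], win @ hi[::-1]


def dwt2(image: np.ndarray, config: WaveletConfig = WaveletConfig()):
    """One decomposition level: returns (LL, (HL, LH, HH)).

    HL carries horizontal detail (high-pass across columns), LH vertical
    detail, HH diagonal.
    """
    image = np.asarray(image, float)
    lo, hi = config.filters
    step = _dwt1d_per if config.mode == "periodization" else _dwt1d_sym
    lo_x, hi_x = step(image, lo, hi)                    # along rows (x)
    ll, lh = step(np.swapaxes(lo_x, 0, 1), lo, hi)      # along columns (y)
    hl, hh = step(np.swapaxes(hi_x, 0, 1), lo, hi)
    swap = lambda a: np.swapaxes(a, 0, 1)
    return swap(ll), (swap(hl), swap(lh), swap(hh))


def idwt2(ll, details, shape, config: WaveletConfig = WaveletConfig()):
    """Inverse of one periodized level back to ``shape``."""
    if config.mode != "periodization":
        raise NotImplementedError("inverse transform is provided for periodization mode")
    hl, lh, hh = details
    lo, hi = config.filters
    nrow, ncol = shape
    mid_rows = nrow + (nrow % 2)
    lo_x = np.swapaxes(_idwt1d_per(np.swapaxes(ll, 0, 1), np.swapaxes(lh, 0, 1),
                                   lo, hi, mid_rows), 0, 1)[:nrow]
    hi_x = np.swapaxes(_idwt1d_per(np.swapaxes(hl, 0, 1), np.swapaxes(hh, 0, 1),
                                   lo, hi, mid_rows), 0, 1)[:nrow]
    out = _idwt1d_per(lo_x[:, :], hi_x[:, :], lo, hi, ncol)
    return out


def max_levels(shape, filter_len: int = len(SYM5_DEC_LO)) -> int:
    n = min(shape)
    lev = 0
    while n >= filter_len:
        n = (n + 1) // 2
        lev += 1
    return lev


def wavedec2(image: np.ndarray, config: WaveletConfig = WaveletConfig()):
    """Multi-level cascade on the LL band (coarsest first in the return).

    Returns ``(ll_J, [details_J, ..., details_1], [shape_J-1, ..., shape_0])``
    where ``details_j = (HL_j, LH_j, HH_j)`` and shapes record the input shape
    of each level for exact inversion.
    """
    image = np.asarray(image, float)
    feasible = max_levels(image.shape)
    if config.levels > feasible:
        raise ValueError(
            f"image of shape {image.shape} supports at most {feasible} "
            f"decomposition level(s) with a {len(SYM5_DEC_LO)}-tap filter")
    details, shapes = [], []
    ll = image
    for _ in range(config.levels):
        shapes.append(ll.shape)
        ll, det = dwt2(ll, config)
        details.append(det)
    return ll, details[::-1], shapes[::-1]


def waverec2(ll, details, shapes, config: WaveletConfig = WaveletConfig()):
    """Exact inverse of :func:`wavedec2` (periodization mode)."""
    out = ll
    for det, shape in zip(details, shapes):
        out = idwt2(out, det, shape, config)
    return out


_SUBBAND_ORDER = ("a", "h", "v", "d")  # LL, HL, LH, HH


def dwt_textures(band: np.ndarray, config: WaveletConfig = WaveletConfig()) -> dict:
    """Multi-scale texture bands: |subband| replicated back to the input grid.

    Returns ``{"a_1": ..., "h_1": ..., ..., "d_L": ...}`` — 4·levels arrays of
    the input shape. Level j coefficients are nearest-neighbour replicated by
    2^j (then cropped), so texture pixels align with the source grid.
    """
    band = np.asarray(band, float)
    nrow, ncol = band.shape
    _, details, _ = wavedec2(band, config)
    # recompute the cascade keeping every level's LL for the "a" textures
    out = {}
    ll = band
    for j in range(1, config.levels + 1):
        ll, (hl, lh, hh) = dwt2(ll, config)
        f = 2 ** j
        for key, sub in zip(_SUBBAND_ORDER, (ll, hl, lh, hh)):
            up = np.repeat(np.repeat(np.abs(sub), f, axis=0), f, axis=1)
            out[f"{key}_{j}"] = up[:nrow, :ncol]
    return out
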