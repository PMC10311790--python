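"""Per-pixel grey-level co-occurrence (GLCM) textures.

Second-order texture statistics of each pixel's 3×3 neighbourhood at the 45°
offset (one step up-right, (Δrow, Δcol) = (−1, +1)), from the symmetric
co-occurrence matrix of the min–max-quantised band. Within a 3×3 window the
45° offset yields four ordered pixel pairs; with their transposes the
symmetric GLCM holds eight entries of probability 1/8 each (coincident pairs
accumulate). Edges use reflected padding.

Eight statistics per pixel: mean, entropy, contrast, dissimilarity, variance,
correlation, homogeneity and angular second moment. A constant window has
undefined correlation; the convention here is correlation = 0.
"""

from __future__ import annotations

import numpy as np

STATISTICS = ("mean", "ent", "con", "dis", "var", "cor", "hom", "asm")

# ordered 45° pairs inside a 3×3 window, as (row, col) offsets of the pair
# base relative to the window centre; the partner sits at (row-1, col+1)
_PAIR_BASES = [(0, -1), (0, 0), (1, -1), (1, 0)]


def quantize(band: np.ndarray, levels: int = 32) -> np.ndarray:
    """Min–max quantisation to integer grey levels 0..levels-1."""
    band = np.asarray(band, float)
    lo = np.nanmin(band)
    hi = np.nanmax(band)
    if hi <= lo:
        return np.zeros(band.shape, int)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def glcm_textures(band: np.ndarray, window: int = 3, direction: float = 45.0,
                  levels: int = 32, prefix: str = "") -> dict:
    """Eight per-pixel GLCM texture bands of ``band``.

    Only the 3×3 window at the 45° offset is implemented — the configuration
    used for the SAR spatial textures. Returns a dict keyed
    ``{prefix}mean, {prefix}ent, ...``.
    """
    if window != 3 or direction != 45.0:
        raise NotImplementedError("GLCM is implemented for a 3×3 window at 45°")
    q = quantize(band, levels)
    qp = np.pad(q, 1, mode="reflect")
    H, W = q.shape

    # stack the 8 ordered co-occurrence entries per pixel: 4 pairs + transposes
    i_list, j_list = [], []
    for dr, dc in _PAIR_BASES:
        a = qp[1 + dr: 1 + dr + H, 1 + dc: 1 + dc + W]
        b = qp[dr: dr + H, 2 + dc: 2 + dc + W]  # partner at (dr-1, dc+1)
        i_list += [a, b]
        j_list += [b, a]
    I = np.stack(i_list).astype(float)   # (8, H, W)
    J = np.stack(j_list).astype(float)

    mean = I.mean(axis=0)                # symmetric: row and column means equal
    var = ((I - mean) ** 2).mean(axis=0)
    con = ((I - J) ** 2).mean(axis=0)
    dis = np.abs(I - J).mean(axis=0)
    hom = (1.0 / (1.0 + (I - J) ** 2)).mean(axis=0)
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = ((I - mean) * (J - mean)).mean(axis=0) / var
    cor = np.where(sd > 0, cor, 0.0)     # constant window: correlation := 0

    # entropy / ASM need multiplicities of identical (i, j) cells
    code = (I * levels + J).astype(np.int32)
    mult = np.zeros((8, H, W))
    for s in range(8):
        mult[s] = (code == code[s]).sum(axis=0)
    asm = (mult / 64.0).sum(axis=0)      # Σ_k (m_k/8)² via slot-wise m/64
    ent = -(np.log(mult / 8.0) / 8.0).sum(axis=0)

    out = {f"{prefix}mean": mean, f"{prefix}ent": ent, f"{prefix}con": con,
           f"{prefix}dis": dis, f"{prefix}var": var, f"{prefix}cor": cor,
           f"{prefix}hom": hom, f"{prefix}asm": asm}
    return out
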