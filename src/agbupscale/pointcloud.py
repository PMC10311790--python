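"""Columnar point-cloud container with LAS-style class codes.

The cloud is a thin wrapper over a pandas DataFrame with the columns
``x, y, z`` (m), ``intensity`` (arbitrary units ≥ 0), ``range`` (sensor–target
slant range, m), ``scan_angle`` (degrees off nadir), ``return_number`` and
``cls`` (classification code). First-return-only acquisitions carry
``return_number == 1`` everywhere. After height normalisation a column
``hn`` (height above ground, m) is added.

I/O is plain CSV (optionally gzipped) — the portable dialect for point tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# LAS-inspired classification codes
UNCLASSIFIED = 1
GROUND = 2
VEGETATION = 5
NOISE = 7

COLUMNS = ["x", "y", "z", "intensity", "range", "scan_angle", "return_number", "cls"]


class PointCloud:
    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"point table missing columns: {missing}")
        if len(df):
            for c in ("x", "y", "z"):
                if not np.isfinite(df[c].to_numpy()).all():
                    raise ValueError(f"non-finite values in column {c!r}")
            if (df["range"].to_numpy() <= 0).any():
                raise ValueError("range must be > 0")
            if (np.abs(df["scan_angle"].to_numpy()) >= 90).any():
                raise ValueError("|scan angle| must be < 90 degrees")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, x, y, z, intensity=None, range_=None, scan_angle=None,
                    return_number=None, cls_code=UNCLASSIFIED) -> "PointCloud":
        n = len(np.asarray(x))
        df = pd.DataFrame({
            "x": np.asarray(x, float), "y": np.asarray(y, float),
            "z": np.asarray(z, float),
            "intensity": np.zeros(n) if intensity is None else np.asarray(intensity, float),
            "range": np.ones(n) if range_ is None else np.asarray(range_, float),
            "scan_angle": np.zeros(n) if scan_angle is None else np.asarray(scan_angle, float),
            "return_number": np.ones(n, int) if return_number is None else np.asarray(return_number, int),
            "cls": np.full(n, cls_code, int) if np.isscalar(cls_code) else np.asarray(cls_code, int),
        })
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "PointCloud":
        return PointCloud(self.df.copy())

    def valid(self) -> "PointCloud":
        """Points not flagged as noise."""
        return PointCloud(self.df[self.df["cls"] != NOISE])

    def __getattr__(self, name):
        # column access as attributes (x, y, z, intensity, ...)
        df = object.__getattribute__(self, "df")
        if name in df.columns:
            return df[name].to_numpy()
        raise AttributeError(name)

    def to_csv(self, path, **kw) -> None:
        self.df.to_csv(path, index=False, **kw)

    @classmethod
    def read_csv(cls, path, **kw) -> "PointCloud":
        return cls(pd.read_csv(path, **kw))
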