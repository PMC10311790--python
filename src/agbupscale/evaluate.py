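"""Accuracy reports: r, R², RMSE, rRMSE, MAE.

rRMSE is the RMSE as a percentage of the mean observed value
(rRMSE = 100·RMSE/ȳ); r is the Pearson correlation of predictions and
observations and R² = r². ``overall_accuracy`` = 100 − rRMSE, the headline
percentage convention of upscaling studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EvalReport:
    r2: float
    rmse: float
    rrmse: float  # percent
    mae: float
    r: float
    n: int
    label: str = ""

    @property
    def overall_accuracy(self) -> float:
        return 100.0 - self.rrmse

    def to_dict(self) -> dict:
        return {"label": self.label, "n": self.n, "R2": self.r2, "RMSE": self.rmse,
                "rRMSE": self.rrmse, "MAE": self.mae, "r": self.r,
                "overall_accuracy": self.overall_accuracy}


def evaluate(y, yhat, label: str = "") -> EvalReport:
    """Score predictions against observations (rows with NaN are dropped)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    ok = np.isfinite(y) & np.isfinite(yhat)
    y, yhat = y[ok], yhat[ok]
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 finite observation/prediction pairs")
    err = yhat - y
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    ybar = float(np.mean(y))
    rrmse = 100.0 * rmse / ybar if ybar != 0 else np.nan
    sy, syh = np.std(y), np.std(yhat)
    r = float(np.corrcoef(y, yhat)[0, 1]) if sy > 0 and syh > 0 else np.nan
    r2 = r ** 2 if np.isfinite(r) else np.nan
    return EvalReport(r2=r2, rmse=rmse, rrmse=rrmse, mae=mae, r=r, n=n, label=label)


def reports_frame(reports) -> pd.DataFrame:
    """Tabulate a list of EvalReports (one row each)."""
    return pd.DataFrame([rep.to_dict() for rep in reports])
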