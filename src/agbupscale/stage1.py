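"""Point→line stage: per-stratum multiple linear regression of plot AGB on
canopy metrics, leave-one-out cross-validation, and prediction over the
LiDAR strip coverage.

``LidarBiomassModel`` follows the statsmodels fit pattern: construct from a
plot table (rows = field plots, columns = canopy metrics + AGB response),
``fit()`` returns a ``LidarBiomassResults`` carrying coefficient estimates,
their standard errors, fit diagnostics and LOO cross-validated accuracy.
OLS itself is delegated to statsmodels; the LOO predictions use the exact
hat-matrix identity e_i/(1 − h_ii) (the brute-force fold loop is the test
oracle). Predictions are clamped at 0 Mg/ha — biomass is nonnegative — with
the clamp count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluate import EvalReport, evaluate
from .grids import RasterStack


def _check_full_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name offending columns by greedy QR elimination
        bad = []
        cols = list(X.columns)
        for i in range(len(cols)):
            sub = np.column_stack([np.ones(len(X))] +
                                  [X[c].to_numpy(float) for j, c in enumerate(cols)
                                   if j <= i and c not in bad])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(cols[i])
        raise ValueError(f"design matrix is rank deficient; collinear feature(s): {bad}")


class LidarBiomassModel:
    """MLR of reference AGB (Mg/ha) on selected canopy metrics, one stratum."""

    def __init__(self, table: pd.DataFrame, features: list[str],
                 response: str = "AGB", stratum: str = ""):
        missing = [f for f in features if f not in table.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        if len(set(features)) < len(features):
            raise ValueError("duplicate features in model specification")
        if len(table) <= len(features) + 1:
            raise ValueError("need n > number of features + 1 plots")
        self.table = table.reset_index(drop=True)
        self.features = list(features)
        self.response = response
        self.stratum = stratum
        self.X = self.table[self.features].astype(float)
        _check_full_rank(self.X)
        self.y = self.table[response].to_numpy(float)

    @classmethod
    def from_dataframe(cls, table, features, response="AGB", stratum=""):
        return cls(table, features, response=response, stratum=stratum)

    def fit(self) -> "LidarBiomassResults":
        exog = sm.add_constant(self.X)
        res = sm.OLS(self.y, exog).fit()
        return LidarBiomassResults(self, res)


@dataclass
class LidarBiomassResults:
    model: LidarBiomassModel
    _ols: object
    n_clamped: int = 0

    @property
    def params(self) -> pd.Series:
        return self._ols.params

    @property
    def bse(self) -> pd.Series:
        return self._ols.bse

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    def predict(self, table, clamp: bool = True) -> np.ndarray:
        X = table[self.model.features].astype(float)
        pred = self._ols.predict(sm.add_constant(X, has_constant="add"))
        pred = np.asarray(pred, float)
        if clamp:
            neg = pred < 0
            self.n_clamped += int(neg.sum())
            pred = np.clip(pred, 0.0, None)
        return pred

    def loocv(self, label: str | None = None) -> EvalReport:
        """Leave-one-out CV via the exact OLS hat-matrix identity."""
        infl = self._ols.get_influence()
        h = infl.hat_matrix_diag
        resid = self._ols.resid
        with np.errstate(divide="ignore", invalid="ignore"):
            loo_resid = resid / (1.0 - h)
        yhat = self.model.y - loo_resid
        bad = ~np.isfinite(yhat) | (h >= 1.0 - 1e-12)
        if bad.any():
            yhat = np.where(bad, np.nan, yhat)
        yhat = np.clip(yhat, 0.0, None)
        lab = label if label is not None else f"loocv[{self.model.stratum}]"
        return evaluate(self.model.y, yhat, label=lab)

    def predict_strip(self, metric_rasters: dict, strip_mask=None) -> np.ndarray:
        """AGB raster over the strip coverage from per-cell metric rasters.

        ``metric_rasters`` maps metric name → 2-D array (all co-gridded).
        Cells with any missing feature, or outside ``strip_mask``, are NaN.
        """
        missing = [f for f in self.model.features if f not in metric_rasters]
        if missing:
            raise KeyError(f"metric raster(s) missing: {missing}")
        shape = next(iter(metric_rasters.values())).shape
        pred = np.full(shape, float(self.params.iloc[0]))
        valid = np.ones(shape, bool)
        for f in self.model.features:
            arr = np.asarray(metric_rasters[f], float)
            if arr.shape != shape:
                raise ValueError("metric rasters are not co-gridded")
            valid &= np.isfinite(arr)
            pred = pred + float(self.params[f]) * np.where(np.isfinite(arr), arr, 0.0)
        if strip_mask is not None:
            valid &= np.asarray(strip_mask, bool)
        neg = valid & (pred < 0)
        self.n_clamped += int(neg.sum())
        pred = np.clip(pred, 0.0, None)
        return np.where(valid, pred, np.nan)

    def summary(self) -> str:
        lines = [f"LiDAR-based AGB model — stratum: {self.model.stratum or 'pooled'}",
                 f"n plots: {len(self.model.y)}   features: {', '.join(self.model.features)}",
                 f"fit R²: {self.rsquared:.3f}", "", "coefficients (Mg/ha per unit):"]
        for name, val, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"  {name:>12s}  {val:10.4f}  (se {se:.4f})")
        try:
            rep = self.loocv()
            lines += ["", ("LOOCV: R²=%.3f RMSE=%.2f Mg/ha rRMSE=%.2f%% "
                           "MAE=%.2f Mg/ha r=%.3f") % (rep.r2, rep.rmse, rep.rrmse,
                                                       rep.mae, rep.r)]
        except ValueError:
            pass
        return "\n".join(lines)

    def plot_validation(self, ax=None):
        """Observed-vs-LOO-predicted scatter with the 1:1 line."""
        import matplotlib.pyplot as plt

        infl = self._ols.get_influence()
        yhat = np.clip(self.model.y - self._ols.resid / (1 - infl.hat_matrix_diag),
                       0, None)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.y, yhat, s=12)
        lim = [0, max(self.model.y.max(), yhat.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("field AGB (Mg/ha)")
        ax.set_ylabel("LOO-predicted AGB (Mg/ha)")
        ax.set_title(f"stage-1 validation — {self.model.stratum or 'pooled'}")
        return ax


def loocv_table(table: pd.DataFrame, features: list[str], response: str = "AGB",
                stratum: str = "") -> EvalReport:
    """Convenience: fit + LOOCV in one call."""
    return LidarBiomassModel(table, features, response, stratum).fit().loocv()
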