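"""Two-step variable selection: Pearson significance filter, then
random-forest importance ranking with a gap-based cut.

Step 1 keeps candidate features whose two-sided Pearson correlation with the
reference AGB is significant (p < 0.05 by default); constant features are
dropped with a warning (their correlation is undefined). Step 2 ranks the
survivors with a seeded random-forest regression (ntree = 1000,
mtry = max(1, round(p/3))) by permutation importance (the %IncMSE-style
index; impurity importance is kept as the secondary index) and cuts the
ranking at the largest relative importance drop within the first ``max_n``
positions — at least 2 and at most ``max_n`` features survive, mirroring the
2–5-variable models this workflow produces. Ties break lexicographically by
feature name so rankings are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance


@dataclass
class FeatureTable:
    """Plot-level design table: named features, response AGB, stratum labels."""

    features: pd.DataFrame
    response: pd.Series
    stratum: pd.Series | None = None

    def __post_init__(self):
        if self.features.columns.duplicated().any():
            dup = self.features.columns[self.features.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names {dup}")
        y = self.response.to_numpy(float)
        if not np.isfinite(y).all() or (y < 0).any():
            raise ValueError("response must be finite and >= 0")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, names) -> "FeatureTable":
        return FeatureTable(self.features[list(names)], self.response, self.stratum)


def pearson_pvalues(X: np.ndarray, y: np.ndarray):
    """Vectorised two-sided Pearson test of each column against y."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[~np.isfinite(r)] = np.nan
    return r, p


def pearson_filter(table: FeatureTable, alpha: float = 0.05):
    """Keep features significantly correlated with the response.

    Returns ``(filtered_table, report)`` where the report tabulates r and p
    per feature. Constant features are dropped with a warning; an empty
    result is returned (not raised) with a warning.
    """
    if table.n < 4:
        raise ValueError("need at least 4 rows for the correlation filter")
    X = table.features.to_numpy(float)
    y = table.response.to_numpy(float)
    r, p = pearson_pvalues(X, y)
    const = ~np.isfinite(r)
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant feature(s): correlation "
                      "undefined", stacklevel=2)
    keep = np.isfinite(p) & (p < alpha)
    report = pd.DataFrame({"feature": table.names, "r": r, "p": p,
                           "kept": keep, "constant": const})
    if not keep.any():
        warnings.warn("no feature passed the significance filter", stacklevel=2)
    kept = [n for n, k in zip(table.names, keep) if k]
    return table.subset(kept), report


@dataclass
class ImportanceRanking:
    """Features ordered by primary (permutation) importance."""

    table: pd.DataFrame  # columns: feature, importance (primary), node_purity
    selected_n: int = 0

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()

    @property
    def importances(self) -> np.ndarray:
        return self.table["importance"].to_numpy()


def default_mtry(p: int) -> int:
    return max(1, int(round(p / 3.0)))


def rf_rank(table: FeatureTable, ntree: int = 1000, mtry: int | None = None,
            seed: int = 0, n_repeats: int = 3) -> ImportanceRanking:
    """Seeded random-forest importance ranking of a filtered table."""
    p = len(table.names)
    if p < 2:
        raise ValueError("need at least 2 features to rank")
    if table.n < 5:
        raise ValueError("need at least 5 rows to rank")
    mtry = default_mtry(p) if mtry is None else mtry
    X = table.features.to_numpy(float)
    y = table.response.to_numpy(float)
    rf = RandomForestRegressor(n_estimators=ntree, max_features=mtry,
                               random_state=seed, n_jobs=1)
    rf.fit(X, y)
    perm = permutation_importance(rf, X, y, n_repeats=n_repeats,
                                  random_state=seed, n_jobs=1)
    tab = pd.DataFrame({"feature": table.names,
                        "importance": perm.importances_mean,
                        "node_purity": rf.feature_importances_})
    tab = tab.sort_values(["importance", "feature"],
                          ascending=[False, True]).reset_index(drop=True)
    return ImportanceRanking(table=tab)


def select_top(ranking: ImportanceRanking, max_n: int = 5,
               gap_factor: float = 2.0) -> list[str]:
    """Cut the ranking at its dominant importance gap.

    Relative drops (to the leader's importance) are computed at each cut
    position within the first ``max_n``; if the largest drop dominates
    (≥ ``gap_factor`` × the mean drop in that window) the cut is taken there,
    otherwise all ``max_n`` leaders are kept. Floor of 2, cap of ``max_n``.
    """
    imps = ranking.importances
    feats = ranking.features
    if len(feats) == 0:
        raise ValueError("empty ranking")
    if len(feats) <= 2:
        ranking.selected_n = len(feats)
        return feats[:]
    window = min(max_n, len(feats) - 1)
    leader = max(abs(imps[0]), 1e-12)
    drops = (imps[:window] - imps[1:window + 1]) / leader
    best = int(np.argmax(drops))
    if drops[best] >= gap_factor * max(drops.mean(), 1e-12):
        n_sel = best + 1
    else:
        n_sel = max_n
    n_sel = int(np.clip(n_sel, 2, min(max_n, len(feats))))
    ranking.selected_n = n_sel
    return feats[:n_sel]


def select_features(table: FeatureTable, alpha: float = 0.05, ntree: int = 1000,
                    mtry: int | None = None, max_n: int = 5, seed: int = 0,
                    gap_factor: float = 2.0, n_repeats: int = 3):
    """Filter → rank → cut; returns (selected names, ranking, filter report)."""
    filtered, report = pearson_filter(table, alpha=alpha)
    if len(filtered.names) < 2:
        # degenerate: fall back to the most significant features by p-value
        order = report.sort_values("p")["feature"].tolist()
        sel = order[:max(2, min(max_n, len(order)))]
        return sel, None, report
    ranking = rf_rank(filtered, ntree=ntree, mtry=mtry, seed=seed,
                      n_repeats=n_repeats)
    selected = select_top(ranking, max_n=max_n, gap_factor=gap_factor)
    return selected, ranking, report
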