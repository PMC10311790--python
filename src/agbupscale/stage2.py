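"""Line→polygon stage: random-forest AGB models on LiDAR sampling plots vs
the satellite feature stack, experiment ladders A–D, dual validation and the
wall-to-wall map.

Experiments gate the feature groups: A = {a} (spectral + VI + biophysical),
B = {a, b} (+ optical wavelet textures), C = {a, b, c} (+ backscatter and
GLCM), D = {a, b, c, d} (+ SAR wavelet textures). Per stratum the candidate
features pass the Pearson filter, the RF importance ranking and the gap cut
before a seeded random forest is fitted on the survivors.

``SatelliteBiomassModel.fit()`` returns a ``SatelliteBiomassResults`` whose
``validate`` scores the stratum models against two validation sets built on
the same plots — reference AGB from the stage-1 LiDAR models (the upscaling
baseline) and from field allometry (the truth scale) — and whose ``map_agb``
routes each pixel through the model of its species stratum (other conifers
through the pooled, non-stratified model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .evaluate import EvalReport, evaluate
from .grids import Grid, RasterStack, overlap_weights
from .sampling import SamplingPlot
from .selection import FeatureTable, default_mtry, select_features
from .synth import CODE_TO_SPECIES, SPECIES_CODES

EXPERIMENTS = {"A": ("a",), "B": ("a", "b"), "C": ("a", "b", "c"),
               "D": ("a", "b", "c", "d")}
POOLED = "non_stratification"


@dataclass(frozen=True)
class ExperimentSpec:
    label: str

    def __post_init__(self):
        if self.label not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {sorted(EXPERIMENTS)}")

    @property
    def groups(self) -> tuple:
        return EXPERIMENTS[self.label]


def build_training_table(plots: list[SamplingPlot], stack: RasterStack,
                         feature_names: list[str] | None = None) -> pd.DataFrame:
    """Plot rows × feature columns by exact area-weighted pixel aggregation.

    Rows keep id, stratum and the plot's reference AGB; plots dominated by
    nodata in any band are dropped with a warning.
    """
    names = feature_names if feature_names is not None else stack.names_in_groups("abcd")
    arrs = {n: stack[n] for n in names}
    rows, dropped = [], 0
    for p in plots:
        r, c, w = overlap_weights(stack.grid, *p.bounds)
        if w.size == 0:
            dropped += 1
            continue
        rec = {"id": p.id, "stratum": p.stratum, "x": p.x, "y": p.y,
               "AGB": p.agb_lidar}
        ok = True
        for n in names:
            sub = arrs[n][np.ix_(r, c)]
            finite = np.isfinite(sub)
            wf = w[finite].sum()
            if wf < 0.5 * w.sum():
                ok = False
                break
            rec[n] = float((sub[finite] * w[finite]).sum() / wf)
        if ok:
            rows.append(rec)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} nodata-dominated plot(s)", stacklevel=2)
    return pd.DataFrame(rows)


@dataclass
class RfConfig:
    ntree: int = 1000
    mtry: int | None = None     # default: max(1, round(p/3))
    selection_ntree: int = 1000
    selection_repeats: int = 3  # permutation-importance repeats
    alpha: float = 0.05
    max_n: int = 5
    gap_factor: float = 2.0


class SatelliteBiomassModel:
    """Per-stratum RF AGB models under one experiment's feature groups."""

    def __init__(self, table: pd.DataFrame, stack_manifest: pd.DataFrame,
                 experiment: str | ExperimentSpec = "D",
                 rf_config: RfConfig = RfConfig(), response: str = "AGB",
                 min_stratum_n: int = 20):
        self.experiment = (experiment if isinstance(experiment, ExperimentSpec)
                           else ExperimentSpec(experiment))
        self.table = table.reset_index(drop=True)
        self.response = response
        self.rf_config = rf_config
        self.min_stratum_n = min_stratum_n
        groups = set(self.experiment.groups)
        self.candidates = [n for n, g in zip(stack_manifest["name"],
                                             stack_manifest["group"])
                           if g in groups and n in table.columns]
        if not self.candidates:
            raise ValueError("no candidate features for this experiment in the table")

    def _strata(self) -> dict:
        out = {}
        for s in ("larch", "chinese_pine"):
            sub = self.table[self.table["stratum"] == s]
            if len(sub) >= self.min_stratum_n:
                out[s] = sub
        out[POOLED] = self.table  # other conifers pool into non-stratification
        return out

    def fit(self, seed: int = 0) -> "SatelliteBiomassResults":
        models, selections = {}, {}
        for stratum, sub in self._strata().items():
            ft = FeatureTable(sub[self.candidates], sub[self.response].astype(float))
            cfg = self.rf_config
            selected, ranking, rep = select_features(
                ft, alpha=cfg.alpha, ntree=cfg.selection_ntree, mtry=cfg.mtry,
                max_n=cfg.max_n, seed=seed, gap_factor=cfg.gap_factor,
                n_repeats=cfg.selection_repeats)
            if not selected:
                raise ValueError(f"empty post-selection feature set for {stratum}")
            rf = RandomForestRegressor(
                n_estimators=cfg.ntree,
                max_features=cfg.mtry or default_mtry(len(selected)),
                random_state=seed, n_jobs=1)
            rf.fit(sub[selected].to_numpy(float), sub[self.response].to_numpy(float))
            models[stratum] = (rf, selected)
            selections[stratum] = {"selected": selected, "ranking": ranking,
                                   "filter": rep}
        return SatelliteBiomassResults(self, models, selections, seed)


@dataclass
class DualValidation:
    """Per-stratum reports against the two reference scales."""
    lidar_based: dict    # stratum -> EvalReport (reference = stage-1 predictions)
    field_based: dict    # stratum -> EvalReport (reference = field/true AGB)

    def frame(self) -> pd.DataFrame:
        rows = []
        for name, reps in (("lidar_based", self.lidar_based),
                           ("field_based", self.field_based)):
            for stratum, rep in reps.items():
                d = rep.to_dict()
                d.update({"validation": name, "stratum": stratum})
                rows.append(d)
        return pd.DataFrame(rows)


class SatelliteBiomassResults:
    def __init__(self, model: SatelliteBiomassModel, models: dict,
                 selections: dict, seed: int):
        self.model = model
        self._models = models
        self.selections = selections
        self.seed = seed

    @property
    def strata(self) -> list[str]:
        return list(self._models)

    def selected_variables(self) -> pd.DataFrame:
        """Model manifest: experiment, stratum, selected variables."""
        return pd.DataFrame([
            {"experiment": self.model.experiment.label, "stratum": s,
             "selected_variables": ", ".join(sel)}
            for s, (rf, sel) in self._models.items()])

    def predict(self, table: pd.DataFrame, stratum: str) -> np.ndarray:
        rf, sel = self._models[stratum]
        return rf.predict(table[sel].to_numpy(float))

    def predict_routed(self, table: pd.DataFrame) -> np.ndarray:
        """Route each row through its stratum's model (fallback: pooled)."""
        out = np.full(len(table), np.nan)
        for i, (_, row) in enumerate(table.iterrows()):
            s = row.get("stratum", POOLED)
            s = s if s in self._models else POOLED
            rf, sel = self._models[s]
            out[i] = rf.predict(row[sel].to_numpy(float)[None, :])[0]
        return out

    def validate(self, validation_table: pd.DataFrame, agb_lidar_col: str,
                 agb_field_col: str, per_stratum: bool = True) -> DualValidation:
        """Score against the LiDAR-based and field-based validation sets.

        ``validation_table`` holds one row per validation plot with the
        aggregated feature columns plus the two reference AGB columns; both
        reports use the identical plot set.
        """
        lid, fld = {}, {}
        groups = [("all", validation_table)]
        if per_stratum:
            groups += [(s, validation_table[validation_table["stratum"] == s])
                       for s in self.strata if s != POOLED]
        for name, sub in groups:
            if len(sub) < 2:
                continue
            stratum = name if name in self._models else POOLED
            pred = self.predict(sub, stratum)
            lid[name] = evaluate(sub[agb_lidar_col], pred,
                                 label=f"{self.model.experiment.label}/{name}/lidar")
            fld[name] = evaluate(sub[agb_field_col], pred,
                                 label=f"{self.model.experiment.label}/{name}/field")
        return DualValidation(lidar_based=lid, field_based=fld)

    def map_agb(self, stack: RasterStack, species_raster: np.ndarray,
                batch: int = 200_000):
        """Wall-to-wall AGB raster: per pixel, the model of its stratum.

        Larch and Chinese-pine pixels use their stratum model where fitted;
        any other (or unmodelled) forest code uses the pooled model;
        non-forest (code 0) and nodata pixels stay NaN. Returns
        ``(agb_map, histogram_frame)`` with 40 Mg/ha histogram classes.
        """
        species = np.asarray(species_raster)
        shape = species.shape
        out = np.full(shape, np.nan)
        needed = sorted({f for rf, sel in self._models.values() for f in sel})
        missing = [f for f in needed if f not in stack]
        if missing:
            raise KeyError(f"feature band(s) missing from stack: {missing}")
        feats = {f: stack[f].ravel() for f in needed}
        flat_species = species.ravel()
        routing = {}
        for code, name in CODE_TO_SPECIES.items():
            routing[code] = name if name in self._models else POOLED
        n_unrouted = 0
        for code in np.unique(flat_species):
            if code == 0:
                continue
            if code not in routing:
                n_unrouted += int((flat_species == code).sum())
                continue
            rf, sel = self._models[routing[code]]
            idx = np.flatnonzero(flat_species == code)
            X = np.column_stack([feats[f][idx] for f in sel])
            ok = np.isfinite(X).all(axis=1)
            pred = np.full(len(idx), np.nan)
            for start in range(0, int(ok.sum()), batch):
                chunk = np.flatnonzero(ok)[start:start + batch]
                pred[chunk] = rf.predict(X[chunk])
            out.ravel()[idx] = pred
        edges = np.arange(0, np.nanmax(out) + 40.0 if np.isfinite(out).any() else 40.0,
                          40.0)
        counts, edges = np.histogram(out[np.isfinite(out)], bins=edges)
        hist = pd.DataFrame({"agb_low": edges[:-1], "agb_high": edges[1:],
                             "pixels": counts})
        self.n_unrouted = n_unrouted
        return out.reshape(shape), hist

    def summary(self) -> str:
        lines = [f"Satellite AGB models — experiment {self.model.experiment.label} "
                 f"(groups {'+'.join(self.model.experiment.groups)})"]
        for s, (rf, sel) in self._models.items():
            n = (self.model.table["stratum"] == s).sum() if s != POOLED else len(self.model.table)
            lines.append(f"  {s:>20s}: n={n:4d}  variables: {', '.join(sel)}")
        return "\n".join(lines)
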