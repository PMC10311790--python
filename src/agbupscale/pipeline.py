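"""End-to-end driver: synthetic scene → LiDAR stage → sampling → satellite
stage → wall-to-wall map.

``run_scene`` executes the full two-stage upscaling on a synthetic scene and
returns every intermediate product, so pipeline behaviour (experiment
ladders, saturation alleviation, stratification benefit, error accumulation)
can be measured end to end without external data. All randomness derives
from the single ``seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lidar as L
from .evaluate import EvalReport, evaluate
from .grids import Grid, RasterStack
from .features import assemble_feature_stack, feature_manifest
from .sampling import SamplingPlot, attach_reference_agb, plots_frame, sample_plots
from .selection import FeatureTable, select_features
from .stage1 import LidarBiomassModel, LidarBiomassResults
from .stage2 import POOLED, RfConfig, SatelliteBiomassModel, build_training_table
from .synth import (AllometryModel, SceneConfig, SPECIES_CODES, CODE_TO_SPECIES,
                    generate_stand, make_dem, make_masks, simulate_imagery,
                    simulate_point_cloud, stand_agb, stand_to_agb_raster)


@dataclass
class ScenePlan:
    """The stated world of one synthetic upscaling run."""

    region: tuple = (0.0, 0.0, 2000.0, 2000.0)
    stem_density: float = 900.0              # stems/ha
    species_layout: dict = field(default_factory=lambda: {
        "larch": 0.45, "chinese_pine": 0.45, "other_conifer": 0.10})
    strips: list | None = None               # default: two E-W strips
    roads: list | None = None                # default: one N-S road mid-region
    allometry: AllometryModel = field(default_factory=lambda: AllometryModel({
        "larch": (0.073, 2.52), "chinese_pine": (0.140, 2.33),
        "other_conifer": (0.100, 2.40)}))
    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        point_density=4.0, intensity_noise_sd=20.0))
    n_field: dict = field(default_factory=lambda: {
        "larch": 22, "chinese_pine": 22, "other_conifer": 6})
    n_lidar: dict = field(default_factory=lambda: {
        "larch": 40, "chinese_pine": 40, "other_conifer": 6})
    field_min_spacing: float = 100.0
    lidar_min_spacing: float = 60.0
    stem_density_variation: float = 0.5      # lognormal sd of the density field
    rf_config: RfConfig = field(default_factory=lambda: RfConfig(
        ntree=300, selection_ntree=150, selection_repeats=2))

    def default_strips(self):
        """Two east–west strips: they cross every species stratum band."""
        if self.strips is not None:
            return self.strips
        xmin, ymin, xmax, ymax = self.region
        hgt = (ymax - ymin)
        sh = min(200.0, 0.25 * hgt)
        return [(xmin, ymin + 0.15 * hgt, xmax, ymin + 0.15 * hgt + sh),
                (xmin, ymin + 0.60 * hgt, xmax, ymin + 0.60 * hgt + sh)]

    def default_roads(self):
        if self.roads is not None:
            return self.roads
        xmin, ymin, xmax, ymax = self.region
        xm = (xmin + xmax) / 2.0
        return [(((xm, ymin), (xm, ymax)), 12.0)]


@dataclass
class SceneRun:
    """Everything one end-to-end run produced."""
    plan: ScenePlan
    seed: int
    grid10: Grid
    grid25: Grid
    dem: np.ndarray
    species: np.ndarray
    strip_mask: np.ndarray
    agb_true: np.ndarray
    stage1_results: dict          # stratum -> LidarBiomassResults
    stage1_loocv: dict            # stratum -> EvalReport
    stage1_selected: dict         # stratum -> feature list
    agb_lidar_25: np.ndarray      # stage-1 strip prediction at 25 m support
    field_table: pd.DataFrame     # field plots: metrics + AGB_field + AGB_lidar refs
    training_table: pd.DataFrame  # sampling plots × feature columns
    validation_table: pd.DataFrame
    stack: RasterStack
    stage2_results: dict          # experiment -> SatelliteBiomassResults
    dual_validation: dict         # experiment -> DualValidation


def _species_at(species: np.ndarray, grid: Grid, x, y) -> np.ndarray:
    row, col = grid.rowcol(x, y)
    row = np.clip(row, 0, grid.nrows - 1)
    col = np.clip(col, 0, grid.ncols - 1)
    return species[row, col]


def _majority_species_25(species: np.ndarray, grid10: Grid, grid25: Grid) -> np.ndarray:
    out = np.zeros(grid25.shape, int)
    f = int(round(grid25.px / grid10.px))
    for r in range(grid25.nrows):
        for c in range(grid25.ncols):
            block = species[r * f:(r + 1) * f, c * f:(c + 1) * f]
            if block.size:
                vals, counts = np.unique(block, return_counts=True)
                out[r, c] = vals[np.argmax(counts)]
    return out


def _prune_collinear(table: pd.DataFrame, features: list[str]) -> list[str]:
    """Greedily drop features that break full rank of [1 | X] (keep order)."""
    kept: list[str] = []
    n = len(table)
    for f in features:
        cols = [np.ones(n)] + [table[c].to_numpy(float) for c in kept + [f]]
        A = np.column_stack(cols)
        if np.linalg.matrix_rank(A) == A.shape[1]:
            kept.append(f)
    return kept


def run_scene(plan: ScenePlan, seed: int, experiments=("A", "B", "C", "D"),
              make_map: bool = False, stop_after_stage1: bool = False):
    """Run the full point→line→polygon chain on one synthetic scene.

    With ``stop_after_stage1`` the run ends after the LiDAR-model stage
    (cheap mode for stage-1-only studies); later SceneRun fields are None.
    """
    rng_base = int(seed) % (2 ** 31 - 10)
    xmin, ymin, xmax, ymax = plan.region
    strips = plan.default_strips()
    strip_mask, road_mask, species, grid10 = make_masks(
        plan.region, strips, plan.default_roads(), plan.species_layout, seed=rng_base, px=10.0)
    dem = make_dem(grid10, plan.scene.terrain, seed=rng_base + 1)

    stand = generate_stand(plan.species_layout, plan.stem_density, plan.region,
                           seed=rng_base + 2,
                           density_variation=plan.stem_density_variation)
    # stems follow the species map so strata are spatially coherent
    codes = _species_at(species, grid10, stand.stems["x"].to_numpy(),
                        stand.stems["y"].to_numpy())
    stand.stems["species"] = [CODE_TO_SPECIES[c] for c in codes]
    agb_true = stand_to_agb_raster(stand, plan.allometry, grid10)
    imagery = simulate_imagery(agb_true, dem, plan.scene, grid10, species,
                               seed=rng_base + 3)

    # ---- LiDAR over the strips: simulate, denoise, normalise, correct -----
    clouds = []
    for i, strip in enumerate(strips):
        pc = simulate_point_cloud(stand, plan.scene, dem, grid10, extent=strip,
                                  seed=rng_base + 10 + i)
        pc = L.denoise(pc, z_low=-50.0, z_high=dem.max() + 60.0)
        pc, _, _ = L.classify_ground_normalize(pc, cell=2.0)
        pc = L.correct_intensity(pc, L.IntensityCorrectionParams(plan.scene.r_ref))
        clouds.append(pc.df)
    cloud = L.PointCloud(pd.concat(clouds, ignore_index=True))

    # ---- field plots and the stage-1 table --------------------------------
    field_plots = sample_plots(strip_mask, species, road_mask, grid10,
                               plan.n_field, min_spacing=plan.field_min_spacing,
                               seed=rng_base + 20)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in field_plots:
            sub = L.clip_to_plot(cloud, (p.x, p.y))
            if len(sub) < 20:
                continue
            try:
                vec = L.compute_metrics(sub)
            except ValueError:
                continue
            rec = vec.to_dict()
            rec.update({"id": p.id, "stratum": p.stratum, "x": p.x, "y": p.y,
                        "AGB": stand_agb(stand, plan.allometry, p.polygon)})
            rows.append(rec)
    field_table = pd.DataFrame(rows)

    # ---- stage-1 models per stratum ----------------------------------------
    stage1_results, stage1_loocv, stage1_selected = {}, {}, {}
    strata = [s for s in ("larch", "chinese_pine")
              if (field_table["stratum"] == s).sum() >= 10] + [POOLED]
    for stratum in strata:
        sub = field_table if stratum == POOLED else \
            field_table[field_table["stratum"] == stratum]
        ft = FeatureTable(sub[L.METRIC_NAMES].fillna(0.0), sub["AGB"])
        selected, _, _ = select_features(
            ft, seed=rng_base + 30, ntree=plan.rf_config.selection_ntree,
            n_repeats=plan.rf_config.selection_repeats)
        selected = _prune_collinear(sub, selected)
        model = LidarBiomassModel(sub, selected, response="AGB", stratum=stratum)
        res = model.fit()
        stage1_results[stratum] = res
        stage1_loocv[stratum] = res.loocv()
        stage1_selected[stratum] = selected

    if stop_after_stage1:
        return SceneRun(plan=plan, seed=seed, grid10=grid10, grid25=None, dem=dem,
                        species=species, strip_mask=strip_mask, agb_true=agb_true,
                        stage1_results=stage1_results, stage1_loocv=stage1_loocv,
                        stage1_selected=stage1_selected, agb_lidar_25=None,
                        field_table=field_table, training_table=None,
                        validation_table=None, stack=None, stage2_results=None,
                        dual_validation=None)

    # ---- AGB_LiDAR strip map at 25 m support -------------------------------
    grid25 = Grid(xmin=grid10.xmin, ymax=grid10.ymax,
                  nrows=int(grid10.nrows * grid10.px // 25),
                  ncols=int(grid10.ncols * grid10.px // 25), px=25.0)
    metric_grids = L.metrics_grid(cloud, grid25)
    species25 = _majority_species_25(species, grid10, grid25)
    agb_lidar_25 = np.full(grid25.shape, np.nan)
    for stratum in strata:
        pred = stage1_results[stratum].predict_strip(metric_grids)
        if stratum == POOLED:
            m = np.isnan(agb_lidar_25)  # pooled fills whatever remains
        else:
            m = species25 == SPECIES_CODES[stratum]
        agb_lidar_25[m] = pred[m]

    # ---- LiDAR sampling plots with stage-1 reference AGB -------------------
    lidar_plots = sample_plots(strip_mask, species, road_mask, grid10,
                               plan.n_lidar, min_spacing=plan.lidar_min_spacing,
                               seed=rng_base + 40)
    lidar_plots = attach_reference_agb(lidar_plots, agb_lidar_25, grid25)

    # ---- satellite feature stack ------------------------------------------
    optical = RasterStack(grid10)
    for b in ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8a", "B11", "B12"):
        optical.add(b, imagery[b], group="a")
    sar = RasterStack(grid10)
    for b in ("VV", "VH"):
        sar.add(b, imagery[b], group="c")
    stack = assemble_feature_stack(optical, sar, dem,
                                   solar_zenith=plan.scene.solar_zenith,
                                   solar_azimuth=plan.scene.solar_azimuth)
    manifest = feature_manifest(stack)

    training_table = build_training_table(lidar_plots, stack)

    # ---- validation table: field plots under both reference scales ---------
    val_plots = [SamplingPlot(p.id, p.stratum, p.x, p.y, agb_lidar=0.0,
                              source="field") for p in field_plots
                 if p.id in set(field_table["id"])]
    validation_table = build_training_table(val_plots, stack)
    validation_table = validation_table.drop(columns=["AGB"]).merge(
        field_table[["id", "AGB"]].rename(columns={"AGB": "AGB_field"}), on="id")
    # LiDAR-based reference: stage-1 model prediction at each field plot
    ref = np.full(len(validation_table), np.nan)
    ft_idx = field_table.set_index("id")
    for i, pid in enumerate(validation_table["id"]):
        stratum = ft_idx.loc[pid, "stratum"]
        stratum = stratum if stratum in stage1_results else POOLED
        row = ft_idx.loc[[pid]]
        ref[i] = stage1_results[stratum].predict(row)[0]
    validation_table["AGB_lidar_ref"] = ref

    # ---- stage-2 experiments ----------------------------------------------
    stage2_results, dual_validation = {}, {}
    for exp in experiments:
        m2 = SatelliteBiomassModel(training_table, manifest, experiment=exp,
                                   rf_config=plan.rf_config)
        res2 = m2.fit(seed=rng_base + 50)
        stage2_results[exp] = res2
        dual_validation[exp] = res2.validate(validation_table,
                                             agb_lidar_col="AGB_lidar_ref",
                                             agb_field_col="AGB_field")

    run = SceneRun(plan=plan, seed=seed, grid10=grid10, grid25=grid25, dem=dem,
                   species=species, strip_mask=strip_mask, agb_true=agb_true,
                   stage1_results=stage1_results, stage1_loocv=stage1_loocv,
                   stage1_selected=stage1_selected, agb_lidar_25=agb_lidar_25,
                   field_table=field_table, training_table=training_table,
                   validation_table=validation_table, stack=stack,
                   stage2_results=stage2_results, dual_validation=dual_validation)
    if make_map and stage2_results:
        exp = experiments[-1]
        run.agb_map, run.agb_histogram = stage2_results[exp].map_agb(stack, species)
    return run
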