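"""End-to-end orchestration: simulate -> terrain -> segment -> features ->
classify -> report, plus the canonical test fixtures.

A run is driven by a YAML-serializable :class:`RunConfig`; every stochastic
stage has an explicit seed, artifacts are written to a directory-per-run
layout, and a provenance log records the config hash and per-stage counts so
training-set attrition (crowns discarded for missing features, unmatched
crowns, ...) is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

import pandas as pd

from . import classify as cls
from .features import FeatureTable, assemble_feature_table
from .pointcloud import PointCloud
from .raster import RasterGrid
from .segmentation import (SegmentationParams, SegmentationResult,
                           crowns_to_geojson, segment)
from .simulate import (Scene, Terrain, Tree, generate_scene, make_sensor,
                       simulate_acquisition)
from .terrain import build_chm, build_dsm, build_dtm


@dataclass
class RunConfig:
    extent: tuple[float, float, float, float] = (0.0, 0.0, 50.0, 50.0)
    species_mix: dict[str, float] = field(default_factory=lambda: {"PI": 1.0})
    stem_density: float = 150.0  # stems / ha
    sensors: list[str] = field(default_factory=lambda: ["ALS12-like"])
    cell_size: float = 0.25
    grouping: str = "twelve_species"
    n_runs: int = 20
    n_estimators: int = 200
    do_selection: bool = False
    mda_threshold: float = 0.1
    r_max: float = 0.9
    n_perm: int = 20
    seed: int = 1
    min_spacing: float = 1.5

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls_, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["extent"] = tuple(d["extent"])
        return cls_(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def match_crowns_to_stems(crowns, scene: Scene, max_dist: float = 2.5) -> dict[int, str]:
    """Ground-truth species label per crown: nearest stem to the crown apex."""
    if not scene.trees:
        return {}
    stems = np.array([[t.x, t.y] for t in scene.trees])
    tree = cKDTree(stems)
    labels = {}
    for crown in crowns:
        dist, idx = tree.query(crown.apex)
        if dist <= max(max_dist, scene.trees[idx].crown_radius):
            labels[crown.id] = scene.trees[idx].species
    return labels


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute every stage, writing artifacts and a provenance log.

    Raises from within a stage leave earlier artifacts in place; the
    provenance log names the completed stages.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: dict = {"config_hash": config.digest(), "stages": {}}

    def _checkpoint(stage: str, **counts) -> None:
        log["stages"][stage] = counts
        with open(out / "provenance.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)

    # 1. simulate -----------------------------------------------------------
    scene = generate_scene(config.extent, config.species_mix,
                           config.stem_density, seed=config.seed,
                           min_spacing=config.min_spacing)
    scene.to_json(out / "scene.json")
    clouds: dict[str, tuple[PointCloud, tuple[int, ...]]] = {}
    for i, name in enumerate(config.sensors):
        sensor = make_sensor(name)
        cloud = simulate_acquisition(scene, sensor, seed=config.seed + 1000 + i)
        cloud.save_csv(out / f"cloud_{sensor.label}.csv")
        clouds[sensor.label] = (cloud, sensor.wavelengths)
    _checkpoint("simulate", n_trees=len(scene.trees),
                points={lbl: len(c) for lbl, (c, _) in clouds.items()})

    # 2. terrain (reference = first sensor) ---------------------------------
    ref_label = make_sensor(config.sensors[0]).label
    ref_cloud = clouds[ref_label][0]
    dtm = build_dtm(ref_cloud, config.cell_size, extent=config.extent)
    dsm = build_dsm(ref_cloud, config.cell_size, extent=config.extent)
    chm = build_chm(dsm, dtm)
    dtm.save(out / "dtm.tif")
    dsm.save(out / "dsm.tif")
    chm.save(out / "chm.tif")
    _checkpoint("terrain", cells=int(np.prod(chm.shape)))

    # 3. segment on the reference CHM; polygons reused for every sensor -----
    seg = segment(chm, SegmentationParams())
    crowns_to_geojson(seg.crowns, out / "crowns.geojson")
    _checkpoint("segment", n_crowns=len(seg.crowns))

    # 4. features -----------------------------------------------------------
    polygons = {c.id: c.polygon for c in seg.crowns}
    table = assemble_feature_table(polygons, clouds, dtm)
    table.save(out / "features")
    _checkpoint("features", columns={lbl: df.shape[1]
                                     for lbl, df in table.tables.items()},
                incomplete={lbl: int(table.flags(lbl).sum())
                            for lbl, df in table.tables.items()})

    # 5. classify -----------------------------------------------------------
    truth = match_crowns_to_stems(seg.crowns, scene)
    labels = pd.Series(truth, name="species")
    labels.to_csv(out / "crown_labels.csv")
    report: dict = {"n_labelled": len(labels)}
    scheme = cls.GROUPINGS[config.grouping]
    mapped = scheme.apply(labels)
    counts = mapped.value_counts()
    if len(counts) >= 2 and counts.min() >= 2:
        pooled = table.pooled()
        idx = pooled.index.intersection(mapped.index)
        pooled = pooled.loc[idx]
        selected = None
        if config.do_selection and pooled.shape[1] > 1:
            sel = cls.select_features(pooled, mapped, config.mda_threshold,
                                      config.r_max, config.n_perm,
                                      seed=config.seed,
                                      n_estimators=config.n_estimators,
                                      vsurf_estimators=config.n_estimators // 2)
            selected = sel.final
            with open(out / "selection.json", "w") as fh:
                json.dump({"final": sel.final, "after_mda": sel.after_mda,
                           "after_correlation": sel.after_correlation,
                           "removal_log": sel.removal_log}, fh, indent=1)
        rep = cls.evaluate(pooled, labels, config.grouping, "all",
                           selected=selected, n_runs=config.n_runs,
                           seed=config.seed, n_estimators=config.n_estimators)
        report.update(rep.to_dict())
    else:
        report["note"] = "fewer than 2 classes with 2+ samples; no model trained"
        report["class_counts"] = counts.to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    _checkpoint("classify", classes=int(len(counts)))
    return out


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------


def analytic_cone_chm(
    peaks: list[tuple[float, float, float, float]],
    extent: tuple[float, float, float, float],
    cell_size: float = 0.25,
) -> RasterGrid:
    """CHM of ideal cones (x, y, height, radius); background 0."""
    xmin, ymin, xmax, ymax = extent
    ncol = int(round((xmax - xmin) / cell_size))
    nrow = int(round((ymax - ymin) / cell_size))
    xs = xmin + (np.arange(ncol) + 0.5) * cell_size
    ys = ymin + (np.arange(nrow) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    chm = np.zeros((nrow, ncol))
    for cx, cy, h, r in peaks:
        d = np.hypot(gx - cx, gy - cy)
        cone = np.where(d <= r, h * (1 - d / r), 0.0)
        chm = np.maximum(chm, cone)
    return RasterGrid(xmin, ymin, cell_size, chm)


def make_plantation_scene(
    n_rows: int = 10,
    n_cols: int = 10,
    spacing: float = 12.0,
    species: tuple[str, str] = ("PI", "MA"),
    seed: int = 0,
) -> Scene:
    """Checkerboard two-species plantation at >= 2x crown-diameter spacing."""
    rng = np.random.default_rng(seed)
    trees = []
    margin = spacing
    for i in range(n_rows):
        for j in range(n_cols):
            code = species[(i + j) % 2]
            h = rng.uniform(18, 24)
            trees.append(Tree(code, margin + j * spacing, margin + i * spacing,
                              h, crown_radius=rng.uniform(2.5, 3.0),
                              crown_ratio=rng.uniform(0.5, 0.7)))
    side_x = 2 * margin + (n_cols - 1) * spacing
    side_y = 2 * margin + (n_rows - 1) * spacing
    return Scene(extent=(0, 0, side_x, side_y), terrain=Terrain(), trees=trees,
                 min_spacing=spacing / 2)


def make_mixed_stand_scene(
    seed: int = 0,
    per_species: int = 42,
    extent: tuple[float, float, float, float] = (0.0, 0.0, 170.0, 170.0),
) -> Scene:
    """12-species mixed stand with at least 35 stems per species."""
    codes = sorted(cls.GROUPINGS["twelve_species"].mapping)
    mix = {c: 1 / len(codes) for c in codes}
    n = per_species * len(codes)
    area_ha = (extent[2] - extent[0]) * (extent[3] - extent[1]) / 1e4
    return generate_scene(extent, mix, stem_density=n / area_ha, seed=seed,
                          min_spacing=1.5)


def make_fixtures(seed: int, outdir) -> dict[str, Path]:
    """Write the canonical scenes and CHMs used across the test suite."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    single = analytic_cone_chm([(15.0, 15.0, 20.0, 4.0)], (0, 0, 30, 30))
    paths["single_cone_chm"] = out / "single_cone_chm.tif"
    single.save(paths["single_cone_chm"])

    dumbbell = analytic_cone_chm(
        [(13.0, 15.0, 20.0, 2.0), (15.7, 15.0, 18.5, 2.0)], (0, 0, 30, 30)
    )
    paths["dumbbell_chm"] = out / "dumbbell_chm.tif"
    dumbbell.save(paths["dumbbell_chm"])

    plantation = make_plantation_scene(seed=seed)
    paths["plantation_scene"] = out / "plantation_scene.json"
    plantation.to_json(paths["plantation_scene"])

    mixed = make_mixed_stand_scene(seed=seed)
    paths["mixed_stand_scene"] = out / "mixed_stand_scene.json"
    mixed.to_json(paths["mixed_stand_scene"])
    return paths
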