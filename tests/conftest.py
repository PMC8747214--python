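"""Shared fixtures: small canonical scenes and one mixed-stand dataset.

The mixed stand is the expensive fixture (three simulated over-flights plus
feature extraction for ~500 crowns); it is built once per session and shared
by the classification tests. Crown polygons there are the ground-truth crown
circles, so classification tests are independent of segmentation quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from crownid import make_sensor, segment, simulate_acquisition
from crownid.features import assemble_feature_table
from crownid.pipeline import (analytic_cone_chm, make_mixed_stand_scene,
                              make_plantation_scene)
from crownid.terrain import build_chm, build_dsm, build_dtm

SEED = 20240917


@pytest.fixture(scope="session")
def plantation():
    """100-tree checkerboard plantation: scene, ALS cloud, CHM, segmentation."""
    scene = make_plantation_scene(seed=3)
    cloud = simulate_acquisition(scene, "ALS12-like", seed=11)
    dtm = build_dtm(cloud, 0.25, extent=scene.extent)
    dsm = build_dsm(cloud, 0.25, extent=scene.extent)
    chm = build_chm(dsm, dtm)
    result = segment(chm)
    return {"scene": scene, "cloud": cloud, "dtm": dtm, "chm": chm,
            "segmentation": result}


@pytest.fixture(scope="session")
def mixed_stand():
    """12-species stand (42 stems/species) observed by all three sensors.

    Returns per-sensor complete feature tables (rows with missing values
    dropped), the pooled table, and ground-truth species labels.
    """
    scene = make_mixed_stand_scene(seed=5)
    clouds = {}
    for i, name in enumerate(["ALS12-like", "MSL16-like", "SPL18-like"]):
        sensor = make_sensor(name)
        cloud = simulate_acquisition(scene, sensor, seed=SEED + i)
        clouds[sensor.label] = (cloud, sensor.wavelengths)
    polygons = {
        i: Point(t.x, t.y).buffer(t.crown_radius * 0.9)
        for i, t in enumerate(scene.trees)
    }
    labels = pd.Series({i: t.species for i, t in enumerate(scene.trees)},
                       name="species")
    dtm = build_dtm(clouds["12"][0], 0.5, extent=scene.extent)
    table = assemble_feature_table(polygons, clouds, dtm)
    complete = {lbl: table.complete(lbl) for lbl in table.tables}
    pooled = table.pooled()
    return {"scene": scene, "table": table, "complete": complete,
            "pooled": pooled, "labels": labels}


@pytest.fixture()
def single_cone_chm():
    return analytic_cone_chm([(15.0, 15.0, 20.0, 4.0)], (0, 0, 30, 30))


@pytest.fixture()
def dumbbell_chm():
    return analytic_cone_chm(
        [(13.0, 15.0, 20.0, 2.0), (15.7, 15.0, 18.5, 2.0)], (0, 0, 30, 30)
    )
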