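"""Crown-level 3D and intensity features from normalized point sets.

Height normalization uses a single DTM value sampled at the crown centroid
(per-point normalization warps crown shape on slopes); returns at or below
2 m above ground are discarded. Size-bearing features are divided by tree
height H (Fn = F / H) so classification is independent of the height
distribution of the training stems; adimensional features (ratios, slopes,
coefficients of variation) pass through unchanged. All percentiles use
linear interpolation (numpy's default definition).

The feature manifest:

* 3D (34, computed on all channels pooled): DI — cv of return heights (all,
  1st); SLOPE — statistics (mn, sd, cv, p25, p50, p75) of the slopes of the
  lines joining the highest return to every other return (all, 1st); RB —
  fraction of returns in the 60–80, 80–90, 90–100 and 95–100 % height bins;
  CH — convex-hull volume over H^3; RM — 15 ratios between return types:
  {mn, p25, p50, p75} height-statistic ratios for the pairs 1st/all, 2nd/all
  and 2nd/1st, plus the three return-count ratios. RM entries that involve
  second returns are missing for crowns without second returns.
* Intensity (16 per channel, first returns unless stated): DI — sd and cv;
  PE — intensity of the first return nearest each height percentile
  p5...p95; MI — mean intensity over all first returns and over the p5–95 /
  p10–90 height bands; RM — {mn, p50} intensity-statistic ratios for
  2nd/1st and 1st/all.
* Multispectral indices (18, three-wavelength sensors only): normalized
  differences (longer - shorter)/(longer + shorter) between matched
  per-channel statistics (mn, p50, p75) for the pairs 532/1064 (G_IR1),
  532/1550 (G_IR2) and 1064/1550 (NDIR), plus the three simple
  shorter/longer ratios at the same statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .pointcloud import NOISE, PointCloud
from .raster import RasterGrid

HEIGHT_CUTOFF = 2.0  # m above ground; returns at or below are discarded

_PE_PERCENTILES = (5, 10, 25, 50, 75, 90, 95)
_SLOPE_STATS = ("mn", "sd", "cv", "p25", "p50", "p75")
_RM_STATS = ("mn", "p25", "p50", "p75")
_RM_PAIRS = ("1st_all", "2nd_all", "2nd_1st")
_NDI_PAIRS = {"G_IR1": (532, 1064), "G_IR2": (532, 1550), "NDIR": (1064, 1550)}
_CH_STATS = ("mn", "p50", "p75")


class CrownUnusableError(ValueError):
    """Crown cannot be normalized (e.g. DTM nodata at its centroid)."""


@dataclass
class CrownPointSet:
    """Returns of one crown, heights normalized to a single ground value."""

    crown_id: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray  # height above ground, all > HEIGHT_CUTOFF
    intensity: np.ndarray
    return_number: np.ndarray
    channel: np.ndarray
    sensor_label: str = ""

    @property
    def H(self) -> float:
        """Tree height: maximum normalized return height."""
        return float(self.z.max()) if len(self.z) else 0.0

    def __len__(self) -> int:
        return len(self.z)

    def subset(self, mask: np.ndarray) -> "CrownPointSet":
        return CrownPointSet(
            self.crown_id, self.x[mask], self.y[mask], self.z[mask],
            self.intensity[mask], self.return_number[mask], self.channel[mask],
            self.sensor_label,
        )


def clip_and_normalize(
    cloud: PointCloud,
    polygon: Polygon,
    dtm: RasterGrid,
    crown_id: int = 0,
    sensor_label: str = "",
) -> CrownPointSet:
    """Extract a crown's returns and normalize heights to the centroid DTM value."""
    if polygon.is_empty or not polygon.is_valid:
        raise ValueError("invalid crown polygon")
    centroid = polygon.centroid
    ground = dtm.sample(centroid.x, centroid.y)
    if np.isnan(ground):
        raise CrownUnusableError(f"crown {crown_id}: DTM nodata at centroid")

    xmin, ymin, xmax, ymax = polygon.bounds
    near = (
        (cloud.x >= xmin) & (cloud.x <= xmax)
        & (cloud.y >= ymin) & (cloud.y <= ymax)
        & (cloud.classification != NOISE)
    )
    idx = np.flatnonzero(near)
    if len(idx):
        inside = shapely.contains_xy(polygon, cloud.x[idx], cloud.y[idx])
        idx = idx[inside]
    z_above = cloud.z[idx] - ground
    keep = z_above > HEIGHT_CUTOFF
    idx = idx[keep]
    return CrownPointSet(
        crown_id=crown_id,
        x=cloud.x[idx], y=cloud.y[idx], z=z_above[keep],
        intensity=cloud.intensity[idx],
        return_number=cloud.return_number[idx],
        channel=cloud.channel[idx],
        sensor_label=sensor_label,
    )


def normalize_feature(F: float, H: float) -> float:
    """Fn = F / H — height normalization for size-bearing features."""
    if H <= 0:
        raise ValueError("tree height H must be > 0")
    return F / H


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _cv(values: np.ndarray) -> float:
    if len(values) < 2:
        return np.nan
    m = values.mean()
    if abs(m) < 1e-12:
        return np.nan
    return float(values.std(ddof=1) / m)


def _stat(values: np.ndarray, stat: str) -> float:
    if len(values) == 0:
        return np.nan
    if stat == "mn":
        return float(values.mean())
    return float(np.percentile(values, int(stat[1:])))


def _slopes(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Slopes of the lines joining the highest return to every other return."""
    if len(z) < 2:
        return np.zeros(0)
    top = int(np.argmax(z))
    dx = x - x[top]
    dy = y - y[top]
    dz = z[top] - z
    horiz = np.hypot(dx, dy)
    ok = horiz > 1e-9
    ok[top] = False
    return dz[ok] / horiz[ok]


# ---------------------------------------------------------------------------
# 3D features
# ---------------------------------------------------------------------------


def compute_3d_features(cps: CrownPointSet) -> dict[str, float]:
    out: dict[str, float] = {}
    n = len(cps)
    if n == 0:
        return {name: np.nan for name in feature_names_3d()}
    z = cps.z
    H = cps.H
    first = cps.return_number == 1
    second = cps.return_number == 2

    out["3D_DI_all_cv"] = _cv(z)
    out["3D_DI_1st_cv"] = _cv(z[first])

    for tag, mask in (("all", np.ones(n, bool)), ("1st", first)):
        sl = _slopes(cps.x[mask], cps.y[mask], z[mask])
        out[f"3D_SLOPE_{tag}_mn"] = float(sl.mean()) if len(sl) else np.nan
        out[f"3D_SLOPE_{tag}_sd"] = float(sl.std(ddof=1)) if len(sl) > 1 else np.nan
        out[f"3D_SLOPE_{tag}_cv"] = _cv(sl)
        for p in (25, 50, 75):
            out[f"3D_SLOPE_{tag}_p{p}"] = (
                float(np.percentile(sl, p)) if len(sl) else np.nan
            )

    rel = z / H
    for lo, hi, name in ((0.60, 0.80, "60_80"), (0.80, 0.90, "80_90"),
                         (0.90, 1.001, "90_100"), (0.95, 1.001, "95_100")):
        out[f"3D_RB_{name}"] = float(np.mean((rel >= lo) & (rel < hi)))

    try:
        hull = ConvexHull(np.column_stack([cps.x, cps.y, z]))
        out["3D_CH"] = float(hull.volume / H**3)
    except (QhullError, ValueError):
        out["3D_CH"] = np.nan

    groups = {"all": z, "1st": z[first], "2nd": z[second]}
    has2 = second.any()
    for stat in _RM_STATS:
        for pair in _RM_PAIRS:
            num_tag, den_tag = pair.split("_")
            if "2nd" in pair and not has2:
                out[f"3D_RM_z{stat}_{pair}"] = np.nan
                continue
            num = _stat(groups[num_tag], stat)
            den = _stat(groups[den_tag], stat)
            out[f"3D_RM_z{stat}_{pair}"] = num / den if den and not np.isnan(den) else np.nan
    counts = {"all": n, "1st": int(first.sum()), "2nd": int(second.sum())}
    for pair in _RM_PAIRS:
        num_tag, den_tag = pair.split("_")
        if "2nd" in pair and not has2:
            out[f"3D_RM_n_{pair}"] = np.nan
        else:
            out[f"3D_RM_n_{pair}"] = (
                counts[num_tag] / counts[den_tag] if counts[den_tag] else np.nan
            )
    return out


def feature_names_3d() -> list[str]:
    names = ["3D_DI_all_cv", "3D_DI_1st_cv"]
    names += [f"3D_SLOPE_{tag}_{s}" for tag in ("all", "1st") for s in _SLOPE_STATS]
    names += [f"3D_RB_{b}" for b in ("60_80", "80_90", "90_100", "95_100")]
    names += ["3D_CH"]
    names += [f"3D_RM_z{s}_{p}" for s in _RM_STATS for p in _RM_PAIRS]
    names += [f"3D_RM_n_{p}" for p in _RM_PAIRS]
    return names


# ---------------------------------------------------------------------------
# intensity features
# ---------------------------------------------------------------------------


def compute_intensity_features(cps: CrownPointSet, channel: int) -> dict[str, float]:
    """Per-channel intensity features (suffix added by the caller)."""
    out: dict[str, float] = {}
    ch = cps.channel == channel
    sub = cps.subset(ch)
    first = sub.return_number == 1
    second = sub.return_number == 2
    i1 = sub.intensity[first]
    z1 = sub.z[first]

    if len(i1) == 0:
        return {name: np.nan for name in feature_names_intensity()}

    out["I_DI_1st_sd"] = float(i1.std(ddof=1)) if len(i1) > 1 else np.nan
    out["I_DI_1st_cv"] = _cv(i1)

    for p in _PE_PERCENTILES:
        target = np.percentile(z1, p)
        # nearest-height first return; ties toward the lower height
        d = np.abs(z1 - target)
        cand = np.lexsort((z1, d))[0]
        out[f"I_PE_p{p}"] = float(i1[cand])

    out["I_MI_all"] = float(i1.mean())
    for lo, hi, name in ((5, 95, "p5_95"), (10, 90, "p10_90")):
        zlo, zhi = np.percentile(z1, [lo, hi])
        band = (z1 >= zlo) & (z1 <= zhi)
        out[f"I_MI_{name}"] = float(i1[band].mean()) if band.any() else np.nan

    iall = sub.intensity
    i2 = sub.intensity[second]
    has2 = len(i2) > 0
    for stat in ("mn", "p50"):
        s1 = _stat(i1, stat)
        out[f"I_RM_{stat}_2nd_1st"] = _stat(i2, stat) / s1 if has2 and s1 else np.nan
        sall = _stat(iall, stat)
        out[f"I_RM_{stat}_1st_all"] = s1 / sall if sall else np.nan
    return out


def feature_names_intensity() -> list[str]:
    names = ["I_DI_1st_sd", "I_DI_1st_cv"]
    names += [f"I_PE_p{p}" for p in _PE_PERCENTILES]
    names += ["I_MI_all", "I_MI_p5_95", "I_MI_p10_90"]
    names += [f"I_RM_{s}_{p}" for s in ("mn", "p50") for p in ("2nd_1st", "1st_all")]
    return names


def compute_msl_indices(cps: CrownPointSet) -> dict[str, float]:
    """NDVI-like normalized differences and simple ratios across wavelengths.

    Sign convention: (longer wavelength - shorter) / (sum), on matched
    per-channel first-return statistics. Simple ratios are shorter/longer.
    """
    out: dict[str, float] = {}
    stats: dict[tuple[int, str], float] = {}
    for wl in (532, 1064, 1550):
        sub = cps.subset((cps.channel == wl) & (cps.return_number == 1))
        for stat in _CH_STATS:
            stats[(wl, stat)] = _stat(sub.intensity, stat)

    for name, (short, long_) in _NDI_PAIRS.items():
        for stat in _CH_STATS:
            a = stats[(long_, stat)]
            b = stats[(short, stat)]
            denom = a + b
            out[f"I_{name}_{stat}"] = (
                (a - b) / denom if denom and not np.isnan(denom) else np.nan
            )
    for short, long_ in ((532, 1064), (532, 1550), (1064, 1550)):
        for stat in _CH_STATS:
            a = stats[(short, stat)]
            b = stats[(long_, stat)]
            out[f"I_SR_{short}_{long_}_{stat}"] = (
                a / b if b and not np.isnan(b) else np.nan
            )
    return out


def feature_names_msl_indices() -> list[str]:
    names = [f"I_{n}_{s}" for n in _NDI_PAIRS for s in _CH_STATS]
    names += [f"I_SR_{a}_{b}_{s}" for a, b in ((532, 1064), (532, 1550), (1064, 1550))
              for s in _CH_STATS]
    return names


# ---------------------------------------------------------------------------
# feature table assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Per-sensor crown x feature matrices with a shared manifest.

    ``tables[label]`` is indexed by crown id; feature names carry the sensor
    label as a suffix (``3D_CH_12`` style). ``flags[label]`` marks rows with
    any missing value; such crowns cannot train a random forest and are
    dropped by :meth:`complete`.
    """

    tables: dict[str, pd.DataFrame]
    manifest: dict[str, dict] = field(default_factory=dict)

    def flags(self, label: str) -> pd.Series:
        return self.tables[label].isna().any(axis=1)

    def complete(self, label: str) -> pd.DataFrame:
        df = self.tables[label]
        return df[~df.isna().any(axis=1)]

    def pooled(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels or sorted(self.tables)
        dfs = [self.complete(lbl) for lbl in labels]
        return pd.concat(dfs, axis=1, join="inner")

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, df in self.tables.items():
            df.to_csv(directory / f"features_{label}.csv")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def extract_crown_features(
    cloud: PointCloud,
    polygon: Polygon,
    dtm: RasterGrid,
    wavelengths: tuple[int, ...],
    crown_id: int = 0,
    sensor_label: str = "",
) -> dict[str, float]:
    """All features of one crown under one sensor (no suffixing)."""
    cps = clip_and_normalize(cloud, polygon, dtm, crown_id, sensor_label)
    if len(cps) == 0:
        raise CrownUnusableError(f"crown {crown_id}: no returns above cutoff")
    feats = dict(compute_3d_features(cps))  # channels pooled for 3D
    multi = len(wavelengths) > 1
    for wl in wavelengths:
        for name, value in compute_intensity_features(cps, wl).items():
            feats[f"{name}_c{wl}" if multi else name] = value
    if multi:
        feats.update(compute_msl_indices(cps))
    return feats


def assemble_feature_table(
    crown_polygons: dict[int, Polygon],
    sensor_clouds: dict[str, tuple[PointCloud, tuple[int, ...]]],
    dtm: RasterGrid,
) -> FeatureTable:
    """Crown x feature matrices for every sensor.

    `sensor_clouds` maps a sensor label (feature-name suffix) to the cloud
    and its wavelength tuple. Crowns whose centroid falls on DTM nodata or
    that contain no usable returns get all-NaN rows (flagged, never silently
    dropped).
    """
    tables: dict[str, pd.DataFrame] = {}
    manifest: dict[str, dict] = {}
    for label, (cloud, wavelengths) in sensor_clouds.items():
        multi = len(wavelengths) > 1
        names = list(feature_names_3d())
        for wl in wavelengths:
            names += [f"{n}_c{wl}" if multi else n for n in feature_names_intensity()]
        if multi:
            names += feature_names_msl_indices()
        rows = {}
        for cid, poly in crown_polygons.items():
            try:
                feats = extract_crown_features(cloud, poly, dtm, wavelengths,
                                               cid, label)
            except CrownUnusableError:
                feats = {n: np.nan for n in names}
            rows[cid] = feats
        df = pd.DataFrame.from_dict(rows, orient="index")
        df = df.reindex(columns=names)
        df.columns = [f"{c}_{label}" for c in df.columns]
        df.index.name = "crown_id"
        tables[label] = df
        for col in df.columns:
            manifest[col] = {
                "sensor": label,
                "family": col.split("_")[0],
                "n_wavelengths": len(wavelengths),
            }
    return FeatureTable(tables=tables, manifest=manifest)
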