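"""Individual-tree-crown delineation from a canopy height model.

The pipeline follows the classic raster recipe used by operational crown
segmenters: (1) Gaussian smoothing whose sigma grows with local canopy
height, (2) treetop detection as local maxima within a height-dependent
exclusion radius, (3) region growing (marker watershed on the inverted
smoothed CHM) with a relative-height stop rule, (4) per-crown attributes and
a weighted plausibility score, and (5) erosion-based resegmentation of
low-scoring or implausibly proportioned crowns.

Proportionality constants for the sigma and exclusion-radius laws, the stop
fraction, and the score weights are not published for any operational
segmenter; the defaults here were calibrated once on synthetic conifer and
broadleaf scenes and are fully exposed through :class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure, morphology
from skimage.segmentation import watershed

from .raster import RasterGrid


# ---------------------------------------------------------------------------
# parameters and crown record
# ---------------------------------------------------------------------------


def default_sigma_fn(height, cell_size: float):
    """Smoothing sigma in pixels: max(0.5, 0.06 * h / cell_size)."""
    return np.maximum(0.5, 0.06 * np.asarray(height, float) / cell_size)


def default_radius_fn(height):
    """Treetop exclusion radius in metres: max(1.0, 0.15 * h)."""
    return np.maximum(1.0, 0.15 * np.asarray(height, float))


#: plausibility windows per attribute: (zero, full_lo, full_hi, zero_hi)
_SUBSCORE_WINDOWS = {
    "crown_ratio": (0.05, 0.30, 0.90, 1.00),
    "circularity": (0.10, 0.40, 1.00, 1.20),
    "height_to_area_ratio": (0.01, 0.05, 2.00, 10.0),
    "crown_area": (1.0, 5.0, 250.0, 600.0),
    "compactness": (0.0, 0.30, 1.00, 1.10),  # 1 - eccentricity
}


@dataclass
class SegmentationParams:
    min_height: float = 2.0  # m, no treetop below this
    growth_stop_fraction: float = 0.3  # crown edge height / apex height
    min_crown_area: float = 3.0  # m2
    score_weights: dict[str, float] = field(
        default_factory=lambda: {k: 1 / len(_SUBSCORE_WINDOWS) for k in _SUBSCORE_WINDOWS}
    )
    resegmentation_score_threshold: float = 0.45
    h2a_bounds: tuple[float, float] = (0.02, 6.0)  # plausible height/area range
    eccentricity_max: float = 0.7  # beyond this a crown is "improbably" elongated
    erosion_step: int = 1  # pixels eroded per resegmentation iteration
    sigma_fn: Callable | None = None  # height m -> sigma px (cell-size aware default)
    exclusion_radius_fn: Callable | None = None  # height m -> radius m

    def __post_init__(self) -> None:
        if not 0 < self.growth_stop_fraction < 1:
            raise ValueError("growth_stop_fraction must be in (0, 1)")
        s = sum(self.score_weights.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError("score_weights must sum to 1")


@dataclass
class Crown:
    id: int
    polygon: Polygon
    apex: tuple[float, float]  # map coords
    attributes: dict[str, float]
    delineation_score: float = float("nan")


# ---------------------------------------------------------------------------
# adaptive smoothing
# ---------------------------------------------------------------------------


def adaptive_gaussian_filter(chm: RasterGrid, sigma_fn: Callable) -> RasterGrid:
    """Gaussian smoothing with per-pixel sigma = sigma_fn(local height).

    Implemented by smoothing at a small bank of quantized sigma levels and
    picking, per pixel, the level nearest its requested sigma (sigma_fn is
    monotone in height so quantization error is bounded by the level step).
    Nodata cells are excluded via normalized convolution and restored.
    """
    v = chm.values
    nodata = np.isnan(v)
    filled = np.where(nodata, 0.0, v)
    sigma_map = np.asarray(sigma_fn(filled), dtype=float)
    if sigma_map.shape != v.shape:
        sigma_map = np.full(v.shape, float(sigma_map))

    out = filled.copy()
    smax = float(sigma_map.max())
    if smax > 0:
        levels = np.unique(np.round(np.clip(sigma_map, 0, None) * 4) / 4)
        levels = levels[levels > 0]
        if len(levels) > 10:
            levels = np.unique(np.quantile(levels, np.linspace(0, 1, 10)))
        weight = (~nodata).astype(float)
        target = np.where(sigma_map > 0, sigma_map, np.inf)
        # nearest level per pixel
        idx = np.abs(target[..., None] - levels[None, None, :]).argmin(axis=-1)
        for li, sigma in enumerate(levels):
            num = ndimage.gaussian_filter(filled * weight, sigma, mode="nearest")
            den = ndimage.gaussian_filter(weight, sigma, mode="nearest")
            with np.errstate(invalid="ignore"):
                sm = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
            sel = (idx == li) & (sigma_map > 0)
            out[sel] = sm[sel]
    out[nodata] = np.nan
    return RasterGrid(chm.origin_x, chm.origin_y, chm.cell_size, out, crs=chm.crs)


# ---------------------------------------------------------------------------
# treetop detection
# ---------------------------------------------------------------------------


def detect_local_maxima(
    filtered_chm: RasterGrid,
    exclusion_radius_fn: Callable = default_radius_fn,
    min_height: float = 2.0,
) -> list[tuple[int, int]]:
    """Treetops: pixels exceeding every pixel within their exclusion radius.

    The radius (metres) depends on the pixel's own height. Ties between
    equal-valued pixels inside each other's radius are broken toward the
    lowest (row, col) — a deterministic convention.
    """
    v = np.where(np.isnan(filtered_chm.values), -np.inf, filtered_chm.values)
    cell = filtered_chm.cell_size
    nrow, ncol = v.shape
    cand_mask = v >= min_height
    if not cand_mask.any():
        return []
    radii = np.asarray(exclusion_radius_fn(np.where(cand_mask, v, 0.0)), dtype=float)
    if radii.shape != v.shape:
        radii = np.full(v.shape, float(radii))

    # conservative prefilter: an apex whose radius spans >= 1 cell cannot be
    # below any of its 4-connected neighbours (diagonals may lie outside the
    # radius, so they are not consulted here)
    if radii[cand_mask].min() >= cell:
        cross = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        mx = ndimage.maximum_filter(v, footprint=cross, mode="constant",
                                    cval=-np.inf)
        cand_mask = cand_mask & (v >= mx)
    rows, cols = np.nonzero(cand_mask)

    apexes = []
    for r, c in zip(rows, cols):
        val = v[r, c]
        rm = float(radii[r, c])
        rad_px = int(np.floor(rm / cell))
        r0, r1 = max(0, r - rad_px), min(nrow, r + rad_px + 1)
        c0, c1 = max(0, c - rad_px), min(ncol, c + rad_px + 1)
        win = v[r0:r1, c0:c1]
        di = (np.arange(r0, r1) - r)[:, None]
        dj = (np.arange(c0, c1) - c)[None, :]
        within = (di**2 + dj**2) * cell**2 <= rm**2
        within[r - r0, c - c0] = False
        if np.any(win[within] > val):
            continue
        ties = within & (win == val)
        if ties.any():
            tr, tc = np.nonzero(ties)
            order = (tr + r0) * ncol + (tc + c0)
            if order.min() < r * ncol + c:
                continue
        apexes.append((int(r), int(c)))
    return apexes


# ---------------------------------------------------------------------------
# region growing
# ---------------------------------------------------------------------------


def grow_regions(
    filtered_chm: RasterGrid,
    apexes: list[tuple[int, int]],
    params: SegmentationParams,
) -> np.ndarray:
    """Marker-watershed flooding with a relative-height stop rule.

    Returns an int label grid (0 = unassigned); label k corresponds to
    ``apexes[k-1]``. Pixels below ``growth_stop_fraction`` times their apex
    height are cut off, and each crown keeps only the connected component
    containing its apex.
    """
    if not apexes:
        return np.zeros(filtered_chm.values.shape, dtype=np.int32)
    v = np.where(np.isnan(filtered_chm.values), 0.0, filtered_chm.values)
    markers = np.zeros(v.shape, dtype=np.int32)
    for k, (r, c) in enumerate(apexes, start=1):
        markers[r, c] = k
    mask = v > 0
    labels = watershed(-v, markers, mask=mask, connectivity=1)

    for k, (r, c) in enumerate(apexes, start=1):
        apex_h = v[r, c]
        region = (labels == k) & (v >= params.growth_stop_fraction * apex_h)
        comp, _ = ndimage.label(region)
        keep = comp == comp[r, c]
        labels[(labels == k) & ~keep] = 0
    return labels


# ---------------------------------------------------------------------------
# attributes and scoring
# ---------------------------------------------------------------------------


def compute_crown_attributes(
    region_mask: np.ndarray,
    unfiltered_chm: RasterGrid,
    apex_rc: tuple[int, int],
    crown_id: int = 0,
) -> Crown:
    """Crown geometry and height attributes from the UNFILTERED CHM."""
    if not region_mask.any():
        raise ValueError("empty crown region")
    cell = unfiltered_chm.cell_size
    vals = unfiltered_chm.values[region_mask]
    vals = vals[~np.isnan(vals)]
    height = float(vals.max()) if len(vals) else 0.0
    low = float(vals.min()) if len(vals) else 0.0
    vertical_extent = max(0.0, height - low)
    npix = int(region_mask.sum())
    area = npix * cell**2
    diameter = cell if npix == 1 else 2.0 * np.sqrt(area / np.pi)

    props = measure.regionprops(region_mask.astype(np.uint8))[0]
    perim = max(props.perimeter_crofton, cell * 1e-6) * cell
    circularity = float(min(4 * np.pi * area / perim**2, 1.2)) if npix > 1 else 1.0
    eccentricity = float(props.eccentricity)

    attrs = {
        "height": height,
        "crown_area": area,
        "diameter": diameter,
        "height_to_area_ratio": height / area if area > 0 else np.nan,
        "vertical_extent": vertical_extent,
        "crown_ratio": vertical_extent / height if height > 0 else 0.0,
        "circularity": circularity,
        "eccentricity": eccentricity,
        "compactness": 1.0 - eccentricity,
        "n_pixels": npix,
    }
    ar, ac = apex_rc
    apex_xy = (
        unfiltered_chm.origin_x + (ac + 0.5) * cell,
        unfiltered_chm.origin_y + (ar + 0.5) * cell,
    )
    poly = _region_polygon(region_mask, unfiltered_chm)
    return Crown(id=crown_id, polygon=poly, apex=apex_xy, attributes=attrs)


def _region_polygon(mask: np.ndarray, grid: RasterGrid) -> Polygon:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    cell = grid.cell_size
    xs = grid.origin_x + (contour[:, 1] - 1 + 0.5) * cell
    ys = grid.origin_y + (contour[:, 0] - 1 + 0.5) * cell
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _trapezoid(x: float, zero_lo: float, full_lo: float, full_hi: float,
               zero_hi: float) -> float:
    if np.isnan(x):
        return 0.0
    if x <= zero_lo or x >= zero_hi:
        return 0.0
    if full_lo <= x <= full_hi:
        return 1.0
    if x < full_lo:
        return (x - zero_lo) / (full_lo - zero_lo)
    return (zero_hi - x) / (zero_hi - full_hi)


def attribute_subscores(crown: Crown) -> dict[str, float]:
    """Map crown attributes onto [0, 1] plausibility sub-scores."""
    return {
        name: _trapezoid(crown.attributes.get(name, np.nan), *window)
        for name, window in _SUBSCORE_WINDOWS.items()
    }


def weighted_score(subscores: dict[str, float], weights: dict[str, float]) -> float:
    if abs(sum(weights.values()) - 1.0) > 1e-6:
        raise ValueError("score weights must sum to 1")
    return float(sum(weights[k] * subscores.get(k, 0.0) for k in weights))


def delineation_score(crown: Crown, score_weights: dict[str, float]) -> float:
    """Weighted mean of attribute plausibility sub-scores, in [0, 1]."""
    return weighted_score(attribute_subscores(crown), score_weights)


# ---------------------------------------------------------------------------
# erosion-based resegmentation
# ---------------------------------------------------------------------------


def resegment_by_erosion(
    labels: np.ndarray,
    crowns: list[Crown],
    chm: RasterGrid,
    params: SegmentationParams,
    label_of: dict[int, int] | None = None,
) -> tuple[np.ndarray, list[Crown]]:
    """Split low-scoring or implausibly proportioned crowns by erosion.

    A flagged crown's region is eroded until it falls apart into two or more
    substantial components (each holding its own height maximum); the
    original region is then re-flooded from those maxima. Crowns that never
    split are left untouched. Labelled area never increases.
    """
    labels = labels.copy()
    out: list[Crown] = []
    next_label = int(labels.max()) + 1
    v = np.where(np.isnan(chm.values), 0.0, chm.values)
    lo, hi = params.h2a_bounds
    min_comp_px = max(6, int(params.min_crown_area / chm.cell_size**2 / 4))

    for crown in crowns:
        flagged = (
            crown.delineation_score < params.resegmentation_score_threshold
            or not (lo <= crown.attributes["height_to_area_ratio"] <= hi)
            or crown.attributes["eccentricity"] > params.eccentricity_max
        )
        lbl = label_of[crown.id] if label_of else crown.id
        region = labels == lbl
        if not flagged or not region.any():
            out.append(crown)
            continue

        mask = region.copy()
        pieces = None
        selem = morphology.disk(max(1, params.erosion_step))
        while mask.any():
            mask = ndimage.binary_erosion(mask, structure=selem)
            comp, ncomp = ndimage.label(mask)
            sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                       index=np.arange(1, ncomp + 1))
            big = [i + 1 for i, s in enumerate(sizes) if s >= min_comp_px]
            if len(big) >= 2:
                pieces = (comp, big)
                break
        if pieces is None:
            out.append(crown)
            continue

        comp, big = pieces
        markers = np.zeros_like(labels)
        seeds = []
        for j, ci in enumerate(big, start=1):
            masked = np.where(comp == ci, v, -np.inf)
            r, c = np.unravel_index(np.argmax(masked), masked.shape)
            markers[r, c] = j
            seeds.append((int(r), int(c)))
        sub = watershed(-v, markers, mask=region, connectivity=1)
        labels[region] = 0
        for j, (r, c) in enumerate(seeds, start=1):
            piece = sub == j
            labels[piece] = next_label
            new = compute_crown_attributes(piece, chm, (r, c), crown_id=next_label)
            new.delineation_score = delineation_score(new, params.score_weights)
            out.append(new)
            next_label += 1
    return labels, out


# ---------------------------------------------------------------------------
# full segmentation
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    crowns: list[Crown]
    labels: np.ndarray
    filtered_chm: RasterGrid
    apexes: list[tuple[int, int]]


def segment(chm: RasterGrid, params: SegmentationParams | None = None) -> SegmentationResult:
    """End-to-end crown delineation on a CHM."""
    params = params or SegmentationParams()
    cell = chm.cell_size
    sigma_fn = params.sigma_fn or (lambda h: default_sigma_fn(h, cell))
    radius_fn = params.exclusion_radius_fn or default_radius_fn

    filtered = adaptive_gaussian_filter(chm, sigma_fn)
    apexes = detect_local_maxima(filtered, radius_fn, params.min_height)
    labels = grow_regions(filtered, apexes, params)

    min_px = max(1, int(round(params.min_crown_area / cell**2)))
    crowns: list[Crown] = []
    label_of: dict[int, int] = {}
    for k, apex_rc in enumerate(apexes, start=1):
        region = labels == k
        if region.sum() < min_px:
            labels[region] = 0
            continue
        crown = compute_crown_attributes(region, chm, apex_rc, crown_id=k)
        crown.delineation_score = delineation_score(crown, params.score_weights)
        label_of[k] = k
        crowns.append(crown)

    labels, crowns = resegment_by_erosion(labels, crowns, chm, params, label_of)
    # re-number sequentially
    for i, crown in enumerate(crowns, start=1):
        crown.id = i
    return SegmentationResult(crowns=crowns, labels=labels, filtered_chm=filtered,
                              apexes=apexes)


# ---------------------------------------------------------------------------
# vector I/O
# ---------------------------------------------------------------------------


def crowns_to_geojson(crowns: list[Crown], path) -> None:
    import json

    from shapely.geometry import mapping

    features = []
    for crown in crowns:
        props = {"id": crown.id, "delineation_score": crown.delineation_score,
                 "apex_x": crown.apex[0], "apex_y": crown.apex[1]}
        props.update({k: float(val) for k, val in crown.attributes.items()})
        features.append(
            {"type": "Feature", "geometry": mapping(crown.polygon), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def crowns_from_geojson(path) -> list[Crown]:
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        collection = json.load(fh)
    crowns = []
    for feat in collection["features"]:
        props = dict(feat["properties"])
        cid = int(props.pop("id"))
        score = float(props.pop("delineation_score", float("nan")))
        apex = (props.pop("apex_x", 0.0), props.pop("apex_y", 0.0))
        crowns.append(Crown(id=cid, polygon=shape(feat["geometry"]), apex=apex,
                            attributes=props, delineation_score=score))
    return crowns
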