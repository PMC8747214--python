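"""Synthetic forest scenes and multi-sensor lidar acquisition simulation.

Three acquisition regimes are modelled after the sensors commonly flown over
temperate research forests:

* a linear monospectral scanner (1550 nm, ~5.8 pts/m2, regular multi-return
  behaviour, continuous intensities),
* a linear multispectral scanner (532/1064/1550 nm at 4.8/12.4/11.9 pts/m2;
  the green channel penetrates thick canopy poorly, so it produces fewer
  ground hits under crowns than the infrared channels),
* a single-photon system (532 nm, ~28.6 pts/m2 from high altitude, a strong
  deficit of second returns, solar-noise points, and an intensity that is
  only a coarsely quantized pulse-width analogue).

One emitted pulse is abstracted to a nadir ray: scan geometry reduces to a
pulse density plus vertical jitter, since nothing downstream consumes
per-pulse trajectories. Crown envelopes are cones (conifers), ellipsoid caps
or paraboloids (broadleaves); return depth below the envelope follows an
exponential attenuation controlled by the species foliage density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .pointcloud import GROUND, NOISE, VEGETATION, PointCloud
from .species import DEFAULT_CATALOGUE, SpeciesProfile

#: ground backscatter means per wavelength (arbitrary units)
GROUND_INTENSITY = {532: 24.0, 1064: 46.0, 1550: 38.0}


# ---------------------------------------------------------------------------
# terrain and scene
# ---------------------------------------------------------------------------


@dataclass
class Terrain:
    """Parametric ground surface: a plane plus optional smooth undulation.

    z(x, y) = base + gx*x + gy*y + sum_k amp_k * cos(2*pi*(fx_k*x + fy_k*y) + phase_k)
    """

    base: float = 0.0
    gx: float = 0.0
    gy: float = 0.0
    waves: list[tuple[float, float, float, float]] = field(default_factory=list)
    # each wave: (amplitude m, fx cycles/m, fy cycles/m, phase rad)

    def elevation(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = self.base + self.gx * x + self.gy * y
        for amp, fx, fy, phase in self.waves:
            z = z + amp * np.cos(2 * math.pi * (fx * x + fy * y) + phase)
        return z

    @classmethod
    def smooth_random(cls, seed: int, base: float = 0.0, relief: float = 2.0) -> "Terrain":
        rng = np.random.default_rng(seed)
        waves = [
            (
                relief * rng.uniform(0.2, 0.5),
                rng.uniform(0.002, 0.01) * rng.choice([-1, 1]),
                rng.uniform(0.002, 0.01) * rng.choice([-1, 1]),
                rng.uniform(0, 2 * math.pi),
            )
            for _ in range(3)
        ]
        return cls(base=base, waves=waves)

    def to_dict(self) -> dict:
        return {"base": self.base, "gx": self.gx, "gy": self.gy,
                "waves": [list(w) for w in self.waves]}

    @classmethod
    def from_dict(cls, d: dict) -> "Terrain":
        return cls(d["base"], d["gx"], d["gy"], [tuple(w) for w in d["waves"]])


@dataclass
class Tree:
    species: str
    x: float
    y: float
    height: float  # m above ground
    crown_radius: float  # m
    crown_ratio: float  # crown vertical extent / height


@dataclass
class Scene:
    """Ground-truth forest: extent, terrain, and a stem list."""

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    terrain: Terrain
    trees: list[Tree]
    min_spacing: float = 1.5

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("degenerate extent")
        for t in self.trees:
            if not (xmin <= t.x <= xmax and ymin <= t.y <= ymax):
                raise ValueError(f"stem ({t.x}, {t.y}) outside extent")
            if t.height <= 2:
                raise ValueError("tree heights must exceed 2 m")

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return (xmax - xmin) * (ymax - ymin)

    def to_json(self, path) -> None:
        d = {
            "extent": list(self.extent),
            "terrain": self.terrain.to_dict(),
            "min_spacing": self.min_spacing,
            "trees": [
                [t.species, t.x, t.y, t.height, t.crown_radius, t.crown_ratio]
                for t in self.trees
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "Scene":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            extent=tuple(d["extent"]),
            terrain=Terrain.from_dict(d["terrain"]),
            trees=[Tree(*row) for row in d["trees"]],
            min_spacing=d.get("min_spacing", 1.5),
        )


# ---------------------------------------------------------------------------
# sensor models
# ---------------------------------------------------------------------------


@dataclass
class SensorModel:
    name: str
    wavelengths: tuple[int, ...]
    per_channel_density: tuple[float, ...]  # pts / m2
    second_return_propensity: float  # P(canopy pulse yields a 2nd return)
    canopy_penetration: dict[int, float]  # wavelength -> P(2nd return reaches ground)
    noise_rate: float = 0.0  # spurious solar-noise points / m2
    intensity_definition: str = "linear-energy"  # or "pulse-width-analogue"
    vertical_noise_sd: float = 0.05  # m, ranging noise
    label: str = ""  # suffix used in feature names (e.g. "12")

    def __post_init__(self) -> None:
        if len(self.wavelengths) != len(self.per_channel_density):
            raise ValueError("one density per wavelength required")
        if any(d <= 0 for d in self.per_channel_density):
            raise ValueError("densities must be > 0")
        if not 0 <= self.second_return_propensity <= 1:
            raise ValueError("second_return_propensity must be in [0, 1]")
        for p in self.canopy_penetration.values():
            if not 0 <= p <= 1:
                raise ValueError("penetration probabilities must be in [0, 1]")

    @property
    def aggregate_density(self) -> float:
        return float(sum(self.per_channel_density))


def make_sensor(name: str) -> SensorModel:
    """Factory for the three built-in acquisition regimes."""
    if name == "ALS12-like":
        return SensorModel(
            name=name, wavelengths=(1550,), per_channel_density=(5.8,),
            second_return_propensity=0.45, canopy_penetration={1550: 0.45},
            noise_rate=0.0, intensity_definition="linear-energy",
            vertical_noise_sd=0.05, label="12",
        )
    if name == "MSL16-like":
        return SensorModel(
            name=name, wavelengths=(532, 1064, 1550),
            per_channel_density=(4.8, 12.4, 11.9),
            second_return_propensity=0.50,
            canopy_penetration={532: 0.12, 1064: 0.45, 1550: 0.42},
            noise_rate=0.0, intensity_definition="linear-energy",
            vertical_noise_sd=0.05, label="16",
        )
    if name == "SPL18-like":
        return SensorModel(
            name=name, wavelengths=(532,), per_channel_density=(28.6,),
            second_return_propensity=0.08, canopy_penetration={532: 0.10},
            noise_rate=0.25, intensity_definition="pulse-width-analogue",
            vertical_noise_sd=0.12, label="18",
        )
    raise ValueError(f"unknown sensor name {name!r}")


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def generate_scene(
    extent: tuple[float, float, float, float],
    species_mix: dict[str, float],
    stem_density: float,
    seed: int,
    catalogue: dict[str, SpeciesProfile] | None = None,
    min_spacing: float = 1.5,
    terrain: Terrain | None = None,
) -> Scene:
    """Place stems with a minimum spacing and draw per-tree structure.

    Species counts are allocated deterministically from the requested
    proportions (largest-remainder apportionment) and then shuffled over stem
    positions, so realized proportions match the request to within one stem.
    """
    if not species_mix:
        raise ValueError("species_mix must not be empty")
    if stem_density <= 0:
        raise ValueError("stem_density must be > 0")
    total = sum(species_mix.values())
    if not math.isclose(total, 1.0, rel_tol=1e-6):
        raise ValueError("species proportions must sum to 1")
    catalogue = catalogue or DEFAULT_CATALOGUE
    for code in species_mix:
        if code not in catalogue:
            raise ValueError(f"unknown species {code!r}")

    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    area_ha = (xmax - xmin) * (ymax - ymin) / 1e4
    n = int(round(stem_density * area_ha))

    # largest-remainder apportionment of species counts
    codes = sorted(species_mix)
    quotas = np.array([species_mix[c] * n for c in codes])
    counts = np.floor(quotas).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(codes, counts)
    rng.shuffle(labels)

    # dart-throwing with a spatial hash for the spacing constraint
    cell = max(min_spacing, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    xs, ys = [], []
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(xs) < n and attempts < max_attempts:
        attempts += 1
        px = rng.uniform(xmin, xmax)
        py = rng.uniform(ymin, ymax)
        ci, cj = int(px // cell), int(py // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if (px - xs[k]) ** 2 + (py - ys[k]) ** 2 < min_spacing**2:
                        ok = False
                        break
        if ok:
            grid.setdefault((ci, cj), []).append(len(xs))
            xs.append(px)
            ys.append(py)
    if len(xs) < n:
        raise ValueError("could not place stems at requested density and spacing")

    trees = []
    for code, px, py in zip(labels, xs, ys):
        prof = catalogue[code]
        h = rng.uniform(*prof.height_range)
        cr = rng.uniform(*prof.crown_ratio_range)
        radius = max(0.8, prof.crown_radius_per_height * h * rng.uniform(0.85, 1.15))
        trees.append(Tree(code, px, py, h, radius, cr))
    return Scene(extent=extent, terrain=terrain or Terrain(), trees=trees,
                 min_spacing=min_spacing)


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------


def _envelope_heights(scene: Scene, x: np.ndarray, y: np.ndarray,
                      catalogue: dict[str, SpeciesProfile]):
    """Top-of-canopy envelope height above ground and owning tree per point.

    Returns (env, tree_idx): env is height above local ground of the crown
    envelope (0 where no crown), tree_idx is -1 in the open.
    """
    env = np.zeros(len(x))
    idx = np.full(len(x), -1, dtype=int)
    if not scene.trees:
        return env, idx
    pts_tree = cKDTree(np.column_stack([x, y])) if len(x) else None
    for ti, t in enumerate(scene.trees):
        if pts_tree is None:
            break
        members = pts_tree.query_ball_point([t.x, t.y], t.crown_radius)
        if not members:
            continue
        m = np.asarray(members)
        d = np.hypot(x[m] - t.x, y[m] - t.y)
        frac = d / t.crown_radius
        extent = t.crown_ratio * t.height
        shape = catalogue[t.species].crown_shape
        if shape == "cone":
            top = t.height - frac * extent
        elif shape == "paraboloid":
            top = t.height - frac**2 * extent
        else:  # ellipsoid cap
            top = (t.height - extent / 2) + (extent / 2) * np.sqrt(
                np.clip(1 - frac**2, 0, 1)
            )
        better = top > env[m]
        env[m[better]] = top[better]
        idx[m[better]] = ti
    return env, idx


def _canopy_fraction(scene: Scene, catalogue) -> float:
    """Deterministic probe-grid estimate of the crown-covered area fraction."""
    xmin, ymin, xmax, ymax = scene.extent
    nx = max(40, min(160, int(xmax - xmin)))
    ny = max(40, min(160, int(ymax - ymin)))
    gx, gy = np.meshgrid(
        np.linspace(xmin, xmax, nx), np.linspace(ymin, ymax, ny)
    )
    env, idx = _envelope_heights(scene, gx.ravel(), gy.ravel(), catalogue)
    return float(np.mean(idx >= 0))


def simulate_acquisition(
    scene: Scene,
    sensor: SensorModel | str,
    seed: int,
    catalogue: dict[str, SpeciesProfile] | None = None,
    include_noise: bool = True,
) -> PointCloud:
    """Simulate one over-flight of `scene` by `sensor`.

    The pulse count per channel is calibrated so the realized aggregate point
    density matches the sensor's nominal density (second returns inflate the
    count by ``P(2nd) * canopy fraction``, estimated on a deterministic probe
    grid). Each canopy pulse returns from an exponential depth below the crown
    envelope; a species- and wavelength-specific intensity is attached.
    """
    if isinstance(sensor, str):
        sensor = make_sensor(sensor)
    catalogue = catalogue or DEFAULT_CATALOGUE
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = scene.extent
    area = scene.area
    fc = _canopy_fraction(scene, catalogue)

    dens = np.array([catalogue[t.species].foliage_density for t in scene.trees])
    heights = np.array([t.height for t in scene.trees])
    extents = np.array([t.crown_ratio * t.height for t in scene.trees])
    species_arr = [t.species for t in scene.trees]

    parts = []
    for wl, density in zip(sensor.wavelengths, sensor.per_channel_density):
        p2 = sensor.second_return_propensity
        n_pulses = int(round(density * area / (1 + p2 * fc)))
        px = rng.uniform(xmin, xmax, n_pulses)
        py = rng.uniform(ymin, ymax, n_pulses)
        ground_z = scene.terrain.elevation(px, py)
        env, tidx = _envelope_heights(scene, px, py, catalogue)
        canopy = tidx >= 0

        n = n_pulses
        x1, y1 = px, py
        z1 = np.empty(n)
        cls1 = np.full(n, GROUND, dtype=int)
        nret = np.ones(n, dtype=int)

        # open-ground pulses: single ground return
        open_m = ~canopy
        z1[open_m] = ground_z[open_m] + rng.normal(0, sensor.vertical_noise_sd,
                                                   open_m.sum())

        # canopy pulses: first return at exponential depth below the envelope
        cm = canopy
        ci = tidx[cm]
        scale = 1.2 / dens[ci]
        depth = rng.exponential(scale)
        depth = np.minimum(depth, extents[ci] * 0.95)
        z1[cm] = (
            ground_z[cm] + env[cm] - depth
            + rng.normal(0, sensor.vertical_noise_sd, cm.sum())
        )
        cls1[cm] = VEGETATION

        # second returns for a fraction of canopy pulses
        has2 = canopy & (rng.random(n) < p2)
        nret[has2] = 2
        i2 = np.flatnonzero(has2)
        t2 = tidx[i2]
        to_ground = rng.random(len(i2)) < sensor.canopy_penetration[wl]
        z2 = np.empty(len(i2))
        cls2 = np.full(len(i2), VEGETATION, dtype=int)
        # ground hits under canopy
        g = to_ground
        z2[g] = ground_z[i2[g]] + rng.normal(0, sensor.vertical_noise_sd, g.sum())
        cls2[g] = GROUND
        # deeper canopy hits
        c2 = ~to_ground
        deeper = 0.5 + rng.exponential(1.2 / dens[t2[c2]])
        z2[c2] = z1[i2[c2]] - deeper
        floor = ground_z[i2[c2]] + 0.3
        z2[c2] = np.maximum(z2[c2], floor)
        z2[c2] = np.minimum(z2[c2], z1[i2[c2]] - 0.1)

        # intensities
        inten1 = np.empty(n)
        gm = cls1 == GROUND
        inten1[gm] = _lognormal(rng, GROUND_INTENSITY[wl], 0.2, gm.sum())
        for ti_, code in enumerate(species_arr):
            sel = cm & (tidx == ti_)
            if not sel.any():
                continue
            prof = catalogue[code]
            inten1[sel] = _lognormal(rng, prof.intensity_mean[wl],
                                     prof.intensity_cv, sel.sum())
        inten2 = np.empty(len(i2))
        inten2[g] = _lognormal(rng, GROUND_INTENSITY[wl], 0.2, g.sum())
        for ti_, code in enumerate(species_arr):
            sel = t2 == ti_
            sel = sel & c2
            if not sel.any():
                continue
            prof = catalogue[code]
            inten2[sel] = _lognormal(rng, prof.intensity_mean[wl] * 0.8,
                                     prof.intensity_cv, sel.sum())
        if sensor.intensity_definition == "pulse-width-analogue":
            inten1 = _quantize_pulse_width(rng, inten1)
            inten2 = _quantize_pulse_width(rng, inten2)

        part = PointCloud(
            x=np.concatenate([x1, px[i2]]),
            y=np.concatenate([y1, py[i2]]),
            z=np.concatenate([z1, z2]),
            intensity=np.concatenate([inten1, inten2]),
            return_number=np.concatenate([np.ones(n, int), np.full(len(i2), 2)]),
            number_of_returns=np.concatenate([nret, np.full(len(i2), 2)]),
            channel=np.full(n + len(i2), wl, dtype=int),
            classification=np.concatenate([cls1, cls2]),
        )
        parts.append(part)

    cloud = PointCloud.concatenate(parts)
    if include_noise and sensor.noise_rate > 0:
        zmin = float(cloud.z.min()) if len(cloud) else 0.0
        zmax = float(cloud.z.max()) + 20.0 if len(cloud) else 20.0
        cloud = add_solar_noise(
            cloud, sensor.noise_rate, (zmin, zmax),
            seed=int(rng.integers(2**31)),
        )
    return cloud


def _lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    """Log-normal samples with the given arithmetic mean and coefficient of variation."""
    if size == 0:
        return np.zeros(0)
    sigma2 = math.log(1 + cv**2)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _quantize_pulse_width(rng, intensity: np.ndarray) -> np.ndarray:
    """Single-photon pulse-width analogue: few discrete levels, high variance."""
    if len(intensity) == 0:
        return intensity
    blurred = intensity * rng.lognormal(0, 0.6, len(intensity))
    levels = np.clip(np.round(blurred / 10.0), 1, 8)
    return levels * 10.0


def add_solar_noise(
    cloud: PointCloud,
    noise_rate: float,
    vertical_range: tuple[float, float],
    seed: int,
) -> PointCloud:
    """Append uniformly distributed solar-noise points over the cloud footprint."""
    if noise_rate < 0:
        raise ValueError("noise_rate must be >= 0")
    if noise_rate == 0 or len(cloud) == 0:
        return cloud
    rng = np.random.default_rng(seed)
    xmin, xmax = float(cloud.x.min()), float(cloud.x.max())
    ymin, ymax = float(cloud.y.min()), float(cloud.y.max())
    area = max((xmax - xmin) * (ymax - ymin), 1e-9)
    n = rng.poisson(noise_rate * area)
    zlo, zhi = vertical_range
    wl = int(np.bincount(cloud.channel).argmax())
    noise = PointCloud(
        x=rng.uniform(xmin, xmax, n),
        y=rng.uniform(ymin, ymax, n),
        z=rng.uniform(zlo, zhi, n),
        intensity=rng.uniform(1, 10, n),
        return_number=np.ones(n, int),
        number_of_returns=np.ones(n, int),
        channel=np.full(n, wl, dtype=int),
        classification=np.full(n, NOISE, dtype=int),
        crs=cloud.crs,
    )
    return PointCloud.concatenate([cloud, noise])


def filter_noise_cell_count(
    cloud: PointCloud, cell_size: float = 1.0, min_neighbors: int = 4
) -> PointCloud:
    """Voxel-occupancy density filter against solar noise.

    Points are binned into ``cell_size`` voxels; a point survives when the
    3x3x3 voxel neighbourhood around it (itself included) holds at least
    ``min_neighbors`` points. This is a stand-in for vendor differential
    cell-count filters whose parameters are unpublished.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if len(cloud) == 0:
        return cloud
    ix = np.floor((cloud.x - cloud.x.min()) / cell_size).astype(int)
    iy = np.floor((cloud.y - cloud.y.min()) / cell_size).astype(int)
    iz = np.floor((cloud.z - cloud.z.min()) / cell_size).astype(int)
    shape = (ix.max() + 1, iy.max() + 1, iz.max() + 1)
    counts = np.zeros(shape, dtype=np.int32)
    np.add.at(counts, (ix, iy, iz), 1)
    neigh = ndimage.uniform_filter(counts.astype(float), size=3, mode="constant") * 27
    keep = neigh[ix, iy, iz] >= min_neighbors - 0.5
    return cloud.select(keep)
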