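"""Species profiles used by the synthetic forest generator.

Each profile states the structural and radiometric quantities that make crown
species separable in lidar data: crown shape (conifers are conical, broadleaf
crowns rounded), the plausible height and crown-ratio ranges, a foliage
density that drives how deep pulses penetrate before returning, and mean
backscatter intensity per laser wavelength (532 / 1064 / 1550 nm). The
twelve entries mirror the Great Lakes–St. Lawrence mixed-forest species codes
commonly used for crown-level classification work: seven hardwoods (AS, BA,
BE, BI, MA, OK, PO) and five softwoods (CE, BF, LA, PI, SP).

Values are field-realistic choices, fixed once: heights span pole-size to
mature stems for each species; green (532 nm) reflectance of foliage is low,
near-infrared high, with hardwoods brighter in the NIR than conifers and
shortwave-infrared (1550 nm) intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

HARDWOOD = "hardwood"
SOFTWOOD = "softwood"

WAVELENGTHS = (532, 1064, 1550)


@dataclass(frozen=True)
class SpeciesProfile:
    name: str
    tree_type: str  # hardwood | softwood
    crown_shape: str  # cone | paraboloid | ellipsoid
    height_range: tuple[float, float]  # m
    crown_ratio_range: tuple[float, float]  # vertical crown extent / height
    foliage_density: float  # proxy, points per m^3; higher = shallower returns
    intensity_mean: dict[int, float]  # wavelength nm -> mean intensity (a.u.)
    intensity_cv: float  # within-crown coefficient of variation
    crown_radius_per_height: float = 0.18  # crown radius ~ this * height

    def __post_init__(self) -> None:
        lo, hi = self.height_range
        if not (0 < lo <= hi):
            raise ValueError("height_range must be positive and ordered")
        clo, chi = self.crown_ratio_range
        if not (0 < clo <= chi <= 1):
            raise ValueError("crown_ratio_range must lie in (0, 1]")
        if any(v <= 0 for v in self.intensity_mean.values()):
            raise ValueError("intensity means must be positive")
        if self.tree_type not in (HARDWOOD, SOFTWOOD):
            raise ValueError(f"unknown tree_type {self.tree_type!r}")


def _sp(name, tree_type, shape, hrange, crrange, dens, i532, i1064, i1550, cv, rph):
    return SpeciesProfile(
        name=name,
        tree_type=tree_type,
        crown_shape=shape,
        height_range=hrange,
        crown_ratio_range=crrange,
        foliage_density=dens,
        intensity_mean={532: i532, 1064: i1064, 1550: i1550},
        intensity_cv=cv,
        crown_radius_per_height=rph,
    )


#: Default 12-species catalogue, keyed by two-letter code.
DEFAULT_CATALOGUE: dict[str, SpeciesProfile] = {
    # hardwoods: rounded crowns, higher NIR backscatter, larger crown radii
    "AS": _sp("AS", HARDWOOD, "ellipsoid", (14, 24), (0.45, 0.70), 1.6, 14, 52, 34, 0.30, 0.22),
    "BA": _sp("BA", HARDWOOD, "ellipsoid", (16, 26), (0.50, 0.75), 1.8, 16, 58, 30, 0.28, 0.24),
    "BE": _sp("BE", HARDWOOD, "ellipsoid", (16, 26), (0.55, 0.80), 2.2, 13, 62, 27, 0.24, 0.25),
    "BI": _sp("BI", HARDWOOD, "ellipsoid", (14, 24), (0.40, 0.65), 1.4, 18, 55, 38, 0.34, 0.20),
    "MA": _sp("MA", HARDWOOD, "ellipsoid", (17, 28), (0.50, 0.80), 2.0, 15, 66, 31, 0.26, 0.24),
    "OK": _sp("OK", HARDWOOD, "ellipsoid", (17, 27), (0.45, 0.70), 1.9, 17, 60, 41, 0.30, 0.26),
    "PO": _sp("PO", HARDWOOD, "ellipsoid", (19, 30), (0.35, 0.60), 1.2, 19, 57, 36, 0.36, 0.19),
    # softwoods: conical crowns, deeper crowns, dimmer NIR
    "CE": _sp("CE", SOFTWOOD, "cone", (9, 17), (0.60, 0.90), 3.0, 11, 33, 22, 0.22, 0.16),
    "BF": _sp("BF", SOFTWOOD, "cone", (11, 20), (0.60, 0.90), 2.8, 10, 36, 20, 0.22, 0.14),
    "LA": _sp("LA", SOFTWOOD, "cone", (14, 22), (0.50, 0.80), 1.5, 13, 44, 26, 0.32, 0.14),
    "PI": _sp("PI", SOFTWOOD, "cone", (18, 34), (0.40, 0.70), 2.0, 9, 40, 18, 0.25, 0.17),
    "SP": _sp("SP", SOFTWOOD, "cone", (13, 24), (0.65, 0.95), 3.2, 8, 30, 16, 0.20, 0.13),
}

#: Hardwood / softwood membership of the default catalogue.
TREE_TYPE = {code: p.tree_type for code, p in DEFAULT_CATALOGUE.items()}
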