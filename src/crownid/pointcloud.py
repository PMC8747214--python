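"""Lidar point-cloud container and I/O.

Point records follow the LAS point-record vocabulary (x, y, z, intensity,
return_number, number_of_returns) extended with a wavelength channel id and a
coarse classification. Because no LAS writer is available in the target
environment, clouds are serialized as a documented CSV with exactly these
columns — one row per return, metre coordinates, arbitrary intensity units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: classification codes (mirroring the ASPRS ground/vegetation split plus noise)
GROUND = 2
VEGETATION = 5
NOISE = 7

COLUMNS = [
    "x",
    "y",
    "z",
    "intensity",
    "return_number",
    "number_of_returns",
    "channel",
    "classification",
]


@dataclass
class PointCloud:
    """Column-oriented lidar returns.

    Attributes
    ----------
    x, y, z : float arrays, metres (projected CRS).
    intensity : float array, sensor-specific arbitrary units, >= 0.
    return_number : int array, 1-based ordinal of the echo within its pulse.
    number_of_returns : int array, echoes recorded for the pulse.
    channel : int array, laser wavelength in nm (532 / 1064 / 1550).
    classification : int array, GROUND / VEGETATION / NOISE.
    crs : free-text label of the projected coordinate system.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray
    return_number: np.ndarray
    number_of_returns: np.ndarray
    channel: np.ndarray
    classification: np.ndarray
    crs: str = "local-metres"

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in COLUMNS:
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"column {name!r} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if n:
            for name in ("x", "y", "z"):
                if not np.all(np.isfinite(getattr(self, name))):
                    raise ValueError(f"non-finite values in {name}")
            if np.any(self.intensity < 0):
                raise ValueError("negative intensity")
            if np.any(self.return_number < 1) or np.any(self.number_of_returns < 1):
                raise ValueError("return numbers must be >= 1")
            if np.any(self.return_number > self.number_of_returns):
                raise ValueError("return_number exceeds number_of_returns")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, crs: str = "local-metres") -> "PointCloud":
        return cls(
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            z=df["z"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            return_number=df["return_number"].to_numpy(int),
            number_of_returns=df["number_of_returns"].to_numpy(int),
            channel=df["channel"].to_numpy(int),
            classification=df["classification"].to_numpy(int),
            crs=crs,
        )

    @classmethod
    def empty(cls, crs: str = "local-metres") -> "PointCloud":
        z = np.zeros(0)
        i = np.zeros(0, dtype=int)
        return cls(z, z.copy(), z.copy(), z.copy(), i, i.copy(), i.copy(), i.copy(), crs)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Row subset; `mask` is boolean or integer index array."""
        return PointCloud(
            *(getattr(self, name)[mask] for name in COLUMNS), crs=self.crs
        )

    @staticmethod
    def concatenate(clouds: list["PointCloud"]) -> "PointCloud":
        crs = clouds[0].crs if clouds else "local-metres"
        return PointCloud(
            *(np.concatenate([getattr(c, name) for c in clouds]) for name in COLUMNS),
            crs=crs,
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, crs: str = "local-metres") -> "PointCloud":
        return cls.from_frame(pd.read_csv(path), crs=crs)
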