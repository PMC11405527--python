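"""Point-cloud container and delimited-table I/O.

Clouds are ground-normalized by convention: ``z`` is height above the local
ground plane (metres). Real ALS normalization (ground classification, DTM
subtraction) is assumed to have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PointCloud:
    """A 3D lidar point cloud.

    Parameters
    ----------
    xyz : ndarray of shape (n, 3)
        Point coordinates in metres.
    ground_elevation : float
        Elevation of the ground plane in the cloud's vertical datum.
    normalized : bool
        True when ``z`` is height above ground.
    """

    xyz: np.ndarray
    ground_elevation: float = 0.0
    normalized: bool = True

    def __post_init__(self) -> None:
        arr = np.asarray(self.xyz, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if not np.isfinite(arr).all():
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "xyz", arr)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def translate(self, dx: float, dy: float, dz: float) -> "PointCloud":
        """Rigid translation; returns a new cloud."""
        offset = np.array([dx, dy, dz], dtype=float)
        if not np.isfinite(offset).all():
            raise ValueError("offsets must be finite")
        return replace(self, xyz=self.xyz + offset)


def read_xyz(path: str | Path, **kwargs) -> PointCloud:
    """Read a delimited x,y,z table (with or without header)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", **kwargs)
    cols = [c.lower() for c in df.columns]
    if {"x", "y", "z"} <= set(cols):
        df.columns = cols
        arr = df[["x", "y", "z"]].to_numpy(dtype=float)
    else:
        # headerless: first row was data
        df = pd.read_csv(path, sep=None, engine="python", header=None, **kwargs)
        arr = df.iloc[:, :3].to_numpy(dtype=float)
    return PointCloud(arr)


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    """Write the cloud as a comma-delimited x,y,z table with header."""
    pd.DataFrame(cloud.xyz, columns=["x", "y", "z"]).to_csv(path, index=False)
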