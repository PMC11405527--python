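"""3D canopy entropy: grid kernel-density entropies of 2D point projections.

The structural complexity of a footprint-clipped point cloud is measured as

    CE_XYZ = sqrt(CE_XY^2 + CE_XZ^2 + CE_YZ^2)

where each planar term is the discrete entropy of a normalized Gaussian
kernel density estimate evaluated on a regular lattice of spacing ``s``
(default 10 cm):

    CE_2d = -sum_i rho_i * ln(rho_i) * s^2        [nats]

The vertical component is the mean of the two vertical planes,
CE_Z = (CE_XZ + CE_YZ) / 2. An adaptive voxel-thinning step equalizes point
density across acquisitions before the projections are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .pointcloud import PointCloud

#: density floor below which lattice nodes are dropped from the entropy sum
RHO_FLOOR = 1e-12


@dataclass(frozen=True)
class DensityGrid:
    """Normalized KDE evaluated on a regular 2D lattice of spacing ``s``."""

    spacing: float
    origin: tuple[float, float]
    rho: np.ndarray          # (nu, nv), density per node, 1/m^2
    bandwidth: float

    @property
    def n(self) -> int:
        return int(self.rho.size)

    def total_mass(self) -> float:
        """Sum rho_i s^2 — should be 1 within the normalization tolerance."""
        return float(self.rho.sum() * self.spacing**2)

    def entropy(self) -> float:
        rho = self.rho[self.rho > RHO_FLOOR]
        return float(-(rho * np.log(rho)).sum() * self.spacing**2)


@dataclass(frozen=True)
class ComplexityMeasures:
    """Planar, vertical and 3D canopy entropies of one footprint (nats)."""

    ce_xy: float
    ce_xz: float
    ce_yz: float
    ce_z: float
    ce_xyz: float

    @classmethod
    def from_planes(cls, ce_xy: float, ce_xz: float, ce_yz: float) -> "ComplexityMeasures":
        ce_z = (ce_xz + ce_yz) / 2.0
        ce_xyz = float(np.sqrt(ce_xy**2 + ce_xz**2 + ce_yz**2))
        return cls(ce_xy=ce_xy, ce_xz=ce_xz, ce_yz=ce_yz, ce_z=ce_z, ce_xyz=ce_xyz)


def footprint_clip(cloud: PointCloud, center: tuple[float, float], diameter: float = 25.0) -> PointCloud:
    """Retain points strictly inside the footprint disk.

    The boundary convention is half-open: a point exactly on the rim is
    excluded, making clipping deterministic under floating-point equality.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cx, cy = center
    r2 = (cloud.x - cx) ** 2 + (cloud.y - cy) ** 2
    mask = r2 < (diameter / 2.0) ** 2
    if not mask.any():
        raise ValueError("empty footprint")
    return PointCloud(cloud.xyz[mask], cloud.ground_elevation, cloud.normalized)


def _occupied_voxels(xyz: np.ndarray, edge: float) -> np.ndarray:
    return np.unique(np.floor(xyz / edge).astype(np.int64), axis=0)


def voxel_thin(cloud: PointCloud, target_count: int) -> PointCloud:
    """Adaptive voxel sampling to a target point count.

    One representative point (the voxel centroid) is kept per occupied
    voxel; the voxel edge is found by bisection so the retained count lands
    within ±10% of ``min(target_count, len(cloud))``. Clouds already at or
    below the target are returned unchanged.
    """
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    n = len(cloud)
    if n <= target_count:
        return cloud
    xyz = cloud.xyz
    span = float(np.ptp(xyz, axis=0).max())
    if span == 0.0:  # all points identical: single voxel
        return PointCloud(xyz.mean(axis=0, keepdims=True), cloud.ground_elevation, cloud.normalized)
    lo, hi = span * 1e-6, span * 2.0
    target = min(target_count, n)
    edge = hi
    for _ in range(60):
        edge = np.sqrt(lo * hi)  # geometric bisection: counts vary over decades
        count = len(_occupied_voxels(xyz, edge))
        if abs(count - target) <= 0.10 * target:
            break
        if count > target:
            lo = edge
        else:
            hi = edge
    keys = np.floor(xyz / edge).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    k = inverse.max() + 1
    sums = np.zeros((k, 3))
    np.add.at(sums, inverse, xyz)
    counts = np.bincount(inverse, minlength=k).astype(float)
    centroids = sums / counts[:, None]
    return PointCloud(centroids, cloud.ground_elevation, cloud.normalized)


def silverman_bandwidth(points_2d: np.ndarray) -> float:
    """Isotropic Silverman bandwidth for a 2D sample (mean of axis scales)."""
    n = len(points_2d)
    sd = points_2d.std(axis=0, ddof=1)
    sigma = float(sd.mean())
    return sigma * n ** (-1.0 / 6.0)


def density_grid(points_2d: np.ndarray, s: float = 0.10, bandwidth: float | None = None) -> DensityGrid:
    """Evaluate a normalized Gaussian KDE on an s-spaced lattice.

    The lattice covers the data bounding box padded by 4 bandwidths. The
    estimate is computed by linear histogram binning at the lattice spacing
    followed by Gaussian convolution (exact up to the s/bandwidth binning
    error, which is negligible at the 10-cm default) and renormalized so
    that sum(rho) * s^2 = 1.
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points_2d must have shape (n, 2)")
    if len(pts) < 2 or (pts == pts[0]).all():
        raise ValueError("degenerate 2D support")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts)
    bandwidth = max(float(bandwidth), s / 2.0)  # numerical floor at half a grid cell
    pad = 4.0 * bandwidth
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    nb = np.maximum(np.ceil((hi - lo) / s).astype(int) + 1, 2)
    H, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=list(nb),
        range=[(lo[0], lo[0] + nb[0] * s), (lo[1], lo[1] + nb[1] * s)],
    )
    rho = gaussian_filter(H, sigma=bandwidth / s, mode="constant", truncate=6.0)
    rho /= rho.sum() * s * s
    return DensityGrid(spacing=s, origin=(float(lo[0]), float(lo[1])), rho=rho, bandwidth=bandwidth)


def ce_2d(points_2d: np.ndarray, s: float = 0.10, bandwidth: float | None = None) -> float:
    """Grid-KDE entropy (nats) of a 2D point projection."""
    return density_grid(points_2d, s=s, bandwidth=bandwidth).entropy()


def ce_components(
    cloud: PointCloud,
    s: float = 0.10,
    target_count: int = 5000,
    bandwidth: float | None = None,
) -> ComplexityMeasures:
    """Full complexity measures of a footprint-clipped, normalized cloud.

    Applies voxel thinning, projects the thinned cloud onto the XY, XZ and
    YZ planes, computes the grid-KDE entropy of each, and assembles CE_Z
    and CE_XYZ.
    """
    thinned = voxel_thin(cloud, target_count)
    xyz = thinned.xyz
    return ComplexityMeasures.from_planes(
        ce_xy=ce_2d(xyz[:, [0, 1]], s=s, bandwidth=bandwidth),
        ce_xz=ce_2d(xyz[:, [0, 2]], s=s, bandwidth=bandwidth),
        ce_yz=ce_2d(xyz[:, [1, 2]], s=s, bandwidth=bandwidth),
    )
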