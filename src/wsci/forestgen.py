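"""Seeded synthetic forest-stand generator and auxiliary-metric emulator.

Produces ground-normalized point clouds of multi-layer stands over a circular
footprint (default 25 m diameter, the GEDI footprint scale), with controllable
tree density, height distribution, vertical layering, crown archetypes
(conifer cone vs broadleaf ellipsoid), understory and ground returns. Also
provides a parametric RH-profile training-table generator used to exercise the
model / conformal / attribution layers at scale without running the full
point-cloud pipeline for every row.

Everything is driven by ``numpy.random.default_rng(seed)``: identical
(params, seed) pairs give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .pointcloud import PointCloud

PFT_LABELS = ("EBT", "DBT", "ENT", "GSW")

#: canopy/ground separation height used by the auxiliary metrics (m)
CANOPY_THRESHOLD = 2.0


@dataclass(frozen=True)
class StandParams:
    """Parameters of one synthetic stand.

    ``height_law`` is a mapping with a ``family`` key (constant, uniform,
    normal, lognormal or weibull) plus that family's parameters; heights in
    metres. ``n_layers`` splits the stems into distinct vertical strata whose
    top heights are scaled fractions of the drawn height.
    """

    footprint_diameter: float = 25.0
    tree_density: float = 400.0          # stems per hectare
    height_law: Mapping = field(default_factory=lambda: {"family": "lognormal", "mean": 22.0, "sd": 6.0})
    n_layers: int = 1
    crown_archetype: str = "ellipsoid"   # "cone" (conifer) or "ellipsoid" (broadleaf)
    understory_fraction: float = 0.2
    ground_point_density: float = 4.0    # points per m^2
    canopy_point_density: float = 12.0   # points per m^2 of crown surface
    noise_sd: float = 0.05               # m, Gaussian jitter on coordinates
    pft_label: str = "EBT"
    site_id: str = "site-0"

    def __post_init__(self) -> None:
        if self.footprint_diameter <= 0:
            raise ValueError("footprint_diameter must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        for name in ("tree_density", "ground_point_density", "canopy_point_density", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.understory_fraction <= 1.0:
            raise ValueError("understory_fraction must be in [0, 1]")
        if self.crown_archetype not in ("cone", "ellipsoid"):
            raise ValueError("crown_archetype must be 'cone' or 'ellipsoid'")
        if self.pft_label not in PFT_LABELS:
            raise ValueError(f"pft_label must be one of {PFT_LABELS}")


def sample_heights(law: Mapping, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n tree heights (m) from a height-law spec."""
    family = law["family"]
    if family == "constant":
        return np.full(n, float(law["value"]))
    if family == "uniform":
        return rng.uniform(law["low"], law["high"], n)
    if family == "normal":
        return np.clip(rng.normal(law["mean"], law["sd"], n), 1.5, None)
    if family == "lognormal":
        # parameterized by arithmetic mean and sd
        mean, sd = float(law["mean"]), float(law["sd"])
        s2 = np.log(1.0 + (sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), n)
    if family == "weibull":
        return law["scale"] * rng.weibull(law["shape"], n)
    raise ValueError(f"unknown height-law family: {family}")


def height_law_mean(law: Mapping) -> float:
    """Expected value of a height-law spec (for property checks)."""
    family = law["family"]
    if family == "constant":
        return float(law["value"])
    if family == "uniform":
        return (law["low"] + law["high"]) / 2.0
    if family in ("normal", "lognormal"):
        return float(law["mean"])
    if family == "weibull":
        from scipy.special import gamma
        return float(law["scale"] * gamma(1.0 + 1.0 / law["shape"]))
    raise ValueError(f"unknown height-law family: {family}")


def _cone_points(rng, apex, top, base_r, n, interior_fraction=0.3):
    """Sample a conical crown: surface of the cone plus interior fill."""
    n_int = int(round(n * interior_fraction))
    n_surf = n - n_int
    crown_depth = top * 0.6  # cone from 0.4*top to apex
    z0 = top - crown_depth
    # surface: lateral area element uniform in (z, angle)
    u = np.sqrt(rng.uniform(0, 1, n_surf))      # uniform on cone surface in slant
    zs = top - u * crown_depth
    rs = base_r * u
    th = rng.uniform(0, 2 * np.pi, n_surf)
    surf = np.c_[apex[0] + rs * np.cos(th), apex[1] + rs * np.sin(th), zs]
    # interior: uniform in the solid cone
    ui = rng.uniform(0, 1, n_int) ** (1 / 3)
    zi = top - ui * crown_depth
    ri = base_r * ui * np.sqrt(rng.uniform(0, 1, n_int))
    ti = rng.uniform(0, 2 * np.pi, n_int)
    inte = np.c_[apex[0] + ri * np.cos(ti), apex[1] + ri * np.sin(ti), zi]
    return np.vstack([surf, inte])


def _ellipsoid_points(rng, center_xy, top, radius_h, n, interior_fraction=0.3):
    """Sample an ellipsoidal crown with vertical semi-axis 0.3*top."""
    semi_v = max(top * 0.3, 0.5)
    cz = top - semi_v
    n_int = int(round(n * interior_fraction))
    n_surf = n - n_int
    v = rng.normal(size=(n_surf, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    surf = v * np.array([radius_h, radius_h, semi_v])
    ri = rng.uniform(0, 1, n_int) ** (1 / 3)
    vi = rng.normal(size=(n_int, 3))
    vi /= np.linalg.norm(vi, axis=1, keepdims=True)
    inte = vi * ri[:, None] * np.array([radius_h, radius_h, semi_v])
    pts = np.vstack([surf, inte])
    pts[:, 0] += center_xy[0]
    pts[:, 1] += center_xy[1]
    pts[:, 2] += cz
    return pts


def generate_stand(params: StandParams, seed: int) -> PointCloud:
    """Generate a seeded synthetic stand over the footprint disk.

    Trees are placed uniformly over the disk, assigned to ``n_layers``
    vertical strata (layer ``l`` of ``L`` scales drawn heights by
    ``(l+1)/L``), and crowns are sampled on the archetype solid's surface
    plus a 30% interior fill. Ground returns sit on the plane z=0 with
    Gaussian vertical noise. Raises if all densities are zero.
    """
    rng = np.random.default_rng(seed)
    R = params.footprint_diameter / 2.0
    area_m2 = np.pi * R * R
    n_trees = rng.poisson(params.tree_density * area_m2 / 1e4)
    n_ground = rng.poisson(params.ground_point_density * area_m2)
    if (n_trees == 0 or params.canopy_point_density == 0) and n_ground == 0:
        raise ValueError("empty stand: all densities are zero")

    chunks = []
    if n_ground > 0:
        r = R * np.sqrt(rng.uniform(0, 1, n_ground))
        th = rng.uniform(0, 2 * np.pi, n_ground)
        gz = rng.normal(0.0, params.noise_sd, n_ground)
        chunks.append(np.c_[r * np.cos(th), r * np.sin(th), gz])

    if n_trees > 0 and params.canopy_point_density > 0:
        heights = sample_heights(params.height_law, n_trees, rng)
        # layers spread stems into distinct strata around the height law's
        # mean: multipliers 2(l+1)/(L+1) average to one, so more layers fill
        # more vertical space instead of shrinking the stand
        layer = rng.integers(0, params.n_layers, n_trees)
        heights = heights * 2.0 * (layer + 1) / (params.n_layers + 1)
        heights = np.clip(heights, 1.0, None)
        under = rng.uniform(0, 1, n_trees) < params.understory_fraction
        heights[under] = rng.uniform(1.0, 4.0, under.sum())
        r = R * np.sqrt(rng.uniform(0, 1, n_trees))
        th = rng.uniform(0, 2 * np.pi, n_trees)
        tx, ty = r * np.cos(th), r * np.sin(th)
        crown_r = np.clip(0.15 * heights * rng.lognormal(0.0, 0.15, n_trees), 0.4, 6.0)
        for i in range(n_trees):
            top = heights[i]
            if params.crown_archetype == "cone" and not under[i]:
                surf_area = np.pi * crown_r[i] * np.hypot(crown_r[i], 0.6 * top)
                n_pts = max(int(rng.poisson(params.canopy_point_density * surf_area)), 3)
                pts = _cone_points(rng, (tx[i], ty[i]), top, crown_r[i], n_pts)
            else:
                semi_v = max(top * 0.3, 0.5)
                surf_area = 4 * np.pi * (crown_r[i] * crown_r[i] * semi_v) ** (2 / 3)
                n_pts = max(int(rng.poisson(params.canopy_point_density * surf_area)), 3)
                pts = _ellipsoid_points(rng, (tx[i], ty[i]), top, crown_r[i], n_pts)
            chunks.append(pts)

    if not chunks:
        raise ValueError("empty stand: no points generated")
    xyz = np.vstack(chunks)
    xyz += rng.normal(0.0, params.noise_sd, xyz.shape)
    xyz[:, 2] = np.clip(xyz[:, 2], -3.0 * params.noise_sd, None)
    return PointCloud(xyz, ground_elevation=0.0, normalized=True)


def apply_known_offset(cloud: PointCloud, dx: float, dy: float, dz: float) -> PointCloud:
    """Rigid translation used to plant geolocation offsets in fixtures."""
    return cloud.translate(dx, dy, dz)


def derive_footprint_metrics(cloud: PointCloud, cell: float = 1.0, bin_height: float = 1.0) -> dict:
    """Emulate the footprint-level auxiliary structure metrics.

    Returns cover fraction (fraction of occupied 1-m ground cells that
    contain canopy points above 2 m), a height proxy (98th height
    percentile), a Beer–Lambert PAI-like scalar, an FHD-like Shannon entropy
    of the 1-m vertical histogram of canopy points, and an AGBD-like scalar
    proportional to height² × cover. Only the rank structure of the *-like
    metrics is meaningful.
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    if not cloud.normalized:
        raise ValueError("cloud must be ground-normalized")
    z = cloud.z
    canopy = z > CANOPY_THRESHOLD
    ix = np.floor(cloud.x / cell).astype(int)
    iy = np.floor(cloud.y / cell).astype(int)
    keys = ix * 100003 + iy
    occupied = np.unique(keys)
    canopy_cells = np.unique(keys[canopy])
    cover = len(canopy_cells) / len(occupied) if len(occupied) else 0.0
    rh98 = float(np.percentile(z, 98))
    pai_like = -np.log(max(1.0 - cover, 1e-3)) / 0.5
    if canopy.any():
        nbins = max(int(np.ceil(z[canopy].max() / bin_height)), 1)
        hist, _ = np.histogram(z[canopy], bins=nbins, range=(CANOPY_THRESHOLD, CANOPY_THRESHOLD + nbins * bin_height))
        p = hist[hist > 0] / hist.sum()
        fhd_like = float(-(p * np.log(p)).sum())
    else:
        fhd_like = 0.0
    agbd_like = 5.0 * max(rh98, 0.0) ** 2 * cover
    return {
        "cover": float(cover),
        "rh98": rh98,
        "pai_like": float(pai_like),
        "fhd_like": fhd_like,
        "agbd_like": float(agbd_like),
    }


def write_manifest(params: StandParams, seed: int, path: str | Path) -> None:
    """Write a YAML stand manifest (site_id, params, seed)."""
    record = {"site_id": params.site_id, "seed": int(seed), "params": asdict(params)}
    record["params"]["height_law"] = dict(params.height_law)
    Path(path).write_text(yaml.safe_dump(record, sort_keys=False))


def read_manifest(path: str | Path) -> tuple[StandParams, int]:
    record = yaml.safe_load(Path(path).read_text())
    return StandParams(**record["params"]), int(record["seed"])


# ---------------------------------------------------------------------------
# Parametric RH -> complexity training tables
# ---------------------------------------------------------------------------

RH_COLUMNS = [f"rh{p}" for p in range(101)]


def _rh_from_profile(h: np.ndarray, ground_frac: np.ndarray, shape_a: np.ndarray,
                     shape_b: float = 1.6) -> np.ndarray:
    """Build (n, 101) RH vectors from a two-part cumulative-energy model.

    Cumulative waveform energy is a ground spike of mass ``ground_frac`` at
    0 m plus a Beta(a, b) canopy energy profile scaled to the canopy height
    ``h``; RHp is the inverse of that cumulative curve at p%.
    """
    from scipy.stats import beta as beta_dist
    n = h.shape[0]
    p = np.linspace(0.0, 1.0, 101)[None, :]
    g = ground_frac[:, None]
    q = (p - g) / (1.0 - g)
    canopy = q > 0
    rh = np.zeros((n, 101))
    a = np.broadcast_to(shape_a[:, None], (n, 101))
    vals = beta_dist.ppf(np.clip(q, 0.0, 1.0), a, shape_b)
    rh = np.where(canopy, h[:, None] * vals, 0.0)
    return rh


def generate_training_table(
    n_rows: int = 4000,
    n_sites: int = 10,
    seed: int = 0,
    pft_label: str = "EBT",
    noise_scale: float = 1.0,
    heteroskedastic: bool = True,
) -> pd.DataFrame:
    """Generate a synthetic shot table linking RH metrics to complexity.

    Each row is one footprint: a 101-element RH profile derived from a
    latent canopy height, cover and layering, plus CE_XY / CE_Z / CE_XYZ
    targets that are smooth functions of those latents with additive noise.
    When ``heteroskedastic`` the noise scale is inversely related to the
    complexity signal, mimicking the larger relative errors observed for
    low-complexity canopies. Sites shift the height distribution slightly so
    spatial blocking is meaningful but generalization remains possible.
    """
    rng = np.random.default_rng(seed)
    site_of_row = rng.integers(0, n_sites, n_rows)
    site_height_shift = rng.normal(0.0, 2.0, n_sites)
    base_h = rng.lognormal(np.log(18.0), 0.45, n_rows)
    h = np.clip(base_h + site_height_shift[site_of_row], 3.0, 70.0)
    cover = np.clip(rng.beta(4.0, 2.0, n_rows), 0.15, 0.98)
    layering = rng.uniform(0.6, 3.0, n_rows)          # latent vertical layering
    ground_frac = np.clip(0.9 * (1.0 - cover), 0.02, 0.7)
    shape_a = layering  # more layering -> energy spread deeper into profile
    rh = _rh_from_profile(h, ground_frac, shape_a)

    # planted complexity surfaces (nats)
    ce_z_sig = 0.9 + 1.05 * np.log1p(h) + 0.45 * np.log(layering + 0.5) + 0.3 * cover
    ce_xy_sig = 2.6 + 1.4 * np.tanh(3.0 * (cover - 0.45)) + 0.35 * np.log1p(h) * 0.5
    ce_xy_sig = np.minimum(ce_xy_sig, 6.3)            # horizontal cap at footprint scale
    if heteroskedastic:
        sd_z = noise_scale * 0.65 / (0.8 + 0.45 * ce_z_sig)
        sd_xy = noise_scale * 0.75 / (0.8 + 0.45 * ce_xy_sig)
    else:
        sd_z = np.full(n_rows, 0.18 * noise_scale)
        sd_xy = np.full(n_rows, 0.22 * noise_scale)
    ce_z = ce_z_sig + rng.normal(0.0, 1.0, n_rows) * sd_z
    ce_xy = np.clip(ce_xy_sig + rng.normal(0.0, 1.0, n_rows) * sd_xy, 0.1, None)
    ce_z = np.clip(ce_z, 0.1, None)
    ce_xyz = np.sqrt(ce_xy**2 + 2.0 * ce_z**2)

    df = pd.DataFrame(rh, columns=RH_COLUMNS)
    df.insert(0, "site_id", [f"site-{s}" for s in site_of_row])
    df.insert(1, "pft_label", pft_label)
    df["ce_xy"] = ce_xy
    df["ce_z"] = ce_z
    df["ce_xyz"] = ce_xyz
    return df
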