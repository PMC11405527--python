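"""Large-footprint waveform simulation, RH metrics, geolocation matching
and shot quality filtering.

A simulated waveform is the vertical histogram of point weights, where each
point is weighted by a Gaussian footprint response
``exp(-d^2 / 2 sigma_f^2)`` in the horizontal distance ``d`` to the footprint
center, convolved with a Gaussian transmit pulse along the height axis.
Relative-height (RH) metrics are the heights at which cumulative waveform
energy, integrated from the bottom, reaches each percentile of the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .pointcloud import PointCloud

#: nominal 25-m footprint treated as +-2 sigma of the Gaussian response
DEFAULT_FOOTPRINT_SIGMA = 6.25
DEFAULT_PULSE_SIGMA = 2.35
DEFAULT_BIN_HEIGHT = 0.15

#: PFT classes with tree cover accepted by the quality filter
TREED_PFT_CLASSES = frozenset({1, 2, 3, 4, 5, 6, 11})


@dataclass(frozen=True)
class Waveform:
    """One footprint waveform: ascending height-bin centers and amplitudes."""

    heights: np.ndarray       # bin centers, m (absolute datum)
    amplitude: np.ndarray     # energy per bin, arbitrary units
    bin_height: float
    ground_elevation: float = 0.0

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        a = np.asarray(self.amplitude, dtype=float)
        if h.shape != a.shape or h.ndim != 1:
            raise ValueError("heights and amplitude must be 1D of equal length")
        if (a < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if a.sum() <= 0:
            raise ValueError("waveform has no energy")
        if (np.diff(h) <= 0).any():
            raise ValueError("heights must be strictly ascending")
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "amplitude", a)

    @property
    def total_energy(self) -> float:
        return float(self.amplitude.sum())


@dataclass(frozen=True)
class ObservedShot:
    """An observed waveform with its nominal footprint center."""

    center: tuple[float, float]
    waveform: Waveform
    shot_id: str = ""


@dataclass(frozen=True)
class OffsetGrid:
    """Search grid for geolocation offsets (m)."""

    dx: np.ndarray = field(default_factory=lambda: np.arange(-20.0, 20.0 + 1e-9, 1.0))
    dy: np.ndarray = field(default_factory=lambda: np.arange(-20.0, 20.0 + 1e-9, 1.0))
    dz: np.ndarray = field(default_factory=lambda: np.arange(-5.0, 5.0 + 1e-9, 0.25))

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size == 0:
                raise ValueError(f"empty search grid along {name}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class OffsetResult:
    dx: float
    dy: float
    dz: float
    mean_r: float
    n_shots: int
    retained: bool = False


@dataclass(frozen=True)
class ShotQualityRecord:
    """Per-shot quality attributes used by the high-fidelity filter."""

    algorithm_run_flag: int
    degrade_flag: int
    water_persistence: float     # %
    urban_proportion: float      # %
    rx_maxamp: float
    sd_corrected: float
    sensitivity: float           # fraction in [0, 1]
    pft_class: int
    in_tropics: bool


def simulate_waveform(
    cloud: PointCloud,
    center: tuple[float, float],
    footprint_sigma: float = DEFAULT_FOOTPRINT_SIGMA,
    pulse_sigma: float = DEFAULT_PULSE_SIGMA,
    bin_height: float = DEFAULT_BIN_HEIGHT,
) -> Waveform:
    """Simulate the large-footprint waveform seen from ``center``.

    Total waveform energy equals the total Gaussian footprint weight of the
    cloud; raises when the cloud carries essentially no weight (footprint
    far from the points).
    """
    if len(cloud) == 0:
        raise ValueError("empty cloud")
    cx, cy = center
    d2 = (cloud.x - cx) ** 2 + (cloud.y - cy) ** 2
    w = np.exp(-d2 / (2.0 * footprint_sigma**2))
    total = w.sum()
    if total < 1e-12:
        raise ValueError("no energy in footprint")
    # pulse support truncated just inside 3 sigma so RH100 stays within
    # 3 pulse widths of the highest return even after binning; the ~0.5%
    # tail mass is restored by renormalization
    pad = 2.8 * pulse_sigma
    lo = cloud.z.min() - pad
    hi = cloud.z.max() + pad
    nb = int(np.ceil((hi - lo) / bin_height)) + 1
    hist, edges = np.histogram(cloud.z, bins=nb, range=(lo, lo + nb * bin_height), weights=w)
    amp = gaussian_filter1d(hist, sigma=pulse_sigma / bin_height, mode="constant", truncate=2.8)
    amp *= total / amp.sum()  # enforce exact energy conservation
    centers = edges[:-1] + bin_height / 2.0
    return Waveform(heights=centers, amplitude=amp, bin_height=bin_height,
                    ground_elevation=cloud.ground_elevation)


def rh_profile(wf: Waveform) -> np.ndarray:
    """101 relative-height percentiles RH0..RH100 (m above ground).

    RHp is the smallest bin height at which cumulative energy, integrated
    from the waveform bottom upward, reaches >= p% of the total, minus the
    ground elevation. RH0 is the lowest bin holding any energy.
    """
    cum = np.cumsum(wf.amplitude)
    total = cum[-1]
    targets = np.arange(101) / 100.0 * total
    idx = np.searchsorted(cum, targets, side="left")
    first = int(np.argmax(wf.amplitude > 0))
    idx = np.clip(np.maximum(idx, first), 0, len(cum) - 1)
    return wf.heights[idx] - wf.ground_elevation


def _correlate(observed: Waveform, simulated: Waveform, dz: float) -> float:
    """Pearson correlation of amplitudes aligned by absolute height.

    The candidate (dx, dy, dz) is interpreted as the displacement of the
    cloud relative to the nominal geolocation, so the simulated waveform is
    shifted *down* by ``dz`` before resampling onto the observed height
    grid; non-overlapping bins are zero-padded.
    """
    sim = np.interp(observed.heights, simulated.heights - dz, simulated.amplitude,
                    left=0.0, right=0.0)
    obs = observed.amplitude
    if sim.std() == 0 or obs.std() == 0:
        return 0.0
    return float(np.corrcoef(obs, sim)[0, 1])


def match_geolocation(
    observed: list[ObservedShot],
    cloud: PointCloud,
    search: OffsetGrid | None = None,
    footprint_sigma: float = DEFAULT_FOOTPRINT_SIGMA,
    pulse_sigma: float = DEFAULT_PULSE_SIGMA,
    bin_height: float = DEFAULT_BIN_HEIGHT,
) -> OffsetResult:
    """Recover the offset maximizing mean waveform correlation across shots.

    For each candidate (dx, dy) the waveform is re-simulated at the shifted
    centers; each candidate dz shifts the simulated heights before
    correlation. Ties are broken by smallest offset norm, then
    lexicographically. The result is passed through the crossover filter to
    set ``retained``.
    """
    if not observed:
        raise ValueError("no observed shots")
    search = search or OffsetGrid()
    best = None
    for dx in search.dx:
        for dy in search.dy:
            sims = []
            for shot in observed:
                cx, cy = shot.center
                try:
                    sims.append(simulate_waveform(
                        cloud, (cx + dx, cy + dy), footprint_sigma, pulse_sigma, bin_height))
                except ValueError:
                    sims.append(None)
            for dz in search.dz:
                rs = [
                    _correlate(shot.waveform, sim, dz) if sim is not None else -1.0
                    for shot, sim in zip(observed, sims)
                ]
                mean_r = float(np.mean(rs))
                norm = dx * dx + dy * dy + dz * dz
                key = (-mean_r, norm, dx, dy, dz)
                if best is None or key < best[0]:
                    best = (key, OffsetResult(float(dx), float(dy), float(dz),
                                              mean_r, len(observed)))
    result = best[1]
    return OffsetResult(result.dx, result.dy, result.dz, result.mean_r,
                        result.n_shots, retained=filter_crossovers(result))


def filter_crossovers(result: OffsetResult, min_shots: int = 10, min_r: float = 0.75) -> bool:
    """Crossover retention rule: >= 10 shots and mean Pearson r >= 0.75."""
    return result.n_shots >= min_shots and result.mean_r >= min_r


def quality_filter(rec: ShotQualityRecord) -> bool:
    """High-fidelity shot filter.

    Passes iff the L2B algorithms ran, geolocation is not degraded, the
    surface is non-urban and non-water, peak amplitude exceeds 8x the
    corrected noise standard deviation, sensitivity clears 0.95 (0.98 in
    the tropics), and the PFT class has tree cover. Any missing field is an
    error, never a silent pass.
    """
    values = [rec.algorithm_run_flag, rec.degrade_flag, rec.water_persistence,
              rec.urban_proportion, rec.rx_maxamp, rec.sd_corrected,
              rec.sensitivity, rec.pft_class, rec.in_tropics]
    for v in values:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError("missing quality field")
    if not 0.0 <= rec.sensitivity <= 1.0:
        raise ValueError("sensitivity must be in [0, 1]")
    sens_floor = 0.98 if rec.in_tropics else 0.95
    return (
        rec.algorithm_run_flag == 1
        and rec.degrade_flag == 0
        and rec.water_persistence < 10
        and rec.urban_proportion < 50
        and rec.rx_maxamp > 8.0 * rec.sd_corrected
        and rec.sensitivity > sens_floor
        and rec.pft_class in TREED_PFT_CLASSES
    )


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

def write_waveforms(shots: list[ObservedShot], path: str | Path) -> None:
    """Long-format table (shot_id, height, amplitude)."""
    frames = []
    for i, shot in enumerate(shots):
        wf = shot.waveform
        frames.append(pd.DataFrame({
            "shot_id": shot.shot_id or f"shot-{i}",
            "height": wf.heights, "amplitude": wf.amplitude,
        }))
    pd.concat(frames).to_csv(path, index=False)


def read_waveforms(path: str | Path, bin_height: float = DEFAULT_BIN_HEIGHT,
                   ground_elevation: float = 0.0) -> dict[str, Waveform]:
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("shot_id", sort=False):
        grp = grp.sort_values("height")
        out[str(sid)] = Waveform(grp["height"].to_numpy(), grp["amplitude"].to_numpy(),
                                 bin_height=bin_height, ground_elevation=ground_elevation)
    return out


def write_rh_table(profiles: dict[str, np.ndarray], path: str | Path) -> None:
    """Wide table (shot_id, rh0..rh100)."""
    df = pd.DataFrame.from_dict(profiles, orient="index",
                                columns=[f"rh{p}" for p in range(101)])
    df.index.name = "shot_id"
    df.to_csv(path)
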