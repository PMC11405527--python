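"""Shapley feature attribution and canopy-strata aggregation.

Per-prediction feature contributions come from TreeSHAP on the fitted
boosted ensemble: contributions plus a base value sum exactly to each
prediction (local accuracy). Mean absolute contributions are accumulated
into three waveform strata — lower (RH0..RH33), middle (RH34..RH66) and
upper (RH67..RH100) — and composited per grid cell as an RGB image
(R=lower, G=middle, B=upper).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost

from .model import RH_COLUMNS, ModelBundle

#: half-open strata over RH percentile indices: lower <= 33 < middle <= 66 < upper
LOWER_SLICE = slice(0, 34)
MIDDLE_SLICE = slice(34, 67)
UPPER_SLICE = slice(67, 101)


@dataclass(frozen=True)
class StrataImportance:
    """Fractions of accumulated absolute importance per waveform stratum."""

    lower: float
    middle: float
    upper: float

    def __post_init__(self) -> None:
        total = self.lower + self.middle + self.upper
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("strata fractions must sum to 1")
        if min(self.lower, self.middle, self.upper) < 0:
            raise ValueError("strata fractions must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.lower, self.middle, self.upper])


def shap_contributions(bundle: ModelBundle, rh: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """TreeSHAP contributions for each RH feature plus the base value.

    Returns ``(contributions, base)`` with shapes (n, 101) and (n,);
    ``base + contributions.sum(axis=1)`` equals the model prediction
    (local accuracy).
    """
    if isinstance(rh, pd.DataFrame):
        rh = rh[RH_COLUMNS].to_numpy()
    rh = np.atleast_2d(np.asarray(rh, dtype=float))
    try:
        booster = bundle.model.get_booster()
    except Exception as exc:  # unfitted sklearn wrapper
        raise ValueError("bundle model is not fitted") from exc
    contrib = booster.predict(xgboost.DMatrix(rh), pred_contribs=True).astype(float)
    return contrib[:, :-1], contrib[:, -1]


def strata_importance(contributions: np.ndarray) -> StrataImportance:
    """Accumulate mean absolute contributions into the three strata.

    RH33 is inclusive in the lower stratum and RH66 in the middle one.
    Raises when every contribution is zero (no importance mass).
    """
    contributions = np.atleast_2d(np.asarray(contributions, dtype=float))
    if contributions.shape[1] != len(RH_COLUMNS):
        raise ValueError(f"expected {len(RH_COLUMNS)} feature contributions")
    mean_abs = np.abs(contributions).mean(axis=0)
    total = mean_abs.sum()
    if total <= 0:
        raise ValueError("no importance mass: all contributions are zero")
    sums = np.array([mean_abs[LOWER_SLICE].sum(), mean_abs[MIDDLE_SLICE].sum(),
                     mean_abs[UPPER_SLICE].sum()]) / total
    return StrataImportance(lower=float(sums[0]), middle=float(sums[1]), upper=float(sums[2]))


def top_decile_importance(contributions: np.ndarray, start_percentile: int = 91) -> float:
    """Fraction of importance in the top RH percentiles (default RH91..RH100)."""
    contributions = np.atleast_2d(np.asarray(contributions, dtype=float))
    mean_abs = np.abs(contributions).mean(axis=0)
    return float(mean_abs[start_percentile:].sum() / mean_abs.sum())


def strata_composite(
    shots: pd.DataFrame,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    rescale: bool = True,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Grid-cell RGB composite of strata fractions.

    ``shots`` needs columns (x, y, lower, middle, upper). Returns a
    (ny, nx, 3) array — R=lower, G=middle, B=upper — of per-cell means,
    min–max rescaled per band over the mapped extent when ``rescale``;
    empty cells hold NaN. Also returns the grid origin (min x, min y).
    """
    required = {"x", "y", "lower", "middle", "upper"}
    if not required <= set(shots.columns):
        raise ValueError(f"shots table needs columns {sorted(required)}")
    if origin is None:
        origin = (float(shots["x"].min()), float(shots["y"].min()))
    ix = np.floor((shots["x"].to_numpy() - origin[0]) / cell_size).astype(int)
    iy = np.floor((shots["y"].to_numpy() - origin[1]) / cell_size).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    img = np.full((ny, nx, 3), np.nan)
    df = shots[["lower", "middle", "upper"]].copy()
    df["ix"], df["iy"] = ix, iy
    means = df.groupby(["iy", "ix"]).mean()
    for (r, c), row in means.iterrows():
        img[r, c] = row[["lower", "middle", "upper"]].to_numpy()
    if rescale:
        for b in range(3):
            band = img[..., b]
            lo, hi = np.nanmin(band), np.nanmax(band)
            if hi > lo:
                img[..., b] = (band - lo) / (hi - lo)
            else:
                img[..., b] = np.where(np.isnan(band), np.nan, 0.5)
    return img, origin


def write_ascii_grid(band: np.ndarray, origin: tuple[float, float],
                     cell_size: float, path: str | Path, nodata: float = -9999.0) -> None:
    """Write one band as an ESRI ASCII grid (text raster format)."""
    ny, nx = band.shape
    header = (f"ncols {nx}\nnrows {ny}\nxllcorner {origin[0]}\nyllcorner {origin[1]}\n"
              f"cellsize {cell_size}\nNODATA_value {nodata}\n")
    body = np.where(np.isnan(band), nodata, band)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body[::-1], fmt="%.6g")  # rows north-to-south
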