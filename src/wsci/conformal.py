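"""Mondrian split-conformal prediction intervals for complexity estimates.

Split-conformal intervals use a calibration set unseen during training: the
(1 - alpha) order-statistic of absolute residuals becomes the interval
half-width. The Mondrian variant computes that quantile separately within
bins of the predicted value, so heteroskedastic residuals — larger relative
errors at low complexity — get locally calibrated widths while retaining
the per-bin marginal coverage guarantee under exchangeability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import RH_COLUMNS, ModelBundle, predict

MIN_BIN_COUNT = 20


@dataclass(frozen=True)
class ConformalCalibration:
    """Per-bin nonconformity quantiles keyed by predicted value."""

    alpha: float
    bin_edges: np.ndarray      # len n_bins + 1, ascending
    q: np.ndarray              # len n_bins, half-widths (nats)
    counts: np.ndarray         # len n_bins, calibration rows per bin

    @property
    def n_bins(self) -> int:
        return len(self.q)

    def bin_of(self, center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin index per prediction plus an out-of-range flag (nearest bin used)."""
        idx = np.searchsorted(self.bin_edges, center, side="right") - 1
        flagged = (idx < 0) | (idx >= self.n_bins)
        return np.clip(idx, 0, self.n_bins - 1), flagged


def _conformal_quantile(abs_residuals: np.ndarray, alpha: float) -> float:
    """The ceil((n+1)(1-alpha))-th smallest absolute residual (clamped to max)."""
    n = len(abs_residuals)
    k = math.ceil((n + 1) * (1.0 - alpha))
    k = min(max(k, 1), n)
    return float(np.sort(abs_residuals)[k - 1])


def calibrate_mondrian(
    bundle: ModelBundle,
    calibration: pd.DataFrame,
    alpha: float = 0.05,
    n_bins: int = 10,
) -> ConformalCalibration:
    """Calibrate Mondrian intervals on held-out-site rows.

    Bins are equal-count quantile bins of the predicted value; bins with
    fewer than 20 rows are merged with a neighbor. Requires at least 40
    calibration rows in total.
    """
    if len(calibration) < 2 * MIN_BIN_COUNT:
        raise ValueError(f"need at least {2 * MIN_BIN_COUNT} calibration rows")
    yhat = predict(bundle, calibration)
    resid = np.abs(calibration[bundle.target].to_numpy() - yhat)
    n_bins = max(min(n_bins, len(calibration) // MIN_BIN_COUNT), 1)
    quantiles = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.unique(np.quantile(yhat, quantiles))
    if len(edges) < 2:  # constant predictions: single bin
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    idx = np.clip(np.searchsorted(edges, yhat, side="right") - 1, 0, len(edges) - 2)
    # merge under-filled bins with their left neighbor (right for the first)
    while len(edges) > 2:
        counts = np.bincount(idx, minlength=len(edges) - 1)
        small = np.flatnonzero(counts < MIN_BIN_COUNT)
        if small.size == 0:
            break
        b = int(small[0])
        edges = np.delete(edges, b if b > 0 else 1)
        idx = np.clip(np.searchsorted(edges, yhat, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    q = np.array([
        _conformal_quantile(resid[idx == b], alpha) if counts[b] > 0 else 0.0
        for b in range(len(edges) - 1)
    ])
    return ConformalCalibration(alpha=alpha, bin_edges=edges, q=q, counts=counts)


def predict_interval(
    cal: ConformalCalibration,
    bundle: ModelBundle,
    rh: pd.DataFrame | np.ndarray,
) -> pd.DataFrame:
    """Point predictions with conformal intervals.

    Returns columns (center, lower, upper, relative_size, out_of_range).
    Predictions outside the calibrated range borrow the nearest bin's
    quantile and are flagged. ``relative_size`` = (upper - lower) / center,
    reported only for positive centers.
    """
    center = predict(bundle, rh)
    idx, flagged = cal.bin_of(center)
    half = cal.q[idx]
    lower, upper = center - half, center + half
    rel = np.where(center > 0, (upper - lower) / center, np.nan)
    return pd.DataFrame({
        "center": center, "lower": lower, "upper": upper,
        "relative_size": rel, "out_of_range": flagged,
    })


def empirical_coverage(
    cal: ConformalCalibration,
    bundle: ModelBundle,
    holdout: pd.DataFrame,
) -> float:
    """Fraction of holdout targets inside their prediction intervals."""
    if len(holdout) == 0:
        raise ValueError("empty holdout")
    intervals = predict_interval(cal, bundle, holdout)
    y = holdout[bundle.target].to_numpy()
    inside = (y >= intervals["lower"].to_numpy()) & (y <= intervals["upper"].to_numpy())
    return float(inside.mean())
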