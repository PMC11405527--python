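"""Downstream analyses: grid aggregation, variance partition, scaling fits.

Complexity–height scaling follows a power law: WSCI linear in ln(RH98), so
the slope of an OLS fit of WSCI on ln canopy height is the scaling
exponent. Per-cell fits flag cells whose slope is not significant at the
5% level (two-tailed t-test). Biome-wide fits use iteratively reweighted
least squares with Tukey's biweight to damp outliers. The PCA/PCR variance
partition quantifies how much complexity information is already carried by
the standard structure metrics (cover, height, PAI, FHD, AGBD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

DEFAULT_METRICS = ("wsci", "cover", "rh98", "pai", "fhd", "agbd")

#: shots at or below this RH98 (m) are treated as non-forest and excluded
MIN_CANOPY_HEIGHT = 5.0


@dataclass(frozen=True)
class ScalingFit:
    """Power-law scaling of complexity with canopy height in one cell."""

    cell_id: tuple[int, int] | str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_shots: int
    excluded: bool
    reason: str = ""


def grid_aggregate(
    shots: pd.DataFrame,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    min_height: float = MIN_CANOPY_HEIGHT,
) -> pd.DataFrame:
    """Per-cell means of WSCI and relative interval size.

    Excludes non-forest shots (RH98 <= ``min_height``); returns one row per
    occupied cell with columns (ix, iy, mean_wsci, mean_pi_relative, n).
    Cell counts sum to the number of qualifying shots.
    """
    required = {"x", "y", "wsci", "pi_relative", "rh98"}
    if not required <= set(shots.columns):
        raise ValueError(f"shots table needs columns {sorted(required)}")
    keep = shots[shots["rh98"] > min_height]
    if keep.empty:
        import warnings
        warnings.warn("no qualifying shots after the height filter")
        return pd.DataFrame(columns=["ix", "iy", "mean_wsci", "mean_pi_relative", "n"])
    if origin is None:
        origin = (float(keep["x"].min()), float(keep["y"].min()))
    ix = np.floor((keep["x"] - origin[0]) / cell_size).astype(int)
    iy = np.floor((keep["y"] - origin[1]) / cell_size).astype(int)
    grouped = keep.assign(ix=ix, iy=iy).groupby(["ix", "iy"])
    out = grouped.agg(mean_wsci=("wsci", "mean"),
                      mean_pi_relative=("pi_relative", "mean"),
                      n=("wsci", "size")).reset_index()
    return out


def pca_pcr(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    n_components: int = 3,
    target: str = "wsci",
) -> dict:
    """Min–max standardized PCA plus principal-components regression.

    Returns loadings, explained-variance shares, and the PCR R² of the
    target on the first ``n_components`` components, for two
    decompositions: including the target among the PCA inputs and
    excluding it. The difference between the two PCR R² values bounds the
    structural information unique to the target.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 complete rows")
    X = table.loc[:, list(metrics)].dropna()
    if len(X) < 3:
        raise ValueError("need at least 3 complete rows")
    rng01 = X.max() - X.min()
    if (rng01 == 0).any():
        bad = rng01.index[rng01 == 0].tolist()
        raise ValueError(f"degenerate standardization: constant columns {bad}")
    Z = (X - X.min()) / rng01
    y = Z[target].to_numpy()

    def _decompose(cols):
        k = min(n_components, len(cols))
        pca = PCA()
        scores = pca.fit_transform(Z[list(cols)].to_numpy())
        reg = LinearRegression().fit(scores[:, :k], y)
        r2 = float(reg.score(scores[:, :k], y))
        return {
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "loadings": pd.DataFrame(pca.components_, columns=list(cols)),
            "pcr_r2": r2,
        }

    with_target = _decompose(metrics)
    without = _decompose(tuple(m for m in metrics if m != target))
    return {"with_target": with_target, "without_target": without,
            "unique_information": with_target["pcr_r2"] - without["pcr_r2"]}


def _fit_cell(cell_id, wsci: np.ndarray, rh98: np.ndarray, fit_floor: int,
              alpha: float = 0.05) -> ScalingFit:
    n = len(wsci)
    if n < fit_floor:
        return ScalingFit(cell_id, np.nan, np.nan, np.nan, np.nan, n, True, "below fit floor")
    x = np.log(rh98)
    if np.ptp(x) == 0:
        return ScalingFit(cell_id, np.nan, np.nan, np.nan, np.nan, n, True, "zero height variance")
    res = stats.linregress(x, wsci)
    excluded = bool(res.pvalue > alpha)
    return ScalingFit(cell_id, float(res.slope), float(res.intercept),
                      float(res.rvalue**2), float(res.pvalue), n, excluded,
                      "slope not significant" if excluded else "")


def pixel_scaling_fit(shots: pd.DataFrame, fit_floor: int = 30) -> ScalingFit:
    """OLS of WSCI on ln(RH98) for the shots of one cell."""
    cell_id = shots["cell_id"].iloc[0] if "cell_id" in shots.columns else "cell"
    return _fit_cell(cell_id, shots["wsci"].to_numpy(), shots["rh98"].to_numpy(), fit_floor)


def scaling_fits(
    shots: pd.DataFrame,
    cell_size: float,
    origin: tuple[float, float] | None = None,
    fit_floor: int = 30,
) -> list[ScalingFit]:
    """Per-cell scaling fits over a projected grid."""
    if origin is None:
        origin = (float(shots["x"].min()), float(shots["y"].min()))
    ix = np.floor((shots["x"] - origin[0]) / cell_size).astype(int)
    iy = np.floor((shots["y"] - origin[1]) / cell_size).astype(int)
    out = []
    for (cx, cy), grp in shots.groupby([ix, iy]):
        out.append(_fit_cell((int(cx), int(cy)), grp["wsci"].to_numpy(),
                             grp["rh98"].to_numpy(), fit_floor))
    return out


def robust_biome_scaling(
    shots: pd.DataFrame,
    biome_col: str = "biome",
    tuning_constant: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-6,
    min_shots: int = 100,
) -> pd.DataFrame:
    """Tukey-biweight IRLS scaling slope per biome.

    Fits WSCI ~ ln(RH98) per biome label with iteratively reweighted least
    squares under Tukey's redescending biweight (default tuning constant
    4.685). Raises on non-convergence, reporting the iteration count.
    """
    rows = []
    for biome, grp in shots.groupby(biome_col):
        if len(grp) < min_shots:
            raise ValueError(f"biome {biome}: need >= {min_shots} shots, got {len(grp)}")
        x = sm.add_constant(np.log(grp["rh98"].to_numpy()))
        y = grp["wsci"].to_numpy()
        model = sm.RLM(y, x, M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
        fit = model.fit(maxiter=max_iter, tol=tol)
        history = fit.fit_history["params"]
        n_iter = len(history)
        if n_iter >= max_iter:
            step = float(np.max(np.abs(history[-1] - history[-2]))) if n_iter >= 2 else np.inf
            if step > tol:
                raise RuntimeError(
                    f"biome {biome}: IRLS did not converge in {n_iter} iterations "
                    f"(last parameter step {step:.2e} > tol {tol:.0e})")
        rows.append({"biome": biome, "slope": float(fit.params[1]),
                     "intercept": float(fit.params[0]), "n_shots": len(grp)})
    return pd.DataFrame(rows)
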