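"""Per-PFT gradient-boosted models of canopy complexity from RH metrics.

Models predict CE_XYZ (the WSCI), CE_XY and CE_Z from the 101 RH
percentiles. Hyperparameters are selected by a site-blocked (spatial)
5-fold grid search minimizing validation RMSE among configurations whose
train/validation generalization gap in both RMSE and R² stays below 5% —
the guard against geographically over-fit models.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost
from sklearn.metrics import mean_squared_error, r2_score
from xgboost import XGBRegressor

RH_COLUMNS = [f"rh{p}" for p in range(101)]
TARGETS = ("ce_xyz", "ce_xy", "ce_z")

#: target name -> reported variable name
TARGET_ALIASES = {"ce_xyz": "WSCI", "ce_xy": "CE_XY", "ce_z": "CE_Z"}


@dataclass(frozen=True)
class Hyperparams:
    """XGBoost hyperparameters searched by the grid."""

    n_estimators: int = 100
    subsample_fraction: float = 0.8
    feature_fraction: float = 0.8
    max_depth: int = 3
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1 and 0 < self.feature_fraction <= 1):
            raise ValueError("fractions must be in (0, 1]")
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def make_regressor(self, seed: int) -> XGBRegressor:
        return XGBRegressor(
            n_estimators=self.n_estimators,
            subsample=self.subsample_fraction,
            colsample_bytree=self.feature_fraction,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )


def default_grid() -> list[Hyperparams]:
    """Small desk-scale grid; spans under- to over-fitting configurations."""
    combos = itertools.product(
        (30, 100, 200),        # n_estimators
        (0.7, 0.9),            # subsample
        (0.7, 0.9),            # colsample
        (2, 3, 6),             # depth
        (0.03, 0.1),           # learning rate
    )
    return [Hyperparams(n, s, f, d, lr) for n, s, f, d, lr in combos]


@dataclass
class ModelBundle:
    """A fitted complexity model for one (PFT, target) pair."""

    pft_label: str
    target: str
    model: XGBRegressor
    hyperparams: Hyperparams
    metrics: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def target_name(self) -> str:
        return TARGET_ALIASES.get(self.target, self.target)

    def save(self, stem: str | Path) -> None:
        """Serialize model (xgboost JSON) plus a sidecar metadata file."""
        stem = Path(stem)
        self.model.get_booster().save_model(str(stem.with_suffix(".model.json")))
        meta = {
            "pft_label": self.pft_label,
            "target": self.target,
            "hyperparams": asdict(self.hyperparams),
            "metrics": self.metrics,
            "seed": self.seed,
        }
        stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "ModelBundle":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".meta.json").read_text())
        hp = Hyperparams(**meta["hyperparams"])
        model = hp.make_regressor(meta["seed"])
        booster = xgboost.Booster()
        booster.load_model(str(stem.with_suffix(".model.json")))
        model._Booster = booster  # attach at Booster level
        return cls(meta["pft_label"], meta["target"], model, hp,
                   meta["metrics"], meta["seed"])


def _rmse(y, yhat) -> float:
    return float(np.sqrt(mean_squared_error(y, yhat)))


def validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in RH_COLUMNS + ["site_id"] if c not in table.columns]
    if missing:
        raise ValueError(f"training table missing columns: {missing[:5]}...")
    if table[RH_COLUMNS].isna().any().any():
        raise ValueError("training table has missing RH values")


def spatial_folds(table: pd.DataFrame, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each row to one of k folds, blocking by site.

    Sites (not rows) are partitioned: every row of a site shares its fold.
    Assignment is greedy by descending site size onto the currently
    smallest fold, which balances fold row counts; a seeded shuffle breaks
    size ties deterministically.
    """
    sites = table["site_id"].to_numpy()
    unique_sites, counts = np.unique(sites, return_counts=True)
    if len(unique_sites) < k:
        raise ValueError(f"need at least {k} distinct sites, got {len(unique_sites)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique_sites))
    order = order[np.argsort(-counts[order], kind="stable")]
    fold_of_site = {}
    fold_sizes = np.zeros(k, dtype=int)
    for idx in order:
        f = int(np.argmin(fold_sizes))
        fold_of_site[unique_sites[idx]] = f
        fold_sizes[f] += counts[idx]
    return np.array([fold_of_site[s] for s in sites])


def train_test_site_split(table: pd.DataFrame, test_fraction: float = 0.2,
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80/20 split by site; the 20% is reserved for conformal calibration."""
    sites = np.unique(table["site_id"])
    rng = np.random.default_rng(seed)
    rng.shuffle(sites)
    n_test = max(int(round(test_fraction * len(sites))), 1)
    test_sites = set(sites[:n_test])
    mask = table["site_id"].isin(test_sites)
    return table[~mask].copy(), table[mask].copy()


def _cv_metrics(table: pd.DataFrame, target: str, hp: Hyperparams,
                folds: np.ndarray, seed: int) -> dict:
    """Cross-validated mean train/validation RMSE and R² for one config."""
    X = table[RH_COLUMNS].to_numpy()
    y = table[target].to_numpy()
    rows = {"rmse_train": [], "rmse_val": [], "r2_train": [], "r2_val": []}
    for f in np.unique(folds):
        tr, va = folds != f, folds == f
        model = hp.make_regressor(seed)
        model.fit(X[tr], y[tr])
        yhat_tr, yhat_va = model.predict(X[tr]), model.predict(X[va])
        rows["rmse_train"].append(_rmse(y[tr], yhat_tr))
        rows["rmse_val"].append(_rmse(y[va], yhat_va))
        rows["r2_train"].append(r2_score(y[tr], yhat_tr))
        rows["r2_val"].append(r2_score(y[va], yhat_va))
    return {k: float(np.mean(v)) for k, v in rows.items()}


def generalization_gaps(metrics: dict, relative: bool = True) -> tuple[float, float]:
    """Train/validation gaps (%) in RMSE and R².

    Relative form (default): |train - val| / |train| * 100. Absolute form
    returns |train - val| * 100 (metric units scaled to percent points).
    """
    def gap(a, b):
        d = abs(a - b)
        return 100.0 * d / abs(a) if relative else 100.0 * d
    return gap(metrics["rmse_train"], metrics["rmse_val"]), gap(metrics["r2_train"], metrics["r2_val"])


def grid_search_select(
    table: pd.DataFrame,
    grid: list[Hyperparams] | None = None,
    target: str = "ce_xyz",
    k: int = 5,
    seed: int = 0,
    max_gap_pct: float = 5.0,
    relative_gap: bool = True,
) -> tuple[Hyperparams, dict]:
    """Site-blocked grid search under the generalization-gap constraint.

    Among grid points whose cross-validated train/validation gaps in RMSE
    and R² are both below ``max_gap_pct``, returns the one minimizing mean
    validation RMSE (ties: fewer estimators, then smaller depth) together
    with its CV metrics. Raises when no configuration is admissible.
    """
    validate_table(table)
    grid = grid or default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = spatial_folds(table, k=k, seed=seed)
    best = None
    for hp in grid:
        m = _cv_metrics(table, target, hp, folds, seed)
        g_rmse, g_r2 = generalization_gaps(m, relative=relative_gap)
        m["gap_rmse_pct"], m["gap_r2_pct"] = g_rmse, g_r2
        if g_rmse >= max_gap_pct or g_r2 >= max_gap_pct:
            continue
        key = (m["rmse_val"], hp.n_estimators, hp.max_depth)
        if best is None or key < best[0]:
            best = (key, hp, m)
    if best is None:
        raise ValueError("no admissible configuration: every grid point "
                         f"exceeds the {max_gap_pct}% train/validation gap")
    return best[1], best[2]


def fit_models(
    table: pd.DataFrame,
    selected: Hyperparams,
    seed: int = 0,
    targets: tuple[str, ...] = TARGETS,
    min_rows: int = 100,
    k: int = 5,
) -> dict[tuple[str, str], ModelBundle]:
    """Fit one bundle per (PFT, target) with the selected hyperparameters.

    Records the cross-validated train/validation metrics alongside the
    final fit on all rows. PFT groups below ``min_rows`` are refused with a
    warning (lower the floor explicitly to override).
    """
    validate_table(table)
    bundles: dict[tuple[str, str], ModelBundle] = {}
    for pft, group in table.groupby("pft_label"):
        if len(group) < min_rows:
            warnings.warn(f"PFT {pft}: only {len(group)} rows (< {min_rows}); refusing to fit")
            continue
        folds = spatial_folds(group, k=min(k, group["site_id"].nunique()), seed=seed)
        X = group[RH_COLUMNS].to_numpy()
        for target in targets:
            y = group[target].to_numpy()
            cv = _cv_metrics(group, target, selected, folds, seed)
            model = selected.make_regressor(seed)
            model.fit(X, y)
            yhat = model.predict(X)
            cv["rmse_fit"], cv["r2_fit"] = _rmse(y, yhat), float(r2_score(y, yhat))
            bundles[(str(pft), target)] = ModelBundle(
                pft_label=str(pft), target=target, model=model,
                hyperparams=selected, metrics=cv, seed=seed)
    return bundles


def predict(bundle: ModelBundle, rh: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Predict complexity (nats) for RH vectors of length 101."""
    if isinstance(rh, pd.DataFrame):
        rh = rh[RH_COLUMNS].to_numpy()
    rh = np.atleast_2d(np.asarray(rh, dtype=float))
    if rh.shape[1] != len(RH_COLUMNS):
        raise ValueError(f"RH vector must have length {len(RH_COLUMNS)}")
    return bundle.model.predict(rh)
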