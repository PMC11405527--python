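"""Train a complexity model with spatial cross-validation and conformal
uncertainty.

Selects hyperparameters by a site-blocked grid search under the 5%
train/validation gap constraint, fits the model, calibrates Mondrian 95%
intervals on held-out sites, and checks empirical coverage on fresh data.
"""

from wsci import (
    calibrate_mondrian, empirical_coverage, fit_models, grid_search_select,
    predict_interval, train_test_site_split,
)
from wsci.forestgen import generate_training_table
from wsci.model import Hyperparams

table = generate_training_table(n_rows=2000, n_sites=10, seed=42)
train_df, cal_df = train_test_site_split(table, test_fraction=0.2, seed=42)

grid = [
    Hyperparams(300, 0.9, 0.9, 8, 0.5),   # over-fits: will be rejected
    Hyperparams(30, 0.7, 0.7, 2, 0.05),
    Hyperparams(100, 0.8, 0.8, 3, 0.1),
]
hp, cv = grid_search_select(train_df, grid, target="ce_xyz", seed=42)
print(f"selected: {hp}")
print(f"  val RMSE {cv['rmse_val']:.3f}, val R2 {cv['r2_val']:.3f}, "
      f"gaps RMSE {cv['gap_rmse_pct']:.1f}% / R2 {cv['gap_r2_pct']:.1f}%")

bundle = fit_models(train_df, hp, seed=42, targets=("ce_xyz",))[("EBT", "ce_xyz")]
cal = calibrate_mondrian(bundle, cal_df, alpha=0.05)

holdout = generate_training_table(n_rows=1000, n_sites=10, seed=43)
coverage = empirical_coverage(cal, bundle, holdout)
print(f"95% interval coverage on fresh holdout: {100 * coverage:.1f}%")

intervals = predict_interval(cal, bundle, holdout.head(3))
print(intervals[["center", "lower", "upper", "relative_size"]].round(3))
# relative_size shrinks as predicted complexity grows: the Mondrian bins
# capture the heteroskedastic residuals of low-complexity canopies.
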