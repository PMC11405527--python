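import numpy as np
import pytest

from wsci import StandParams, generate_stand, fit_models, train_test_site_split, calibrate_mondrian
from wsci.forestgen import generate_training_table
from wsci.model import Hyperparams

#: strongly regularized configuration used wherever a fitted model is
#: needed without exercising the grid search itself; regular enough to meet
#: the 5% train/validation gap constraint on the desk-scale tables
FIXTURE_HP = Hyperparams(n_estimators=30, subsample_fraction=0.7,
                         feature_fraction=0.7, max_depth=2, learning_rate=0.05)

#: higher-capacity configuration for signal-recovery checks where the
#: generalization-gap constraint is not the property under test
STRONG_HP = Hyperparams(n_estimators=200, subsample_fraction=0.9,
                        feature_fraction=0.9, max_depth=4, learning_rate=0.1)


@pytest.fixture(scope="session")
def stand():
    params = StandParams(tree_density=350.0, n_layers=2, understory_fraction=0.15,
                         canopy_point_density=8.0, ground_point_density=3.0)
    return generate_stand(params, seed=7)


@pytest.fixture(scope="session")
def training_table():
    return generate_training_table(n_rows=2000, n_sites=10, seed=5)


@pytest.fixture(scope="session")
def site_split(training_table):
    return train_test_site_split(training_table, test_fraction=0.2, seed=5)


@pytest.fixture(scope="session")
def bundle(site_split):
    train_df, _ = site_split
    bundles = fit_models(train_df, FIXTURE_HP, seed=5, targets=("ce_xyz",))
    return bundles[("EBT", "ce_xyz")]


@pytest.fixture(scope="session")
def calibration(bundle, site_split):
    _, cal_df = site_split
    return calibrate_mondrian(bundle, cal_df, alpha=0.05, n_bins=10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)
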