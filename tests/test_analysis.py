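"""Grid aggregation, PCA/PCR variance partition, scaling fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wsci import grid_aggregate, pca_pcr, pixel_scaling_fit, robust_biome_scaling, scaling_fits

METRICS = ("wsci", "cover", "rh98", "pai", "fhd", "agbd")


def make_shots(n=400, seed=0, x_range=100.0):
    rng = np.random.default_rng(seed)
    h = rng.uniform(6.0, 40.0, n)
    return pd.DataFrame({
        "x": rng.uniform(0, x_range, n), "y": rng.uniform(0, x_range, n),
        "rh98": h,
        "wsci": 2.0 + 1.3 * np.log(h) + rng.normal(0, 0.3, n),
        "pi_relative": rng.uniform(0.1, 0.5, n),
    })


class TestGridAggregate:
    def test_single_shot_cell_mean(self):
        shots = make_shots(1, seed=3)
        agg = grid_aggregate(shots, cell_size=50.0)
        assert len(agg) == 1
        assert agg["mean_wsci"].iloc[0] == pytest.approx(shots["wsci"].iloc[0])
        assert agg["n"].iloc[0] == 1

    def test_low_canopy_shots_excluded(self):
        shots = make_shots(50, seed=1)
        shots.loc[:9, "rh98"] = 5.0  # boundary: excluded (strictly greater required)
        agg = grid_aggregate(shots, cell_size=200.0)
        assert agg["n"].sum() == 40

    def test_counts_conserved(self):
        shots = make_shots(500, seed=2)
        agg = grid_aggregate(shots, cell_size=25.0)
        assert agg["n"].sum() == (shots["rh98"] > 5.0).sum()

    def test_mean_decomposes_over_halves(self):
        shots = make_shots(64, seed=4, x_range=10.0)  # single cell
        agg = grid_aggregate(shots, cell_size=50.0)
        half = len(shots) // 2
        m1 = shots["wsci"][:half].mean()
        m2 = shots["wsci"][half:].mean()
        assert agg["mean_wsci"].iloc[0] == pytest.approx((m1 + m2) / 2)

    def test_no_qualifying_shots_warns_empty(self):
        shots = make_shots(20, seed=5)
        shots["rh98"] = 3.0
        with pytest.warns(UserWarning, match="no qualifying shots"):
            agg = grid_aggregate(shots, cell_size=50.0)
        assert agg.empty


class TestPcaPcr:
    def test_rank_one_table(self, rng):
        latent = rng.normal(0, 1, 500)
        table = pd.DataFrame({m: a * latent + b for m, (a, b) in zip(
            METRICS, [(1, 5), (2, 1), (3, 10), (1, 2), (1.5, 3), (4, 20)])})
        res = pca_pcr(table)
        assert res["with_target"]["explained_variance_ratio"][0] == pytest.approx(1.0)
        assert res["with_target"]["pcr_r2"] == pytest.approx(1.0)

    def test_all_components_match_full_linear_fit(self, rng):
        n = 300
        table = pd.DataFrame(rng.uniform(0, 1, (n, 6)), columns=METRICS)
        res = pca_pcr(table, n_components=5)
        # regressing on all 5 non-target components spans the same space as
        # the ordinary linear fit on the raw metrics
        from sklearn.linear_model import LinearRegression
        X = table[[m for m in METRICS if m != "wsci"]]
        Z = (X - X.min()) / (X.max() - X.min())
        full_r2 = LinearRegression().fit(Z, res_y := _scaled_target(table)).score(Z, res_y)
        assert res["without_target"]["pcr_r2"] == pytest.approx(full_r2, abs=1e-9)

    def test_two_factor_shares_match_covariance_oracle(self):
        """Explained-variance shares recovered from a planted 2-factor table
        agree within 2% with shares computed independently from a very
        large sample of the same generator."""
        loadings = np.array([
            [1.0, 0.2], [0.8, 0.0], [0.6, 0.5], [0.0, 1.0], [0.3, 0.9], [0.7, 0.3]])

        def draw(n, seed):
            rng = np.random.default_rng(seed)
            f = rng.uniform(0, 1, (n, 2))
            return pd.DataFrame(f @ loadings.T + rng.normal(0, 0.01, (n, 6)),
                                columns=METRICS)

        shares = pca_pcr(draw(2000, 1))["with_target"]["explained_variance_ratio"]
        big = draw(200_000, 2)
        Z = (big - big.min()) / (big.max() - big.min())
        eigvals = np.linalg.eigvalsh(np.cov(Z.to_numpy().T))[::-1]
        oracle = eigvals / eigvals.sum()
        np.testing.assert_allclose(shares[:3], oracle[:3], atol=0.02)

    def test_pcr_r2_monotone_in_components(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, (300, 6)), columns=METRICS)
        r2 = [pca_pcr(table, n_components=k)["without_target"]["pcr_r2"]
              for k in (1, 2, 3, 4, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_constant_column_raises(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, (100, 6)), columns=METRICS)
        table["pai"] = 1.0
        with pytest.raises(ValueError, match="degenerate standardization"):
            pca_pcr(table)


def _scaled_target(table):
    y = table["wsci"]
    return ((y - y.min()) / (y.max() - y.min())).to_numpy()


class TestScalingFits:
    def test_noiseless_power_law_recovered_exactly(self):
        h = np.linspace(6, 40, 100)
        shots = pd.DataFrame({"rh98": h, "wsci": 1.3 * np.log(h) + 2.0})
        fit = pixel_scaling_fit(shots)
        assert fit.slope == pytest.approx(1.3, abs=1e-9)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert not fit.excluded

    def test_null_relationship_excluded_at_nominal_rate(self):
        """Under independence the two-tailed slope test rejects ~5% of the
        time, so ~95% of cells are flagged excluded."""
        excluded = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            shots = pd.DataFrame({"rh98": rng.uniform(6, 40, 100),
                                  "wsci": rng.normal(4, 1, 100)})
            excluded += pixel_scaling_fit(shots).excluded
        assert 0.90 <= excluded / reps <= 0.99

    def test_duplicating_shots_leaves_fit_unchanged(self):
        shots = make_shots(80, seed=6, x_range=10.0)
        doubled = pd.concat([shots, shots], ignore_index=True)
        a, b = pixel_scaling_fit(shots), pixel_scaling_fit(doubled)
        assert b.slope == pytest.approx(a.slope, abs=1e-12)
        assert b.intercept == pytest.approx(a.intercept, abs=1e-12)

    def test_below_fit_floor_excluded(self):
        fit = pixel_scaling_fit(make_shots(10, seed=7))
        assert fit.excluded and fit.reason == "below fit floor"

    def test_zero_height_variance_excluded(self):
        shots = pd.DataFrame({"rh98": np.full(50, 20.0), "wsci": np.random.default_rng(0).normal(4, 1, 50)})
        fit = pixel_scaling_fit(shots)
        assert fit.excluded and "variance" in fit.reason

    def test_per_cell_fits_cover_all_cells(self):
        shots = make_shots(800, seed=8)
        fits = scaling_fits(shots, cell_size=50.0, fit_floor=30)
        assert len(fits) == 4
        for f in fits:
            assert not f.excluded
            assert f.slope == pytest.approx(1.3, abs=0.15)


class TestRobustScaling:
    def test_clean_line_matches_ols_exactly(self):
        h = np.linspace(6, 40, 150)
        shots = pd.DataFrame({"rh98": h, "wsci": 1.3 * np.log(h) + 2.0, "biome": "t"})
        out = robust_biome_scaling(shots)
        ols = stats.linregress(np.log(h), shots["wsci"])
        assert out["slope"].iloc[0] == pytest.approx(ols.slope, abs=1e-6)

    def test_outlier_resistance(self):
        """Gross +10-nat outliers concentrated in short canopies bias the
        OLS slope by more than 5% while the Tukey-biweight fit stays within
        5% of the clean-data slope."""
        rng = np.random.default_rng(11)
        n = 2000
        h = rng.uniform(6.0, 40.0, n)
        clean = 2.0 + 1.3 * np.log(h) + rng.normal(0, 0.2, n)
        clean_slope = stats.linregress(np.log(h), clean).slope
        contaminated = clean.copy()
        low = np.argsort(h)[: n // 10]     # 10% gross outliers at short canopies
        contaminated[low] += 10.0
        shots = pd.DataFrame({"rh98": h, "wsci": contaminated, "biome": "t"})
        robust_slope = robust_biome_scaling(shots)["slope"].iloc[0]
        ols_slope = stats.linregress(np.log(h), contaminated).slope
        assert abs(robust_slope - clean_slope) / clean_slope < 0.05
        assert abs(ols_slope - clean_slope) / clean_slope > 0.05

    def test_biome_specific_slopes_recovered(self):
        """Planted biome scaling exponents (1.0 vs 1.3) recovered within 5%
        at 2,000 shots per biome."""
        rng = np.random.default_rng(13)
        frames = []
        for biome, slope in (("tropical", 1.0), ("temperate", 1.3)):
            h = rng.uniform(6.0, 45.0, 2000)
            frames.append(pd.DataFrame({
                "rh98": h, "biome": biome,
                "wsci": 3.0 + slope * np.log(h) + rng.normal(0, 0.3, 2000)}))
        out = robust_biome_scaling(pd.concat(frames)).set_index("biome")
        assert out.loc["tropical", "slope"] == pytest.approx(1.0, rel=0.05)
        assert out.loc["temperate", "slope"] == pytest.approx(1.3, rel=0.05)

    def test_too_few_shots_raises(self):
        shots = make_shots(50, seed=9).assign(biome="t")
        with pytest.raises(ValueError, match="need >= 100"):
            robust_biome_scaling(shots)
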