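"""Waveform simulation, RH metrics, geolocation matching, shot filters."""

import numpy as np
import pytest

from wsci import (
    ObservedShot, OffsetGrid, OffsetResult, PointCloud, ShotQualityRecord,
    StandParams, apply_known_offset, filter_crossovers, generate_stand,
    match_geolocation, quality_filter, rh_profile, simulate_waveform,
)
from wsci.waveform import Waveform


def spike_waveform(heights_amps, bin_height=0.15):
    h = np.arange(0.0, 40.0, bin_height)
    a = np.zeros_like(h)
    for height, amp in heights_amps:
        a[np.argmin(np.abs(h - height))] = amp
    return Waveform(heights=h, amplitude=a, bin_height=bin_height)


class TestSimulateWaveform:
    def test_unit_impulse(self):
        cloud = PointCloud(np.array([[0.0, 0.0, 12.0]]))
        wf = simulate_waveform(cloud, (0, 0))
        assert wf.total_energy == pytest.approx(1.0, rel=1e-6)
        assert wf.heights[np.argmax(wf.amplitude)] == pytest.approx(12.0, abs=wf.bin_height)

    def test_two_layers_give_two_modes(self, rng):
        n = 500
        xy = rng.uniform(-5, 5, (n, 2))
        low = np.c_[xy, np.zeros(n)]
        high = np.c_[xy, np.full(n, 30.0)]
        wf = simulate_waveform(PointCloud(np.vstack([low, high])), (0, 0))
        a = wf.amplitude
        interior = (a[1:-1] > a[:-2]) & (a[1:-1] >= a[2:]) & (a[1:-1] > a.max() * 0.2)
        modes = wf.heights[1:-1][interior]
        assert len(modes) == 2
        assert modes[0] == pytest.approx(0.0, abs=1.0)
        assert modes[1] == pytest.approx(30.0, abs=1.0)

    def test_linearity_under_duplication(self, rng):
        xyz = rng.uniform(-5, 5, (300, 3)) * [1, 1, 4]
        wf1 = simulate_waveform(PointCloud(xyz), (0, 0))
        wf2 = simulate_waveform(PointCloud(np.vstack([xyz, xyz])), (0, 0))
        np.testing.assert_allclose(wf2.amplitude, 2 * wf1.amplitude, rtol=1e-9)

    def test_energy_conservation(self, stand):
        wf = simulate_waveform(stand, (3.0, -2.0))
        d2 = (stand.x - 3.0) ** 2 + (stand.y + 2.0) ** 2
        expected = np.exp(-d2 / (2 * 6.25**2)).sum()
        assert wf.total_energy == pytest.approx(expected, rel=1e-6)

    def test_far_cloud_raises(self):
        cloud = PointCloud(np.array([[0.0, 0.0, 10.0]]))
        with pytest.raises(ValueError, match="no energy"):
            simulate_waveform(cloud, (1e4, 1e4))


class TestRHProfile:
    def test_degenerate_single_bin(self):
        wf = spike_waveform([(7.5, 1.0)])
        rh = rh_profile(wf)
        assert np.all(np.abs(rh - 7.5) < wf.bin_height)

    def test_equal_spikes_tie_convention(self):
        wf = spike_waveform([(0.0, 1.0), (30.0, 1.0)])
        rh = rh_profile(wf)
        assert np.all(np.abs(rh[:51]) < wf.bin_height)        # p <= 50 -> ground
        assert np.all(np.abs(rh[51:] - 30.0) < wf.bin_height)  # p > 50 -> canopy

    @pytest.mark.parametrize("seed", range(5))
    def test_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        h = np.arange(0, 35, 0.15)
        wf = Waveform(h, rng.uniform(0, 1, len(h)), 0.15)
        assert (np.diff(rh_profile(wf)) >= -1e-12).all()

    def test_rh100_tracks_canopy_top(self, stand):
        wf = simulate_waveform(stand, (0, 0))
        rh = rh_profile(wf)
        assert abs(rh[100] - stand.z.max()) <= 3 * 2.35


@pytest.fixture(scope="module")
def crossover():
    params = StandParams(tree_density=300.0, n_layers=2, canopy_point_density=6.0,
                         ground_point_density=2.0)
    cloud = generate_stand(params, seed=11)
    rng = np.random.default_rng(12)
    centers = [tuple(rng.uniform(-8, 8, 2)) for _ in range(10)]
    observed = [ObservedShot(c, simulate_waveform(cloud, c)) for c in centers]
    return cloud, observed


class TestMatchGeolocation:
    def test_self_match_recovers_zero(self, crossover):
        cloud, observed = crossover
        grid = OffsetGrid(np.arange(-2, 3, 1.0), np.arange(-2, 3, 1.0),
                          np.arange(-1, 1.1, 0.5))
        res = match_geolocation(observed, cloud, grid)
        assert (res.dx, res.dy, res.dz) == (0.0, 0.0, 0.0)
        assert res.mean_r > 0.999
        assert res.retained

    def test_planted_offset_recovered(self, crossover):
        cloud, observed = crossover
        shifted = apply_known_offset(cloud, 3.0, -2.0, 1.0)
        grid = OffsetGrid(np.arange(-4, 5, 1.0), np.arange(-4, 5, 1.0),
                          np.arange(-2, 2.1, 0.5))
        res = match_geolocation(observed, shifted, grid)
        assert abs(res.dx - 3.0) <= 1.0
        assert abs(res.dy + 2.0) <= 1.0
        assert abs(res.dz - 1.0) <= 0.5
        assert res.mean_r > 0.99

    def test_grid_excluding_truth_scores_below_self_match(self, crossover):
        cloud, observed = crossover
        shifted = apply_known_offset(cloud, 3.0, -2.0, 1.0)
        bad_grid = OffsetGrid(np.array([-8.0, -6.0]), np.array([6.0, 8.0]),
                              np.array([0.0]))
        res = match_geolocation(observed, shifted, bad_grid)
        assert res.mean_r < 0.999

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError, match="empty search grid"):
            OffsetGrid(np.array([]), np.array([0.0]), np.array([0.0]))


@pytest.mark.parametrize("n_shots,mean_r,expected", [
    (9, 0.99, False),   # too few shots, however well correlated
    (50, 0.74, False),  # correlation below the floor
    (10, 0.75, True),   # both thresholds inclusive
])
def test_crossover_filter(n_shots, mean_r, expected):
    res = OffsetResult(0, 0, 0, mean_r=mean_r, n_shots=n_shots)
    assert filter_crossovers(res) is expected


def good_record(**overrides):
    base = dict(algorithm_run_flag=1, degrade_flag=0, water_persistence=0.0,
                urban_proportion=0.0, rx_maxamp=100.0, sd_corrected=10.0,
                sensitivity=0.96, pft_class=2, in_tropics=False)
    base.update(overrides)
    return ShotQualityRecord(**base)


@pytest.mark.parametrize("overrides,expected", [
    ({}, True),
    ({"sensitivity": 0.96, "in_tropics": True}, False),     # tropics floor is 0.98
    ({"sensitivity": 0.985, "in_tropics": True}, True),
    ({"rx_maxamp": 79.9}, False),                           # amplitude below 8x noise sd
    ({"rx_maxamp": 80.0}, False),                           # strict inequality
    ({"algorithm_run_flag": 0}, False),
    ({"degrade_flag": 1}, False),
    ({"water_persistence": 10.0}, False),
    ({"urban_proportion": 50.0}, False),
    ({"pft_class": 7}, False),
    ({"pft_class": 11}, True),
])
def test_quality_filter_truth_table(overrides, expected):
    assert quality_filter(good_record(**overrides)) is expected


def test_quality_filter_missing_field_errors_never_passes():
    rec = good_record(sensitivity=float("nan"))
    with pytest.raises(ValueError, match="missing quality field"):
        quality_filter(rec)
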