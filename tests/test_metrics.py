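import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glymflux import (
    FluxMap,
    RoiMask,
    build_trajectory,
    classify_voxels,
    net_rate,
    phase_means,
    regional_volumes,
    smooth_trajectory,
)
from glymflux.metrics import RegionTrajectory, _centered_moving_average

VOX = (0.2, 0.2, 0.2)


def _map(values, interval=(30.0, 40.0), pair_index=0):
    return FluxMap(values=np.asarray(values, dtype=float), interval=interval,
                   pair_index=pair_index)


def _full_roi(shape, name="roi"):
    return RoiMask(name=name, mask=np.ones(shape, bool), voxel_size=VOX)


class TestClassify:
    def test_forced_three_voxel_example(self):
        values = np.zeros((3, 1, 1))
        values[:, 0, 0] = [0.002, -0.002, 0.0005]
        influx, clearance = classify_voxels(_map(values), 0.001)
        assert influx[:, 0, 0].tolist() == [True, False, False]
        assert clearance[:, 0, 0].tolist() == [False, True, False]

    def test_all_zero_map_classifies_nothing(self):
        influx, clearance = classify_voxels(_map(np.zeros((4, 4, 4))), 0.001)
        assert not influx.any() and not clearance.any()

    def test_exact_threshold_values_belong_to_neither(self):
        values = np.full((2, 1, 1), 0.001)
        values[1] = -0.001
        influx, clearance = classify_voxels(_map(values), 0.001)
        assert not influx.any() and not clearance.any()

    def test_random_map_matches_brute_force_scan(self, rng):
        values = rng.normal(0, 0.002, (10, 10, 10))
        influx, clearance = classify_voxels(_map(values), 0.001)
        n_in = n_cl = 0
        for x in values.ravel():
            if x > 0.001:
                n_in += 1
            elif x < -0.001:
                n_cl += 1
        assert influx.sum() == n_in
        assert clearance.sum() == n_cl
        assert not np.any(influx & clearance)


class TestVolumes:
    def test_influx_everywhere_gives_fraction_one(self):
        shape = (6, 6, 6)
        (v, _), (f, _) = regional_volumes(
            np.ones(shape, bool), np.zeros(shape, bool), _full_roi(shape)
        )
        assert f == 1.0
        assert v == pytest.approx(216 * 0.008)

    def test_ten_voxels_at_stated_resolution(self):
        shape = (10, 10, 10)
        influx = np.zeros(shape, bool)
        influx.ravel()[:10] = True
        (v, _), _ = regional_volumes(influx, np.zeros(shape, bool), _full_roi(shape))
        assert v == pytest.approx(10 * 0.008)  # 0.2 mm isotropic voxels

    def test_random_masks_match_brute_force_ratio(self, rng):
        shape = (9, 9, 9)
        influx = rng.random(shape) > 0.6
        clearance = ~influx & (rng.random(shape) > 0.5)
        roi_mask = rng.random(shape) > 0.3
        roi = RoiMask("r", roi_mask, VOX)
        _, (fi, fc) = regional_volumes(influx, clearance, roi)
        assert fi == pytest.approx((influx & roi_mask).sum() / roi_mask.sum())
        assert fc == pytest.approx((clearance & roi_mask).sum() / roi_mask.sum())

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            regional_volumes(
                np.ones((4, 4, 4), bool), np.ones((4, 4, 4), bool), _full_roi((5, 5, 5))
            )


class TestNetRate:
    def test_uniform_map(self):
        assert net_rate(_map(np.full((5, 5, 5), 0.43)), _full_roi((5, 5, 5))) == pytest.approx(0.43)

    def test_three_voxel_arithmetic(self):
        values = np.zeros((3, 1, 1))
        values[:, 0, 0] = [0.6, 0.3, 0.0]
        assert net_rate(_map(values), _full_roi((3, 1, 1))) == pytest.approx(0.3)

    def test_large_random_roi_matches_brute_force_mean(self, rng):
        values = rng.normal(0, 1, (12, 12, 12))
        mask = rng.random((12, 12, 12)) > 0.4
        roi = RoiMask("r", mask, VOX)
        total = n = 0
        for idx in np.ndindex(*values.shape):
            if mask[idx]:
                total += values[idx]
                n += 1
        assert net_rate(_map(values), roi) == pytest.approx(total / n, rel=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_linearity_under_superposition(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (6, 6, 6))
        b = rng.normal(0, 1, (6, 6, 6))
        roi = _full_roi((6, 6, 6))
        assert net_rate(_map(2 * a + 3 * b), roi) == pytest.approx(
            2 * net_rate(_map(a), roi) + 3 * net_rate(_map(b), roi), rel=1e-10, abs=1e-12
        )


def _traj(net, times=None):
    n = len(net)
    times = np.asarray(times if times is not None else 35.0 + 10.0 * np.arange(n))
    zero = np.zeros(n)
    return RegionTrajectory(
        roi="t", times=times, influx_volume=zero, clearance_volume=zero,
        influx_fraction=zero, clearance_fraction=zero, net_rate=np.asarray(net, float),
    )


class TestTrajectory:
    def test_fourteen_maps_give_fourteen_point_trajectory(self, rng):
        maps = [
            _map(rng.normal(0, 0.002, (8, 8, 8)), (30.0 + 10 * k, 40.0 + 10 * k), k)
            for k in range(14)
        ]
        traj = build_trajectory(maps, _full_roi((8, 8, 8)), 0.001)
        assert len(traj) == 14
        np.testing.assert_allclose(traj.times, 35.0 + 10.0 * np.arange(14))
        assert np.all(traj.influx_fraction + traj.clearance_fraction <= 1 + 1e-12)

    def test_zero_maps_give_zero_metrics(self):
        maps = [_map(np.zeros((6, 6, 6)), (10.0 * k, 10.0 * (k + 1)), k) for k in range(3)]
        traj = build_trajectory(maps, _full_roi((6, 6, 6)), 0.001)
        assert np.all(traj.influx_fraction == 0)
        assert np.all(traj.clearance_fraction == 0)
        assert np.all(traj.net_rate == 0)

    def test_injected_scenario_phase_structure(self, scenario_series):
        """Ground-truth maps show declining influx and rising clearance
        fractions over the last four time points, per the scenario schedule."""
        series, gt = scenario_series
        maps = [
            _map(gt.source[k], (series.frame_times[k], series.frame_times[k + 1]), k)
            for k in range(gt.n_pairs)
        ]
        roi = RoiMask("tissue", series.tissue_mask, VOX)
        traj = build_trajectory(maps, roi, 0.001)
        last4 = slice(-4, None)
        assert np.all(np.diff(traj.influx_fraction[last4]) <= 0)
        assert np.all(np.diff(traj.clearance_fraction[last4]) >= 0)

    def test_grid_mismatch_across_maps_rejected(self):
        maps = [
            _map(np.zeros((6, 6, 6)), (0.0, 10.0), 0),
            _map(np.zeros((5, 5, 5)), (10.0, 20.0), 1),
        ]
        with pytest.raises(ValueError, match="grid"):
            build_trajectory(maps, _full_roi((6, 6, 6)), 0.001)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        traj = smooth_trajectory(_traj([0.4] * 6), window=1)
        np.testing.assert_allclose(traj.net_rate, 0.4)
        assert traj.smoothed

    def test_truncated_end_rule(self):
        out = _centered_moving_average(np.array([0.0, 3.0, 0.0]), 1)
        np.testing.assert_allclose(out, [1.5, 1.0, 1.5])

    def test_window_zero_is_identity(self):
        traj = _traj([1.0, 2.0, 5.0])
        out = smooth_trajectory(traj, window=0)
        np.testing.assert_array_equal(out.net_rate, traj.net_rate)

    def test_length_preserved(self, rng):
        traj = _traj(rng.normal(0, 1, 14))
        assert len(smooth_trajectory(traj, 2)) == 14


class TestPhaseMeans:
    def test_constant_net_rate_reproduces_worked_magnitude(self):
        # constant 0.43 %/min, the brainstem influx-phase magnitude
        summary = phase_means(_traj([0.43] * 14))
        assert summary.influx_net_rate == pytest.approx(0.43)
        assert summary.clearance_net_rate == pytest.approx(0.43)

    def test_window_resolution_counts_midpoints(self):
        # midpoints 35..165: 8 in [30,110], 4 in [120,160]
        net = np.arange(14.0)
        summary = phase_means(_traj(net))
        assert summary.influx_net_rate == pytest.approx(np.mean(net[:8]))
        assert summary.clearance_net_rate == pytest.approx(np.mean(net[9:13]))

    def test_late_negative_sources_order_the_phases(self, scenario_series):
        series, gt = scenario_series
        maps = [
            _map(gt.source[k], (series.frame_times[k], series.frame_times[k + 1]), k)
            for k in range(gt.n_pairs)
        ]
        roi = RoiMask("tissue", series.tissue_mask, VOX)
        summary = phase_means(build_trajectory(maps, roi, 0.001))
        assert summary.clearance_net_rate < summary.influx_net_rate

    def test_one_point_window_returns_that_point(self):
        summary = phase_means(_traj([1.0, 2.0, 4.0]), (30.0, 40.0), (50.0, 60.0))
        assert summary.influx_net_rate == pytest.approx(1.0)
        assert summary.clearance_net_rate == pytest.approx(4.0)

    def test_empty_window_rejected_with_window_named(self):
        with pytest.raises(ValueError, match="500"):
            phase_means(_traj([1.0, 2.0]), (30.0, 40.0), (500.0, 600.0))


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_classification_partition_and_fraction_sum(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 0.003, (8, 8, 8))
        roi_mask = rng.random((8, 8, 8)) > 0.3
        if not roi_mask.any():
            roi_mask[0, 0, 0] = True
        roi = RoiMask("r", roi_mask, VOX)
        influx, clearance = classify_voxels(_map(values), 0.001)
        neither = ~influx & ~clearance
        assert np.all(influx.astype(int) + clearance.astype(int) + neither.astype(int) == 1)
        _, (fi, fc) = regional_volumes(influx, clearance, roi)
        assert 0 <= fi <= 1 and 0 <= fc <= 1
        assert fi + fc <= 1 + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), factor=st.floats(1.0, 10.0))
    def test_threshold_monotonicity(self, seed, factor):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 0.003, (8, 8, 8))
        roi = _full_roi((8, 8, 8))
        lo = classify_voxels(_map(values), 0.001)
        hi = classify_voxels(_map(values), 0.001 * factor)
        _, (fi_lo, fc_lo) = regional_volumes(*lo, roi)
        _, (fi_hi, fc_hi) = regional_volumes(*hi, roi)
        assert fi_hi <= fi_lo
        assert fc_hi <= fc_lo

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_smoothing_never_extends_range(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 14)
        out = _centered_moving_average(x, 1)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12
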