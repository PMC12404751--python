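import numpy as np
import pytest

from glymflux import (
    SourceField,
    UromtConfig,
    default_alpha_schedule,
    rflux_from_pair,
    run_series,
    solve_pair,
)
from glymflux.containers import DceSeries
from glymflux.solver import _PairObjective
from glymflux.transport import GroundTruth, forward_transport

SMALL = (5, 5, 5)


def test_adjoint_gradient_matches_finite_differences():
    """The hand-coded adjoint through the splitting scheme is exact."""
    rng = np.random.default_rng(3)
    rho0 = rng.uniform(0.5, 2.0, SMALL)
    rho1 = rng.uniform(0.5, 2.0, SMALL)
    obj = _PairObjective(
        rho0, rho1, np.ones(SMALL, bool), UromtConfig(n_substeps=3),
        alpha=100.0, duration=2.0,
    )
    x = rng.normal(0, 0.05, 4 * obj.n_mask)
    _, grad = obj.value_and_grad(x)
    eps = 1e-6
    for i in rng.choice(len(x), 15, replace=False):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        fd = (obj.value_and_grad(xp)[0] - obj.value_and_grad(xm)[0]) / (2 * eps)
        assert abs(fd - grad[i]) <= 1e-5 * max(abs(fd), 1.0)


def test_identical_frames_give_zero_motion_and_zero_source():
    rho = np.full((24, 24, 24), 2.0)
    v, r, diag = solve_pair(rho, rho, UromtConfig(), pair_index=0, n_pairs=14)
    assert np.abs(r.values).mean() < 0.001
    assert v.speed.mean() < 1e-3
    assert diag["final_mismatch"] <= diag["initial_mismatch"]


def test_uniform_exponential_growth_recovers_source_rate():
    """Mass gain under zero-flux boundaries cannot come from advection,
    so the recovered source must carry the full growth rate."""
    r0 = 0.004
    rho0 = np.full((24, 24, 24), 1.0)
    rho1 = rho0 * np.exp(r0 * 10.0)
    _, r, diag = solve_pair(rho0, rho1, UromtConfig(), pair_index=0, n_pairs=14)
    assert abs(r.values.mean() - r0) <= 0.1 * r0
    assert diag["converged"]


def test_translated_blob_recovered_as_advection_not_source():
    grids = np.ogrid[0:24, 0:24, 0:24]
    d2 = sum((g - 12) ** 2 for g in grids)
    blob = 1.0 + 5.0 * np.exp(-d2 / (2 * 3.0**2))
    vel = np.zeros((3, 24, 24, 24))
    vel[0] = 0.2  # 2 voxels over the 10-minute pair
    gt = GroundTruth(velocity=vel, source=np.zeros((24, 24, 24)), sigma=0.002)
    rho1 = forward_transport(blob, gt, 10.0, 10)
    config = UromtConfig(max_iters=400, rel_tol=1e-7)
    v, r, _ = solve_pair(blob, rho1, config, pair_index=0, n_pairs=14)
    assert np.abs(r.values).mean() < config.flux_threshold
    support = blob > 1.5
    gt_stack = np.concatenate([vel[d][support] for d in range(3)])
    rec_stack = np.concatenate([v.components[d][support] for d in range(3)])
    corr = np.corrcoef(gt_stack, rec_stack)[0, 1]
    assert corr > 0.5


def test_energy_history_non_increasing_and_mismatch_bounded():
    rng = np.random.default_rng(0)
    rho0 = rng.uniform(0.5, 2.0, (12, 12, 12))
    rho1 = rho0 * np.exp(rng.uniform(-0.05, 0.05, (12, 12, 12)))
    _, _, diag = solve_pair(rho0, rho1, UromtConfig(), pair_index=0, n_pairs=1)
    hist = np.asarray(diag["energy_history"])
    assert np.all(np.diff(hist) <= 1e-9 * np.abs(hist[:-1]))
    assert diag["final_mismatch"] <= diag["initial_mismatch"]


def test_solver_is_deterministic():
    rng = np.random.default_rng(4)
    rho0 = rng.uniform(0.5, 2.0, (10, 10, 10))
    rho1 = rng.uniform(0.5, 2.0, (10, 10, 10))
    cfg = UromtConfig(max_iters=20)
    va, ra, da = solve_pair(rho0, rho1, cfg)
    vb, rb, db = solve_pair(rho0, rho1, cfg)
    assert np.array_equal(va.components, vb.components)
    assert np.array_equal(ra.values, rb.values)
    assert da["energy"] == db["energy"]


def test_mismatched_grids_rejected():
    with pytest.raises(ValueError, match="grid"):
        solve_pair(np.ones((8, 8, 8)), np.ones((8, 8, 9)), UromtConfig())


def test_increasing_alpha_shrinks_the_source_norm():
    """Stronger source regularization never grows the recovered r."""
    rng = np.random.default_rng(1)
    rho0 = rng.uniform(0.5, 2.0, (10, 10, 10))
    rho1 = rho0 * np.exp(rng.uniform(-0.03, 0.06, (10, 10, 10)))
    norms = []
    for alpha in (5_000.0, 20_000.0, 40_000.0):
        cfg = UromtConfig(alpha_schedule=np.array([alpha]), max_iters=100)
        _, r, _ = solve_pair(rho0, rho1, cfg, pair_index=0, n_pairs=1)
        norms.append(float(np.sum(r.values**2)))
    assert norms[0] >= norms[1] >= norms[2]


class TestRflux:
    def test_constant_in_time_source_is_its_own_average(self):
        values = np.random.default_rng(0).normal(0, 0.01, (6, 6, 6))
        fm = rflux_from_pair(
            SourceField(values=values), UromtConfig(), interval=(30.0, 40.0)
        )
        np.testing.assert_array_equal(fm.values, values)
        assert fm.midpoint == 35.0

    def test_alternating_source_averages_to_zero(self):
        c = 0.02 * np.ones((4, 4, 4))
        stack = np.stack([c, -c, c, -c])
        fm = rflux_from_pair(
            SourceField(values=stack), UromtConfig(), interval=(0.0, 10.0)
        )
        np.testing.assert_allclose(fm.values, 0.0, atol=1e-15)

    def test_substep_stack_matches_brute_force_accumulation(self, rng):
        stack = rng.normal(0, 0.01, (7, 5, 5, 5))
        fm = rflux_from_pair(
            SourceField(values=stack), UromtConfig(), interval=(0.0, 10.0)
        )
        expected = np.zeros((5, 5, 5))
        for k in range(7):
            expected += stack[k]
        expected /= 7
        np.testing.assert_allclose(fm.values, expected, rtol=1e-12)


class TestRunSeries:
    def _series(self, frames, times):
        return DceSeries(
            frames=np.asarray(frames),
            frame_times=np.asarray(times),
            voxel_size=(0.2, 0.2, 0.2),
            tissue_mask=np.ones(np.asarray(frames).shape[1:], bool),
        )

    def test_two_identical_frames_give_one_near_zero_map(self):
        rho = np.full((10, 10, 10), 1.5)
        series = self._series([rho, rho], [30.0, 40.0])
        maps = run_series(series, UromtConfig())
        assert len(maps) == 1
        assert np.abs(maps[0].values).max() < 1e-6

    def test_alpha_schedule_length_must_match_pairs(self):
        rho = np.full((8, 8, 8), 1.0)
        series = self._series([rho, rho, rho], [0.0, 10.0, 20.0])
        cfg = UromtConfig(alpha_schedule=np.array([5_000.0, 10_000.0, 40_000.0]))
        with pytest.raises(ValueError, match="alpha_schedule"):
            run_series(series, cfg)

    def test_default_schedule_spans_endpoints_monotonically(self):
        sched = default_alpha_schedule(14)
        assert sched[0] == 5_000.0
        assert sched[-1] == 40_000.0
        assert np.all(np.diff(sched) > 0)

    def test_scenario_maps_have_contiguous_intervals_and_sign_structure(
        self, scenario_series, solved_maps
    ):
        series, _ = scenario_series
        assert len(solved_maps) == 14
        for k, m in enumerate(solved_maps):
            assert m.interval == (series.frame_times[k], series.frame_times[k + 1])
        tissue = series.tissue_mask
        assert solved_maps[0].values[tissue].mean() > 0
        assert solved_maps[-1].values[tissue].mean() < 0
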