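"""Speed filtering, occupancy, grid-shift-averaged rate maps."""

import numpy as np
import pytest

from morphtrack import (
    EmptyMapError,
    PlaceCellModel,
    SpikeTrain,
    Trajectory,
    compute_occupancy,
    compute_rate_map,
    constant_schedule,
    linear_grid,
    make_configuration,
    peak_rate,
    simulate_spikes,
    speed_filter,
)
from morphtrack.ratemaps import draw_shifts, peak_bin_xl, planar_grid


def _const_speed_traj(track, speed, duration=30.0, fs=25.0):
    """Motion along the fully extended top arm at a constant planar speed."""
    cfg = make_configuration(track, 160.0, 160.0, config_id="frozen")
    sched = constant_schedule(track, cfg, duration)
    t = np.arange(0, duration, 1 / fs)
    x_l = np.minimum(speed * t, 159.0)
    from morphtrack import layout_planar
    lay = layout_planar(track, cfg)
    p = lay.to_planar(x_l, 0.0)
    return Trajectory(track, sched, t, p[:, 0], p[:, 1], x_l,
                      np.zeros_like(t), np.zeros(len(t), dtype=int))


def _toy_spikes(cell_id, x_l, y_l=None, t=None):
    x_l = np.asarray(x_l, dtype=float)
    n = len(x_l)
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, float)
    y_l = np.zeros(n) if y_l is None else np.asarray(y_l, float)
    return SpikeTrain(cell_id, t, np.zeros(n), np.zeros(n), x_l, y_l,
                      np.zeros(n, dtype=int))


class TestSpeedFilter:
    def test_constant_speeds(self, track_a):
        fast = speed_filter(_const_speed_traj(track_a, 5.0))
        assert fast.included.all()
        slow = speed_filter(_const_speed_traj(track_a, 2.0))
        assert not slow.included.any()

    def test_mixed_speed_brute_force(self, track_a, rng):
        traj = _const_speed_traj(track_a, 5.0)
        # re-time the same path so half the samples move slowly
        warp = np.where(np.arange(traj.n) % 50 < 25, 1.0, 3.0)
        t = np.concatenate([[0.0], np.cumsum(warp[:-1] * 0.04)])
        traj = Trajectory(traj.track, traj.schedule, t, traj.x, traj.y,
                          traj.x_l, traj.y_l, traj.epoch_idx)
        out = speed_filter(traj, v_min=3.0, smooth_samples=5)
        # independent estimator: explicit odd-reflection padding, loop-based
        # box smoothing, central differences
        h = 2

        def smooth(a):
            pad = np.concatenate([2 * a[0] - a[h:0:-1], a, 2 * a[-1] - a[-2:-h - 2:-1]])
            return np.array([pad[i:i + 2 * h + 1].mean() for i in range(len(a))])

        xs, ys = smooth(traj.x), smooth(traj.y)
        v = np.hypot(np.gradient(xs, t), np.gradient(ys, t))
        assert np.array_equal(out.included, v >= 3.0)

    def test_spike_flags_follow_interpolated_speed(self, track_a):
        traj = _const_speed_traj(track_a, 5.0)
        spikes = _toy_spikes("c", [10.0, 20.0], t=[1.0, 2.0])
        _, flagged = speed_filter(traj, spikes)
        assert flagged.included.all()

    def test_empty_trajectory_warns(self, track_a):
        cfg = make_configuration(track_a, 160.0, 160.0)
        empty = Trajectory(track_a, constant_schedule(track_a, cfg, 1.0),
                           np.array([]), np.array([]), np.array([]),
                           np.array([]), np.array([]), np.array([], dtype=int))
        with pytest.warns(UserWarning):
            speed_filter(empty)


class TestOccupancy:
    def test_hand_tally_10_sample_fixture(self, track_a):
        cfg = make_configuration(track_a, 160.0, 160.0, config_id="frozen")
        sched = constant_schedule(track_a, cfg, 10.0)
        x_l = np.array([1, 1, 1, 4, 4, 7, 1, 4, 7, 7], dtype=float)
        t = np.arange(10, dtype=float)
        traj = Trajectory(track_a, sched, t, x_l.copy(), np.zeros(10), x_l,
                          np.zeros(10), np.zeros(10, dtype=int))
        grid = linear_grid(track_a)
        occ = compute_occupancy(traj, grid)
        # grid origin -3: x_l 1 -> column 1, 4 -> 2, 7 -> 3; y_l 0 -> row 2
        assert occ[1, 2] == pytest.approx(4.0)   # samples 0,1,2,6 (1 s each)
        assert occ[2, 2] == pytest.approx(3.0)   # samples 3,4,7
        assert occ[3, 2] == pytest.approx(2.0)   # samples 5,8 (last has no interval)
        assert occ.sum() == pytest.approx(t[-1] - t[0], abs=1e-9)

    def test_single_bin(self, track_a):
        cfg = make_configuration(track_a, 160.0, 160.0, config_id="frozen")
        sched = constant_schedule(track_a, cfg, 5.0)
        t = np.arange(5, dtype=float)
        traj = Trajectory(track_a, sched, t, np.full(5, 1.0), np.zeros(5),
                          np.full(5, 1.0), np.zeros(5), np.zeros(5, dtype=int))
        occ = compute_occupancy(traj, linear_grid(track_a))
        assert occ.max() == pytest.approx(4.0)
        assert occ.sum() == pytest.approx(4.0)


class TestRateMap:
    def test_unshifted_equals_count_over_occupancy(self, straight_trajectory,
                                                   track_a):
        cells = [PlaceCellModel("c", "linear_fraction", center_fraction=0.2)]
        spikes = simulate_spikes(straight_trajectory, cells, seed=1)["c"]
        grid = linear_grid(track_a)
        rm = compute_rate_map(straight_trajectory, spikes, grid,
                              shifts=np.zeros((1, 2)))
        vis = rm.occupancy > 0
        assert np.allclose(rm.rate[vis], rm.counts[vis] / rm.occupancy[vis])
        assert np.isnan(rm.rate[~vis]).all()

    def test_spike_count_conserved_in_every_shift(self, straight_trajectory,
                                                  track_a, rng):
        cells = [PlaceCellModel("c", "linear_fraction", center_fraction=0.5)]
        spikes = simulate_spikes(straight_trajectory, cells, seed=2)["c"]
        grid = linear_grid(track_a)
        for _ in range(5):
            off = rng.uniform(-1.5, 1.5, size=(1, 2))
            rm = compute_rate_map(straight_trajectory, spikes, grid, shifts=off)
            assert rm.counts.sum() == spikes.n

    def test_homogeneous_rate_recovered(self, straight_trajectory, track_a):
        """Flat 5 Hz firing: the occupancy-weighted mean rate must sit within
        3 Poisson standard errors of 5 Hz."""
        lam = 5.0
        cell = PlaceCellModel("flat", "planar", center_planar=(1e6, 1e6),
                              baseline_hz=lam, peak_hz=lam + 1e-9)
        spikes = simulate_spikes(straight_trajectory, [cell], seed=3)["flat"]
        grid = linear_grid(track_a)
        rm = compute_rate_map(straight_trajectory, spikes, grid, n_shifts=25,
                              seed=0)
        T = rm.occupancy.sum()
        mean_rate = rm.counts.sum() / T
        assert abs(mean_rate - lam) < 3 * np.sqrt(lam / T)

    def test_shift_average_matches_unshifted_for_uniform_field(
            self, straight_trajectory, track_a):
        cell = PlaceCellModel("flat", "planar", center_planar=(1e6, 1e6),
                              baseline_hz=5.0, peak_hz=5.0 + 1e-9)
        spikes = simulate_spikes(straight_trajectory, [cell], seed=4)["flat"]
        grid = linear_grid(track_a)
        shifted = compute_rate_map(straight_trajectory, spikes, grid,
                                   n_shifts=25, seed=1)
        vis = shifted.visited & (shifted.occupancy > 0.5)
        assert abs(np.nanmean(shifted.rate[vis]) - 5.0) < 1.0

    def test_peak_rate(self, track_a):
        grid = linear_grid(track_a)
        cfg = make_configuration(track_a, 160.0, 160.0, config_id="frozen")
        sched = constant_schedule(track_a, cfg, 3.0)
        t = np.array([0.0, 1.0, 2.0])
        traj = Trajectory(track_a, sched, t, np.zeros(3), np.zeros(3),
                          np.full(3, 10.0), np.zeros(3), np.zeros(3, dtype=int))
        spikes = _toy_spikes("c", [10.0] * 8, t=[0.1] * 8)
        rm = compute_rate_map(traj, spikes, grid, shifts=np.zeros((1, 2)))
        assert peak_rate(rm) == pytest.approx(8 / 2.0)  # 8 spikes over 2 s
        # no-spike map peaks at 0 Hz
        rm0 = compute_rate_map(traj, _toy_spikes("c", []), grid,
                               shifts=np.zeros((1, 2)))
        assert peak_rate(rm0) == 0.0
        assert peak_bin_xl(rm) == pytest.approx(10.5)   # center of bin [9, 12)

    def test_peak_rate_empty_map_errors(self, track_a):
        grid = linear_grid(track_a)
        cfg = make_configuration(track_a, 160.0, 160.0, config_id="frozen")
        sched = constant_schedule(track_a, cfg, 1.0)
        traj = Trajectory(track_a, sched, np.array([0.0]), np.zeros(1),
                          np.zeros(1), np.zeros(1), np.zeros(1),
                          np.zeros(1, dtype=int),
                          included=np.array([False]))
        rm = compute_rate_map(traj, _toy_spikes("c", []), grid,
                              shifts=np.zeros((1, 2)))
        with pytest.raises(EmptyMapError):
            peak_rate(rm)

    def test_brute_force_binning_oracle(self, track_a):
        """Unshifted rate map equals a per-sample brute-force tally."""
        cfg = make_configuration(track_a, 160.0, 160.0, config_id="frozen")
        sched = constant_schedule(track_a, cfg, 10.0)
        rs = np.random.default_rng(7)
        x_l = rs.uniform(0, 380, 10)
        y_l = rs.uniform(-4, 4, 10)
        t = np.arange(10, dtype=float)
        traj = Trajectory(track_a, sched, t, x_l.copy(), y_l.copy(), x_l, y_l,
                          np.zeros(10, dtype=int))
        spikes = _toy_spikes("c", x_l[:4], y_l[:4], t=t[:4])
        grid = linear_grid(track_a)
        rm = compute_rate_map(traj, spikes, grid, shifts=np.zeros((1, 2)))
        occ = np.zeros((grid.n_x, grid.n_y))
        cnt = np.zeros((grid.n_x, grid.n_y))
        for i in range(10):
            ix = int(np.floor((x_l[i] - grid.x0) / grid.bin_w))
            iy = int(np.floor((y_l[i] - grid.y0) / grid.bin_h))
            if i < 9:
                occ[ix, iy] += t[i + 1] - t[i]
            if i < 4:
                cnt[ix, iy] += 1
        assert np.allclose(rm.occupancy, occ)
        assert np.allclose(rm.counts, cnt)
        vis = occ > 0
        assert np.allclose(rm.rate[vis], cnt[vis] / occ[vis])


class TestGrid:
    def test_flatten_is_bijection(self, track_a):
        grid = planar_grid(track_a)
        ix, iy = np.meshgrid(np.arange(grid.n_x), np.arange(grid.n_y),
                             indexing="ij")
        pos = grid.vector_position(ix.ravel(), iy.ravel())
        assert sorted(pos) == list(range(grid.n_bins))
        # vector starts at the top-right bin and runs downward
        assert grid.vector_position(grid.n_x - 1, grid.n_y - 1) == 0
        assert grid.vector_position(grid.n_x - 1, grid.n_y - 2) == 1

    def test_out_of_grid_raises(self, track_a):
        grid = linear_grid(track_a)
        with pytest.raises(Exception):
            grid.flat_indices(np.array([1e5]), np.array([0.0]))

    def test_profile_grid_shifts_along_track_only(self, track_a, rng):
        from morphtrack import profile_grid
        g = profile_grid(track_a)
        sh = draw_shifts(g, 10, rng)
        assert np.all(sh[:, 1] == 0)
        assert np.all(np.abs(sh[:, 0]) <= g.bin_w / 2)
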