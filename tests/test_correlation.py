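"""Section grouping, correlation matrices, decay curves, frame tests."""

import numpy as np
import pytest
from scipy import stats

from morphtrack import (
    ConfigSchedule,
    Epoch,
    build_correlation_matrix,
    classify_mobile_static,
    decay_curve,
    ensemble_curves,
    ensemble_matrix,
    frame_comparison_test,
    group_by_section,
    linear_grid,
    make_configuration,
    masked_pearson,
    pair_correlation,
    pooled_rate_map,
    speed_filter,
    valid_bin_mask,
)
from morphtrack.correlation import CorrelationMatrix, subdiagonal_entries
from morphtrack.geometry import section_of_extent
from morphtrack.ratemaps import BinGrid, RateMap, compute_rate_map


def _schedule_with_extents(track, extents):
    epochs, t = [], 0.0
    for i, (top, bot) in enumerate(extents):
        cfg = make_configuration(track, top, bot, config_id=f"c{i}")
        epochs.append(Epoch(cfg, t, t + 10.0))
        t += 10.0
    return ConfigSchedule(track, epochs)


def _map_from_rate(grid_rows, rate_row, counts_row=None, occ_row=None):
    """A 1-row-grid RateMap built directly from a rate vector."""
    n = len(rate_row)
    grid = BinGrid("linear", 0.0, -1.5, n, 1, 3.0, 3.0)
    rate = np.asarray(rate_row, dtype=float)[:, None]
    occ = (np.ones((n, 1)) if occ_row is None
           else np.asarray(occ_row, dtype=float)[:, None])
    cnt = (np.where(np.isfinite(rate) & (rate > 0), 1.0, 0.0) if counts_row is None
           else np.asarray(counts_row, dtype=float)[:, None])
    visited = occ > 0
    return RateMap(grid, occ, cnt, rate, visited, 1)


class TestGrouping:
    def test_brute_force_membership(self, track_a, rng):
        extents = [(float(rng.uniform(52, 160)), float(rng.uniform(52, 160)))
                   for _ in range(60)]
        sched = _schedule_with_extents(track_a, extents)
        groups = group_by_section(sched, "top", min_count=3)
        want = {}
        for ei, (top, _) in enumerate(extents):
            want.setdefault(section_of_extent(track_a, top), []).append(ei)
        want = {v: ids for v, ids in want.items() if len(ids) >= 3}
        got = {g.section: list(g.epoch_ids) for g in groups}
        assert got == want

    def test_small_sections_dropped(self, track_a):
        # sections 1 (x3), 5 (x2): the pair is dropped
        extents = [(53.0, 100.0), (54.0, 100.0), (55.0, 100.0),
                   (90.0, 100.0), (91.0, 100.0)]
        sched = _schedule_with_extents(track_a, extents)
        groups = group_by_section(sched, "top")
        assert [g.section for g in groups] == [1]
        assert groups[0].n == 3

    def test_all_in_one_section(self, track_a):
        extents = [(53.0 + 0.5 * i, 100.0) for i in range(8)]
        sched = _schedule_with_extents(track_a, extents)
        groups = group_by_section(sched, "top")
        assert len(groups) == 1 and groups[0].n == 8

    def test_no_surviving_group_errors(self, track_a):
        sched = _schedule_with_extents(track_a, [(53.0, 100.0), (90.0, 100.0)])
        with pytest.raises(ValueError):
            group_by_section(sched, "top")


class TestPooledMap:
    def test_pooling_equals_concatenation(self, small_session, track_a):
        bundle, _ = small_session
        traj, spikes = speed_filter(bundle.trajectory, bundle.spikes)
        groups = group_by_section(bundle.schedule, "top")
        g = max(groups, key=lambda g: g.n)
        grid = linear_grid(track_a)
        tr = spikes.trains[0]
        pooled = pooled_rate_map(traj, tr, g, grid, shifts=np.zeros((1, 2)))
        # oracle: single-epoch maps, counts and occupancy summed
        occ = np.zeros_like(pooled.occupancy)
        cnt = np.zeros_like(pooled.counts)
        for eid in g.epoch_ids:
            m = compute_rate_map(traj, tr, grid, shifts=np.zeros((1, 2)),
                                 sample_mask=traj.epoch_idx == eid,
                                 spike_mask=tr.epoch_idx == eid)
            occ += m.occupancy
            cnt += m.counts
        assert np.allclose(pooled.occupancy, occ, atol=1e-9)
        assert np.allclose(pooled.counts, cnt)
        vis = occ > 0
        assert np.allclose(pooled.rate[vis], cnt[vis] / occ[vis])

    def test_single_epoch_group_identity(self, small_session, track_a):
        bundle, _ = small_session
        traj, spikes = speed_filter(bundle.trajectory, bundle.spikes)
        from morphtrack.correlation import SectionGroup
        g = SectionGroup("top", 1, (0,), (bundle.schedule.epochs[0].config.config_id,))
        tr = spikes.trains[0]
        grid = linear_grid(track_a)
        pooled = pooled_rate_map(traj, tr, g, grid, shifts=np.zeros((1, 2)))
        single = compute_rate_map(traj, tr, grid, shifts=np.zeros((1, 2)),
                                  sample_mask=traj.epoch_idx == 0,
                                  spike_mask=tr.epoch_idx == 0)
        assert np.allclose(pooled.occupancy, single.occupancy)
        assert np.allclose(pooled.counts, single.counts)


class TestMaskAndPearson:
    def test_disjoint_visited_empty_mask(self):
        m1 = _map_from_rate(4, [1, 2, np.nan, np.nan], occ_row=[1, 1, 0, 0])
        m2 = _map_from_rate(4, [np.nan, np.nan, 3, 4], occ_row=[0, 0, 1, 1])
        assert valid_bin_mask(m1, m2).sum() == 0

    def test_identical_maps_mask_is_spiking_visited(self):
        rate = [0.0, 2.0, 3.0, 0.0]
        m = _map_from_rate(4, rate, counts_row=[0, 2, 3, 0])
        mask = valid_bin_mask(m, m)
        assert mask.ravel().tolist() == [False, True, True, False]

    def test_mask_rules_brute_force(self, rng):
        occ1, occ2 = rng.integers(0, 2, 20), rng.integers(0, 2, 20)
        c1, c2 = rng.integers(0, 3, 20), rng.integers(0, 3, 20)
        m1 = _map_from_rate(20, c1 / np.maximum(occ1, 1), counts_row=c1, occ_row=occ1)
        m2 = _map_from_rate(20, c2 / np.maximum(occ2, 1), counts_row=c2, occ_row=occ2)
        either = valid_bin_mask(m1, m2, "either").ravel()
        both = valid_bin_mask(m1, m2, "both").ravel()
        for k in range(20):
            vis = occ1[k] > 0 and occ2[k] > 0
            assert either[k] == (vis and (c1[k] + c2[k] > 0))
            assert both[k] == (vis and c1[k] > 0 and c2[k] > 0)

    def test_self_correlation_is_one(self):
        m = _map_from_rate(12, np.arange(12, dtype=float),
                           counts_row=np.ones(12))
        r, n = pair_correlation(m, m)
        assert r == pytest.approx(1.0)
        assert n == 12

    def test_exact_anticorrelation(self):
        m1 = _map_from_rate(3, [1, 2, 3], counts_row=[1, 1, 1])
        m2 = _map_from_rate(3, [3, 2, 1], counts_row=[1, 1, 1])
        r, _ = pair_correlation(m1, m2, min_bins=3)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # vectors (0,1,2,4) and (1,1,3,5): covariance sum 9.5,
        # sums of squares 8.75 and 11.0  ->  r = 9.5 / sqrt(96.25)
        r = masked_pearson(np.array([0, 1, 2, 4.0]), np.array([1, 1, 3, 5.0]))
        assert r == pytest.approx(9.5 / np.sqrt(96.25), abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(masked_pearson(np.ones(5), np.arange(5.0)))

    def test_min_bins_floor(self):
        m1 = _map_from_rate(5, [1, 2, 3, 4, 5], counts_row=np.ones(5))
        m2 = _map_from_rate(5, [2, 3, 4, 5, 6], counts_row=np.ones(5))
        r, n = pair_correlation(m1, m2, min_bins=10)
        assert np.isnan(r) and n == 5


class TestDecayCurve:
    def _matrix(self, C):
        C = np.asarray(C, dtype=float)
        return CorrelationMatrix("linear", "c", len(C), C,
                                 np.ones_like(C, dtype=int))

    def test_all_ones(self):
        c = decay_curve(self._matrix(np.ones((5, 5))))
        assert np.allclose(c.r, 1.0)

    def test_mean_of_two_subdiagonal_entries(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.5
        C[1, 2] = C[2, 1] = 0.7
        C[0, 2] = C[2, 0] = np.nan
        c = decay_curve(self._matrix(C))
        assert c.r[1] == pytest.approx(0.6)      # mean of 0.5 and 0.7
        assert np.isnan(c.r[2])
        assert c.n[1] == 2

    def test_brute_force_12x12(self, rng):
        C = rng.uniform(-1, 1, (12, 12))
        C = (C + C.T) / 2
        C[rng.uniform(size=(12, 12)) < 0.2] = np.nan
        C = np.where(np.isnan(C) | np.isnan(C.T), np.nan, (C + C.T) / 2)
        c = decay_curve(self._matrix(C))
        for d in range(12):
            vals = [C[i, i + d] for i in range(12 - d)
                    if not np.isnan(C[i, i + d])]
            if vals:
                assert c.r[d] == pytest.approx(np.mean(vals))
            else:
                assert np.isnan(c.r[d])

    def test_ensemble_single_cell_identity(self):
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        m = self._matrix(C)
        curve = ensemble_curves([m])
        assert np.allclose(curve.r, decay_curve(m).r)

    def test_ensemble_two_constant_matrices(self):
        m1 = self._matrix(np.full((4, 4), 0.2))
        m2 = self._matrix(np.full((4, 4), 0.8))
        curve = ensemble_curves([m1, m2])
        assert np.allclose(curve.r, 0.5)

    def test_ensemble_brute_force_20_cells(self, rng):
        mats = []
        for _ in range(20):
            C = rng.uniform(-1, 1, (6, 6))
            C = (C + C.T) / 2
            mats.append(self._matrix(C))
        ens = ensemble_matrix(mats)
        assert np.allclose(ens.C, np.mean([m.C for m in mats], axis=0))


class TestClassification:
    def _map_with_peak(self, track, xl_peak):
        grid = linear_grid(track)
        rate = np.full((grid.n_x, grid.n_y), np.nan)
        occ = np.zeros((grid.n_x, grid.n_y))
        cnt = np.zeros((grid.n_x, grid.n_y))
        ix = int(np.floor((xl_peak - grid.x0) / grid.bin_w))
        rate[ix, 2], occ[ix, 2], cnt[ix, 2] = 5.0, 1.0, 5.0
        return RateMap(grid, occ, cnt, rate, occ > 0, 1)

    def test_static_and_mobile(self, track_a):
        assert classify_mobile_static(
            track_a, self._map_with_peak(track_a, 180.0)) == ("static", "base")
        assert classify_mobile_static(
            track_a, self._map_with_peak(track_a, 60.0)) == ("mobile", "top")
        assert classify_mobile_static(
            track_a, self._map_with_peak(track_a, 300.0)) == ("mobile", "bottom")

    def test_half_open_boundaries(self, track_a):
        # bins are [left, right): the 4/5 junction bin [160.5] is static,
        # the bin just below stays mobile; 240 falls on the bottom arm
        assert classify_mobile_static(
            track_a, self._map_with_peak(track_a, 160.5))[0] == "static"
        assert classify_mobile_static(
            track_a, self._map_with_peak(track_a, 157.5))[0] == "mobile"
        assert classify_mobile_static(
            track_a, self._map_with_peak(track_a, 240.5)) == ("mobile", "bottom")

    def test_no_spikes_unclassified(self, track_a):
        grid = linear_grid(track_a)
        empty = RateMap(grid, np.ones((grid.n_x, grid.n_y)),
                        np.zeros((grid.n_x, grid.n_y)),
                        np.zeros((grid.n_x, grid.n_y)),
                        np.ones((grid.n_x, grid.n_y), dtype=bool), 1)
        assert classify_mobile_static(track_a, empty) == (None, None)


class TestFrameComparison:
    def test_identical_sets_p_near_one(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        p = frame_comparison_test({1: vals}, {1: vals.copy()})
        assert p[1] > 0.5

    def test_separated_sets_tiny_p(self, rng):
        a = 1.0 + rng.normal(0, 1e-3, 20)
        b = 0.0 + rng.normal(0, 1e-3, 20)
        p = frame_comparison_test({0: a}, {0: b})
        assert p[0] < 1e-6

    def test_welch_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 6.0, 8.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_hand = 2 * stats.t.sf(abs(t), dof)
        p = frame_comparison_test({0: a}, {0: b})
        assert p[0] == pytest.approx(p_hand, abs=1e-9)

    def test_insufficient_entries_flagged(self):
        p = frame_comparison_test({0: np.array([1.0])}, {0: np.array([0.0, 0.1])})
        assert np.isnan(p[0])


def test_subdiagonal_entries_skip_undefined():
    C = np.full((4, 4), np.nan)
    C[0, 0] = C[1, 1] = 1.0
    C[0, 2] = C[2, 0] = 0.4
    m = CorrelationMatrix("linear", "c", 4, C, np.ones((4, 4), dtype=int))
    e = subdiagonal_entries(m)
    assert list(e[0]) == [1.0, 1.0]
    assert list(e[2]) == [0.4]
    assert len(e[1]) == 0
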