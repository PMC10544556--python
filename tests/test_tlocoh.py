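import numpy as np
import pytest
from scipy.spatial import ConvexHull

from sympatry.errors import ValidationError
from sympatry.tlocoh import (TlocohParams, build_hullset, isopleths,
                             select_neighbors_adaptive, suggest_s,
                             time_use_metrics, tsd_distance)
from sympatry.trajectory import compute_vmax

H = 3600.0


class TestTsdDistance:
    def test_s_zero_is_planar_euclidean(self):
        assert tsd_distance([3.0, 4.0], 9999.0, 0.0, 2.0) == pytest.approx(5.0)

    def test_zero_time_gap_is_planar_euclidean(self):
        assert tsd_distance([3.0, 4.0], 0.0, 0.5, 2.0) == pytest.approx(5.0)

    def test_hand_arithmetic(self):
        # dx=3, dy=4, dt=1 h, s=0.05, v_max=1 -> sqrt(25 + 180^2)
        got = tsd_distance([3.0, 4.0], 3600.0, 0.05, 1.0)
        assert got == pytest.approx(np.sqrt(25 + 180.0 ** 2))
        assert got == pytest.approx(180.069, abs=1e-3)


class TestAdaptiveNeighbors:
    def params(self, a, s=0.0):
        return TlocohParams(s=s, a=a)

    def test_huge_a_selects_all(self, traj_factory):
        tr = traj_factory([[0, 0], [10, 0], [20, 0], [5, 5]],
                          np.arange(4) * H)
        nb = select_neighbors_adaptive(tr, 0, self.params(1e9), v_max=1.0)
        assert nb.tolist() == [0, 1, 2, 3]

    def test_tiny_a_keeps_minimum_three_points(self, traj_factory):
        tr = traj_factory([[0, 0], [10, 0], [20, 0], [300, 300]],
                          np.arange(4) * H)
        nb = select_neighbors_adaptive(tr, 0, self.params(1e-9), v_max=1.0)
        assert nb.size == 3 and 0 in nb

    def test_cumulative_sum_rule(self, traj_factory):
        # distances 1,2,3,4 from the parent; a=6 admits exactly 1+2+3.
        tr = traj_factory([[0, 0], [1, 0], [2, 0], [3, 0], [4, 0]],
                          np.zeros(5))
        nb = select_neighbors_adaptive(tr, 0, self.params(6.0), v_max=1.0)
        assert nb.tolist() == [0, 1, 2, 3]

    def test_too_few_fixes_is_error(self, traj_factory):
        tr = traj_factory([[0, 0], [1, 1]], [0.0, H])
        with pytest.raises(ValidationError):
            select_neighbors_adaptive(tr, 0, self.params(10.0), v_max=1.0)


class TestHullset:
    def test_unit_square_hulls(self, traj_factory):
        tr = traj_factory([[0, 0], [1, 0], [1, 1], [0, 1]], np.arange(4) * H)
        hs = build_hullset(tr, TlocohParams(s=0.0, a=1e9), v_max=1.0)
        assert len(hs.hulls) == 4
        for h in hs.hulls:
            assert h.area == pytest.approx(1.0)
            assert h.n_enclosed == 4

    def test_matches_brute_force_hull_area_on_toys(self, traj_factory):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            xy = rng.uniform(0, 100, (n, 2))
            tr = traj_factory(xy, np.arange(n) * H)
            hs = build_hullset(tr, TlocohParams(s=0.0, a=1e9), v_max=1.0)
            oracle = ConvexHull(xy).volume  # 2-D "volume" is area
            for h in hs.hulls:
                assert h.area == pytest.approx(oracle, rel=1e-12)

    def test_duplicated_den_fixes_skipped_and_reported(self, traj_factory):
        # Three coincident den fixes among a ring of distinct ones; with a
        # tiny a, the den parents' neighbourhoods are degenerate.
        ring = [[100 * np.cos(a), 100 * np.sin(a)]
                for a in np.linspace(0, 2 * np.pi, 18, endpoint=False)]
        xy = [[0.0, 0.0]] * 3 + ring
        tr = traj_factory(xy, np.arange(21) * H)
        hs = build_hullset(tr, TlocohParams(s=0.0, a=1e-6), v_max=1.0)
        assert hs.skipped == [0, 1, 2]
        assert len(hs.hulls) + len(hs.skipped) == 21

    def test_every_hull_contains_its_parent(self, short_track):
        v = compute_vmax(short_track)
        hs = build_hullset(short_track, TlocohParams(s=0.02, a=2000.0),
                           v_max=v)
        xy = short_track.xy
        for h in hs.hulls[::7]:
            assert h.polygon.covers(
                __import__("shapely").points(*xy[h.parent]))
            assert h.parent in h.enclosed


class TestTimeUseMetrics:
    def test_single_visit(self):
        nsv, mnlv = time_use_metrics(np.arange(5) * 3600.0, ivg=43200.0)
        assert (nsv, mnlv) == (1, 5.0)

    def test_gap_rule_two_visits(self):
        nsv, mnlv = time_use_metrics([0.0, 24 * H], ivg=43200.0)
        assert (nsv, mnlv) == (2, 1.0)

    def test_gap_rule_two_visits_of_two(self):
        nsv, mnlv = time_use_metrics([0.0, 2 * H, 14 * H, 16 * H], ivg=43200.0)
        assert (nsv, mnlv) == (2, 2.0)

    def test_nsv_one_implies_mnlv_is_count(self, short_track):
        v = compute_vmax(short_track)
        hs = build_hullset(short_track, TlocohParams(s=0.02, a=2000.0), v_max=v)
        for h in hs.hulls:
            if h.nsv == 1:
                assert h.mnlv == h.n_enclosed
            assert h.nsv * h.mnlv == pytest.approx(h.n_enclosed)


class TestIsopleths:
    def test_full_level_encloses_everything(self, short_track):
        hs = build_hullset(short_track, TlocohParams(s=0.0, a=3000.0),
                           v_max=1.0)
        iso = isopleths(hs, "density", (1.0,))[0]
        assert iso.n_fixes == short_track.n
        assert not iso.partial

    def test_nesting_and_area_order(self, short_track):
        v = compute_vmax(short_track)
        hs = build_hullset(short_track, TlocohParams(s=0.02, a=2000.0), v_max=v)
        for ordering in ("density", "nsv", "mnlv"):
            i50, i95 = isopleths(hs, ordering, (0.5, 0.95))
            assert i50.area <= i95.area
            assert i95.polygon.buffer(1e-6).covers(i50.polygon)

    def test_density_ordering_concentrates_use(self, short_track):
        v = compute_vmax(short_track)
        hs = build_hullset(short_track, TlocohParams(s=0.02, a=2000.0), v_max=v)
        i50, i95 = isopleths(hs, "density", (0.5, 0.95))
        assert i50.n_fixes / i50.area >= i95.n_fixes / i95.area

    def test_two_clusters_level_half_selects_denser_one(self, traj_factory):
        # 50 dense fixes near the origin, 50 sparse ones 10 km east: under
        # density ordering the 50% isopleth is built entirely from the dense
        # cluster's hulls.
        dense = np.stack(np.meshgrid(np.arange(5) * 10.0,
                                     np.arange(10) * 10.0), -1).reshape(-1, 2)
        sparse = 3.0 * dense + [10000.0, 0.0]
        xy = np.r_[dense, sparse]
        tr = traj_factory(xy, np.arange(100) * H)
        hs = build_hullset(tr, TlocohParams(s=0.0, a=60.0), v_max=1.0)
        half = isopleths(hs, "density", (0.5,))[0]
        full = isopleths(hs, "density", (1.0,))[0]
        assert half.n_fixes == 50
        assert half.polygon.bounds[2] < 5000.0  # west cluster only
        assert half.area < 0.5 * full.area

    def test_s_zero_invariant_to_timestamp_permutation(self, traj_factory):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 1000, (60, 2))
        t = np.arange(60) * H
        a = TlocohParams(s=0.0, a=500.0)
        hs1 = build_hullset(traj_factory(xy, t), a, v_max=1.0)
        hs2 = build_hullset(traj_factory(xy, rng.permutation(t)), a, v_max=1.0)
        areas1 = sorted(h.area for h in hs1.hulls)
        areas2 = sorted(h.area for h in hs2.hulls)
        np.testing.assert_allclose(areas1, areas2)
        i1 = isopleths(hs1, "density", (0.95,))[0]
        i2 = isopleths(hs2, "density", (0.95,))[0]
        assert i1.area == pytest.approx(i2.area)


class TestSuggestS:
    def test_scaling_law_time_dilation(self, resident_track):
        v = compute_vmax(resident_track)
        s1 = suggest_s(resident_track, 12.0, v_max=v)
        dilated = resident_track.with_fixes(resident_track.fixes.assign(
            t=resident_track.fixes["t"].iloc[0]
            + 2 * (resident_track.fixes["t"]
                   - resident_track.fixes["t"].iloc[0])))
        # Same physical pairs, twice the separation: s halves.
        s2 = suggest_s(dilated, 24.0, v_max=v)
        assert s2 == pytest.approx(s1 / 2, rel=1e-9)

    def test_stationary_track_clamps_with_warning(self, traj_factory):
        tr = traj_factory([[0.0, 0.0]] * 120, np.arange(120) * 6300.0)
        with pytest.warns(UserWarning):
            assert suggest_s(tr, v_max=1.0) == 0.001

    def test_fox_like_track_in_plausible_range(self, resident_track):
        s = suggest_s(resident_track)
        assert 0.005 <= s <= 0.2
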