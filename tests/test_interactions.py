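import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from sympatry.errors import DegenerateError, ValidationError
from sympatry.interactions import (classify_dyad, find_dyads, l_ixn_from_odds,
                                   minta_spatial, minta_temporal,
                                   overlap_index, simultaneous_pairs)
from sympatry.synthetic import SimConfig, simulate_dyad


class TestFindDyads:
    def test_overlapping_ranges_pair_at_distance_zero(self):
        ranges = {"a": box(0, 0, 10, 10), "b": box(5, 5, 15, 15)}
        dyads = find_dyads(ranges, threshold=3200.0)
        assert len(dyads) == 1 and dyads[0].boundary_distance == 0.0

    def test_neighbour_rule_is_strict(self):
        ranges = {"a": box(0, 0, 1000, 1000),
                  "b": box(4300, 0, 5300, 1000)}  # boundaries 3300 m apart
        assert find_dyads(ranges, threshold=3200.0) == []
        assert len(find_dyads(ranges, threshold=3400.0)) == 1

    def test_three_mutual_neighbours_give_three_dyads(self):
        ranges = {k: box(i * 500, 0, i * 500 + 1000, 1000)
                  for i, k in enumerate("abc")}
        dyads = find_dyads(ranges, threshold=3200.0,
                           species={"a": "AF", "b": "RF", "c": "AF"})
        assert len(dyads) == 3
        assert {d.pair_type for d in dyads} == {"AF-RF", "AF-AF"}


class TestOverlapIndex:
    def test_identical_polygons(self):
        p = box(0, 0, 10, 10)
        assert overlap_index(p, p) == pytest.approx(1.0)

    def test_disjoint_polygons(self):
        assert overlap_index(box(0, 0, 1, 1), box(5, 5, 6, 6)) == 0.0

    def test_symmetry(self):
        a, b = box(0, 0, 10, 10), box(5, 0, 20, 10)
        assert overlap_index(a, b) == pytest.approx(overlap_index(b, a))

    def test_directed_fractions_geometric_mean(self):
        # Directed fractions 0.25 and 0.31 give the published 0.28 index.
        a = box(0.0, 0.0, 1.0, 1.0)
        b = box(-(0.25 / 0.31 - 0.25), 0.0, 0.25, 1.0)
        idx = overlap_index(a, b)
        assert idx == pytest.approx(math.sqrt(0.25 * 0.31), abs=1e-9)
        assert round(idx, 2) == 0.28

    def test_bounded_by_larger_directed_fraction(self):
        a, b = box(0, 0, 10, 10), box(8, 0, 30, 10)
        shared = a.intersection(b).area
        assert overlap_index(a, b) <= max(shared / a.area, shared / b.area)

    def test_zero_area_rejected(self):
        with pytest.raises(ValidationError):
            overlap_index(box(0, 0, 1, 1), Point(0, 0).buffer(0))


def track(times_min, traj_factory):
    times = np.asarray(times_min, dtype=float) * 60.0
    return traj_factory(np.zeros((times.size, 2)), times)


class TestSimultaneousPairs:
    def test_identical_schedules_pair_everything(self, traj_factory):
        a = track(np.arange(10) * 105, traj_factory)
        pairs = simultaneous_pairs(a, a, buffer=300.0)
        assert pairs.shape == (10, 2)
        assert (pairs[:, 0] == pairs[:, 1]).all()

    def test_six_minute_offset_pairs_nothing(self, traj_factory):
        a = track(np.arange(10) * 105, traj_factory)
        b = track(np.arange(10) * 105 + 6, traj_factory)
        assert simultaneous_pairs(a, b, buffer=300.0).shape[0] == 0

    def test_greedy_matching_oracle(self, traj_factory):
        a = track([0, 120, 240], traj_factory)
        b = track([2, 119, 360], traj_factory)
        pairs = simultaneous_pairs(a, b, buffer=300.0)
        assert pairs.tolist() == [[0, 0], [1, 1]]

    def test_pairs_are_disjoint_and_bounded(self, traj_factory):
        rng = np.random.default_rng(0)
        a = track(np.sort(rng.uniform(0, 5000, 80)), traj_factory)
        b = track(np.sort(rng.uniform(0, 5000, 60)), traj_factory)
        pairs = simultaneous_pairs(a, b, buffer=300.0)
        assert pairs.shape[0] <= 60
        assert np.unique(pairs[:, 0]).size == pairs.shape[0]
        assert np.unique(pairs[:, 1]).size == pairs.shape[0]
        ta, tb = a.t_seconds, b.t_seconds
        assert np.all(np.abs(ta[pairs[:, 0]] - tb[pairs[:, 1]]) <= 300.0)


class TestMintaSpatial:
    def hr(self):
        return box(0, 0, 100, 100)

    def shared(self, q):
        return box(0, 0, 100 * q, 100)

    def fixes(self, k, m, q, traj_factory):
        xy = np.r_[np.tile([50.0 * q, 50.0], (k, 1)),
                   np.tile([100.0 * q + 1.0, 50.0], (m, 1))]
        return traj_factory(xy, np.arange(k + m) * 3600.0)

    def test_area_proportional_use_is_zero(self, traj_factory):
        tr = self.fixes(25, 75, 0.25, traj_factory)
        res = minta_spatial(tr, self.hr(), self.shared(0.25))
        assert res.L == pytest.approx(0.0)
        assert res.response == "random"

    def test_hand_arithmetic_ln_three(self, traj_factory):
        tr = self.fixes(50, 50, 0.25, traj_factory)
        res = minta_spatial(tr, self.hr(), self.shared(0.25))
        assert res.L == pytest.approx(math.log(3.0))
        assert res.p < 0.05 and res.response == "attraction"

    def test_balanced_half_share_is_null(self, traj_factory):
        tr = self.fixes(40, 40, 0.5, traj_factory)
        res = minta_spatial(tr, self.hr(), self.shared(0.5))
        assert res.L == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_empty_shared_use_gives_sentinel(self, traj_factory):
        tr = self.fixes(0, 60, 0.25, traj_factory)
        res = minta_spatial(tr, self.hr(), self.shared(0.25))
        assert res.L == -math.inf
        assert res.p < 0.05 and res.response == "avoidance"

    def test_no_in_range_fixes_is_degenerate(self, traj_factory):
        tr = traj_factory([[1e6, 1e6]] * 5, np.arange(5) * 3600.0)
        with pytest.raises(DegenerateError):
            minta_spatial(tr, self.hr(), self.shared(0.25))


class TestMintaTemporal:
    def from_counts(self, n_ab, n_a0, n_0b, n_00, **kw):
        a = np.r_[np.ones(n_ab + n_a0), np.zeros(n_0b + n_00)].astype(bool)
        b = np.r_[np.ones(n_ab), np.zeros(n_a0),
                  np.ones(n_0b), np.zeros(n_00)].astype(bool)
        return minta_temporal(a, b, **kw)

    def test_observed_equal_expected_is_zero(self):
        res = self.from_counts(25, 25, 25, 25)
        np.testing.assert_allclose(res.table.odds, 1.0)
        assert res.L_ixn == pytest.approx(0.0)
        assert res.label == "random"

    def test_hand_arithmetic_ln_four(self):
        res = self.from_counts(40, 10, 10, 40)
        np.testing.assert_allclose(res.table.odds, [1.6, 0.4, 0.4, 1.6])
        assert res.L_ixn == pytest.approx(math.log(4.0))
        assert res.p < 0.05 and res.label == "simultaneous"

    def test_published_odds_reconstruction(self):
        # The strongly cohesive male pair: odds 33, 3.66, 3.83, 0.34.
        assert l_ixn_from_odds(33.0, 3.66, 3.83, 0.34) == pytest.approx(
            1.49, abs=0.005)

    def test_cell_counts_partition_and_probs_sum(self):
        res = self.from_counts(7, 13, 21, 9)
        t = res.table
        assert t.n_ab + t.n_a0 + t.n_0b + t.n_00 == t.n
        assert t.p_ab + t.p_a0 + t.p_0b + t.p_00 == pytest.approx(1.0)

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateError):
            minta_temporal(np.ones(10, bool), np.r_[np.ones(5),
                                                    np.zeros(5)].astype(bool))

    def test_zero_denominator_sentinel(self):
        res = self.from_counts(30, 0, 0, 30)
        assert res.L_ixn == math.inf
        assert res.label == "simultaneous"

    def test_rotation_p_reproducible(self):
        r1 = self.from_counts(40, 10, 10, 40, p_method="rotation",
                              n_rotations=199, rng=5)
        r2 = self.from_counts(40, 10, 10, 40, p_method="rotation",
                              n_rotations=199, rng=5)
        assert r1.p == r2.p
        assert r1.p >= 1 / 200


class TestClassifyDyad:
    def spatial(self, response):
        from sympatry.interactions import SpatialResult
        sig = response != "random"
        return SpatialResult(1.0 if response == "attraction" else -1.0,
                             0.01 if sig else 0.5, 100, 30, 0.2, response)

    def temporal(self, label):
        from sympatry.interactions import ContingencyTable, TemporalResult
        t = ContingencyTable(100, 25, 25, 25, 25, .25, .25, .25, .25)
        return TemporalResult(1.0, 0.01, t, label)

    @pytest.mark.parametrize("ra,rb,expected", [
        ("attraction", "attraction", "symmetric attraction"),
        ("avoidance", "avoidance", "symmetric avoidance"),
        ("attraction", "avoidance", "asymmetric"),
        ("random", "avoidance", "singular avoidance"),
        ("attraction", "random", "singular attraction"),
        ("random", "random", "random"),
    ])
    def test_spatial_labels(self, ra, rb, expected):
        label, _ = classify_dyad(self.spatial(ra), self.spatial(rb),
                                 self.temporal("simultaneous"))
        assert label == expected

    def test_temporal_label_passes_through(self):
        _, label = classify_dyad(self.spatial("random"),
                                 self.spatial("random"),
                                 self.temporal("solitary trend"))
        assert label == "solitary trend"


class TestRegimeRecovery:
    """Small-sample sign recovery; the full calibration lives in the
    acceptance suite."""

    @pytest.mark.parametrize("regime,sign", [("cohesive", 1),
                                             ("exclusive", -1)])
    def test_coupled_regimes_recover_sign(self, regime, sign):
        from shapely.geometry import Point
        from sympatry.interactions import _covers_mask
        hits = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, regime=regime)
            a, b, truth = simulate_dyad(cfg)
            shared = Point(truth["shared_center"]).buffer(
                truth["shared_radius"])
            pairs = simultaneous_pairs(a, b)
            res = minta_temporal(_covers_mask(shared, a.xy[pairs[:, 0]]),
                                 _covers_mask(shared, b.xy[pairs[:, 1]]))
            hits += (np.sign(res.L_ixn) == sign)
        assert hits >= 19
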