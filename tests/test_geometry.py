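import math

import numpy as np
import pandas as pd
import pytest

from aedplace.geometry import (CandidateSet, DemandPoint, HourlyDemand,
                               LocalTransverseMercator, compute_sample_size,
                               coverage_sets, demands_from_table,
                               jitter_visitors, pairwise_distances,
                               project_coordinates, sample_demand,
                               walking_radius)


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        d = HourlyDemand(0, [DemandPoint("p", 0, 0)])
        c = CandidateSet(["c"], [3.0], [4.0])
        assert pairwise_distances(d, c).loc["p", "c"] == pytest.approx(5.0)

    def test_coincident_points_have_zero_distance(self):
        d = HourlyDemand(0, [DemandPoint("p", 7, 2)])
        c = CandidateSet(["c"], [7.0], [2.0])
        assert pairwise_distances(d, c).loc["p", "c"] == 0.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        di = rng.uniform(0, 1000, size=(20, 2))
        dj = rng.uniform(0, 1000, size=(10, 2))
        d = HourlyDemand(0, [DemandPoint(i, *di[i]) for i in range(20)])
        c = CandidateSet(list(range(10)), dj[:, 0], dj[:, 1])
        table = pairwise_distances(d, c).to_numpy()
        for i in range(20):
            for j in range(10):
                naive = math.dist(di[i], dj[j])
                assert table[i, j] == pytest.approx(naive, abs=1e-9)

    def test_empty_inputs_rejected(self):
        c = CandidateSet(["c"], [0.0], [0.0])
        with pytest.raises(ValueError):
            pairwise_distances(HourlyDemand(0, []), c)


class TestCoverageSets:
    def test_toy_line_fixture(self, toy_demand, toy_candidates):
        cov = coverage_sets(toy_demand, toy_candidates, 100.0)
        assert dict(cov.cover_sets) == {"P1": {"C1"}, "P2": {"C1"},
                                        "P3": {"C2"}, "P4": {"C2"}}

    def test_boundary_distance_is_covered(self):
        d = HourlyDemand(0, [DemandPoint("p", 0, 0)])
        c = CandidateSet(["c"], [100.0], [0.0])
        cov = coverage_sets(d, c, 100.0)
        assert cov.cover_sets["p"] == {"c"}

    def test_boundary_perturbation_flips_exactly_one_membership(self):
        S = 100.0
        eps = 1e-6
        d = HourlyDemand(0, [DemandPoint("p", 0, 0)])
        c_out = CandidateSet(["a", "b"], [S + eps, 50.0], [0.0, 0.0])
        c_in = CandidateSet(["a", "b"], [S - eps, 50.0], [0.0, 0.0])
        assert coverage_sets(d, c_out, S).cover_sets["p"] == {"b"}
        assert coverage_sets(d, c_in, S).cover_sets["p"] == {"a", "b"}

    def test_equals_filtered_bruteforce_table(self):
        rng = np.random.default_rng(7)
        d = HourlyDemand(0, [DemandPoint(i, *rng.uniform(0, 500, 2))
                             for i in range(25)])
        c = CandidateSet(list(range(8)), rng.uniform(0, 500, 8),
                         rng.uniform(0, 500, 8))
        S = float(rng.uniform(50, 400))
        cov = coverage_sets(d, c, S)
        dist = pairwise_distances(d, c)
        for i in d.ids():
            expected = {j for j in c.ids if dist.loc[i, j] <= S}
            assert cov.cover_sets[i] == expected

    def test_nonpositive_radius_rejected(self, toy_demand, toy_candidates):
        with pytest.raises(ValueError):
            coverage_sets(toy_demand, toy_candidates, 0.0)


class TestJitter:
    def _table(self, count, hour=0):
        return pd.DataFrame({"poi_id": ["a"], "x": [100.0], "y": [200.0],
                             "hour": [hour], "visits": [count]})

    def test_zero_radius_reproduces_poi_location(self):
        out = jitter_visitors(self._table(5), 0.0, np.random.default_rng(0))
        pts = out[0].points
        assert len(pts) == 5
        assert all(p.x == 100.0 and p.y == 200.0 and p.weight == 1.0 for p in pts)

    def test_containment_and_mean_radius_of_uniform_disc(self):
        R = 414.3
        out = jitter_visitors(self._table(20000), R, np.random.default_rng(1))
        pts = out[0].coords() - [100.0, 200.0]
        r = np.hypot(pts[:, 0], pts[:, 1])
        assert (r <= R + 1e-9).all()
        # uniform disc: E[r] = 2R/3
        assert r.mean() == pytest.approx(2 * R / 3, rel=0.01)

    def test_zero_count_emits_nothing(self):
        out = jitter_visitors(self._table(0), 100.0, np.random.default_rng(0))
        assert len(out[0]) == 0

    def test_count_conservation_per_period(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({
            "poi_id": [f"poi{i}" for i in range(6)] * 2,
            "x": np.tile(rng.uniform(0, 1000, 6), 2),
            "y": np.tile(rng.uniform(0, 1000, 6), 2),
            "hour": [0] * 6 + [1] * 6,
            "visits": rng.integers(0, 30, 12),
        })
        out = jitter_visitors(table, 50.0, rng)
        for h in (0, 1):
            assert len(out[h]) == table.loc[table.hour == h, "visits"].sum()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            jitter_visitors(self._table(-1), 10.0, np.random.default_rng(0))


class TestSampling:
    def _demand(self, n):
        return HourlyDemand(0, [DemandPoint(i, float(i), 0.0) for i in range(n)])

    def test_full_fraction_is_identity(self):
        d = self._demand(10)
        out = sample_demand(d, fraction=1.0, rng=np.random.default_rng(0))
        assert out.ids() == d.ids()

    def test_zero_n_is_empty(self):
        out = sample_demand(self._demand(10), n=0, rng=np.random.default_rng(0))
        assert len(out) == 0

    def test_equal_seeds_reproduce_and_fraction_is_floor(self):
        d = self._demand(10_000)
        a = sample_demand(d, fraction=1 / 6, rng=np.random.default_rng(5))
        b = sample_demand(d, fraction=1 / 6, rng=np.random.default_rng(5))
        assert a.ids() == b.ids()
        assert len(a) == 10_000 // 6
        c = sample_demand(d, fraction=1 / 6, rng=np.random.default_rng(6))
        assert c.ids() != a.ids()

    def test_inclusion_probability_is_uniform(self):
        d = self._demand(300)
        hits = np.zeros(300)
        for seed in range(100):
            s = sample_demand(d, fraction=1 / 6, rng=np.random.default_rng(seed))
            hits[[p.id for p in s.points]] += 1
        # each point should appear in about 1/6 of samples
        assert hits.mean() / 100 == pytest.approx(1 / 6, rel=0.05)

    def test_oversized_n_rejected(self):
        with pytest.raises(ValueError):
            sample_demand(self._demand(3), n=4, rng=np.random.default_rng(0))


class TestScalarHelpers:
    @pytest.mark.parametrize("total,days,divisor,expected", [
        (134_850_972, 365, 6, 61_575),
        (2_190, 365, 6, 1),
        (2_189, 365, 6, 0),
    ])
    def test_sample_size_truncates_toward_zero(self, total, days, divisor, expected):
        assert compute_sample_size(total, days, divisor) == expected

    def test_sample_size_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_sample_size(0)
        with pytest.raises(ValueError):
            compute_sample_size(100, days=-1)

    @pytest.mark.parametrize("speed,minutes,expected", [
        (138.10, 5, 414.3),
        (100.0, 1, 60.0),
        (0.0, 30, 0.0),
    ])
    def test_walking_radius(self, speed, minutes, expected):
        assert walking_radius(speed, minutes) == expected

    def test_walking_radius_rejects_negative(self):
        with pytest.raises(ValueError):
            walking_radius(-1, 5)


class TestProjection:
    def test_small_latitude_offset_maps_to_meters(self):
        frame = pd.DataFrame({"site_id": ["a", "b"],
                              "lon": [-77.0, -77.0], "lat": [38.9, 38.901]})
        out, proj = project_coordinates(frame)
        planar = math.dist((out.x[0], out.y[0]), (out.x[1], out.y[1]))
        # spherical great-circle oracle for a pure-latitude offset
        oracle = math.radians(0.001) * 6_371_008.8
        assert planar == pytest.approx(oracle, rel=0.01)
        assert planar == pytest.approx(111.3, rel=0.01)

    def test_round_trip_within_1e6_degrees(self):
        rng = np.random.default_rng(11)
        lon = -77 + rng.uniform(-0.2, 0.2, 50)
        lat = 38.9 + rng.uniform(-0.2, 0.2, 50)
        proj = LocalTransverseMercator(-77.0, 38.9)
        x, y = proj.forward(lon, lat)
        lon2, lat2 = proj.inverse(x, y)
        assert np.abs(lon2 - lon).max() < 1e-6
        assert np.abs(lat2 - lat).max() < 1e-6

    def test_identical_inputs_identical_outputs(self):
        frame = pd.DataFrame({"lon": [-77.0, -77.0], "lat": [38.9, 38.9]})
        out, _ = project_coordinates(frame)
        assert out.x[0] == out.x[1] and out.y[0] == out.y[1]

    def test_projected_flag_passes_through(self):
        frame = pd.DataFrame({"x": [1.0], "y": [2.0]})
        out, proj = project_coordinates(frame, projected=True)
        assert proj is None
        assert out.x[0] == 1.0 and out.y[0] == 2.0

    def test_out_of_range_rejected(self):
        frame = pd.DataFrame({"lon": [200.0], "lat": [0.0]})
        with pytest.raises(ValueError):
            project_coordinates(frame)


class TestCoverageProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n_i=st.integers(1, 12), n_j=st.integers(1, 6),
           S=st.floats(10.0, 500.0), seed=st.integers(0, 2**31 - 1))
    def test_coverage_sets_equal_bruteforce_filter(self, n_i, n_j, S, seed):
        """N_i always equals filtering the naive distance table at d <= S."""
        rng = np.random.default_rng(seed)
        d = HourlyDemand(0, [DemandPoint(i, *rng.uniform(0, 600, 2))
                             for i in range(n_i)])
        c = CandidateSet(list(range(n_j)), rng.uniform(0, 600, n_j),
                         rng.uniform(0, 600, n_j))
        cov = coverage_sets(d, c, S)
        for p in d.points:
            expected = {j for j in c.ids
                        if math.dist((p.x, p.y),
                                     (c.xs[c.ids.index(j)],
                                      c.ys[c.ids.index(j)])) <= S}
            assert cov.cover_sets[p.id] == expected


class TestDemandsFromTable:
    def test_aggregate_mode_weights_by_count(self):
        table = pd.DataFrame({"poi_id": ["a", "b"], "x": [0.0, 1.0],
                              "y": [0.0, 0.0], "hour": [0, 0],
                              "visits": [3, 5]})
        out = demands_from_table(table, jitter=False)
        assert out[0].total_weight == 8.0
        assert len(out[0]) == 2
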