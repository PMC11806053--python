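import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from benthocur import geo
from _oracles import brute_haversine, brute_pairwise, brute_single_linkage

R = geo.EARTH_RADIUS_M


class TestHaversine:
    @pytest.mark.parametrize("a,b,expected", [
        ((12.3, -45.6), (12.3, -45.6), 0.0),
        ((0.0, 0.0), (0.0, 1.0), math.pi * R / 180.0),       # one equator degree
        ((0.0, 0.0), (90.0, 0.0), math.pi * R / 2.0),        # pole quadrant
    ])
    def test_closed_forms(self, a, b, expected):
        assert geo.haversine_m(a[0], a[1], b[0], b[1]) == pytest.approx(
            expected, abs=1e-6)

    @given(st.lists(st.tuples(st.floats(-80, 80), st.floats(-179, 179)),
                    min_size=3, max_size=3))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_triangle_inequality(self, pts):
        (a, b, c) = pts
        dab = geo.haversine_m(a[0], a[1], b[0], b[1])
        dba = geo.haversine_m(b[0], b[1], a[0], a[1])
        dac = geo.haversine_m(a[0], a[1], c[0], c[1])
        dcb = geo.haversine_m(c[0], c[1], b[0], b[1])
        assert dab == pytest.approx(dba, abs=1e-6)
        assert dab <= dac + dcb + 1e-6

    def test_agrees_with_scalar_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.uniform([-80, -179], [80, 179])
            b = a + rng.uniform(-0.01, 0.01, 2)
            assert geo.haversine_m(*a, *b) == pytest.approx(
                brute_haversine(*a, *b), rel=1e-9)


class TestThresholdClusters:
    def test_coincident_points_form_one_cluster(self):
        lat = np.full(10, 44.5)
        lon = np.full(10, -63.5)
        assert set(geo.threshold_clusters(lat, lon, 1000.0)) == {0}

    def test_two_blobs_5km_apart(self):
        from conftest import metres_to_deg
        rng = np.random.default_rng(3)
        east = np.concatenate([rng.uniform(0, 50, 10),
                               5000 + rng.uniform(0, 50, 10)])
        north = rng.uniform(0, 50, 20)
        dlat, dlon = metres_to_deg(44.5, east, north)
        ids = geo.threshold_clusters(44.5 + dlat, -63.5 + dlon, 1000.0)
        assert len(set(ids)) == 2
        assert len(set(ids[:10])) == 1 and len(set(ids[10:])) == 1

    def test_chain_links_into_one_cluster(self):
        # 900 m steps chain together below a 1000 m threshold
        from conftest import metres_to_deg
        east = np.arange(11) * 900.0
        dlat, dlon = metres_to_deg(44.5, east, np.zeros(11))
        ids = geo.threshold_clusters(44.5 + dlat, -63.5 + dlon, 1000.0)
        assert set(ids) == {0}

    def test_matches_brute_force_union_find(self):
        from conftest import random_points
        rng = np.random.default_rng(11)
        lat, lon = random_points(rng, 120, extent_m=800.0)
        for thr in (50.0, 100.0, 300.0):
            ours = geo.threshold_clusters(lat, lon, thr)
            ref = brute_single_linkage(lat, lon, thr)
            # same partition up to relabelling
            assert len(set(ours)) == len(set(ref))
            mapping = {}
            for a, b in zip(ours, ref):
                assert mapping.setdefault(a, b) == b

    def test_order_invariance(self):
        from conftest import random_points
        rng = np.random.default_rng(4)
        lat, lon = random_points(rng, 60, extent_m=500.0)
        base = geo.threshold_clusters(lat, lon, 120.0)
        perm = rng.permutation(60)
        shuf = geo.threshold_clusters(lat[perm], lon[perm], 120.0)
        mapping = {}
        for a, b in zip(base[perm], shuf):
            assert mapping.setdefault(a, b) == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            geo.threshold_clusters([], [], 100.0)

    def test_subsite_counts(self):
        from conftest import metres_to_deg
        # three blobs pairwise >= 150 m apart -> 3 subsites at the 100 m rule
        east = np.array([0.0, 1.0, 150.0, 151.0, 300.0, 301.0])
        dlat, dlon = metres_to_deg(44.5, east, np.zeros(6))
        assert geo.count_subsites(44.5 + dlat, -63.5 + dlon) == 3
        # two blobs 50 m apart merge into one subsite
        east = np.array([0.0, 1.0, 50.0, 51.0])
        dlat, dlon = metres_to_deg(44.5, east, np.zeros(4))
        assert geo.count_subsites(44.5 + dlat, -63.5 + dlon) == 1


class TestMeanCentre:
    def test_single_point_and_symmetry(self):
        assert geo.mean_centre([10.0], [20.0]) == (10.0, 20.0)
        assert geo.mean_centre([-1.0, 1.0], [30.0, 30.0]) == (0.0, 30.0)
        assert geo.mean_centre([10.0, 12.0], [20.0, 22.0]) == (11.0, 21.0)

    def test_empty_and_antimeridian_rejected(self):
        with pytest.raises(ValueError):
            geo.mean_centre([], [])
        with pytest.raises(ValueError):
            geo.mean_centre([0.0, 0.0], [-179.0, 179.0])


class TestNeighbourIndex:
    def test_zero_radius_hits_coincident_point(self):
        idx = geo.NeighbourIndex([44.5, 44.6], [-63.5, -63.4])
        assert list(idx.query_radius(44.5, -63.5, 0.0)) == [0]

    def test_empty_index(self):
        idx = geo.NeighbourIndex([], [])
        assert idx.query_radius(0.0, 0.0, 100.0).size == 0

    @pytest.mark.parametrize("r", [0.625, 50.0, 100.0, 1000.0])
    def test_equals_brute_force_scan(self, r):
        from conftest import random_points
        rng = np.random.default_rng(int(r * 16))
        lat, lon = random_points(rng, 2000, extent_m=3000.0)
        idx = geo.NeighbourIndex(lat, lon)
        d = brute_pairwise(lat, lon)
        for q in rng.choice(2000, size=25, replace=False):
            got = set(idx.query_radius(lat[q], lon[q], r))
            ref = set(np.flatnonzero(d[q] <= r))
            assert got == ref
            # returned order is ascending by distance
            order = idx.query_radius(lat[q], lon[q], r)
            dd = [geo.haversine_m(lat[q], lon[q], lat[i], lon[i])
                  for i in order]
            assert dd == sorted(dd)


class TestGeoGrid:
    def test_nearest_stratum_on_cell_centre(self, small_grid):
        assert geo.nearest_stratum([40.25], [-63.75], small_grid)[0] == 11.0

    def test_nearest_stratum_matches_brute_force(self, small_grid):
        rng = np.random.default_rng(9)
        lat = rng.uniform(39.9, 41.2, 40)
        lon = rng.uniform(-64.1, -63.1, 40)
        glat, glon = small_grid.cell_centres()
        valid = ~small_grid.mask
        got = geo.nearest_stratum(lat, lon, small_grid)
        for k in range(40):
            d = brute_pairwise(
                np.append(glat[valid], lat[k]),
                np.append(glon[valid], lon[k]))[-1, :-1]
            assert got[k] == small_grid.values[valid][np.argmin(d)]

    def test_masked_cell_never_assigned(self, small_grid):
        # query exactly on the masked cell centre -> some valid neighbour
        got = geo.nearest_stratum([40.5], [-63.5], small_grid)[0]
        assert got != 22.0 and np.isfinite(got)

    def test_all_masked_rejected(self):
        g = geo.GeoGrid(0.0, 0.0, 1.0, np.full((2, 2), np.nan))
        with pytest.raises(ValueError):
            geo.nearest_stratum([0.0], [0.0], g)

    def test_ascii_round_trip(self, small_grid, tmp_path):
        p = tmp_path / "grid.asc"
        small_grid.write_ascii(p)
        back = geo.GeoGrid.read_ascii(p)
        assert back.cell_size == small_grid.cell_size
        assert back.origin_lat == small_grid.origin_lat
        assert np.array_equal(back.mask, small_grid.mask)
        assert np.allclose(back.values[~back.mask],
                           small_grid.values[~small_grid.mask])


class TestBilinear:
    def test_node_and_centre_values(self, small_grid):
        # at a grid node: the node value
        assert geo.bilinear_depth(small_grid, 40.25, -63.75) == 11.0
        # at a cell centre: mean of the four corners
        v = geo.bilinear_depth(small_grid, 40.125, -63.875)
        assert v == pytest.approx((0 + 1 + 10 + 11) / 4)

    def test_constant_grid_is_constant(self):
        g = geo.GeoGrid(0.0, 0.0, 0.5, np.full((4, 4), 7.5))
        rng = np.random.default_rng(2)
        for _ in range(10):
            lat, lon = rng.uniform(0, 1.5, 2)
            assert geo.bilinear_depth(g, lat, lon) == pytest.approx(7.5)

    def test_outside_extent_and_masked_corner_rejected(self, small_grid):
        with pytest.raises(ValueError):
            geo.bilinear_depth(small_grid, 39.0, -63.5)
        with pytest.raises(ValueError):
            geo.bilinear_depth(small_grid, 40.4, -63.4)  # cell with mask corner
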