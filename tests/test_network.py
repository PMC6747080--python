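"""Network construction, snapping, lixels and exact network distances."""

import numpy as np
import pytest
from conftest import (
    enumerate_path_distance,
    make_grid,
    oracle_distance_matrix,
    random_network,
    random_points,
)

from netpatterns import (
    NetworkPoint,
    NetworkPointSet,
    build_network,
    clip_network,
    largest_component,
    lixelize,
    network_distance,
    point_distance_matrix,
    snap_to_network,
)


class TestBuildNetwork:
    def test_unit_square(self, square_net):
        assert square_net.n_nodes == 4
        assert square_net.n_edges == 4
        assert square_net.total_length == pytest.approx(400.0)

    def test_edge_lengths_match_geometry(self, square_net):
        for e, geom in enumerate(square_net.edge_geometries):
            assert square_net.edge_lengths[e] == pytest.approx(
                geom.length, rel=1e-6
            )

    def test_endpoint_merge_within_tolerance(self):
        net = build_network(
            [[(0, 0), (100, 0)], [(100.005, 0.005), (200, 0)]],
            node_snap_tolerance=0.01,
        )
        assert net.n_nodes == 3
        assert net.n_edges == 2

    def test_grid_total_length(self):
        # n x n grid has 2 n (n-1) edges of one spacing each
        net = make_grid(10, 100.0)
        assert net.n_edges == 2 * 10 * 9
        assert net.total_length == pytest.approx(18_000.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network([])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            build_network([[(0, 0), (np.nan, 100)]])

    def test_geographic_coordinates_rejected(self):
        with pytest.raises(ValueError, match="geographic"):
            build_network([[(113.9, 22.5), (114.1, 22.6)]])


class TestLargestComponent:
    def test_connected_network_unchanged(self, square_net):
        sub = largest_component(square_net)
        assert sub.total_length == pytest.approx(400.0)
        assert sub.dropped_length == 0.0

    def test_disjoint_segment_dropped(self):
        net = build_network(
            [
                [(0, 0), (100, 0)],
                [(100, 0), (100, 100)],
                [(100, 100), (0, 100)],
                [(0, 100), (0, 0)],
                [(500, 500), (550, 500)],
            ]
        )
        sub = largest_component(net)
        assert sub.total_length == pytest.approx(400.0)
        assert sub.dropped_length == pytest.approx(50.0)

    def test_tie_keeps_lowest_node_id(self):
        # two disjoint 100 m segments: exact tie in length
        net = build_network([[(0, 0), (100, 0)], [(500, 500), (600, 500)]])
        sub = largest_component(net)
        assert sub.n_edges == 1
        assert tuple(sub.node_coords[0]) == (0.0, 0.0)


class TestSnap:
    def test_perpendicular_projection(self, square_net):
        pts, report = snap_to_network(square_net, [(50.0, 5.0)])
        assert len(pts) == 1
        assert pts.offsets[0] == pytest.approx(50.0)
        assert pts.snap_distances[0] == pytest.approx(5.0)
        assert report.n_excluded == 0

    def test_equidistant_tie_lower_edge_id(self, square_net):
        # center of the square is 50 m from all four edges
        pts, _ = snap_to_network(square_net, [(50.0, 50.0)])
        assert pts.edge_ids[0] == 0

    def test_beyond_max_distance_excluded(self, square_net):
        with pytest.warns(UserWarning, match="excluded"):
            pts, report = snap_to_network(
                square_net, [(50.0, 5.0), (50.0, 700.0)], max_snap_distance=500.0
            )
        assert len(pts) == 1
        assert report.n_excluded == 1
        assert list(report.excluded_indices) == [1]

    def test_all_beyond_gives_empty_set_not_error(self, square_net):
        with pytest.warns(UserWarning):
            pts, report = snap_to_network(
                square_net, [(5000.0, 5000.0)], max_snap_distance=100.0
            )
        assert len(pts) == 0
        assert report.n_excluded == 1

    def test_weights_and_labels_carried(self, square_net):
        pts, _ = snap_to_network(
            square_net, [(50, 5), (95, 50)], weights=[2.0, 3.0], labels=["a", "b"]
        )
        assert list(pts.weights) == [2.0, 3.0]
        assert pts.labels == ["a", "b"]


class TestLixelize:
    def test_ceil_split(self):
        net = build_network([[(0, 0), (250, 0)]])
        lix = lixelize(net, 100.0)
        assert len(lix) == 3
        np.testing.assert_allclose(lix.lengths, 250.0 / 3)
        np.testing.assert_allclose(
            lix.centers.offsets, [250 / 6, 125.0, 250 * 5 / 6]
        )

    def test_exact_fit_single_lixel(self):
        net = build_network([[(0, 0), (100, 0)]])
        lix = lixelize(net, 100.0)
        assert len(lix) == 1
        assert lix.centers.offsets[0] == pytest.approx(50.0)

    def test_conserves_total_length(self, square_net):
        lix = lixelize(square_net, 100.0)
        assert lix.lengths.sum() == pytest.approx(square_net.total_length, rel=1e-9)

    def test_random_networks_conserve_length(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            net = random_network(rng)
            lix = lixelize(net, 73.0)
            assert lix.lengths.sum() == pytest.approx(net.total_length, rel=1e-6)
            # per-edge tiling has no gaps or overlaps
            for e in range(net.n_edges):
                mask = lix.edge_ids == e
                starts = np.sort(lix.start_offsets[mask])
                ends = np.sort(lix.end_offsets[mask])
                assert starts[0] == 0.0
                assert ends[-1] == pytest.approx(net.edge_lengths[e])
                np.testing.assert_allclose(starts[1:], ends[:-1])

    def test_nonpositive_length_rejected(self, square_net):
        with pytest.raises(ValueError):
            lixelize(square_net, 0.0)


class TestNetworkDistance:
    def test_same_edge(self, square_net):
        src = NetworkPoint(edge_id=0, offset=20.0)
        targets = NetworkPointSet(square_net, [0], [70.0])
        assert network_distance(square_net, src, targets)[0] == pytest.approx(50.0)

    def test_opposite_corners_use_network_metric(self, square_net):
        src = NetworkPoint(edge_id=0, offset=0.0)  # corner (0,0)
        targets = NetworkPointSet(square_net, [1], [100.0])  # corner (100,100)
        assert network_distance(square_net, src, targets)[0] == pytest.approx(200.0)

    def test_cutoff_omits_far_targets(self, square_net):
        src = NetworkPoint(edge_id=0, offset=0.0)
        targets = NetworkPointSet(square_net, [0, 1], [50.0, 100.0])
        out = network_distance(square_net, src, targets, cutoff=100.0)
        assert set(out) == {0}

    def test_missing_edge_rejected(self, square_net):
        src = NetworkPoint(edge_id=99, offset=0.0)
        with pytest.raises(ValueError):
            network_distance(square_net, src, NetworkPointSet(square_net, [0], [0.0]))

    def test_matches_dijkstra_oracle_on_grid(self):
        net = make_grid(4, 100.0)
        rng = np.random.default_rng(1)
        a = random_points(net, 6, rng)
        b = random_points(net, 7, rng)
        ours = point_distance_matrix(net, a, b)
        oracle = oracle_distance_matrix(net, a, b)
        np.testing.assert_allclose(ours, oracle, rtol=1e-9, atol=1e-9)

    def test_matches_path_enumeration_on_tiny_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            net = random_network(rng, n=2)  # <= 4 nodes
            assert net.n_nodes <= 4
            for _ in range(5):
                ea, eb = rng.integers(0, net.n_edges, 2)
                oa = rng.uniform(0, net.edge_lengths[ea])
                ob = rng.uniform(0, net.edge_lengths[eb])
                pa = NetworkPointSet(net, [ea], [oa])
                pb = NetworkPointSet(net, [eb], [ob])
                ours = point_distance_matrix(net, pa, pb)[0, 0]
                exact = enumerate_path_distance(net, (ea, oa), (eb, ob))
                assert ours == pytest.approx(exact, abs=1e-9)

    def test_metric_properties(self):
        """Symmetry, triangle inequality, and lower bound by planar distance."""
        rng = np.random.default_rng(11)
        n_triples = 0
        for _ in range(4):
            net = random_network(rng)
            pts = random_points(net, 12, rng)
            d = point_distance_matrix(net, pts, pts)
            np.testing.assert_allclose(d, d.T, atol=1e-9)
            coords = pts.coordinates()
            planar = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            assert np.all(d >= planar - 1e-9)
            for _ in range(30):
                i, j, k = rng.integers(0, len(pts), 3)
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
                n_triples += 1
        assert n_triples >= 100


class TestClipNetwork:
    def test_fragments_kept(self, square_net):
        from shapely.geometry import box

        sub = clip_network(square_net, box(-10, -10, 50, 110))
        # left edge whole (100), half of top and bottom edges (50 each)
        assert sub.total_length == pytest.approx(200.0)

    def test_disjoint_polygon_rejected(self, square_net):
        from shapely.geometry import box

        with pytest.raises(ValueError):
            clip_network(square_net, box(1000, 1000, 1100, 1100))
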