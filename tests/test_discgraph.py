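"""Graph construction: normalization, features, encodings, and edge oracles."""
import numpy as np
import pytest
import trimesh

from ivdpipe.discgraph import (
    GraphConfig,
    build_disc_graph,
    center_distance,
    faces_to_edges,
    hypernode_distances,
    laplacian_pe,
    load_graph,
    normalize_coords,
    radius_edges,
    random_walk_pe,
    save_graph,
    undirected_edge_count,
)
from ivdpipe.reconstruction import DiscPointCloud


def undirected_set(edges):
    return {tuple(sorted(e)) for e in np.asarray(edges).reshape(-1, 2)}


class TestNormalizeCoords:
    def test_two_point_line_maps_to_unit_interval(self):
        out, _ = normalize_coords(np.array([[0, 0, 0], [2, 0, 0.0]]))
        np.testing.assert_allclose(out, [[-1, 0, 0], [1, 0, 0]])

    def test_max_abs_coordinate_is_exactly_one(self):
        rng = np.random.default_rng(2)
        out, _ = normalize_coords(rng.normal(size=(50, 3)) * [5, 1, 9])
        assert np.abs(out).max() == pytest.approx(1.0, abs=1e-9)

    def test_aspect_ratio_preserved(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, (200, 3)) * [10.0, 3.0, 10.0]
        out, _ = normalize_coords(pts)

        def ratio(p):
            ext = p.max(axis=0) - p.min(axis=0)
            return ext[1] / ext[0]

        assert ratio(out) == pytest.approx(ratio(pts), abs=1e-9)

    def test_transform_inverts(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 3)) * 7 + 3
        out, tf = normalize_coords(pts)
        np.testing.assert_allclose(out * tf["scale"] + tf["center"], pts, atol=1e-9)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError):
            normalize_coords(np.ones((5, 3)))


class TestCenterDistance:
    def test_matches_brute_force_norms(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(60, 3))
        d = center_distance(pts)
        c = pts.mean(axis=0)
        expected = np.array([np.sqrt(((p - c) ** 2).sum()) for p in pts])
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_symmetric_pair_equidistant_and_centroid_zero(self):
        pts = np.array([[1, 1, 1], [-1, -1, -1], [0, 0, 0.0]])
        d = center_distance(pts)
        assert d[0] == pytest.approx(d[1])
        assert d[2] == pytest.approx(0.0)

    def test_rigid_motion_before_normalization_preserves_distance_profile(self):
        # translation leaves normalized distances unchanged exactly; rotation
        # preserves them up to the single isotropic normalization scale
        # (max-|coordinate| is axis-dependent), so compare after rescaling
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(40, 3))
        d0 = center_distance(normalize_coords(pts)[0])
        shifted = pts + np.array([5.0, -2.0, 1.0])
        np.testing.assert_allclose(center_distance(normalize_coords(shifted)[0]),
                                   d0, atol=1e-9)
        rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        d1 = center_distance(normalize_coords(pts @ rot.T)[0])
        np.testing.assert_allclose(d1 / d1.max(), d0 / d0.max(), atol=1e-6)


class TestHypernodeDistances:
    def test_each_hypernode_has_zero_self_distance(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(30, 3))
        dists, idx = hypernode_distances(pts)
        for col, node in enumerate(idx):
            assert dists[node, col] == pytest.approx(0.0)

    def test_unit_cube_corners_enumerate_known_distances(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        dists, idx = hypernode_distances(corners)
        allowed = {0.0, 1.0, np.sqrt(2), np.sqrt(3)}
        assert set(np.round(np.unique(dists), 12)) <= set(np.round(sorted(allowed), 12))
        assert set(idx) <= set(range(8))

    def test_matches_brute_force_argmin_argmax_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(50, 3))
        dists, idx = hypernode_distances(pts)
        expected_idx = []
        for ax in range(3):
            expected_idx += [int(np.argmin(pts[:, ax])), int(np.argmax(pts[:, ax]))]
        assert list(idx) == expected_idx
        for col, node in enumerate(expected_idx):
            np.testing.assert_allclose(
                dists[:, col], np.linalg.norm(pts - pts[node], axis=1), atol=1e-12
            )

    def test_translation_and_scale_invariance_after_normalization(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(40, 3))
        moved = pts * 3.7 + np.array([1.0, 2.0, -4.0])
        d0, _ = hypernode_distances(normalize_coords(pts)[0])
        d1, _ = hypernode_distances(normalize_coords(moved)[0])
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestRadiusEdges:
    def test_single_pair_inside_radius(self):
        edges = radius_edges(np.array([[0, 0, 0], [0.05, 0, 0.0]]), radius=0.1)
        assert undirected_set(edges) == {(0, 1)}
        assert len(edges) == 2  # symmetric closure

    def test_pair_outside_radius_excluded(self):
        edges = radius_edges(np.array([[0, 0, 0], [0.2, 0, 0.0]]), radius=0.1)
        assert len(edges) == 0

    def test_matches_brute_force_pair_scan_on_200_points(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(-1, 1, (200, 3))
        edges = radius_edges(pts, radius=0.25)
        brute = set()
        for i in range(200):
            for j in range(i + 1, 200):
                if 0 < np.linalg.norm(pts[i] - pts[j]) <= 0.25:
                    brute.add((i, j))
        assert undirected_set(edges) == brute

    def test_degree_cap_limits_neighbourhoods(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-0.1, 0.1, (40, 3))
        capped = radius_edges(pts, radius=0.5, max_degree=3)
        # symmetric closure may raise degree above the cap, but the kept
        # pre-closure adjacency is bounded, so totals shrink sharply
        assert len(capped) < len(radius_edges(pts, radius=0.5))

    def test_no_self_loops(self):
        pts = np.vstack([np.zeros(3), np.zeros(3) + 0.01, np.ones(3)])
        edges = radius_edges(pts, radius=0.1)
        assert (edges[:, 0] != edges[:, 1]).all()


class TestFacesToEdges:
    def test_single_triangle(self):
        assert undirected_set(faces_to_edges([[0, 1, 2]])) == {(0, 1), (1, 2), (0, 2)}

    def test_shared_edge_deduplicated(self):
        edges = faces_to_edges([[0, 1, 2], [1, 2, 3]])
        assert len(undirected_set(edges)) == 5

    def test_icosahedron_has_thirty_edges(self):
        ico = trimesh.creation.icosahedron()
        edges = faces_to_edges(np.asarray(ico.faces))
        assert undirected_edge_count(edges) == 30  # V - E + F = 2 with V=12, F=20

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            faces_to_edges([[0, 1, 5]], n_nodes=3)


class TestLaplacianPE:
    def test_edgeless_graph_encodes_to_zero(self):
        pe = laplacian_pe(np.empty((0, 2), int), n_nodes=5, k=4)
        assert pe.shape == (5, 4)
        assert (pe == 0).all()

    def test_path_graph_matches_dense_eigendecomposition(self):
        edges = np.array([[0, 1], [1, 0], [1, 2], [2, 1]])
        pe = laplacian_pe(edges, 3, k=2)
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        dinv = np.diag(a.sum(1) ** -0.5)
        lap = np.eye(3) - dinv @ a @ dinv
        w, v = np.linalg.eigh(lap)
        for col in range(2):
            ours, ref = pe[:, col], v[:, col + 1]
            agree = min(np.abs(ours - ref).max(), np.abs(ours + ref).max())
            assert agree < 1e-8

    def test_eigenpair_residual_below_tolerance(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-1, 1, (80, 3))
        edges = radius_edges(pts, radius=0.6)
        k = 6
        pe = laplacian_pe(edges, 80, k=k)
        a = np.zeros((80, 80))
        a[edges[:, 0], edges[:, 1]] = 1
        deg = a.sum(1)
        dinv = np.where(deg > 0, deg ** -0.5, 0)
        lap = np.eye(80) - dinv[:, None] * a * dinv[None, :]
        w = np.linalg.eigvalsh(lap)
        assert w.min() > -1e-9 and w.max() < 2 + 1e-9  # spectral range
        nonzero = np.sort(w[w > 1e-8])[:k]
        for col in range(k):
            v = pe[:, col]
            if np.linalg.norm(v) == 0:
                continue
            lam = v @ lap @ v
            assert np.linalg.norm(lap @ v - lam * v) <= 1e-6
            assert abs(lam - nonzero[col]) < 1e-6

    def test_small_component_zero_pads_missing_columns(self):
        edges = np.array([[0, 1], [1, 0]])
        pe = laplacian_pe(edges, 2, k=5)
        assert pe.shape == (2, 5)
        assert (pe[:, 1:] == 0).all()
        assert np.abs(pe[:, 0]).max() > 0


class TestRandomWalkPE:
    def test_isolated_node_self_loops_to_all_ones(self):
        pe = random_walk_pe(np.empty((0, 2), int), 1, steps=4)
        np.testing.assert_allclose(pe, 1.0)

    def test_two_node_path_alternates_return_probability(self):
        edges = np.array([[0, 1], [1, 0]])
        pe = random_walk_pe(edges, 2, steps=6)
        np.testing.assert_allclose(pe[0], [0, 1, 0, 1, 0, 1])

    def test_matches_explicit_matrix_power_oracle(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(-1, 1, (30, 3))
        edges = radius_edges(pts, radius=0.8)
        steps = 8
        pe = random_walk_pe(edges, 30, steps=steps)
        a = np.zeros((30, 30))
        a[edges[:, 0], edges[:, 1]] = 1
        iso = a.sum(1) == 0
        a[iso, iso] = 1
        p = a / a.sum(1, keepdims=True)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)  # row-stochastic
        m = np.eye(30)
        for t in range(steps):
            m = m @ p
            np.testing.assert_allclose(pe[:, t], np.diag(m), atol=1e-9)


class TestBuildDiscGraph:
    def test_feature_matrix_shape_and_finiteness(self, toy_graph):
        assert toy_graph.node_features.shape == (80, 48)
        assert np.isfinite(toy_graph.node_features).all()
        assert toy_graph.label == 3

    def test_same_input_same_config_bit_identical(self, toy_cloud):
        g1 = build_disc_graph(toy_cloud, 2, GraphConfig(radius=0.3))
        g2 = build_disc_graph(toy_cloud, 2, GraphConfig(radius=0.3))
        assert np.array_equal(g1.node_features, g2.node_features)
        assert np.array_equal(g1.edges, g2.edges)

    def test_permuting_points_permutes_graph_consistently(self, toy_cloud):
        rng = np.random.default_rng(14)
        perm = rng.permutation(len(toy_cloud.points))
        permuted = DiscPointCloud(
            toy_cloud.points[perm], "voxel", toy_cloud.intensity[perm],
            toy_cloud.provenance,
        )
        cfg = GraphConfig(radius=0.35)
        g = build_disc_graph(toy_cloud, 3, cfg)
        gp = build_disc_graph(permuted, 3, cfg)
        # geometry-derived columns follow the permutation exactly
        np.testing.assert_allclose(gp.coords, g.coords[perm], atol=1e-12)
        np.testing.assert_allclose(gp.node_features[:, :8], g.node_features[perm, :8],
                                   atol=1e-9)
        # node i of the permuted graph is node perm[i] of the original
        assert undirected_set(np.take(perm, gp.edges)) == undirected_set(g.edges)

    def test_face_edges_concatenated_when_requested(self, toy_cloud):
        faces = np.array([[0, 1, 2], [2, 3, 4]])
        g = build_disc_graph(toy_cloud, 1, GraphConfig(radius=1e-6, use_faces=True),
                             faces=faces)
        assert undirected_set(g.edges) >= undirected_set(faces_to_edges(faces))

    def test_missing_intensity_flagged_and_zero_filled(self):
        rng = np.random.default_rng(15)
        cloud = DiscPointCloud(rng.normal(size=(30, 3)), "ellipsoid")
        g = build_disc_graph(cloud, 4, GraphConfig())
        assert not g.has_intensity
        assert (g.node_features[:, 0] == 0).all()

    def test_serialization_roundtrip(self, toy_graph, tmp_path):
        path = tmp_path / "disc.npz"
        save_graph(toy_graph, path)
        back = load_graph(path)
        assert np.array_equal(back.node_features, toy_graph.node_features)
        assert np.array_equal(back.edges, toy_graph.edges)
        assert back.label == toy_graph.label
        assert back.layout_version == toy_graph.layout_version
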