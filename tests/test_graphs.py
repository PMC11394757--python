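"""Voxel downsampling, radius-graph construction and initial-state
aggregation against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketgnn import nn
from pocketgnn.graphs import (AggregationNet, GraphConfig,
                              aggregate_initial_states, aggregation_pairs,
                              build_radius_graph, voxel_downsample)
from pocketgnn.surface import SurfacePointCloud
from oracles import brute_force_edges, brute_force_voxel


def _cloud(coords, labels=None):
    dirs = np.tile([0.0, 0.0, 1.0], (len(coords), 1))
    c = SurfacePointCloud(np.asarray(coords, dtype=float), dirs)
    if labels is not None:
        c.labels = np.asarray(labels)
    return c


class TestVoxelDownsample:
    def test_all_points_in_one_voxel(self, rng):
        coords = 0.2 + 0.5 * rng.random((8, 3))
        assert len(voxel_downsample(_cloud(coords), 1.0)) == 1

    def test_well_separated_points_all_kept(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 5.0, 0], [0, 0, 5.0]])
        np.testing.assert_array_equal(voxel_downsample(_cloud(coords), 1.0),
                                      np.arange(4))

    def test_matches_bruteforce_hash(self, rng):
        for _ in range(10):
            coords = rng.uniform(0, 5, (100, 3))
            got = voxel_downsample(_cloud(coords), 1.0)
            assert got.tolist() == brute_force_voxel(coords, 1.0)

    def test_zero_voxel_disables_downsampling(self, rng):
        coords = rng.uniform(0, 2, (30, 3))
        np.testing.assert_array_equal(voxel_downsample(_cloud(coords), 0),
                                      np.arange(30))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_larger_voxels_never_increase_count(self, seed):
        coords = np.random.default_rng(seed).uniform(0, 8, (60, 3))
        cloud = _cloud(coords)
        counts = [len(voxel_downsample(cloud, v)) for v in (0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestRadiusGraph:
    def test_pair_below_radius(self):
        edges = build_radius_graph(np.array([[0.0, 0, 0], [3.0, 0, 0]]), 4.0)
        assert edges.tolist() == [[0, 1], [1, 0]]

    def test_pair_above_radius(self):
        edges = build_radius_graph(np.array([[0.0, 0, 0], [5.0, 0, 0]]), 4.0)
        assert len(edges) == 0

    def test_boundary_distance_excluded(self):
        """Edge rule is a strict inequality."""
        edges = build_radius_graph(np.array([[0.0, 0, 0], [4.0, 0, 0]]), 4.0)
        assert len(edges) == 0

    def test_matches_allpairs_oracle(self, rng):
        for _ in range(10):
            coords = rng.uniform(0, 20, (150, 3))
            got = build_radius_graph(coords, 4.0, max_edges=8)
            assert got.tolist() == [list(e) for e in
                                    brute_force_edges(coords, 4.0, 8)]

    def test_out_degree_capped(self, rng):
        coords = rng.uniform(0, 3, (80, 3))  # dense cluster
        edges = build_radius_graph(coords, 4.0, max_edges=5)
        src, counts = np.unique(edges[:, 0], return_counts=True)
        assert counts.max() <= 5


class TestAggregation:
    def test_singleton_vertex_state_is_own_embedding(self, rng):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        feats = rng.standard_normal((2, 16)).astype(np.float32)
        net = AggregationNet(rng, state_dim=32)
        states = aggregate_initial_states(feats, coords, np.array([0, 1]),
                                          2.0, net)
        # manual: MLP([h ⊕ 0]) per point
        h = nn.add_bias_relu(nn.constant(feats) @ net.W_feat,
                             nn.constant(np.zeros((2, 3))) @ net.W_rel, net.b1)
        expected = net.lin2(h).data
        np.testing.assert_allclose(states.data, expected, atol=1e-6)

    def test_duplicated_neighbor_leaves_state_unchanged(self, rng):
        coords = rng.uniform(0, 2, (10, 3))
        feats = rng.standard_normal((10, 16)).astype(np.float32)
        net = AggregationNet(rng, state_dim=16)
        sel = np.array([0, 4])
        s1 = aggregate_initial_states(feats, coords, sel, 2.0, net).data
        coords2 = np.vstack([coords, coords[7]])
        feats2 = np.vstack([feats, feats[7]])
        s2 = aggregate_initial_states(feats2, coords2, sel, 2.0, net).data
        np.testing.assert_allclose(s1, s2, atol=1e-6)

    def test_matches_bruteforce_loop(self, rng):
        """Vectorized aggregation equals an O(N·M) per-vertex loop."""
        coords = rng.uniform(0, 6, (50, 3))
        feats = rng.standard_normal((50, 16)).astype(np.float32)
        net = AggregationNet(rng, state_dim=24)
        sel = np.sort(rng.choice(50, 8, replace=False))
        got = aggregate_initial_states(feats, coords, sel, 2.0, net).data

        W1 = np.vstack([net.W_feat.data, net.W_rel.data])
        for v, s in enumerate(sel):
            rows = []
            for p in range(50):
                rel = coords[p] - coords[s]
                if np.linalg.norm(rel) <= 2.0:
                    x = np.concatenate([feats[p], rel]).astype(np.float32)
                    h = np.maximum(x @ W1 + net.b1.data, 0)
                    rows.append(h @ net.lin2.W.data + net.lin2.b.data)
            np.testing.assert_allclose(got[v], np.max(rows, axis=0),
                                       rtol=2e-5, atol=2e-5)

    def test_every_point_reaches_a_vertex(self, rng):
        """With voxel <= r0/sqrt(3) (diagonal <= r0), every original point
        lies within r0 of its voxel's representative."""
        for seed in range(5):
            coords = np.random.default_rng(seed).uniform(0, 10, (200, 3))
            cloud = _cloud(coords)
            r0 = 2.0
            voxel = r0 / np.sqrt(3) * 0.999
            sel = voxel_downsample(cloud, voxel)
            _, pids, _ = aggregation_pairs(coords, sel, r0)
            assert set(pids.tolist()) == set(range(200))


class TestTranslationInvariance:
    def test_shift_preserves_selection_edges_and_states(self, rng):
        """A shift by a multiple of the voxel size leaves the selected
        indices, edge list and vertex states identical."""
        coords = rng.uniform(0, 10, (120, 3))
        feats = rng.standard_normal((120, 16)).astype(np.float32)
        shift = np.array([50.0, -30.0, 20.0])
        cloud_a, cloud_b = _cloud(coords), _cloud(coords + shift)
        sel_a = voxel_downsample(cloud_a, 1.0)
        sel_b = voxel_downsample(cloud_b, 1.0)
        np.testing.assert_array_equal(sel_a, sel_b)
        e_a = build_radius_graph(coords[sel_a], 4.0, 32)
        e_b = build_radius_graph((coords + shift)[sel_b], 4.0, 32)
        np.testing.assert_array_equal(e_a, e_b)
        net = AggregationNet(rng, state_dim=16)
        s_a = aggregate_initial_states(feats, coords, sel_a, 2.0, net).data
        s_b = aggregate_initial_states(feats, coords + shift, sel_b, 2.0,
                                       net).data
        np.testing.assert_allclose(s_a, s_b, atol=1e-5)


def test_graph_config_validation():
    with pytest.raises(ValueError):
        GraphConfig(r=0.5, voxel_size=1.0)
    with pytest.raises(ValueError):
        GraphConfig(max_edges=0)
    with pytest.raises(ValueError):
        GraphConfig(r0=-1.0)
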