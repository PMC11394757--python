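"""Graph construction: voxel downsampling, initial-state aggregation and
the fixed-radius edge list.

The dense surface cloud is thinned by keeping one representative point
per occupied voxel (the real point nearest the voxel's centroid, so
predictions stay on the actual surface).  Information from the discarded
dense points is preserved by aggregating, for every vertex, the original
points within radius ``r0``: each is embedded by a two-layer MLP on
[16-dim features ⊕ relative coordinates] and reduced with an elementwise
Max.  Edges connect vertices strictly closer than ``r``, truncated to the
``max_edges`` nearest neighbors per vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .surface import SurfacePointCloud


@dataclass
class GraphConfig:
    """Downsampling / graph hyperparameters (all lengths in Å)."""

    voxel_size: float = 1.0
    r0: float = 2.0           # aggregation radius
    r: float = 4.0            # edge radius (strict <)
    max_edges: int = 32
    state_dim: int = 300

    def __post_init__(self):
        if self.voxel_size < 0 or self.r0 <= 0 or self.r <= 0:
            raise ValueError("radii must be positive")
        if self.voxel_size and self.r <= self.voxel_size:
            raise ValueError("edge radius must exceed voxel size")
        if self.max_edges < 1:
            raise ValueError("max_edges must be >= 1")


@dataclass
class PointGraph:
    """Downsampled vertices with states and a fixed-radius edge list."""

    vertex_coords: np.ndarray
    vertex_states: object          # nn.Tensor (M, state_dim) or None
    edges: np.ndarray              # (E, 2) directed, sorted by (i, j)
    vertex_labels: np.ndarray = None
    provenance: list = field(default=None, repr=False)
    config: GraphConfig = None

    def __len__(self):
        return len(self.vertex_coords)


def voxel_downsample(cloud, voxel_size: float) -> np.ndarray:
    """Indices of one representative point per occupied voxel.

    Voxels are axis-aligned cubes of edge ``voxel_size`` anchored at the
    coordinate origin.  The representative is the point nearest the
    centroid of the voxel's points (ties: lowest index).  Passing 0
    disables downsampling (all indices returned).
    """
    coords = cloud.coords if isinstance(cloud, SurfacePointCloud) else np.asarray(cloud)
    if voxel_size == 0:
        return np.arange(len(coords))
    if voxel_size < 0:
        raise ValueError("voxel_size must be >= 0")
    keys = np.floor(coords / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
    order = np.argsort(inverse, kind="stable")
    boundaries = np.r_[0, np.cumsum(counts)]
    selected = np.empty(len(counts), dtype=np.int64)
    for v in range(len(counts)):
        members = order[boundaries[v]:boundaries[v + 1]]
        centroid = coords[members].mean(axis=0)
        # round to 1e-9 Å so exact geometric ties (e.g. two points mirrored
        # about their centroid) resolve to the lowest index, independent of
        # float summation order
        d = np.round(np.linalg.norm(coords[members] - centroid, axis=1), 9)
        selected[v] = members[np.argmin(d)]
    return np.sort(selected)


class AggregationNet:
    """Two-layer MLP (19 -> state_dim -> state_dim, ReLU hidden) embedding
    [point features ⊕ relative coordinates]; the first-layer weight is
    stored as a feature block (16) and a relative-coordinate block (3)."""

    def __init__(self, rng: np.random.Generator, state_dim: int = 300):
        W1 = _kaiming(rng, 19, state_dim)  # one 19 x D map, stored in blocks
        self.W_feat = nn.Parameter(W1[:16])
        self.W_rel = nn.Parameter(W1[16:])
        self.b1 = nn.Parameter(np.zeros(state_dim, dtype=np.float32))
        self.lin2 = nn.Linear(state_dim, state_dim, rng)
        self.state_dim = state_dim

    def parameters(self):
        return [self.W_feat, self.W_rel, self.b1] + self.lin2.parameters()


def _kaiming(rng, fan_in, fan_out):
    from .nn.layers import kaiming
    return kaiming(rng, fan_in, fan_out)


def aggregation_pairs(coords: np.ndarray, selected: np.ndarray, r0: float):
    """(vertex_id, point_id, relative coordinate) triples for all original
    points within ``r0`` of each selected vertex (inclusive; every vertex
    contains at least itself).  Vertex ids are sorted ascending."""
    vert_xyz = coords[selected]
    tree = cKDTree(coords)
    vertex_ids, point_ids = [], []
    lists = tree.query_ball_point(vert_xyz, r0)
    for v, members in enumerate(lists):
        members = sorted(members)
        vertex_ids.extend([v] * len(members))
        point_ids.extend(members)
    vertex_ids = np.asarray(vertex_ids, dtype=np.int64)
    point_ids = np.asarray(point_ids, dtype=np.int64)
    relpos = coords[point_ids] - vert_xyz[vertex_ids]
    return vertex_ids, point_ids, relpos


def aggregate_initial_states(full_feat, coords, selected, r0,
                             net: AggregationNet,
                             pairs=None) -> "nn.Tensor":
    """Max-aggregated initial vertex states (M, state_dim).

    ``full_feat`` may be a constant array or an ``nn.Tensor`` carrying
    gradients from the chemical network.
    """
    if pairs is None:
        pairs = aggregation_pairs(np.asarray(coords), np.asarray(selected), r0)
    vertex_ids, point_ids, relpos = pairs
    feats = full_feat if isinstance(full_feat, nn.Tensor) else nn.constant(full_feat)
    feat_emb = feats @ net.W_feat                      # (N, D)
    hidden = nn.add_bias_relu(nn.gather_rows(feat_emb, point_ids),
                              nn.constant(relpos) @ net.W_rel, net.b1)
    embedded = net.lin2(hidden)                        # (P, D)
    return nn.segment_max(embedded, vertex_ids, len(selected))


def build_radius_graph(vertex_coords: np.ndarray, r: float,
                       max_edges: int = 32) -> np.ndarray:
    """Directed edges (i, j) with ``|x_i - x_j| < r`` (strict), keeping at
    most the ``max_edges`` nearest neighbors per source vertex (distance
    ties broken by lower index).  Returned sorted by (i, j)."""
    coords = np.asarray(vertex_coords, dtype=np.float64)
    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, r)
    edges = []
    for i, members in enumerate(neighbor_lists):
        nbrs = np.asarray([j for j in members if j != i], dtype=np.int64)
        if nbrs.size == 0:
            continue
        d = np.linalg.norm(coords[nbrs] - coords[i], axis=1)
        strict = d < r
        nbrs, d = nbrs[strict], d[strict]
        if nbrs.size > max_edges:
            order = np.lexsort((nbrs, d))[:max_edges]
            nbrs = nbrs[order]
        for j in sorted(nbrs):
            edges.append((i, j))
    if not edges:
        return np.empty((0, 2), dtype=np.int64)
    return np.asarray(edges, dtype=np.int64)


def build_graph(cloud: SurfacePointCloud, config: GraphConfig = None,
                label_rule: str = "representative") -> PointGraph:
    """Full graph construction (states left to the model's aggregation).

    ``label_rule``: "representative" takes the selected point's own label;
    "any" marks a vertex positive if any point in its voxel is positive.
    """
    config = config or GraphConfig()
    selected = voxel_downsample(cloud, config.voxel_size)
    edges = build_radius_graph(cloud.coords[selected], config.r,
                               config.max_edges)
    labels = None
    if cloud.labels is not None:
        if label_rule == "representative":
            labels = cloud.labels[selected]
        elif label_rule == "any":
            keys = np.floor(cloud.coords / max(config.voxel_size, 1e-9))
            labels = np.empty(len(selected), dtype=np.int64)
            for v, s in enumerate(selected):
                same = np.all(keys == keys[s], axis=1)
                labels[v] = int(cloud.labels[same].max())
        else:
            raise ValueError(f"unknown label_rule {label_rule!r}")
    vids, pids, relpos = aggregation_pairs(cloud.coords, selected, config.r0)
    provenance = np.split(pids, np.flatnonzero(np.diff(vids)) + 1)
    graph = PointGraph(cloud.coords[selected], None, edges,
                       vertex_labels=labels, provenance=list(provenance),
                       config=config)
    graph.selected = selected
    graph.agg_pairs = (vids, pids, relpos)
    return graph


def dump_graph(graph: PointGraph, edge_csv, vertex_csv):
    """Debug dump: edges as (i, j, distance) and vertices as
    (x, y, z, label, provenance_count) CSV files."""
    import pandas as pd
    coords = graph.vertex_coords
    if len(graph.edges):
        d = np.linalg.norm(coords[graph.edges[:, 0]]
                           - coords[graph.edges[:, 1]], axis=1)
        pd.DataFrame({"i": graph.edges[:, 0], "j": graph.edges[:, 1],
                      "distance": d}).to_csv(edge_csv, index=False)
    else:
        pd.DataFrame(columns=["i", "j", "distance"]).to_csv(edge_csv,
                                                            index=False)
    labels = (graph.vertex_labels if graph.vertex_labels is not None
              else np.zeros(len(coords), dtype=int))
    prov = ([len(m) for m in graph.provenance] if graph.provenance
            else [1] * len(coords))
    pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
                  "label": labels, "provenance_count": prov}
                 ).to_csv(vertex_csv, index=False)
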