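"""End-to-end wiring: structure -> surface -> graph -> model -> pockets.

``encode_structure`` precomputes everything about a structure that does
not depend on model weights (surface points, curvature features, the
fixed chemical-network input, the downsampled graph); the model then
runs its learned featurization and message passing on the encoding.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .graphs import GraphConfig, aggregation_pairs, build_radius_graph, voxel_downsample
from .inference import (DEFAULT_MAX_EPS, DEFAULT_MIN_SAMPLES, DEFAULT_THRESHOLD,
                        DEFAULT_XI, cluster_pockets, select_top_n,
                        threshold_points)
from .metrics import compute_dvo, match_sites, summarize
from .surface import (CurvatureScales, SurfacePointCloud, chem_pair_input,
                      compute_curvature_features, label_points, sample_surface)


@dataclass
class SurfaceConfig:
    probe_radius: float = 1.5
    target_density: float = 1.0     # points per Å^2
    scales: tuple = (1.0, 2.0, 3.5, 6.0, 10.0)
    label_threshold: float = 4.0    # Å to site center
    chem_k: int = 16


@dataclass
class InferenceConfig:
    threshold: float = DEFAULT_THRESHOLD
    min_samples: int = DEFAULT_MIN_SAMPLES
    max_eps: float = DEFAULT_MAX_EPS
    xi: float = DEFAULT_XI


@dataclass
class EncodedStructure:
    """Model-independent encoding of one structure."""

    structure_id: str
    point_coords: np.ndarray        # (N, 3) dense surface points
    geom_feat: np.ndarray           # (N, 10)
    chem_pair_input: np.ndarray     # (Q, 7)
    chem_point_ids: np.ndarray      # (Q,)
    selected: np.ndarray            # (M,) indices into points
    vertex_coords: np.ndarray       # (M, 3)
    edges: np.ndarray               # (E, 2)
    agg_pairs: tuple                # (vertex_ids, point_ids, relpos)
    vertex_labels: np.ndarray = None
    point_labels: np.ndarray = None
    sites: list = field(default_factory=list)
    group_key: str = ""

    @property
    def n_points(self):
        return len(self.point_coords)

    @property
    def n_vertices(self):
        return len(self.vertex_coords)


def encode_structure(atoms, sites=None, surface_cfg: SurfaceConfig = None,
                     graph_cfg: GraphConfig = None, structure_id: str = "",
                     group_key: str = "", cloud: SurfacePointCloud = None,
                     aggregate: bool = True) -> EncodedStructure:
    """Build the full model input for one structure.

    ``aggregate=False`` restricts every vertex's aggregation set to the
    vertex itself (the downsampling-without-feature-aggregation
    configuration); ``graph_cfg.voxel_size=0`` disables downsampling.
    """
    surface_cfg = surface_cfg or SurfaceConfig()
    graph_cfg = graph_cfg or GraphConfig()
    if cloud is None:
        cloud = sample_surface(atoms, surface_cfg.probe_radius,
                               surface_cfg.target_density)
        compute_curvature_features(cloud, CurvatureScales(surface_cfg.scales))
    point_labels = None
    if sites:
        point_labels = label_points(cloud, sites, surface_cfg.label_threshold)

    selected = voxel_downsample(cloud, graph_cfg.voxel_size)
    vertex_coords = cloud.coords[selected]
    edges = build_radius_graph(vertex_coords, graph_cfg.r, graph_cfg.max_edges)
    if aggregate:
        pairs = aggregation_pairs(cloud.coords, selected, graph_cfg.r0)
    else:
        m = len(selected)
        pairs = (np.arange(m), selected.copy(), np.zeros((m, 3)))
    pair_input, point_ids = chem_pair_input(cloud, atoms, surface_cfg.chem_k)
    return EncodedStructure(
        structure_id=structure_id, point_coords=cloud.coords,
        geom_feat=cloud.geom_feat, chem_pair_input=pair_input,
        chem_point_ids=point_ids, selected=selected,
        vertex_coords=vertex_coords, edges=edges, agg_pairs=pairs,
        vertex_labels=(point_labels[selected] if point_labels is not None else None),
        point_labels=point_labels, sites=list(sites or []),
        group_key=group_key)


def encode_synthetic(structure, surface_cfg=None, graph_cfg=None,
                     aggregate: bool = True) -> EncodedStructure:
    return encode_structure(structure.atoms, structure.sites, surface_cfg,
                            graph_cfg, structure_id=structure.structure_id,
                            group_key=structure.group_key, aggregate=aggregate)


def predict_pockets(model, enc: EncodedStructure,
                    inference_cfg: InferenceConfig = None):
    """Run the model on an encoded structure and cluster the positive
    vertices into ranked pockets.  Returns (clusters, probabilities)."""
    cfg = inference_cfg or InferenceConfig()
    probs = model.forward(enc)
    pos = threshold_points(probs, cfg.threshold)
    if pos.size == 0:
        return [], probs
    clusters = cluster_pockets(enc.vertex_coords[pos], probs[pos],
                               min_samples=cfg.min_samples,
                               max_eps=cfg.max_eps, xi=cfg.xi)
    # re-index members back to vertex ids
    for c in clusters:
        c.member_indices = pos[c.member_indices]
    return clusters, probs


def evaluate_structure(model, enc: EncodedStructure,
                       inference_cfg: InferenceConfig = None,
                       dvo_voxel: float = 2.0):
    """Top-n prediction and per-site evaluation records for one structure."""
    clusters, probs = predict_pockets(model, enc, inference_cfg)
    top, _ = select_top_n(clusters, max(1, len(enc.sites)))
    records = match_sites(top, enc.sites, enc.structure_id)
    by_rank = {c.rank: c for c in top}
    for rec, site in zip(records, enc.sites):
        if rec.missing or rec.matched_rank not in by_rank:
            continue
        site_points = enc.point_coords[
            np.linalg.norm(enc.point_coords - site.center, axis=1) <= 4.0]
        if len(site_points):
            rec.dvo = compute_dvo(by_rank[rec.matched_rank].member_coords,
                                  site_points, voxel=dvo_voxel)
    return records, clusters, probs


def evaluate_dataset(model, encodings, inference_cfg=None, dvo_voxel=2.0,
                     time_inference: bool = False):
    """Evaluation summary over encoded structures.

    Returns (summary, records, per_structure_seconds or None).
    """
    all_records = []
    seconds = [] if time_inference else None
    for enc in encodings:
        t0 = time.perf_counter()
        records, _, _ = evaluate_structure(model, enc, inference_cfg, dvo_voxel)
        if time_inference:
            seconds.append(time.perf_counter() - t0)
        all_records.extend(records)
    return summarize(all_records), all_records, seconds
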