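"""From a dense surface cloud to the downsampled point-cloud graph.

Shows voxel downsampling (one representative per occupied cube), the
fixed-radius edge rule (strictly below 4 Å, at most 32 nearest
neighbors), and what the r0 = 2 Å aggregation neighborhoods look like.
"""

import numpy as np

import pocketgnn as pg
from pocketgnn.graphs import GraphConfig, aggregation_pairs

structure = pg.make_blob_structure(pg.SyntheticSpec(n_structures=1, seed=7), 0)
cloud = pg.sample_surface(structure.atoms, target_density=0.6)

cfg = GraphConfig(voxel_size=2.0, r0=2.0, r=4.0, max_edges=32)
selected = pg.voxel_downsample(cloud, cfg.voxel_size)
edges = pg.build_radius_graph(cloud.coords[selected], cfg.r, cfg.max_edges)

print(f"dense cloud: {len(cloud)} points")
print(f"after 2.0 Å voxel downsampling: {len(selected)} vertices "
      f"({len(cloud) / len(selected):.1f}x reduction)")

deg = np.bincount(edges[:, 0], minlength=len(selected))
dists = np.linalg.norm(cloud.coords[selected][edges[:, 0]]
                       - cloud.coords[selected][edges[:, 1]], axis=1)
print(f"edges: {len(edges)} directed, out-degree mean {deg.mean():.1f} "
      f"(max {deg.max()} <= {cfg.max_edges}), "
      f"longest edge {dists.max():.2f} Å < r = {cfg.r} Å")

vids, pids, _ = aggregation_pairs(cloud.coords, selected, cfg.r0)
per_vertex = np.bincount(vids)
print(f"aggregation: each vertex summarizes {per_vertex.mean():.1f} dense "
      f"points within r0 = {cfg.r0} Å (min {per_vertex.min()}, "
      f"max {per_vertex.max()})")
print("-> the graph keeps surface resolution where it matters while the "
      "Max-aggregated states retain information from every dense point.")
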