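"""Sample a molecular surface and inspect its per-point features.

Builds one synthetic structure with a planted pocket, samples the
solvent-accessible surface as an oriented point cloud, and computes the
16-dimensional feature vector (6 learned chemical + 10 curvature
scalars).  Pocket points should stand out with systematically lower
mean curvature (the carved indentation) and oxygen-enriched linings.
"""

import numpy as np

import pocketgnn as pg
from pocketgnn.surface import ChemNet, compute_chemical_features

structure = pg.make_blob_structure(pg.SyntheticSpec(n_structures=1, seed=7), 0)
print(f"structure: {len(structure.atoms)} atoms, "
      f"{len(structure.sites)} planted pocket(s)")

cloud = pg.sample_surface(structure.atoms, probe_radius=1.5,
                          target_density=0.6)
print(f"surface: {len(cloud)} oriented points "
      f"(unit normals, max |1-|n|| = "
      f"{np.abs(np.linalg.norm(cloud.normals, axis=1) - 1).max():.1e})")

pg.compute_curvature_features(cloud)          # 10 geometric scalars
compute_chemical_features(cloud, structure.atoms,
                          ChemNet(np.random.default_rng(0)))  # 6 chemical
labels = pg.label_points(cloud, structure.sites)

H = cloud.geom_feat[:, 4]  # mean curvature at the 3.5 Å scale
print(f"labeled (pocket) fraction: {labels.mean():.3f}")
print(f"mean curvature at 3.5 Å   pocket: {H[labels == 1].mean():+.3f} Å^-1"
      f"   elsewhere: {H[labels == 0].mean():+.3f} Å^-1")
print("-> pocket points sit in the carved indentation, so their mean "
      "curvature is systematically below the convex background: exactly "
      "the geometric signal the predictor learns.")
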