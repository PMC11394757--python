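"""Molecular surface sampling and per-point featurization.

The protein surface is represented as an oriented point cloud sampled on
the solvent-accessible surface (SAS): for every atom, points are placed
on the sphere of radius ``vdW + probe`` and rejected if they fall inside
any other atom's inflated sphere.  Each surviving point carries a unit
normal (away from its owning atom) and a 16-dimensional feature vector:

* 6 chemical scalars — a learned summary of the 16 nearest atoms, each
  encoded as one-hot chemical type plus inverse distance, embedded by a
  small MLP (hidden width 6, ReLU, batch norm), summed and linearly
  mapped;
* 10 geometric scalars — mean and Gaussian curvature estimated at five
  spatial scales by a local quadric fit in each point's tangent frame.

Sign convention: with outward normals, convex regions have positive mean
curvature and concave pockets negative mean curvature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import nn
from .structure_io import CHEM_ALPHABET, AtomSet, LigandSite

logger = logging.getLogger(__name__)

#: van der Waals radii (Å) by element symbol
VDW_RADII = {
    "C": 1.70, "H": 1.20, "O": 1.52, "N": 1.55, "S": 1.80, "SE": 1.90,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

DEFAULT_PROBE_RADIUS = 1.5     # Å, water-sized probe
DEFAULT_DENSITY = 1.0          # points per Å^2
CHEM_NEIGHBORS = 16            # atoms summarised per surface point


class SurfaceError(RuntimeError):
    """Raised when surface sampling produces no points."""


class FeaturizationError(RuntimeError):
    """Raised when chemical featurization has no eligible atoms."""


@dataclass
class CurvatureScales:
    """Five ascending curvature radii σ in [1, 10] Å."""

    scales: tuple = (1.0, 2.0, 3.5, 6.0, 10.0)

    def __post_init__(self):
        s = tuple(float(v) for v in self.scales)
        if len(s) != 5 or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("need exactly 5 strictly increasing scales")
        if s[0] < 1.0 or s[-1] > 10.0:
            raise ValueError("scales must lie in [1, 10] Å")
        self.scales = s


@dataclass
class SurfacePointCloud:
    """Oriented surface points with features and optional binary labels."""

    coords: np.ndarray
    normals: np.ndarray
    chem_feat: np.ndarray = None
    geom_feat: np.ndarray = None
    labels: np.ndarray = None
    owner_atom: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if len(self.coords) < 1:
            raise ValueError("empty point cloud")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("normals must be unit length")

    def __len__(self):
        return len(self.coords)

    @property
    def full_feat(self) -> np.ndarray:
        """Chemical block then geometric block, N x 16."""
        if self.chem_feat is None or self.geom_feat is None:
            raise ValueError("features not computed yet")
        return np.hstack([self.chem_feat, self.geom_feat])

    def to_dataframe(self):
        import pandas as pd
        cols = {c: self.coords[:, i] for i, c in enumerate("xyz")}
        cols.update({f"n{c}": self.normals[:, i] for i, c in enumerate("xyz")})
        full = self.full_feat
        for i in range(full.shape[1]):
            cols[f"f{i + 1}"] = full[:, i]
        cols["label"] = (self.labels if self.labels is not None
                         else np.zeros(len(self), dtype=int))
        return pd.DataFrame(cols)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit directions (deterministic)."""
    i = np.arange(n, dtype=np.float64)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def atom_radii(atoms: AtomSet) -> np.ndarray:
    return np.array([VDW_RADII.get(e.upper(), DEFAULT_VDW)
                     for e in atoms.elements])


def sample_surface(atoms: AtomSet, probe_radius: float = DEFAULT_PROBE_RADIUS,
                   target_density: float = DEFAULT_DENSITY) -> SurfacePointCloud:
    """Sample the solvent-accessible surface as an oriented point cloud.

    Deterministic: per-atom Fibonacci lattices, no randomness.  A point on
    atom ``a``'s inflated sphere survives iff it is not strictly inside any
    other atom's inflated sphere (small tolerance avoids seam artifacts
    between tangent spheres).
    """
    radii = atom_radii(atoms) + probe_radius
    centers = atoms.coords
    tree = cKDTree(centers)
    max_r = radii.max()
    tol = 1e-6

    pts, nrm, owner = [], [], []
    for a in range(len(atoms)):
        R = radii[a]
        n_pts = max(8, int(round(4.0 * np.pi * R * R * target_density)))
        dirs = fibonacci_sphere(n_pts)
        cand = centers[a] + R * dirs
        neighbor_idx = tree.query_ball_point(centers[a], R + max_r)
        keep = np.ones(len(cand), dtype=bool)
        for b in neighbor_idx:
            if b == a:
                continue
            d = np.linalg.norm(cand - centers[b], axis=1)
            inside = d < radii[b] - tol
            # points exactly on a shared boundary (coincident/tangent
            # spheres) belong to the lower-index atom, avoiding duplicates
            shared = (np.abs(d - radii[b]) <= tol) & (b < a)
            keep &= ~(inside | shared)
        if keep.any():
            pts.append(cand[keep])
            nrm.append(dirs[keep])
            owner.append(np.full(int(keep.sum()), a))

    if not pts:
        raise SurfaceError("no surface points survived rejection sampling")
    return SurfacePointCloud(np.vstack(pts), np.vstack(nrm),
                             owner_atom=np.concatenate(owner))


class ChemNet:
    """Learned chemical-feature network.

    Per-atom embedding MLP: input 7 (one-hot(6) + inverse distance),
    hidden 6 with ReLU and batch normalization, output 6; contributions of
    the nearest atoms are summed and linearly mapped (6 -> 6).  Trained
    end-to-end with the GNN.
    """

    def __init__(self, rng: np.random.Generator):
        self.lin1 = nn.Linear(7, 6, rng)
        self.bn = nn.BatchNorm1d(6)
        self.lin2 = nn.Linear(6, 6, rng)
        self.post = nn.Linear(6, 6, rng)

    def __call__(self, pair_input: nn.Tensor, point_ids: np.ndarray,
                 n_points: int) -> nn.Tensor:
        h = nn.relu(self.bn(self.lin1(pair_input)))
        contrib = self.lin2(h)
        summed = nn.segment_sum(contrib, point_ids, n_points)
        return self.post(summed)

    def parameters(self):
        return (self.lin1.parameters() + self.bn.parameters()
                + self.lin2.parameters() + self.post.parameters())

    def set_training(self, flag: bool):
        self.bn.training = flag


def chem_pair_input(cloud: SurfacePointCloud, atoms: AtomSet,
                    k: int = CHEM_NEIGHBORS):
    """Fixed input to the chemical network: for each surface point, its
    ``k`` nearest alphabet atoms encoded as one-hot(6) + 1/distance.

    Returns ``(pair_input (Q,7), point_ids (Q,))`` with point ids sorted.
    """
    eligible = np.flatnonzero(atoms.chem_index >= 0)
    if eligible.size == 0:
        raise FeaturizationError("no atoms in the chemical alphabet")
    tree = cKDTree(atoms.coords[eligible])
    kk = min(k, eligible.size)
    dist, idx = tree.query(cloud.coords, k=kk)
    if kk == 1:
        dist, idx = dist[:, None], idx[:, None]
    chem = atoms.chem_index[eligible][idx]              # (N, kk)
    onehot = np.eye(len(CHEM_ALPHABET))[chem]           # (N, kk, 6)
    inv_d = 1.0 / np.maximum(dist, 1e-3)
    pair = np.concatenate([onehot, inv_d[..., None]], axis=2)
    n = len(cloud)
    point_ids = np.repeat(np.arange(n), kk)
    return pair.reshape(n * kk, 7), point_ids


def compute_chemical_features(cloud: SurfacePointCloud, atoms: AtomSet,
                              chem_net: ChemNet,
                              k: int = CHEM_NEIGHBORS) -> np.ndarray:
    """Evaluate the chemical network (inference mode) and attach the
    resulting N x 6 features to the cloud."""
    pair, point_ids = chem_pair_input(cloud, atoms, k)
    was_training = chem_net.bn.training
    chem_net.set_training(False)
    out = chem_net(nn.constant(pair), point_ids, len(cloud))
    chem_net.set_training(was_training)
    cloud.chem_feat = out.data.astype(np.float64)
    return cloud.chem_feat


def _tangent_frame(normal: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def compute_curvature_features(cloud: SurfacePointCloud,
                               scales: CurvatureScales = None) -> np.ndarray:
    """Mean and Gaussian curvature at five scales by local quadric fit.

    For each point and scale σ, neighbors within σ are expressed in the
    tangent frame (u, v, n) and a quadric ``h = a u² + b uv + c v² + d u
    + e v + f`` is fitted by least squares; H and K follow from the first
    and second fundamental forms.  Scales with fewer than 6 neighbors
    yield zeros.  Output columns: [H(σ1), K(σ1), ..., H(σ5), K(σ5)].
    """
    scales = scales or CurvatureScales()
    pts = cloud.coords
    nrms = cloud.normals
    tree = cKDTree(pts)
    n = len(pts)
    out = np.zeros((n, 10))
    n_degenerate = 0
    neighbor_lists = tree.query_ball_point(pts, scales.scales[-1])
    for i in range(n):
        nb_far = np.asarray(neighbor_lists[i])
        rel_far = pts[nb_far] - pts[i]
        d_far = np.linalg.norm(rel_far, axis=1)
        u, v = _tangent_frame(nrms[i])
        pu = rel_far @ u
        pv = rel_far @ v
        ph = rel_far @ nrms[i]
        for s, sigma in enumerate(scales.scales):
            sel = d_far <= sigma
            if int(sel.sum()) < 6:
                n_degenerate += 1
                continue
            x, y, h = pu[sel], pv[sel], ph[sel]
            A = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(A, h, rcond=None)
            a, b, c, d, e, _ = coef
            fxx, fxy, fyy, fx, fy = 2 * a, b, 2 * c, d, e
            w = 1.0 + fx * fx + fy * fy
            # minus sign: height is measured along the outward normal, so a
            # convex surface (neighbors below the tangent plane) gets H > 0
            H = -((1 + fy * fy) * fxx - 2 * fx * fy * fxy
                  + (1 + fx * fx) * fyy) / (2.0 * w ** 1.5)
            K = (fxx * fyy - fxy * fxy) / (w * w)
            out[i, 2 * s] = H
            out[i, 2 * s + 1] = K
    if n_degenerate:
        logger.debug("curvature: %d (point, scale) pairs had <6 neighbors",
                     n_degenerate)
    cloud.geom_feat = out
    return out


def label_points(cloud: SurfacePointCloud, sites, threshold: float = 4.0,
                 use_ligand_atoms: bool = False) -> np.ndarray:
    """Binary labels: 1 iff a point lies within ``threshold`` Å of any
    site center (or of any ligand atom when ``use_ligand_atoms``)."""
    if not sites:
        raise ValueError("need at least one ligand site")
    labels = np.zeros(len(cloud), dtype=np.int64)
    for site in sites:
        ref = site.atom_coords if use_ligand_atoms else site.center[None, :]
        d = np.linalg.norm(cloud.coords[:, None, :] - ref[None, :, :], axis=2)
        labels |= (d.min(axis=1) <= threshold).astype(np.int64)
    cloud.labels = labels
    return labels
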