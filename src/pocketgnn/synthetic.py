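"""Synthetic labeled structures with planted binding pockets.

A structure is a roughly spherical "blob" of pseudo-atoms (jittered
grid inside a ball, heavy-atom element frequencies close to real
proteins).  Each pocket is carved by removing the atoms inside a
spherical-cap indentation on the blob's boundary; the atoms lining the
cavity are biased toward a chosen element, so pockets carry both a
geometric signature (concavity) and a chemical one, mirroring what the
predictor is supposed to exploit on real proteins.  The pseudo-ligand is
a single dummy heavy atom placed just inside the cavity mouth, making
the ground-truth site center exact.

Determinism: structure ``index`` under a given ``seed`` is bit-identical
across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import CHEM_ALPHABET, AtomSet, LigandSite, write_structure

#: background element frequencies (C, N, O, S) for protein heavy atoms
BACKGROUND_ELEMENTS = ("C", "N", "O", "S")
BACKGROUND_PROBS = (0.62, 0.16, 0.20, 0.02)

ATOM_SPACING = 1.8        # Å, pseudo-atom grid spacing
LINING_SHELL = 2.5        # Å, thickness of the chem-biased shell
LINING_PROB = 0.85        # probability a lining atom takes the bias element
CENTER_INSET = 1.0        # Å, ligand center sits this far inside the mouth


class PocketPlacementError(RuntimeError):
    """Raised when non-overlapping pocket directions cannot be drawn."""


@dataclass
class SyntheticSpec:
    n_structures: int = 60
    surface_kind: str = "blob"
    radius_range: tuple = (5.5, 7.0)
    n_pockets: int = 1
    pocket_cap_angle: float = 0.55   # radians, half-angle of the carved cap
    pocket_chem_bias: int = 2        # index into [C, H, O, N, S, Se]; 2 = O
    noise_sd: float = 0.3            # Å, jitter on the atom grid
    seed: int = 0
    n_archetypes: int = 12           # geometry groups for leakage-free splits

    def __post_init__(self):
        if min(self.radius_range) <= 0:
            raise ValueError("radii must be positive")
        if not (0 < self.pocket_cap_angle <= np.pi / 2):
            raise ValueError("cap angle must be in (0, pi/2]")
        if self.n_pockets < 1:
            raise ValueError("need at least one pocket")


@dataclass
class SyntheticStructure:
    structure_id: str
    group_key: str
    atoms: AtomSet
    sites: list
    pocket_centers: np.ndarray = field(default=None)

    def write_pdb(self, path):
        write_structure(self.atoms, path, ligands=self.sites)


def _ball_grid(rng: np.random.Generator, radius: float, noise_sd: float):
    half = int(np.ceil(radius / ATOM_SPACING))
    axis = np.arange(-half, half + 1) * ATOM_SPACING
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts[np.linalg.norm(pts, axis=1) <= radius]


def _pocket_directions(rng, n_pockets, cap_angle, max_tries=200):
    min_sep = 2.0 * cap_angle + 0.6  # radians between pocket axes
    for _ in range(max_tries):
        dirs = rng.normal(size=(n_pockets, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        ok = all(np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1)) > min_sep
                 for i in range(n_pockets) for j in range(i))
        if ok:
            return dirs
    raise PocketPlacementError(
        f"could not place {n_pockets} pockets with cap angle {cap_angle}")


def _structure_radius(spec: SyntheticSpec, archetype: int) -> float:
    lo, hi = spec.radius_range
    if spec.n_archetypes == 1:
        return 0.5 * (lo + hi)
    return lo + (hi - lo) * (archetype / (spec.n_archetypes - 1))


def make_blob_structure(spec: SyntheticSpec, index: int) -> SyntheticStructure:
    """Generate structure ``index`` of the dataset defined by ``spec``."""
    rng = np.random.default_rng([spec.seed, index])
    archetype = index % spec.n_archetypes
    radius = _structure_radius(spec, archetype)

    coords = _ball_grid(rng, radius, spec.noise_sd)
    elements = np.array(rng.choice(BACKGROUND_ELEMENTS, size=len(coords),
                                   p=BACKGROUND_PROBS))
    dirs = _pocket_directions(rng, spec.n_pockets, spec.pocket_cap_angle)

    # carve radius giving a boundary cap of half-angle pocket_cap_angle
    rc = radius * np.sqrt(2.0 * (1.0 - np.cos(spec.pocket_cap_angle)))
    bias_element = CHEM_ALPHABET[spec.pocket_chem_bias]
    centers = []
    keep = np.ones(len(coords), dtype=bool)
    for u in dirs:
        q = radius * u
        d = np.linalg.norm(coords - q, axis=1)
        keep &= d >= rc
        lining = (d >= rc) & (d < rc + LINING_SHELL)
        flip = rng.random(len(coords)) < LINING_PROB
        elements = np.where(lining & flip, bias_element, elements)
        centers.append((radius - CENTER_INSET) * u)

    coords, elements = coords[keep], elements[keep]
    if len(coords) < 50:
        raise PocketPlacementError("carving removed too many atoms")
    atoms = AtomSet.from_elements(coords, list(elements))
    sites = [LigandSite(f"PCK_{k}", c[None, :]) for k, c in enumerate(centers)]
    return SyntheticStructure(
        structure_id=f"synth_{spec.seed}_{index:04d}",
        group_key=f"arch{archetype}",
        atoms=atoms, sites=sites, pocket_centers=np.array(centers))


def make_dataset(spec: SyntheticSpec):
    """All structures of the generator settings, in index order."""
    return [make_blob_structure(spec, i) for i in range(spec.n_structures)]


def make_separable_dataset(spec: SyntheticSpec, split_seed: int = None):
    """Generate the dataset and split it 8:1:1 with whole geometry
    archetypes confined to one split.  Returns (train, val, test) lists."""
    from .training import SplitSpec, make_splits
    if spec.n_structures < 10:
        raise ValueError("need at least 10 structures for a grouped split")
    structures = make_dataset(spec)
    items = [(s.structure_id, s.group_key) for s in structures]
    split_seed = spec.seed if split_seed is None else split_seed
    train_ids, val_ids, test_ids = make_splits(items, SplitSpec(), split_seed)
    by_id = {s.structure_id: s for s in structures}
    return ([by_id[i] for i in train_ids], [by_id[i] for i in val_ids],
            [by_id[i] for i in test_ids])


def write_manifest(structures, path):
    import pandas as pd
    rows = []
    for s in structures:
        for k, site in enumerate(s.sites):
            rows.append({"id": s.structure_id, "group_key": s.group_key,
                         "n_sites": len(s.sites), "site": k,
                         "cx": site.center[0], "cy": site.center[1],
                         "cz": site.center[2]})
    pd.DataFrame(rows).to_csv(path, index=False)
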