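"""Surface sampling geometry, curvature against analytic shapes,
chemical featurization, and labeling rules."""

import numpy as np
import pytest

from pocketgnn import nn
from pocketgnn.structure_io import AtomSet, LigandSite
from pocketgnn.surface import (ChemNet, CurvatureScales, SurfaceError,
                               SurfacePointCloud, chem_pair_input,
                               compute_chemical_features,
                               compute_curvature_features, fibonacci_sphere,
                               label_points, sample_surface)


def _single_atom(element="C"):
    return AtomSet.from_elements(np.zeros((1, 3)), [element])


class TestSampling:
    def test_single_atom_points_on_inflated_sphere(self):
        cloud = sample_surface(_single_atom(), probe_radius=1.5)
        d = np.linalg.norm(cloud.coords, axis=1)
        np.testing.assert_allclose(d, 3.2, atol=0.01)  # vdW 1.7 + probe 1.5
        # normals point away from the atom center
        np.testing.assert_allclose(cloud.normals, cloud.coords / d[:, None],
                                   atol=1e-9)

    def test_coincident_atoms_do_not_duplicate_surface(self):
        one = sample_surface(_single_atom())
        two = sample_surface(AtomSet.from_elements(np.zeros((2, 3)), ["C", "C"]))
        assert abs(len(two) - len(one)) <= 0.1 * len(one)

    def test_distant_atoms_give_two_shells(self):
        atoms = AtomSet.from_elements(
            np.array([[0.0, 0, 0], [20.0, 0, 0]]), ["C", "C"])
        one = sample_surface(_single_atom())
        two = sample_surface(atoms)
        assert abs(len(two) - 2 * len(one)) <= 0.1 * 2 * len(one)

    def test_density_within_factor_two(self):
        cloud = sample_surface(_single_atom(), target_density=1.0)
        area = 4 * np.pi * 3.2 ** 2
        assert area / 2 <= len(cloud) <= area * 2

    def test_buried_atom_contributes_no_points(self):
        # central atom fully inside a tight shell of neighbors
        dirs = fibonacci_sphere(30)
        coords = np.vstack([[0.0, 0, 0], 1.5 * dirs])
        atoms = AtomSet.from_elements(coords, ["C"] * 31)
        cloud = sample_surface(atoms)
        assert not np.any(cloud.owner_atom == 0)


class TestCurvature:
    @pytest.mark.parametrize("radius,tol_h,tol_k", [(5.0, 0.15, 0.25),
                                                    (10.0, 0.15, 0.25)])
    def test_sphere_curvatures(self, radius, tol_h, tol_k):
        """Convex sphere: H = 1/R, K = 1/R^2 at sigma = 2.5 Å."""
        n = int(4 * np.pi * radius ** 2 * 2.0)
        dirs = fibonacci_sphere(n)
        cloud = SurfacePointCloud(radius * dirs, dirs)
        scales = CurvatureScales((1.0, 2.0, 2.5, 6.0, 10.0))
        geom = compute_curvature_features(cloud, scales)
        H, K = geom[:, 4], geom[:, 5]
        assert abs(H.mean() - 1 / radius) < tol_h / radius
        assert abs(K.mean() - 1 / radius ** 2) < tol_k / radius ** 2
        assert (H > 0).mean() > 0.99  # convex => positive mean curvature

    def test_plane_is_flat(self, rng):
        xy = rng.uniform(-10, 10, (800, 2))
        pts = np.column_stack([xy, np.zeros(len(xy))])
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        cloud = SurfacePointCloud(pts, normals)
        geom = compute_curvature_features(cloud, CurvatureScales((1, 2, 2.5, 6, 10)))
        assert np.abs(geom[:, 4]).max() < 0.01   # |H| at sigma 2.5
        assert np.abs(geom[:, 5]).max() < 0.01

    def test_cylinder_has_zero_gaussian_curvature(self, rng):
        radius = 5.0
        theta = rng.uniform(0, 2 * np.pi, 2000)
        z = rng.uniform(-15, 15, 2000)
        pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
        normals = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(2000)])
        cloud = SurfacePointCloud(pts, normals)
        geom = compute_curvature_features(cloud, CurvatureScales((1, 2, 2.5, 6, 10)))
        # interior points only (away from the open ends)
        interior = np.abs(z) < 10
        H, K = geom[interior, 2], geom[interior, 3]  # sigma = 2 Å
        assert abs(np.median(H) - 1 / (2 * radius)) < 0.3 / (2 * radius)
        assert np.abs(K).mean() < 0.25 / radius ** 2

    def test_sparse_neighborhoods_yield_zeros(self):
        pts = np.array([[0.0, 0, 0], [30.0, 0, 0], [60.0, 0, 0]])
        normals = np.tile([0.0, 0, 1.0], (3, 1))
        cloud = SurfacePointCloud(pts, normals)
        geom = compute_curvature_features(cloud)
        assert np.all(geom == 0)


class TestChemicalFeatures:
    def test_output_shape_and_attachment(self, rng, small_structure):
        cloud = sample_surface(small_structure.atoms, target_density=0.4)
        net = ChemNet(rng)
        feat = compute_chemical_features(cloud, small_structure.atoms, net)
        assert feat.shape == (len(cloud), 6)
        assert np.all(np.isfinite(feat))
        assert cloud.chem_feat is feat

    def test_zero_weights_give_bias_only(self, rng, small_structure):
        cloud = sample_surface(small_structure.atoms, target_density=0.4)
        net = ChemNet(rng)
        for p in net.parameters():
            p.data = np.zeros_like(p.data)
        net.post.b.data = np.full(6, 1.5, dtype=np.float32)
        feat = compute_chemical_features(cloud, small_structure.atoms, net)
        np.testing.assert_allclose(feat, 1.5, atol=1e-6)

    def test_pre_linear_sum_matches_bruteforce(self, rng):
        """The k-nearest-atom sum equals an explicit per-atom loop."""
        atoms = AtomSet.from_elements(rng.uniform(-5, 5, (20, 3)),
                                      rng.choice(["C", "N", "O"], 20))
        pts = rng.uniform(-6, 6, (15, 3))
        dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cloud = SurfacePointCloud(pts, dirs)
        pair, ids = chem_pair_input(cloud, atoms, k=16)
        assert pair.shape == (15 * 16, 7)
        from scipy.spatial import cKDTree
        for i in range(15):
            d = np.linalg.norm(atoms.coords - pts[i], axis=1)
            nearest = np.sort(d)[:16]
            got = np.sort(1.0 / pair[ids == i][:, 6])
            np.testing.assert_allclose(np.sort(got), np.sort(nearest), rtol=1e-6)

    def test_duplicated_atoms_double_the_sum(self, rng):
        """Summing over 2k duplicated atoms doubles the pre-linear
        representation (linearity of the sum)."""
        atoms = AtomSet.from_elements(rng.uniform(-5, 5, (12, 3)),
                                      ["C", "O", "N"] * 4)
        doubled = AtomSet.from_elements(
            np.vstack([atoms.coords, atoms.coords]),
            list(atoms.elements) * 2)
        pts = rng.uniform(-6, 6, (8, 3))
        dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cloud = SurfacePointCloud(pts, dirs)
        net = ChemNet(rng)
        net.set_training(False)

        def pre_linear_sum(a, k):
            pair, ids = chem_pair_input(cloud, a, k=k)
            h = nn.relu(net.bn(net.lin1(nn.constant(pair))))
            contrib = net.lin2(h)
            return nn.segment_sum(contrib, ids, len(cloud)).data

        np.testing.assert_allclose(2 * pre_linear_sum(atoms, 12),
                                   pre_linear_sum(doubled, 24),
                                   rtol=1e-4, atol=1e-5)


class TestLabels:
    def _cloud(self, pts):
        dirs = np.tile([0.0, 0, 1.0], (len(pts), 1))
        return SurfacePointCloud(pts, dirs)

    def test_distance_threshold_boundary(self):
        cloud = self._cloud(np.array([[3.9, 0, 0], [4.1, 0, 0]]))
        site = LigandSite("L", np.zeros((1, 3)))
        labels = label_points(cloud, [site], threshold=4.0)
        assert labels.tolist() == [1, 0]

    def test_any_site_rule(self):
        cloud = self._cloud(np.array([[50.0, 0, 0]]))
        far = LigandSite("A", np.zeros((1, 3)))
        near = LigandSite("B", np.array([[49.0, 0, 0]]))
        assert label_points(cloud, [far, near]).tolist() == [1]

    def test_label_fraction_strictly_interior(self, small_structure):
        cloud = sample_surface(small_structure.atoms, target_density=0.6)
        labels = label_points(cloud, small_structure.sites)
        assert 0 < labels.mean() < 1


class TestRigidMotion:
    def test_translation_moves_points_and_preserves_features(self, small_structure):
        """The per-atom sampling lattice is translation-covariant, so
        points correspond 1:1 and all features are unchanged."""
        atoms = small_structure.atoms
        t = np.array([12.0, -7.0, 3.0])
        moved = AtomSet(atoms.coords + t, atoms.elements, atoms.chem_index)
        c1 = sample_surface(atoms, target_density=0.4)
        c2 = sample_surface(moved, target_density=0.4)
        np.testing.assert_allclose(c2.coords, c1.coords + t, atol=1e-8)
        np.testing.assert_allclose(c2.normals, c1.normals, atol=1e-12)
        np.testing.assert_allclose(compute_curvature_features(c2),
                                   compute_curvature_features(c1), atol=1e-4)
        net = ChemNet(np.random.default_rng(0))
        np.testing.assert_allclose(
            compute_chemical_features(c2, moved, net),
            compute_chemical_features(c1, atoms, net), atol=1e-4)

    def test_rotating_cloud_and_atoms_preserves_features(self, small_structure):
        """Features of a fixed point set depend only on distances and the
        local frame, so rotating cloud + atoms together changes nothing."""
        from scipy.spatial.transform import Rotation
        atoms = small_structure.atoms
        R = Rotation.from_euler("zyx", [30, -40, 75], degrees=True).as_matrix()
        moved = AtomSet(atoms.coords @ R.T, atoms.elements, atoms.chem_index)
        c1 = sample_surface(atoms, target_density=0.4)
        c2 = SurfacePointCloud(c1.coords @ R.T, c1.normals @ R.T)
        np.testing.assert_allclose(compute_curvature_features(c2),
                                   compute_curvature_features(c1), atol=1e-4)
        net = ChemNet(np.random.default_rng(0))
        np.testing.assert_allclose(
            compute_chemical_features(c2, moved, net),
            compute_chemical_features(c1, atoms, net), atol=1e-4)


def test_full_feature_vector_is_chem_then_geom(small_structure, rng):
    cloud = sample_surface(small_structure.atoms, target_density=0.4)
    compute_curvature_features(cloud)
    compute_chemical_features(cloud, small_structure.atoms, ChemNet(rng))
    full = cloud.full_feat
    assert full.shape == (len(cloud), 16)
    np.testing.assert_array_equal(full[:, :6], cloud.chem_feat)
    np.testing.assert_array_equal(full[:, 6:], cloud.geom_feat)


def test_curvature_scales_validation():
    with pytest.raises(ValueError):
        CurvatureScales((1, 2, 3))
    with pytest.raises(ValueError):
        CurvatureScales((0.5, 2, 3, 4, 5))
    with pytest.raises(ValueError):
        CurvatureScales((1, 2, 3, 4, 12))
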