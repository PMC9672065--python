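"""Geometric primitives: Gaussian potentials, alignment, reflection, r_-."""

import numpy as np
import pytest

from mshk.geometry import (
    Geometry,
    kabsch_align,
    oxygen_oxygen_distance,
    proton_transfer_coordinate,
    reflect_geometry,
    weighted_rmsd,
)
from mshk.grid import GridSpec, gaussian_potential, potential_l2_distance
from mshk.surrogate import SIGMA_V_PERMUTATION, template_geometry


class TestGaussianPotential:
    def test_single_atom_on_grid_point(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=0.5, shape=(5, 5, 5))
        g = Geometry([1], [[1.0, 1.0, 1.0]])
        field = gaussian_potential(g, grid, sigma_pot=0.2)
        # atom sits exactly on grid index (2,2,2): exponent is zero there
        assert field.reshaped()[2, 2, 2] == pytest.approx(1.0)

    def test_value_at_one_sigma(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=0.2, shape=(4, 1, 1))
        g = Geometry([8], [[0.0, 0.0, 0.0]])
        field = gaussian_potential(g, grid, sigma_pot=0.2)
        # grid point at distance sigma: value Z * exp(-1/2)
        assert field.reshaped()[1, 0, 0] == pytest.approx(8.0 * np.exp(-0.5))

    def test_two_atoms_superpose(self, small_grid):
        a = Geometry([8], [[0.0, 0.5, 0.0]])
        b = Geometry([1], [[0.4, -0.2, 0.1]])
        ab = Geometry([8, 1], [[0.0, 0.5, 0.0], [0.4, -0.2, 0.1]])
        va = gaussian_potential(a, small_grid).values
        vb = gaussian_potential(b, small_grid).values
        vab = gaussian_potential(ab, small_grid).values
        np.testing.assert_allclose(vab, va + vb, rtol=1e-12)

    def test_translation_covariance(self):
        g = Geometry([6, 8], [[0.1, 0.2, 0.3], [1.0, 0.5, -0.2]])
        grid1 = GridSpec(origin=(-2, -2, -2), spacing=0.4, shape=(12, 12, 12))
        shift = np.array([0.37, -0.85, 0.12])
        g2 = g.with_coordinates(g.coordinates + shift)
        grid2 = GridSpec(origin=tuple(np.array(grid1.origin) + shift), spacing=0.4, shape=(12, 12, 12))
        v1 = gaussian_potential(g, grid1).values
        v2 = gaussian_potential(g2, grid2).values
        np.testing.assert_allclose(v1, v2, rtol=0, atol=1e-13)

    def test_rejects_bad_inputs(self, small_grid):
        g = Geometry([1], [[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="sigma_pot"):
            gaussian_potential(g, small_grid, sigma_pot=-0.1)
        with pytest.raises(ValueError):
            Geometry([], np.zeros((0, 3)))

    def test_warns_outside_grid(self):
        grid = GridSpec(origin=(0, 0, 0), spacing=0.2, shape=(4, 4, 4))
        g = Geometry([1], [[5.0, 5.0, 5.0]])
        with pytest.warns(UserWarning, match="outside"):
            gaussian_potential(g, grid)


class TestPotentialMetric:
    def test_identity_and_symmetry(self, small_grid, perturbed_geometries):
        f1 = gaussian_potential(perturbed_geometries[0], small_grid)
        f2 = gaussian_potential(perturbed_geometries[1], small_grid)
        assert potential_l2_distance(f1, f1) == 0.0
        assert potential_l2_distance(f1, f2) == pytest.approx(
            potential_l2_distance(f2, f1)
        )

    def test_matches_bruteforce_quadrature(self, small_grid, perturbed_geometries):
        f1 = gaussian_potential(perturbed_geometries[0], small_grid)
        f2 = gaussian_potential(perturbed_geometries[2], small_grid)
        acc = 0.0
        for a, b in zip(f1.values, f2.values):
            acc += (a - b) ** 2 * small_grid.voxel_volume
        assert potential_l2_distance(f1, f2) == pytest.approx(np.sqrt(acc), rel=1e-12)

    def test_triangle_inequality(self, small_grid, perturbed_geometries):
        fields = [
            gaussian_potential(g, small_grid) for g in perturbed_geometries[:3]
        ]
        d01 = potential_l2_distance(fields[0], fields[1])
        d12 = potential_l2_distance(fields[1], fields[2])
        d02 = potential_l2_distance(fields[0], fields[2])
        assert d02 <= d01 + d12 + 1e-12

    def test_grid_mismatch_raises(self, small_grid):
        g = Geometry([1], [[0.0, 0.0, 0.0]])
        other = GridSpec(origin=small_grid.origin, spacing=0.3, shape=small_grid.shape)
        f1 = gaussian_potential(g, small_grid)
        f2 = gaussian_potential(g, other)
        with pytest.raises(ValueError, match="GridSpec"):
            potential_l2_distance(f1, f2)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabschAlign:
    def test_identity(self, template):
        aligned = kabsch_align(template, template)
        np.testing.assert_allclose(aligned.coordinates, template.coordinates, atol=1e-12)

    def test_recovers_rigid_motion(self, template, rng):
        rot = _random_rotation(rng)
        moved = template.with_coordinates(template.coordinates @ rot + [1.0, -2.0, 0.5])
        aligned = kabsch_align(moved, template)
        assert weighted_rmsd(aligned, template) < 1e-10

    def test_beats_rotation_grid_oracle(self, template, rng):
        """Kabsch RMSD must match brute-force minimisation over rotations."""
        from scipy.spatial.transform import Rotation

        distorted = template.with_coordinates(
            template.coordinates + 0.05 * rng.standard_normal((9, 3))
        )
        rot = _random_rotation(rng)
        moved = distorted.with_coordinates(distorted.coordinates @ rot + [0.3, 0.1, -0.7])
        aligned = kabsch_align(moved, template)
        kabsch_rmsd = weighted_rmsd(aligned, template)

        # oracle: dense random search over rotations about weighted centroids
        w = (template.atomic_numbers > 1).astype(float)
        wn = w / w.sum()
        x = moved.coordinates - (wn[:, None] * moved.coordinates).sum(axis=0)
        y = template.coordinates - (wn[:, None] * template.coordinates).sum(axis=0)
        best = np.inf
        r_or = np.random.default_rng(0)
        for rotation in Rotation.random(4000, rng=r_or):
            trial = x @ rotation.as_matrix().T
            best = min(best, np.sqrt((wn * ((trial - y) ** 2).sum(axis=1)).sum()))
        assert kabsch_rmsd <= best + 1e-9

    def test_mismatched_atoms_raise(self, template):
        other = Geometry([1, 8], [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="same number of atoms"):
            kabsch_align(other, template)


class TestReflection:
    def test_c2v_template_is_fixed_point(self, template):
        refl = reflect_geometry(template, SIGMA_V_PERMUTATION)
        np.testing.assert_allclose(refl.coordinates, template.coordinates, atol=1e-12)

    def test_involution(self, perturbed_geometries):
        g = perturbed_geometries[0]
        twice = reflect_geometry(
            reflect_geometry(g, SIGMA_V_PERMUTATION), SIGMA_V_PERMUTATION
        )
        np.testing.assert_allclose(twice.coordinates, g.coordinates, atol=1e-14)

    def test_negates_proton_transfer_coordinate(self, perturbed_geometries):
        for g in perturbed_geometries[:5]:
            r = proton_transfer_coordinate(g)
            rr = proton_transfer_coordinate(reflect_geometry(g, SIGMA_V_PERMUTATION))
            assert rr == pytest.approx(-r, abs=1e-12)

    def test_preserves_distances(self, perturbed_geometries):
        g = perturbed_geometries[1]
        gr = reflect_geometry(g, SIGMA_V_PERMUTATION)
        d = np.linalg.norm(g.coordinates[:, None] - g.coordinates[None], axis=-1)
        dr = np.linalg.norm(gr.coordinates[:, None] - gr.coordinates[None], axis=-1)
        perm = np.asarray(SIGMA_V_PERMUTATION)
        np.testing.assert_allclose(dr[np.ix_(perm, perm)], d, atol=1e-12)

    def test_non_involutive_permutation_rejected(self, template):
        with pytest.raises(ValueError, match="involution"):
            reflect_geometry(template, (1, 2, 0, 3, 4, 5, 6, 7, 8))


class TestProtonTransferCoordinate:
    def test_hand_computed_value(self):
        g = Geometry(
            [8, 8, 1],
            [[0.0, 0.0, 0.0], [2.5, 0.0, 0.0], [1.0, 0.0, 0.0]],
            labels={"O1": 0, "O2": 1, "H": 2},
        )
        assert proton_transfer_coordinate(g) == pytest.approx(1.0 - 1.5)
        assert oxygen_oxygen_distance(g) == pytest.approx(2.5)

    def test_symmetric_geometry_is_zero(self, template):
        assert proton_transfer_coordinate(template) == pytest.approx(0.0, abs=1e-12)

    def test_missing_labels_raise(self):
        g = Geometry([8, 8, 1], np.random.default_rng(0).standard_normal((3, 3)))
        with pytest.raises(KeyError, match="O1"):
            proton_transfer_coordinate(g)
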