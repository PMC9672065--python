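"""MD engine: restraint, numerical forces, NVE integrity, sampling."""

import numpy as np
import pytest

from mshk.constants import ATOMIC_MASSES, BOHR_TO_ANGSTROM, KB_KCAL_MOL, KCAL_MOL_TO_MECH
from mshk.geometry import Geometry
from mshk.md import (
    AnalyticForceField,
    MDState,
    RestraintSpec,
    energy_drift,
    kinetic_energy,
    langevin_gs_sampler,
    numerical_forces,
    restraint_energy_forces,
    velocity_verlet_run,
    vertical_excitation_initial_conditions,
)
from mshk.surrogate import SurrogateSurface, template_geometry


class TestRestraint:
    def test_planar_geometry_has_zero_restraint(self, template):
        e, f = restraint_energy_forces(template, RestraintSpec())
        assert e == 0.0
        assert np.all(f == 0.0)

    def test_hydrogen_at_one_bohr(self):
        g = Geometry([1], [[0.0, 0.0, BOHR_TO_ANGSTROM]])
        e, f = restraint_energy_forces(g, RestraintSpec())
        # 1/2 * 9 kcal/(mol bohr^2) * (1 bohr)^2
        assert e == pytest.approx(4.5)
        # force in kcal/(mol A); in bohr units it is -9 kcal/(mol bohr)
        assert f[0, 2] * BOHR_TO_ANGSTROM == pytest.approx(-9.0)
        assert np.all(f[:, :2] == 0.0)

    def test_quadratic_scaling(self):
        g1 = Geometry([8], [[0.0, 0.0, 0.2]])
        g2 = Geometry([8], [[0.0, 0.0, 0.4]])
        e1, _ = restraint_energy_forces(g1, RestraintSpec())
        e2, _ = restraint_energy_forces(g2, RestraintSpec())
        assert e2 == pytest.approx(4.0 * e1)

    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            RestraintSpec(k_hydrogen=-1.0)


class _Harmonic1D:
    def __init__(self, k):
        self.k = k

    def energy(self, geometry):
        return 0.5 * self.k * geometry.coordinates[0, 0] ** 2

    def energy_and_forces(self, geometry):
        f = np.zeros_like(geometry.coordinates)
        f[0, 0] = -self.k * geometry.coordinates[0, 0]
        return self.energy(geometry), f


class TestNumericalForces:
    def test_constant_surface_zero_forces(self, template):
        class Flat:
            def energy(self, geometry):
                return 3.14

        f = numerical_forces(Flat(), template)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_harmonic_force_error_below_1e6(self):
        surf = _Harmonic1D(1.0)
        g = Geometry([1], [[0.5, 0.0, 0.0]])
        f = numerical_forces(surf, g, dx=0.001)
        assert abs(f[0, 0] - (-0.5)) < 1e-6

    def test_surrogate_matches_analytic_to_1em4(self, spec, perturbed_geometries):
        g = perturbed_geometries[2]
        surf = SurrogateSurface(spec, 2)
        numeric = numerical_forces(surf, g, dx=0.001)
        np.testing.assert_allclose(numeric, surf.forces(g), atol=1e-4)

    def test_nonfinite_energy_reported_with_displacement(self, template):
        class Bad:
            def energy(self, geometry):
                return np.nan

        with pytest.raises(FloatingPointError, match="atom=0"):
            numerical_forces(Bad(), template)


class TestVelocityVerlet:
    def test_free_flight_is_exact(self):
        class Free:
            def energy_and_forces(self, geometry):
                return 0.0, np.zeros_like(geometry.coordinates)

        g = Geometry([1], [[0.0, 0.0, 0.0]])
        v0 = np.array([[0.01, -0.02, 0.005]])
        traj = velocity_verlet_run(AnalyticForceField(Free()), MDState(g, v0), timestep=0.5, n_steps=100)
        np.testing.assert_allclose(traj.positions[-1, 0], v0[0] * 50.0, atol=1e-12)

    def test_harmonic_period(self):
        k = 100.0
        surf = _Harmonic1D(k)
        g = Geometry([1], [[0.3, 0.0, 0.0]])
        traj = velocity_verlet_run(
            AnalyticForceField(surf), MDState(g, np.zeros((1, 3))), timestep=0.25, n_steps=500
        )
        x = traj.positions[:, 0, 0]
        crossings = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0))
        measured = np.mean(np.diff(crossings)) * traj.timestep
        expected = 2 * np.pi * np.sqrt(ATOMIC_MASSES[1] / (k * KCAL_MOL_TO_MECH))
        assert measured == pytest.approx(expected, rel=1e-3)

    def test_total_energy_recorded(self, spec, template):
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        traj = velocity_verlet_run(
            ff, MDState(template, np.zeros((9, 3))), timestep=0.25, n_steps=10
        )
        assert traj.n_frames == 11
        assert np.all(np.isfinite(traj.total_energies))

    def test_xy_momentum_conserved_under_restraint(self, spec, template, rng):
        masses = template.masses
        v0 = 0.01 * rng.standard_normal((9, 3))
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        traj = velocity_verlet_run(ff, MDState(template, v0), timestep=0.25, n_steps=200)
        p0 = (masses[:, None] * traj.velocities[0]).sum(axis=0)
        p1 = (masses[:, None] * traj.velocities[-1]).sum(axis=0)
        # the z-restraint breaks only the z translation
        np.testing.assert_allclose(p1[:2], p0[:2], atol=1e-10)

    def test_determinism(self, spec, template, rng):
        v0 = 0.01 * rng.standard_normal((9, 3))
        ff = AnalyticForceField(SurrogateSurface(spec, 2), RestraintSpec())
        t1 = velocity_verlet_run(ff, MDState(template, v0.copy()), n_steps=50)
        t2 = velocity_verlet_run(ff, MDState(template, v0.copy()), n_steps=50)
        np.testing.assert_array_equal(t1.positions, t2.positions)


class TestLangevin:
    def test_equipartition(self, spec, template):
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        traj = langevin_gs_sampler(
            ff,
            MDState(template, np.zeros((9, 3))),
            temperature=300.0,
            friction=0.05,
            timestep=0.5,
            n_steps=30000,
            seed=7,
        )
        kt_per_dof = traj.kinetic_energies[4000:].mean() / (3 * 9 / 2)
        assert kt_per_dof == pytest.approx(KB_KCAL_MOL * 300.0, rel=0.05)

    def test_zero_temperature_limit_relaxes(self, spec, template, rng):
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        hot = MDState(template, 0.02 * rng.standard_normal((9, 3)))
        traj = langevin_gs_sampler(
            ff, hot, temperature=1e-6, friction=0.5, timestep=0.5, n_steps=4000, seed=3
        )
        assert traj.kinetic_energies[-1] < 1e-4
        assert traj.potential_energies[-1] < traj.potential_energies[0] + 1e-6

    def test_seed_reproducibility(self, spec, template):
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        t1 = langevin_gs_sampler(ff, MDState(template, np.zeros((9, 3))), n_steps=100, seed=5)
        t2 = langevin_gs_sampler(ff, MDState(template, np.zeros((9, 3))), n_steps=100, seed=5)
        np.testing.assert_array_equal(t1.positions, t2.positions)


class TestVerticalExcitation:
    def test_counting(self, spec, template):
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        traj = langevin_gs_sampler(
            ff, MDState(template, np.zeros((9, 3))), timestep=0.5, n_steps=2000, seed=1
        )  # 1000 fs
        ics = vertical_excitation_initial_conditions(traj, interval_fs=100.0, target_state=2)
        assert len(ics) == 10

    def test_phase_space_point_unchanged(self, spec, template):
        ff = AnalyticForceField(SurrogateSurface(spec, 0), RestraintSpec())
        traj = langevin_gs_sampler(
            ff, MDState(template, np.zeros((9, 3))), timestep=0.5, n_steps=600, seed=1
        )
        ics = vertical_excitation_initial_conditions(traj, interval_fs=100.0)
        frame = ics[0].provenance["source_frame"]
        np.testing.assert_array_equal(ics[0].geometry.coordinates, traj.positions[frame])
        np.testing.assert_array_equal(ics[0].velocities, traj.velocities[frame])

    def test_empty_trajectory_rejected(self, spec, template):
        ff = AnalyticForceField(SurrogateSurface(spec, 0))
        traj = velocity_verlet_run(ff, MDState(template, np.zeros((9, 3))), n_steps=1)
        with pytest.raises(ValueError):
            vertical_excitation_initial_conditions(
                traj.__class__(**{**traj.__dict__, "positions": traj.positions[:0],
                                  "velocities": traj.velocities[:0], "times": traj.times[:0],
                                  "potential_energies": traj.potential_energies[:0],
                                  "restraint_energies": traj.restraint_energies[:0],
                                  "kinetic_energies": traj.kinetic_energies[:0]}),
                100.0,
            )


def test_kinetic_energy_definition(rng):
    masses = np.array([1.008, 15.999])
    v = rng.standard_normal((2, 3)) * 0.01
    expected = 0.5 * (masses[:, None] * v**2).sum() / KCAL_MOL_TO_MECH
    assert kinetic_energy(masses, v) == pytest.approx(expected, rel=1e-12)
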