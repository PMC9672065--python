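"""Excited-state molecular dynamics on ML or analytic surfaces.

NVE propagation uses velocity Verlet with a 0.25 fs default timestep.
Forces on ML surfaces are obtained by central finite differences with a
step of dx = 0.001 A (6N energy evaluations per step, batched where the
surface supports it); analytic surfaces supply their own gradients.
Planarity is maintained by a harmonic restraint on the out-of-plane
coordinate of every atom,

    V_rest = sum_a 1/2 k_a z_a^2,

with k_a = 9 kcal/(mol bohr^2) for hydrogen and 40 kcal/(mol bohr^2)
for heavy atoms (stiffer, because backbone torsions drive the S2/S1
electronic crossing that planarity is meant to suppress).

Internal units: A, fs, amu, kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_TO_ANGSTROM, KB_KCAL_MOL, KCAL_MOL_TO_MECH, MECH_TO_KCAL_MOL
from .geometry import Geometry

__all__ = [
    "RestraintSpec",
    "MDState",
    "Trajectory",
    "AnalyticForceField",
    "NumericalForceField",
    "restraint_energy_forces",
    "numerical_forces",
    "kinetic_energy",
    "velocity_verlet_run",
    "energy_drift",
    "langevin_gs_sampler",
    "vertical_excitation_initial_conditions",
]

DEFAULT_TIMESTEP_FS = 0.25
DEFAULT_FD_STEP = 0.001  # A


@dataclass(frozen=True)
class RestraintSpec:
    """Per-element planarity force constants, input in kcal/(mol bohr^2)."""

    k_hydrogen: float = 9.0
    k_heavy: float = 40.0

    def __post_init__(self):
        if self.k_hydrogen < 0 or self.k_heavy < 0:
            raise ValueError("restraint force constants must be non-negative")

    def constants_per_angstrom2(self, atomic_numbers: np.ndarray) -> np.ndarray:
        """k_a converted to kcal/(mol A^2), one per atom."""
        k = np.where(np.asarray(atomic_numbers) == 1, self.k_hydrogen, self.k_heavy)
        return k / BOHR_TO_ANGSTROM**2


def restraint_energy_forces(
    geometry: Geometry, restraint: RestraintSpec
) -> tuple[float, np.ndarray]:
    """V_rest = sum 1/2 k_a z_a^2 with analytic forces (z only)."""
    k = restraint.constants_per_angstrom2(geometry.atomic_numbers)
    z = geometry.coordinates[:, 2]
    energy = float(0.5 * np.sum(k * z**2))
    forces = np.zeros_like(geometry.coordinates)
    forces[:, 2] = -k * z
    return energy, forces


def _batch_energies(surface, geometries: list[Geometry]) -> np.ndarray:
    if hasattr(surface, "energy_batch"):
        return np.asarray(surface.energy_batch(geometries), dtype=float)
    return np.array([surface.energy(g) for g in geometries], dtype=float)


def numerical_forces(surface, geometry: Geometry, dx: float = DEFAULT_FD_STEP) -> np.ndarray:
    """Central-difference forces F_i = -(E(+dx e_i) - E(-dx e_i)) / 2 dx.

    ``surface`` must expose ``energy(geometry) -> float`` (kcal/mol) and
    may expose ``energy_batch(list[Geometry])`` to amortise kernel
    evaluations over all 6N displacements.
    """
    if dx <= 0:
        raise ValueError("finite-difference step dx must be positive")
    n = geometry.n_atoms
    displaced = []
    base = geometry.coordinates
    for i in range(n):
        for ax in range(3):
            for sign in (+1.0, -1.0):
                xyz = base.copy()
                xyz[i, ax] += sign * dx
                displaced.append(geometry.with_coordinates(xyz))
    energies = _batch_energies(surface, displaced)
    if not np.all(np.isfinite(energies)):
        bad = int(np.flatnonzero(~np.isfinite(energies))[0])
        atom, rem = divmod(bad, 6)
        axis, sign = divmod(rem, 2)
        raise FloatingPointError(
            f"non-finite energy at displacement atom={atom} axis={axis} "
            f"sign={'+' if sign == 0 else '-'}dx"
        )
    e = energies.reshape(n, 3, 2)
    return -(e[:, :, 0] - e[:, :, 1]) / (2.0 * dx)


class NumericalForceField:
    """Adapter: energy surface + optional restraint -> energies and forces.

    Surface forces come from central differences; restraint forces are
    analytic.  The total potential is E_surface + V_rest.
    """

    def __init__(self, surface, restraint: RestraintSpec | None = None, dx: float = DEFAULT_FD_STEP):
        self.surface = surface
        self.restraint = restraint
        self.dx = dx

    def energy_and_forces(self, geometry: Geometry) -> tuple[float, float, np.ndarray]:
        e_surf = float(self.surface.energy(geometry))
        f = numerical_forces(self.surface, geometry, self.dx)
        e_rest = 0.0
        if self.restraint is not None:
            e_rest, f_rest = restraint_energy_forces(geometry, self.restraint)
            f = f + f_rest
        return e_surf, e_rest, f


class AnalyticForceField:
    """Same contract for surfaces with analytic gradients."""

    def __init__(self, surface, restraint: RestraintSpec | None = None):
        self.surface = surface
        self.restraint = restraint

    def energy_and_forces(self, geometry: Geometry) -> tuple[float, float, np.ndarray]:
        e_surf, f = self.surface.energy_and_forces(geometry)
        e_rest = 0.0
        if self.restraint is not None:
            e_rest, f_rest = restraint_energy_forces(geometry, self.restraint)
            f = f + f_rest
        return float(e_surf), e_rest, f


@dataclass
class MDState:
    """Instantaneous phase-space point (A, A/fs, fs, kcal/mol)."""

    geometry: Geometry
    velocities: np.ndarray
    time: float = 0.0
    potential_energy: float = np.nan
    kinetic_energy: float = np.nan
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.shape != self.geometry.coordinates.shape:
            raise ValueError("velocities must match coordinates in shape")


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """1/2 sum m v^2 in kcal/mol."""
    return float(0.5 * np.sum(masses[:, None] * velocities**2) * MECH_TO_KCAL_MOL)


@dataclass
class Trajectory:
    """Uniformly spaced time series of an MD run."""

    atomic_numbers: np.ndarray
    labels: dict
    positions: np.ndarray      # (T, N, 3) A
    velocities: np.ndarray     # (T, N, 3) A/fs
    times: np.ndarray          # (T,) fs
    potential_energies: np.ndarray
    restraint_energies: np.ndarray
    kinetic_energies: np.ndarray
    timestep: float
    surface_id: int = 0
    restraint: RestraintSpec | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def total_energies(self) -> np.ndarray:
        return self.potential_energies + self.restraint_energies + self.kinetic_energies

    def frame(self, i: int) -> Geometry:
        return Geometry(self.atomic_numbers, self.positions[i], self.labels)

    def state(self, i: int) -> MDState:
        return MDState(
            geometry=self.frame(i),
            velocities=self.velocities[i],
            time=float(self.times[i]),
            potential_energy=float(self.potential_energies[i] + self.restraint_energies[i]),
            kinetic_energy=float(self.kinetic_energies[i]),
        )


def velocity_verlet_run(
    force_field,
    initial: MDState,
    timestep: float = DEFAULT_TIMESTEP_FS,
    n_steps: int = 240,
    surface_id: int = 0,
    record_every: int = 1,
) -> Trajectory:
    """Microcanonical velocity-Verlet propagation.

    ``force_field`` exposes
    ``energy_and_forces(geometry) -> (E_surface, E_restraint, F)`` with
    forces in kcal/(mol A).  Total energy (surface + restraint +
    kinetic) is recorded for every stored frame.
    """
    geom = initial.geometry
    masses = geom.masses
    inv_m = (KCAL_MOL_TO_MECH / masses)[:, None]  # F [kcal/mol/A] -> a [A/fs^2]
    x = geom.coordinates.copy()
    v = initial.velocities.copy()
    e_surf, e_rest, f = force_field.energy_and_forces(geom.with_coordinates(x))

    n_rec = n_steps // record_every + 1
    pos = np.empty((n_rec, geom.n_atoms, 3))
    vel = np.empty_like(pos)
    times = np.empty(n_rec)
    e_pot = np.empty(n_rec)
    e_res = np.empty(n_rec)
    e_kin = np.empty(n_rec)

    def record(idx, step):
        pos[idx] = x
        vel[idx] = v
        times[idx] = initial.time + step * timestep
        e_pot[idx] = e_surf
        e_res[idx] = e_rest
        e_kin[idx] = kinetic_energy(masses, v)

    record(0, 0)
    rec = 1
    for step in range(1, n_steps + 1):
        v_half = v + 0.5 * timestep * f * inv_m
        x = x + timestep * v_half
        e_surf, e_rest, f = force_field.energy_and_forces(geom.with_coordinates(x))
        v = v_half + 0.5 * timestep * f * inv_m
        if step % record_every == 0:
            record(rec, step)
            rec += 1

    return Trajectory(
        atomic_numbers=geom.atomic_numbers,
        labels=dict(geom.labels),
        positions=pos,
        velocities=vel,
        times=times,
        potential_energies=e_pot,
        restraint_energies=e_res,
        kinetic_energies=e_kin,
        timestep=timestep * record_every,
        surface_id=surface_id,
        restraint=getattr(force_field, "restraint", None),
    )


def langevin_gs_sampler(
    force_field,
    initial: MDState,
    temperature: float = 300.0,
    friction: float = 0.1,
    timestep: float = 0.5,
    n_steps: int = 20000,
    seed: int = 0,
    record_every: int = 1,
    surface_id: int = 0,
) -> Trajectory:
    """Canonical (NVT) sampling with the BAOAB Langevin splitting.

    Used to draw thermalised ground-state configurations at 300 K from
    which vertical excitations are launched.  Fully reproducible for a
    fixed seed.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if friction < 0:
        raise ValueError("friction must be non-negative")
    rng = np.random.default_rng(seed)
    geom = initial.geometry
    masses = geom.masses
    inv_m = (KCAL_MOL_TO_MECH / masses)[:, None]
    kt_mech = KB_KCAL_MOL * temperature * KCAL_MOL_TO_MECH  # amu A^2/fs^2
    sigma_v = np.sqrt(kt_mech / masses)[:, None]            # A/fs
    c1 = np.exp(-friction * timestep)
    c2 = np.sqrt(max(0.0, 1.0 - c1**2))

    x = geom.coordinates.copy()
    v = initial.velocities.copy()
    e_surf, e_rest, f = force_field.energy_and_forces(geom.with_coordinates(x))

    n_rec = n_steps // record_every + 1
    pos = np.empty((n_rec, geom.n_atoms, 3))
    vel = np.empty_like(pos)
    times = np.empty(n_rec)
    e_pot = np.empty(n_rec)
    e_res = np.empty(n_rec)
    e_kin = np.empty(n_rec)

    pos[0], vel[0], times[0] = x, v, initial.time
    e_pot[0], e_res[0], e_kin[0] = e_surf, e_rest, kinetic_energy(masses, v)
    rec = 1
    for step in range(1, n_steps + 1):
        v = v + 0.5 * timestep * f * inv_m
        x = x + 0.5 * timestep * v
        v = c1 * v + c2 * sigma_v * rng.standard_normal(v.shape)
        x = x + 0.5 * timestep * v
        e_surf, e_rest, f = force_field.energy_and_forces(geom.with_coordinates(x))
        v = v + 0.5 * timestep * f * inv_m
        if step % record_every == 0:
            pos[rec], vel[rec] = x, v
            times[rec] = initial.time + step * timestep
            e_pot[rec], e_res[rec] = e_surf, e_rest
            e_kin[rec] = kinetic_energy(masses, v)
            rec += 1

    return Trajectory(
        atomic_numbers=geom.atomic_numbers,
        labels=dict(geom.labels),
        positions=pos,
        velocities=vel,
        times=times,
        potential_energies=e_pot,
        restraint_energies=e_res,
        kinetic_energies=e_kin,
        timestep=timestep * record_every,
        surface_id=surface_id,
        restraint=getattr(force_field, "restraint", None),
        provenance={"seed": seed, "temperature": temperature, "friction": friction},
    )


def vertical_excitation_initial_conditions(
    gs_trajectory: Trajectory, interval_fs: float = 100.0, target_state: int = 2
) -> list[MDState]:
    """Snapshots every ``interval_fs`` with positions/velocities unchanged.

    A vertical excitation promotes the electronic state at fixed nuclear
    phase-space point; only the surface index changes (bookkept by the
    caller via ``target_state``).
    """
    if gs_trajectory.n_frames == 0:
        raise ValueError("ground-state trajectory is empty")
    stride = max(1, int(round(interval_fs / gs_trajectory.timestep)))
    states = []
    for i in range(stride, gs_trajectory.n_frames, stride):
        s = gs_trajectory.state(i)
        s.provenance = {"source_frame": i, "target_state": target_state}
        states.append(s)
    return states


def energy_drift(trajectory: Trajectory) -> float:
    """Secular total-energy drift over a run (kcal/mol).

    The absolute linear-trend change |slope * duration| of the total
    energy.  A symplectic integrator shows bounded quasi-periodic energy
    fluctuation; the secular trend is the meaningful conservation
    metric, and it scales as O(dt^2) for velocity Verlet.
    """
    t = trajectory.times - trajectory.times[0]
    e = trajectory.total_energies
    if t.size < 2:
        return 0.0
    slope = np.polyfit(t, e, 1)[0]
    return float(abs(slope * (t[-1] - t[0])))
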