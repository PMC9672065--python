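"""Analytic multistate reference surface and densities (synthetic oracle).

This module is a self-contained, fully synthetic stand-in for the
electronic-structure reference: a planar malonaldehyde-like molecule
(C3O2H4, 9 atoms) with closed-form state energies, analytic forces and
smooth atom-centred Gaussian densities.  It lets every stage of the
pipeline (dataset construction, density/energy learning, excited-state
MD, observables) be exercised and checked against exact answers.

Energy model per electronic state j (kcal/mol):

    E_j = A_j (d_OO - d_j)^2                       donor-acceptor stretch
        + B_j (r_-^4 - 2 c_j(d_OO) r_-^2)          gated proton double well
        + 1/2 k_+ (r_+ - r_+^ref)^2                keeps H between the O's
        + 1/2 k_bb sum_pairs (d_ab - d_ab^ref)^2   backbone stiffness
        + Delta_j                                  vertical offset

with r_± = r_HO1 ± r_HO2 and a smoothly *gated* well separation
c_j(d_OO) that is ~ s_j (d_OO - g_j) above the gating distance g_j and
exponentially small below it.  The well minima sit at r_-^2 = c_j with
a proton-transfer barrier of B_j c_j(d_OO)^2 in closed form; below the
gate the double well collapses into a single minimum at r_- = 0 and
the barrier vanishes.  The default parameters put the S2 gate at
2.45 A and the ground-state equilibrium d_OO near 2.57 A, mimicking the
scales of the real photoacid physics (contraction of the O-O distance
gates an essentially barrierless excited-state proton transfer) without
claiming any ab initio number.

Densities are sums of normalised atom-centred Gaussians whose weights
are state dependent (S1 piles charge onto the central carbon, S2
depletes it), so the state density differences are nonzero, distinct
and symmetric under the donor/acceptor exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import DensityField
from .geometry import Geometry
from .grid import GridSpec
from .md import (
    AnalyticForceField,
    MDState,
    RestraintSpec,
    Trajectory,
    langevin_gs_sampler,
    velocity_verlet_run,
    vertical_excitation_initial_conditions,
)

__all__ = [
    "StateParams",
    "SurrogateSpec",
    "default_spec",
    "crossing_spec",
    "template_geometry",
    "SIGMA_V_PERMUTATION",
    "surrogate_energies",
    "surrogate_forces",
    "surrogate_density",
    "closed_form_barrier",
    "SurrogateSurface",
    "SurrogateReference",
    "generate_reference_dataset",
]

# ---------------------------------------------------------------- template

_TEMPLATE_Z = np.array([8, 8, 6, 6, 6, 1, 1, 1, 1])
_TEMPLATE_XYZ = np.array(
    [
        [-1.30, 1.10, 0.0],   # O1 donor oxygen
        [1.30, 1.10, 0.0],    # O2 acceptor oxygen
        [-1.20, -0.15, 0.0],  # C1
        [0.00, -0.85, 0.0],   # C2 (central)
        [1.20, -0.15, 0.0],   # C3
        [0.00, 1.45, 0.0],    # Ht (transferring proton)
        [-2.15, -0.60, 0.0],  # H1 on C1
        [0.00, -1.95, 0.0],   # H2 on C2
        [2.15, -0.60, 0.0],   # H3 on C3
    ]
)
_TEMPLATE_LABELS = {"O1": 0, "O2": 1, "H": 5}

#: sigma_v' involution: O1<->O2, C1<->C3, H1<->H3; the rest are on the plane.
SIGMA_V_PERMUTATION = (1, 0, 4, 3, 2, 5, 8, 7, 6)


def template_geometry() -> Geometry:
    """Planar C2v proton-transfer transition-state template (r_- = 0)."""
    return Geometry(_TEMPLATE_Z.copy(), _TEMPLATE_XYZ.copy(), dict(_TEMPLATE_LABELS))


# ----------------------------------------------------------------- spec


@dataclass(frozen=True)
class StateParams:
    """Per-state parameters of the analytic surface."""

    oo_stiffness: float   # A_j, kcal/(mol A^2)
    oo_center: float      # d_j, A
    well_strength: float  # B_j, kcal/(mol A^4)
    well_slope: float     # s_j, A (c_j has units A^2)
    gate_distance: float  # g_j, A
    offset: float         # Delta_j, kcal/mol
    gate_width: float = 0.1   # A; smoothing of the gate switch
    density_shift: dict = field(default_factory=dict)  # atom index -> delta weight (e)

    def well_separation(self, d_oo) -> np.ndarray:
        """c_j(d_OO) = s_j * w * softplus((d_OO - g_j) / w).

        A smooth (C-infinity) gating of the well separation: linear with
        slope s_j well above the gate distance g_j, exponentially small
        below it, rounded over a width w.  Smoothness keeps the MD
        forces free of corners at the gate.
        """
        t = (np.asarray(d_oo, float) - self.gate_distance) / self.gate_width
        return self.well_slope * self.gate_width * np.logaddexp(0.0, t)

    def well_separation_slope(self, d_oo) -> np.ndarray:
        """dc_j/dd_OO (logistic switch)."""
        t = (np.asarray(d_oo, float) - self.gate_distance) / self.gate_width
        with np.errstate(over="ignore"):
            return self.well_slope / (1.0 + np.exp(-t))


@dataclass(frozen=True)
class SurrogateSpec:
    """Full parameterisation of the synthetic multistate system."""

    states: tuple[StateParams, ...]
    k_plus: float = 25.0           # kcal/(mol A^2) on r_+ = r_HO1 + r_HO2
    k_backbone: float = 160.0      # kcal/(mol A^2) per heavy-heavy pair
    k_backbone_h: float = 8.0      # kcal/(mol A^2) per H-involving pair
    density_width: float = 0.5     # s_dens, A
    coupling_w: float = 0.0        # kcal/mol; diabatic coupling between states 1 and 2
    cross_weight: float = 1.0      # e; amplitude of the interference density

    def __post_init__(self):
        for st in self.states:
            if st.oo_stiffness <= 0 or st.well_strength <= 0 or st.well_slope <= 0:
                raise ValueError("state stiffness parameters must be positive")
        if min(self.k_plus, self.k_backbone, self.k_backbone_h, self.density_width) <= 0:
            raise ValueError("spec stiffness/width parameters must be positive")

    def backbone_constants(self) -> np.ndarray:
        """Per-pair force constants: soft where a hydrogen is involved.

        Hydrogen-coupled pairs are softer so that the fastest vibrations
        stay well resolved by the 0.25 fs production timestep.
        """
        is_h = (_TEMPLATE_Z[_PAIRS[:, 0]] == 1) | (_TEMPLATE_Z[_PAIRS[:, 1]] == 1)
        return np.where(is_h, self.k_backbone_h, self.k_backbone)

    @property
    def n_states(self) -> int:
        return len(self.states)


def _backbone_pairs() -> list[tuple[int, int]]:
    """All pairs among the non-transferring atoms except (O1, O2)."""
    heavy = [0, 1, 2, 3, 4, 6, 7, 8]
    pairs = [
        (a, b) for i, a in enumerate(heavy) for b in heavy[i + 1 :] if (a, b) != (0, 1)
    ]
    return pairs


_PAIRS = np.array(_backbone_pairs())
_TPL_PAIR_DIST = np.linalg.norm(
    _TEMPLATE_XYZ[_PAIRS[:, 0]] - _TEMPLATE_XYZ[_PAIRS[:, 1]], axis=1
)
_RPLUS_REF = float(
    np.linalg.norm(_TEMPLATE_XYZ[5] - _TEMPLATE_XYZ[0])
    + np.linalg.norm(_TEMPLATE_XYZ[5] - _TEMPLATE_XYZ[1])
)


def default_spec() -> SurrogateSpec:
    """Shipped default parameters (see docs for the rationale).

    Ground state: double well with a ~2.0 kcal/mol barrier at its
    equilibrium d_OO = 2.57 A, matching the thermochemistry of the
    hybrid-DFT reference the oracle stands in for (the proton hops
    occasionally at 300 K, so the transition-state ridge is represented
    in thermal data).  S2: equilibrium d_OO at the 2.45 A gate, so
    excitation drives an O-O contraction that switches off the
    proton-transfer barrier (~2.2 kcal/mol at 2.57 A, vanishing below
    2.45 A).  Vertical offsets place S1/S2 at roughly 4.1/5.2 eV.  All
    stiffnesses are soft enough that a 0.25 fs NVE step resolves the
    fastest mode by a factor of ~50.
    """
    s0 = StateParams(100.0, 2.53, 8.0, 1.06, 2.10, 0.0)
    # Both excitations move charge from the terminal C-H bonds onto the
    # ring carbons (a component shared by the two excited diabats, so
    # any mixture of them stays distinguishable from the ground state);
    # the opposite-signed C2/O patterns distinguish the two excited
    # characters.  The transferring proton keeps its full weight in
    # every state so each state's density resolves the proton position.
    s1 = StateParams(
        90.0, 2.52, 6.25, 1.40, 2.00, 95.0,
        density_shift={6: -0.3, 8: -0.3, 2: +0.3, 4: +0.3, 3: +1.0, 0: -0.5, 1: -0.5},
    )
    s2 = StateParams(
        160.0, 2.45, 8.4, 3.42, 2.45, 120.0,
        density_shift={6: -0.3, 8: -0.3, 2: +0.3, 4: +0.3, 3: -1.0, 0: +0.5, 1: +0.5},
    )
    return SurrogateSpec(states=(s0, s1, s2))


def crossing_spec() -> SurrogateSpec:
    """Variant whose S1/S2 surfaces nearly intersect along a d_OO seam.

    The two excited diabats get different O-O curvatures and offsets so
    that their order swaps inside the thermally sampled region (seam
    near d_OO ~ 2.47 A), and a small diabatic coupling W turns the
    intersection into an avoided crossing: adiabatic energies

        E_mp = (E_1 + E_2)/2 -/+ sqrt(((E_2 - E_1)/2)^2 + W^2)

    approach within 2W at the seam and curve sharply there (radius set
    by W), while the adiabatic densities interpolate smoothly between
    the two diabatic characters and carry an interference component
    that keeps the two states' densities distinct at the seam.  Direct
    per-state potential->energy regression must resolve the sharp
    avoided-crossing feature; the density route sees only smooth maps.
    """
    base = default_spec()
    s1 = replace(
        base.states[1], oo_stiffness=300.0, oo_center=2.75, offset=96.34
    )
    return SurrogateSpec(
        states=(base.states[0], s1, base.states[2]), coupling_w=0.02
    )


# ------------------------------------------------------------- energies


def _internal_coordinates(geometry: Geometry):
    xyz = geometry.coordinates
    io1, io2, ih = (
        geometry.labeled_index("O1"),
        geometry.labeled_index("O2"),
        geometry.labeled_index("H"),
    )
    v1 = xyz[ih] - xyz[io1]
    v2 = xyz[ih] - xyz[io2]
    voo = xyz[io1] - xyz[io2]
    r1 = float(np.linalg.norm(v1))
    r2 = float(np.linalg.norm(v2))
    doo = float(np.linalg.norm(voo))
    return io1, io2, ih, v1, v2, voo, r1, r2, doo


def _shared_terms(geometry: Geometry, spec: SurrogateSpec):
    """State-independent energy pieces: r_+ spring and backbone pairs."""
    xyz = geometry.coordinates
    *_, r1, r2, _ = _internal_coordinates(geometry)
    e_plus = 0.5 * spec.k_plus * (r1 + r2 - _RPLUS_REF) ** 2
    d = np.linalg.norm(xyz[_PAIRS[:, 0]] - xyz[_PAIRS[:, 1]], axis=1)
    e_bb = 0.5 * np.sum(spec.backbone_constants() * (d - _TPL_PAIR_DIST) ** 2)
    return float(e_plus + e_bb)


def _diabatic_energies(spec: SurrogateSpec, geometry: Geometry) -> np.ndarray:
    *_, r1, r2, doo = _internal_coordinates(geometry)
    rm = r1 - r2
    shared = _shared_terms(geometry, spec)
    out = np.empty(spec.n_states)
    for j, st in enumerate(spec.states):
        c = float(st.well_separation(doo))
        # depressed quartic B (r^4 - 2 c r^2): same wells (r^2 = c) and
        # barrier (B c^2) as B (r^2 - c)^2, but linear in the gated c so
        # the gate contributes no steep cross-curvature to the forces
        out[j] = (
            st.oo_stiffness * (doo - st.oo_center) ** 2
            + st.well_strength * (rm**4 - 2.0 * c * rm**2)
            + shared
            + st.offset
        )
    return out


def _mixing(spec: SurrogateSpec, e_diab: np.ndarray) -> tuple[np.ndarray, float]:
    """Adiabatic energies and the lower-state diabat-1 population c1^2.

    With ``coupling_w`` = 0 the diabats are the adiabats (c1^2 = 1).
    Otherwise states 1 and 2 form a two-level avoided crossing with
    constant diabatic coupling W.
    """
    if spec.coupling_w == 0.0 or spec.n_states < 3:
        return e_diab, 1.0
    e1, e2 = e_diab[1], e_diab[2]
    m = 0.5 * (e1 + e2)
    q = 0.5 * (e2 - e1)
    s = np.hypot(q, spec.coupling_w)
    out = e_diab.copy()
    out[1], out[2] = m - s, m + s
    c1sq = 0.5 * (1.0 + q / s)
    return out, float(c1sq)


def surrogate_energies(spec: SurrogateSpec, geometry: Geometry) -> np.ndarray:
    """Per-state adiabatic energies (kcal/mol)."""
    e, _ = _mixing(spec, _diabatic_energies(spec, geometry))
    return e


def _diabatic_gradient(spec: SurrogateSpec, geometry: Geometry, state: int) -> np.ndarray:
    st = spec.states[state]
    io1, io2, ih, v1, v2, voo, r1, r2, doo = _internal_coordinates(geometry)
    xyz = geometry.coordinates
    u1, u2, uoo = v1 / r1, v2 / r2, voo / doo
    rm = r1 - r2
    c = float(st.well_separation(doo))
    w = rm**2 - c
    grad = np.zeros_like(xyz)

    # O-O stretch
    g = 2.0 * st.oo_stiffness * (doo - st.oo_center)
    grad[io1] += g * uoo
    grad[io2] -= g * uoo

    # double well: dE/dr- and the gated dE/dc chain through d_OO
    g_rm = 4.0 * st.well_strength * w * rm
    grad[ih] += g_rm * (u1 - u2)
    grad[io1] += -g_rm * u1
    grad[io2] += g_rm * u2
    g_c = -2.0 * st.well_strength * rm**2 * float(st.well_separation_slope(doo))
    grad[io1] += g_c * uoo
    grad[io2] -= g_c * uoo

    # r_+ spring
    g_p = spec.k_plus * (r1 + r2 - _RPLUS_REF)
    grad[ih] += g_p * (u1 + u2)
    grad[io1] += -g_p * u1
    grad[io2] += -g_p * u2

    # backbone pairs
    da = xyz[_PAIRS[:, 0]] - xyz[_PAIRS[:, 1]]
    dn = np.linalg.norm(da, axis=1)
    g_bb = (spec.backbone_constants() * (dn - _TPL_PAIR_DIST) / dn)[:, None] * da
    np.add.at(grad, _PAIRS[:, 0], g_bb)
    np.add.at(grad, _PAIRS[:, 1], -g_bb)
    return grad


def surrogate_forces(spec: SurrogateSpec, geometry: Geometry, state: int = 0) -> np.ndarray:
    """Analytic forces -dE_state/dR in kcal/(mol A).

    For the coupled excited states the Hellmann-Feynman gradient of the
    two-level eigenvalue is the population-weighted diabatic gradient.
    """
    if spec.coupling_w == 0.0 or state == 0 or spec.n_states < 3:
        return -_diabatic_gradient(spec, geometry, state)
    _, c1sq = _mixing(spec, _diabatic_energies(spec, geometry))
    g1 = _diabatic_gradient(spec, geometry, 1)
    g2 = _diabatic_gradient(spec, geometry, 2)
    if state == 1:
        return -(c1sq * g1 + (1.0 - c1sq) * g2)
    return -((1.0 - c1sq) * g1 + c1sq * g2)


def closed_form_barrier(spec: SurrogateSpec, state: int, d_oo: float) -> float:
    """Exact proton-transfer barrier at fixed d_OO: B_j c_j(d_OO)^2."""
    st = spec.states[state]
    c = float(st.well_separation(d_oo))
    return st.well_strength * c**2


class SurrogateSurface:
    """Single-state energy surface view used by the MD engine."""

    def __init__(self, spec: SurrogateSpec, state: int):
        if not 0 <= state < spec.n_states:
            raise ValueError(f"state {state} not in spec with {spec.n_states} states")
        self.spec = spec
        self.state = state

    def energy(self, geometry: Geometry) -> float:
        return float(surrogate_energies(self.spec, geometry)[self.state])

    def energy_batch(self, geometries) -> np.ndarray:
        return np.array([self.energy(g) for g in geometries])

    def forces(self, geometry: Geometry) -> np.ndarray:
        return surrogate_forces(self.spec, geometry, self.state)

    def energy_and_forces(self, geometry: Geometry) -> tuple[float, np.ndarray]:
        return self.energy(geometry), self.forces(geometry)


# ------------------------------------------------------------- densities


def state_density_weights(spec: SurrogateSpec, state: int) -> np.ndarray:
    """Per-atom Gaussian weights w_{a,j}; sum = 38 electrons for C3O2H4."""
    w = _TEMPLATE_Z.astype(float).copy()
    for idx, dw in spec.states[state].density_shift.items():
        w[idx] += dw
    return w


def _gaussian_sum(weights, centers, s: float, grid: GridSpec) -> np.ndarray:
    norm = (2.0 * np.pi * s**2) ** -1.5
    inv = 1.0 / (2.0 * s**2)
    axes = [grid.axis_coordinates(i) for i in range(3)]
    out = np.zeros(grid.shape)
    for wa, pos in zip(weights, centers):
        if wa == 0.0:
            continue
        gx = np.exp(-inv * (axes[0] - pos[0]) ** 2)
        gy = np.exp(-inv * (axes[1] - pos[1]) ** 2)
        gz = np.exp(-inv * (axes[2] - pos[2]) ** 2)
        out += wa * norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    return out


def surrogate_density(
    spec: SurrogateSpec, geometry: Geometry, state: int, grid: GridSpec
) -> DensityField:
    """State density on the grid (e/A^3).

    Uncoupled states: n_j(r) = sum_a w_{a,j} G(r; R_a, s_dens).  With a
    diabatic coupling, the two excited adiabats carry the
    population-weighted mixture of the two diabatic densities plus an
    interference term (a zero-charge dipolar pattern between the
    central carbon and the O-O midpoint, weight +/- 2 c1 c2 *
    cross_weight) that keeps the two states' densities distinct even at
    the seam where the populations are equal.
    """
    import warnings

    s = spec.density_width
    xyz = geometry.coordinates
    if spec.coupling_w == 0.0 or state == 0 or spec.n_states < 3:
        w = state_density_weights(spec, state)
        out = _gaussian_sum(w, xyz, s, grid)
    else:
        _, c1sq = _mixing(spec, _diabatic_energies(spec, geometry))
        p1 = c1sq if state == 1 else 1.0 - c1sq
        w = p1 * state_density_weights(spec, 1) + (1.0 - p1) * state_density_weights(spec, 2)
        out = _gaussian_sum(w, xyz, s, grid)
        amp = 2.0 * np.sqrt(max(c1sq * (1.0 - c1sq), 0.0)) * spec.cross_weight
        sign = -1.0 if state == 1 else +1.0
        mid_oo = 0.5 * (xyz[geometry.labeled_index("O1")] + xyz[geometry.labeled_index("O2")])
        c2_pos = xyz[3]
        out += _gaussian_sum(
            [sign * amp, -sign * amp], [c2_pos, mid_oo], s, grid
        )
    field_ = DensityField(grid=grid, values=out.ravel(), state_index=state)
    captured = field_.integral() / _TEMPLATE_Z.sum()
    if captured < 0.99:
        warnings.warn(
            f"grid captures only {100 * captured:.1f}% of the density mass",
            stacklevel=2,
        )
    return field_


def density_matrix_for_states(
    spec: SurrogateSpec, geometries, states, grid: GridSpec
) -> np.ndarray:
    """Flattened densities for all (geometry, state) pairs: (M, S, P)."""
    out = np.empty((len(geometries), len(states), grid.n_points))
    for i, g in enumerate(geometries):
        for sj, j in enumerate(states):
            out[i, sj] = surrogate_density(spec, g, j, grid).values
    return out


# ----------------------------------------------------- dataset generation


@dataclass
class RawDataset:
    """Unprocessed reference frames with per-state energies."""

    geometries: list
    energies: np.ndarray          # (n_frames, n_states) kcal/mol
    provenance: pd.DataFrame      # columns: source, trajectory, frame
    spec: SurrogateSpec
    seed: int

    @property
    def n_frames(self) -> int:
        return len(self.geometries)


def generate_reference_dataset(
    spec: SurrogateSpec | None = None,
    n_gs_frames: int = 2000,
    n_es_trajectories: int = 30,
    es_steps: int = 480,
    seed: int = 0,
    restraint: RestraintSpec | None = None,
    temperature: float = 300.0,
    excitation_state: int = 2,
    gs_timestep: float = 0.5,
    es_timestep: float = 0.25,
    gs_stride: int = 40,
) -> RawDataset:
    """Emulate the reference-data protocol on the synthetic system.

    One thermalised 300 K ground-state Langevin trajectory supplies
    ``n_gs_frames`` training frames and, every 100 fs, the vertical
    excitation initial conditions for ``n_es_trajectories`` NVE runs on
    the target excited state (``es_steps`` x 0.25 fs = 120 fs each, one
    stored frame per timestep).  Defaults give 2000 + 30 x 480 = 16,400
    frames.  Bit-reproducible for a fixed seed.
    """
    if spec is None:
        spec = default_spec()
    if restraint is None:
        restraint = RestraintSpec()

    gs_ff = AnalyticForceField(SurrogateSurface(spec, 0), restraint)
    template = template_geometry()
    burn_in = 2000
    # ground-state frames are taken every gs_stride steps (20 fs at the
    # default stride) so successive training frames are decorrelated
    n_production = max(
        n_gs_frames * gs_stride,
        int(np.ceil(n_es_trajectories * 100.0 / gs_timestep)),
    )
    gs_traj = langevin_gs_sampler(
        gs_ff,
        MDState(geometry=template, velocities=np.zeros((template.n_atoms, 3))),
        temperature=temperature,
        timestep=gs_timestep,
        n_steps=burn_in + n_production,
        seed=seed,
    )
    # drop burn-in, keep the production window
    production = Trajectory(
        atomic_numbers=gs_traj.atomic_numbers,
        labels=gs_traj.labels,
        positions=gs_traj.positions[burn_in:],
        velocities=gs_traj.velocities[burn_in:],
        times=gs_traj.times[burn_in:] - gs_traj.times[burn_in],
        potential_energies=gs_traj.potential_energies[burn_in:],
        restraint_energies=gs_traj.restraint_energies[burn_in:],
        kinetic_energies=gs_traj.kinetic_energies[burn_in:],
        timestep=gs_traj.timestep,
        surface_id=0,
        restraint=restraint,
    )

    geometries: list[Geometry] = []
    rows = []
    gs_indices = np.linspace(0, production.n_frames - 1, n_gs_frames).round().astype(int)
    for k, idx in enumerate(gs_indices):
        geometries.append(production.frame(int(idx)))
        rows.append({"source": "gs", "trajectory": 0, "frame": int(idx)})

    ics = vertical_excitation_initial_conditions(
        production, interval_fs=100.0, target_state=excitation_state
    )
    if len(ics) < n_es_trajectories:
        raise RuntimeError(
            f"ground-state run too short for {n_es_trajectories} excitations"
        )
    es_ff = AnalyticForceField(SurrogateSurface(spec, excitation_state), restraint)
    for t, ic in enumerate(ics[:n_es_trajectories]):
        traj = velocity_verlet_run(
            es_ff, ic, timestep=es_timestep, n_steps=es_steps, surface_id=excitation_state
        )
        # one frame per timestep, initial (ground-state) frame excluded
        for f in range(1, traj.n_frames):
            geometries.append(traj.frame(f))
            rows.append({"source": "es", "trajectory": t, "frame": f})

    energies = np.stack([surrogate_energies(spec, g) for g in geometries])
    return RawDataset(
        geometries=geometries,
        energies=energies,
        provenance=pd.DataFrame(rows),
        spec=spec,
        seed=seed,
    )


class SurrogateReference:
    """Reference-data provider facade used by the dataset pipeline."""

    def __init__(self, spec: SurrogateSpec):
        self.spec = spec

    def energies(self, geometry: Geometry) -> np.ndarray:
        return surrogate_energies(self.spec, geometry)

    def density(self, geometry: Geometry, state: int, grid: GridSpec) -> DensityField:
        return surrogate_density(self.spec, geometry, state, grid)
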