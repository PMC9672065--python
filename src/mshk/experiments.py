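"""Reusable desk-scale experiment protocols.

These drivers wire the full pipeline together at the problem sizes the
package uses for its own validation studies: a 0.25 A grid of
36 x 30 x 14 points around the template molecule and a 9 x 9 x 7
Fourier basis (567 coefficients).  They are shared by the test suite,
the command-line examples and the reproduction script so that every
reported number comes from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import BasisSpec, project_density
from .dataset import TrainingSet, build_training_set, canonicalize
from .geometry import Geometry, oxygen_oxygen_distance, proton_transfer_coordinate
from .grid import GridSpec, gaussian_potential
from .krr import KernelParams, cross_validate
from .md import (
    AnalyticForceField,
    MDState,
    RestraintSpec,
    langevin_gs_sampler,
    velocity_verlet_run,
    vertical_excitation_initial_conditions,
)
from .models import MSHKModel, MSKSMap, predict_msks, train_msks
from .surrogate import (
    SIGMA_V_PERMUTATION,
    SurrogateReference,
    SurrogateSpec,
    _RPLUS_REF,
    crossing_spec,
    default_spec,
    generate_reference_dataset,
    surrogate_density,
    surrogate_energies,
    template_geometry,
)

DESK_GRID_SHAPE = (36, 30, 14)
DESK_GRID_SPACING = 0.25
DESK_BASIS_MODES = (13, 13, 9)


def desk_grid(
    shape=DESK_GRID_SHAPE, spacing: float = DESK_GRID_SPACING
) -> GridSpec:
    """Grid centred on the template centroid (mirror-symmetric in x)."""
    centroid = tuple(template_geometry().coordinates.mean(axis=0))
    return GridSpec.centered(center=centroid, spacing=spacing, shape=shape)


def desk_basis(grid: GridSpec | None = None, modes=DESK_BASIS_MODES) -> BasisSpec:
    return BasisSpec(grid or desk_grid(), modes)


def desk_training_set(
    spec: SurrogateSpec | None = None,
    n_gs_frames: int = 2000,
    n_es_trajectories: int = 30,
    k: int = 1000,
    seed: int = 0,
    grid: GridSpec | None = None,
    basis: BasisSpec | None = None,
    states=(0, 1, 2),
) -> TrainingSet:
    """Raw reference frames -> canonicalised, clustered, doubled set."""
    spec = spec or default_spec()
    grid = grid or desk_grid()
    basis = basis or desk_basis(grid)
    raw = generate_reference_dataset(
        spec, n_gs_frames=n_gs_frames, n_es_trajectories=n_es_trajectories, seed=seed
    )
    is_gs = (raw.provenance["source"] == "gs").to_numpy()
    gs = [g for g, t in zip(raw.geometries, is_gs) if t]
    es = [g for g, t in zip(raw.geometries, is_gs) if not t]
    return build_training_set(
        gs,
        es,
        reference=template_geometry(),
        k=k,
        seed=seed,
        reference_provider=SurrogateReference(spec),
        grid=grid,
        basis=basis,
        permutation=SIGMA_V_PERMUTATION,
        states=states,
        downsample=2,
        pca_components=64,
    )


def select_hyperparameters(
    ts: TrainingSet, seed: int = 0, max_samples: int = 600, max_rows: int = 1500
) -> tuple[KernelParams, KernelParams]:
    """Cross-validated kernel widths/ridges for both KRR stages.

    CV runs on a seeded subsample to keep the grid search affordable;
    each stage is scored on its own targets (potential -> density
    coefficients, coefficient rows -> energies).
    """
    rng = np.random.default_rng(seed)
    scale = np.sqrt(ts.grid.voxel_volume)
    idx = rng.choice(ts.n_samples, min(max_samples, ts.n_samples), replace=False)
    sel_v = cross_validate(
        ts.potentials[idx] * scale,
        ts.coefficients[idx].reshape(idx.size, -1),
        folds=4,
        seed=seed,
    )
    u_rows = ts.coefficients.reshape(-1, ts.coefficients.shape[-1])
    e_rows = ts.energies.reshape(-1)
    ridx = rng.choice(u_rows.shape[0], min(max_rows, u_rows.shape[0]), replace=False)
    sel_u = cross_validate(u_rows[ridx], e_rows[ridx], folds=4, seed=seed)
    return sel_v, sel_u


def median_hyperparameters(ts: TrainingSet) -> tuple[KernelParams, KernelParams]:
    """Median-distance kernel widths with floor-level regularisation.

    The potential kernel takes 10x the median pairwise L2-potential
    distance (the descriptor targets are smooth and noiseless, so a wide
    interpolating kernel is appropriate); the density-coefficient kernel
    takes 2x the median pairwise row distance, wide enough to
    generalise across the thermal manifold while still resolving the
    sub-kcal/mol well structure that a cross-validated global-MAE
    objective is insensitive to.  Ridges sit at the numerical floor
    because the reference data carry no noise.
    """
    from .krr import median_pairwise_distance

    scale = np.sqrt(ts.grid.voxel_volume)
    med_v = median_pairwise_distance(ts.potentials * scale)
    u_rows = ts.coefficients.reshape(-1, ts.coefficients.shape[-1])
    med_u = median_pairwise_distance(u_rows)
    return (
        KernelParams(sigma=10.0 * med_v, ridge_lambda=1e-12),
        KernelParams(sigma=2.0 * med_u, ridge_lambda=1e-10),
    )


def fit_desk_model(ts: TrainingSet, seed: int = 0, selection: str = "median") -> MSHKModel:
    if selection == "cv":
        sel_v, sel_u = select_hyperparameters(ts, seed=seed)
    else:
        sel_v, sel_u = median_hyperparameters(ts)
    return MSHKModel(
        sigma_v=sel_v.sigma,
        lambda_v=sel_v.ridge_lambda,
        sigma_u=sel_u.sigma,
        lambda_u=sel_u.ridge_lambda,
    ).fit(ts)


# ------------------------------------------------------- scan geometries


def proton_scan_geometry(d_oo: float, r_minus: float) -> Geometry:
    """Template-backbone geometry at prescribed (d_OO, r_-).

    The oxygens sit symmetrically on the x axis of the aligned frame at
    separation d_OO; the transferring proton is placed on the ellipse of
    constant r_+ (the template bite distance), so that along an r_-
    scan at fixed d_OO only the double-well term of the analytic
    surface varies.
    """
    tmpl = template_geometry()
    xyz = tmpl.coordinates.copy()
    o_y = 1.10
    xyz[0] = [-d_oo / 2.0, o_y, 0.0]
    xyz[1] = [+d_oo / 2.0, o_y, 0.0]
    r1 = 0.5 * (_RPLUS_REF + r_minus)
    r2 = 0.5 * (_RPLUS_REF - r_minus)
    x = (r1**2 - r2**2) / (2.0 * d_oo)
    y2 = max(r1**2 - (x + d_oo / 2.0) ** 2, 1e-12)
    xyz[5] = [x, o_y + np.sqrt(y2), 0.0]
    return tmpl.with_coordinates(xyz)


def proton_scan(d_oo: float, r_values) -> list[Geometry]:
    return [proton_scan_geometry(d_oo, r) for r in r_values]


# ----------------------------------------------------------- experiments


@dataclass
class BarrierRecovery:
    d_oo_values: list
    true_barriers: list
    ml_barriers: list

    @property
    def errors(self) -> np.ndarray:
        return np.abs(np.asarray(self.ml_barriers) - np.asarray(self.true_barriers))


def barrier_recovery(
    model: MSHKModel,
    spec: SurrogateSpec,
    d_oo_values=(2.50, 2.45, 2.35),
    r_max: float = 0.65,
    n_points: int = 53,
    state: int = 2,
) -> BarrierRecovery:
    """Scan the ML surface at fixed d_OO and compare to B_j c_j(d)^2.

    The scan values bracket the gating distance, where the reaction
    actually switches on: a clearly nonzero barrier just above the
    gate, the residual barrier at the gate, and the vanished barrier
    below it.
    """
    from .analysis import pes_scan, proton_transfer_barrier
    from .surrogate import closed_form_barrier

    rvals = np.linspace(-r_max, r_max, n_points)
    true_b, ml_b = [], []
    for d in d_oo_values:
        geoms = proton_scan(d, rvals)
        e = pes_scan(model, geoms, states=[state]).ravel()
        ml_b.append(proton_transfer_barrier(rvals, e))
        true_b.append(closed_form_barrier(spec, state, d))
    return BarrierRecovery(list(d_oo_values), true_b, ml_b)


def learning_curve(
    sizes=(50, 100, 200, 400, 800),
    n_seeds: int = 5,
    seed: int = 0,
    n_test: int = 200,
    state: int = 2,
    spec: SurrogateSpec | None = None,
) -> dict:
    """Out-of-sample S2 MAE of the full chain versus training-set size.

    One shared reference pool per run; per seed, nested random training
    subsets (so larger M strictly extends smaller M) and a disjoint test
    set.  Hyperparameters are selected once by CV on a mid-sized subset
    and held fixed across M, as in a standard learning-curve protocol.
    """
    from .basis import project_density_matrix
    from .models import DensityMap, MultistateEnergyFunctional

    spec = spec or default_spec()
    grid = desk_grid()
    basis = desk_basis(grid)
    raw = generate_reference_dataset(
        spec, n_gs_frames=500, n_es_trajectories=5, seed=seed
    )
    canon, _ = canonicalize(
        raw.geometries, template_geometry(), SIGMA_V_PERMUTATION
    )
    energies = raw.energies
    pots = np.stack([gaussian_potential(g, grid).values for g in canon])
    dens = np.empty((len(canon), 3, grid.n_points))
    for i, g in enumerate(canon):
        for j in range(3):
            dens[i, j] = surrogate_density(spec, g, j, grid).values
    coeffs = project_density_matrix(
        dens.reshape(-1, grid.n_points), basis
    ).reshape(len(canon), 3, -1)
    x = pots * np.sqrt(grid.voxel_volume)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(canon))
    test_idx = order[:n_test]
    pool = order[n_test:]

    cv_sub = pool[: min(300, pool.size)]
    sel_v = cross_validate(x[cv_sub], energies[cv_sub], folds=4, seed=seed)
    u_sub = coeffs[cv_sub].reshape(-1, coeffs.shape[-1])
    e_sub = energies[cv_sub].reshape(-1)
    sel_u = cross_validate(u_sub, e_sub, folds=4, seed=seed)

    maes = np.empty((n_seeds, len(sizes)))
    for s in range(n_seeds):
        r = np.random.default_rng(seed + 1000 + s)
        shuffled = pool[r.permutation(pool.size)]
        for mi, m in enumerate(sizes):
            sub = shuffled[:m]
            dm = DensityMap(sel_v.sigma, sel_v.ridge_lambda).fit(x[sub], coeffs[sub])
            fn = MultistateEnergyFunctional(sel_u.sigma, sel_u.ridge_lambda).fit(
                coeffs[sub].reshape(-1, coeffs.shape[-1]), energies[sub].reshape(-1)
            )
            u_pred = dm.predict(x[test_idx])
            n, ns, l = u_pred.shape
            e_pred = fn.predict(u_pred.reshape(n * ns, l)).reshape(n, ns)
            maes[s, mi] = np.abs(e_pred - energies[test_idx])[:, state].mean()
    return {
        "sizes": list(sizes),
        "mae": maes,
        "median": np.median(maes, axis=0),
        "kernel_v": sel_v,
        "kernel_u": sel_u,
    }


def crossing_comparison(
    seed: int = 0,
    n_gs_frames: int = 600,
    n_es_trajectories: int = 12,
    k: int = 800,
    d_values=None,
    r_minus_values=(0.0, 0.3, -0.3),
) -> dict:
    """Single multistate functional vs state-specific map at the seam.

    Both models are trained on the same clustered set from the
    avoided-crossing oracle with hyperparameters chosen by the same CV
    protocol.  Errors of the two excited states are evaluated along
    proton-frame paths in d_OO that cross the seam: the functional is
    fed the reference state densities (its natural input), the direct
    map the external potential.
    """
    from .models import MultistateEnergyFunctional

    spec = crossing_spec()
    grid = desk_grid()
    basis = desk_basis(grid)
    ts = desk_training_set(
        spec,
        n_gs_frames=n_gs_frames,
        n_es_trajectories=n_es_trajectories,
        k=k,
        seed=seed,
        grid=grid,
        basis=basis,
    )
    sel_v, sel_u = select_hyperparameters(ts, seed=seed)
    u_rows = ts.coefficients.reshape(-1, ts.coefficients.shape[-1])
    e_rows = ts.energies.reshape(-1)
    functional = MultistateEnergyFunctional(sel_u.sigma, sel_u.ridge_lambda).fit(
        u_rows, e_rows
    )
    msks = train_msks(ts, sigma=sel_v.sigma, ridge_lambda=sel_v.ridge_lambda)

    if d_values is None:
        d_values = np.linspace(2.40, 2.58, 37)
    func_err, msks_err = [], []
    for rm in r_minus_values:
        geoms = [proton_scan_geometry(d, rm) for d in d_values]
        e_true = np.stack([surrogate_energies(spec, g) for g in geoms])
        u_true = np.stack(
            [
                [
                    project_density(surrogate_density(spec, g, j, grid), basis).coefficients
                    for j in range(3)
                ]
                for g in geoms
            ]
        )
        ef = functional.predict(u_true.reshape(-1, u_true.shape[-1])).reshape(-1, 3)
        ek = predict_msks(msks, geoms)
        func_err.append(np.abs(ef - e_true)[:, 1:])
        msks_err.append(np.abs(ek - e_true)[:, 1:])
    func_err = np.concatenate(func_err)
    msks_err = np.concatenate(msks_err)
    return {
        "functional_max": float(func_err.max()),
        "functional_mean": float(func_err.mean()),
        "msks_max": float(msks_err.max()),
        "msks_mean": float(msks_err.mean()),
        "kernel_v": sel_v,
        "kernel_u": sel_u,
    }


def espt_ensemble(
    spec: SurrogateSpec | None = None,
    n_trajectories: int = 50,
    n_steps: int = 240,
    seed: int = 0,
    temperature: float = 300.0,
    restraint: RestraintSpec | None = None,
):
    """Vertical-excitation NVE ensemble on the S2 surrogate surface.

    Ground-state Langevin sampling at 300 K supplies initial conditions
    every 100 fs; each is propagated for ``n_steps`` x 0.25 fs on the
    excited surface with the planarity restraint.
    """
    from .surrogate import SurrogateSurface

    spec = spec or default_spec()
    restraint = restraint or RestraintSpec()
    tmpl = template_geometry()
    gs_ff = AnalyticForceField(SurrogateSurface(spec, 0), restraint)
    n_steps_gs = 2000 + int(np.ceil(n_trajectories * 100.0 / 0.5))
    gs = langevin_gs_sampler(
        gs_ff,
        MDState(geometry=tmpl, velocities=np.zeros((tmpl.n_atoms, 3))),
        temperature=temperature,
        timestep=0.5,
        n_steps=n_steps_gs,
        seed=seed,
    )
    ics = vertical_excitation_initial_conditions(gs, interval_fs=100.0, target_state=2)
    # drop ICs drawn from the thermalisation window
    ics = [ic for ic in ics if ic.time > 1000.0][:n_trajectories]
    es_ff = AnalyticForceField(SurrogateSurface(spec, 2), restraint)
    return [
        velocity_verlet_run(es_ff, ic, timestep=0.25, n_steps=n_steps, surface_id=2)
        for ic in ics
    ]


def symmetry_errors(model: MSHKModel, seed: int = 0, n_geometries: int = 100, amplitude: float = 0.06) -> np.ndarray:
    """|E(g) - E(reflect g)| over random thermal-scale distortions."""
    from .geometry import reflect_geometry

    rng = np.random.default_rng(seed)
    tmpl = template_geometry()
    errs = np.empty(n_geometries)
    for i in range(n_geometries):
        g = tmpl.with_coordinates(
            tmpl.coordinates + amplitude * rng.standard_normal((tmpl.n_atoms, 3))
        )
        gr = reflect_geometry(g, SIGMA_V_PERMUTATION)
        errs[i] = np.abs(model.predict(g) - model.predict(gr)).max()
    return errs
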