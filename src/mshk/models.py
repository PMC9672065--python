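"""The three learned maps of the multistate Hohenberg-Kohn framework.

* :class:`DensityMap` -- per-state potential -> density-coefficient
  regression (one shared potential kernel, all basis coefficients of all
  states solved in a single factorisation).
* :class:`MultistateEnergyFunctional` -- ONE density -> energy map
  trained on pooled (geometry, state) rows: the functional itself
  carries no state index; the state of a prediction is simply the state
  of the density fed in.
* :class:`MSKSMap` -- the direct, state-specific potential -> energy
  regression used as the baseline (no density intermediate); expected to
  degrade near electronic crossings where per-state energies are not
  smooth in the potential.
* :class:`MSHKModel` -- the end-to-end composition
  geometry -> aligned frame -> Gaussian potential -> per-state density
  coefficients -> per-state energies.

All estimators follow the scikit-learn protocol (``fit``/``predict``/
``get_params``; fitted attributes end in an underscore).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .basis import BasisSpec, DensityCoefficients
from .geometry import Geometry, default_alignment_weights, kabsch_align
from .grid import DEFAULT_SIGMA_POT, GridSpec, gaussian_potential
from .krr import GaussianKRR, KernelParams, LAMBDA_FLOOR

__all__ = [
    "DensityMap",
    "MultistateEnergyFunctional",
    "MSKSMap",
    "MSHKModel",
    "MSHKSurface",
    "MSKSSurface",
    "train_msks",
    "predict_msks",
]


class DensityMap(BaseEstimator):
    """KRR from potential descriptors to per-state basis coefficients.

    ``fit`` takes descriptors ``V`` of shape (M, P) (pre-scaled so the
    Euclidean norm realises the L2-potential metric) and coefficients of
    shape (M, S, L); every coefficient of every state shares the same
    kernel matrix and (sigma, lambda).
    """

    def __init__(self, sigma: float = 1.0, ridge_lambda: float = LAMBDA_FLOOR):
        self.sigma = sigma
        self.ridge_lambda = ridge_lambda

    def fit(self, V, coefficients):
        v = np.atleast_2d(np.asarray(V, dtype=float))
        u = np.asarray(coefficients, dtype=float)
        if u.ndim != 3:
            raise ValueError("coefficients must have shape (M, n_states, L)")
        if u.shape[0] != v.shape[0]:
            raise ValueError("every training potential needs coefficients for every state")
        if not np.all(np.isfinite(u)):
            raise ValueError("coefficients must be finite")
        m, s, l = u.shape
        self.n_states_, self.n_coefficients_ = s, l
        self._krr = GaussianKRR(self.sigma, self.ridge_lambda)
        self._krr.fit(v, u.reshape(m, s * l))
        return self

    def predict(self, V) -> np.ndarray:
        check_is_fitted(self, "n_states_")
        flat = self._krr.predict(np.atleast_2d(np.asarray(V, dtype=float)))
        return flat.reshape(-1, self.n_states_, self.n_coefficients_)


class MultistateEnergyFunctional(RegressorMixin, BaseEstimator):
    """Single density-coefficient -> energy functional over pooled states.

    Each training row is one (geometry, state) pair with descriptor
    u_{i,k} and target E_{i,k}; the kernel metric is plain Euclidean
    distance in coefficient space (optionally standardised).  Targets are
    centred on a recorded offset for conditioning and the offset is
    re-added at prediction.
    """

    def __init__(
        self,
        sigma: float = 1.0,
        ridge_lambda: float = LAMBDA_FLOOR,
        standardize: bool = False,
    ):
        self.sigma = sigma
        self.ridge_lambda = ridge_lambda
        self.standardize = standardize

    def _transform(self, U):
        u = np.atleast_2d(np.asarray(U, dtype=float))
        if self.standardize:
            return (u - self.scale_mean_) / self.scale_std_
        return u

    def fit(self, U, energies):
        u = np.atleast_2d(np.asarray(U, dtype=float))
        e = np.asarray(energies, dtype=float).ravel()
        if e.size != u.shape[0]:
            raise ValueError("one energy per coefficient row is required")
        if self.standardize:
            self.scale_mean_ = u.mean(axis=0)
            std = u.std(axis=0)
            self.scale_std_ = np.where(std > 0, std, 1.0)
        self.energy_offset_ = float(e.mean())
        self._krr = GaussianKRR(self.sigma, self.ridge_lambda)
        self._krr.fit(self._transform(u), e - self.energy_offset_)
        return self

    def predict(self, U) -> np.ndarray:
        check_is_fitted(self, "energy_offset_")
        return self._krr.predict(self._transform(U)) + self.energy_offset_

    def __call__(self, coeffs: DensityCoefficients) -> float:
        """Evaluate the functional on a single density."""
        return float(self.predict(coeffs.coefficients[None, :])[0])


class MSKSMap(RegressorMixin, BaseEstimator):
    """State-specific potential -> energy KRR (one column per state)."""

    def __init__(self, sigma: float = 1.0, ridge_lambda: float = LAMBDA_FLOOR):
        self.sigma = sigma
        self.ridge_lambda = ridge_lambda

    def fit(self, V, energies):
        v = np.atleast_2d(np.asarray(V, dtype=float))
        e = np.asarray(energies, dtype=float)
        if e.ndim == 1:
            e = e[:, None]
        if e.shape[0] != v.shape[0]:
            raise ValueError("energies must have one row per training potential")
        self.n_states_ = e.shape[1]
        self.energy_offset_ = e.mean(axis=0)
        self._krr = GaussianKRR(self.sigma, self.ridge_lambda)
        self._krr.fit(v, e - self.energy_offset_)
        return self

    def predict(self, V) -> np.ndarray:
        check_is_fitted(self, "n_states_")
        p = self._krr.predict(np.atleast_2d(np.asarray(V, dtype=float)))
        return p.reshape(-1, self.n_states_) + self.energy_offset_


def _looks_like_training_set(ts) -> bool:
    return all(
        hasattr(ts, a)
        for a in ("potentials", "coefficients", "energies", "grid", "basis", "states")
    )


class MSHKModel(BaseEstimator):
    """End-to-end multistate Hohenberg-Kohn model.

    Composes a :class:`DensityMap` and a single
    :class:`MultistateEnergyFunctional`.  ``fit`` consumes a
    ``TrainingSet`` (see :mod:`mshk.dataset`); ``predict`` takes raw
    geometries, aligns them to the training reference frame with
    heavy-atom Kabsch superposition, builds the Gaussian potential on the
    model grid and returns per-state energies (and, optionally, density
    coefficients).

    Parameters
    ----------
    sigma_v, lambda_v
        Kernel width / ridge of the potential -> density stage.
    sigma_u, lambda_u
        Kernel width / ridge of the density -> energy stage.
    functional_states
        Which states' rows enter the energy-functional training
        (``None`` = all states present in the training set).  Density
        maps are always trained for every state in the training set.
    """

    def __init__(
        self,
        sigma_v: float = 1.0,
        lambda_v: float = LAMBDA_FLOOR,
        sigma_u: float = 1.0,
        lambda_u: float = LAMBDA_FLOOR,
        functional_states: tuple[int, ...] | None = None,
        standardize_coefficients: bool = False,
    ):
        self.sigma_v = sigma_v
        self.lambda_v = lambda_v
        self.sigma_u = sigma_u
        self.lambda_u = lambda_u
        self.functional_states = functional_states
        self.standardize_coefficients = standardize_coefficients

    # ------------------------------------------------------------ fitting

    def fit(self, training_set):
        if not _looks_like_training_set(training_set):
            raise TypeError("fit expects a TrainingSet (see mshk.dataset)")
        ts = training_set
        self.grid_: GridSpec = ts.grid
        self.basis_: BasisSpec = ts.basis
        self.sigma_pot_: float = ts.sigma_pot
        self.states_: tuple[int, ...] = tuple(ts.states)
        self.reference_: Geometry = ts.reference
        self._scale = np.sqrt(self.grid_.voxel_volume)

        v_desc = ts.potentials * self._scale
        self.density_map_ = DensityMap(self.sigma_v, self.lambda_v).fit(
            v_desc, ts.coefficients
        )

        pool = self.functional_states
        if pool is None:
            pool = self.states_
        missing = set(pool) - set(self.states_)
        if missing:
            raise ValueError(f"functional_states {sorted(missing)} absent from the training set")
        cols = [self.states_.index(s) for s in pool]
        u_rows = np.concatenate([ts.coefficients[:, c, :] for c in cols], axis=0)
        e_rows = np.concatenate([ts.energies[:, c] for c in cols], axis=0)
        self.functional_ = MultistateEnergyFunctional(
            self.sigma_u, self.lambda_u, standardize=self.standardize_coefficients
        ).fit(u_rows, e_rows)
        self.n_training_ = ts.potentials.shape[0]
        return self

    # --------------------------------------------------------- prediction

    def _descriptors(self, geometries) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "density_map_")
        lo, hi = self.grid_.bounds()
        xs, flags = [], []
        for g in geometries:
            aligned = kabsch_align(g, self.reference_, default_alignment_weights(g))
            field = gaussian_potential(aligned, self.grid_, self.sigma_pot_)
            xyz = aligned.coordinates
            flags.append(bool(np.any(xyz < lo) or np.any(xyz > hi)))
            xs.append(field.values * self._scale)
        flags = np.asarray(flags)
        if np.any(flags):
            warnings.warn(
                f"{int(flags.sum())} geometr{'y' if flags.sum() == 1 else 'ies'} "
                "extend outside the model grid; predictions are extrapolations",
                stacklevel=3,
            )
        return np.stack(xs), flags

    def predict(self, geometries, return_details: bool = False):
        """Per-state energies for one geometry or a sequence of them.

        Returns an (n, n_states) array, or with ``return_details`` a dict
        holding ``energies``, predicted ``coefficients`` (n, S, L) and
        the per-geometry ``extrapolated`` flags.
        """
        single = isinstance(geometries, Geometry)
        geoms = [geometries] if single else list(geometries)
        x, flags = self._descriptors(geoms)
        u = self.density_map_.predict(x)                    # (n, S, L)
        n, s, l = u.shape
        e = self.functional_.predict(u.reshape(n * s, l)).reshape(n, s)
        if return_details:
            return {
                "energies": e[0] if single else e,
                "coefficients": u[0] if single else u,
                "extrapolated": flags[0] if single else flags,
            }
        return e[0] if single else e

    def predict_density_coefficients(self, geometries) -> np.ndarray:
        x, _ = self._descriptors(
            [geometries] if isinstance(geometries, Geometry) else list(geometries)
        )
        return self.density_map_.predict(x)

    # ------------------------------------------------------ serialisation

    def save(self, path) -> None:
        """Bit-stable archive of weights, descriptors and hyperparameters."""
        check_is_fitted(self, "density_map_")
        meta = {
            "params": self.get_params(),
            "states": list(self.states_),
            "sigma_pot": self.sigma_pot_,
            "grid": {
                "origin": list(self.grid_.origin),
                "spacing": self.grid_.spacing,
                "shape": list(self.grid_.shape),
            },
            "basis_per_axis": list(self.basis_.per_axis_count),
            "energy_offset": self.functional_.energy_offset_,
            "n_training": self.n_training_,
            "reference_labels": dict(self.reference_.labels),
        }
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            density_X=self.density_map_._krr.X_fit_,
            density_W=self.density_map_._krr.dual_coef_,
            functional_X=self.functional_._krr.X_fit_,
            functional_W=self.functional_._krr.dual_coef_,
            reference_z=self.reference_.atomic_numbers,
            reference_xyz=self.reference_.coordinates,
        )

    @classmethod
    def load(cls, path) -> "MSHKModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            model = cls(**{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in meta["params"].items()
            })
            model.grid_ = GridSpec(
                origin=tuple(meta["grid"]["origin"]),
                spacing=meta["grid"]["spacing"],
                shape=tuple(meta["grid"]["shape"]),
            )
            model.basis_ = BasisSpec(model.grid_, tuple(meta["basis_per_axis"]))
            model.sigma_pot_ = meta["sigma_pot"]
            model.states_ = tuple(meta["states"])
            model._scale = np.sqrt(model.grid_.voxel_volume)
            model.reference_ = Geometry(
                npz["reference_z"], npz["reference_xyz"], meta["reference_labels"]
            )
            dmap = DensityMap(model.sigma_v, model.lambda_v)
            dmap._krr = GaussianKRR(model.sigma_v, model.lambda_v)
            dmap._krr.X_fit_ = npz["density_X"]
            dmap._krr.dual_coef_ = npz["density_W"]
            dmap._krr._single_target = False
            dmap.n_states_ = len(model.states_)
            dmap.n_coefficients_ = npz["density_W"].shape[1] // len(model.states_)
            model.density_map_ = dmap
            fun = MultistateEnergyFunctional(model.sigma_u, model.lambda_u)
            fun._krr = GaussianKRR(model.sigma_u, model.lambda_u)
            fun._krr.X_fit_ = npz["functional_X"]
            fun._krr.dual_coef_ = npz["functional_W"]
            fun._krr._single_target = True
            fun.energy_offset_ = meta["energy_offset"]
            model.functional_ = fun
            model.n_training_ = meta["n_training"]
        return model


class MSHKSurface:
    """Single-state energy view of an MSHK model for the MD engine."""

    def __init__(self, model: MSHKModel, state: int):
        if state not in model.states_:
            raise ValueError(f"state {state} not trained; available: {model.states_}")
        self.model = model
        self.column = model.states_.index(state)
        self.state = state

    def energy(self, geometry: Geometry) -> float:
        return float(self.model.predict(geometry)[self.column])

    def energy_batch(self, geometries) -> np.ndarray:
        return self.model.predict(list(geometries))[:, self.column]


def train_msks(training_set, sigma: float, ridge_lambda: float = LAMBDA_FLOOR) -> MSKSMap:
    """Fit the direct potential -> per-state-energy map on a TrainingSet."""
    scale = np.sqrt(training_set.grid.voxel_volume)
    m = MSKSMap(sigma, ridge_lambda)
    m.fit(training_set.potentials * scale, training_set.energies)
    m.grid_ = training_set.grid
    m.sigma_pot_ = training_set.sigma_pot
    m.reference_ = training_set.reference
    m.states_ = tuple(training_set.states)
    return m


def predict_msks(model: MSKSMap, geometries) -> np.ndarray:
    """Energies of raw geometries under an MSKS map fit by :func:`train_msks`."""
    single = isinstance(geometries, Geometry)
    geoms = [geometries] if single else list(geometries)
    scale = np.sqrt(model.grid_.voxel_volume)
    x = np.stack(
        [
            gaussian_potential(
                kabsch_align(g, model.reference_), model.grid_, model.sigma_pot_
            ).values
            * scale
            for g in geoms
        ]
    )
    e = model.predict(x)
    return e[0] if single else e


class MSKSSurface:
    """Single-state energy view of an MSKS map for the MD engine."""

    def __init__(self, model: MSKSMap, state: int):
        self.model = model
        self.column = model.states_.index(state)

    def energy(self, geometry: Geometry) -> float:
        return float(predict_msks(self.model, geometry)[self.column])

    def energy_batch(self, geometries) -> np.ndarray:
        return predict_msks(self.model, list(geometries))[:, self.column]
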