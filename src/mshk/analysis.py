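"""Non-equilibrium observables of the proton-transfer ensembles.

The central quantity is the proton-location response function

    S(t) = mean over trajectories of  r_-(0) r_-(t) / |r_-(0) r_-(t)|,

the ensemble-averaged sign of the product of the initial and current
proton-transfer coordinates.  S = 1: every proton still remembers its
reactant basin; S = -1: all transferred; S = 0: memory lost, which for a
symmetric donor/acceptor means the reaction is complete.  Uncertainty
bands are percentile-bootstrap 95% confidence intervals with the
trajectory (not the frame) as the resampling unit, matching the
independence structure of the ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import bootstrap as _scipy_bootstrap

from .geometry import Geometry

__all__ = [
    "ResponseFunction",
    "response_function",
    "bootstrap_ci",
    "mean_distance_series",
    "pes_scan",
    "proton_transfer_barrier",
]


@dataclass
class ResponseFunction:
    """S(t) with optional bootstrap confidence band."""

    times: np.ndarray
    values: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    ensemble_size: int = 0

    def __post_init__(self):
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("S(t) must lie in [-1, 1]")


def _r_minus_series(traj) -> np.ndarray:
    io1, io2, ih = traj.labels["O1"], traj.labels["O2"], traj.labels["H"]
    pos = traj.positions
    r1 = np.linalg.norm(pos[:, ih] - pos[:, io1], axis=1)
    r2 = np.linalg.norm(pos[:, ih] - pos[:, io2], axis=1)
    return r1 - r2


def sign_product_matrix(trajectories) -> tuple[np.ndarray, np.ndarray]:
    """Per-trajectory sign(r_-(0) r_-(t)) rows; drops undefined starters.

    A frame with r_-(t) exactly 0 (measure zero) inherits the sign of the
    previous frame; a trajectory with r_-(0) = 0 has no defined basin and
    is excluded with a warning.
    """
    rows, times = [], None
    dropped = 0
    for traj in trajectories:
        rm = _r_minus_series(traj)
        if rm[0] == 0.0:
            dropped += 1
            continue
        s = np.sign(rm)
        for i in range(1, s.size):
            if s[i] == 0.0:
                s[i] = s[i - 1]
        rows.append(s[0] * s)
        if times is None:
            times = traj.times - traj.times[0]
        elif rows[-1].size != times.size:
            raise ValueError("all trajectories must share length and timestep")
    if dropped:
        warnings.warn(
            f"excluded {dropped} trajectories with r_-(0) = 0 (undefined basin sign)",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no usable trajectories")
    return np.stack(rows), times


def bootstrap_ci(
    per_trajectory_series: np.ndarray,
    n_resamples: int = 9999,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile-bootstrap band for the ensemble mean at each time.

    Resamples whole trajectories (rows) with replacement and returns the
    (lower, upper) percentile envelopes of the recomputed means.
    """
    data = np.atleast_2d(np.asarray(per_trajectory_series, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("bootstrap needs at least 2 trajectories")
    if n_resamples < 100:
        warnings.warn("fewer than 100 bootstrap resamples gives unstable bands", stacklevel=2)
    res = _scipy_bootstrap(
        (data,),
        np.mean,
        axis=0,
        vectorized=True,
        n_resamples=n_resamples,
        confidence_level=confidence,
        method="percentile",
        rng=np.random.default_rng(seed),
    )
    return np.asarray(res.confidence_interval.low), np.asarray(res.confidence_interval.high)


def response_function(
    trajectories,
    with_ci: bool = True,
    n_resamples: int = 9999,
    confidence: float = 0.95,
    seed: int = 0,
) -> ResponseFunction:
    """Ensemble S(t) with optional bootstrap confidence band."""
    rows, times = sign_product_matrix(trajectories)
    mean = rows.mean(axis=0)
    lower = upper = None
    if with_ci and rows.shape[0] >= 2:
        lower, upper = bootstrap_ci(rows, n_resamples, confidence, seed)
        # a degenerate (all-identical) ensemble collapses the band to the mean
        lower = np.minimum(lower, mean)
        upper = np.maximum(upper, mean)
    return ResponseFunction(
        times=times, values=mean, lower=lower, upper=upper, ensemble_size=rows.shape[0]
    )


def mean_distance_series(trajectories, atom_pair: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean |R_a - R_b|(t), e.g. the gating O-O distance."""
    a, b = atom_pair
    series, times = [], None
    for traj in trajectories:
        pos = traj.positions
        if a >= pos.shape[1] or b >= pos.shape[1]:
            raise ValueError(f"atom pair {atom_pair} outside trajectory with {pos.shape[1]} atoms")
        series.append(np.linalg.norm(pos[:, a] - pos[:, b], axis=1))
        if times is None:
            times = traj.times - traj.times[0]
        elif series[-1].size != times.size:
            raise ValueError("all trajectories must share length and timestep")
    return times, np.stack(series).mean(axis=0)


def pes_scan(surface, geometries, states=None) -> np.ndarray:
    """Energies along a supplied geometry series.

    ``surface`` is either a single-state surface (``energy``/
    ``energy_batch``) giving a 1-D profile, or a multistate model with a
    ``predict`` method giving an (n_geometries, n_states) table
    (optionally restricted to ``states`` columns).
    """
    geoms = list(geometries)
    if hasattr(surface, "predict"):
        e = np.atleast_2d(surface.predict(geoms))
        if states is not None:
            cols = [surface.states_.index(s) for s in states]
            e = e[:, cols]
        return e
    if hasattr(surface, "energy_batch"):
        return np.asarray(surface.energy_batch(geoms), dtype=float)
    return np.array([surface.energy(g) for g in geoms], dtype=float)


def proton_transfer_barrier(r_minus_values: np.ndarray, energies: np.ndarray) -> float:
    """Barrier of a symmetric profile: E at r_- = 0 minus the path minimum."""
    r = np.asarray(r_minus_values, dtype=float)
    e = np.asarray(energies, dtype=float)
    if r.shape != e.shape:
        raise ValueError("r_minus_values and energies must align")
    top = e[np.argmin(np.abs(r))]
    return float(top - e.min())


def plot_response(result: ResponseFunction, ax=None, label=None, color=None):
    """Matplotlib panel of S(t) with its confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.times, result.values, label=label, color=color)
    if result.lower is not None:
        ax.fill_between(result.times, result.lower, result.upper, alpha=0.3, color=color)
    ax.set_xlabel("t (fs)")
    ax.set_ylabel("S(t)")
    ax.set_ylim(-1.05, 1.05)
    if label:
        ax.legend()
    return ax
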