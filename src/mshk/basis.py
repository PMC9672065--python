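"""Orthonormal Fourier representation of electron densities.

Densities are expanded in a truncated real Fourier basis,

    n_j(r) = sum_{l=1}^{L} u_j^(l) phi_l(r),

with phi_l a product of per-axis modes {1, cos, sin} on a periodic box
whose period along each axis equals ``n_points * spacing`` of the grid.
With that period the modes are *exactly* orthonormal under the grid
quadrature (discrete Fourier orthogonality), so projection is a plain
inner product, projection o reconstruction is idempotent, and Parseval's
identity holds to machine precision as long as the per-axis mode count
does not exceed the number of grid points per axis.

The production-scale default keeps 50 modes per axis (125,000
coefficients in total).  Coefficient vectors u_j are the descriptors of the multistate
density-to-energy functional and the targets of the potential-to-density
map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

__all__ = [
    "BasisSpec",
    "DensityField",
    "DensityCoefficients",
    "project_density",
    "reconstruct_density",
    "integrated_density_mae",
]

DEFAULT_MODES_PER_AXIS = (50, 50, 50)


@dataclass(frozen=True)
class DensityField:
    """Electron density sampled on a grid, in e/A^3.

    ``values`` may be negative for density *differences*; total densities
    are non-negative with integral ~ electron count.
    """

    grid: GridSpec
    values: np.ndarray
    state_index: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != self.grid.n_points:
            raise ValueError("density values do not match the grid size")
        if not np.all(np.isfinite(v)):
            raise ValueError("density values must be finite")
        if self.state_index < 0:
            raise ValueError("state_index must be >= 0")
        object.__setattr__(self, "values", v)

    def integral(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume)

    def reshaped(self) -> np.ndarray:
        return self.values.reshape(self.grid.shape)


@dataclass(frozen=True)
class DensityCoefficients:
    """Truncated Fourier expansion coefficients of one state's density."""

    coefficients: np.ndarray
    state_index: int = 0

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float).ravel()
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "coefficients", c)

    @property
    def size(self) -> int:
        return self.coefficients.size


class BasisSpec:
    """Real 3D Fourier basis over a grid box.

    Parameters
    ----------
    box
        Grid the basis is defined over; the periodic box length per axis
        is ``shape[axis] * spacing``.
    per_axis_count
        Number of modes per axis, ordered DC, cos(1), sin(1), cos(2), ...
        Total size L is the product (default 50^3 = 125,000).
    """

    def __init__(
        self,
        box: GridSpec,
        per_axis_count: tuple[int, int, int] = DEFAULT_MODES_PER_AXIS,
    ):
        per_axis_count = tuple(int(n) for n in per_axis_count)
        if len(per_axis_count) != 3 or any(n <= 0 for n in per_axis_count):
            raise ValueError("per_axis_count must be 3 positive integers")
        self.box = box
        self.per_axis_count = per_axis_count

    @property
    def size(self) -> int:
        a, b, c = self.per_axis_count
        return a * b * c

    def __eq__(self, other):
        return (
            isinstance(other, BasisSpec)
            and self.box == other.box
            and self.per_axis_count == other.per_axis_count
        )

    def __repr__(self):
        return f"BasisSpec(per_axis_count={self.per_axis_count}, box={self.box})"

    def axis_design_matrix(self, axis: int, coords: np.ndarray | None = None) -> np.ndarray:
        """Per-axis mode values: shape (per_axis_count[axis], n_coords).

        Mode m=0 is the constant 1/sqrt(Lbox); m=2k-1 is
        sqrt(2/Lbox) cos(2 pi k t) and m=2k is sqrt(2/Lbox) sin(2 pi k t)
        with t the fractional coordinate along the periodic box.
        """
        n_modes = self.per_axis_count[axis]
        period = self.box.shape[axis] * self.box.spacing
        if coords is None:
            coords = self.box.axis_coordinates(axis)
        t = (np.asarray(coords, dtype=float) - self.box.origin[axis]) / period
        rows = np.empty((n_modes, t.size))
        rows[0] = 1.0 / np.sqrt(period)
        amp = np.sqrt(2.0 / period)
        for m in range(1, n_modes):
            k = (m + 1) // 2
            phase = 2.0 * np.pi * k * t
            rows[m] = amp * (np.cos(phase) if m % 2 == 1 else np.sin(phase))
        return rows

    def gram_matrix(self) -> np.ndarray:
        """Full 3D overlap matrix under grid quadrature (small bases only)."""
        gs = [
            self.axis_design_matrix(ax) @ self.axis_design_matrix(ax).T * self.box.spacing
            for ax in range(3)
        ]
        g = np.einsum("ad,be,cf->abcdef", gs[0], gs[1], gs[2])
        return g.reshape(self.size, self.size)


def project_density(density: DensityField, basis: BasisSpec) -> DensityCoefficients:
    """Inner products <phi_l, n> under grid quadrature, C-ordered over axes."""
    if density.grid != basis.box:
        raise ValueError("density grid does not match the basis box")
    n3 = density.reshaped()
    px = basis.axis_design_matrix(0)
    py = basis.axis_design_matrix(1)
    pz = basis.axis_design_matrix(2)
    # separable contraction: u_abc = h^3 * px_ai py_bj pz_ck n_ijk
    t = np.tensordot(px, n3, axes=(1, 0))        # (A, ny, nz)
    t = np.tensordot(py, t, axes=(1, 1))         # (B, A, nz)
    t = np.tensordot(pz, t, axes=(1, 2))         # (C, B, A)
    u = np.transpose(t, (2, 1, 0)) * density.grid.voxel_volume
    return DensityCoefficients(coefficients=u.ravel(), state_index=density.state_index)


def project_density_matrix(values_matrix: np.ndarray, basis: BasisSpec) -> np.ndarray:
    """Project many flattened densities at once: (M, n_points) -> (M, L)."""
    vm = np.asarray(values_matrix, dtype=float)
    m = vm.shape[0]
    n3 = vm.reshape((m,) + basis.box.shape)
    px = basis.axis_design_matrix(0)
    py = basis.axis_design_matrix(1)
    pz = basis.axis_design_matrix(2)
    t = np.tensordot(n3, px, axes=(1, 1))        # (M, ny, nz, A)
    t = np.tensordot(t, py, axes=(1, 1))         # (M, nz, A, B)
    t = np.tensordot(t, pz, axes=(1, 1))         # (M, A, B, C)
    return t.reshape(m, -1) * basis.box.voxel_volume


def reconstruct_density(
    coeffs: DensityCoefficients, basis: BasisSpec, grid: GridSpec | None = None
) -> DensityField:
    """Evaluate the truncated expansion on the grid."""
    if grid is None:
        grid = basis.box
    if grid != basis.box:
        raise ValueError("reconstruction grid must match the basis box")
    if coeffs.size != basis.size:
        raise ValueError(
            f"coefficient length {coeffs.size} does not match basis size {basis.size}"
        )
    u = coeffs.coefficients.reshape(basis.per_axis_count)
    px = basis.axis_design_matrix(0)
    py = basis.axis_design_matrix(1)
    pz = basis.axis_design_matrix(2)
    t = np.tensordot(u, px, axes=(0, 0))         # (B, C, nx)
    t = np.tensordot(t, py, axes=(0, 0))         # (C, nx, ny)
    t = np.tensordot(t, pz, axes=(0, 0))         # (nx, ny, nz)
    return DensityField(grid=grid, values=t.ravel(), state_index=coeffs.state_index)


def integrated_density_mae(predicted: DensityField, reference: DensityField) -> float:
    """Integral of |n_pred - n_ref| by grid quadrature, in electrons."""
    if predicted.grid != reference.grid:
        raise ValueError("density fields must share the same grid")
    return float(
        np.abs(predicted.values - reference.values).sum() * predicted.grid.voxel_volume
    )


def resample_density(
    values3d: np.ndarray,
    axis_coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    target: GridSpec,
    state_index: int = 0,
) -> DensityField:
    """Trilinear resampling of a density given on another regular grid."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        axis_coords, np.asarray(values3d, dtype=float), bounds_error=False, fill_value=0.0
    )
    return DensityField(grid=target, values=interp(target.points()), state_index=state_index)
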