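"""Molecular geometries and the geometric operations of the pipeline.

A :class:`Geometry` is a set of nuclei (atomic numbers + Cartesian
coordinates in Angstrom) with optional role labels naming the proton
donor oxygen (``O1``), acceptor oxygen (``O2``) and transferring proton
(``H``).  The proton-transfer coordinate is

    r_minus = |R_H - R_O1| - |R_H - R_O2|,

negative when the proton sits nearer the donor oxygen.  Geometries are
brought into a common frame by weighted Kabsch superposition onto a
reference structure (the planar C2v transition state), and the mirror
symmetry exchanging the two oxygens is realised by an x-coordinate flip
followed by an atom permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import ATOMIC_MASSES

__all__ = [
    "Geometry",
    "kabsch_align",
    "reflect_geometry",
    "proton_transfer_coordinate",
    "oxygen_oxygen_distance",
]


@dataclass(frozen=True)
class Geometry:
    """Nuclear configuration of one conformation.

    Parameters
    ----------
    atomic_numbers
        Integer nuclear charges, shape ``(N,)``.
    coordinates
        Cartesian positions in Angstrom, shape ``(N, 3)``.
    labels
        Optional mapping from role tag (``"O1"``, ``"O2"``, ``"H"``) to
        atom index.
    """

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    labels: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        z = np.asarray(self.atomic_numbers, dtype=int)
        xyz = np.asarray(self.coordinates, dtype=float)
        if z.ndim != 1 or z.size == 0 or np.any(z <= 0):
            raise ValueError("atomic_numbers must be a non-empty sequence of positive integers")
        if xyz.shape != (z.size, 3):
            raise ValueError(f"coordinates must have shape ({z.size}, 3), got {xyz.shape}")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "atomic_numbers", z)
        object.__setattr__(self, "coordinates", xyz)
        object.__setattr__(self, "labels", dict(self.labels))

    @property
    def n_atoms(self) -> int:
        return self.atomic_numbers.size

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[int(z)] for z in self.atomic_numbers])

    def with_coordinates(self, coordinates: np.ndarray) -> "Geometry":
        return replace(self, coordinates=np.asarray(coordinates, dtype=float))

    def labeled_index(self, tag: str) -> int:
        try:
            return self.labels[tag]
        except KeyError:
            raise KeyError(
                f"geometry is missing the {tag!r} label; labels present: {sorted(self.labels)}"
            ) from None


def _require_labels(geometry: Geometry) -> tuple[int, int, int]:
    return (
        geometry.labeled_index("O1"),
        geometry.labeled_index("O2"),
        geometry.labeled_index("H"),
    )


def proton_transfer_coordinate(geometry: Geometry) -> float:
    """r_minus = r_HO1 - r_HO2 in Angstrom (requires O1/O2/H labels)."""
    io1, io2, ih = _require_labels(geometry)
    xyz = geometry.coordinates
    r1 = float(np.linalg.norm(xyz[ih] - xyz[io1]))
    r2 = float(np.linalg.norm(xyz[ih] - xyz[io2]))
    return r1 - r2


def oxygen_oxygen_distance(geometry: Geometry) -> float:
    """Donor-acceptor O-O distance d_OO in Angstrom."""
    io1 = geometry.labeled_index("O1")
    io2 = geometry.labeled_index("O2")
    return float(np.linalg.norm(geometry.coordinates[io1] - geometry.coordinates[io2]))


def default_alignment_weights(geometry: Geometry) -> np.ndarray:
    """Heavy atoms weight 1, hydrogens 0.

    Mass-weighting the transferring proton would let its large-amplitude
    motion skew the molecular frame, so superposition is done on the
    heavy-atom skeleton only.
    """
    return (geometry.atomic_numbers > 1).astype(float)


def kabsch_align(
    geometry: Geometry,
    reference: Geometry,
    weights: Sequence[float] | None = None,
) -> Geometry:
    """Rigid-body superposition of ``geometry`` onto ``reference``.

    Solves the weighted orthogonal Procrustes problem with the standard
    SVD (Kabsch) construction, restricted to proper rotations
    (``det(R) = +1`` -- no reflection is ever introduced here; mirror
    images are handled explicitly by :func:`reflect_geometry`).
    """
    if geometry.n_atoms != reference.n_atoms:
        raise ValueError("geometry and reference must have the same number of atoms")
    if not np.array_equal(geometry.atomic_numbers, reference.atomic_numbers):
        raise ValueError("geometry and reference must list the same elements in the same order")
    if weights is None:
        w = default_alignment_weights(geometry)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (geometry.n_atoms,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum, one per atom")
    wn = w / w.sum()

    x = geometry.coordinates
    y = reference.coordinates
    xc = (wn[:, None] * x).sum(axis=0)
    yc = (wn[:, None] * y).sum(axis=0)
    xm = x - xc
    ym = y - yc

    h = (wn[:, None] * xm).T @ ym
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    rot = u @ s @ vt  # maps geometry frame -> reference frame (right-multiplication)
    aligned = xm @ rot + yc
    return geometry.with_coordinates(aligned)


def weighted_rmsd(
    a: Geometry, b: Geometry, weights: Sequence[float] | None = None
) -> float:
    w = default_alignment_weights(a) if weights is None else np.asarray(weights, float)
    wn = w / w.sum()
    d2 = ((a.coordinates - b.coordinates) ** 2).sum(axis=1)
    return float(np.sqrt((wn * d2).sum()))


def reflect_geometry(
    geometry: Geometry,
    permutation: Sequence[int],
    plane_normal_axis: int = 0,
) -> Geometry:
    """Mirror through the aligned-frame plane perpendicular to an axis.

    The coordinate along ``plane_normal_axis`` (default x, the long
    molecular axis, so the plane is the sigma_v' mirror) is negated and
    the configured involutive atom permutation is applied so that
    symmetry-equivalent atoms (O1<->O2 etc.) swap roles.  Role labels are
    left untouched: after the swap the atom *at* the O1 index is again a
    donor-side oxygen.
    """
    perm = np.asarray(permutation, dtype=int)
    n = geometry.n_atoms
    if perm.shape != (n,) or sorted(perm.tolist()) != list(range(n)):
        raise ValueError("permutation must be a permutation of atom indices")
    if not np.array_equal(perm[perm], np.arange(n)):
        raise ValueError("permutation must be an involution (its own inverse)")
    if plane_normal_axis not in (0, 1, 2):
        raise ValueError("plane_normal_axis must be 0 (x), 1 (y) or 2 (z)")
    if not np.array_equal(
        geometry.atomic_numbers[perm], geometry.atomic_numbers
    ):
        raise ValueError("permutation must map atoms onto atoms of the same element")

    xyz = geometry.coordinates.copy()
    xyz[:, plane_normal_axis] *= -1.0
    xyz = xyz[perm]
    return geometry.with_coordinates(xyz)
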