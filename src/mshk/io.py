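"""File formats and run configuration.

Formats handled: extended XYZ (geometries and trajectories, Angstrom),
Gaussian cube (volumetric densities; Bohr header by convention, with the
negative-atom-count flag marking Angstrom files), columnar TSV energy
tables, and a YAML run configuration validated against a strict schema
(unknown keys are rejected).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .basis import DensityField, resample_density
from .constants import BOHR_TO_ANGSTROM, ELEMENT_SYMBOLS, SYMBOL_TO_Z
from .geometry import Geometry
from .grid import GridSpec

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_cube",
    "write_cube",
    "RunConfig",
    "load_config",
    "write_energy_table",
    "read_energy_table",
]

# ----------------------------------------------------------------- XYZ


def write_xyz(path, geometries, comments=None, labels_in_comment: bool = True) -> None:
    """Write one or more frames as (extended) XYZ in Angstrom."""
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    lines = []
    for i, g in enumerate(geometries):
        comment = "" if comments is None else str(comments[i])
        if labels_in_comment and g.labels and "labels=" not in comment:
            tag = ",".join(f"{k}:{v}" for k, v in sorted(g.labels.items()))
            comment = (comment + f" labels={tag}").strip()
        lines.append(str(g.n_atoms))
        lines.append(comment)
        for z, (x, y, zc) in zip(g.atomic_numbers, g.coordinates):
            sym = ELEMENT_SYMBOLS.get(int(z), str(int(z)))
            lines.append(f"{sym:2s} {x:18.10f} {y:18.10f} {zc:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_labels(comment: str) -> dict:
    labels = {}
    for token in comment.split():
        if token.startswith("labels="):
            for item in token[len("labels="):].split(","):
                if ":" in item:
                    key, val = item.split(":")
                    labels[key] = int(val)
    return labels


def read_xyz(path) -> list[Geometry]:
    """Read all frames of an (extended) XYZ file."""
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError as err:
            raise ValueError(f"XYZ parse error at line {i + 1}: expected atom count") from err
        comment = text[i + 1] if i + 1 < len(text) else ""
        zs, xyz = [], []
        for j in range(n):
            parts = text[i + 2 + j].split()
            sym = parts[0]
            zs.append(SYMBOL_TO_Z.get(sym, int(sym) if sym.isdigit() else None))
            if zs[-1] is None:
                raise ValueError(f"unknown element symbol {sym!r} at line {i + 3 + j}")
            xyz.append([float(p) for p in parts[1:4]])
        frames.append(Geometry(np.array(zs), np.array(xyz), _parse_labels(comment)))
        i += 2 + n
    return frames


# ---------------------------------------------------------------- cube


def write_cube(path, density: DensityField, geometry: Geometry, comment: str = "") -> None:
    """Gaussian cube file: Bohr coordinates, values in e/Bohr^3."""
    grid = density.grid
    org = np.asarray(grid.origin) / BOHR_TO_ANGSTROM
    step = grid.spacing / BOHR_TO_ANGSTROM
    vals = density.reshaped() * BOHR_TO_ANGSTROM**3  # e/A^3 -> e/Bohr^3
    lines = [comment or "cube file", "generated by mshk"]
    lines.append(f"{geometry.n_atoms:5d} {org[0]:12.6f} {org[1]:12.6f} {org[2]:12.6f}")
    for ax in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[ax] = step
        lines.append(
            f"{grid.shape[ax]:5d} {vec[0]:12.6f} {vec[1]:12.6f} {vec[2]:12.6f}"
        )
    for z, pos in zip(geometry.atomic_numbers, geometry.coordinates):
        pb = pos / BOHR_TO_ANGSTROM
        lines.append(f"{int(z):5d} {float(z):12.6f} {pb[0]:12.6f} {pb[1]:12.6f} {pb[2]:12.6f}")
    flat = vals.ravel()  # x fastest axis outermost, z innermost (Fortran text order)
    for start in range(0, flat.size, 6):
        lines.append(" ".join(f"{v:13.5E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path, target_grid: GridSpec | None = None) -> tuple[DensityField, Geometry]:
    """Read a Gaussian cube file into (DensityField in e/A^3, Geometry).

    A negative atom count in the header flags Angstrom coordinates
    (otherwise Bohr).  Orthogonal axes are required; the density is
    trilinearly resampled when ``target_grid`` differs from the native
    grid.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ValueError(f"cube file truncated at line {len(lines)}")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(v) for v in head[1:4]])
    except (ValueError, IndexError) as err:
        raise ValueError("cube parse error at line 3 (atom count/origin)") from err
    angstrom = natoms < 0
    natoms = abs(natoms)
    unit = 1.0 if angstrom else BOHR_TO_ANGSTROM

    shape, steps = [], []
    for ax in range(3):
        parts = lines[3 + ax].split()
        try:
            n = int(parts[0])
            vec = np.array([float(v) for v in parts[1:4]])
        except (ValueError, IndexError) as err:
            raise ValueError(f"cube parse error at line {4 + ax} (axis record)") from err
        if np.count_nonzero(vec) != 1 or vec[ax] <= 0:
            raise ValueError("only orthogonal, positively oriented cube axes are supported")
        shape.append(abs(n))
        steps.append(vec[ax] * unit)  # -> Angstrom

    zs, xyz = [], []
    for a in range(natoms):
        parts = lines[6 + a].split()
        zs.append(int(parts[0]))
        xyz.append([float(v) for v in parts[2:5]])
    geometry = Geometry(np.array(zs), np.array(xyz) * unit)

    data = []
    for ln, line in enumerate(lines[6 + natoms :], start=7 + natoms):
        data.extend(float(v) for v in line.split())
    expected = shape[0] * shape[1] * shape[2]
    if len(data) != expected:
        raise ValueError(
            f"cube data length {len(data)} != {expected} expected from header (near line {ln})"
        )
    vals = np.asarray(data).reshape(shape) / BOHR_TO_ANGSTROM**3  # e/Bohr^3 -> e/A^3

    origin_a = origin * unit
    spacings = steps
    iso = np.allclose(spacings, spacings[0], rtol=1e-8)
    if iso and target_grid is None:
        grid = GridSpec(origin=tuple(origin_a), spacing=float(spacings[0]), shape=tuple(shape))
        return DensityField(grid=grid, values=vals.ravel()), geometry
    axes = tuple(origin_a[i] + spacings[i] * np.arange(shape[i]) for i in range(3))
    if target_grid is None:
        raise ValueError(
            "cube has anisotropic spacing; pass target_grid to resample onto an isotropic grid"
        )
    return resample_density(vals, axes, target_grid), geometry


# --------------------------------------------------------------- tables


def write_energy_table(path, energies: np.ndarray, states, frame_ids=None) -> None:
    """Long-format TSV: frame, state, energy (kcal/mol)."""
    e = np.atleast_2d(np.asarray(energies, dtype=float))
    frames = np.arange(e.shape[0]) if frame_ids is None else np.asarray(frame_ids)
    rows = [
        {"frame": int(frames[i]), "state": int(s), "energy_kcal_mol": float(e[i, j])}
        for i in range(e.shape[0])
        for j, s in enumerate(states)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_energy_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --------------------------------------------------------------- config


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    origin: tuple[float, float, float] | None = None
    spacing: float = Field(0.2, gt=0)
    shape: tuple[int, int, int] = (60, 50, 30)


class PotentialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_pot: float = Field(0.2, gt=0)


class BasisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    per_axis_count: tuple[int, int, int] = (50, 50, 50)


class SymmetryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    permutation: list[int] = Field(default_factory=lambda: [1, 0, 4, 3, 2, 5, 8, 7, 6])


class LabelsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    O1: int = 0
    O2: int = 1
    H: int = 5


class KernelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_v: float | None = None
    lambda_v: float = Field(1e-12, ge=0)
    sigma_u: float | None = None
    lambda_u: float = Field(1e-12, ge=0)
    cv_folds: int = Field(5, ge=2)


class MDConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    timestep_fs: float = Field(0.25, gt=0)
    n_steps: int = Field(240, gt=0)
    fd_step: float = Field(0.001, gt=0)
    restraint_k_hydrogen: float = Field(9.0, ge=0)
    restraint_k_heavy: float = Field(40.0, ge=0)
    excitation_interval_fs: float = Field(100.0, gt=0)


class DatasetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_clusters: int = Field(2500, gt=0)
    n_gs_frames: int = Field(2000, gt=0)
    n_es_trajectories: int = Field(30, gt=0)
    es_steps: int = Field(480, gt=0)
    states: tuple[int, ...] = (0, 1, 2)
    downsample: int = Field(2, ge=1)
    pca_components: int | None = 64


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_resamples: int = Field(9999, ge=1)
    confidence: float = Field(0.95, gt=0, lt=1)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    grid: GridConfig = Field(default_factory=GridConfig)
    potential: PotentialConfig = Field(default_factory=PotentialConfig)
    basis: BasisConfig = Field(default_factory=BasisConfig)
    symmetry: SymmetryConfig = Field(default_factory=SymmetryConfig)
    labels: LabelsConfig = Field(default_factory=LabelsConfig)
    kernel: KernelConfig = Field(default_factory=KernelConfig)
    md: MDConfig = Field(default_factory=MDConfig)
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; defaults apply where absent."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


# ----------------------------------------------------------- trajectories


def write_trajectory(prefix, trajectory) -> None:
    """Write a trajectory as extended XYZ + a columnar energy log.

    ``prefix.xyz`` holds the frames (positions and velocities, with the
    per-frame energies in the comment line); ``prefix_energies.tsv``
    holds time, potential, kinetic, restraint and total energies.
    """
    prefix = Path(prefix)
    lines = []
    n = trajectory.atomic_numbers.size
    tag = ",".join(f"{k}:{v}" for k, v in sorted(trajectory.labels.items()))
    for i in range(trajectory.n_frames):
        lines.append(str(n))
        lines.append(
            f"t={trajectory.times[i]:.6f} E_pot={trajectory.potential_energies[i]:.10f} "
            f"E_rest={trajectory.restraint_energies[i]:.10f} "
            f"E_kin={trajectory.kinetic_energies[i]:.10f} "
            f"surface={trajectory.surface_id} labels={tag}"
        )
        for a in range(n):
            sym = ELEMENT_SYMBOLS.get(int(trajectory.atomic_numbers[a]), "X")
            x, y, z = trajectory.positions[i, a]
            vx, vy, vz = trajectory.velocities[i, a]
            lines.append(
                f"{sym:2s} {x:16.10f} {y:16.10f} {z:16.10f} {vx:16.10f} {vy:16.10f} {vz:16.10f}"
            )
    prefix.with_suffix(".xyz").write_text("\n".join(lines) + "\n")
    df = pd.DataFrame(
        {
            "time_fs": trajectory.times,
            "E_pot": trajectory.potential_energies,
            "E_kin": trajectory.kinetic_energies,
            "E_restraint": trajectory.restraint_energies,
            "E_total": trajectory.total_energies,
        }
    )
    df.to_csv(str(prefix) + "_energies.tsv", sep="\t", index=False)


def read_trajectory(prefix):
    """Read a trajectory written by :func:`write_trajectory`."""
    from .md import Trajectory

    prefix = Path(prefix)
    text = prefix.with_suffix(".xyz").read_text().splitlines()
    pos, vel, times, e_pot, e_rest, e_kin = [], [], [], [], [], []
    labels, zs, surface_id = {}, None, 0
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        n = int(text[i].strip())
        fields = dict(
            token.split("=", 1) for token in text[i + 1].split() if "=" in token
        )
        times.append(float(fields.get("t", len(times))))
        e_pot.append(float(fields.get("E_pot", "nan")))
        e_rest.append(float(fields.get("E_rest", "0")))
        e_kin.append(float(fields.get("E_kin", "nan")))
        surface_id = int(fields.get("surface", 0))
        labels = _parse_labels(text[i + 1])
        fz, fx, fv = [], [], []
        for a in range(n):
            parts = text[i + 2 + a].split()
            fz.append(SYMBOL_TO_Z[parts[0]])
            fx.append([float(v) for v in parts[1:4]])
            fv.append([float(v) for v in parts[4:7]] if len(parts) >= 7 else [0.0, 0.0, 0.0])
        zs = np.array(fz)
        pos.append(fx)
        vel.append(fv)
        i += 2 + n
    times = np.asarray(times)
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    return Trajectory(
        atomic_numbers=zs,
        labels=labels,
        positions=np.asarray(pos),
        velocities=np.asarray(vel),
        times=times,
        potential_energies=np.asarray(e_pot),
        restraint_energies=np.asarray(e_rest),
        kinetic_energies=np.asarray(e_kin),
        timestep=dt,
        surface_id=surface_id,
    )
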