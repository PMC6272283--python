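"""CoMFA molecular interaction fields.

A rectangular grid is laid over the aligned ensemble and a probe atom (by
default an sp3 carbon carrying +1 e) is placed at every grid point.  Two
interaction energies are evaluated per molecule per point:

* steric: a Lennard-Jones 6-12 potential in the "R, epsilon" form
  ``eps_ij * [(R_ij/r)**12 - 2*(R_ij/r)**6]`` with the minimum at
  ``R_ij = r_probe + r_atom`` and depth ``eps_ij = sqrt(eps_probe*eps_atom)``;
* electrostatic: a Coulomb potential ``332.0 * q_i * q_probe / (D(r) * r)``
  with the distance-dependent dielectric ``D(r) = r`` (hence a 1/r**2 law).

Both are truncated at a cutoff (default 30 kcal/mol).  A grid point whose
steric energy hits the positive cutoff lies inside the molecular volume and
is flagged "sterically excluded"; at such cells the electrostatic value is,
by default, replaced column-wise by the mean over the non-excluded compounds
(plain clamping is available as an alternative dialect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError
from .structures import Molecule3D

__all__ = [
    "COULOMB_CONSTANT",
    "VDW_PARAMS",
    "GridSpec",
    "ProbeAtom",
    "FieldMatrix",
    "build_grid",
    "steric_energy",
    "electrostatic_energy",
    "compute_field_matrix",
]

#: Conversion constant for Coulomb energies, kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0

#: Per-element Lennard-Jones parameters (vdW radius in Angstrom, well depth in
#: kcal/mol), general-purpose values for the elements occurring in this
#: compound class.  Unlisted elements fall back to the carbon entry.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
    "P": (1.80, 0.314),
}


@dataclass(frozen=True)
class ProbeAtom:
    """The CoMFA probe: an sp3 carbon with unit positive charge by default."""

    vdw_radius: float = 1.70  # Angstrom
    well_depth: float = 0.107  # kcal/mol
    charge: float = 1.0  # e

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0 or self.well_depth <= 0:
            raise ValueError("probe radius and well depth must be positive")


@dataclass(frozen=True)
class GridSpec:
    """A regular rectangular grid, optionally in a rotated frame.

    Points are ``origin + (i,j,k) * spacing @ axes.T`` for integer indices
    ``0 <= i < shape[0]`` etc.  ``axes`` rows are orthonormal direction
    vectors; the identity keeps the grid aligned with the template frame.
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]
    axes: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(s < 2 for s in self.shape):
            raise ValueError("grid needs at least 2 steps per axis")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """All grid points as an (n_points, 3) array, x fastest last axis order
        (C order over (i, j, k))."""
        nx, ny, nz = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        local = idx * self.spacing
        return np.asarray(self.origin) + local @ np.asarray(self.axes)

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "GridSpec":
        """The same grid carried through the rigid motion x -> R x + t."""
        origin = R @ np.asarray(self.origin) + np.asarray(t)
        axes = np.asarray(self.axes) @ R.T
        return GridSpec(
            origin=tuple(float(v) for v in origin),
            spacing=self.spacing,
            shape=self.shape,
            axes=tuple(tuple(float(v) for v in row) for row in axes),
        )

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "shape": list(self.shape),
            "axes": [list(r) for r in self.axes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            origin=tuple(d["origin"]),
            spacing=float(d["spacing"]),
            shape=tuple(int(v) for v in d["shape"]),
            axes=tuple(tuple(float(v) for v in r) for r in d["axes"]),
        )


def build_grid(
    ensemble: list[Molecule3D], spacing: float = 2.0, margin: float = 4.0
) -> GridSpec:
    """Axis-aligned grid enclosing every atom of the ensemble plus a margin.

    The grid frame is the template frame the ensemble was aligned in.  The
    origin is the low corner of the padded bounding box; the number of steps
    per axis is the smallest count whose span covers the padded box.
    """
    if not ensemble:
        raise GridError("cannot build a grid around an empty ensemble")
    coords = []
    for m in ensemble:
        if m.coords is None:
            raise GridError(f"molecule {m.id!r} has no coordinates")
        coords.append(m.coords)
    allxyz = np.vstack(coords)
    lo = allxyz.min(axis=0) - margin
    hi = allxyz.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    shape = tuple(max(2, s) for s in shape)
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=spacing, shape=shape)


# ---------------------------------------------------------------------------
# probe energies


def _lj_params(elements: list[str], probe: ProbeAtom) -> tuple[np.ndarray, np.ndarray]:
    radii = np.array([VDW_PARAMS.get(e, VDW_PARAMS["C"])[0] for e in elements])
    eps = np.array([VDW_PARAMS.get(e, VDW_PARAMS["C"])[1] for e in elements])
    r_min = probe.vdw_radius + radii
    eps_ij = np.sqrt(probe.well_depth * eps)
    return r_min, eps_ij


def _steric_at(
    points: np.ndarray, mol: Molecule3D, probe: ProbeAtom, cutoff: float
) -> np.ndarray:
    r_min, eps_ij = _lj_params(mol.elements, probe)
    d = np.linalg.norm(points[:, None, :] - mol.coords[None, :, :], axis=-1)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (r_min[None, :] / d) ** 6
        e = eps_ij[None, :] * (ratio6**2 - 2.0 * ratio6)
    e = np.where(np.isfinite(e), e, cutoff)
    total = e.sum(axis=1)
    return np.clip(total, -cutoff, cutoff)


def _electrostatic_at(
    points: np.ndarray, mol: Molecule3D, probe: ProbeAtom, cutoff: float
) -> np.ndarray:
    if mol.partial_charges is None:
        raise GridError(f"molecule {mol.id!r} has no partial charges")
    d = np.linalg.norm(points[:, None, :] - mol.coords[None, :, :], axis=-1)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        # distance-dependent dielectric D(r) = r  =>  K q q' / r^2
        e = COULOMB_CONSTANT * probe.charge * mol.partial_charges[None, :] / d**2
    e = np.where(np.isfinite(e), e, np.sign(mol.partial_charges[None, :]) * cutoff)
    total = e.sum(axis=1)
    return np.clip(total, -cutoff, cutoff)


def steric_energy(
    point, mol: Molecule3D, probe: ProbeAtom = ProbeAtom(), cutoff: float = 30.0
) -> float:
    """Lennard-Jones probe energy (kcal/mol) at one point, clamped to the cutoff."""
    pts = np.asarray(point, dtype=float).reshape(1, 3)
    return float(_steric_at(pts, mol, probe, cutoff)[0])


def electrostatic_energy(
    point, mol: Molecule3D, probe: ProbeAtom = ProbeAtom(), cutoff: float = 30.0
) -> float:
    """Coulomb probe energy (kcal/mol, D(r)=r dielectric) at one point."""
    pts = np.asarray(point, dtype=float).reshape(1, 3)
    return float(_electrostatic_at(pts, mol, probe, cutoff)[0])


# ---------------------------------------------------------------------------
# field matrix


@dataclass
class FieldMatrix:
    """Compounds x grid-columns energy matrix, steric block then electrostatic.

    ``values`` has shape (n_compounds, 2 * n_points); the first block holds
    steric energies, the second electrostatic, both in kcal/mol and truncated
    at ``cutoff``.  ``excluded_mask`` (n_compounds, n_points) marks sterically
    excluded compound/point cells.  ``es_mode`` records which dialect filled
    the electrostatic block inside molecular volume: ``"column_mean"`` or
    ``"clamp"``.
    """

    compound_ids: list[str]
    values: np.ndarray
    grid: GridSpec
    cutoff: float
    excluded_mask: np.ndarray
    es_mode: str = "column_mean"
    probe: ProbeAtom = field(default_factory=ProbeAtom)

    @property
    def n_points(self) -> int:
        return self.values.shape[1] // 2

    @property
    def steric(self) -> np.ndarray:
        return self.values[:, : self.n_points]

    @property
    def electrostatic(self) -> np.ndarray:
        return self.values[:, self.n_points :]

    @property
    def column_kinds(self) -> np.ndarray:
        return np.array(["steric"] * self.n_points + ["electrostatic"] * self.n_points)

    @property
    def column_grid_index(self) -> np.ndarray:
        return np.concatenate([np.arange(self.n_points), np.arange(self.n_points)])

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"S{i:05d}" for i in range(self.n_points)] + [
            f"E{i:05d}" for i in range(self.n_points)
        ]
        return pd.DataFrame(self.values, index=self.compound_ids, columns=cols)

    def save(self, table_path, meta_path) -> None:
        """Tabular text dump plus a JSON sidecar with grid/probe metadata."""
        self.to_dataframe().to_csv(table_path, index_label="compound")
        meta = {
            "grid": self.grid.to_dict(),
            "cutoff": self.cutoff,
            "es_mode": self.es_mode,
            "probe": {
                "vdw_radius": self.probe.vdw_radius,
                "well_depth": self.probe.well_depth,
                "charge": self.probe.charge,
            },
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def compute_field_matrix(
    ensemble: list[Molecule3D],
    grid: GridSpec,
    probe: ProbeAtom = ProbeAtom(),
    cutoff: float = 30.0,
    es_mode: str = "column_mean",
    points: np.ndarray | None = None,
) -> FieldMatrix:
    """Evaluate steric and electrostatic fields for every aligned compound.

    ``points`` overrides the sampling locations (defaults to ``grid.points()``);
    it exists so the same computation can be checked under rigid motions of
    grid and molecules together.
    """
    if not ensemble:
        raise GridError("empty ensemble")
    if es_mode not in ("column_mean", "clamp"):
        raise ValueError(f"unknown electrostatic dialect {es_mode!r}")
    pts = grid.points() if points is None else np.asarray(points, dtype=float)
    n = len(ensemble)
    m = pts.shape[0]
    steric = np.empty((n, m))
    elec = np.empty((n, m))
    axes = np.asarray(grid.axes)
    span = (np.asarray(grid.shape) - 1) * grid.spacing
    for i, mol in enumerate(ensemble):
        if mol.coords is None:
            raise GridError(f"molecule {mol.id!r} has no coordinates")
        if points is None:
            local = (mol.coords - np.asarray(grid.origin)) @ axes.T
            if np.any(local < -1e-9) or np.any(local > span + 1e-9):
                raise GridError(f"grid does not enclose compound {mol.id!r}")
        steric[i] = _steric_at(pts, mol, probe, cutoff)
        elec[i] = _electrostatic_at(pts, mol, probe, cutoff)
    excluded = steric >= cutoff
    if es_mode == "column_mean":
        with np.errstate(invalid="ignore"):
            masked = np.where(excluded, np.nan, elec)
            col_mean = np.nanmean(
                np.where(np.all(excluded, axis=0)[None, :], 0.0, masked), axis=0
            )
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        elec = np.where(excluded, col_mean[None, :], elec)
    values = np.hstack([steric, elec])
    return FieldMatrix(
        compound_ids=[mol.id for mol in ensemble],
        values=values,
        grid=grid,
        cutoff=cutoff,
        excluded_mask=excluded,
        es_mode=es_mode,
        probe=probe,
    )
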