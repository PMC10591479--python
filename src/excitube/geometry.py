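"""Nanotube wall geometry: planar lattices rolled into cylinders.

The walls of a double-walled dye nanotube are modelled as a planar
two-dimensional lattice of point molecules (each carrying an in-plane
transition-dipole angle) that is rolled seamlessly onto a cylinder.
Sheet coordinates are ``(u, v)`` in nm with ``u`` the circumferential
(rolling) direction and ``v`` the axial direction; the rolled frame is
stored in Angstrom (see :mod:`excitube.frames`).

The true wall packing of the C8S3 dye is not parameterised here; the
default :meth:`LatticeSpec.brickwork` motif is a placeholder with a
1.1 nm stacking period along the tube axis, molecular columns every
1.05 nm around the circumference (a 2.1 nm cell with a half-staggered
two-molecule motif, ~0.9 molecules/nm^2), and dipoles tilted 85 degrees
from the circumferential direction (mostly axial).  The stacking period
is kept larger than the 0.7 nm extended-dipole charge arm so charges of
neighbouring molecules never overlap.  Everything downstream depends
only on the structural invariants (unit dipoles on a cylinder, local
order), not on these constants.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .frames import NM_TO_ANGSTROM, MoleculeFrame

__all__ = [
    "LatticeSpec",
    "TubeSpec",
    "Sheet",
    "build_lattice",
    "roll_to_cylinder",
    "rolled_wall",
    "double_wall",
]


@dataclasses.dataclass(frozen=True)
class LatticeSpec:
    """Planar unit cell of a wall lattice.

    ``basis_a`` is the circumferential repeat and ``basis_b`` the axial
    repeat, both in nm.  ``dipole_angle`` (radians) is the in-plane angle
    of every transition dipole measured from ``basis_a``; ``motif_offsets``
    are fractional positions of the molecules inside one cell.
    """

    basis_a: tuple[float, float] = (2.1, 0.0)
    basis_b: tuple[float, float] = (0.0, 1.1)
    dipole_angle: float = math.radians(85.0)
    motif_offsets: tuple[tuple[float, float], ...] = ((0.0, 0.0),)

    def __post_init__(self) -> None:
        a = np.asarray(self.basis_a, float)
        b = np.asarray(self.basis_b, float)
        det = a[0] * b[1] - a[1] * b[0]
        scale = max(np.linalg.norm(a), np.linalg.norm(b))
        if scale == 0 or abs(det) < 1e-12 * scale**2:
            raise ValueError("lattice basis vectors are degenerate")
        if len(self.motif_offsets) < 1:
            raise ValueError("motif_offsets must contain at least one molecule")

    @classmethod
    def brickwork(cls, dipole_angle: float = math.radians(85.0)) -> "LatticeSpec":
        """Two-molecule staggered (brickwork) cell with placeholder constants."""
        return cls(
            basis_a=(2.1, 0.0),
            basis_b=(0.0, 1.1),
            dipole_angle=dipole_angle,
            motif_offsets=((0.0, 0.0), (0.5, 0.5)),
        )

    @property
    def molecules_per_cell(self) -> int:
        return len(self.motif_offsets)

    @property
    def cell_matrix(self) -> np.ndarray:
        """Columns are the basis vectors (nm)."""
        return np.column_stack([self.basis_a, self.basis_b])

    def min_spacing(self) -> float:
        """Smallest intermolecular distance in the infinite lattice (nm)."""
        cell = self.cell_matrix
        offsets = np.asarray(self.motif_offsets, float)
        shifts = [(i, j) for i in (-1, 0, 1) for j in (-1, 0, 1)]
        best = math.inf
        for fx, fy in offsets:
            for gx, gy in offsets:
                for si, sj in shifts:
                    frac = np.array([gx - fx + si, gy - fy + sj])
                    if np.all(frac == 0):
                        continue
                    best = min(best, float(np.linalg.norm(cell @ frac)))
        return best


@dataclasses.dataclass(frozen=True)
class TubeSpec:
    """Concentric cylinder dimensions of the double wall (nm).

    Defaults match inner/outer diameters of 6.9 and 13.5 nm.
    """

    radius_iw: float = 3.45
    radius_ow: float = 6.75
    length: float = 20.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.radius_iw < self.radius_ow:
            raise ValueError("need 0 < radius_iw < radius_ow")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if np.linalg.norm(self.axis) == 0:
            raise ValueError("axis must be non-zero")


@dataclasses.dataclass(frozen=True)
class Sheet:
    """Planar sheet of molecules prior to rolling.

    ``positions`` are (M, 2) sheet coordinates in nm, ``angles`` the
    in-plane dipole angles, ``width`` the periodic repeat along ``u``.
    """

    positions: np.ndarray
    angles: np.ndarray
    width: float
    lattice: LatticeSpec


def build_lattice(spec: LatticeSpec, n_a: int, n_b: int) -> Sheet:
    """Tile ``n_a`` x ``n_b`` unit cells of ``spec`` into a planar sheet.

    Returns ``n_a * n_b * molecules_per_cell`` sites with exact
    translational periodicity; every site carries ``spec.dipole_angle``.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("n_a and n_b must be >= 1")
    cell = spec.cell_matrix
    ii, jj = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
    cells = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    offsets = np.asarray(spec.motif_offsets, float)
    frac = (cells[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    positions = frac @ cell.T
    angles = np.full(len(positions), spec.dipole_angle)
    width = n_a * spec.basis_a[0]
    if width <= 0:
        raise ValueError("basis_a must have a positive circumferential component")
    return Sheet(positions, angles, width, spec)


def cylinder_embed(
    u: np.ndarray, v: np.ndarray, width: float, radius: float, axis
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map sheet coordinates onto a cylinder of ``radius`` about ``axis``.

    The sheet is closed seamlessly: the circumferential angle is
    ``2*pi*u/width``.  Returns positions (nm) plus the local tangent
    (circumferential) and axial unit vectors at each site, all in the
    rotated frame whose z-axis is ``axis``.
    """
    theta = 2.0 * np.pi * np.asarray(u, float) / width
    rot = _frame_from_axis(axis)
    pos_local = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.asarray(v, float)]
    )
    tan_local = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    positions = pos_local @ rot.T
    tangents = tan_local @ rot.T
    axial = np.broadcast_to(rot[:, 2], positions.shape)
    return positions, tangents, axial


def _frame_from_axis(axis) -> np.ndarray:
    """Orthonormal matrix whose third column is the unit ``axis``."""
    ez = np.asarray(axis, float)
    ez = ez / np.linalg.norm(ez)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(ez @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    ex = helper - (helper @ ez) * ez
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    return np.column_stack([ex, ey, ez])


def roll_to_cylinder(
    sheet: Sheet, radius: float, axis=(0.0, 0.0, 1.0), wall_tag: str = "OW"
) -> MoleculeFrame:
    """Roll a planar sheet onto a cylinder of the given radius (nm).

    Every position ends up exactly at ``radius`` from the axis.  In-plane
    dipole angles become tangent-plane vectors
    ``cos(angle) * tangent + sin(angle) * axial``; each dipole is flipped
    if needed so its axial component is non-negative (the two chromophore
    directions are physically equivalent, so the axial-positive
    representative is chosen).

    If the sheet width differs from the circumference ``2*pi*radius`` by
    more than one lattice constant a warning is issued; the circumference
    is always rescaled so the wall closes seamlessly.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    circumference = 2.0 * np.pi * radius
    lattice_const = max(
        np.linalg.norm(sheet.lattice.basis_a), np.linalg.norm(sheet.lattice.basis_b)
    )
    if abs(sheet.width - circumference) > lattice_const:
        warnings.warn(
            f"sheet width {sheet.width:.3f} nm differs from circumference "
            f"{circumference:.3f} nm by more than one lattice constant; "
            "rescaling circumference",
            stacklevel=2,
        )
    u, v = sheet.positions[:, 0], sheet.positions[:, 1]
    positions, tangents, axial = cylinder_embed(u, v, sheet.width, radius, axis)
    dipoles = (
        np.cos(sheet.angles)[:, None] * tangents
        + np.sin(sheet.angles)[:, None] * axial
    )
    dipoles /= np.linalg.norm(dipoles, axis=1, keepdims=True)
    ax = np.asarray(axis, float) / np.linalg.norm(axis)
    flip = dipoles @ ax < 0
    dipoles[flip] *= -1.0
    pos_ang = positions * NM_TO_ANGSTROM
    span = (pos_ang.max(axis=0) - pos_ang.min(axis=0)).max() if len(pos_ang) else 0.0
    box = max(span, 2 * radius * NM_TO_ANGSTROM)
    tags = np.full(len(positions), wall_tag)
    return MoleculeFrame(pos_ang, dipoles, ax, box, tags)


def rolled_wall(
    lattice: LatticeSpec,
    radius: float,
    length: float,
    axis=(0.0, 0.0, 1.0),
    wall_tag: str = "OW",
) -> MoleculeFrame:
    """Defect-free wall: tile the lattice to fit ``2*pi*radius`` x ``length``."""
    n_a = max(1, round(2.0 * np.pi * radius / lattice.basis_a[0]))
    n_b = max(1, round(length / lattice.basis_b[1]))
    sheet = build_lattice(lattice, n_a, n_b)
    return roll_to_cylinder(sheet, radius, axis, wall_tag)


def double_wall(
    tube: TubeSpec, lattice: LatticeSpec, lattice_ow: LatticeSpec | None = None
) -> MoleculeFrame:
    """Defect-free double wall (inner + outer) for a tube specification."""
    iw = rolled_wall(lattice, tube.radius_iw, tube.length, tube.axis, "IW")
    ow = rolled_wall(
        lattice_ow or lattice, tube.radius_ow, tube.length, tube.axis, "OW"
    )
    return MoleculeFrame.concatenate(iw, ow)
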