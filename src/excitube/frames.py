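"""Molecular configuration frames.

A frame is the minimal description of one configuration of a dye
aggregate: per-molecule positions (in Angstrom), unit transition-dipole
vectors, the tube (alignment) axis and a bounding-box scale.  Frames are
what the exciton model, the patch clustering and the observable pipeline
consume; they can come from the synthetic generators in this package or
from an external plain-text table.

The on-disk format is a 7-column whitespace table, one molecule per row::

    # id  x  y  z  dx  dy  dz        (positions in Angstrom)
    0  1.0  0.0  0.0  0.0  0.0  1.0

Dipole vectors are renormalised to unit length on read.  Dipole vectors
are first-class here, which is why a bespoke table is used instead of a
trajectory format that has no slot for them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = ["MoleculeFrame", "read_frame", "write_frame", "FrameParseError"]

#: conversion factor between the nm geometry API and the Angstrom frame storage
NM_TO_ANGSTROM = 10.0

_UNIT_TOL = 1e-9


class FrameParseError(ValueError):
    """Raised when a frame table cannot be parsed; carries the line number."""


def _as_unit_rows(vectors: np.ndarray, tol: float = _UNIT_TOL) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0) or not np.all(np.isfinite(norms)):
        raise ValueError("zero-length or non-finite dipole vector")
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError(f"dipole norms deviate from 1 by more than {tol}")
    return vectors


@dataclasses.dataclass(frozen=True)
class MoleculeFrame:
    """One configuration: positions (Å), unit dipoles, axis and box scale.

    Parameters
    ----------
    positions : (N, 3) float array, Angstrom
    dipoles : (N, 3) float array
        Unit transition-dipole vectors (norm 1 within 1e-9).
    axis : (3,) unit vector
        The tube / flow-alignment axis.
    box_max_dim : float, Angstrom
        Largest dimension of the bounding box; must cover the coordinate
        extent.  Used to regularise positions for patch clustering.
    wall_tag : (N,) array of str
        ``"IW"`` (inner wall) or ``"OW"`` (outer wall) per molecule.
    """

    positions: np.ndarray
    dipoles: np.ndarray
    axis: np.ndarray
    box_max_dim: float
    wall_tag: np.ndarray

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        dip = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        axis = np.asarray(self.axis, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if dip.shape != pos.shape:
            raise ValueError("dipoles must match positions in shape")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite coordinates")
        if len(pos):
            _as_unit_rows(dip)
        norm = np.linalg.norm(axis)
        if axis.shape != (3,) or norm == 0:
            raise ValueError("axis must be a non-zero 3-vector")
        axis = axis / norm
        tags = np.asarray(self.wall_tag)
        if tags.shape != (len(pos),):
            raise ValueError("wall_tag must have one entry per molecule")
        extent = _max_extent(pos)
        box = float(self.box_max_dim)
        if box < extent - 1e-9:
            raise ValueError(
                f"box_max_dim {box} smaller than coordinate extent {extent}"
            )
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dipoles", dip)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "box_max_dim", box)
        object.__setattr__(self, "wall_tag", tags.astype("U2"))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_inner(self) -> int:
        return int(np.sum(self.wall_tag == "IW"))

    @property
    def n_outer(self) -> int:
        return int(np.sum(self.wall_tag == "OW"))

    def select(self, mask: np.ndarray) -> "MoleculeFrame":
        """Sub-frame with the same axis and box scale."""
        mask = np.asarray(mask)
        return MoleculeFrame(
            self.positions[mask],
            self.dipoles[mask],
            self.axis,
            self.box_max_dim,
            self.wall_tag[mask],
        )

    def wall(self, tag: str) -> "MoleculeFrame":
        return self.select(self.wall_tag == tag)

    @staticmethod
    def concatenate(first: "MoleculeFrame", second: "MoleculeFrame") -> "MoleculeFrame":
        """Stack two frames; axes must agree, box scale is re-derived."""
        if not np.allclose(first.axis, second.axis):
            raise ValueError("cannot concatenate frames with different axes")
        pos = np.vstack([first.positions, second.positions])
        box = max(first.box_max_dim, second.box_max_dim, _max_extent(pos))
        return MoleculeFrame(
            pos,
            np.vstack([first.dipoles, second.dipoles]),
            first.axis,
            box,
            np.concatenate([first.wall_tag, second.wall_tag]),
        )


def _max_extent(positions: np.ndarray) -> float:
    if len(positions) == 0:
        return 0.0
    span = positions.max(axis=0) - positions.min(axis=0)
    return float(span.max())


def write_frame(frame: MoleculeFrame, path: str | Path) -> None:
    """Write a frame as the 7-column text table (id, x, y, z, dx, dy, dz)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# excitube frame: id x y z dx dy dz (positions in Angstrom)\n")
        fh.write(
            "# axis %.12g %.12g %.12g  box_max_dim %.12g\n"
            % (*frame.axis, frame.box_max_dim)
        )
        fh.write("# wall_tag " + " ".join(frame.wall_tag) + "\n")
        for i, (r, d) in enumerate(zip(frame.positions, frame.dipoles)):
            fh.write(
                "%d %.10g %.10g %.10g %.10g %.10g %.10g\n"
                % (i, r[0], r[1], r[2], d[0], d[1], d[2])
            )


def read_frame(path: str | Path) -> MoleculeFrame:
    """Read a 7-column frame table; dipoles are renormalised to unit length.

    Comment lines start with ``#``.  The optional header comments written by
    :func:`write_frame` restore the axis, box scale and wall tags; without
    them the axis defaults to z and the box scale to the coordinate extent.
    """
    path = Path(path)
    axis = np.array([0.0, 0.0, 1.0])
    box: float | None = None
    tags: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if fields[:1] == ["axis"]:
                axis = np.array([float(v) for v in fields[1:4]])
                box = float(fields[5])
            elif fields[:1] == ["wall_tag"]:
                tags = fields[1:]
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FrameParseError(
                f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FrameParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise FrameParseError(f"{path}: no molecule rows")
    data = np.array(rows)
    positions, dipoles = data[:, :3], data[:, 3:]
    norms = np.linalg.norm(dipoles, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        raise FrameParseError(f"{path}: zero-length dipole in molecule row {bad}")
    dipoles = dipoles / norms[:, None]
    if tags is None:
        tags = ["OW"] * len(positions)
    if box is None:
        box = _max_extent(positions)
    return MoleculeFrame(positions, dipoles, axis, box, np.array(tags))
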