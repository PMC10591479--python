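"""Patch identification by density clustering of positions and orientations.

A patch is a group of molecules that are close in space *and* share a
similar orientation.  Positions are made dimensionless by dividing by
the largest bounding-box dimension and concatenated with the unit dipole
vectors into a 6-dimensional feature space; DBSCAN (Euclidean metric,
``eps = 0.2``, at least two points per neighbourhood including the point
itself) then returns the patches, with isolated molecules labelled as
noise (-1).

Because the two directions of a chromophore are physically equivalent,
dipoles are mapped to the hemisphere with a non-negative axial component
before clustering; otherwise one physical patch containing antiparallel
dipole representations would split in two.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .frames import MoleculeFrame

__all__ = [
    "PatchFeatures",
    "PatchAssignment",
    "regularize",
    "identify_patches",
    "patch_timeseries",
]


@dataclasses.dataclass(frozen=True)
class PatchFeatures:
    """N x 6 dimensionless features: scaled positions + unit dipoles."""

    matrix: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[1] != 6:
            raise ValueError("features must be N x 6")
        if np.any(np.abs(m[:, :3]) > 1.0 + 1e-9):
            raise ValueError("scaled positions must lie in [-1, 1]")
        norms = np.linalg.norm(m[:, 3:], axis=1)
        if len(m) and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("dipole features must be unit vectors")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return len(self.matrix)


@dataclasses.dataclass(frozen=True)
class PatchAssignment:
    """Per-molecule patch labels plus summary statistics.

    ``labels`` uses -1 for noise and 0..n_patches-1 otherwise, numbered
    by first occurrence in input order.  ``axial_order`` is the global
    order parameter ``f = <(d . axis)^2>`` over the clustered molecules.
    """

    labels: np.ndarray
    n_patches: int
    sizes: np.ndarray
    mean_dipoles: np.ndarray
    axial_order: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, int)
        if self.n_patches != len(self.sizes):
            raise ValueError("sizes must have one entry per patch")
        if int(np.sum(self.sizes)) + int(np.sum(labels == -1)) != len(labels):
            raise ValueError("sizes plus noise count must equal N")
        if np.any(self.sizes < 2):
            raise ValueError("every patch must have at least 2 members")
        object.__setattr__(self, "labels", labels)

    @property
    def noise_count(self) -> int:
        return int(np.sum(self.labels == -1))

    @property
    def largest_fraction(self) -> float:
        total = len(self.labels)
        if total == 0 or self.n_patches == 0:
            return 0.0
        return float(np.max(self.sizes)) / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"molecule": np.arange(len(self.labels)),
                             "patch": self.labels})


def regularize(frame: MoleculeFrame, wall: str | None = None) -> PatchFeatures:
    """Dimensionless clustering features of a frame.

    Positions are divided by ``box_max_dim`` (after centring, so they
    lie in [-1, 1]); dipoles are unit vectors flipped to the axial
    non-negative hemisphere.
    """
    sub = frame if wall is None else frame.wall(wall)
    if frame.box_max_dim <= 0:
        raise ValueError("box_max_dim must be > 0")
    pos = sub.positions - (
        (frame.positions.max(axis=0) + frame.positions.min(axis=0)) / 2.0
        if len(frame)
        else 0.0
    )
    pos = pos / frame.box_max_dim
    dip = sub.dipoles.copy()
    flip = dip @ sub.axis < 0
    dip[flip] *= -1.0
    return PatchFeatures(np.hstack([pos, dip]), sub.axis)


def identify_patches(
    features: PatchFeatures,
    eps: float = 0.2,
    min_points: int = 2,
    orientation_weight: float = 1.0,
) -> PatchAssignment:
    """DBSCAN patch assignment in the 6-D feature space.

    A point is a core point when at least ``min_points`` points
    (itself included) lie within ``eps``; clusters are the connected
    core neighbourhoods plus their border points, everything else is
    noise.  ``orientation_weight`` scales the dipole features relative
    to the positional ones (1 = equal weighting).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if len(features) == 0:
        raise ValueError("no molecules to cluster")
    matrix = features.matrix.copy()
    matrix[:, 3:] *= orientation_weight
    raw = DBSCAN(eps=eps, min_samples=min_points).fit_predict(matrix)
    labels = _relabel_by_first_occurrence(raw)
    n_patches = int(labels.max()) + 1 if np.any(labels >= 0) else 0
    sizes = np.array(
        [int(np.sum(labels == k)) for k in range(n_patches)], dtype=int
    )
    mean_dipoles = np.zeros((n_patches, 3))
    for k in range(n_patches):
        d = features.matrix[labels == k, 3:]
        mean = d.mean(axis=0)
        nrm = np.linalg.norm(mean)
        mean_dipoles[k] = mean / nrm if nrm > 0 else mean
    clustered = labels >= 0
    if np.any(clustered):
        proj = features.matrix[clustered, 3:] @ features.axis
        f = float(np.mean(proj**2))
    else:
        f = float("nan")
    return PatchAssignment(labels, n_patches, sizes, mean_dipoles, f)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def patch_timeseries(
    frames: Sequence[MoleculeFrame],
    eps: float = 0.2,
    min_points: int = 2,
    wall: str | None = "OW",
) -> pd.DataFrame:
    """Per-frame patch statistics of a trajectory.

    Columns: frame index, number of patches, fraction of molecules in
    the largest patch, and the axial order parameter ``f``.  Frames with
    an empty selection report zero patches.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    rows = []
    for i, frame in enumerate(frames):
        sub = frame if wall is None else frame.wall(wall)
        if len(sub) == 0:
            rows.append(
                {"frame": i, "n_patches": 0, "largest_fraction": 0.0,
                 "axial_order": np.nan}
            )
            continue
        assignment = identify_patches(regularize(frame, wall), eps, min_points)
        rows.append(
            {
                "frame": i,
                "n_patches": assignment.n_patches,
                "largest_fraction": assignment.largest_fraction,
                "axial_order": assignment.axial_order,
            }
        )
    return pd.DataFrame(rows)
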