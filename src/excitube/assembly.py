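"""Synthetic outer-wall recovery: patchworks and toy assembly dynamics.

After the outer wall (OW) of a double-walled nanotube is dissolved, it
recovers on the surviving inner wall (IW) as a *patchwork*: spatially
contiguous groups of molecules that are locally ordered but whose group
orientations are mutually random, only later converging to one global
orientation.  This module generates such configurations directly
(:func:`generate_patchwork`) and as a seeded stochastic trajectory
(:func:`simulate_assembly`).

The dynamics here is an intentionally minimal lattice model — adsorption
onto empty outer-wall sites, orientation adoption from occupied
neighbours, nucleation of new patches with a configurable orientation
spread, and whole-patch reorientation toward the preferred lattice
orientation at a rate inversely proportional to patch size.  Nothing
downstream depends on these rules; they only have to produce the
statistical structure the analysis assumes (monotone occupancy, early
orientational disorder, late global order).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .frames import NM_TO_ANGSTROM, MoleculeFrame
from .geometry import LatticeSpec, TubeSpec, build_lattice, cylinder_embed

__all__ = [
    "AssemblySimParams",
    "OuterWallSites",
    "generate_patchwork",
    "simulate_assembly",
    "axial_order",
    "in_surface_angles",
    "patch_dispersion",
]


@dataclasses.dataclass(frozen=True)
class AssemblySimParams:
    """Parameters of the toy outer-wall assembly model.

    ``adsorption_rate`` is the per-step probability that any given empty
    site becomes occupied; ``nucleation_orientation_spread`` (radians)
    is the half-width of the uniform angle window around the preferred
    lattice orientation from which a freshly nucleated patch draws its
    in-surface angle (``pi`` = fully random, 0 = immediately ordered);
    ``patch_reorientation_rate`` is the per-step rate at which a patch of
    size ``s`` snaps to the preferred orientation (probability
    ``min(1, rate / s)``).
    """

    n_sites: int | None = None
    adsorption_rate: float = 0.02
    nucleation_orientation_spread: float = np.pi
    patch_reorientation_rate: float = 0.0
    n_steps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adsorption_rate < 0 or self.patch_reorientation_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.nucleation_orientation_spread < 0:
            raise ValueError("nucleation_orientation_spread must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_sites is not None and self.n_sites < 1:
            raise ValueError("n_sites must be >= 1 when given")


class OuterWallSites:
    """Lattice of candidate outer-wall adsorption sites on a cylinder.

    Carries the rolled 3-D positions (Angstrom) together with the local
    tangent/axial surface frame and the unrolled sheet coordinates used
    for periodic surface distances.
    """

    def __init__(self, tube: TubeSpec, lattice: LatticeSpec):
        radius = tube.radius_ow
        n_a = max(1, round(2.0 * np.pi * radius / lattice.basis_a[0]))
        n_b = max(1, round(tube.length / lattice.basis_b[1]))
        sheet = build_lattice(lattice, n_a, n_b)
        pos_nm, tangents, axial = cylinder_embed(
            sheet.positions[:, 0], sheet.positions[:, 1], sheet.width,
            radius, tube.axis,
        )
        self.tube = tube
        self.lattice = lattice
        self.sheet_uv = sheet.positions
        self.width = sheet.width
        self.positions = pos_nm * NM_TO_ANGSTROM
        self.tangents = tangents
        self.axial = np.array(axial[0], float)
        self.min_spacing = lattice.min_spacing() * NM_TO_ANGSTROM

    def __len__(self) -> int:
        return len(self.positions)

    def surface_distance(self, i: int, other: np.ndarray | slice) -> np.ndarray:
        """Unrolled (periodic-in-u) surface distance in nm from site ``i``."""
        du = np.abs(self.sheet_uv[other, 0] - self.sheet_uv[i, 0])
        du = np.minimum(du, self.width - du)
        dv = self.sheet_uv[other, 1] - self.sheet_uv[i, 1]
        return np.hypot(du, dv)

    def dipoles_from_angles(self, idx: np.ndarray, angles: np.ndarray) -> np.ndarray:
        """Tangent-plane dipoles with in-surface angle per selected site.

        The axial-positive representative of each dipole is returned
        (the two chromophore directions are equivalent).
        """
        d = (
            np.cos(angles)[:, None] * self.tangents[idx]
            + np.sin(angles)[:, None] * self.axial[None, :]
        )
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        flip = d @ self.axial < 0
        d[flip] *= -1.0
        return d

    def frame(
        self, iw: MoleculeFrame, idx: np.ndarray, angles: np.ndarray
    ) -> MoleculeFrame:
        """IW plus the selected occupied OW sites as one frame."""
        ow_box = 2 * self.tube.radius_ow * NM_TO_ANGSTROM
        box = max(iw.box_max_dim if len(iw) else 0.0, ow_box, self.tube.length
                  * NM_TO_ANGSTROM)
        if len(idx) == 0:
            if len(iw) == 0:
                raise ValueError("empty frame")
            return MoleculeFrame(iw.positions, iw.dipoles, iw.axis, box, iw.wall_tag)
        ow = MoleculeFrame(
            self.positions[idx],
            self.dipoles_from_angles(idx, angles),
            self.axial,
            box,
            np.full(len(idx), "OW"),
        )
        if len(iw) == 0:
            return ow
        merged = MoleculeFrame.concatenate(iw, ow)
        return MoleculeFrame(
            merged.positions, merged.dipoles, merged.axis, box, merged.wall_tag
        )


def generate_patchwork(
    iw: MoleculeFrame,
    tube: TubeSpec,
    lattice: LatticeSpec,
    n_ow: int,
    n_patches: int,
    seed: int,
    return_labels: bool = False,
):
    """Place ``n_ow`` outer-wall molecules in ``n_patches`` oriented patches.

    Patch seed sites are drawn at random on the outer-wall lattice; sites
    are claimed round-robin by surface distance to the seeds, giving
    spatially contiguous, near-equal patches.  All molecules of a patch
    share one uniformly random in-surface dipole angle; angles of
    different patches are independent.  Molecules sit on lattice sites,
    so no two are closer than the lattice spacing.

    With ``return_labels=True`` also returns the per-OW-molecule patch
    label and the patch angles.
    """
    if n_ow < 0:
        raise ValueError("n_ow must be >= 0")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    sites = OuterWallSites(tube, lattice)
    if n_ow > len(sites):
        raise ValueError(
            f"n_ow={n_ow} exceeds outer-surface capacity {len(sites)}"
        )
    rng = np.random.default_rng(seed)
    if n_ow == 0:
        out = iw
        if return_labels:
            return out, np.empty(0, int), np.empty(0)
        return out
    n_patches = min(n_patches, n_ow)
    # farthest-point seed placement spreads the patches over the wall
    seeds = [int(rng.integers(len(sites)))]
    min_dist = sites.surface_distance(seeds[0], slice(None))
    while len(seeds) < n_patches:
        candidates = np.flatnonzero(min_dist == min_dist.max())
        nxt = int(rng.choice(candidates))
        seeds.append(nxt)
        min_dist = np.minimum(min_dist, sites.surface_distance(nxt, slice(None)))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_patches)
    # round-robin breadth-first growth on the site adjacency graph keeps
    # every patch spatially contiguous
    cutoff = _neighbour_cutoff(sites, np.arange(len(sites)))
    tree = cKDTree(sites.positions)
    neighbours = tree.query_ball_point(sites.positions, cutoff)
    claimed = np.full(len(sites), -1, dtype=int)
    frontiers: list[list[int]] = []
    for p, s in enumerate(seeds):
        claimed[s] = p
        frontiers.append(sorted(j for j in neighbours[s] if j != s))
    n_claimed = n_patches
    while n_claimed < n_ow:
        progress = False
        for p in range(n_patches):
            if n_claimed == n_ow:
                break
            frontier = [j for j in frontiers[p] if claimed[j] < 0]
            if not frontier:
                continue
            dists = sites.surface_distance(seeds[p], np.asarray(frontier))
            j = frontier[int(np.argmin(dists))]
            claimed[j] = p
            frontiers[p] = [x for x in frontier if x != j] + [
                x for x in neighbours[j] if claimed[x] < 0
            ]
            n_claimed += 1
            progress = True
        if not progress:  # all frontiers exhausted: claim nearest unclaimed
            for p in range(n_patches):
                if n_claimed == n_ow:
                    break
                free = np.flatnonzero(claimed < 0)
                if not len(free):
                    break
                dists = sites.surface_distance(seeds[p], free)
                claimed[free[int(np.argmin(dists))]] = p
                n_claimed += 1
    idx = np.flatnonzero(claimed >= 0)
    labels = claimed[idx]
    frame = sites.frame(iw, idx, angles[labels])
    if return_labels:
        return frame, labels, angles
    return frame


def simulate_assembly(
    iw: MoleculeFrame,
    tube: TubeSpec,
    lattice: LatticeSpec,
    params: AssemblySimParams,
    return_labels: bool = False,
):
    """Seeded stochastic outer-wall recovery trajectory.

    Returns ``n_steps + 1`` frames (initial inner-wall-only frame first).
    Site occupancy is non-decreasing; with a positive reorientation rate
    patches progressively snap to the preferred lattice orientation and
    merge into one global domain.

    With ``return_labels=True`` returns ``(frames, label_arrays)`` where
    each label array gives the patch label of the OW molecules of the
    corresponding frame (in frame order after the IW block).
    """
    rng = np.random.default_rng(params.seed)
    sites = OuterWallSites(tube, lattice)
    available = np.arange(len(sites))
    if params.n_sites is not None and params.n_sites < len(sites):
        available = np.sort(
            rng.choice(len(sites), size=params.n_sites, replace=False)
        )
    preferred = lattice.dipole_angle
    neighbour_cutoff = _neighbour_cutoff(sites, available)
    tree = cKDTree(sites.positions[available])

    occupied: list[int] = []          # indices into `available`
    label_of: dict[int, int] = {}     # available-index -> patch label
    angle_of: dict[int, float] = {}   # patch label -> in-surface angle
    aligned_label: int | None = None
    next_label = 0

    frames: list[MoleculeFrame] = []
    labels_out: list[np.ndarray] = []

    def emit() -> None:
        idx_sorted = np.sort(np.asarray(occupied, dtype=int))
        site_idx = available[idx_sorted]
        ang = np.array([angle_of[label_of[i]] for i in idx_sorted])
        frames.append(sites.frame(iw, site_idx, ang))
        labels_out.append(np.array([label_of[i] for i in idx_sorted], int))

    emit()
    occupied_mask = np.zeros(len(available), dtype=bool)
    for _ in range(params.n_steps):
        empty = np.flatnonzero(~occupied_mask)
        n_new = rng.binomial(len(empty), min(params.adsorption_rate, 1.0))
        new_sites = rng.choice(empty, size=n_new, replace=False) if n_new else []
        for i in new_sites:
            neigh = tree.query_ball_point(
                sites.positions[available[i]], neighbour_cutoff
            )
            neigh = [j for j in neigh if occupied_mask[j]]
            if neigh:
                dists = np.linalg.norm(
                    sites.positions[available[neigh]]
                    - sites.positions[available[i]],
                    axis=1,
                )
                label = label_of[neigh[int(np.argmin(dists))]]
            else:
                spread = params.nucleation_orientation_spread
                ang = preferred + rng.uniform(-spread, spread)
                label = next_label
                next_label += 1
                angle_of[label] = ang % (2.0 * np.pi)
            label_of[i] = label
            occupied_mask[i] = True
            occupied.append(i)
        # whole-patch reorientation toward the preferred orientation
        if params.patch_reorientation_rate > 0:
            sizes: dict[int, int] = {}
            for i in occupied:
                sizes[label_of[i]] = sizes.get(label_of[i], 0) + 1
            for label in sorted(sizes):
                if label == aligned_label:
                    continue
                p_snap = min(1.0, params.patch_reorientation_rate / sizes[label])
                if rng.random() < p_snap:
                    if aligned_label is None:
                        aligned_label = label
                        angle_of[label] = preferred
                    else:
                        for i in occupied:
                            if label_of[i] == label:
                                label_of[i] = aligned_label
                        del angle_of[label]
        emit()
    if return_labels:
        return frames, labels_out
    return frames


def _neighbour_cutoff(sites: OuterWallSites, available: np.ndarray) -> float:
    """Distance (Angstrom) that connects a site to its in-wall neighbours."""
    pos = sites.positions[available]
    k = min(5, len(pos))
    if k < 2:
        return sites.min_spacing * 1.5
    tree = cKDTree(pos)
    dists, _ = tree.query(pos, k=k)
    return 1.05 * float(np.median(dists[:, k - 1]))


def axial_order(frame: MoleculeFrame, wall: str | None = "OW") -> float:
    """Global axial alignment order parameter ``f = <(d . axis)^2>``.

    1 for perfectly axial dipoles, 1/3 for an isotropic 3-D distribution,
    1/2 for dipoles uniformly random within the tangent planes of a
    cylinder whose axis is the reference axis.
    """
    sub = frame if wall is None else frame.wall(wall)
    if len(sub) == 0:
        raise ValueError("no molecules selected")
    proj = sub.dipoles @ sub.axis
    return float(np.mean(proj**2))


def in_surface_angles(frame: MoleculeFrame, wall: str | None = "OW") -> np.ndarray:
    """In-surface dipole angle per molecule on a cylindrical wall.

    The angle is measured in the local tangent plane, from the
    circumferential direction toward the axis, in ``(-pi, pi]``.
    """
    sub = frame if wall is None else frame.wall(wall)
    axis = sub.axis
    radial = sub.positions - np.outer(sub.positions @ axis, axis)
    nrm = np.linalg.norm(radial, axis=1, keepdims=True)
    if np.any(nrm == 0):
        raise ValueError("molecule on the tube axis has no tangent frame")
    radial /= nrm
    tangent = np.cross(np.broadcast_to(axis, radial.shape), radial)
    return np.arctan2(sub.dipoles @ axis, np.einsum("ij,ij->i", sub.dipoles, tangent))


def patch_dispersion(angles: np.ndarray) -> float:
    """Orientational dispersion of one patch: ``1 - <cos(phi_i - phi_j)>``.

    Computed on the in-surface angle representation, i.e. the mean
    pairwise dot product of the unit vectors ``(cos phi, sin phi)``;
    0 when all molecules of the patch share one in-surface angle.
    """
    angles = np.asarray(angles, float)
    if len(angles) < 2:
        return 0.0
    c, s = np.cos(angles), np.sin(angles)
    n = len(angles)
    total = (c.sum() ** 2 + s.sum() ** 2 - n) / (n * (n - 1))
    return float(1.0 - total)
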