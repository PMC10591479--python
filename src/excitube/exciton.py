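"""Frenkel exciton model with diagonal disorder and extended-dipole couplings.

Each dye molecule is a two-level chromophore with transition frequency
``nu_n`` drawn from a Gaussian of mean ``nu0`` and width ``sigma_site``
(static diagonal disorder), shifted down by the gas-to-crystal shift
``delta`` in the aggregate.  The one-exciton Hamiltonian is

    H_nn = nu_n - delta,        H_nm = J_nm  (n != m),

where the resonant coupling ``J_nm`` is evaluated in the extended-dipole
approximation: each transition dipole of magnitude ``mu = q*l`` is split
into charges ``+q`` and ``-q`` placed ``l/2`` on either side of the
molecular position along the unit dipole vector, and ``J_nm`` is the
Coulomb sum over the four inter-molecular charge pairs,

    J_nm = alpha * (mu/l)^2 * sum_{s,s'} s s' / |r_n + s(l/2)d_n - r_m - s'(l/2)d_m|

with ``s, s' = +-1`` and ``alpha`` converting D^2/A^3 to wavenumbers.
Polarized absorption is the disorder average of the stick spectrum

    A(nu) = < sum_k |<g| e.mu |k>|^2 D(nu - nu_k) >,

with a zero-mean Gaussian lineshape ``D`` of width ``sigma_line``.
All frequencies are in cm^-1, distances in Angstrom, dipoles in Debye.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .frames import MoleculeFrame
from .geometry import _frame_from_axis

__all__ = [
    "ExcitonParams",
    "HamiltonianRealization",
    "Spectrum",
    "extended_dipole_coupling",
    "coupling_matrix",
    "build_hamiltonian",
    "stick_spectrum",
    "absorption_spectrum",
    "full_spectrum",
    "default_grid",
    "EANGSTROM_TO_DEBYE",
]

#: 1 e*Angstrom in Debye
EANGSTROM_TO_DEBYE = 4.8032

#: charge pairs closer than this (Angstrom) are treated as overlapping molecules
MIN_CHARGE_DISTANCE = 0.1

#: A_iso below this fraction of its maximum marks LD_r undefined (NaN)
LDR_FLOOR = 1e-6


@dataclasses.dataclass(frozen=True)
class ExcitonParams:
    """All parameters of the exciton model.

    Attributes
    ----------
    nu0 : monomer transition frequency, cm^-1.
    sigma_site : std of the Gaussian diagonal disorder, cm^-1.
    delta : gas-to-crystal red shift subtracted from site energies, cm^-1.
    q : extended-dipole charge magnitude, units of the elementary charge.
    l : charge separation, Angstrom.
    mu : transition-dipole magnitude in Debye; derived as ``q*l`` converted
        to Debye when not given (0.34 e x 7 A = 11.4 D).
    alpha : unit-conversion constant, cm^-1 A^3 D^-2.  The value 5.04e3
        makes ``alpha * D^2 / A^3`` a wavenumber (1 D^2/A^3 = 5.034e3
        cm^-1); couplings would be physically negligible with any smaller
        order of magnitude.
    sigma_line : Gaussian lineshape width, cm^-1.
    n_realizations : number of independent disorder realizations averaged.
    seed : default seed for the disorder sampling.
    """

    nu0: float = 19498.0
    sigma_site: float = 231.0
    delta: float = 350.0
    q: float = 0.34
    l: float = 7.0
    mu: float | None = None
    alpha: float = 5.04e3
    sigma_line: float = 75.0
    n_realizations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_line <= 0:
            raise ValueError("sigma_line must be > 0")
        if self.sigma_site < 0:
            raise ValueError("sigma_site must be >= 0")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.l <= 0:
            raise ValueError("l must be > 0")
        derived = self.q * self.l * EANGSTROM_TO_DEBYE
        if self.mu is None:
            object.__setattr__(self, "mu", derived)
        elif abs(self.mu - derived) > 0.005 * derived:
            raise ValueError(
                f"mu={self.mu} D inconsistent with q*l={derived:.3f} D (>0.5%)"
            )


@dataclasses.dataclass(frozen=True)
class HamiltonianRealization:
    """One disorder realization of the exciton Hamiltonian (cm^-1)."""

    matrix: np.ndarray
    site_frequencies: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        f = np.asarray(self.site_frequencies, float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(f):
            raise ValueError("matrix must be N x N with N site frequencies")
        if np.max(np.abs(m - m.T), initial=0.0) > 1e-9:
            raise ValueError("Hamiltonian must be symmetric")
        if not np.allclose(np.diag(m), f - self.delta, atol=1e-9):
            raise ValueError("diagonal must equal site_frequencies - delta")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "site_frequencies", f)


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """Polarized absorption on a common wavenumber grid.

    ``ld = a_par - a_perp``; ``a_iso = (a_par + 2*a_perp)/3`` (uniaxial
    alignment); ``ld_r = ld / a_iso`` with NaN where ``a_iso`` is below
    the numerical floor.
    """

    grid: np.ndarray
    a_par: np.ndarray
    a_perp: np.ndarray
    a_iso: np.ndarray
    ld: np.ndarray
    ld_r: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.grid, self.a_par, self.a_perp, self.a_iso, self.ld, self.ld_r]
        n = len(self.grid)
        if any(len(a) != n for a in arrays):
            raise ValueError("all spectrum columns must share one grid")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(self.a_par < -1e-12) or np.any(self.a_perp < -1e-12):
            raise ValueError("absorbances must be non-negative")

    @classmethod
    def from_polarized(
        cls, grid: np.ndarray, a_par: np.ndarray, a_perp: np.ndarray
    ) -> "Spectrum":
        a_iso = (a_par + 2.0 * a_perp) / 3.0
        ld = a_par - a_perp
        floor = LDR_FLOOR * np.max(a_iso, initial=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ld_r = np.where(a_iso > floor, ld / a_iso, np.nan)
        return cls(grid, a_par, a_perp, a_iso, ld, ld_r)

    def to_tsv(self, path) -> None:
        header = "grid\ta_par\ta_perp\ta_iso\tld\tld_r"
        data = np.column_stack(
            [self.grid, self.a_par, self.a_perp, self.a_iso, self.ld, self.ld_r]
        )
        np.savetxt(path, data, delimiter="\t", header=header, comments="")

    @classmethod
    def from_tsv(cls, path) -> "Spectrum":
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(*(data[:, i] for i in range(6)))

    def plot(self, ax=None):
        """Quick-look plot of the polarized components and reduced LD."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.a_par, label=r"$A_\parallel$")
        ax.plot(self.grid, self.a_perp, label=r"$A_\perp$")
        ax.plot(self.grid, self.a_iso, label=r"$A_{iso}$")
        ax.set_xlabel(r"wavenumber (cm$^{-1}$)")
        ax.set_ylabel("absorbance (arb. u.)")
        ax.legend()
        return ax


def default_grid(params: ExcitonParams, step: float = 2.0) -> np.ndarray:
    """Wavenumber grid covering [nu0 - 5000, nu0 + 2000] cm^-1."""
    return np.arange(params.nu0 - 5000.0, params.nu0 + 2000.0 + step, step)


def _charge_positions(
    positions: np.ndarray, dipoles: np.ndarray, l: float
) -> tuple[np.ndarray, np.ndarray]:
    half = 0.5 * l
    return positions + half * dipoles, positions - half * dipoles


def extended_dipole_coupling(r_n, d_n, r_m, d_m, params: ExcitonParams) -> float:
    """Excitonic coupling (cm^-1) between two molecules.

    Coulomb sum over the four charge pairs of the two extended dipoles;
    symmetric under exchange of the molecules.  Raises if any charge pair
    (nearly) coincides.
    """
    r_n, d_n = np.asarray(r_n, float), np.asarray(d_n, float)
    r_m, d_m = np.asarray(r_m, float), np.asarray(d_m, float)
    if np.linalg.norm(r_n - r_m) == 0:
        raise ValueError("molecules coincide")
    charge = params.mu / params.l  # D / Angstrom
    total = 0.0
    for s_n in (+1.0, -1.0):
        for s_m in (+1.0, -1.0):
            rr = (r_n + s_n * 0.5 * params.l * d_n) - (
                r_m + s_m * 0.5 * params.l * d_m
            )
            dist = float(np.linalg.norm(rr))
            if dist < MIN_CHARGE_DISTANCE:
                raise ValueError(
                    f"charge pair distance {dist:.3g} A below "
                    f"{MIN_CHARGE_DISTANCE} A: overlapping molecules"
                )
            total += s_n * s_m / dist
    return params.alpha * charge**2 * total


def coupling_matrix(frame: MoleculeFrame, params: ExcitonParams) -> np.ndarray:
    """Full N x N extended-dipole coupling matrix (cm^-1), zero diagonal."""
    plus, minus = _charge_positions(frame.positions, frame.dipoles, params.l)
    n = len(frame)
    total = np.zeros((n, n))
    eye = np.eye(n, dtype=bool)
    for a, sa in ((plus, +1.0), (minus, -1.0)):
        for b, sb in ((plus, +1.0), (minus, -1.0)):
            diff = a[:, None, :] - b[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            if np.any(dist[~eye] < MIN_CHARGE_DISTANCE):
                raise ValueError(
                    "overlapping molecules: inter-molecular charge distance "
                    f"below {MIN_CHARGE_DISTANCE} A"
                )
            np.fill_diagonal(dist, np.inf)
            total += sa * sb / dist
    charge = params.mu / params.l
    return params.alpha * charge**2 * total


def build_hamiltonian(
    frame: MoleculeFrame,
    params: ExcitonParams,
    rng: np.random.Generator | None = None,
    couplings: np.ndarray | None = None,
) -> HamiltonianRealization:
    """One disorder realization of the Hamiltonian for a frame.

    Site frequencies are sampled ``Normal(nu0, sigma_site)``; the
    diagonal is ``nu_n - delta`` and off-diagonal entries are the
    extended-dipole couplings (computed once and reusable via
    ``couplings``).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    if couplings is None:
        couplings = coupling_matrix(frame, params)
    freqs = rng.normal(params.nu0, params.sigma_site, size=len(frame))
    matrix = couplings.copy()
    np.fill_diagonal(matrix, freqs - params.delta)
    return HamiltonianRealization(matrix, freqs, params.delta)


def stick_spectrum(
    H: HamiltonianRealization,
    dipoles: np.ndarray,
    polarization: np.ndarray,
    mu: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenstate energies and oscillator strengths for one polarization.

    ``strength_k = |sum_n c_nk (mu * d_n . e)|^2``.  The strengths obey
    the sum rule ``sum_k strength_k = sum_n (mu * d_n . e)^2`` exactly
    (orthogonality of the eigenvectors).
    """
    energies, vectors = np.linalg.eigh(H.matrix)
    proj = mu * (np.asarray(dipoles, float) @ np.asarray(polarization, float))
    strengths = (vectors.T @ proj) ** 2
    return energies, strengths


def _deposit(accumulator: np.ndarray, grid: np.ndarray,
             energies: np.ndarray, weights: np.ndarray) -> None:
    """Linear-split deposition of sticks onto a uniform grid (in place)."""
    step = grid[1] - grid[0]
    x = (energies - grid[0]) / step
    inside = (x >= 0) & (x <= len(grid) - 1)
    x, w = x[inside], weights[inside]
    lo = np.floor(x).astype(int)
    frac = x - lo
    hi = np.minimum(lo + 1, len(grid) - 1)
    np.add.at(accumulator, lo, w * (1.0 - frac))
    np.add.at(accumulator, hi, w * frac)


def _gaussian_broaden(sticks: np.ndarray, grid: np.ndarray, sigma: float) -> np.ndarray:
    step = grid[1] - grid[0]
    half = int(np.ceil(6.0 * sigma / step))
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2.0 * np.pi))
    return np.convolve(sticks, kernel * step, mode="same") / step

def _polarized_sticks(
    frame: MoleculeFrame,
    params: ExcitonParams,
    grid: np.ndarray,
    pol_vectors: list[np.ndarray],
    rng: np.random.Generator,
    site_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Disorder-averaged stick accumulations, one per polarization.

    With ``site_mask`` the transition-dipole operator is restricted to
    the selected molecules (wall-projected spectrum); the Hamiltonian
    and its eigenstates still include every molecule.
    """
    steps = np.diff(grid)
    if np.any(np.abs(steps - steps[0]) > 1e-9 * steps[0]):
        raise ValueError("grid must be uniform")
    if steps[0] > params.sigma_line:
        warnings.warn(
            f"grid step {steps[0]:.1f} cm^-1 exceeds sigma_line "
            f"{params.sigma_line:.1f} cm^-1: lineshape under-resolved",
            stacklevel=2,
        )
    couplings = coupling_matrix(frame, params)
    projections = [
        params.mu * (frame.dipoles @ np.asarray(e, float)) for e in pol_vectors
    ]
    if site_mask is not None:
        site_mask = np.asarray(site_mask, bool)
        projections = [np.where(site_mask, proj, 0.0) for proj in projections]
    accumulators = [np.zeros(len(grid)) for _ in pol_vectors]
    for _ in range(params.n_realizations):
        H = build_hamiltonian(frame, params, rng, couplings)
        energies, vectors = np.linalg.eigh(H.matrix)
        for proj, acc in zip(projections, accumulators):
            strengths = (vectors.T @ proj) ** 2
            _deposit(acc, grid, energies, strengths)
    return [acc / params.n_realizations for acc in accumulators]


def absorption_spectrum(
    frame: MoleculeFrame,
    params: ExcitonParams,
    polarization: np.ndarray,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    site_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Disorder-averaged absorption for one polarization vector.

    Couplings are computed once per frame; each of ``n_realizations``
    samples independent site frequencies, and the averaged stick spectrum
    is convolved with the Gaussian lineshape of width ``sigma_line``.
    ``site_mask`` restricts the transition-dipole operator to a subset of
    molecules (e.g. one wall) while keeping the full coupled Hamiltonian.
    """
    grid = default_grid(params) if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(params.seed) if rng is None else rng
    sticks = _polarized_sticks(frame, params, grid, [polarization], rng,
                               site_mask)[0]
    return _gaussian_broaden(sticks, grid, params.sigma_line)


def perpendicular_vector(axis: np.ndarray) -> np.ndarray:
    """Fixed unit vector perpendicular to the alignment axis."""
    return _frame_from_axis(axis)[:, 0]


def full_spectrum(
    frame: MoleculeFrame,
    params: ExcitonParams,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    site_mask: np.ndarray | None = None,
) -> Spectrum:
    """Parallel/perpendicular/isotropic absorption, LD and reduced LD.

    ``A_par`` uses the tube axis as polarization; ``A_perp`` a fixed
    perpendicular direction (perfect flow alignment of the tube is
    assumed).  Both share the same disorder realizations, diagonalized
    once per realization.  ``site_mask`` restricts the transition-dipole
    operator to a subset of molecules while keeping the coupled
    Hamiltonian.
    """
    grid = default_grid(params) if grid is None else np.asarray(grid, float)
    rng = np.random.default_rng(params.seed) if rng is None else rng
    e_par = frame.axis
    e_perp = perpendicular_vector(frame.axis)
    sticks = _polarized_sticks(frame, params, grid, [e_par, e_perp], rng,
                               site_mask)
    a_par = _gaussian_broaden(sticks[0], grid, params.sigma_line)
    a_perp = _gaussian_broaden(sticks[1], grid, params.sigma_line)
    return Spectrum.from_polarized(grid, a_par, a_perp)
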