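"""Exciton Hamiltonian, couplings and disorder-averaged spectra."""

import numpy as np
import pytest

from excitube.assembly import generate_patchwork
from excitube.exciton import (
    EANGSTROM_TO_DEBYE,
    ExcitonParams,
    HamiltonianRealization,
    absorption_spectrum,
    build_hamiltonian,
    coupling_matrix,
    default_grid,
    extended_dipole_coupling,
    full_spectrum,
    stick_spectrum,
)
from excitube.frames import MoleculeFrame


PARAMS = ExcitonParams()


def test_transition_dipole_magnitude_is_11_4_debye():
    assert PARAMS.mu == pytest.approx(0.34 * 7.0 * EANGSTROM_TO_DEBYE)
    assert PARAMS.mu == pytest.approx(11.4, abs=0.05)
    with pytest.raises(ValueError, match="inconsistent"):
        ExcitonParams(mu=10.0)


class TestExtendedDipoleCoupling:
    def test_decays_to_zero_at_large_separation(self):
        j = extended_dipole_coupling(
            [0, 0, 0], [0, 0, 1], [1e6, 0, 0], [0, 0, 1], PARAMS
        )
        assert abs(j) < 1e-6

    def test_head_to_tail_matches_direct_coulomb_sum(self):
        # independent arithmetic: charges +-mu/l at x = +-3.5 and 10 +- 3.5
        j = extended_dipole_coupling(
            [0, 0, 0], [1, 0, 0], [10.0, 0, 0], [1, 0, 0], PARAMS
        )
        q = PARAMS.mu / PARAMS.l
        expected = PARAMS.alpha * q * q * (
            1.0 / 10.0 + 1.0 / 10.0 - 1.0 / 3.0 - 1.0 / 17.0
        )
        assert expected < 0
        assert j == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "d_n, d_m",
        [([0, 0, 1], [0, 0, 1]), ([1, 0, 0], [0, 0, 1]), ([0, 1, 0], [0, 1, 0])],
    )
    def test_point_dipole_limit_at_50l(self, d_n, d_m):
        r = 50.0 * PARAMS.l
        r_m = np.array([0.6, -0.3, 0.74]) / np.linalg.norm([0.6, -0.3, 0.74]) * r
        j = extended_dipole_coupling([0, 0, 0], d_n, r_m, d_m, PARAMS)
        rhat = r_m / r
        kappa = np.dot(d_n, d_m) - 3 * np.dot(d_n, rhat) * np.dot(d_m, rhat)
        j_point = PARAMS.alpha * PARAMS.mu**2 * kappa / r**3
        if abs(j_point) > 1e-12:
            assert j == pytest.approx(j_point, rel=0.01)

    def test_symmetric_under_exchange(self):
        rng = np.random.default_rng(3)
        r_n, r_m = rng.uniform(-20, 20, (2, 3))
        d_n, d_m = rng.normal(size=(2, 3))
        d_n, d_m = d_n / np.linalg.norm(d_n), d_m / np.linalg.norm(d_m)
        assert extended_dipole_coupling(r_n, d_n, r_m, d_m, PARAMS) == pytest.approx(
            extended_dipole_coupling(r_m, d_m, r_n, d_n, PARAMS), rel=1e-12
        )

    def test_overlapping_charges_raise(self):
        with pytest.raises(ValueError, match="overlap|coincide"):
            extended_dipole_coupling(
                [0, 0, 0], [0, 0, 1], [0, 0, 7.0], [0, 0, 1], PARAMS
            )


class TestHamiltonian:
    def test_single_molecule_zero_disorder_diagonal(self):
        frame = MoleculeFrame([[0, 0, 0]], [[0, 0, 1]], [0, 0, 1], 1.0, ["OW"])
        params = ExcitonParams(sigma_site=0.0)
        H = build_hamiltonian(frame, params)
        np.testing.assert_allclose(H.matrix, [[19498.0 - 350.0]])
        assert H.matrix[0, 0] == 19148.0

    def test_matrix_symmetric_and_offdiagonal_matches_pair_function(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-30, 30, (6, 3))
        dip = rng.normal(size=(6, 3))
        dip /= np.linalg.norm(dip, axis=1, keepdims=True)
        frame = MoleculeFrame(pos, dip, [0, 0, 1], 80.0, ["OW"] * 6)
        J = coupling_matrix(frame, PARAMS)
        np.testing.assert_allclose(J, J.T, atol=1e-9)
        assert np.all(np.diag(J) == 0)
        for n in range(6):
            for m in range(n + 1, 6):
                assert J[n, m] == pytest.approx(
                    extended_dipole_coupling(pos[n], dip[n], pos[m], dip[m], PARAMS),
                    rel=1e-10,
                )

    def test_sampled_diagonal_statistics(self):
        # 10^4 sampled site frequencies: 100 molecules x 100 realizations
        n_mol, n_real = 100, 100
        rng = np.random.default_rng(12)
        pos = np.column_stack(
            [np.arange(n_mol) * 20.0, np.zeros(n_mol), np.zeros(n_mol)]
        )
        dip = np.tile([0.0, 0.0, 1.0], (n_mol, 1))
        frame = MoleculeFrame(pos, dip, [0, 0, 1], n_mol * 20.0, ["OW"] * n_mol)
        samples = []
        last = None
        for _ in range(n_real):
            last = build_hamiltonian(frame, PARAMS, rng)
            samples.append(last.site_frequencies)
        samples = np.concatenate(samples)
        n = len(samples)
        assert n == 10_000
        assert abs(samples.mean() - 19498.0) < 3 * 231.0 / np.sqrt(n)
        assert samples.std() == pytest.approx(231.0, rel=0.05)
        np.testing.assert_allclose(
            np.diag(last.matrix), last.site_frequencies - 350.0, atol=1e-9
        )

    def test_overlapping_molecules_raise_geometry_error(self):
        frame = MoleculeFrame(
            [[0, 0, 0], [0, 0, 7.0]],
            [[0, 0, 1], [0, 0, 1]],
            [0, 0, 1],
            10.0,
            ["OW", "OW"],
        )
        with pytest.raises(ValueError, match="overlap"):
            coupling_matrix(frame, PARAMS)


class TestStickSpectrum:
    def test_perpendicular_polarization_gives_zero_strength(self):
        frame = MoleculeFrame([[0, 0, 0]], [[0, 0, 1]], [0, 0, 1], 1.0, ["OW"])
        H = build_hamiltonian(frame, ExcitonParams(sigma_site=0.0))
        _, strengths = stick_spectrum(H, frame.dipoles, [1, 0, 0], PARAMS.mu)
        np.testing.assert_allclose(strengths, 0.0, atol=1e-20)

    def test_symmetric_dimer_matches_closed_form(self):
        # two parallel dipoles along z at 12 A separation along x
        pos = np.array([[0, 0, 0], [12.0, 0, 0]])
        dip = np.tile([0.0, 0.0, 1.0], (2, 1))
        frame = MoleculeFrame(pos, dip, [0, 0, 1], 12.0, ["OW"] * 2)
        params = ExcitonParams(sigma_site=0.0)
        J = extended_dipole_coupling(pos[0], dip[0], pos[1], dip[1], params)
        H = build_hamiltonian(frame, params)
        energies, strengths = stick_spectrum(H, dip, [0, 0, 1], params.mu)
        e0 = 19498.0 - 350.0
        np.testing.assert_allclose(np.sort(energies), np.sort([e0 - J, e0 + J]),
                                   atol=1e-8)
        # symmetric state (in-phase) carries all strength: |(mu + mu)/sqrt 2|^2
        idx = np.argsort(energies)
        bright = energies[idx][1] if J > 0 else energies[idx][0]
        assert bright == pytest.approx(e0 + J)
        np.testing.assert_allclose(
            np.sort(strengths), np.sort([0.0, 2 * params.mu**2]), atol=1e-8
        )

    def test_sum_rule_per_polarization(self, iw_frame):
        params = ExcitonParams()
        rng = np.random.default_rng(9)
        H = build_hamiltonian(iw_frame, params, rng)
        for e in ([0, 0, 1], [1, 0, 0], [0.6, 0.8, 0.0]):
            _, strengths = stick_spectrum(H, iw_frame.dipoles, e, params.mu)
            expected = np.sum((params.mu * iw_frame.dipoles @ np.asarray(e)) ** 2)
            assert np.sum(strengths) == pytest.approx(expected, rel=1e-8)


class TestAbsorptionSpectrum:
    def test_monomer_band_peaks_near_nu0_minus_delta(self, monomer_frame):
        params = ExcitonParams(n_realizations=1000, seed=4)
        grid = default_grid(params)
        a = absorption_spectrum(monomer_frame, params, [0, 0, 1], grid)
        peak = grid[np.argmax(a)]
        assert abs(peak - 19148.0) < 60.0

    def test_no_disorder_monomer_is_pure_lineshape(self, monomer_frame):
        params = ExcitonParams(sigma_site=0.0, n_realizations=1, seed=0)
        grid = default_grid(params)
        a = absorption_spectrum(monomer_frame, params, [0, 0, 1], grid)
        centroid = np.sum(grid * a) / np.sum(a)
        width = np.sqrt(np.sum((grid - centroid) ** 2 * a) / np.sum(a))
        assert centroid == pytest.approx(19148.0, abs=0.5)
        assert width == pytest.approx(75.0, rel=2e-3)

    def test_monomer_ensemble_width_is_quadrature_sum(self, monomer_frame):
        params = ExcitonParams(n_realizations=2000, seed=8)
        grid = default_grid(params)
        a = absorption_spectrum(monomer_frame, params, [0, 0, 1], grid)
        centroid = np.sum(grid * a) / np.sum(a)
        width = np.sqrt(np.sum((grid - centroid) ** 2 * a) / np.sum(a))
        assert width == pytest.approx(np.hypot(231.0, 75.0), rel=0.05)

    def test_coarse_grid_warns(self, monomer_frame):
        params = ExcitonParams(n_realizations=1)
        grid = np.arange(14000.0, 22000.0, 100.0)
        with pytest.warns(UserWarning, match="under-resolved"):
            absorption_spectrum(monomer_frame, params, [0, 0, 1], grid)

    def test_fixed_seed_is_bit_identical(self, iw_frame):
        params = ExcitonParams(n_realizations=5, seed=42)
        a = absorption_spectrum(iw_frame, params, [0, 0, 1])
        b = absorption_spectrum(iw_frame, params, [0, 0, 1])
        assert np.array_equal(a, b)


class TestFullSpectrum:
    def test_axial_frame_has_ldr_3(self):
        rng = np.random.default_rng(0)
        pos = np.column_stack(
            [rng.uniform(-40, 40, 20), rng.uniform(-40, 40, 20), np.zeros(20)]
        )
        dip = np.tile([0.0, 0.0, 1.0], (20, 1))
        frame = MoleculeFrame(pos, dip, [0, 0, 1], 80.0, ["OW"] * 20)
        spec = full_spectrum(frame, ExcitonParams(n_realizations=10, seed=1))
        defined = ~np.isnan(spec.ld_r)
        assert np.any(defined)
        np.testing.assert_allclose(spec.ld_r[defined], 3.0, atol=1e-9)
        np.testing.assert_allclose(spec.a_perp, 0.0, atol=1e-15)

    def test_isotropic_dipoles_have_small_band_ldr(self):
        rng = np.random.default_rng(21)
        n = 500
        g = np.arange(8) * 15.0  # cubic grid, no close contacts
        pos = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T[:n]
        dip = rng.normal(size=(n, 3))
        dip /= np.linalg.norm(dip, axis=1, keepdims=True)
        frame = MoleculeFrame(pos, dip, [0, 0, 1], 120.0, ["OW"] * n)
        params = ExcitonParams(n_realizations=30, seed=2)
        spec = full_spectrum(frame, params)
        band = (spec.grid > 18000) & (spec.grid < 20500)
        ld_r = np.mean(spec.ld[band]) / np.mean(spec.a_iso[band])
        assert abs(ld_r) < 0.1

    def test_iso_is_weighted_average_of_polarizations(self, monomer_frame):
        spec = full_spectrum(monomer_frame, ExcitonParams(n_realizations=3, seed=0))
        np.testing.assert_allclose(
            spec.a_iso, (spec.a_par + 2 * spec.a_perp) / 3.0, atol=1e-15
        )
        np.testing.assert_allclose(spec.ld, spec.a_par - spec.a_perp, atol=1e-15)

    def test_rolled_wall_shows_red_shifted_parallel_peak(self, iw_frame):
        params = ExcitonParams(n_realizations=20, seed=6)
        spec = full_spectrum(iw_frame, params)
        peak = spec.grid[np.argmax(spec.a_par)]
        assert peak < 19148.0 - 500.0  # J-aggregate: well below the monomer band

    def test_interactions_between_separate_patches_are_weak(
        self, iw_frame, small_tube, lattice
    ):
        frame, labels, _ = generate_patchwork(iw_frame, small_tube, lattice,
                                              n_ow=40, n_patches=2, seed=2,
                                              return_labels=True)
        ow = frame.wall("OW")
        gap = np.linalg.norm(
            ow.positions[labels == 0][:, None] - ow.positions[labels == 1][None],
            axis=-1,
        ).min()
        assert gap > 50.0  # the two patches are genuinely separated
        params = ExcitonParams(sigma_site=0.0, n_realizations=1)
        grid = np.arange(14000.0, 21000.0, 4.0)
        joint = absorption_spectrum(ow, params, [0, 0, 1], grid)
        separate = np.sum(
            [
                absorption_spectrum(ow.select(labels == k), params, [0, 0, 1], grid)
                for k in np.unique(labels)
            ],
            axis=0,
        )
        diff = np.trapezoid(np.abs(joint - separate), grid)
        assert diff < 0.05 * np.trapezoid(joint, grid)


def test_hamiltonian_realization_validation():
    with pytest.raises(ValueError, match="symmetric"):
        HamiltonianRealization(np.array([[1.0, 2.0], [0.0, 1.0]]),
                               np.array([1.0, 1.0]) + 350.0, 350.0)
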