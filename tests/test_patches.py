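"""Patch identification: feature regularization and DBSCAN clustering.

The brute-force oracle exploits that with ``min_points = 2`` every point
with at least one neighbour within ``eps`` is a core point, so the
clustering is exactly the connected components of the eps-neighbourhood
graph, with isolated points as noise.
"""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from excitube.assembly import generate_patchwork, simulate_assembly, AssemblySimParams
from excitube.frames import MoleculeFrame
from excitube.patches import (
    PatchFeatures,
    identify_patches,
    patch_timeseries,
    regularize,
)


def brute_force_partition(features: np.ndarray, eps: float):
    """Connected components of the eps-graph; singletons labelled -1."""
    d = np.linalg.norm(features[:, None] - features[None], axis=-1)
    adj = (d <= eps) & ~np.eye(len(features), dtype=bool)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    labels = np.full(len(features), -1)
    next_label = {}
    for i, c in enumerate(comp):
        if adj[i].any():  # not isolated
            if c not in next_label:
                next_label[c] = len(next_label)
            labels[i] = next_label[c]
    return labels


def _random_features(n, seed, spread=0.6):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-spread, spread, (n, 3))
    dip = rng.normal(size=(n, 3))
    dip /= np.linalg.norm(dip, axis=1, keepdims=True)
    dip[dip[:, 2] < 0] *= -1
    return PatchFeatures(np.hstack([pos, dip]), np.array([0.0, 0.0, 1.0]))


class TestRegularize:
    def test_positions_scaled_by_box_dimension(self):
        frame = MoleculeFrame(
            [[0, 0, 0], [100.0, 0, 0]],
            [[0, 0, 1], [0, 0, 1]],
            [0, 0, 1],
            200.0,
            ["OW", "OW"],
        )
        features = regularize(frame)
        # extent 100, box 200: scaled coordinates span 0.5
        assert np.ptp(features.matrix[:, 0]) == pytest.approx(0.5)

    def test_dipoles_mapped_to_axial_hemisphere(self):
        frame = MoleculeFrame(
            [[0, 0, 0], [30.0, 0, 0]],
            [[0, 0, -1], [0, 0, 1]],
            [0, 0, 1],
            30.0,
            ["OW", "OW"],
        )
        features = regularize(frame)
        np.testing.assert_allclose(features.matrix[:, 3:],
                                   [[0, 0, 1], [0, 0, 1]])

    def test_all_features_bounded(self, iw_frame):
        features = regularize(iw_frame)
        assert np.all(features.matrix >= -1.0 - 1e-9)
        assert np.all(features.matrix <= 1.0 + 1e-9)


class TestIdentifyPatches:
    def test_two_separated_groups_with_orthogonal_orientations(self):
        rng = np.random.default_rng(1)
        pos_a = rng.uniform(-0.05, 0.05, (20, 3)) + [-0.5, 0, 0]
        pos_b = rng.uniform(-0.05, 0.05, (20, 3)) + [0.5, 0, 0]
        dip_a = np.tile([0.0, 0.0, 1.0], (20, 1))
        dip_b = np.tile([1.0, 0.0, 0.0], (20, 1))
        features = PatchFeatures(
            np.vstack([np.hstack([pos_a, dip_a]), np.hstack([pos_b, dip_b])]),
            np.array([0.0, 0.0, 1.0]),
        )
        result = identify_patches(features)
        assert result.n_patches == 2
        assert sorted(result.sizes) == [20, 20]
        assert result.noise_count == 0

    def test_isolated_molecule_is_noise(self):
        features = PatchFeatures(
            np.array([[0.9, 0.9, 0.9, 0, 0, 1.0],
                      [-0.5, 0, 0, 0, 0, 1.0],
                      [-0.5, 0.05, 0, 0, 0, 1.0]]),
            np.array([0.0, 0.0, 1.0]),
        )
        result = identify_patches(features)
        assert result.labels[0] == -1
        assert result.n_patches == 1

    def test_colocated_co_oriented_molecules_form_one_patch(self):
        n = 17
        features = PatchFeatures(
            np.hstack([np.zeros((n, 3)), np.tile([0, 0, 1.0], (n, 1))]),
            np.array([0.0, 0.0, 1.0]),
        )
        result = identify_patches(features)
        assert result.n_patches == 1
        assert result.sizes[0] == n

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("n", [20, 80, 200])
    def test_matches_brute_force_oracle(self, n, seed):
        features = _random_features(n, seed)
        result = identify_patches(features)
        oracle = brute_force_partition(features.matrix, eps=0.2)
        # identical partitions (label values may differ only by renaming)
        assert (result.labels == -1).tolist() == (oracle == -1).tolist()
        for k in np.unique(oracle[oracle >= 0]):
            members = np.flatnonzero(oracle == k)
            assert len(set(result.labels[members])) == 1

    def test_partition_invariant_under_permutation(self):
        features = _random_features(120, seed=3)
        result = identify_patches(features)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(features))
        permuted = PatchFeatures(features.matrix[perm], features.axis)
        result_p = identify_patches(permuted)

        def partition(labels):
            groups = {}
            for i, lab in enumerate(labels):
                if lab >= 0:
                    groups.setdefault(lab, set()).add(i)
            return {frozenset(g) for g in groups.values()}

        original = partition(result.labels)
        mapped = {
            frozenset(perm[list(g)].tolist()) for g in partition(result_p.labels)
        }
        assert original == mapped

    def test_group_count_nonincreasing_in_eps(self):
        # growing eps only adds edges to the neighbourhood graph, so the
        # number of connected groups (patches + isolated molecules) can
        # only drop; the patch count alone may transiently rise as noise
        # points first acquire neighbours
        features = _random_features(150, seed=7)
        groups = []
        for e in (0.05, 0.1, 0.2, 0.4, 0.8):
            result = identify_patches(features, eps=e)
            groups.append(result.n_patches + result.noise_count)
        assert groups == sorted(groups, reverse=True)

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError, match="eps"):
            identify_patches(_random_features(5, 0), eps=0.0)


class TestPatchTimeseries:
    def test_constructed_five_patch_frame_recovered(
        self, iw_frame, small_tube, lattice
    ):
        frame, labels, _ = generate_patchwork(
            iw_frame, small_tube, lattice, 50, 5, seed=17, return_labels=True
        )
        result = identify_patches(regularize(frame, "OW"))
        assert result.n_patches == 5
        assert sorted(result.sizes) == sorted(np.bincount(labels).tolist())

    def test_empty_outer_wall_reports_zero_patches(self, iw_frame):
        df = patch_timeseries([iw_frame], wall="OW")
        assert df.loc[0, "n_patches"] == 0

    def test_fast_reorientation_ends_in_single_patch(
        self, iw_frame, small_tube, lattice
    ):
        params = AssemblySimParams(
            adsorption_rate=0.1, patch_reorientation_rate=5.0, n_steps=80, seed=6
        )
        frames = simulate_assembly(iw_frame, small_tube, lattice, params)
        df = patch_timeseries(frames[::20])
        assert df["n_patches"].iloc[-1] == 1
        assert df["largest_fraction"].iloc[-1] == pytest.approx(1.0)
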