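"""Kernel construction, normalization, transition matrices, spectra, DCs."""

import numpy as np
import pytest

from dmapcv import dmap
from dmapcv.coordinates import pairwise_feature_distances
from dmapcv.dmap import (
    KernelConfig,
    alpha_normalize,
    build_diffusion_map,
    build_kernel,
    diffusion_coordinates,
    diffusion_distance,
    generator,
    local_scales,
    spectral_decompose,
    transition_matrix,
)


class TestLocalScales:
    def test_collinear_points_hand_enumeration(self):
        # 4 points on a line at spacing 1, r=0.5 -> k=2: endpoints see their
        # 2nd-nearest neighbor at distance 2, interior points at distance 1
        X = np.arange(4.0)[:, None]
        D = pairwise_feature_distances(X)
        np.testing.assert_allclose(local_scales(D, 0.5), [2.0, 1.0, 1.0, 2.0])

    def test_small_r_gives_nearest_neighbor(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 2))
        D = pairwise_feature_distances(X)
        eps = local_scales(D, 1e-4)  # k = 1
        nn = np.array([np.min(np.delete(D[i], i)) for i in range(200)])
        np.testing.assert_allclose(eps, nn)

    def test_duplicates_floored_with_warning(self):
        X = np.zeros((5, 2))
        D = pairwise_feature_distances(X)
        with pytest.warns(RuntimeWarning, match="floor"):
            eps = local_scales(D, 0.3)
        assert np.all(eps > 0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            local_scales(np.zeros((1, 1)), 0.5)


class TestBuildKernel:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 2))
        for kind in ("constant", "alpha_normalized", "locally_scaled"):
            A, _, _ = build_kernel(X, KernelConfig(kind=kind, epsilon=1.0, r=0.2))
            np.testing.assert_allclose(np.diag(A), 1.0)
            np.testing.assert_allclose(A, A.T)
            assert np.all(A >= 0)

    def test_constant_kernel_two_points(self):
        X = np.array([[0.0], [1.0]])
        A, _, eps = build_kernel(X, KernelConfig(kind="constant", epsilon=1.0))
        np.testing.assert_allclose(A[0, 1], np.exp(-1.0))
        assert eps == 1.0

    def test_local_scaling_brightens_sparse_cluster(self):
        # dense cluster (spacing ~0.05) and sparse cluster (spacing ~1):
        # with a constant bandwidth tuned to the dense cluster, the sparse
        # cluster's within-cluster kernel values nearly vanish; local scales
        # restore them
        rng = np.random.default_rng(2)
        dense = 0.05 * rng.standard_normal((10, 2))
        sparse = np.array([10.0, 0.0]) + 1.0 * rng.standard_normal((10, 2))
        X = np.vstack([dense, sparse])
        eps_dense = np.median(pairwise_feature_distances(dense) ** 2)
        Ac, _, _ = build_kernel(X, KernelConfig(kind="constant", epsilon=eps_dense))
        Al, _, _ = build_kernel(X, KernelConfig(kind="locally_scaled", r=0.2))
        iu = np.triu_indices(10, k=1)
        sparse_block_const = Ac[10:, 10:][iu]
        sparse_block_local = Al[10:, 10:][iu]
        assert np.median(sparse_block_local) > 10 * np.median(sparse_block_const)

    def test_locally_scaled_equals_constant_when_scales_equal(self):
        # equilateral triangle: every k=1 neighbor distance equals the side,
        # so eps_i eps_j = side^2 reproduces the constant kernel exactly
        side = 1.3
        X = side * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        Al, eps_l, _ = build_kernel(X, KernelConfig(kind="locally_scaled", r=0.4))
        Ac, _, _ = build_kernel(X, KernelConfig(kind="constant", epsilon=side**2))
        np.testing.assert_allclose(eps_l, side)
        np.testing.assert_allclose(Al, Ac, atol=1e-14)

    def test_energy_kernel_requires_energies(self):
        X = np.random.default_rng(0).standard_normal((10, 1))
        with pytest.raises(ValueError, match="energies"):
            build_kernel(X, KernelConfig(kind="energy_based", epsilon=1.0))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KernelConfig(kind="bogus")
        with pytest.raises(ValueError):
            KernelConfig(kind="locally_scaled", r=1.5)
        with pytest.raises(ValueError):
            KernelConfig(alpha=2.0)
        with pytest.raises(ValueError):
            KernelConfig(epsilon=-1.0)


class TestNormalization:
    def test_alpha_zero_identity(self):
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_allclose(alpha_normalize(K, 0.0), K)

    def test_alpha_one_on_constant_matrix_uniform(self):
        K = np.full((4, 4), 0.7)
        A = alpha_normalize(K, 1.0)
        assert np.ptp(A) == pytest.approx(0.0, abs=1e-15)

    def test_alpha_half_hand_matrix(self):
        K = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        p = K.sum(axis=1)
        expected = K / np.sqrt(np.outer(p, p))
        np.testing.assert_allclose(alpha_normalize(K, 0.5), expected)

    def test_transition_matrix_rows_and_uniform_case(self):
        K = np.full((5, 5), 2.0)
        P = transition_matrix(K)
        np.testing.assert_allclose(P, 1.0 / 5)
        K2 = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        P2 = transition_matrix(K2)
        np.testing.assert_allclose(P2.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(P2, K2 / K2.sum(axis=1)[:, None])

    def test_zero_row_sum_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.zeros((3, 3)))


class TestGeneratorAndSpectrum:
    def test_generator_rows_and_null_mode(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 2))
        model = build_diffusion_map(X, KernelConfig(kind="alpha_normalized", epsilon=1.0))
        L = model.generator_matrix()
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-10)
        gev = model.generator_eigenvalues
        assert abs(gev[0]) < 1e-8
        psi0 = model.eigenvectors[:, 0]
        assert np.ptp(psi0) < 1e-8 * np.abs(psi0).max()

    def test_generator_requires_positive_scale(self):
        with pytest.raises(ValueError):
            generator(np.eye(3), 0.0)

    def test_eigenvalues_within_stochastic_bounds(self, local_dmap_2d):
        assert np.all(local_dmap_2d.eigenvalues <= 1.0 + 1e-10)
        assert np.all(local_dmap_2d.eigenvalues >= -1.0 - 1e-10)
        assert local_dmap_2d.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_cluster_second_eigenvector_splits(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [0.1 * rng.standard_normal((15, 1)), 5.0 + 0.1 * rng.standard_normal((15, 1))]
        )
        model = build_diffusion_map(X, KernelConfig(kind="constant", epsilon=0.5), n_modes=3)
        psi2 = model.eigenvectors[:, 1]
        assert np.all(np.sign(psi2[:15]) == -np.sign(psi2[15:]))

    def test_ou_generator_eigenvalue_recovery(self, ou_dmap, ou_system):
        """Leading nontrivial generator eigenvalue ~ -k for OU samples."""
        lam2 = ou_dmap.generator_eigenvalues[1]
        k = ou_system.params["k"]
        assert abs(lam2 + k) / k < 0.2

    def test_ou_dmap_matches_fd_oracle(self, ou_dmap, ou_system):
        """Diffusion-map spectrum agrees with the grid discretization oracle."""
        from dmapcv import synthetic

        _, fd_vals, _ = synthetic.fd_generator_1d(ou_system, np.linspace(-3, 3, 400))
        assert abs(ou_dmap.generator_eigenvalues[1] - fd_vals[1]) / abs(fd_vals[1]) < 0.2

    def test_n_modes_capped(self):
        X = np.random.default_rng(5).standard_normal((6, 1))
        with pytest.raises(ValueError):
            A, _, _ = build_kernel(X, KernelConfig(kind="constant", epsilon=1.0))
            spectral_decompose(A, 10)


class TestDiffusionCoordinates:
    def test_identical_snapshots_identical_dcs(self):
        X = np.array([[0.0], [0.0], [1.0], [2.0]])
        model = build_diffusion_map(X, KernelConfig(kind="constant", epsilon=2.0), n_modes=3)
        np.testing.assert_allclose(model.dcs[0], model.dcs[1], atol=1e-9)

    def test_truncated_distance_within_gap_bound(self, local_dmap_2d):
        # discarding modes past k changes squared diffusion distances by at
        # most |lam_{k+1}|^{2t} * sum of discarded eigenvector differences
        model = local_dmap_2d
        vals, vecs = model.eigenvalues, model.eigenvectors
        dcs_full, _ = diffusion_coordinates(vals, vecs, t=1.0)
        k = 1
        i, j = 10, 500
        full = diffusion_distance(dcs_full[i], dcs_full[j])
        trunc = diffusion_distance(dcs_full[i, :k], dcs_full[j, :k])
        dpsi2 = ((vecs[i, k + 1 :] - vecs[j, k + 1 :]) ** 2).sum()
        bound = vals[k + 1] ** 2 * dpsi2
        assert trunc <= full + 1e-12
        assert full**2 - trunc**2 <= bound + 1e-12

    def test_distance_direct_sum_oracle(self):
        # 5-point fixture: diffusion distance equals the eigenvalue-weighted
        # eigenvector sum computed directly
        X = np.array([[0.0], [0.3], [1.1], [2.0], [2.2]])
        model = build_diffusion_map(X, KernelConfig(kind="constant", epsilon=1.0), n_modes=5)
        lam, psi = model.eigenvalues, model.eigenvectors
        direct = np.sqrt(sum(lam[j] ** 2 * (psi[0, j] - psi[3, j]) ** 2 for j in range(1, 5)))
        dcs, _ = diffusion_coordinates(lam, psi, t=1.0)
        assert diffusion_distance(dcs[0], dcs[3]) == pytest.approx(direct, abs=1e-12)

    def test_triangle_inequality_random_triples(self):
        rng = np.random.default_rng(6)
        dcs = rng.standard_normal((30, 4))
        for _ in range(50):
            i, j, k = rng.integers(0, 30, 3)
            assert diffusion_distance(dcs[i], dcs[j]) <= (
                diffusion_distance(dcs[i], dcs[k]) + diffusion_distance(dcs[k], dcs[j]) + 1e-12
            )

    def test_label_convention(self, local_dmap_2d):
        assert local_dmap_2d.dc_labels[:2] == ["DC2", "DC3"]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            diffusion_coordinates(np.array([1.0, 0.5]), np.ones((4, 2)), k=5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            diffusion_distance(np.zeros(3), np.zeros(4))


class TestModelCap:
    def test_sample_cap_enforced(self, monkeypatch):
        monkeypatch.setattr(dmap, "MAX_SAMPLES", 50)
        X = np.random.default_rng(7).standard_normal((51, 1))
        with pytest.raises(ValueError, match="cap"):
            build_kernel(X, KernelConfig(kind="constant", epsilon=1.0))


class TestSerialization:
    def test_spectral_archive_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 2))
        model = build_diffusion_map(X, KernelConfig(kind="locally_scaled", r=0.1), n_modes=4)
        path = tmp_path / "model.npz"
        model.save(path)
        back = dmap.DiffusionMapModel.load_spectral(path)
        np.testing.assert_array_equal(back["eigenvalues"], model.eigenvalues)
        np.testing.assert_array_equal(back["eigenvectors"], model.eigenvectors)
        np.testing.assert_array_equal(back["dcs"], model.dcs)
        np.testing.assert_array_equal(back["local_scales"], model.local_scales)
        assert back["dc_labels"] == model.dc_labels
        assert back["config"] == model.config
        assert float(back["epsilon_effective"]) == model.epsilon_effective
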