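"""Relationship kernels against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import genoconnect as gc
from genoconnect.kernels import KernelMatrix

from conftest import random_genotypes


def pedigree_from_rows(rows):
    return gc.Pedigree(pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "generation"]))


class TestNumeratorRelationship:
    def test_founders_identity(self):
        ped = pedigree_from_rows([(i, 0, 0, 1 + i % 2, 0) for i in range(1, 6)])
        A = gc.numerator_relationship(ped)
        np.testing.assert_allclose(A.values, np.eye(5))

    def test_classic_relationships(self):
        # 1 x 2 -> 3, 4 (full sibs); 3 x 5 would need sexes; use 3 x 4 mating
        ped = pedigree_from_rows([
            (1, 0, 0, 1, 0), (2, 0, 0, 2, 0),
            (3, 1, 2, 1, 1), (4, 1, 2, 2, 1),
            (5, 3, 4, 1, 2),       # offspring of full sibs, inbred
        ])
        A = gc.numerator_relationship(ped)
        ix = {i: k for k, i in enumerate(A.ids)}
        assert A.values[ix[1], ix[3]] == pytest.approx(0.5)   # parent-offspring
        assert A.values[ix[3], ix[4]] == pytest.approx(0.5)   # full sibs
        assert A.values[ix[5], ix[5]] == pytest.approx(1.25)  # F = 0.25

    def test_unsorted_pedigree_handled(self):
        rows = [(3, 1, 2, 1, 1), (1, 0, 0, 1, 0), (2, 0, 0, 2, 0)]
        A = gc.numerator_relationship(pedigree_from_rows(rows))
        sub = A.subset([1, 3])
        assert sub.values[0, 1] == pytest.approx(0.5)

    def test_cyclic_pedigree_raises(self):
        rows = [(1, 2, 3, 1, 0), (2, 1, 3, 1, 0), (3, 0, 0, 2, 0)]
        with pytest.raises(ValueError, match="cycl"):
            gc.numerator_relationship(pedigree_from_rows(rows))


class TestAdditiveKernel:
    def test_single_snp_closed_form(self):
        geno = gc.GenotypeMatrix(np.array([[0], [1], [2]], np.uint8),
                                 np.arange(3))
        G = gc.additive_kernel(geno)
        np.testing.assert_allclose(
            G.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]])

    def test_entries_sum_to_zero(self):
        G = gc.additive_kernel(random_genotypes(15, 40, seed=1))
        assert G.values.sum() == pytest.approx(0.0, abs=1e-9)

    def test_brute_force_oracle(self):
        geno = random_genotypes(10, 50, seed=2)
        G = gc.additive_kernel(geno)
        p = geno.allele_freqs
        den = 2 * np.sum(p * (1 - p))
        expected = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                expected[i, j] = sum(
                    (geno.dosages[i, k] - 2 * p[k])
                    * (geno.dosages[j, k] - 2 * p[k])
                    for k in range(50)) / den
        np.testing.assert_allclose(G.values, expected, atol=1e-10)

    def test_column_order_invariance(self):
        geno = random_genotypes(12, 30, seed=3)
        perm = np.random.default_rng(4).permutation(30)
        G1 = gc.additive_kernel(geno)
        G2 = gc.additive_kernel(geno.subset_loci(perm))
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-12)

    def test_monomorphic_only_raises(self):
        geno = gc.GenotypeMatrix(np.full((4, 3), 2, np.uint8), np.arange(4))
        with pytest.raises(ValueError, match="monomorphic"):
            gc.additive_kernel(geno)


class TestDominanceKernel:
    def test_single_snp_codes(self):
        geno = gc.GenotypeMatrix(np.array([[0], [1], [2]], np.uint8),
                                 np.arange(3))
        D = gc.dominance_kernel(geno)
        # codes (-0.5, 0.5, -0.5) at p = 0.5, denominator (2pq)^2 = 0.25
        expected = np.outer([-0.5, 0.5, -0.5], [-0.5, 0.5, -0.5]) / 0.25
        np.testing.assert_allclose(D.values, expected)

    def test_hardy_weinberg_column_mean_zero(self):
        # exact HWE counts at p = 0.6 over 100 individuals
        p = 0.6
        counts = np.array([16, 48, 36])   # q^2, 2pq, p^2 x 100
        dos = np.repeat([0, 1, 2], counts).astype(np.uint8)[:, None]
        q = 1 - p
        code = np.where(dos == 0, -2 * p ** 2,
                        np.where(dos == 1, 2 * p * q, -2 * q ** 2))
        assert code.mean() == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle(self):
        geno = random_genotypes(10, 50, seed=5)
        D = gc.dominance_kernel(geno)
        p = geno.allele_freqs
        q = 1 - p
        W = np.empty((10, 50))
        for i in range(10):
            for k in range(50):
                w = geno.dosages[i, k]
                W[i, k] = (-2 * p[k] ** 2 if w == 0
                           else 2 * p[k] * q[k] if w == 1 else -2 * q[k] ** 2)
        expected = W @ W.T / np.sum((2 * p * q) ** 2)
        np.testing.assert_allclose(D.values, expected, atol=1e-10)

    def test_column_order_invariance(self):
        geno = random_genotypes(12, 30, seed=6)
        perm = np.random.default_rng(7).permutation(30)
        D1 = gc.dominance_kernel(geno)
        D2 = gc.dominance_kernel(geno.subset_loci(perm))
        np.testing.assert_allclose(D1.values, D2.values, atol=1e-12)


class TestHadamardKernel:
    def test_ones_identity(self):
        geno = random_genotypes(8, 20, seed=8)
        G = gc.additive_kernel(geno)
        ones = KernelMatrix(np.ones((8, 8)), G.ids, "D")
        np.testing.assert_allclose(gc.hadamard_kernel(G, ones).values,
                                   G.values)

    def test_entrywise_product(self):
        rng = np.random.default_rng(9)
        ids = np.arange(5)
        A = rng.normal(size=(5, 5))
        A = KernelMatrix(A @ A.T, ids, "G")
        B = rng.normal(size=(5, 5))
        B = KernelMatrix(B @ B.T, ids, "D")
        H = gc.hadamard_kernel(A, B)
        for i in range(5):
            for j in range(5):
                assert H.values[i, j] == pytest.approx(
                    A.values[i, j] * B.values[i, j])

    def test_schur_product_stays_psd(self):
        rng = np.random.default_rng(10)
        ids = np.arange(12)
        for _ in range(5):
            M1 = rng.normal(size=(12, 6))
            M2 = rng.normal(size=(12, 6))
            H = gc.hadamard_kernel(KernelMatrix(M1 @ M1.T, ids, "G"),
                                   KernelMatrix(M2 @ M2.T, ids, "D"))
            assert H.min_eigenvalue() >= -1e-8

    def test_id_mismatch_raises(self):
        G = KernelMatrix(np.eye(3), np.arange(3), "G")
        D = KernelMatrix(np.eye(3), np.arange(3) + 1, "D")
        with pytest.raises(ValueError, match="identifiers"):
            gc.hadamard_kernel(G, D)


class TestGaussianKernel:
    def test_diagonal_is_one(self):
        geno = random_genotypes(10, 30, seed=11)
        for theta in (0.1, 1.0, 5.0):
            GK = gc.gaussian_kernel(geno, theta)
            np.testing.assert_allclose(np.diag(GK.values), 1.0)
            assert (GK.values > 0).all() and (GK.values <= 1).all()

    def test_raw_distance_closed_form(self):
        geno = gc.GenotypeMatrix(np.array([[0, 2], [1, 1]], np.uint8),
                                 np.arange(2))
        GK = gc.gaussian_kernel(geno, 0.5, scaling="raw")
        assert GK.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_global_and_local_limits(self):
        geno = random_genotypes(10, 30, seed=12)
        near_one = gc.gaussian_kernel(geno, 1e-8).values
        assert np.min(near_one) > 0.999
        local = gc.gaussian_kernel(geno, 1e4).values
        off = local[np.triu_indices(10, 1)]
        assert np.max(off) < 1e-6

    def test_offdiag_mean_decreasing_in_theta(self):
        geno = random_genotypes(15, 40, seed=13)
        thetas = [0.05, 0.2, 0.5, 1.0, 2.0, 4.0]
        means = []
        for t in thetas:
            K = gc.gaussian_kernel(geno, t).values
            means.append(K[np.triu_indices(15, 1)].mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_invalid_theta_raises(self):
        geno = random_genotypes(4, 10, seed=14)
        with pytest.raises(ValueError):
            gc.gaussian_kernel(geno, 0.0)

    def test_mean_scaling_matches_printed_theta_mapping(self):
        """With mean-scaled distances the grid theta = 0.22/0.5/0.9/1.6
        yields mean off-diagonals near 0.8/0.6/0.4/0.2."""
        geno = random_genotypes(200, 500, seed=15)
        for theta, target in [(0.22, 0.8), (0.5, 0.6), (0.9, 0.4), (1.6, 0.2)]:
            K = gc.gaussian_kernel(geno, theta).values
            mean_off = K[np.triu_indices(200, 1)].mean()
            assert mean_off == pytest.approx(target, abs=0.05)


class TestCalibrateTheta:
    @pytest.mark.parametrize("target", [0.8, 0.6, 0.4, 0.2])
    def test_target_reproduced(self, target):
        geno = random_genotypes(30, 60, seed=16)
        theta = gc.calibrate_theta(geno, target)
        K = gc.gaussian_kernel(geno, theta).values
        mean_off = K[np.triu_indices(30, 1)].mean()
        assert mean_off == pytest.approx(target, abs=2e-4)

    def test_agrees_with_grid_search(self):
        geno = random_genotypes(20, 40, seed=17)
        target = 0.5
        theta = gc.calibrate_theta(geno, target, tol=1e-6)
        grid = np.linspace(1e-4, 5.0, 50_001)
        d2 = gc.kernels._sq_distances(geno, "mean")
        off = d2[np.triu_indices(20, 1)]
        means = np.exp(-np.outer(grid, off)).mean(axis=1)
        best = grid[np.argmin(np.abs(means - target))]
        assert theta == pytest.approx(best, abs=1e-3)

    def test_small_theta_for_target_near_one(self):
        geno = random_genotypes(10, 30, seed=18)
        assert gc.calibrate_theta(geno, 0.999) < gc.calibrate_theta(geno, 0.5)

    def test_invalid_target_raises(self):
        geno = random_genotypes(5, 10, seed=19)
        with pytest.raises(ValueError):
            gc.calibrate_theta(geno, 1.2)


class TestAverageKernels:
    def test_table_weights(self):
        ids = np.arange(4)
        G = KernelMatrix(np.eye(4), ids, "G")
        D = KernelMatrix(2 * np.eye(4), ids, "D")
        K = gc.average_kernels([G, D], [0.3, 0.1])
        np.testing.assert_allclose(K.params["weights"], [0.75, 0.25])
        assert sum(K.params["weights"]) == pytest.approx(1.0)

    def test_single_kernel_unchanged(self):
        G = KernelMatrix(np.eye(3), np.arange(3), "G")
        assert gc.average_kernels([G], [0.5]) is G

    def test_explicit_weighted_sum(self):
        rng = np.random.default_rng(20)
        ids = np.arange(8)
        mats = [rng.normal(size=(8, 4)) for _ in range(3)]
        kernels = [KernelMatrix(m @ m.T, ids, k) for m, k in zip(mats, "GDX")]
        v = [0.5, 0.3, 0.2]
        K = gc.average_kernels(kernels, v)
        expected = sum(w * k.values for w, k in zip(v, kernels))
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_zero_variances_raise(self):
        G = KernelMatrix(np.eye(3), np.arange(3), "G")
        with pytest.raises(ValueError, match="zero"):
            gc.average_kernels([G, G], [0.0, 0.0])


class TestKernelMatrixContainer:
    def test_tsv_round_trip(self, tmp_path):
        geno = random_genotypes(6, 20, seed=21)
        G = gc.additive_kernel(geno)
        path = tmp_path / "g.tsv"
        G.write_tsv(path)
        back = KernelMatrix.read_tsv(path)
        np.testing.assert_allclose(back.values, G.values, atol=1e-12)
        np.testing.assert_array_equal(back.ids, G.ids)
        assert back.kind == "G"

    def test_hdf5_round_trip(self, tmp_path):
        geno = random_genotypes(6, 20, seed=22)
        G = gc.gaussian_kernel(geno, 0.7)
        path = tmp_path / "k.h5"
        G.write_hdf5(path)
        back = KernelMatrix.read_hdf5(path)
        np.testing.assert_allclose(back.values, G.values)
        np.testing.assert_array_equal(back.ids, G.ids)
        assert back.params["theta"] == pytest.approx(0.7)

    def test_psd_jitter_logged(self, caplog):
        vals = np.array([[1.0, 1.1], [1.1, 1.0]])   # indefinite
        K = KernelMatrix(vals, np.arange(2), "G")
        with caplog.at_level("WARNING"):
            fixed = K.ensure_psd()
        assert "jitter" in caplog.text
        assert fixed.params["jitter"] == pytest.approx(1e-6)
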