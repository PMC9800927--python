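import numpy as np
import pytest

import clonegs as cg
from clonegs.genotypes import GenotypeMatrix, build_designs, from_dosages
from clonegs.kinship import (KinshipError, RelationshipMatrix, additive_G,
                             condition_psd, dominance_classical,
                             dominance_genotypic, gaussian_kernel)


def hwe_matrix(n, m, seed=0, p=None):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m) if p is None else np.asarray(p)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    # small n can fix an allele by chance; force every marker polymorphic
    mono = (dos.min(axis=0) == dos.max(axis=0))
    dos[0, mono] = np.where(dos[0, mono] > 0, dos[0, mono] - 1,
                            dos[0, mono] + 1)
    return from_dosages([f"c{i}" for i in range(n)],
                        [f"m{j}" for j in range(m)], dos, orient_major=False)


class TestAdditive:
    def test_single_marker_hand_value(self):
        # p=0.5, clone MM, centered Z = 2 - 2*0.5 = 1 -> diag 1/(2*0.25) = 2
        g = GenotypeMatrix(np.array(["mm_clone", "x"]), np.array(["m", "m2"]),
                          np.array([[2.0, 1.0], [0.0, 1.0]]),
                          np.array([0.5, 0.5]))
        G = additive_G(build_designs(g))
        # contribution of marker 1 alone would be 1/0.5 = 2; marker 2 adds 0
        assert G.values[0, 0] == pytest.approx(1.0**2 / (2 * (0.25 + 0.25)))

    def test_duplicate_clones_share_row(self):
        g = hwe_matrix(6, 40, seed=1)
        dos = g.dosages.copy()
        dos[1] = dos[0]
        g2 = from_dosages(g.clone_ids, g.marker_ids, dos, orient_major=False)
        G = additive_G(build_designs(g2))
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])
        assert G.values[1, 1] == pytest.approx(G.values[0, 0])

    def test_hwe_mean_diagonal_near_one(self):
        G = additive_G(build_designs(hwe_matrix(2000, 5000, seed=3)))
        assert 0.95 < G.values.diagonal().mean() < 1.05

    def test_orientation_flip_invariance(self):
        g = hwe_matrix(20, 30, seed=4)
        designs = build_designs(g)
        flipped = from_dosages(g.clone_ids, g.marker_ids, 2.0 - g.dosages,
                               orient_major=False)
        d2 = build_designs(flipped)
        np.testing.assert_allclose(additive_G(designs).values,
                                   additive_G(d2).values, atol=1e-10)

    def test_marker_order_invariance(self):
        g = hwe_matrix(15, 25, seed=5)
        perm = np.random.default_rng(0).permutation(25)
        g2 = GenotypeMatrix(g.clone_ids, g.marker_ids[perm],
                            g.dosages[:, perm], g.p[perm])
        np.testing.assert_allclose(additive_G(build_designs(g)).values,
                                   additive_G(build_designs(g2)).values,
                                   atol=1e-12)


class TestDominance:
    def test_all_het_single_half_marker(self):
        g = GenotypeMatrix(np.array(["a", "b"]), np.array(["m", "m2"]),
                          np.array([[1.0, 1.0], [1.0, 1.0]]),
                          np.array([0.5, 0.5]))
        D = dominance_classical(build_designs(g))
        # each marker: het entry 0.5, denominator sum (2pq)^2 = 0.5
        np.testing.assert_allclose(D.values, 1.0)

    def test_classical_equals_genotypic_at_half_frequency(self):
        g = hwe_matrix(30, 20, seed=6, p=np.full(20, 0.5))
        g = GenotypeMatrix(g.clone_ids, g.marker_ids, g.dosages,
                           np.full(20, 0.5))  # force exact p = 0.5
        d = build_designs(g)
        np.testing.assert_allclose(dominance_classical(d).values,
                                   dominance_genotypic(d).values, atol=1e-10)

    def test_hwe_mean_diagonal(self):
        D = dominance_classical(build_designs(hwe_matrix(2000, 5000, seed=8)))
        assert 0.9 < D.values.diagonal().mean() < 1.1

    def test_additive_dominance_orthogonality_surrogate(self):
        # Hadamard off-diagonals of G and D average ~0 on an HWE panel
        d = build_designs(hwe_matrix(800, 2000, seed=9))
        G, D = additive_G(d).values, dominance_classical(d).values
        off = ~np.eye(len(G), dtype=bool)
        assert abs((G * D)[off].mean()) < 5e-4


class TestKernel:
    def test_identical_clones_and_diagonal(self):
        g = hwe_matrix(8, 50, seed=10)
        dos = g.dosages.copy()
        dos[1] = dos[0]
        g2 = from_dosages(g.clone_ids, g.marker_ids, dos, orient_major=False)
        K = gaussian_kernel(g2)
        assert K.values[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(K.values.diagonal(), 1.0)
        assert np.all(K.values > 0) and np.all(K.values <= 1)

    def test_entry_at_median_distance(self):
        g = hwe_matrix(40, 60, seed=11)
        K = gaussian_kernel(g, h=1.0)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(g.dosages - 1, "sqeuclidean"))
        med = np.median(d[~np.eye(40, dtype=bool)])
        i, j = np.unravel_index(np.argmin(np.abs(d - med) + np.eye(40) * 1e9),
                                d.shape)
        assert K.values[i, j] == pytest.approx(np.exp(-d[i, j] / med))

    def test_small_bandwidth_limit_towards_ones(self):
        g = hwe_matrix(10, 30, seed=12)
        K = gaussian_kernel(g, h=1e-9)
        np.testing.assert_allclose(K.values, 1.0, atol=1e-6)

    def test_zero_distances_rejected(self):
        g = GenotypeMatrix(np.array(["a", "b"]), np.array(["m"]),
                           np.array([[1.0], [1.0]]), np.array([0.5]))
        with pytest.raises(KinshipError):
            gaussian_kernel(g)


class TestConditioning:
    def test_psd_unchanged(self):
        G = additive_G(build_designs(hwe_matrix(10, 100, seed=13)))
        out = condition_psd(G)
        assert not out.bending_applied or out.min_eigenvalue() >= -1e-8

    def test_rank_deficient_becomes_invertible(self):
        g = hwe_matrix(10, 4, seed=14)  # more clones than markers
        G = additive_G(build_designs(g))
        assert G.min_eigenvalue() < 1e-10
        out = condition_psd(G)
        assert out.bending_applied
        np.linalg.cholesky(out.values)  # must not raise

    def test_zero_epsilon_rejected_on_indefinite(self):
        g = hwe_matrix(10, 4, seed=15)
        G = additive_G(build_designs(g))
        with pytest.raises(KinshipError, match="epsilon"):
            condition_psd(G, epsilon=0.0)

    def test_permutation_equivariance(self):
        g = hwe_matrix(12, 50, seed=16)
        perm = np.random.default_rng(1).permutation(12)
        g2 = GenotypeMatrix(g.clone_ids[perm], g.marker_ids,
                            g.dosages[perm], g.p)
        for ctor in (lambda d: additive_G(d), lambda d: dominance_classical(d),
                     lambda d: dominance_genotypic(d)):
            A = ctor(build_designs(g)).values
            B = ctor(build_designs(g2)).values
            np.testing.assert_allclose(B, A[np.ix_(perm, perm)], atol=1e-10)
        A = gaussian_kernel(g).values
        B = gaussian_kernel(g2).values
        np.testing.assert_allclose(B, A[np.ix_(perm, perm)], atol=1e-10)
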