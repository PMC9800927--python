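import numpy as np
import pytest

from clonegs.genotypes import (GenotypeError, GenotypeMatrix, build_designs,
                               from_dosages, impute_mean, load_genotypes,
                               quality_filter)

TSV = """clone\tm1\tm2\tm3
A\t0\t1\t2
B\t1\t-1\t2
C\t2\t1\t1
"""

VCF = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC
1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\ts2\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t300\ts3\tC\tT\t.\tPASS\t.\tGT\t./.\t0/1\t1/1
"""


class TestLoading:
    def test_tsv_roundtrip(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text(TSV)
        g = load_genotypes(f, orient_major=False)
        assert g.n_clones == 3 and g.n_markers == 3
        # frequencies from non-missing calls only
        np.testing.assert_allclose(g.p, [0.5, 0.5, 5 / 6])
        assert g.missing_mask.sum() == 1

    def test_vcf_drops_multiallelic(self, tmp_path):
        f = tmp_path / "g.vcf"
        f.write_text(VCF)
        with pytest.warns(UserWarning, match="non-biallelic"):
            g = load_genotypes(f, orient_major=False)
        assert list(g.marker_ids) == ["s1", "s3"]
        np.testing.assert_allclose(g.dosages[:, 0], [0, 1, 2])
        assert g.dosages[0, 1] == -1  # ./. missing

    def test_out_of_domain_dosage_rejected(self):
        with pytest.raises(GenotypeError, match="dosage"):
            from_dosages(["a"], ["m"], [[3.0]])

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "dup.tsv"
        f.write_text("clone\tm1\nA\t0\nA\t1\n")
        with pytest.raises(GenotypeError, match="duplicate"):
            load_genotypes(f)

    def test_major_orientation(self):
        dos = np.array([[0.0], [0.0], [1.0]])  # coded-allele freq 1/6
        g = from_dosages(["a", "b", "c"], ["m"], dos)
        assert g.p[0] == pytest.approx(5 / 6)
        np.testing.assert_allclose(g.dosages[:, 0], [2, 2, 1])


class TestQualityFilter:
    def make(self, dosages, p=None):
        dosages = np.asarray(dosages, dtype=float)
        n, m = dosages.shape
        return from_dosages([f"c{i}" for i in range(n)],
                            [f"m{j}" for j in range(m)], dosages,
                            orient_major=False)

    def test_call_rate_filter(self):
        # marker 0: 1 of 10 missing (call rate 0.9 passes); marker 1: 2 of 10
        dos = np.ones((10, 2))
        dos[0, 0] = -1
        dos[0, 1] = dos[1, 1] = -1
        dos[2, :] = 0  # keep polymorphic
        g = self.make(dos)
        out = quality_filter(g, min_call_rate=0.90, min_maf=0.0)
        assert list(out.marker_ids) == ["m0"]

    def test_maf_exactly_at_threshold_removed(self):
        # 10 clones; one heterozygote -> MAF 0.05 exactly
        dos = np.zeros((10, 1))
        dos[0, 0] = 1
        g = self.make(dos)
        with pytest.raises(GenotypeError):  # the only marker is removed
            quality_filter(g, min_call_rate=0.0, min_maf=0.05)

    def test_no_failures_identity_and_idempotence(self, tiny_genotypes):
        once = quality_filter(tiny_genotypes, 0.9, 0.05)
        np.testing.assert_array_equal(once.dosages, tiny_genotypes.dosages)
        twice = quality_filter(once, 0.9, 0.05)
        np.testing.assert_array_equal(twice.dosages, once.dosages)
        np.testing.assert_array_equal(twice.marker_ids, once.marker_ids)


class TestImputation:
    @pytest.mark.parametrize("p, expected", [(0.5, 1.0), (0.9, 1.8)])
    def test_missing_becomes_2p(self, p, expected):
        g = GenotypeMatrix(np.array(["a", "b"]), np.array(["m"]),
                           np.array([[-1.0], [1.0]]), np.array([p]))
        out = impute_mean(g)
        assert out.dosages[0, 0] == pytest.approx(expected)
        assert out.imputed

    def test_no_missing_unchanged(self, tiny_genotypes):
        out = impute_mean(tiny_genotypes)
        np.testing.assert_array_equal(out.dosages, tiny_genotypes.dosages)


class TestDesigns:
    def test_classical_coding_at_half_frequency(self, half_freq_matrix):
        d = build_designs(impute_mean(half_freq_matrix))
        # p=q=0.5: (MM, Mm, mm) -> (-2q^2, 2pq, -2p^2) = (-0.5, 0.5, -0.5)
        np.testing.assert_allclose(d.H_classical[:, 0], [-0.5, 0.5, 0.5, -0.5])
        # genotypic coincides with classical at p=0.5
        np.testing.assert_allclose(d.H_genotypic, d.H_classical)

    def test_centered_additive_zero_column_means(self, tiny_genotypes):
        g = impute_mean(tiny_genotypes)
        d = build_designs(g, center_additive=True)
        # centered by the stored frequencies: complete data -> exact zeros
        np.testing.assert_allclose(d.Z_add.mean(axis=0), 0.0, atol=1e-10)

    def test_uncentered_additive_is_minus1_0_1(self, tiny_genotypes):
        d = build_designs(impute_mean(tiny_genotypes), center_additive=False)
        assert set(np.unique(d.Z_add)) <= {-1.0, 0.0, 1.0}

    def test_heterozygote_rows(self):
        g = GenotypeMatrix(np.array(["het"]), np.array(["m1", "m2"]),
                           np.array([[1.0, 1.0]]), np.array([0.5, 0.7]))
        d = build_designs(g)
        np.testing.assert_allclose(d.Z_add[0], [0.0, 1 - 2 * 0.7])
        np.testing.assert_allclose(d.H_classical[0], 2 * d.p * (1 - d.p))
        np.testing.assert_allclose(d.H_genotypic[0], d.p**2 + (1 - d.p) ** 2)

    def test_monomorphic_rejected(self):
        g = GenotypeMatrix(np.array(["a"]), np.array(["m"]),
                           np.array([[2.0]]), np.array([1.0]))
        with pytest.raises(GenotypeError, match="monomorphic"):
            build_designs(g)

    def test_dominance_zero_mean_under_hwe(self):
        # large HWE population: classical dominance columns average ~0
        rng = np.random.default_rng(7)
        p = np.array([0.3, 0.5, 0.8])
        n = 4000
        dos = rng.binomial(2, p, size=(n, 3)).astype(float)
        g = from_dosages([f"c{i}" for i in range(n)], ["a", "b", "c"], dos,
                         orient_major=False)
        d = build_designs(g)
        se = np.sqrt(np.var(d.H_classical, axis=0) / n)
        assert np.all(np.abs(d.H_classical.mean(axis=0)) < 3 * se + 1e-3)
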