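"""Quality-control filters, panel merging, IBS matrix and PCA outliers."""

import numpy as np
import pytest
from scipy import stats

from dcmscan.genio import MISSING, GenioError
from dcmscan.qc import (
    QcThresholds,
    filter_panel,
    hwe_chisq_pvalue,
    ibs_matrix,
    merge_panels,
    pca_from_ibs,
)

from conftest import build_panel


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_chisq_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_returns_one(self):
        assert hwe_chisq_pvalue(50, 0, 0) == 1.0
        assert hwe_chisq_pvalue(0, 0, 7) == 1.0

    def test_heterozygote_excess_matches_hand_chisq(self):
        # (10, 80, 10): p = 0.5, expected (25, 50, 25),
        # chi2 = 15^2/25 + 30^2/50 + 15^2/25 = 36
        assert hwe_chisq_pvalue(10, 80, 10) == pytest.approx(stats.chi2.sf(36.0, 1))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_chisq_pvalue(-1, 2, 3)


class TestFilterPanel:
    def _clean_panel(self, rng, n_samples=20, n_snps=10):
        f = rng.uniform(0.3, 0.7, n_snps)
        H = (rng.random((2 * n_samples, n_snps)) < f).astype(np.int8)
        return build_panel(H)

    def test_low_maf_snp_removed_and_tallied(self, rng):
        panel = self._clean_panel(rng)
        H = panel.H.copy()
        H[:, 4] = 0
        H[0, 4] = 1  # 1/40 alleles -> MAF 0.025
        panel = build_panel(H)
        out, rep = filter_panel(panel)
        assert rep.maf_removed == 1
        assert out.n_variants == panel.n_variants - 1
        assert "snp4" not in out.variants["id"].tolist()

    def test_hwe_violation_removed(self, rng):
        panel = self._clean_panel(rng, n_samples=40)
        H = panel.H.copy()
        H[0::2, 2] = 0
        H[1::2, 2] = 1  # all 40 samples heterozygous: chi2 = 40, p ~ 2.5e-10
        out, rep = filter_panel(build_panel(H))
        assert rep.hwe_removed == 1

    def test_sex_chrom_and_low_callrate_sample(self, rng):
        panel = self._clean_panel(rng)
        v = panel.variants.copy()
        v.loc[7, "chrom"] = "X"
        H = panel.H.copy()
        H[0:2, :6] = MISSING  # sample 0 call rate 4/10 at autosomes
        panel = build_panel(H)
        panel.variants = v
        out, rep = filter_panel(panel)
        assert rep.sex_unplaced_removed == 1
        assert rep.sample_call_rate_removed == 1
        assert out.n_samples == panel.n_samples - 1

    def test_clean_panel_is_identity_and_idempotent(self, rng):
        panel = self._clean_panel(rng)
        out, rep = filter_panel(panel)
        assert out.equals(panel)
        assert (
            rep.duplicate_removed == rep.sex_unplaced_removed == rep.maf_removed
            == rep.hwe_removed == rep.snp_call_rate_removed
            == rep.sample_call_rate_removed == 0
        )
        again, rep2 = filter_panel(out)
        assert again.equals(out)

    def test_counts_reconcile(self, rng):
        panel = self._clean_panel(rng, n_samples=30, n_snps=20)
        H = panel.H.copy()
        H[:, 0] = 0
        H[0, 0] = 1          # low MAF
        H[2 * 3:2 * 30:2, 5] = MISSING  # SNP 5 call rate 3/30
        panel = build_panel(H)
        out, rep = filter_panel(panel)
        removed = (
            rep.duplicate_removed + rep.sex_unplaced_removed
            + rep.snp_call_rate_removed + rep.maf_removed + rep.hwe_removed
        )
        assert rep.n_snps_out + removed == rep.n_snps_in

    def test_all_removed_raises(self, rng):
        H = np.zeros((8, 3), dtype=np.int8)  # all monomorphic -> MAF 0
        with pytest.raises(GenioError, match="empty panel"):
            filter_panel(build_panel(H))


class TestMerge:
    def test_intersection_by_key(self, rng):
        a = build_panel(rng.integers(0, 2, (4, 4)).astype(np.int8),
                        positions=[100, 200, 300, 400])
        b_full = build_panel(rng.integers(0, 2, (6, 4)).astype(np.int8),
                             positions=[200, 300, 400, 500])
        b_full.variants["id"] = ["snp1", "snp2", "snp3", "snpZ"]
        b_full.samples = [f"t{i}" for i in range(3)]
        merged = merge_panels(a, b_full)
        assert merged.variants["id"].tolist() == ["snp1", "snp2", "snp3"]
        assert merged.n_samples == 5
        assert np.array_equal(merged.H[:4], a.H[:, 1:4])

    def test_allele_mismatch_raises(self, rng):
        a = build_panel(rng.integers(0, 2, (4, 2)).astype(np.int8))
        b = build_panel(rng.integers(0, 2, (4, 2)).astype(np.int8), ref="C", alt="G")
        b.samples = ["t0", "t1"]
        with pytest.raises(GenioError, match="allele mismatch"):
            merge_panels(a, b)

    def test_strand_flip_accepted(self, rng):
        a = build_panel(rng.integers(0, 2, (4, 2)).astype(np.int8), ref="A", alt="G")
        b = build_panel(rng.integers(0, 2, (4, 2)).astype(np.int8), ref="T", alt="C")
        b.samples = ["t0", "t1"]
        merged = merge_panels(a, b)
        assert merged.n_variants == 2

    def test_same_variants_all_kept(self, rng):
        H = rng.integers(0, 2, (4, 5)).astype(np.int8)
        a = build_panel(H)
        b = build_panel(H)
        b.samples = ["t0", "t1"]
        assert merge_panels(a, b).n_variants == 5


class TestIbs:
    def test_identical_opposite_and_het(self):
        # samples: hom-ref, hom-ref, hom-alt, het
        H = np.array([[0], [0], [0], [0], [1], [1], [0], [1]], dtype=np.int8)
        panel = build_panel(H)
        m = ibs_matrix(panel)
        assert m[0, 1] == 1.0      # identical genotypes
        assert m[0, 2] == 0.0      # opposite homozygotes
        assert m[0, 3] == 0.5      # het vs hom shares 1 of 2 alleles
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_sample_permutation_equivariance(self, two_pop_panel, rng):
        m = ibs_matrix(two_pop_panel)
        perm = rng.permutation(two_pop_panel.n_samples)
        m2 = ibs_matrix(two_pop_panel.take_samples(perm))
        assert np.allclose(m2, m[np.ix_(perm, perm)])

    def test_no_joint_calls_raises(self):
        H = np.array([[0, MISSING], [0, MISSING], [MISSING, 1], [MISSING, 1]],
                     dtype=np.int8)
        with pytest.raises(GenioError, match="jointly called"):
            ibs_matrix(build_panel(H))


class TestPca:
    def test_two_blocks_separate_on_pc1(self):
        ibs = np.full((6, 6), 0.5)
        ibs[:3, :3] = 1.0
        ibs[3:, 3:] = 1.0
        coords, evals, _ = pca_from_ibs(ibs)
        pc1 = coords[:, 0]
        assert np.ptp(np.sign(pc1[:3])) == 0 and np.ptp(np.sign(pc1[3:])) == 0
        assert np.sign(pc1[0]) != np.sign(pc1[3])

    def test_identical_samples_collapse_to_origin(self):
        coords, evals, flags = pca_from_ibs(np.ones((5, 5)))
        assert np.allclose(coords, 0.0)
        assert not flags.any()

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.random((8, 8))
        ibs = (a + a.T) / 2
        np.fill_diagonal(ibs, 1.0)
        c1, _, _ = pca_from_ibs(ibs)
        c2, _, _ = pca_from_ibs(ibs + 0.17)
        assert np.allclose(np.abs(c1), np.abs(c2), atol=1e-8)

    def test_planted_outlier_is_flagged(self, rng):
        n = 12
        fA = rng.uniform(0.1, 0.9, 200)
        fB = np.clip(1.0 - fA + rng.normal(0, 0.1, 200), 0.02, 0.98)
        HA = (rng.random((2 * n, 200)) < fA).astype(np.int8)
        HB = (rng.random((2 * n, 200)) < fB).astype(np.int8)
        Hout = (rng.random((2, 200)) < fB).astype(np.int8)  # breed-A label, B genotypes
        panel = build_panel(np.vstack([HA, Hout, HB]),
                            pops=["A"] * (n + 1) + ["B"] * n)
        # a cross-cluster sample is orders of magnitude beyond z = 6, while
        # genuine members stay inside it even in tight clusters
        coords, evals, flags = pca_from_ibs(
            ibs_matrix(panel), pops=panel.pops, outlier_z=6.0
        )
        assert flags[n]                       # the planted sample
        assert flags.sum() == 1

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pca_from_ibs(np.arange(9.0).reshape(3, 3))
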