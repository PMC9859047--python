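"""Genotype QC, allele statistics, LD, PCA and IBS kinship oracles."""

import numpy as np
import pytest
from scipy import stats

from mirqtl.containers import hard_call
from mirqtl.genotype import (allele_stats, eqtl_variant_filter, genotype_pca,
                             hwe_chisq_p, ibs_kinship, ld_prune, ld_r2,
                             standard_variant_filter)
from mirqtl.simulate import SimConfig, simulate_genotypes

from conftest import make_genotypes


class TestHardCalls:
    def test_half_integer_ties_go_to_heterozygote(self):
        d = np.array([[0.4, 0.5, 1.5, 1.6, 2.0]])
        assert hard_call(d).tolist() == [[0, 1, 1, 2, 2]]


class TestAlleleStats:
    def test_all_heterozygote_column(self):
        gm = make_genotypes(np.ones((6, 1)))
        st = allele_stats(gm)
        assert st.loc[0, "maf"] == 0.5
        assert st.loc[0, "n_het"] == 6
        assert st.loc[0, "n_hom_minor"] == 0

    def test_mixed_column(self):
        gm = make_genotypes(np.array([[0.0], [0.0], [2.0]]))
        st = allele_stats(gm)
        assert st.loc[0, "maf"] == pytest.approx(1 / 3)
        assert st.loc[0, "n_het"] == 0
        assert st.loc[0, "n_hom_minor"] == 1

    def test_matches_direct_tally(self, rng):
        d = rng.integers(0, 3, size=(50, 20)).astype(float)
        st = allele_stats(make_genotypes(d))
        for j in range(20):
            col = d[:, j]
            f = col.mean() / 2
            minor = 2 if f <= 0.5 else 0
            assert st.loc[j, "n_het"] == int((col == 1).sum())
            assert st.loc[j, "n_hom_minor"] == int((col == minor).sum())

    def test_empty_matrix_rejected(self):
        gm = make_genotypes(np.ones((4, 1)))
        with pytest.raises(ValueError):
            allele_stats(gm.subset_variants(np.array([], dtype=int)))


class TestStandardFilter:
    def test_rare_variant_dropped(self, rng):
        n = 1000
        common = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        rare = np.zeros((n, 1))
        rare[:10, 0] = 1.0  # MAF 0.005
        gm = make_genotypes(np.hstack([common, rare]))
        out = standard_variant_filter(gm)
        assert list(out.variants["id"]) == ["v000"]

    def test_exact_hwe_kept(self):
        d = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2.0)])
        gm = make_genotypes(d[:, None])
        assert standard_variant_filter(gm).n_variants == 1

    def test_het_deficit_dropped_with_hand_chisq(self):
        # counts (50, 0, 50): chi-square equals n = 100, p << 1e-6
        assert hwe_chisq_p(50, 0, 50) == pytest.approx(
            float(stats.chi2.sf(100, 1)))
        d = np.concatenate([np.zeros(50), np.full(50, 2.0)])
        balanced = np.concatenate([np.zeros(25), np.ones(50),
                                   np.full(25, 2.0)])
        gm = make_genotypes(np.column_stack([d, balanced]))
        out = standard_variant_filter(gm)
        assert list(out.variants["id"]) == ["v001"]

    def test_everything_removed_is_an_error(self):
        rare = np.zeros((1000, 1))
        rare[:5, 0] = 1.0
        with pytest.raises(ValueError, match="every variant"):
            standard_variant_filter(make_genotypes(rare))


class TestEqtlCountFilter:
    @pytest.mark.parametrize("het,hom_minor,kept", [
        (2, 0, True),    # two hets, no hom-minor
        (10, 1, False),  # exactly one hom-minor sample
        (1, 0, False),   # a single het is not enough
        (5, 2, True),
    ])
    def test_count_rule(self, het, hom_minor, kept):
        n = 100
        col = np.zeros(n)
        col[:het] = 1.0
        col[het:het + hom_minor] = 2.0
        anchor = np.tile([0.0, 1.0, 1.0, 2.0], 25)  # always passes
        gm = make_genotypes(np.column_stack([col, anchor]))
        out = eqtl_variant_filter(gm)
        assert ("v000" in set(out.variants["id"])) == kept


class TestLd:
    def test_self_and_flipped(self, rng):
        d = rng.integers(0, 3, size=(20, 1)).astype(float)
        gm = make_genotypes(np.column_stack([d, 2 - d]))
        assert ld_r2(gm, "v000", "v000") == pytest.approx(1.0)
        assert ld_r2(gm, "v000", "v001") == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        a = np.array([0, 1, 2, 1, 0, 2, 1, 1], float)
        b = np.array([0, 1, 1, 1, 0, 2, 2, 1], float)
        gm = make_genotypes(np.column_stack([a, b]))
        r = np.cov(a, b, ddof=1)[0, 1] / (a.std(ddof=1) * b.std(ddof=1))
        assert ld_r2(gm, "v000", "v001") == pytest.approx(r * r)

    def test_monomorphic_rejected(self):
        gm = make_genotypes(np.column_stack([np.ones(5), np.arange(5) % 3]))
        with pytest.raises(ValueError, match="zero-variance"):
            ld_r2(gm, "v000", "v001")

    def test_ld_prune_bounds_pairwise_r2(self):
        cfg = SimConfig(n_samples=150, n_variants=200, n_blocks=4,
                        n_features=4, seed=3)
        gm = simulate_genotypes(cfg)
        pruned = ld_prune(gm, r2_max=0.2)
        D = pruned.dosages
        r2 = np.corrcoef(D, rowvar=False) ** 2
        off = r2[np.triu_indices_from(r2, k=1)]
        # adjacent kept variants obey the bound by construction
        assert all(r2[i, i + 1] < 0.2 for i in range(D.shape[1] - 1))
        assert pruned.n_variants < gm.n_variants


class TestGenotypePca:
    def test_separates_subpopulations(self):
        cfg = SimConfig(n_samples=300, n_variants=600, n_blocks=12,
                        n_features=4, n_subpops=2, fst=0.1, seed=8)
        gm = simulate_genotypes(cfg)
        # as in the pipeline: prune local LD so ancestry, not haplotype
        # blocks, dominates the leading axes
        scores = genotype_pca(ld_prune(gm, r2_max=0.2), k=2)
        labels = gm.subpop_labels.astype(float)
        r = abs(np.corrcoef(scores["genoPC1"], labels)[0, 1])
        assert r > 0.9

    def test_standardized_columns_centered(self, rng):
        d = rng.binomial(2, 0.4, size=(80, 30)).astype(float)
        f = d.mean(axis=0) / 2
        z = (d - 2 * f) / np.sqrt(2 * f * (1 - f))
        assert np.allclose(z.mean(axis=0), 0, atol=1e-10)

    def test_pc1_share_matches_eigen_oracle(self, rng):
        d = rng.binomial(2, 0.3, size=(40, 12)).astype(float)
        gm = make_genotypes(d)
        scores = genotype_pca(gm, k=1)
        f = d.mean(axis=0) / 2
        z = (d - 2 * f) / np.sqrt(2 * f * (1 - f))
        eigvals = np.linalg.eigvalsh(z @ z.T)[::-1]
        share_oracle = eigvals[0] / eigvals.sum()
        share = scores["genoPC1"].to_numpy().var() * 40 / eigvals.sum()
        assert share == pytest.approx(share_oracle, rel=1e-8)

    def test_monomorphic_variant_rejected(self):
        d = np.column_stack([np.ones(10), np.arange(10) % 3]).astype(float)
        d[:, 0] = 2.0
        with pytest.raises(ValueError, match="monomorphic"):
            genotype_pca(make_genotypes(d), k=1)


class TestKinship:
    def test_duplicate_samples_score_one(self, rng):
        row = rng.integers(0, 3, size=20).astype(float)
        d = np.vstack([row, row, rng.integers(0, 3, 20)])
        k = ibs_kinship(make_genotypes(d))
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_score_zero(self):
        d = np.array([[0.0, 0.0], [2.0, 2.0]])
        k = ibs_kinship(make_genotypes(d))
        assert k.values[0, 1] == pytest.approx(0.0)

    def test_half_identity_hand_oracle(self):
        d = np.array([[0.0, 2.0], [2.0, 2.0]])
        k = ibs_kinship(make_genotypes(d))
        # per-site IBS: (1 - 2/2) and (1 - 0/2) -> mean 0.5
        assert k.values[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal_on_random_input(self, rng):
        d = rng.integers(0, 3, size=(25, 60)).astype(float)
        k = ibs_kinship(make_genotypes(d))
        assert np.allclose(k.values, k.values.T)
        assert np.allclose(np.diag(k.values), 1.0)
        assert k.values.min() >= 0 and k.values.max() <= 1

    def test_loco_exclusion(self, rng):
        d = rng.integers(0, 3, size=(10, 6)).astype(float)
        chroms = ["chr1"] * 3 + ["chr2"] * 3
        gm = make_genotypes(d, chrom=chroms)
        k = ibs_kinship(gm, exclude_chrom="chr1")
        oracle = ibs_kinship(gm.subset_variants(np.arange(3, 6)))
        assert np.allclose(k.values, oracle.values)
        single = make_genotypes(d, chrom="chr1")
        with pytest.raises(ValueError, match="no kinship variants"):
            ibs_kinship(single, exclude_chrom="chr1")

    def test_filter_order_insensitive(self, rng):
        d = rng.integers(0, 3, size=(60, 40)).astype(float)
        gm = make_genotypes(d)
        a = eqtl_variant_filter(standard_variant_filter(gm))
        b = standard_variant_filter(eqtl_variant_filter(gm))
        assert set(a.variants["id"]) == set(b.variants["id"])
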