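"""Generator checks: determinism, allele-frequency targets, noise limits,
planted-effect calibration, GWAS cohort statistics, fixture round trips."""

import numpy as np
import pandas as pd
import pytest

from mirqtl import vcfio
from mirqtl.simulate import (SimConfig, beta_for_variance_explained,
                             default_fixture, nb_noise_variance,
                             simulate_expression, simulate_genotypes,
                             simulate_gwas_summary, write_fixture_set)


def small_config(**kw):
    base = dict(n_samples=120, n_variants=120, n_blocks=6, n_features=12,
                seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestGenotypes:
    def test_deterministic_given_seed(self):
        a = simulate_genotypes(small_config())
        b = simulate_genotypes(small_config())
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_no_differentiation_at_fst_zero(self):
        cfg = small_config(n_variants=1200, n_blocks=24, fst=0.0,
                           n_subpops=2, n_samples=400)
        gm = simulate_genotypes(cfg)
        sub = gm.subpop_labels
        f0 = gm.dosages[sub == 0].mean(axis=0) / 2
        f1 = gm.dosages[sub == 1].mean(axis=0) / 2
        assert abs(np.mean(f0 - f1)) < 0.01

    def test_maf_matches_target_by_allele_counting(self):
        cfg = small_config(n_variants=2000, n_blocks=20, n_samples=400,
                           maf_range=(0.3, 0.3))
        gm = simulate_genotypes(cfg)
        # oracle: direct allele counting on hard calls
        alt = gm.hard_calls.sum(axis=0) / (2 * gm.n_samples)
        maf = np.minimum(alt, 1 - alt)
        assert abs(maf.mean() - 0.3) < 0.02

    def test_dosage_bounds_and_block_structure(self):
        gm = simulate_genotypes(small_config())
        assert gm.dosages.min() >= 0 and gm.dosages.max() <= 2
        assert gm.variants["block"].nunique() == 6
        # blocks round-robin over two chromosomes
        assert set(gm.variants["chrom"]) == {"chr1", "chr2"}

    def test_subpops_exceeding_samples_rejected(self):
        with pytest.raises(ValueError, match="n_subpops"):
            small_config(n_subpops=200)

    def test_copy_group_has_unit_ld(self):
        # rho=1 with a degenerate frequency range makes every variant in a
        # block a founder copy of the first: r^2 = 1 within the group
        cfg = small_config(ld_rho=1.0, maf_range=(0.4, 0.4), fst=0.0,
                           n_subpops=1, n_variants=20, n_blocks=2)
        gm = simulate_genotypes(cfg)
        block0 = gm.dosages[:, :10]
        r2 = np.corrcoef(block0, rowvar=False) ** 2
        assert np.allclose(r2, 1.0)


class TestExpression:
    def test_deterministic_and_counts_nonnegative(self):
        cfg = small_config()
        gm = simulate_genotypes(cfg)
        e1, c1, t1 = simulate_expression(gm, cfg)
        e2, c2, t2 = simulate_expression(gm, cfg)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        pd.testing.assert_frame_equal(c1, c2)
        assert (e1.values.to_numpy() >= 0).all()

    def test_overflowing_effect_rejected(self):
        cfg = small_config()
        gm = simulate_genotypes(cfg)
        vid = gm.variants["id"].iloc[0]
        bad = SimConfig(**{**cfg.__dict__,
                           "planted_eqtls": [("mir000", vid, 50.0, 1)]})
        with pytest.raises(OverflowError):
            simulate_expression(gm, bad)

    def test_poisson_limit_of_dispersion(self):
        # with every structured noise source off, alpha -> 0 makes the
        # counts Poisson: variance/mean -> 1 within sampling error
        cfg = small_config(nb_dispersion=0.0, n_samples=400,
                           n_hidden_factors=0, batch_levels=1,
                           bio_noise_max=0.0, libsize_sd=0.0,
                           covariate_effect_sd=0.0)
        gm = simulate_genotypes(cfg)
        expr, _, _ = simulate_expression(gm, cfg)
        counts = expr.values.to_numpy(float)
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.2

    def test_planted_variance_fraction_recovered(self):
        """beta calibrated for 30% variance explained yields 30 +/- 10."""
        ves = []
        for seed in range(30):
            cfg = SimConfig(n_samples=200, n_variants=30, n_blocks=2,
                            n_features=4, seed=seed, n_hidden_factors=0,
                            batch_levels=1, bio_noise_max=0.0)
            gm = simulate_genotypes(cfg)
            f = gm.dosages.mean(axis=0) / 2
            maf = np.minimum(f, 1 - f)
            vidx = int(np.argmax(maf))
            beta = beta_for_variance_explained(0.30, float(maf[vidx]),
                                               nb_noise_variance(cfg))
            cfg = SimConfig(**{**cfg.__dict__, "planted_eqtls": [
                ("mir000", gm.variants["id"].iloc[vidx], beta, 1)]})
            expr, _, _ = simulate_expression(gm, cfg)
            y = np.log2(expr.values.loc["mir000"].to_numpy(float) + 1)
            g = gm.dosages[:, vidx]
            ves.append(100 * np.corrcoef(y, g)[0, 1] ** 2)
        assert abs(np.mean(ves) - 30) < 10

    def test_truth_table_round_trip_fields(self):
        gm, expr, cov, truth, cfg = default_fixture(3)
        assert set(truth.table["feature_id"]) <= set(expr.values.index)
        assert truth.table["degree"].min() == 1


class TestGwasSummary:
    def test_null_calibration(self):
        cfg = small_config(n_variants=400, n_blocks=8)
        gm = simulate_genotypes(cfg)
        ss = simulate_gwas_summary(gm, gm.variants["id"].iloc[0], beta=0.0,
                                   n_gwas=500, seed=9)
        frac = (ss.table["p"] < 0.05).mean()
        assert 0.02 < frac < 0.09

    def test_power_monotone_in_sample_size(self):
        cfg = small_config()
        gm = simulate_genotypes(cfg)
        vid = gm.variants["id"].iloc[3]
        z_small = [abs(simulate_gwas_summary(gm, vid, 0.3, 200, seed=s)
                       .table.set_index("id").loc[vid, "z"])
                   for s in range(8)]
        z_big = [abs(simulate_gwas_summary(gm, vid, 0.3, 400, seed=s)
                     .table.set_index("id").loc[vid, "z"])
                 for s in range(8)]
        assert np.median(z_big) > np.median(z_small)

    def test_ld_propagation_to_perfect_proxy(self):
        # a founder-copy block gives exact r^2 = 1 proxies
        cfg = small_config(ld_rho=1.0, maf_range=(0.4, 0.4), fst=0.0,
                           n_subpops=1, n_variants=10, n_blocks=1)
        gm = simulate_genotypes(cfg)
        ids = gm.variants["id"]
        ss = simulate_gwas_summary(gm, ids.iloc[0], 0.4, 500, seed=4)
        tab = ss.table.set_index("id")
        assert tab.loc[ids.iloc[0], "z"] == pytest.approx(
            tab.loc[ids.iloc[5], "z"], abs=1e-9)

    def test_small_cohort_rejected(self):
        cfg = small_config()
        gm = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="n_gwas"):
            simulate_gwas_summary(gm, gm.variants["id"].iloc[0], 0.1, 5,
                                  seed=1)


class TestFixtureFiles:
    def test_round_trip_exact(self, tmp_path):
        gm, expr, cov, truth, cfg = default_fixture(7)
        paths = write_fixture_set(gm, expr, cov, truth, tmp_path)
        back = vcfio.read_genotypes(paths["vcf"])
        np.testing.assert_array_equal(back.dosages, gm.dosages)
        assert back.samples == gm.samples
        counts = vcfio.read_counts(paths["counts"])
        pd.testing.assert_frame_equal(counts, expr.values, check_names=False)
        feats = vcfio.read_bed(paths["bed"])
        assert (feats["start"] == expr.features["start"]).all()
        cov_back = vcfio.read_covariates(paths["covariates"])
        assert np.allclose(cov_back["gestation_week"], cov["gestation_week"])
        assert (cov_back["batch"] == cov["batch"]).all()

    def test_vcf_record_count_matches(self, tmp_path):
        gm, expr, cov, truth, _ = default_fixture(7)
        paths = write_fixture_set(gm, expr, cov, truth, tmp_path)
        with open(paths["vcf"]) as fh:
            n_records = sum(1 for line in fh if not line.startswith("#"))
        assert n_records == gm.n_variants

    def test_empty_feature_set_writes_header_only(self, tmp_path):
        from mirqtl.containers import ExpressionMatrix

        gm, expr, cov, truth, _ = default_fixture(7)
        empty = ExpressionMatrix(
            values=expr.values.iloc[:0], features=expr.features, stage="raw")
        paths = write_fixture_set(gm, empty, cov, truth, tmp_path)
        lines = open(paths["counts"]).read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("feature_id")
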