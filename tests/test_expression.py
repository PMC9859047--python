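"""Expression preparation: filters, size factors, transform, batch removal,
PCA and residualization, each against a hand or linear-algebra oracle."""

import numpy as np
import pandas as pd
import pytest

from mirqtl.containers import ExpressionMatrix
from mirqtl.expression import (expression_pca, filter_expressed, remove_batch,
                               residualize, size_factors, vst_transform)


def make_expr(values, stage="raw", samples=None):
    values = np.asarray(values)
    fids = [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    feats = pd.DataFrame({"chrom": "chr1",
                          "start": 100 + 10 * np.arange(len(fids)),
                          "end": 121 + 10 * np.arange(len(fids)),
                          "strand": "+"}, index=fids)
    return ExpressionMatrix(values=pd.DataFrame(values, index=fids,
                                                columns=samples),
                            features=feats, stage=stage)


class TestFilter:
    def test_boundary_feature_kept(self):
        row = [10] * 10 + [0] * 5
        expr = make_expr([row])
        assert filter_expressed(expr).values.shape[0] == 1

    def test_all_zero_dropped(self):
        expr = make_expr([[0] * 12, [20] * 12])
        out = filter_expressed(expr)
        assert list(out.values.index) == ["f1"]

    def test_matches_row_scan_oracle(self, rng):
        counts = rng.integers(0, 25, size=(100, 30))
        expr = make_expr(counts)
        expected = ((counts >= 10).sum(axis=1) >= 10)  # direct boolean scan
        out = filter_expressed(expr)
        assert out.values.shape[0] == int(expected.sum())

    def test_min_samples_beyond_n_rejected(self):
        with pytest.raises(ValueError, match="min_samples"):
            filter_expressed(make_expr([[1, 2]]), min_samples=5)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        expr = make_expr([[5, 5], [9, 9], [2, 2]])
        assert np.allclose(size_factors(expr), 1.0)

    def test_doubled_column_hand_oracle(self):
        # column 2 = 2 x column 1: ratios to the geometric mean are
        # 1/sqrt(2) and sqrt(2) for every feature
        expr = make_expr([[4, 8], [10, 20], [7, 14]])
        f = size_factors(expr)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_feature_hand_oracle(self):
        expr = make_expr([[4, 9]])
        assert np.allclose(size_factors(expr), [4 / 6, 9 / 6])

    def test_zero_containing_features_excluded_from_reference(self):
        expr = make_expr([[0, 100], [4, 9]])
        assert np.allclose(size_factors(expr), [4 / 6, 9 / 6])

    def test_no_all_positive_feature_is_an_error(self):
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(make_expr([[0, 1], [1, 0]]))


class TestVst:
    def test_known_values(self):
        expr = make_expr([[0, 3]])
        out = vst_transform(expr, pd.Series([1.0, 1.0], index=["s0", "s1"]))
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == pytest.approx(2.0)  # log2(4)
        assert out.stage == "normalized"

    def test_rank_order_preserved_within_sample(self, rng):
        counts = rng.integers(0, 1000, size=(40, 6))
        expr = make_expr(counts)
        f = size_factors(make_expr(rng.integers(1, 50, size=(10, 6))))
        out = vst_transform(expr, f)
        for j in range(6):
            assert (np.argsort(counts[:, j], kind="stable")
                    == np.argsort(out.values.to_numpy()[:, j],
                                  kind="stable")).all()

    def test_nonpositive_factor_rejected(self):
        expr = make_expr([[1, 2]])
        with pytest.raises(ValueError):
            vst_transform(expr, pd.Series([1.0, 0.0], index=["s0", "s1"]))


def _cov(n, rng, batches=2):
    return pd.DataFrame({
        "batch": [f"b{i % batches}" for i in range(n)],
        "gestation_week": rng.uniform(14, 21, n),
    }, index=[f"s{j}" for j in range(n)])


class TestRemoveBatch:
    def test_constant_batch_is_identity(self, rng):
        vals = rng.normal(size=(5, 8))
        expr = make_expr(vals, stage="normalized")
        cov = _cov(8, rng, batches=1)
        out = remove_batch(expr, cov, ["batch"], ["gestation_week"])
        assert np.allclose(out.values, vals)

    def test_planted_offsets_removed(self, rng):
        n = 40
        cov = _cov(n, rng)
        base = rng.normal(size=(6, n))
        offset = np.where(np.array([b == "b1" for b in cov["batch"]]), 1.7, 0)
        expr = make_expr(base + offset, stage="normalized")
        out = remove_batch(expr, cov, ["batch"], ["gestation_week"])
        # refit oracle: the batch coefficient of a joint
        # [intercept | protected | batch] regression on the cleaned rows is 0
        X = np.column_stack([np.ones(n), cov["gestation_week"],
                             (cov["batch"] == "b1").astype(float)])
        for row in out.values.to_numpy():
            coef = np.linalg.lstsq(X, row, rcond=None)[0]
            assert abs(coef[2]) < 1e-8

    def test_protected_effect_untouched(self, rng):
        n = 50
        cov = _cov(n, rng)
        gest = cov["gestation_week"].to_numpy()
        batch = (cov["batch"] == "b1").to_numpy(float)
        y = 0.8 * gest + 1.2 * batch + rng.normal(size=n)
        expr = make_expr(y[None, :], stage="normalized")
        out = remove_batch(expr, cov, ["batch"], ["gestation_week"])

        def gest_coef(v):
            X = np.column_stack([np.ones(n), gest, batch])
            return np.linalg.lstsq(X, v, rcond=None)[0][1]

        assert gest_coef(out.values.to_numpy()[0]) == pytest.approx(
            gest_coef(y), abs=1e-8)

    def test_aliased_batch_design_rejected(self, rng):
        n = 10
        cov = _cov(n, rng)
        cov["copy"] = cov["batch"]
        expr = make_expr(rng.normal(size=(3, n)), stage="normalized")
        with pytest.raises(ValueError, match="rank"):
            remove_batch(expr, cov, ["batch", "copy"], ["gestation_week"])


class TestPca:
    def test_rank_one_matrix_concentrates_on_pc1(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=9)
        vals = np.outer(u, v) + 1e-9 * rng.normal(size=(6, 9))
        expr = make_expr(vals, stage="normalized")
        scores = expression_pca(expr, k=2)
        share = scores.var(ddof=0) / scores.var(ddof=0).sum()
        assert share.iloc[0] > 0.999

    def test_matches_svd_oracle_up_to_sign(self, rng):
        vals = rng.normal(size=(5, 4))
        expr = make_expr(vals, stage="normalized")
        scores = expression_pca(expr, k=2).to_numpy()
        centered = vals - vals.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        oracle = Vt[:2].T * s[:2]
        for j in range(2):
            assert (np.allclose(scores[:, j], oracle[:, j], atol=1e-10)
                    or np.allclose(scores[:, j], -oracle[:, j], atol=1e-10))

    def test_sample_permutation_equivariance(self, rng):
        vals = rng.normal(size=(8, 7))
        expr = make_expr(vals, stage="normalized")
        perm = rng.permutation(7)
        permuted = make_expr(vals[:, perm], stage="normalized",
                             samples=[f"s{j}" for j in perm])
        a = expression_pca(expr, k=3).to_numpy()
        b = expression_pca(permuted, k=3).to_numpy()
        assert np.allclose(a[perm], b, atol=1e-10)

    def test_excessive_k_rejected(self, rng):
        expr = make_expr(rng.normal(size=(4, 6)), stage="normalized")
        with pytest.raises(ValueError, match="k="):
            expression_pca(expr, k=4)


class TestResidualize:
    def test_residuals_orthogonal_to_design(self, rng):
        n = 30
        cov = _cov(n, rng)
        expr = make_expr(rng.normal(size=(5, n)), stage="normalized")
        out = residualize(expr, cov)
        gest = cov["gestation_week"].to_numpy()
        batch = (cov["batch"] == "b1").to_numpy(float)
        for row in out.values.to_numpy():
            assert abs(row @ gest) < 1e-8
            assert abs(row @ batch) < 1e-8
            assert abs(row.sum()) < 1e-8

    def test_matches_projection_oracle(self, rng):
        n = 6
        cov = pd.DataFrame({"x": rng.normal(size=n)},
                           index=[f"s{j}" for j in range(n)])
        y = rng.normal(size=(1, n))
        expr = make_expr(y, stage="normalized")
        out = residualize(expr, cov).values.to_numpy()[0]
        X = np.column_stack([np.ones(n), cov["x"]])
        P = X @ np.linalg.inv(X.T @ X) @ X.T
        assert np.allclose(out, (np.eye(n) - P) @ y[0], atol=1e-10)

    def test_idempotent(self, rng):
        n = 25
        cov = _cov(n, rng)
        expr = make_expr(rng.normal(size=(4, n)), stage="normalized")
        once = residualize(expr, cov)
        twice = residualize(
            ExpressionMatrix(values=once.values, features=once.features,
                             stage="normalized"), cov)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_singular_design_rejected(self, rng):
        n = 12
        cov = _cov(n, rng)
        cov["gest_copy"] = cov["gestation_week"]
        expr = make_expr(rng.normal(size=(2, n)), stage="normalized")
        with pytest.raises(ValueError, match="singular"):
            residualize(expr, cov)

    def test_missing_covariates_rejected(self, rng):
        n = 8
        cov = _cov(n, rng)
        cov.loc["s3", "gestation_week"] = np.nan
        expr = make_expr(rng.normal(size=(2, n)), stage="normalized")
        with pytest.raises(ValueError, match="missing"):
            residualize(expr, cov)
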