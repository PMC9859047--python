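"""Expression preparation: filter, normalize, de-batch, residualize.

Raw small-RNA counts become association-ready expression in five steps:
an expressed-feature filter (>=10 counts in >=10 samples), median-of-ratios
size factors, a variance-stabilizing log transform, limma-style batch
removal that protects biological covariates, and per-feature OLS
residualization against the full covariate design (known covariates plus
expression and genotype PCs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


def filter_expressed(expression: ExpressionMatrix, min_count: int = 10,
                     min_samples: int = 10) -> ExpressionMatrix:
    """Keep features with count >= min_count in >= min_samples samples."""
    if expression.stage != "raw":
        raise ValueError("expression filter applies to raw counts")
    n = len(expression.sample_ids)
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds {n} samples")
    counts = expression.values.to_numpy()
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return ExpressionMatrix(values=expression.values.loc[keep],
                            features=expression.features, stage="raw")


def size_factors(expression: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference is the per-feature geometric mean over samples; features
    containing any zero are excluded from the reference set.  Each sample's
    factor is the median ratio of its counts to the reference.
    """
    counts = expression.values.to_numpy(float)
    usable = (counts > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no feature is positive in all samples; supply a "
                         "pseudo-reference or filter more stringently")
    sub = counts[usable]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=expression.sample_ids, name="size_factor")


def vst_transform(expression: ExpressionMatrix,
                  factors: pd.Series) -> ExpressionMatrix:
    """Variance-stabilizing transform: log2(count / size_factor + 1).

    A shifted-log stand-in for a dispersion-trend VST: monotone in the
    count at fixed factor, zero at zero, and approximately variance-
    stabilizing for overdispersed counts.
    """
    f = factors.reindex(expression.sample_ids).to_numpy(float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and cover all samples")
    vals = np.log2(expression.values.to_numpy(float) / f[None, :] + 1.0)
    return expression.with_values(
        pd.DataFrame(vals, index=expression.feature_ids,
                     columns=expression.sample_ids),
        stage="normalized")


def _design(columns: dict[str, np.ndarray], n: int) -> np.ndarray:
    mats = [np.ones((n, 1))]
    for arr in columns.values():
        mats.append(np.asarray(arr, float).reshape(n, -1))
    return np.hstack(mats)


def _encode(covariates: pd.DataFrame, cols: list[str]) -> dict[str, np.ndarray]:
    """Dummy-encode categorical columns (drop first level), pass numerics."""
    out: dict[str, np.ndarray] = {}
    for c in cols:
        col = covariates[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            out[c] = dummies.to_numpy(float)
        else:
            out[c] = col.to_numpy(float)
    return out


def remove_batch(expression: ExpressionMatrix, covariates: pd.DataFrame,
                 batch_cols: list[str],
                 protected_cols: list[str] | None = None) -> ExpressionMatrix:
    """Subtract fitted batch effects, preserving protected covariates.

    Per feature, a joint linear model on [intercept | protected | batch] is
    fit and only the batch component of the fit is removed, so estimates of
    the protected effects are untouched.
    """
    if expression.stage != "normalized":
        raise ValueError("batch removal applies to normalized expression")
    protected_cols = protected_cols or []
    cov = covariates.loc[expression.sample_ids]
    n = len(expression.sample_ids)
    prot = _encode(cov, protected_cols)
    batch = _encode(cov, batch_cols)
    X = _design({**prot, **batch}, n)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"batch design rank-deficient; check columns {batch_cols} "
            f"against {protected_cols} for aliasing")
    n_prot = 1 + sum(v.reshape(n, -1).shape[1] for v in prot.values())
    Y = expression.values.to_numpy(float).T  # samples x features
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_part = X[:, n_prot:] @ coef[n_prot:]
    cleaned = (Y - batch_part).T
    return expression.with_values(
        pd.DataFrame(cleaned, index=expression.feature_ids,
                     columns=expression.sample_ids),
        stage="normalized")


def expression_pca(expression: ExpressionMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal-component scores of the feature-centered matrix.

    Features are rows; each feature is mean-centered across samples and the
    SVD taken over samples.  Signs are fixed by making the largest-|loading|
    entry of each component positive.  Returns samples x k scores.
    """
    vals = expression.values.to_numpy(float)
    n_feat, n_samp = vals.shape
    if k >= min(n_feat, n_samp):
        raise ValueError(f"k={k} must be < min(features, samples)="
                         f"{min(n_feat, n_samp)}")
    centered = vals - vals.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    for j in range(k):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    scores = (Vt[:k].T * s[:k])
    return pd.DataFrame(scores, index=expression.sample_ids,
                        columns=[f"exprPC{j + 1}" for j in range(k)])


def residualize(expression: ExpressionMatrix,
                covariates: pd.DataFrame) -> ExpressionMatrix:
    """Per-feature OLS residuals on the covariate design with intercept.

    All covariate columns (numeric, or categorical which are dummy-encoded)
    enter jointly; residuals are orthogonal to every design column.
    """
    cov = covariates.loc[expression.sample_ids]
    if cov.isna().any().any():
        bad = list(cov.columns[cov.isna().any()])
        raise ValueError(f"missing covariate values in {bad}")
    n = len(expression.sample_ids)
    X = _design(_encode(cov, list(cov.columns)), n)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j in range(1, X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(j)
        raise ValueError(f"singular covariate design (aliased design "
                         f"columns at positions {bad})")
    Y = expression.values.to_numpy(float).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ coef).T
    return expression.with_values(
        pd.DataFrame(resid, index=expression.feature_ids,
                     columns=expression.sample_ids),
        stage="residualized")


def covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Encoded design matrix [intercept | covariates] for downstream models.

    The same encoding ``residualize`` uses, exposed so association scans can
    project variant dosages onto the identical covariate space (leaving the
    covariates in the fixed-effect design avoids shadow signals that arise
    from regressing residualized expression on unresidualized dosages).
    """
    n = len(covariates)
    return _design(_encode(covariates, list(covariates.columns)), n)


def assemble_covariates(known: pd.DataFrame, expr_pcs: pd.DataFrame,
                        geno_pcs: pd.DataFrame) -> pd.DataFrame:
    """Join known covariates with expression and genotype PCs, no missing."""
    out = known.join(expr_pcs, how="inner").join(geno_pcs, how="inner")
    if len(out) != len(known):
        raise ValueError("sample sets of covariates and PCs do not agree")
    if out.isna().any().any():
        raise ValueError("assembled covariate table has missing values")
    return out
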