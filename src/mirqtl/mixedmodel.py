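"""EMMA-style REML variance components and EMMAX per-variant GLS scan.

The association model per expression feature is

    y = W a + g b + u + e,   u ~ N(0, sigma_g2 K),  e ~ N(0, sigma_e2 I)

with y the residualized expression vector, W the fixed-effect design and K
an identity-by-state kinship.  Following the EMMAX approximation, the
variance components are estimated once per feature under the no-variant
null by restricted maximum likelihood, then held fixed while every cis
variant is tested by generalized least squares.  A single eigen-
decomposition of K rotates the model to independent errors, making each
variant test an ordinary regression in the rotated space (O(n) per variant).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .containers import GenotypeMatrix, KinshipMatrix, VarianceComponents

EIGEN_FLOOR = 1e-10  # keeps sigma_g2*K + sigma_e2*I positive definite

_GRID_LO, _GRID_HI, _GRID_N = -10.0, 10.0, 100


def _restricted_loglik(log_delta: float, lam: np.ndarray,
                       eta2: np.ndarray) -> float:
    """EMMA restricted log-likelihood at delta = exp(log_delta).

    ``lam`` are the nonzero eigenvalues of S K S (S the projection off the
    fixed-effect span) and ``eta2`` the squared projections of y onto the
    corresponding eigenvectors.
    """
    delta = np.exp(log_delta)
    q = lam.size
    denom = lam + delta
    ss = np.sum(eta2 / denom)
    return 0.5 * (q * np.log(q / (2 * np.pi)) - q
                  - q * np.log(ss) - np.sum(np.log(denom)))


def emma_reml(y: np.ndarray, W: np.ndarray,
              kinship: KinshipMatrix) -> VarianceComponents:
    """REML variance components of the null mixed model y = W a + u + e.

    The profile restricted likelihood over log(delta) (delta = sigma_e2 /
    sigma_g2) is evaluated on a 100-point grid on [-10, 10] and refined by
    bounded scalar optimization around the best grid point.  A boundary hit
    is flagged, never silently accepted.
    """
    y = np.asarray(y, float).reshape(-1)
    W = np.asarray(W, float)
    if W.ndim == 1:
        W = W[:, None]
    n = y.size
    p = W.shape[1]
    if kinship.values.shape[0] != n or W.shape[0] != n:
        raise ValueError("y, W and K sample dimensions disagree")
    if not np.allclose(kinship.values, kinship.values.T, atol=1e-8):
        raise ValueError("kinship not symmetric within tolerance")
    if np.linalg.matrix_rank(W) < p:
        raise ValueError("fixed-effect design W is rank deficient")
    if n <= p + 1:
        raise ValueError("need n > columns(W) + 1 samples")

    # project off the fixed effects and eigen-decompose the restricted kinship
    Q, _ = np.linalg.qr(W)
    K = kinship.values
    SKS = K - Q @ (Q.T @ K)
    SKS = SKS - (SKS @ Q) @ Q.T
    SKS = (SKS + SKS.T) / 2
    vals, vecs = np.linalg.eigh(SKS)
    order = np.argsort(vals)[::-1]
    q = n - p
    lam = np.clip(vals[order[:q]], 0.0, None)
    U_r = vecs[:, order[:q]]
    eta = U_r.T @ y
    eta2 = eta**2

    rss = float(np.sum(eta2))
    scale = float(y @ y) + 1.0
    if rss / scale < 1e-14:
        # y lies in the span of W: no residual variance to decompose
        return VarianceComponents(sigma_g2=0.0, sigma_e2=0.0, delta=np.inf,
                                  reml_loglik=np.nan, degenerate=True)

    grid = np.linspace(_GRID_LO, _GRID_HI, _GRID_N)
    ll = np.array([_restricted_loglik(g, lam, eta2) for g in grid])
    best = int(np.argmax(ll))
    boundary = best in (0, _GRID_N - 1)
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, _GRID_N - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_restricted_loglik(g, lam, eta2),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8})
    log_delta = float(res.x) if -res.fun >= ll[best] else float(grid[best])
    delta = float(np.exp(log_delta))
    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / q)
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, delta=delta,
        reml_loglik=float(_restricted_loglik(log_delta, lam, eta2)),
        boundary=boundary)


def _rotation(kinship: KinshipMatrix,
              vc: VarianceComponents) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors of K and per-eigenvalue whitening weights of V."""
    vals, vecs = np.linalg.eigh(kinship.values)
    vals = np.clip(vals, EIGEN_FLOOR, None)
    v_diag = vc.sigma_g2 * vals + vc.sigma_e2
    if np.any(v_diag <= 0):
        raise ValueError("variance components give a singular V")
    return vecs, 1.0 / np.sqrt(v_diag)


def emmax_scan(y: np.ndarray, W: np.ndarray, kinship: KinshipMatrix,
               vc: VarianceComponents, genotypes: GenotypeMatrix,
               feature_id: str = "feature") -> "pd.DataFrame":
    """GLS association of every variant against one expression vector.

    With V = sigma_g2 K + sigma_e2 I held fixed, each variant's effect is
    estimated in the rotated (whitened) model; the two-sided p-value uses a
    t reference with n - columns(W) - 1 degrees of freedom.  Variants
    collinear with the design get a ``collinear`` flag and a missing p.
    """
    import pandas as pd

    y = np.asarray(y, float).reshape(-1)
    W = np.asarray(W, float)
    if W.ndim == 1:
        W = W[:, None]
    n = y.size
    p = W.shape[1]
    if vc.degenerate:
        raise ValueError("degenerate variance components; cannot scan")
    vecs, w = _rotation(kinship, vc)
    yr = w * (vecs.T @ y)
    Wr = w[:, None] * (vecs.T @ W)
    Gr = w[:, None] * (vecs.T @ genotypes.dosages)

    Q, _ = np.linalg.qr(Wr)
    ry = yr - Q @ (Q.T @ yr)
    RG = Gr - Q @ (Q.T @ Gr)
    gg = np.einsum("ij,ij->j", RG, RG)
    total = np.einsum("ij,ij->j", Gr, Gr) + 1e-30
    ok = gg / total > 1e-12

    beta = np.full(genotypes.n_variants, np.nan)
    se = np.full(genotypes.n_variants, np.nan)
    tstat = np.full(genotypes.n_variants, np.nan)
    pval = np.full(genotypes.n_variants, np.nan)
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("not enough samples for the design")
    num = RG.T @ ry
    beta[ok] = num[ok] / gg[ok]
    rss = float(ry @ ry) - beta**2 * gg
    sigma2 = np.maximum(rss / dof, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se[ok] = np.sqrt(sigma2[ok] / gg[ok])
        tstat[ok] = beta[ok] / se[ok]
    pval[ok] = 2 * stats.t.sf(np.abs(tstat[ok]), df=dof)

    out = genotypes.variants[["id", "chrom", "pos"]].rename(
        columns={"id": "variant_id"}).copy()
    out["feature_id"] = feature_id
    out["beta"] = beta
    out["se"] = se
    out["stat"] = tstat
    out["p"] = pval
    out["n"] = n
    out["flags"] = np.where(ok, "", "collinear")
    return out


def conditional_design(W: np.ndarray,
                       index_genotypes: list[np.ndarray],
                       index_ids: list[str] | None = None) -> np.ndarray:
    """Augment the fixed-effect design with discovered index genotypes."""
    W = np.asarray(W, float)
    if W.ndim == 1:
        W = W[:, None]
    if not index_genotypes:
        return W
    ids = index_ids or [f"index{i + 1}" for i in range(len(index_genotypes))]
    X = W
    for g, name in zip(index_genotypes, ids):
        g = np.asarray(g, float).reshape(-1, 1)
        if g.shape[0] != W.shape[0]:
            raise ValueError(f"index genotype {name} has wrong length")
        cand = np.hstack([X, g])
        if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(X):
            raise ValueError(
                f"index variant {name} is collinear with the design")
        X = cand
    return X


def draw_mixed_null(kinship: KinshipMatrix, sigma_g2: float, sigma_e2: float,
                    rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Draw y ~ N(0, sigma_g2 K + sigma_e2 I); shape (size, n)."""
    vals, vecs = np.linalg.eigh(kinship.values)
    vals = np.clip(vals, 0.0, None)
    n = vals.size
    z = rng.standard_normal((size, n))
    genetic = (z * np.sqrt(sigma_g2 * vals)) @ vecs.T
    return genetic + np.sqrt(sigma_e2) * rng.standard_normal((size, n))
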