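"""Colocalization by LD overlap + conditional confirmation, SMR, and pi1.

Two association signals are called colocalized when (i) the r^2 >= 0.8 LD
sets around the two index variants — each computed in its own reference
genotype panel — share at least one variant, and (ii) conditioning the
eQTL scan on the partner index variant extinguishes the eQTL signal (the
conditional window minimum p rises above the declaration threshold).

Cross-dataset sharing is quantified by Storey's pi1 = 1 - pi0 on the
replication p-values of the discovery index pairs, with a bootstrap
percentile confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix, VarianceComponents
from .mixedmodel import conditional_design, emma_reml, emmax_scan


@dataclass
class ColocResult:
    eqtl_index: str
    partner_index: str
    eqtl_ld_set: list[str] = field(default_factory=list)
    partner_ld_set: list[str] = field(default_factory=list)
    overlap: bool = False
    conditional_p: float | None = None
    verdict: str = "untestable"  # colocalized | not_colocalized | untestable

    def __post_init__(self) -> None:
        if self.verdict not in ("colocalized", "not_colocalized", "untestable"):
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass
class Pi1Result:
    pi0: float
    pi1: float
    n_bootstrap: int
    ci_low: float
    ci_high: float
    m_pvalues: int
    n_dropped: int = 0
    method: str = "smoother"


def _ld_set(genotypes: GenotypeMatrix, index: str,
            r2_threshold: float) -> list[str]:
    g = genotypes.dosage_of(index)
    if g.std() == 0:
        raise ValueError(f"index variant {index} monomorphic in its panel")
    D = genotypes.dosages
    sd = D.std(axis=0)
    ok = sd > 0
    gc = g - g.mean()
    Dc = D - D.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Dc.T @ gc) / (np.sqrt((Dc**2).sum(axis=0)) * np.sqrt((gc**2).sum()))
    r2 = np.where(ok, r**2, 0.0)
    ids = genotypes.variants["id"].to_numpy()
    return list(ids[r2 >= r2_threshold])


def ld_overlap(eqtl_index: str, partner_index: str,
               eqtl_panel: GenotypeMatrix, partner_panel: GenotypeMatrix,
               r2_threshold: float = 0.8) -> ColocResult:
    """LD-credible sets for both indices and their overlap flag.

    The eQTL-side set comes from the study genotypes, the partner-side set
    from the partner's own reference panel; the two panels are never
    substituted for one another.
    """
    try:
        set_a = _ld_set(eqtl_panel, eqtl_index, r2_threshold)
        set_b = _ld_set(partner_panel, partner_index, r2_threshold)
    except ValueError:
        return ColocResult(eqtl_index=eqtl_index, partner_index=partner_index,
                           verdict="untestable")
    overlap = bool(set(set_a) & set(set_b))
    return ColocResult(eqtl_index=eqtl_index, partner_index=partner_index,
                       eqtl_ld_set=set_a, partner_ld_set=set_b,
                       overlap=overlap,
                       verdict="untestable" if overlap else "not_colocalized")


def conditional_confirmation(
    result: ColocResult, partner_dosage: np.ndarray, y: np.ndarray,
    W: np.ndarray, kinship: KinshipMatrix, window: GenotypeMatrix,
    threshold: float, vc: VarianceComponents | None = None,
    mode: str = "window_min",
) -> ColocResult:
    """Complete a coloc verdict by conditioning the eQTL scan on the partner.

    The window is re-scanned with the partner genotype in the design; the
    conditional p is the window minimum (or the eQTL index variant's own p
    with ``mode='index_only'``).  A conditional p above the declaration
    threshold confirms the colocalization.
    """
    if not result.overlap:
        raise ValueError("conditional confirmation requires an LD overlap")
    if mode not in ("window_min", "index_only"):
        raise ValueError("mode must be 'window_min' or 'index_only'")
    if vc is None:
        vc = emma_reml(y, W, kinship)
    try:
        design = conditional_design(W, [np.asarray(partner_dosage, float)],
                                    [result.partner_index])
    except ValueError:
        result.verdict = "untestable"
        return result
    scan = emmax_scan(y, design, kinship, vc, window)
    valid = scan[scan["p"].notna()]
    if mode == "index_only":
        valid = valid[valid["variant_id"] == result.eqtl_index]
    if valid.empty:
        # the whole signal is absorbed by the partner genotype
        result.conditional_p = 1.0
        result.verdict = "colocalized"
        return result
    result.conditional_p = float(valid["p"].min())
    result.verdict = ("colocalized" if result.conditional_p > threshold
                      else "not_colocalized")
    return result


def signal_correlation(p_a: pd.Series, p_b: pd.Series) -> float:
    """Pearson correlation of -log10 p over the shared variant ids."""
    shared = p_a.index.intersection(p_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared variants")
    x = -np.log10(np.clip(p_a.loc[shared].to_numpy(float), 1e-300, 1.0))
    y = -np.log10(np.clip(p_b.loc[shared].to_numpy(float), 1e-300, 1.0))
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def smr_test(z_eqtl: float, z_gwas: float) -> tuple[float, float]:
    """Summary-based Mendelian randomization statistic.

    T = z_eqtl^2 z_gwas^2 / (z_eqtl^2 + z_gwas^2), referred to chi-square
    with 1 df.  Symmetric in its arguments and bounded by min(z^2).
    """
    z1, z2 = float(z_eqtl), float(z_gwas)
    if not (np.isfinite(z1) and np.isfinite(z2)):
        raise ValueError("z-scores must be finite")
    if z1 == 0 and z2 == 0:
        raise ValueError("both z-scores are zero")
    denom = z1**2 + z2**2
    if denom == 0:  # both z subnormal: T <= min(z^2) is indistinguishable from 0
        t = 0.0
    else:
        t = (z1 * z2) ** 2 / denom
        if not np.isfinite(t):
            t = min(z1**2, z2**2)
    return float(t), float(stats.chi2.sf(t, df=1))


def estimate_pi0(p_values: np.ndarray,
                 lambda_grid: np.ndarray | None = None,
                 small_m_cutoff: int = 100,
                 fixed_lambda: float = 0.5) -> tuple[float, str]:
    """Storey's pi0 from a p-value list.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)).  With at least
    ``small_m_cutoff`` p-values, a cubic polynomial is fit to pi0(lambda)
    over the grid and evaluated at the largest lambda (smoother
    extrapolation toward 1); below the cutoff the estimator at the single
    fixed lambda is used, which is far more stable at small m.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("no p-values")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    if p.size < small_m_cutoff:
        pi0 = np.mean(p > fixed_lambda) / (1 - fixed_lambda)
        return float(np.clip(pi0, 0.0, 1.0)), "fixed_lambda"
    pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambda_grid])
    spline = _cubic_smoother(lambda_grid, pi0_l)
    pi0 = float(spline(lambda_grid.max()))
    return float(np.clip(pi0, 0.0, 1.0)), "smoother"


from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=8)
def _smoother_penalty(x_key: tuple, df: float) -> float:
    """Penalty giving a smoothing spline ~``df`` effective degrees of
    freedom on the fixed abscissa grid (bisection on the smoother trace)."""
    from scipy.interpolate import make_smoothing_spline

    x = np.array(x_key)
    n = x.size

    def trace(lam: float) -> float:
        t = 0.0
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            t += float(make_smoothing_spline(x, e, lam=lam)(x[i]))
        return t

    lo, hi = 1e-8, 1e4
    for _ in range(40):
        mid = float(np.sqrt(lo * hi))
        if trace(mid) > df:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _cubic_smoother(x: np.ndarray, y: np.ndarray, df: float = 3.0):
    """Cubic smoothing spline with ~``df`` effective degrees of freedom.

    df = 3 is nearly quadratic, which keeps the lambda -> 1 extrapolation
    of pi0(lambda) stable on the 19-point default grid.
    """
    from scipy.interpolate import make_smoothing_spline

    lam = _smoother_penalty(tuple(np.round(x, 12)), df)
    return make_smoothing_spline(x, y, lam=lam)


def pi1_sharing(discovery_pairs: list[tuple[str, str]],
                replication_scan: pd.DataFrame,
                lambda_grid: np.ndarray | None = None,
                n_bootstrap: int = 100, seed: int = 0) -> Pi1Result:
    """Fraction of discovery associations that are non-null in replication.

    Replication p-values are looked up for the exact (feature, variant)
    pairs; pairs absent from the replication scan are dropped and counted.
    pi1 = 1 - pi0 with a percentile bootstrap CI over ``n_bootstrap``
    resamples of the p-value list.
    """
    lookup = replication_scan.set_index(["feature_id", "variant_id"])["p"]
    ps, dropped = [], 0
    for pair in discovery_pairs:
        if pair in lookup.index and np.isfinite(lookup.loc[pair]):
            ps.append(float(lookup.loc[pair]))
        else:
            dropped += 1
    if not ps:
        raise ValueError("no discovery pair is present in the replication scan")
    p = np.array(ps)
    pi0, method = estimate_pi0(p, lambda_grid)
    pi1 = float(np.clip(1.0 - pi0, 0.0, 1.0))
    rng = np.random.default_rng(seed)

    def pi1_stat(sample):
        b_pi0, _ = estimate_pi0(np.asarray(sample), lambda_grid)
        return float(np.clip(1.0 - b_pi0, 0.0, 1.0))

    # BCa corrects the smoother's bias, which a plain percentile interval
    # under-covers; fall back to percentile when BCa degenerates
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # BCa warns before degenerating
            res = stats.bootstrap((p,), pi1_stat, n_resamples=n_bootstrap,
                                  method="BCa", confidence_level=0.95,
                                  random_state=rng)
        lo, hi = res.confidence_interval
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("degenerate BCa interval")
    except ValueError:
        boots = [pi1_stat(rng.choice(p, size=p.size, replace=True))
                 for _ in range(n_bootstrap)]
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return Pi1Result(pi0=pi0, pi1=pi1, n_bootstrap=n_bootstrap,
                     ci_low=float(np.clip(min(lo, pi1), 0, 1)),
                     ci_high=float(np.clip(max(hi, pi1), 0, 1)),
                     m_pvalues=int(p.size), n_dropped=dropped, method=method)
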