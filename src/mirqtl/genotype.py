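"""Genotype QC, allele statistics, LD, PCA and LOCO IBS kinship.

Two variant filters are applied before association: the standard PLINK-style
QC (MAF, Hardy-Weinberg, per-variant and per-sample missingness) and a
bespoke per-variant count filter that drops variants whose association
could be driven by a single outlier sample (exactly one homozygous-minor
sample, or at most one heterozygote).

Kinship is mean identity-by-state on hard calls, computed once per excluded
chromosome (leave-one-chromosome-out) so the random effect never absorbs
the cis signal being tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix


def allele_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant MAF, het/hom-minor counts and missing rate.

    Allele frequency comes from the dosages (f = mean dosage / 2); genotype
    class counts come from hard calls.  Dosages are complete after QC, so
    the missing rate reflects any NaNs still present in raw input.
    """
    if genotypes.n_variants == 0:
        raise ValueError("empty genotype matrix")
    D = genotypes.dosages
    miss = np.isnan(D)
    f = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    H = genotypes.hard_calls.astype(float)
    H = np.where(miss, np.nan, H)
    het = np.nansum(H == 1, axis=0)
    n_hom_alt = np.nansum(H == 2, axis=0)
    n_hom_ref = np.nansum(H == 0, axis=0)
    minor_is_alt = f <= 0.5
    hom_minor = np.where(minor_is_alt, n_hom_alt, n_hom_ref)
    return pd.DataFrame({
        "id": genotypes.variants["id"].to_numpy(),
        "freq_alt": f,
        "maf": maf,
        "n_het": het.astype(int),
        "n_hom_minor": hom_minor.astype(int),
        "missing_rate": miss.mean(axis=0),
    })


def hwe_chisq_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg 1-df chi-square p on hard-call genotype counts."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_alt + n_het) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    ok = exp > 0
    chi2 = float(((obs[ok] - exp[ok]) ** 2 / exp[ok]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def standard_variant_filter(
    genotypes: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6,
    geno_miss_max: float = 0.05, mind_miss_max: float = 0.1,
) -> GenotypeMatrix:
    """PLINK-style QC: drop variants failing MAF/HWE/missingness and samples
    failing individual missingness."""
    D = genotypes.dosages
    sample_miss = np.isnan(D).mean(axis=1)
    keep_samples = sample_miss <= mind_miss_max
    g = genotypes.subset_samples(keep_samples) if not keep_samples.all() \
        else genotypes
    st = allele_stats(g)
    H = g.hard_calls
    miss = np.isnan(g.dosages)
    Hm = np.where(miss, np.nan, H.astype(float))
    hwe_p = np.array([
        hwe_chisq_p(int(np.nansum(Hm[:, j] == 0)),
                    int(np.nansum(Hm[:, j] == 1)),
                    int(np.nansum(Hm[:, j] == 2)))
        for j in range(g.n_variants)])
    keep = ((st["maf"].to_numpy() >= maf_min)
            & (hwe_p >= hwe_p_min)
            & (st["missing_rate"].to_numpy() <= geno_miss_max))
    if not keep.any():
        raise ValueError("standard variant filter removed every variant")
    return g.subset_variants(keep)


def eqtl_variant_filter(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Drop variants vulnerable to single-sample-driven associations.

    A variant is kept iff its homozygous-minor count is not exactly one and
    it has more than one heterozygous sample.
    """
    st = allele_stats(genotypes)
    keep = (st["n_hom_minor"].to_numpy() != 1) & (st["n_het"].to_numpy() > 1)
    if not keep.any():
        import warnings
        warnings.warn("eqtl variant filter removed every variant")
    return genotypes.subset_variants(keep)


def ld_r2(genotypes: GenotypeMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = genotypes.dosage_of(variant_a)
    b = genotypes.dosage_of(variant_b)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for a zero-variance variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise r^2 over dosage columns (all columns must be polymorphic)."""
    sd = dosages.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("LD undefined for zero-variance variants")
    r = np.corrcoef(dosages, rowvar=False)
    return r * r


def ld_prune(genotypes: GenotypeMatrix, r2_max: float = 0.2,
             window: int = 50) -> GenotypeMatrix:
    """Greedy LD pruning: keep a variant only if its r^2 with every kept
    variant in the trailing ``window`` stays below ``r2_max``.

    Population-structure PCA runs on the pruned set so that local LD blocks
    do not masquerade as ancestry axes (and cis signals are not re-absorbed
    as fixed effects).
    """
    D = genotypes.dosages
    sd = D.std(axis=0)
    kept: list[int] = []
    Dc = D - D.mean(axis=0)
    norms = np.sqrt((Dc**2).sum(axis=0))
    for j in range(genotypes.n_variants):
        if sd[j] == 0:
            continue
        ok = True
        for i in kept[-window:]:
            r = (Dc[:, i] @ Dc[:, j]) / (norms[i] * norms[j])
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    if not kept:
        raise ValueError("LD pruning removed every variant")
    return genotypes.subset_variants(np.array(kept))


def genotype_pca(genotypes: GenotypeMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k PCs of standardized dosages (x - 2f) / sqrt(2 f (1-f))."""
    D = genotypes.dosages
    f = D.mean(axis=0) / 2.0
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("monomorphic variants present; filter before PCA")
    Z = (D - 2 * f) / np.sqrt(2 * f * (1 - f))
    if k >= min(Z.shape):
        raise ValueError(f"k={k} too large for matrix of shape {Z.shape}")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(scores, index=genotypes.samples,
                        columns=[f"genoPC{j + 1}" for j in range(k)])


def ibs_kinship(genotypes: GenotypeMatrix,
                exclude_chrom: str | None = None) -> KinshipMatrix:
    """Mean identity-by-state similarity on hard calls.

    K_ij = mean over included variants of 1 - |g_i - g_j| / 2, so duplicate
    samples score 1 and opposite homozygotes score 0.  ``exclude_chrom``
    drops that chromosome's variants (leave-one-chromosome-out) so cis
    variants never contribute to the covariance they are tested against.
    """
    if exclude_chrom is not None:
        keep = (genotypes.variants["chrom"] != exclude_chrom).to_numpy()
        if not keep.any():
            raise ValueError(
                f"excluding {exclude_chrom} leaves no kinship variants")
        genotypes = genotypes.subset_variants(keep)
    H = genotypes.hard_calls.astype(float)
    n, m = H.shape
    # 1 - |gi - gj|/2 averaged over variants, via pairwise L1 distances
    abs_diff = np.zeros((n, n))
    for cls in (0.0, 1.0, 2.0):
        ind = (H == cls).astype(float)
        # sum over variants of |gi - gj| restricted to gi == cls
        abs_diff += ind @ np.abs(cls - H).T
    K = 1.0 - abs_diff / (2.0 * m)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(values=K, samples=list(genotypes.samples),
                         excluded_chrom=exclude_chrom)


def loco_kinships(genotypes: GenotypeMatrix) -> dict[str, KinshipMatrix]:
    """One IBS kinship per chromosome, each excluding that chromosome."""
    return {c: ibs_kinship(genotypes, exclude_chrom=c)
            for c in dict.fromkeys(genotypes.variants["chrom"])}
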