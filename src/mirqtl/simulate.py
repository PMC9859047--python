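"""Synthetic genotype/expression fixtures with planted cis-eQTL truth.

The generator emulates the statistical structure a local-miRNA-eQTL scan
assumes: a few hundred donors of mixed ancestry, imputed dosages organised
into LD blocks, and overdispersed small-RNA counts whose log-means carry
planted variant effects, batch offsets and hidden expression factors.

Genotypes come from a blockwise founder-haplotype pool: each LD block holds
``n_founders`` haplotypes per subpopulation, generated from a latent AR(1)
Gaussian copula so linkage decays with distance inside a block, and each
individual draws two founders per block (recombination only at block
boundaries).  Subpopulation allele frequencies follow a Balding-Nichols
model at the configured Fst.  The pool is retained on the returned matrix
so an independent GWAS cohort can be drawn from the same haplotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, SummaryStats, TruthTable

_LOGMEAN_OVERFLOW = 30.0  # natural-log mean above this would overflow counts


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``planted_eqtls`` lists (feature_id, variant_id, beta, degree[, shared])
    tuples; ``beta`` is the additive effect per alt-allele dosage unit on
    the natural-log count mean.
    """

    n_samples: int = 212
    n_variants: int = 1200
    n_blocks: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 2
    fst: float = 0.01
    n_features: int = 200
    planted_eqtls: list[tuple] = field(default_factory=list)
    nb_dispersion: float = 0.15
    batch_levels: int = 2
    n_hidden_factors: int = 3
    bio_noise_max: float = 0.7  # per-feature extra log-sd ~ U(0, max)
    libsize_sd: float = 0.2     # per-sample log library-size sd
    covariate_effect_sd: float = 0.03  # gestation-week effect sd per feature
    seed: int = 0
    # generator mechanics (documented defaults, not study quantities)
    n_founders: int = 24
    ld_rho: float = 0.97
    n_chroms: int = 2
    variant_spacing: int = 5_000
    block_gap: int = 3_000_000

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_variants", "n_blocks", "n_features",
                     "n_subpops", "batch_levels", "n_founders", "n_chroms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_hidden_factors < 0:
            raise ValueError("n_hidden_factors must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.fst < 0.5):
            raise ValueError("fst must lie in [0, 0.5)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_subpops > self.n_samples:
            raise ValueError("n_subpops may not exceed n_samples")
        if not (0 <= self.ld_rho <= 1):
            raise ValueError("ld_rho must lie in [0, 1]")
        for rec in self.planted_eqtls:
            if len(rec) not in (4, 5):
                raise ValueError("planted eQTL tuples are (feature, variant, beta, degree[, shared])")


@dataclass
class HaplotypePool:
    """Founder haplotypes per block and subpopulation; supports fresh draws."""

    founders: list[np.ndarray]        # per block: (n_subpops, n_founders, block_size)
    block_slices: list[slice]
    subpop_weights: np.ndarray

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` individuals; returns (dosages, subpop labels)."""
        n_subpops = len(self.subpop_weights)
        subpop = rng.choice(n_subpops, size=n, p=self.subpop_weights)
        n_variants = sum(f.shape[2] for f in self.founders)
        dos = np.empty((n, n_variants), dtype=float)
        for founders, sl in zip(self.founders, self.block_slices):
            k = founders.shape[1]
            h1 = rng.integers(0, k, size=n)
            h2 = rng.integers(0, k, size=n)
            dos[:, sl] = founders[subpop, h1] + founders[subpop, h2]
        return dos, subpop


def _block_layout(config: SimConfig) -> tuple[list[slice], pd.DataFrame]:
    """Assign variants to blocks, blocks round-robin to chromosomes."""
    base = config.n_variants // config.n_blocks
    sizes = [base + (1 if b < config.n_variants % config.n_blocks else 0)
             for b in range(config.n_blocks)]
    slices, rows = [], []
    offset = 0
    next_start = {f"chr{c + 1}": 1 for c in range(config.n_chroms)}
    for b, size in enumerate(sizes):
        chrom = f"chr{(b % config.n_chroms) + 1}"
        start = next_start[chrom]
        for j in range(size):
            rows.append({
                "id": f"v{offset + j:05d}",
                "chrom": chrom,
                "pos": start + j * config.variant_spacing,
                "ref": "A",
                "alt": "G",
                "block": b,
            })
        next_start[chrom] = start + size * config.variant_spacing + config.block_gap
        slices.append(slice(offset, offset + size))
        offset += size
    return slices, pd.DataFrame(rows)


def simulate_genotypes(config: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Simulate a samples x variants dosage matrix from a founder pool.

    Deterministic given ``config.seed`` (or an explicit ``seed`` override).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    slices, meta = _block_layout(config)
    lo, hi = config.maf_range

    founders_per_block: list[np.ndarray] = []
    for sl in slices:
        size = sl.stop - sl.start
        # ancestral frequencies follow an AR(1) on a Gaussian scale mapped
        # through its CDF, so they are marginally ~U(lo, hi) but neighboring
        # variants have similar frequencies (a prerequisite for strong LD)
        w = np.empty(size)
        w[0] = rng.standard_normal()
        rho_f = config.ld_rho
        for j in range(1, size):
            w[j] = rho_f * w[j - 1] + math.sqrt(max(0.0, 1 - rho_f**2)) \
                * rng.standard_normal()
        p_anc = lo + (hi - lo) * stats.norm.cdf(w)
        # Balding-Nichols subpopulation frequencies at the configured Fst
        if config.fst > 0:
            a = p_anc * (1 - config.fst) / config.fst
            b = (1 - p_anc) * (1 - config.fst) / config.fst
            p_sub = rng.beta(a, b, size=(config.n_subpops, size))
            p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
        else:
            p_sub = np.broadcast_to(p_anc, (config.n_subpops, size)).copy()
        # latent AR(1) copula along the block -> LD decays with distance
        rho = config.ld_rho
        z = np.empty((config.n_subpops, config.n_founders, size))
        z[:, :, 0] = rng.standard_normal((config.n_subpops, config.n_founders))
        if size > 1:
            innov = rng.standard_normal((config.n_subpops, config.n_founders, size - 1))
            scale = math.sqrt(max(0.0, 1 - rho * rho))
            for j in range(1, size):
                z[:, :, j] = rho * z[:, :, j - 1] + scale * innov[:, :, j - 1]
        thresholds = stats.norm.ppf(p_sub)[:, None, :]
        founders_per_block.append((z < thresholds).astype(np.int8))

    pool = HaplotypePool(
        founders=founders_per_block,
        block_slices=slices,
        subpop_weights=np.full(config.n_subpops, 1.0 / config.n_subpops),
    )
    dosages, subpop = pool.draw(config.n_samples, rng)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]
    gm = GenotypeMatrix(dosages=dosages, samples=samples,
                        variants=meta[["id", "chrom", "pos", "ref", "alt", "block"]],
                        pool=pool)
    gm.subpop_labels = subpop  # exposed for structure diagnostics
    return gm


def beta_for_variance_explained(target_ve: float, maf: float,
                                noise_var: float) -> float:
    """Effect size (log-mean scale) giving a target variance-explained fraction.

    For an additive dosage effect at allele frequency f, the genetic variance
    is 2 f (1-f) beta^2 and VE = var_g / (var_g + noise_var); inverting gives
    beta = sqrt(VE / (1-VE) * noise_var / (2 f (1-f))).
    """
    if not (0 < target_ve < 1):
        raise ValueError("target_ve must lie in (0, 1)")
    if not (0 < maf < 1):
        raise ValueError("maf must lie in (0, 1)")
    var_g = target_ve / (1 - target_ve) * noise_var
    return math.sqrt(var_g / (2 * maf * (1 - maf)))


def nb_noise_variance(config: SimConfig, baseline_mean: float = 500.0) -> float:
    """Natural-log-scale residual variance of the count noise.

    The gamma-Poisson mixture at dispersion alpha has
    Var(log lambda) = psi'(1/alpha) (trigamma); the Poisson layer adds
    ~1/mu by the delta method.
    """
    from scipy.special import polygamma

    alpha = config.nb_dispersion
    gamma_var = float(polygamma(1, 1.0 / alpha)) if alpha > 1e-8 else 0.0
    return gamma_var + 1.0 / baseline_mean


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimConfig, seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthTable]:
    """Negative-binomial counts with planted cis effects, batches and factors.

    Returns the raw count matrix, a covariate table (batch label plus two
    continuous covariates standing in for gestation week and RIN), and the
    machine-readable truth table.  Deterministic given the seed.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n = genotypes.n_samples
    feature_ids = [f"mir{f:03d}" for f in range(config.n_features)]
    fid_set = set(feature_ids)

    planted: dict[str, list[tuple[str, float, int, bool]]] = {}
    for rec in config.planted_eqtls:
        fid, vid, beta, degree = rec[0], rec[1], float(rec[2]), int(rec[3])
        shared = bool(rec[4]) if len(rec) == 5 else False
        if fid not in fid_set:
            raise ValueError(f"planted feature {fid!r} not among simulated features")
        genotypes.variant_index(vid)  # raises if absent
        planted.setdefault(fid, []).append((vid, beta, degree, shared))

    # feature coordinates: planted features sit 10 kb from their primary
    # variant (inside the cis window); the rest spread round-robin over blocks
    blocks = genotypes.variants["block"].to_numpy() if "block" in genotypes.variants \
        else np.zeros(genotypes.n_variants, dtype=int)
    feat_rows = []
    for f, fid in enumerate(feature_ids):
        if fid in planted:
            vidx = genotypes.variant_index(planted[fid][0][0])
            chrom = genotypes.variants.loc[vidx, "chrom"]
            start = int(genotypes.variants.loc[vidx, "pos"]) + 10_000
        else:
            b = f % int(blocks.max() + 1)
            in_block = np.flatnonzero(blocks == b)
            mid = in_block[len(in_block) // 2]
            chrom = genotypes.variants.loc[mid, "chrom"]
            start = int(genotypes.variants.loc[mid, "pos"]) + 1_000
        feat_rows.append({"chrom": chrom, "start": start, "end": start + 21,
                          "strand": "+"})
    features = pd.DataFrame(feat_rows, index=feature_ids)

    # covariates
    batch = rng.integers(0, config.batch_levels, size=n)
    gest_week = rng.uniform(14.0, 21.0, size=n)
    rin = rng.normal(8.0, 0.5, size=n)
    covariates = pd.DataFrame({
        "batch": [f"pool{b + 1}" for b in batch],
        "gestation_week": gest_week,
        "rin": rin,
    }, index=genotypes.samples)

    log_baseline = rng.normal(math.log(500.0), 0.8, size=config.n_features)
    batch_fx = rng.normal(0.0, 0.15, size=(config.n_features, config.batch_levels))
    loadings = rng.normal(0.0, 0.2, size=(config.n_features, config.n_hidden_factors))
    factors = rng.standard_normal((config.n_hidden_factors, n))
    gest_coef = rng.normal(0.0, config.covariate_effect_sd,
                           size=config.n_features)
    log_libsize = rng.normal(0.0, config.libsize_sd, size=n)
    # heterogeneous per-feature biological noise, as in real small-RNA data;
    # planted features carry only counting noise so their configured effect
    # sizes translate directly into variance-explained fractions
    bio_sd = rng.uniform(0.0, config.bio_noise_max, size=config.n_features)
    bio_noise = rng.standard_normal((config.n_features, n))
    for f, fid in enumerate(feature_ids):
        if fid in planted:
            bio_sd[f] = 0.0

    log_mu = (log_baseline[:, None]
              + batch_fx[:, batch]
              + loadings @ factors
              + gest_coef[:, None] * (gest_week - gest_week.mean())[None, :]
              + log_libsize[None, :]
              + bio_sd[:, None] * bio_noise)
    truth_rows = []
    for f, fid in enumerate(feature_ids):
        for vid, beta, degree, shared in planted.get(fid, []):
            log_mu[f] += beta * genotypes.dosage_of(vid)
            truth_rows.append({"feature_id": fid, "variant_id": vid,
                               "beta": beta, "degree": degree,
                               "shared_with_gwas": shared})
    if np.any(log_mu > _LOGMEAN_OVERFLOW):
        raise OverflowError("planted effects push log-mean beyond "
                            f"{_LOGMEAN_OVERFLOW}; counts would overflow")

    mu = np.exp(log_mu)
    alpha = config.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        counts = rng.poisson(lam)
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=feature_ids, columns=genotypes.samples),
        features=features, stage="raw")
    truth = TruthTable(pd.DataFrame(
        truth_rows, columns=["feature_id", "variant_id", "beta", "degree",
                             "shared_with_gwas"]))
    return expr, covariates, truth


def simulate_gwas_summary(
    genotypes: GenotypeMatrix, causal_variant: str, beta: float,
    n_gwas: int, seed: int, label: str = "gwas",
    causal_variants: dict[str, float] | None = None,
) -> SummaryStats:
    """Marginal summary statistics for a fresh cohort from the same pool.

    A quantitative phenotype is simulated on ``n_gwas`` new individuals drawn
    from the haplotype pool the eQTL cohort came from, then every variant is
    regressed marginally.  ``causal_variants`` optionally maps additional
    variant ids to effects (the named ``causal_variant``/``beta`` pair is the
    primary signal either way).
    """
    if n_gwas < 10:
        raise ValueError("n_gwas must be at least 10")
    if genotypes.pool is None:
        raise ValueError("genotype matrix carries no haplotype pool to redraw from")
    effects = {causal_variant: float(beta)}
    if causal_variants:
        effects.update({k: float(v) for k, v in causal_variants.items()})
    for vid in effects:
        genotypes.variant_index(vid)

    rng = np.random.default_rng(seed)
    G, _ = genotypes.pool.draw(n_gwas, rng)
    y = rng.standard_normal(n_gwas)
    for vid, b in effects.items():
        y = y + b * G[:, genotypes.variant_index(vid)]

    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    gxx = np.einsum("ij,ij->j", Gc, Gc)
    poly = gxx > 1e-12
    bhat = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.nan)
    bhat[poly] = (Gc[:, poly].T @ yc) / gxx[poly]
    rss = np.sum(yc**2) - bhat**2 * gxx
    dof = n_gwas - 2
    sigma2 = np.maximum(rss / dof, 1e-300)
    se[poly] = np.sqrt(sigma2[poly] / gxx[poly])
    z = np.zeros(G.shape[1])
    z[poly] = bhat[poly] / se[poly]
    p = np.ones(G.shape[1])
    p[poly] = 2 * stats.norm.sf(np.abs(z[poly]))

    table = genotypes.variants[["id", "chrom", "pos"]].copy()
    table["beta"] = bhat
    table["se"] = se
    table["z"] = z
    table["p"] = p
    return SummaryStats(table=table, label=label)


def default_fixture(seed: int = 0, config: SimConfig | None = None,
                    ve_targets: tuple[float, ...] = (0.15, 0.20, 0.25, 0.35,
                                                     0.50, 0.65)):
    """Simulate the default study: genotypes plus planted-eQTL expression.

    Plants one primary eQTL per target variance-explained fraction (the
    defaults span the 10-65% range a well-powered miRNA-eQTL scan observes),
    choosing common variants (MAF >= 0.2) mid-block so every cis window is
    populated.  Returns (genotypes, expression, covariates, truth, config).
    """
    config = config if config is not None else SimConfig(seed=seed)
    if config.seed != seed:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    genotypes = simulate_genotypes(config)
    freqs = genotypes.dosages.mean(axis=0) / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    blocks = genotypes.variants["block"].to_numpy()
    noise = nb_noise_variance(config)

    planted = []
    used_blocks: set[int] = set()
    f = 0
    for ve in ve_targets:
        cand = np.flatnonzero((maf >= 0.2) & ~np.isin(blocks, list(used_blocks)))
        if cand.size == 0:
            break
        # mid-block candidate so the +/-1 Mb window holds the whole block
        b = blocks[cand[0]]
        in_block = cand[blocks[cand] == b]
        vidx = int(in_block[len(in_block) // 2])
        beta = beta_for_variance_explained(ve, float(maf[vidx]), noise)
        planted.append((f"mir{f:03d}", genotypes.variants.loc[vidx, "id"],
                        beta, 1))
        used_blocks.add(int(b))
        f += 1
    config = SimConfig(**{**config.__dict__, "planted_eqtls": planted})
    expr, covars, truth = simulate_expression(genotypes, config)
    return genotypes, expr, covars, truth, config


def write_fixture_set(genotypes: GenotypeMatrix, expression: ExpressionMatrix,
                      covariates: pd.DataFrame, truth: TruthTable,
                      directory, summary: SummaryStats | None = None) -> dict:
    """Write the full fixture set (VCF, counts, BED, covariates, truth, stats).

    Returns a dict of written paths; reading the files back reproduces the
    in-memory matrices exactly.
    """
    from . import vcfio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "counts": directory / "counts.tsv",
        "bed": directory / "features.bed",
        "covariates": directory / "covariates.tsv",
        "truth": directory / "truth.tsv",
    }
    vcfio.write_vcf(genotypes, paths["vcf"])
    vcfio.write_counts(expression, paths["counts"])
    vcfio.write_bed(expression.features, paths["bed"])
    vcfio.write_covariates(covariates, paths["covariates"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    if summary is not None:
        paths["summary"] = directory / "gwas_summary.tsv"
        vcfio.write_summary_stats(summary, paths["summary"])
    return paths
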