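# Methods

This note documents the statistical model behind `mirqtl`, the synthetic
data its tests run on, the numerical choices inside each stage, and the
limits of what the simulation studies demonstrate.

## The association model

For each expression feature (a mature miRNA quantified by small-RNA
sequencing), expression across $n$ donors is modelled as

$$ y = W\alpha + g\beta + u + \varepsilon,\qquad
   u \sim \mathcal N(0, \sigma_g^2 K),\quad
   \varepsilon \sim \mathcal N(0, \sigma_e^2 I), $$

where $g$ is the alternate-allele dosage of one variant, $W$ a fixed-effect
design, and $K$ an identity-by-state (IBS) kinship matrix that absorbs
cryptic relatedness and residual population structure. $\beta$ is the
expression change per alt-allele dosage unit.

Estimation follows the EMMA/EMMAX two-step scheme:

1. **Null REML.** With $\beta = 0$, the restricted likelihood is profiled
   over $\delta = \sigma_e^2/\sigma_g^2$ using the eigenvalues of
   $S K S$ ($S$ the projection off the span of $W$). The profile is
   evaluated on a 100-point grid over $\log\delta \in [-10, 10]$ and
   refined by bounded scalar optimization around the best grid point; a
   boundary hit sets a flag on the result rather than failing silently. If
   $y$ lies in the span of $W$ the fit is flagged degenerate.
2. **Per-variant GLS.** $V = \sigma_g^2 K + \sigma_e^2 I$ is then held
   fixed for every variant in the window. One eigendecomposition of $K$
   (eigenvalues floored at $10^{-10}$ to keep $V$ positive definite)
   whitens the model, after which each variant test is an ordinary
   regression in the rotated space — $O(n)$ per variant. The two-sided
   p-value uses a $t$ reference with $n - \mathrm{cols}(W) - 1$ degrees of
   freedom, which matters only for very small fixtures. Variants collinear
   with $W$ are flagged and reported with a missing p-value.

Estimating the variance components once per feature (not per variant) is
the standard EMMAX approximation; its null calibration is verified
empirically (type-I error within [0.04, 0.06] at $\alpha=0.05$ on 10^4
structured-kinship null tests).

**Kinship.** $K_{ij}$ is the mean per-variant identity-by-state on hard
calls, $1 - |g_i - g_j|/2$, computed once per *excluded* chromosome
(leave-one-chromosome-out), so cis variants never contribute to the
covariance they are tested against. Hard calls round dosage to the nearest
genotype class with exact half-integer ties resolved toward the
heterozygote. Kinship uses hard calls to match the IBS definition; the
association itself stays on dosages.

**Covariates.** Expression is residualized on the full covariate design
(known covariates, 10 expression PCs, 10 genotype PCs, all dummy-encoded
with an intercept) before scanning, and the same design is passed as $W$
to the scan. Keeping the covariates in $W$ means the dosage side is
projected onto the identical covariate space (Frisch–Waugh), which at
small panel sizes prevents two artifacts of the residualize-y-only
shortcut: attenuated effect estimates and shadow "secondary" signals at
LD neighbours of a true signal. At biobank-scale variant panels the two
approaches are indistinguishable; at a few thousand simulated variants the
difference is material.

**Genotype PCA.** Population-structure PCs are computed on standardized
dosages $(x - 2f)/\sqrt{2f(1-f)}$ after greedy LD pruning (r² < 0.2 in a
sliding window). Without pruning, the leading eigenvectors of a small
blocky genome are haplotype blocks rather than ancestry, and including
them as fixed effects re-absorbs the cis signals under test.

## Preparation pipeline

Raw counts pass through, in order:

1. expressed-feature filter — keep features with ≥ 10 counts in ≥ 10
   samples (both configurable);
2. median-of-ratios size factors — the per-feature geometric mean over
   samples is the reference; features containing any zero are excluded
   from the reference set;
3. variance-stabilizing transform — `log2(count / factor + 1)`. This is a
   shifted-log stand-in for a dispersion-trend VST: monotone, zero at
   zero, and adequate because every downstream check is
   invariance- or recovery-based rather than tied to exact transformed
   values;
4. batch removal — a joint per-feature linear model on
   [intercept | protected | batch]; only the fitted batch component is
   subtracted, so protected biological covariates (gestation week by
   default) are untouched;
5. expression PCA — top 10 scores of the feature-centered matrix, signs
   fixed by making each component's largest-|loading| entry positive;
6. residualization — per-feature OLS on the assembled covariate table;
   residuals are orthogonal to every design column and the operation is
   idempotent. Missing covariate values are refused rather than imputed.

## Multiple testing and discovery

- **Local adjustment (effective tests).** Within each feature's cis window
  (feature interval ± 1 Mb, floored at position 1), variants are
  partitioned into consecutive blocks of 200; per block, the effective
  test count is the smallest k whose top-k eigenvalues of the variant
  correlation matrix reach 99% of the total; the window's $M_\mathrm{eff}$
  is the block sum and the adjusted minimum p is
  $\min(1, M_\mathrm{eff}\,p_\min)$. The adjustment tracks a
  1000-permutation min-p oracle within a factor of two on average.
- **Hierarchical threshold (stringent).** Benjamini–Hochberg across
  feature loci on the locally adjusted minimum p-values at FDR 5%. The
  stringent *nominal* threshold is defined as the largest nominal index p
  among the features that survive — the published analyses report a
  single nominal cutoff without its derivation, and this definition
  reproduces the intended behaviour (every declared feature's index
  variant lies below it) while remaining computable on any dataset.
- **Global threshold (relaxed).** BH across all nominal p-values; the
  relaxed threshold is the largest p with BH q ≤ 0.05, or undefined
  (flagged) when nothing is rejected. The stringent threshold is never
  larger than the relaxed one when both exist.
- **Stepwise conditional discovery.** For each feature passing the FDR
  stage, the unconditional scan's minimum-p variant is the primary index
  (ties break by smaller position, then lexicographic variant id). Each
  later round adds all discovered index genotypes to the fixed-effect
  design, re-scans the window with the *same* null variance components,
  and appends the new minimum-p variant while its nominal p stays strictly
  below the regime threshold. The single fixed nominal cutoff is used in
  every round; rank failure of the augmented design stops the loop with a
  partial result.
- **Variance explained** is `100 × corr(g, y_resid)²` on the residualized
  expression, reported per record.

## Colocalization, SMR and pi1

Two signals colocalize when (i) the r² ≥ 0.8 LD sets around the two index
variants overlap — each set computed in its own reference panel, never
substituting one panel for the other — and (ii) conditioning the eQTL
window scan on the partner index raises the window minimum p above the
declaration threshold. The window minimum (rather than the index variant's
own p) is the default confirmation statistic because it is the quantity
the threshold was calibrated on; an index-only mode exists behind a flag.

The SMR statistic is $T = z_1^2 z_2^2/(z_1^2+z_2^2)$ referred to
$\chi^2_1$ — symmetric in its arguments and bounded by the smaller $z^2$.

Cross-dataset sharing uses Storey's $\pi_0$: $\hat\pi_0(\lambda) =
\#\{p > \lambda\}/(m(1-\lambda))$ over $\lambda = 0.05, \dots, 0.95$,
extrapolated to $\lambda \to 1$ with a cubic smoothing spline constrained
to ~3 effective degrees of freedom (nearly quadratic, chosen because the
unpenalized spline extrapolates the very noisy last grid point). Below
m = 100 p-values the single fixed-λ = 0.5 estimator is used instead — the
smoother is unstable at the m ≈ 50 scale where tissue-sharing analyses
operate. The 95% CI comes from a BCa bootstrap with 100 resamples
(percentile fallback when BCa degenerates); BCa corrects the smoother's
bias, which a plain percentile interval under-covers.

## Allele-specific expression

Reads are assigned to the reference- or alternate-allele mature sequence
by exact, forward-strand, zero-mismatch matching: a read shorter than the
mature sequence matches by exact prefix, a longer read never matches (no
soft clipping). Reads shorter than the first discriminating base match
both alleles and are counted as ambiguous; assignment conserves reads.
The within-heterozygote test is a classical paired two-sided t-test on
per-donor (ref, alt) counts, by default on the log2(count+1) scale (the
raw-count mode is retained because skewed counts are the norm but the
published test's scale is unstated). Exact ties are flagged rather than
producing an undefined statistic.

## The synthetic study

The default fixture emulates a mid-gestation cortical-tissue small-RNA
eQTL study: 212 donors, 1200 variants in 60 LD blocks round-robin across
two synthetic chromosomes (5 kb spacing within a block, 3 Mb between
blocks so each ±1 Mb cis window holds exactly one block), two
subpopulations at Fst = 0.01, and 200 features with negative-binomial
counts (dispersion 0.15, log-baseline ~ N(log 500, 0.8)).

Genotypes come from a blockwise founder-haplotype pool: 24 founders per
subpopulation per block, generated through a latent AR(1) Gaussian copula
(ρ = 0.97 per 5 kb step) whose thresholds are Balding–Nichols
subpopulation frequencies; ancestral frequencies themselves follow an
AR(1)-through-CDF scheme so that neighbouring variants have similar
frequencies — a prerequisite for r² ≥ 0.8 proxy sets. Individuals draw
two founders per block (recombination only at block boundaries), so a
degenerate configuration (ρ = 1, fixed frequency) yields exact-copy
variant groups with r² = 1, used by the LD and GWAS-propagation tests.
The pool is retained on the genotype matrix so an independent GWAS cohort
can be drawn from the same haplotypes.

Expression log-means sum a feature baseline, planted variant effects,
batch offsets (two levels, sd 0.15), loadings on three hidden Gaussian
factors (sd 0.2 — deliberately fewer than the 10 expression PCs, so the
PC correction over-captures them), a small gestation-week effect, a
per-sample log library size (sd 0.2), and per-feature biological noise
with sd ~ U(0, 0.7). The heterogeneous biological noise mirrors real
small-RNA data and keeps the PCA spectrum spread out; planted features
carry only counting noise, so a planted effect calibrated by
$\beta = \sqrt{\mathrm{VE}/(1-\mathrm{VE})\cdot\sigma^2_\mathrm{noise}/(2f(1-f))}$
(with $\sigma^2_\mathrm{noise} = \psi'(1/\alpha) + 1/\mu$) lands near its
target variance-explained fraction. Default planted targets span 15–65%
of expression variance, the range a well-powered miRNA-eQTL study
observes; the realized post-correction values are attenuated by the PC
adjustment and typically span ~7–52%.

What the generator does **not** emulate: read-level sequencing artifacts,
isomiRs and multi-locus miRNA families, imputation uncertainty (dosages
are exact integer haplotype sums), linkage between blocks, missing
genotypes, and any real LD or allele-frequency spectrum. Passing tests
therefore demonstrate the statistical machinery — calibration, FDR
control, conditional and colocalization logic — on data satisfying the
model's assumptions, not robustness to the full messiness of real
sequencing studies.

## Numerical and design choices

- All randomness in a pipeline run flows from one seed, split per stage by
  fixed offsets (simulation, expression + 1, GWAS cohort + 2,
  bootstrap + 3); two runs with the same configuration are byte-identical.
- HWE uses a 1-df chi-square on hard-call counts without continuity
  correction (matching the common QC tool's behaviour at these
  thresholds); an exact test is deliberately omitted.
- The IBS kinship is used raw (no rescaling); the mixed model absorbs its
  scale into $\sigma_g^2$.
- Dosage ties at half-integers go to the heterozygote; association always
  uses the unrounded dosage.
- $\beta$ is oriented per alt-allele dosage unit.
- Coordinates are 1-based inclusive internally; BED's 0-based half-open
  intervals are converted at the I/O boundary.
- Missing dosages are refused after QC; a mean-impute flag exists only for
  reading external files.
- Simulation-study problem sizes (replicate counts, cohort sizes, variants
  per window) are chosen so each study resolves its target rate with
  binomial noise well inside the decision margin while the whole
  validation suite stays quick to run; the acceptance script uses
  moderately reduced replicate counts for the same quantities.

## Known limitations

- The stringent-threshold definition (max nominal index p among surviving
  features) is one of several consistent constructions; on data sets where
  the BH boundary is sparse it can be conservative.
- The VST stand-in does not reproduce a dispersion-trend VST's exact
  values; analyses that depend on absolute transformed scales (not ranks
  or residual structure) would need the reference implementation.
- At small feature panels the expression PCs absorb part of any strong
  single-feature genetic signal; realized variance explained is biased
  downward relative to the planted target (quantified above). This
  attenuation shrinks roughly linearly with panel size.
- The smoother-based $\pi_1$ occasionally produces large errors on single
  replicates at m = 200 (the final $\hat\pi_0(\lambda)$ grid point has
  binomial sd ≈ 0.28); averages and CI coverage behave, single estimates
  should be read with the CI.
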