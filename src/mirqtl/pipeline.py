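"""End-to-end orchestration: prep -> kinship -> scan -> correction -> conditional.

``run_pipeline`` executes the full local-eQTL analysis on a RunConfig,
either loading the referenced files or simulating the default fixture when
no genotype path is given.  All stage outputs are plain TSV/JSON under the
configured output directory, and a manifest records the seed, thresholds
and per-stage record counts.  Re-running with the same config reproduces
every output byte-for-byte: all randomness flows from the single seed,
split per stage by fixed offsets (simulation seed, expression seed + 1,
GWAS cohort seed + 2, bootstrap seed + 3).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import discovery, expression, genotype, simulate, vcfio
from .containers import (EqtlRecord, ExpressionMatrix, GenotypeMatrix,
                         eqtl_records_frame)

log = logging.getLogger("mirqtl")

SEED_SIM, SEED_EXPR, SEED_GWAS, SEED_BOOT = 0, 1, 2, 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    outdir: str = "mirqtl_run"
    seed: int = 0
    regime: str = "stringent"
    genotypes: str | None = None
    counts: str | None = None
    features_bed: str | None = None
    covariates: str | None = None
    summary_stats: str | None = None
    fdr: float = 0.05
    flank: int = 1_000_000
    min_count: int = 10
    min_samples: int = 10
    expr_pcs: int = 10
    geno_pcs: int = 10
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    geno_miss_max: float = 0.05
    mind_miss_max: float = 0.1
    eigenmt_window: int = 200
    eigenmt_var_threshold: float = 0.99
    prune_r2_max: float = 0.2
    ld_r2_threshold: float = 0.8
    batch_cols: list[str] = field(default_factory=lambda: ["batch"])
    protected_cols: list[str] = field(default_factory=lambda: ["gestation_week"])
    write_fixture: bool = True

    def __post_init__(self) -> None:
        if self.regime not in ("stringent", "relaxed"):
            raise ValueError("regime must be 'stringent' or 'relaxed'")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr must lie in (0, 1]")
        for p in (self.genotypes, self.counts, self.features_bed,
                  self.covariates, self.summary_stats):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_inputs(cfg: RunConfig):
    """Load configured files, or simulate the default fixture."""
    if cfg.genotypes is None:
        log.info("simulate: generating default fixture (seed=%d)", cfg.seed)
        gm, expr, covars, truth, sim_cfg = simulate.default_fixture(cfg.seed)
        return gm, expr, covars, truth
    gm = vcfio.read_genotypes(cfg.genotypes)
    counts = vcfio.read_counts(cfg.counts)
    features = vcfio.read_bed(cfg.features_bed)
    covars = vcfio.read_covariates(cfg.covariates)
    expr = ExpressionMatrix(values=counts, features=features, stage="raw")
    return gm, expr, covars, None


def prepare_genotypes(gm: GenotypeMatrix, cfg: RunConfig):
    """Standard QC, genotype PCA, eQTL count filter, LOCO kinships."""
    qc = genotype.standard_variant_filter(
        gm, maf_min=cfg.maf_min, hwe_p_min=cfg.hwe_p_min,
        geno_miss_max=cfg.geno_miss_max, mind_miss_max=cfg.mind_miss_max)
    pruned = genotype.ld_prune(qc, r2_max=cfg.prune_r2_max)
    geno_pcs = genotype.genotype_pca(
        pruned, k=min(cfg.geno_pcs, min(pruned.dosages.shape) - 1))
    scan_set = genotype.eqtl_variant_filter(qc)
    kinships = genotype.loco_kinships(qc)
    return qc, scan_set, geno_pcs, kinships


def prepare_expression(expr: ExpressionMatrix, covars: pd.DataFrame,
                       geno_pcs: pd.DataFrame, cfg: RunConfig):
    """Filter, normalize, de-batch, PCA, residualize."""
    kept = expression.filter_expressed(expr, cfg.min_count, cfg.min_samples)
    factors = expression.size_factors(kept)
    norm = expression.vst_transform(kept, factors)
    cleaned = expression.remove_batch(norm, covars, cfg.batch_cols,
                                      cfg.protected_cols)
    k = min(cfg.expr_pcs, min(len(cleaned.feature_ids),
                              len(cleaned.sample_ids)) - 1)
    expr_pcs = expression.expression_pca(cleaned, k=k)
    full_cov = expression.assemble_covariates(covars, expr_pcs, geno_pcs)
    resid = expression.residualize(norm, full_cov)
    return resid, full_cov


def _scan_design(resid: ExpressionMatrix,
                 covariates: pd.DataFrame | None) -> np.ndarray:
    n = len(resid.sample_ids)
    if covariates is None:
        return np.ones((n, 1))
    return expression.covariate_design(covariates.loc[resid.sample_ids])


def scan_features(resid: ExpressionMatrix, scan_set: GenotypeMatrix,
                  kinships, cfg: RunConfig,
                  covariates: pd.DataFrame | None = None):
    """Mixed-model cis scan per feature locus plus eigenMT local adjustment.

    When the full covariate table is supplied, the scan design is
    [intercept | covariates]; the expression side is already residualized,
    so this only projects the dosages onto the same covariate space.
    """
    W = _scan_design(resid, covariates)
    all_scans, locus_rows = [], []
    for fid in resid.feature_ids:
        frow = resid.features.loc[fid]
        window = discovery.define_cis_window(fid, frow, scan_set.variants,
                                             flank=cfg.flank)
        if not window.variant_ids:
            continue
        sub = scan_set.subset_variants(
            scan_set.variants["id"].isin(window.variant_ids).to_numpy())
        y = resid.values.loc[fid].to_numpy(float)
        kin = kinships[window.chrom]
        vc = discovery.emma_reml(y, W, kin)
        scan = discovery.emmax_scan(y, W, kin, vc, sub, feature_id=fid)
        all_scans.append(scan)
        valid = scan[scan["p"].notna()]
        if valid.empty:
            continue
        top = valid.sort_values(["p", "pos", "variant_id"]).iloc[0]
        p_adj, m_eff = discovery.eigen_mt(
            sub.dosages, float(top["p"]), window_size=cfg.eigenmt_window,
            var_threshold=cfg.eigenmt_var_threshold)
        locus_rows.append({"feature_id": fid, "chrom": window.chrom,
                           "index_variant": top["variant_id"],
                           "p_nominal": float(top["p"]), "m_eff": m_eff,
                           "p_adj": p_adj, "n_variants": sub.n_variants})
    if not all_scans:
        raise PipelineError("scan", "no feature locus had cis variants")
    return pd.concat(all_scans, ignore_index=True), pd.DataFrame(locus_rows)


def apply_corrections(locus_table: pd.DataFrame, scan_table: pd.DataFrame,
                      cfg: RunConfig):
    """Hierarchical (eigenMT + BH) and global-only BH thresholds."""
    adjusted, thresholds = discovery.hierarchical_fdr(locus_table, fdr=cfg.fdr)
    relaxed, m_tests = discovery.global_fdr(
        scan_table["p"].dropna().to_numpy(), fdr=cfg.fdr)
    thresholds.relaxed = relaxed
    thresholds.m_tests = m_tests
    return adjusted, thresholds


def discover_conditional(resid: ExpressionMatrix, scan_set: GenotypeMatrix,
                         kinships, adjusted: pd.DataFrame,
                         thresholds, cfg: RunConfig,
                         covariates: pd.DataFrame | None = None) -> list[EqtlRecord]:
    """Stepwise conditional discovery for every significant feature."""
    threshold = thresholds.for_regime(cfg.regime)
    records: list[EqtlRecord] = []
    if threshold is None:
        return records
    W = _scan_design(resid, covariates)
    emirs = adjusted.loc[adjusted["significant"], "feature_id"]
    for fid in emirs:
        frow = resid.features.loc[fid]
        window = discovery.define_cis_window(fid, frow, scan_set.variants,
                                             flank=cfg.flank)
        sub = scan_set.subset_variants(
            scan_set.variants["id"].isin(window.variant_ids).to_numpy())
        y = resid.values.loc[fid].to_numpy(float)
        recs = discovery.stepwise_conditional(
            fid, sub, y, W, kinships[window.chrom], threshold,
            regime=cfg.regime)
        locus = adjusted.set_index("feature_id")
        for r in recs:
            r.variance_explained_pct = discovery.variance_explained(
                y, sub.dosage_of(r.variant_id))
            if r.degree == 1:
                r.p_local_adj = float(locus.loc[fid, "p_adj"])
                r.q_global = float(locus.loc[fid, "q"])
        records.extend(recs)
    return records


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and write the result bundle."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    counts_by_stage: dict[str, int] = {}
    try:
        try:
            gm, expr, covars, truth = load_inputs(cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("load", str(e)) from e
        if cfg.genotypes is None and cfg.write_fixture:
            simulate.write_fixture_set(gm, expr, covars, truth,
                                       outdir / "fixture")
        counts_by_stage["samples"] = gm.n_samples
        counts_by_stage["variants_raw"] = gm.n_variants
        counts_by_stage["features_raw"] = len(expr.feature_ids)

        try:
            qc, scan_set, geno_pcs, kinships = prepare_genotypes(gm, cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("genotype_prep", str(e)) from e
        counts_by_stage["variants_qc"] = qc.n_variants
        counts_by_stage["variants_scan"] = scan_set.n_variants
        log.info("genotype_prep: %d variants after QC, %d after count filter",
                 qc.n_variants, scan_set.n_variants)

        try:
            resid, full_cov = prepare_expression(expr, covars, geno_pcs, cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("expression_prep", str(e)) from e
        counts_by_stage["features_tested"] = len(resid.feature_ids)
        resid.values.to_csv(outdir / "expression_residual.tsv", sep="\t",
                            index_label="feature_id")
        vcfio.write_covariates(full_cov, outdir / "covariates_full.tsv")
        for chrom, kin in kinships.items():
            vcfio.write_kinship(kin, outdir / f"kinship_loco_{chrom}.tsv")

        try:
            scan_table, locus_table = scan_features(resid, scan_set,
                                                    kinships, cfg, full_cov)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("scan", str(e)) from e
        counts_by_stage["association_tests"] = int(scan_table["p"].notna().sum())
        scan_table.to_csv(outdir / "associations.tsv", sep="\t", index=False)

        try:
            adjusted, thresholds = apply_corrections(locus_table, scan_table,
                                                     cfg)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("correction", str(e)) from e
        adjusted.to_csv(outdir / "feature_loci.tsv", sep="\t", index=False)
        with open(outdir / "thresholds.json", "w") as fh:
            json.dump(dataclasses.asdict(thresholds), fh, indent=2)
        counts_by_stage["emirs"] = int(adjusted["significant"].sum())
        log.info("correction: stringent=%s relaxed=%s emiRs=%d",
                 thresholds.stringent, thresholds.relaxed,
                 counts_by_stage["emirs"])

        try:
            records = discover_conditional(resid, scan_set, kinships,
                                           adjusted, thresholds, cfg,
                                           full_cov)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("conditional", str(e)) from e
        rec_frame = eqtl_records_frame(records)
        rec_frame.to_csv(outdir / "eqtls.tsv", sep="\t", index=False)
        counts_by_stage["eqtls"] = len(rec_frame)

        pi1_result = None
        coloc_frame = None
        if cfg.summary_stats is not None and len(rec_frame):
            try:
                summary = vcfio.read_summary_stats(cfg.summary_stats)
                coloc_frame, pi1_result = coloc_stage(
                    resid, scan_set, kinships, records, summary, thresholds,
                    cfg, full_cov)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("coloc", str(e)) from e
            coloc_frame.to_csv(outdir / "coloc.tsv", sep="\t", index=False)
            with open(outdir / "pi1.json", "w") as fh:
                json.dump(dataclasses.asdict(pi1_result), fh, indent=2)

        manifest = {
            "package": "mirqtl",
            "seed": cfg.seed,
            "regime": cfg.regime,
            "thresholds": {"stringent": thresholds.stringent,
                           "relaxed": thresholds.relaxed,
                           "fdr": cfg.fdr,
                           "m_features": thresholds.m_features,
                           "m_tests": thresholds.m_tests},
            "counts": counts_by_stage,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return {"manifest": manifest, "thresholds": thresholds,
                "eqtls": rec_frame, "adjusted": adjusted,
                "scan": scan_table, "truth": truth, "coloc": coloc_frame,
                "pi1": pi1_result, "outdir": outdir}
    finally:
        log.removeHandler(handler)
        handler.close()


def coloc_stage(resid, scan_set, kinships, records, summary, thresholds,
                cfg: RunConfig, covariates: pd.DataFrame | None = None):
    """Colocalize each primary eQTL with the summary-stat signal and
    estimate pi1 of the discovery pairs in the partner dataset."""
    threshold = thresholds.for_regime(cfg.regime)
    gwas_index = summary.table.sort_values(["p", "pos", "id"]).iloc[0]["id"]
    W = _scan_design(resid, covariates)
    rows = []
    for r in records:
        if r.degree != 1:
            continue
        res = coloc_mod.ld_overlap(r.variant_id, str(gwas_index),
                                   scan_set, scan_set,
                                   r2_threshold=cfg.ld_r2_threshold)
        if res.overlap:
            frow = resid.features.loc[r.feature_id]
            window = discovery.define_cis_window(
                r.feature_id, frow, scan_set.variants, flank=cfg.flank)
            sub = scan_set.subset_variants(
                scan_set.variants["id"].isin(window.variant_ids).to_numpy())
            y = resid.values.loc[r.feature_id].to_numpy(float)
            res = coloc_mod.conditional_confirmation(
                res, scan_set.dosage_of(str(gwas_index)), y, W,
                kinships[window.chrom], sub, threshold)
        rows.append({"feature_id": r.feature_id,
                     "eqtl_index": res.eqtl_index,
                     "partner_index": res.partner_index,
                     "overlap": res.overlap,
                     "conditional_p": res.conditional_p,
                     "verdict": res.verdict})
    # pi1: replication p of each discovery index variant in the partner data
    lookup = summary.table.set_index("id")["p"]
    rep_rows = [{"feature_id": r.feature_id, "variant_id": r.variant_id,
                 "p": float(lookup.loc[r.variant_id])}
                for r in records if r.variant_id in lookup.index]
    pairs = [(r.feature_id, r.variant_id) for r in records]
    pi1 = coloc_mod.pi1_sharing(pairs, pd.DataFrame(rep_rows),
                                seed=cfg.seed + SEED_BOOT)
    return pd.DataFrame(rows), pi1
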